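"""Shannon-Wiener diversity and descriptive statistics for trait panels.

For qualitative traits the Shannon-Wiener index H' = -sum(Pi ln Pi) is taken
over the relative frequencies of observed level codes. For quantitative
traits, values are first binned into 10 grades centered on the sample mean X
with half-standard-deviation steps: grade 1 below X - 2*delta, grades 2-9 in
successive 0.5*delta intervals, grade 10 at or above X + 2*delta; H' is then
computed on the grade frequencies. Descriptive statistics use the sample
(n-1) standard deviation and report the coefficient of variation CV =
100*sd/mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trait_model import TraitMatrix


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class FrequencyTable:
    """Relative frequencies Pi of a trait's categories (levels or grades)."""

    trait: str
    categories: list
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.categories) != len(self.frequencies):
            raise ValueError("categories and frequencies differ in length")
        if (self.frequencies < 0).any():
            raise ValueError("negative frequency")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"frequencies of {self.trait!r} sum to "
                f"{self.frequencies.sum()!r}, not 1")


@dataclass
class GradeScheme:
    """10-grade binning scheme: cut points X + k*0.5*delta for k = -4..4."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(
                "grade scheme needs sd > 0; constant traits carry no "
                "diversity information and should be dropped from H'")

    @property
    def boundaries(self) -> np.ndarray:
        """The 9 strictly increasing cut points from X-2d to X+2d."""
        return self.mean + 0.5 * self.sd * np.arange(-4, 5)


@dataclass
class TraitSummary:
    """Descriptive statistics of one quantitative trait."""

    trait: str
    mean: float
    sd: float
    min: float
    max: float
    range: float
    cv: float  # percent; NaN when the mean is zero
    h_prime: float | None = None


def category_frequencies(matrix: TraitMatrix, trait: str) -> FrequencyTable:
    """Relative frequencies of observed level codes of a qualitative trait.

    Proportions are of the non-missing count; all values missing is an error.
    """
    descriptor = matrix.descriptor(trait)
    if not descriptor.is_qualitative:
        raise ValueError(f"{trait!r} is quantitative; use quantitative_shannon")
    values = matrix.values(trait)
    if not values:
        raise ValueError(f"{trait!r}: all values missing")
    codes, counts = np.unique(np.asarray(values, dtype=int), return_counts=True)
    return FrequencyTable(trait, list(codes), counts / counts.sum())


def shannon_index(freqs) -> float:
    """Shannon-Wiener index H' = -sum(Pi ln Pi), natural log.

    ``freqs`` is a :class:`FrequencyTable` or a sequence of proportions.
    Zero frequencies contribute 0 (the p ln p -> 0 limit).
    """
    p = np.asarray(
        freqs.frequencies if isinstance(freqs, FrequencyTable) else freqs,
        dtype=float)
    if (p < 0).any():
        raise ValueError("negative frequency")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def grade_quantitative(values, scheme: GradeScheme | None = None) -> np.ndarray:
    """Assign each value a grade 1-10 under ``scheme``.

    Intervals are closed on the left and open on the right, so X itself falls
    in grade 6 and X + 2*delta in grade 10; every real value gets exactly one
    grade. When ``scheme`` is None it is built from the sample mean and
    sample sd of ``values``.
    """
    values = np.asarray(values, dtype=float)
    if scheme is None:
        sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        scheme = GradeScheme(float(np.mean(values)), sd)
    return np.searchsorted(scheme.boundaries, values, side="right") + 1


def quantitative_shannon(values) -> float:
    """H' of a quantitative trait after 10-grade binning on its own mean/sd."""
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("need >=2 distinct values to grade a trait")
    grades = grade_quantitative(values)
    _, counts = np.unique(grades, return_counts=True)
    return shannon_index(counts / counts.sum())


def describe(values, trait: str = "") -> TraitSummary:
    """Mean, sample sd, min, max, range and CV% of a numeric vector."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >=2 values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else math.nan
    return TraitSummary(trait, mean, sd, float(values.min()),
                        float(values.max()),
                        float(values.max() - values.min()), cv)


def qualitative_diversity_table(matrix: TraitMatrix) -> pd.DataFrame:
    """Per-trait level frequencies (long format) with H' per trait."""
    rows = []
    for trait in matrix.qualitative_traits():
        ft = category_frequencies(matrix, trait)
        h = shannon_index(ft)
        for code, p in zip(ft.categories, ft.frequencies):
            rows.append({"trait": trait, "level": int(code),
                         "frequency": float(p), "h_prime": h})
    return pd.DataFrame(rows)


def quantitative_summary_table(matrix: TraitMatrix) -> pd.DataFrame:
    """Per-trait descriptive statistics plus 10-grade H' (wide format)."""
    rows = []
    for trait in matrix.quantitative_traits():
        values = matrix.values(trait)
        s = describe(values, trait)
        try:
            s.h_prime = quantitative_shannon(values)
        except ValueError:
            s.h_prime = math.nan
        rows.append({"trait": trait, "mean": s.mean, "sd": s.sd,
                     "min": s.min, "max": s.max, "range": s.range,
                     "cv": s.cv, "h_prime": s.h_prime})
    return pd.DataFrame(rows).set_index("trait")
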