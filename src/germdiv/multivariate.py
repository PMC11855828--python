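"""Correlation screening, clustering, and PCA-based comprehensive evaluation.

The comprehensive evaluation of a germplasm panel proceeds as:

1. standardize the quantitative trait matrix (min-max "range" scaling or
   z-scoring);
2. check factorability of the trait correlation matrix with the
   Kaiser-Meyer-Olkin measure of sampling adequacy and Bartlett's sphericity
   test;
3. eigendecompose the Pearson correlation matrix, retain components with
   eigenvalue >= 1;
4. project each accession onto the retained unit eigenvectors to obtain
   component scores Y_k;
5. combine them into a composite score Z = sum_k w_k Y_k with weights w_k
   proportional to each component's variance contribution (normalized to sum
   to 1), and rank accessions by descending Z.

Hierarchical clustering (Ward linkage on Euclidean distance of the
standardized matrix) groups accessions, and group profiles flag each group's
trait means as higher/lower than the panel mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .trait_model import TraitMatrix

logger = logging.getLogger(__name__)


def _as_frame(matrix, traits=None) -> pd.DataFrame:
    df = matrix.to_dataframe() if isinstance(matrix, TraitMatrix) else pd.DataFrame(matrix)
    if traits is not None:
        df = df[list(traits)]
    return df.astype(float)


# ---------------------------------------------------------------------------
# Correlation screening
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    traits: list[str]
    r: pd.DataFrame          # Pearson coefficients, pairwise complete
    r2: pd.DataFrame         # elementwise squares
    p: pd.DataFrame          # two-sided p-values (t transform, n-2 df)
    n_pairs: pd.DataFrame    # pairwise-complete observation counts
    constant_traits: list[str]


def correlation_matrix(matrix, traits=None) -> CorrelationResult:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Constant traits yield undefined (NaN) correlations and are reported in
    ``constant_traits`` rather than raising.
    """
    df = _as_frame(matrix, traits)
    constant = [c for c in df.columns if df[c].nunique(dropna=True) <= 1]
    if constant:
        logger.warning("constant trait(s) %s: correlations undefined", constant)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = df.corr(method="pearson", min_periods=3)
    notna = df.notna().astype(int)
    n = pd.DataFrame(notna.T.values @ notna.values,
                     index=df.columns, columns=df.columns)
    # two-sided p from t = r sqrt((n-2)/(1-r^2))
    rv = r.values.copy()
    nv = n.values.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((nv - 2) / np.clip(1.0 - rv**2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), np.clip(nv - 2, 1, None))
    p[np.isclose(np.abs(rv), 1.0)] = 0.0
    np.fill_diagonal(p, 0.0)
    p = pd.DataFrame(p, index=df.columns, columns=df.columns)
    return CorrelationResult(list(df.columns), r, r**2, p, n, constant)


def benjamini_hochberg(p: pd.DataFrame) -> pd.DataFrame:
    """BH-adjusted q-values for the upper triangle of a p-value matrix."""
    cols = p.columns
    iu = np.triu_indices(len(cols), k=1)
    raw = p.values[iu]
    order = np.argsort(raw)
    m = len(raw)
    q = np.empty(m)
    q[order] = np.minimum.accumulate(
        (raw[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.zeros_like(p.values)
    out[iu] = np.clip(q, 0, 1)
    out = out + out.T
    return pd.DataFrame(out, index=cols, columns=cols)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def range_standardize(matrix, traits=None) -> pd.DataFrame:
    """Min-max ("range method") scaling: x' = (x - min)/(max - min), in [0,1]."""
    df = _as_frame(matrix, traits)
    rng = df.max() - df.min()
    bad = list(rng.index[rng == 0])
    if bad:
        raise ValueError(f"constant trait(s) cannot be range-scaled: {bad}")
    return (df - df.min()) / rng


def zscore_standardize(matrix, traits=None) -> pd.DataFrame:
    """Column-wise z-scoring to sample mean 0 and sample sd 1."""
    df = _as_frame(matrix, traits)
    sd = df.std(ddof=1)
    bad = list(sd.index[sd == 0])
    if bad:
        raise ValueError(f"constant trait(s) cannot be z-scored: {bad}")
    return (df - df.mean()) / sd


# ---------------------------------------------------------------------------
# Factorability statistics
# ---------------------------------------------------------------------------

def _as_corr(r) -> np.ndarray:
    r = r.r.values if isinstance(r, CorrelationResult) else np.asarray(r, float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    return r


def kmo_statistic(r) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q_ij are
    the anti-image partial correlations obtained from the inverse of r.
    Values near 1 indicate the correlation structure is suitable for
    factor/principal-component analysis; ~0.5 indicates no shared variance.
    """
    r = _as_corr(r)
    eigvals = np.linalg.eigvalsh(r)
    if eigvals.min() <= 1e-12:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; KMO undefined (consider a small "
            "ridge, e.g. r + 1e-8*I, if near-singularity is numerical)")
    inv = np.linalg.inv(r)
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(len(r), dtype=bool)
    r2 = (r[off] ** 2).sum()
    q2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + q2))


@dataclass
class BartlettResult:
    chi2: float
    df: int
    pvalue: float


def bartlett_sphericity(r, n: int) -> BartlettResult:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) ln|r| on p(p-1)/2 degrees of freedom, where
    n is the number of observations behind r.
    """
    r = _as_corr(r)
    p = r.shape[0]
    if n <= p:
        raise ValueError(f"need n > p observations (n={n}, p={p})")
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise np.linalg.LinAlgError("correlation matrix determinant <= 0")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return BartlettResult(float(chi2), int(df), float(stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# PCA on the correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Eigendecomposition of the trait Pearson correlation matrix.

    ``eigenvectors`` columns are unit loadings; signs are fixed so each
    column's largest-magnitude entry is positive. ``contribution`` is
    100*lambda_k/p; ``retained`` the indices with eigenvalue >= threshold.
    """

    traits: list[str]
    eigenvalues: np.ndarray
    eigenvectors: pd.DataFrame
    contribution: np.ndarray
    cumulative: np.ndarray
    retained: list[int]

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def pca_correlation(standardized: pd.DataFrame,
                    threshold: float = 1.0) -> PCAResult:
    """Principal components of the Pearson correlation matrix of the columns.

    Works identically on range-scaled or z-scored input since Pearson
    correlation is affine-invariant per column.
    """
    df = _as_frame(standardized)
    if not np.isfinite(df.values).all():
        raise ValueError("non-finite values in standardized matrix")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need >=2 accessions and >=2 traits")
    corr = np.corrcoef(df.values, rowvar=False)
    eigenvalues, vectors = np.linalg.eigh(corr)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    vectors = vectors[:, order]
    # deterministic sign: largest-|entry| positive per component
    for k in range(vectors.shape[1]):
        j = np.argmax(np.abs(vectors[:, k]))
        if vectors[j, k] < 0:
            vectors[:, k] = -vectors[:, k]
    p = df.shape[1]
    contribution = 100.0 * eigenvalues / p
    loadings = pd.DataFrame(
        vectors, index=list(df.columns),
        columns=[f"PC{k}" for k in range(1, p + 1)])
    result = PCAResult(list(df.columns), eigenvalues, loadings,
                       contribution, np.cumsum(contribution), [])
    result.retained = select_components(result, threshold)
    return result


def select_components(pca: PCAResult, threshold: float = 1.0) -> list[int]:
    """Indices of components with eigenvalue >= threshold (at least one)."""
    retained = [k for k, lam in enumerate(pca.eigenvalues) if lam >= threshold]
    if not retained:
        logger.warning("no eigenvalue >= %.3g; retaining the first component",
                       threshold)
        retained = [0]
    return retained


def component_scores(standardized: pd.DataFrame, pca: PCAResult,
                     components: list[int] | None = None) -> pd.DataFrame:
    """Project accessions onto retained unit eigenvectors: Y_k per accession."""
    df = _as_frame(standardized)
    if list(df.columns) != pca.traits:
        raise ValueError("standardized matrix columns do not match PCA traits")
    components = pca.retained if components is None else components
    vectors = pca.eigenvectors.values[:, components]
    scores = df.values @ vectors
    return pd.DataFrame(scores, index=df.index,
                        columns=[f"Y{k + 1}" for k in components])


# ---------------------------------------------------------------------------
# Composite scoring and ranking
# ---------------------------------------------------------------------------

def composite_score(y: pd.DataFrame, contributions) -> pd.DataFrame:
    """Composite score Z = sum_k w_k Y_k with normalized contribution weights.

    ``contributions`` holds one positive variance contribution per component
    column of ``y`` (percent or fraction; only ratios matter, so Z is
    invariant to rescaling all contributions by a constant). Rank 1 is the
    largest Z; ties are broken by ascending accession id.
    """
    contributions = np.asarray(contributions, dtype=float)
    if contributions.ndim != 1 or len(contributions) != y.shape[1]:
        raise ValueError(
            f"{len(contributions)} contribution(s) for {y.shape[1]} component(s)")
    if (contributions <= 0).any():
        raise ValueError("contributions must be positive")
    w = contributions / contributions.sum()
    out = y.copy()
    out["z"] = y.values @ w
    out["rank"] = _rank_desc(out["z"], out.index)
    return out


def _rank_desc(z: pd.Series, ids) -> np.ndarray:
    order = sorted(range(len(z)), key=lambda i: (-z.iloc[i], str(ids[i])))
    ranks = np.empty(len(z), dtype=int)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks


def rank_accessions(scores: pd.DataFrame) -> pd.DataFrame:
    """Return the score table sorted by rank (recomputed from z)."""
    out = scores.copy()
    out["rank"] = _rank_desc(out["z"], out.index)
    return out.sort_values("rank")


# ---------------------------------------------------------------------------
# Clustering and group profiling
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    groups: pd.Series        # accession id -> group 1..k
    linkage: np.ndarray      # scipy merge history with heights
    k: int


def cluster_accessions(standardized: pd.DataFrame, k: int,
                       method: str = "ward",
                       metric: str = "euclidean") -> ClusterAssignment:
    """Agglomerative clustering of accessions cut at ``k`` groups.

    Ward linkage on Euclidean distance of the standardized traits by
    default; deterministic given input order. Groups are renumbered 1..k in
    order of first appearance.
    """
    df = _as_frame(standardized)
    n = df.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    link = hierarchy.linkage(df.values, method=method, metric=metric)
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    groups = pd.Series([remap[lab] for lab in labels], index=df.index,
                       name="group")
    return ClusterAssignment(groups, link, k)


def profile_groups(matrix, assignment: ClusterAssignment,
                   traits=None) -> pd.DataFrame:
    """Group trait means with higher/lower flags vs the overall mean.

    Long format: one row per (group, trait) with the group mean, overall
    mean, and a direction flag ('higher', 'lower', 'neutral'). Flags are
    invariant to affine rescaling of a trait.
    """
    df = _as_frame(matrix, traits)
    overall = df.mean()
    rows = []
    for group, members in assignment.groups.groupby(assignment.groups):
        sub = df.loc[members.index]
        means = sub.mean()
        for trait in df.columns:
            diff = means[trait] - overall[trait]
            flag = "neutral" if diff == 0 else ("higher" if diff > 0 else "lower")
            rows.append({"group": int(group), "n": len(sub), "trait": trait,
                         "group_mean": float(means[trait]),
                         "overall_mean": float(overall[trait]),
                         "direction": flag})
    return pd.DataFrame(rows)
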