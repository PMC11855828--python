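"""Trait data model for germplasm evaluation.

An evaluation panel is a :class:`TraitMatrix`: accessions (rows) scored for a
set of traits (columns). Each trait is described by a :class:`TraitDescriptor`
that is either *qualitative* (discrete, coded levels such as ``1 = vine type``)
or *quantitative* (numeric measurement with units). Qualitative values are
stored as integer level codes; quantitative values as floats; missing values
as ``None`` (serialized as the ``NA`` sentinel).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class TraitDescriptor:
    """Metadata for a single trait.

    Parameters
    ----------
    name
        Trait identifier, matched exactly (after whitespace trimming) against
        table headers.
    kind
        ``"qualitative"`` or ``"quantitative"``.
    levels
        For qualitative traits, an ordered mapping of integer level code to
        label (e.g. ``{1: "vine type", 2: "half-vine type", 3: "upright"}``).
    units
        For quantitative traits, free-text units (e.g. ``"cm"``).
    """

    name: str
    kind: str
    levels: dict[int, str] | None = None
    units: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("qualitative", "quantitative"):
            raise ValueError(f"unknown trait kind {self.kind!r} for {self.name!r}")
        if self.kind == "qualitative":
            if not self.levels or len(self.levels) < 2:
                raise ValueError(
                    f"qualitative trait {self.name!r} needs >=2 level codes")
            if any((not isinstance(c, int)) or c < 0 for c in self.levels):
                raise ValueError(
                    f"level codes of {self.name!r} must be non-negative integers")
        elif self.levels:
            raise ValueError(f"quantitative trait {self.name!r} must not have levels")

    @property
    def is_qualitative(self) -> bool:
        return self.kind == "qualitative"


@dataclass
class AccessionRecord:
    """Values of one accession: trait name -> level code, measurement or None."""

    accession_id: str
    values: dict[str, float | int | None] = field(default_factory=dict)


@dataclass
class TraitMatrix:
    """A validated accessions x traits table."""

    descriptors: list[TraitDescriptor]
    records: list[AccessionRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("TraitMatrix needs at least one record")
        ids = [r.accession_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate accession ids: {dup}")
        by_name = {d.name: d for d in self.descriptors}
        for rec in self.records:
            for trait, value in rec.values.items():
                if trait not in by_name:
                    raise KeyError(
                        f"accession {rec.accession_id!r} has value for unknown "
                        f"trait {trait!r}")
                if value is None:
                    continue
                d = by_name[trait]
                if d.is_qualitative and value not in d.levels:
                    raise ValueError(
                        f"accession {rec.accession_id!r}, trait {trait!r}: "
                        f"code {value!r} not in {sorted(d.levels)}")

    def descriptor(self, name: str) -> TraitDescriptor:
        for d in self.descriptors:
            if d.name == name:
                return d
        raise KeyError(f"no descriptor for trait {name!r}")

    @property
    def trait_names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    @property
    def accession_ids(self) -> list[str]:
        return [r.accession_id for r in self.records]

    def qualitative_traits(self) -> list[str]:
        return [d.name for d in self.descriptors if d.is_qualitative]

    def quantitative_traits(self) -> list[str]:
        return [d.name for d in self.descriptors if not d.is_qualitative]

    def values(self, trait: str, drop_missing: bool = True) -> list:
        """Column of values for ``trait``; missing dropped by default."""
        self.descriptor(trait)
        col = [r.values.get(trait) for r in self.records]
        if drop_missing:
            col = [v for v in col if v is not None]
        return col

    def to_dataframe(self) -> pd.DataFrame:
        """Accession x trait DataFrame (index = accession id, NaN = missing)."""
        data = {
            r.accession_id: [
                math.nan if r.values.get(t) is None else r.values.get(t)
                for t in self.trait_names
            ]
            for r in self.records
        }
        return pd.DataFrame.from_dict(
            data, orient="index", columns=self.trait_names)


def encode_qualitative(label: str, descriptor: TraitDescriptor) -> int:
    """Return the level code whose label matches ``label``.

    Matching is case-insensitive after trimming surrounding whitespace.
    """
    if not descriptor.is_qualitative:
        raise ValueError(f"{descriptor.name!r} is not qualitative")
    needle = label.strip().lower()
    for code, lab in descriptor.levels.items():
        if lab.strip().lower() == needle:
            return code
    valid = ", ".join(f"{c}={lab}" for c, lab in descriptor.levels.items())
    raise ValueError(
        f"label {label!r} not a level of {descriptor.name!r}; valid: {valid}")


def _parse_cell(text: str, descriptor: TraitDescriptor):
    """Parse one cell; returns (value, ok). Empty/NA -> (None, True)."""
    text = text.strip()
    if text == "" or text.upper() == MISSING_TOKEN:
        return None, True
    if descriptor.is_qualitative:
        try:
            code = int(text)
        except ValueError:
            return None, False
        if code not in descriptor.levels:
            return None, False
        return code, True
    try:
        return float(text), True
    except ValueError:
        return None, False


def _detect_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def load_trait_table(path: str | Path,
                     coding: list[TraitDescriptor],
                     provenance: str | None = None) -> TraitMatrix:
    """Read a delimited accession x trait table against a coding dictionary.

    The first row holds trait names (first column = accession id); the
    delimiter (tab or comma) is auto-detected from the header line.
    Unparseable cells become missing, with a logged warning count. An unknown
    trait column or a duplicate accession id is an error.
    """
    path = Path(path)
    by_name = {d.name: d for d in coding}
    with path.open(encoding="utf-8") as fh:
        header_line = fh.readline()
        sep = _detect_sep(header_line)
        header = [h.strip() for h in header_line.rstrip("\n").split(sep)]
        traits = header[1:]
        unknown = [t for t in traits if t not in by_name]
        if unknown:
            raise KeyError(
                f"{path.name}: column(s) {unknown} not in coding dictionary")
        records: list[AccessionRecord] = []
        bad_cells = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(sep)
            acc = cells[0].strip()
            values: dict[str, float | int | None] = {}
            for trait, cell in zip(traits, cells[1:]):
                value, ok = _parse_cell(cell, by_name[trait])
                if not ok:
                    bad_cells += 1
                    logger.warning(
                        "%s line %d: cannot parse %r for trait %r "
                        "(accession %r); treated as missing",
                        path.name, lineno, cell.strip(), trait, acc)
                values[trait] = value
            records.append(AccessionRecord(acc, values))
    if bad_cells:
        logger.warning("%s: %d unparseable cell(s) set to missing",
                       path.name, bad_cells)
    descriptors = [by_name[t] for t in traits]
    return TraitMatrix(descriptors, records,
                       provenance=provenance or str(path))


def save_trait_table(matrix: TraitMatrix, path: str | Path,
                     sep: str = "\t") -> None:
    """Write a TraitMatrix as delimited text (``NA`` for missing)."""
    path = Path(path)
    traits = matrix.trait_names
    with path.open("w", encoding="utf-8") as fh:
        fh.write(sep.join(["accession_id"] + traits) + "\n")
        for rec in matrix.records:
            cells = [rec.accession_id]
            for t in traits:
                v = rec.values.get(t)
                if v is None:
                    cells.append(MISSING_TOKEN)
                elif matrix.descriptor(t).is_qualitative:
                    cells.append(str(int(v)))
                else:
                    cells.append(repr(float(v)))
            fh.write(sep.join(cells) + "\n")


def load_coding(path: str | Path) -> list[TraitDescriptor]:
    """Read a coding dictionary file (one descriptor block per trait).

    Format::

        [plant type]
        kind: qualitative
        1: vine type
        2: half-vine type
        3: upright

        [plant height]
        kind: quantitative
        units: cm
    """
    descriptors: list[TraitDescriptor] = []
    name = None
    fields: dict[str, str] = {}
    levels: dict[int, str] = {}

    def _flush():
        if name is None:
            return
        kind = fields.get("kind", "qualitative" if levels else "quantitative")
        if kind == "qualitative":
            descriptors.append(TraitDescriptor(name, kind, levels=dict(levels)))
        else:
            descriptors.append(
                TraitDescriptor(name, kind, units=fields.get("units")))

    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            _flush()
            name = line[1:-1].strip()
            fields, levels = {}, {}
            continue
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key.lstrip("-").isdigit():
            levels[int(key)] = value
        else:
            fields[key] = value
    _flush()
    return descriptors


def save_coding(descriptors: list[TraitDescriptor], path: str | Path) -> None:
    """Write a coding dictionary file readable by :func:`load_coding`."""
    lines: list[str] = []
    for d in descriptors:
        lines.append(f"[{d.name}]")
        lines.append(f"kind: {d.kind}")
        if d.is_qualitative:
            for code, label in d.levels.items():
                lines.append(f"{code}: {label}")
        elif d.units:
            lines.append(f"units: {d.units}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
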