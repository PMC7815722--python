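"""Data model and I/O for intensity matrices, sample sheets and assay tables.

The discovery arm consumes a protein-by-sample label-free quantification
(LFQ) table in the tab-separated ``proteinGroups`` dialect of MaxQuant:
intensity columns share a common prefix, decoy/contaminant rows are marked
with ``+`` in dedicated flag columns, and an LFQ value of 0 (or an empty
cell) means the protein was not quantified in that sample.

The validation arm consumes immunoassay (ELISA) concentration tables, one
row per (sample, analyte) with three replicate wells in ng/ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "GROUPS",
    "TUMOR_GROUPS",
    "SUBTYPE_PARENT",
    "IntensityMatrix",
    "SampleSheet",
    "AssayPanel",
    "VennPartition",
    "read_protein_matrix",
    "write_matrix",
    "read_matrix",
    "read_sample_sheet",
    "read_assay_table",
    "venn_partition",
    "round_half_up",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Structurally valid input violates a semantic constraint."""


#: Clinical strata. ``control`` covers hydrocephalus controls; the
#: validation cohort adds a post-haemorrhagic non-tumor stratum.
GROUPS = ("control", "post_hemorrhagic", "LGG_GT", "EMB", "other_tumor")
TUMOR_GROUPS = ("LGG_GT", "EMB", "other_tumor")
#: Histological subtypes are nested inside one parent group each:
#: pilocytic astrocytoma under low-grade glioma + glioneuronal tumors,
#: medulloblastoma under embryonal tumors.
SUBTYPE_PARENT = {"PA": "LGG_GT", "MB": "EMB"}

FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, matching printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Intensity matrix
# ---------------------------------------------------------------------------


@dataclass
class IntensityMatrix:
    """Proteins x samples abundance table.

    ``values`` is a DataFrame indexed by protein accession with one column
    per sample; missing cells are ``NaN``.  ``is_log2`` records whether the
    values are on the log2 scale (raw LFQ intensities are strictly
    positive).  ``protein_meta`` keeps the full semicolon-separated
    accession group for each canonical (first) accession.
    """

    values: pd.DataFrame
    is_log2: bool = False
    protein_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate protein ids: {dupes}")
        if cols.has_duplicates:
            dupes = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dupes}")
        arr = self.values.to_numpy(dtype=float)
        if not self.is_log2 and np.any(arr[np.isfinite(arr)] <= 0):
            raise ValidationError("raw intensities must be strictly positive")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def present(self) -> pd.DataFrame:
        """Boolean mask of quantified cells."""
        return self.values.notna()

    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def copy_with(self, values: pd.DataFrame, *, is_log2: bool | None = None) -> "IntensityMatrix":
        meta = None
        if self.protein_meta is not None:
            meta = self.protein_meta.reindex(values.index)
        return IntensityMatrix(
            values=values,
            is_log2=self.is_log2 if is_log2 is None else is_log2,
            protein_meta=meta,
        )


def read_protein_matrix(
    path: str | Path,
    intensity_prefix: str = "LFQ intensity ",
    drop_flagged: bool = True,
    id_column: str = "Protein IDs",
) -> IntensityMatrix:
    """Read a MaxQuant-style ``proteinGroups`` table.

    Sample columns are those whose header starts with ``intensity_prefix``
    (the prefix is stripped to obtain the sample id).  Zeros and empty
    cells become missing.  With ``drop_flagged`` the decoy ("Reverse"),
    contaminant and only-identified-by-site rows are removed.  The first
    accession of a semicolon-separated protein group is used as the
    canonical id; the full group string is kept in ``protein_meta``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if id_column not in df.columns:
        raise FormatError(f"missing required column {id_column!r} in {path.name}")
    sample_cols = [c for c in df.columns if c.startswith(intensity_prefix)]
    if not sample_cols:
        raise FormatError(
            f"no columns with intensity prefix {intensity_prefix!r} in {path.name}"
        )
    if drop_flagged:
        keep = pd.Series(True, index=df.index)
        for col in FLAG_COLUMNS:
            if col in df.columns:
                keep &= df[col].fillna("") != "+"
        df = df.loc[keep]

    full_ids = df[id_column].astype(str)
    canonical = full_ids.str.split(";").str[0]
    if canonical.duplicated().any():
        dupes = sorted(canonical[canonical.duplicated()].unique())
        raise ValidationError(f"duplicate protein ids after collapsing groups: {dupes}")

    values = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    values.columns = [c[len(intensity_prefix):] for c in sample_cols]
    values.index = pd.Index(canonical, name="protein_id")
    # MaxQuant writes 0 for unquantified LFQ cells
    values = values.where(values > 0)

    meta = pd.DataFrame({"accession_group": full_ids.values}, index=values.index)
    return IntensityMatrix(values=values, is_log2=False, protein_meta=meta)


def write_matrix(m: IntensityMatrix, path: str | Path) -> None:
    """Write a matrix as TSV (missing cells left empty)."""
    out = m.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path: str | Path, is_log2: bool = False) -> IntensityMatrix:
    """Read a matrix previously written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col="protein_id",
                     float_precision="round_trip")
    return IntensityMatrix(values=df, is_log2=is_log2)


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Assignment of samples to clinical groups (and optional subtype).

    Wraps a DataFrame with columns ``sample_id``, ``group`` and optionally
    ``subtype`` and ``assay``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample_id", "group"):
            if col not in t.columns:
                raise FormatError(f"sample sheet missing required column {col!r}")
        if len(t) == 0:
            raise ValidationError("sample sheet is empty")
        if t["sample_id"].duplicated().any():
            dupes = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"].unique())
            raise ValidationError(f"duplicate sample ids: {dupes}")
        bad = sorted(set(t["group"]) - set(GROUPS))
        if bad:
            raise ValidationError(f"unknown group labels: {bad} (allowed: {list(GROUPS)})")
        if "subtype" in t.columns:
            sub = t["subtype"].fillna("none")
            for st, parent in SUBTYPE_PARENT.items():
                wrong = t.loc[(sub == st) & (t["group"] != parent), "sample_id"]
                if len(wrong):
                    raise ValidationError(
                        f"subtype {st} only allowed under group {parent}; "
                        f"violated by samples {sorted(wrong)}"
                    )
            extra = sorted(set(sub) - set(SUBTYPE_PARENT) - {"none"})
            if extra:
                raise ValidationError(f"unknown subtypes: {extra}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> list[str]:
        """Distinct groups in canonical order."""
        present = set(self.table["group"])
        return [g for g in GROUPS if g in present]

    def group_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]

    def samples_in(self, group: str | Iterable[str]) -> list[str]:
        wanted = {group} if isinstance(group, str) else set(group)
        t = self.table
        return list(t.loc[t["group"].isin(wanted), "sample_id"])

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        t = self.table
        return SampleSheet(t[t["sample_id"].isin(set(sample_ids))].copy())

    def check_covers(self, m: IntensityMatrix) -> None:
        missing = sorted(set(m.sample_ids) - set(self.sample_ids))
        if missing:
            raise ValidationError(f"samples in matrix but not in sheet: {missing}")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a CSV/TSV sample sheet with columns sample_id, group[, subtype]."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"sample sheet {path.name} is empty") from exc
    return SampleSheet(df)


# ---------------------------------------------------------------------------
# Assay panel (ELISA)
# ---------------------------------------------------------------------------


@dataclass
class AssayPanel:
    """Triplicate immunoassay concentrations (ng/ml) for one analyte.

    ``concentrations`` is indexed by sample_id with columns rep1..rep3.
    The per-sample reported value is the mean of the triplicate.  Values
    whose mean falls below the assay's lower limit of quantification
    (LLOQ) are flagged and, for downstream statistics, substituted by
    LLOQ/2.
    """

    analyte: str
    concentrations: pd.DataFrame
    lloq: float = 0.0

    def __post_init__(self) -> None:
        cols = list(self.concentrations.columns)
        if cols != ["rep1", "rep2", "rep3"]:
            raise ValidationError(
                f"{self.analyte}: expected exactly columns rep1..rep3, got {cols}"
            )
        if self.lloq < 0:
            raise ValidationError(f"{self.analyte}: negative LLOQ")
        arr = self.concentrations.to_numpy(dtype=float)
        if np.isnan(arr).any() or (arr < 0).any():
            raise ValidationError(f"{self.analyte}: concentrations must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.concentrations.index)

    def sample_values(self, lloq_substitute: bool = True) -> pd.Series:
        """Per-sample value = triplicate mean; below-LLOQ set to LLOQ/2."""
        v = self.concentrations.mean(axis=1)
        if lloq_substitute and self.lloq > 0:
            v = v.where(v >= self.lloq, self.lloq / 2.0)
        return v.rename(self.analyte)

    def below_lloq(self) -> pd.Series:
        return (self.concentrations.mean(axis=1) < self.lloq).rename(self.analyte)


def read_assay_table(
    path: str | Path, lloq: Mapping[str, float] | None = None
) -> dict[str, AssayPanel]:
    """Read a long-format assay CSV: sample_id, analyte, rep1, rep2, rep3.

    An optional ``lloq`` column in the file (constant per analyte) or the
    ``lloq`` mapping argument supplies limits of quantification.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "analyte", "rep1", "rep2", "rep3"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"assay table missing columns {sorted(missing)}")
    panels: dict[str, AssayPanel] = {}
    for analyte, sub in df.groupby("analyte", sort=True):
        if sub["sample_id"].duplicated().any():
            raise ValidationError(f"{analyte}: duplicated sample rows")
        conc = sub.set_index("sample_id")[["rep1", "rep2", "rep3"]].astype(float)
        if lloq is not None and analyte in lloq:
            limit = float(lloq[analyte])
        elif "lloq" in sub.columns:
            limit = float(sub["lloq"].iloc[0])
        else:
            limit = 0.0
        panels[str(analyte)] = AssayPanel(str(analyte), conc, lloq=limit)
    return panels


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------


@dataclass
class VennPartition:
    """Counts of proteins per Venn region over two or more presence sets."""

    region_counts: dict[str, int]
    total: int
    #: optional denominator for percentages when regions are reported
    #: against a larger reference set (e.g. all identified proteins)
    reference_total: int | None = None

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValidationError("empty union")
        if sum(self.region_counts.values()) != self.total:
            raise ValidationError("region counts do not sum to total")

    def percentages(self, denominator: int | None = None) -> dict[str, float]:
        """Region percentages at one decimal, ties rounded half-up."""
        denom = denominator or self.reference_total or self.total
        return {
            k: round_half_up(100.0 * v / denom, 1) for k, v in self.region_counts.items()
        }


def _region_label(groups: frozenset[str], all_groups: Sequence[str]) -> str:
    if len(groups) == len(all_groups):
        return "shared"
    if len(groups) == 1:
        return f"{next(iter(groups))}_only"
    return "&".join(g for g in all_groups if g in groups)


def venn_partition(
    presence: Mapping[str, set[str]], reference_total: int | None = None
) -> VennPartition:
    """Partition the union of presence sets into exclusive Venn regions.

    ``presence`` maps a group label to the set of protein ids detected in
    that group.  Every protein in the union is assigned to exactly one
    region (the subset of groups it appears in); empty regions are
    reported with count 0.
    """
    if len(presence) < 2:
        raise ValidationError("need at least 2 groups for a Venn partition")
    group_names = list(presence)
    union: set[str] = set().union(*presence.values())
    if not union:
        raise ValidationError("empty union")
    counts: dict[frozenset[str], int] = {}
    for pid in union:
        key = frozenset(g for g in group_names if pid in presence[g])
        counts[key] = counts.get(key, 0) + 1
    # enumerate all non-empty subsets so absent regions are reported as 0
    from itertools import combinations

    region_counts: dict[str, int] = {}
    for r in range(1, len(group_names) + 1):
        for combo in combinations(group_names, r):
            key = frozenset(combo)
            region_counts[_region_label(key, group_names)] = counts.get(key, 0)
    return VennPartition(
        region_counts=region_counts, total=len(union), reference_total=reference_total
    )
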