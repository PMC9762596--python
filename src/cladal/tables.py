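"""ASV count tables, taxonomy, and sample metadata.

All three containers wrap pandas DataFrames and enforce the structural
invariants the downstream regressions rely on (integral non-negative
counts, unique identifiers, one diet/study/age per host).  Tables are
samples x features; a BIOM-style features-in-rows TSV dialect is
supported on read/write via ``features_in_rows=True``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tree import ValidationError

RANKS = ("phylum", "class", "order", "family", "genus")
UNKNOWN = "unknown"

AGE_LEVELS = ("young", "old")
DIET_LEVELS = ("ZD", "ZA", "ZS")
STUDY_LEVELS = ("ZAM1", "ZAM2")
TIMEPOINTS = ("wk0", "wk6")


class AsvTable:
    """Samples x ASVs integer count matrix."""

    def __init__(self, counts: pd.DataFrame):
        counts = counts.copy()
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise ValidationError("duplicate sample or feature identifiers")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise ValidationError("counts must be non-negative integers")
        self.counts = counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @classmethod
    def read_tsv(cls, path, features_in_rows: bool = False) -> "AsvTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if features_in_rows:
            df = df.T
        return cls(df)

    def to_tsv(self, path, features_in_rows: bool = False) -> None:
        df = self.counts.T if features_in_rows else self.counts
        df.to_csv(path, sep="\t")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<AsvTable {self.shape[0]} samples x {self.shape[1]} features>"


def prevalence_filter(table: AsvTable, min_samples: int = 5) -> AsvTable:
    """Retain features with nonzero counts in at least ``min_samples`` samples.

    The default of 5 is half an experimental unit of 10 mice, the
    threshold used to arrive at the 361-ASV analysis table.
    """
    if min_samples < 1:
        raise ValidationError("min_samples must be a positive integer")
    if min_samples > table.shape[0]:
        raise ValidationError(
            f"min_samples={min_samples} exceeds the number of samples ({table.shape[0]})"
        )
    prevalence = (table.counts > 0).sum(axis=0)
    keep = prevalence[prevalence >= min_samples].index
    return AsvTable(table.counts[keep])


def rarefy(table: AsvTable, depth: int, seed: int) -> AsvTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a warning.
    Each sample's rarefied vector is a multivariate-hypergeometric draw
    from its own counts, so no feature can gain reads.  Reproducible
    for a fixed seed.
    """
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    totals = table.sample_totals()
    shallow = totals[totals < depth]
    if len(shallow):
        warnings.warn(
            f"dropping {len(shallow)} sample(s) below depth {depth}: "
            f"{list(shallow.index)[:5]}...",
            UserWarning,
            stacklevel=2,
        )
    keep = totals[totals >= depth].index
    rng = np.random.default_rng(seed)
    out = np.empty((len(keep), table.shape[1]), dtype=np.int64)
    for i, s in enumerate(keep):
        row = table.counts.loc[s].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return AsvTable(pd.DataFrame(out, index=keep, columns=table.counts.columns))


def relative_abundance(table: AsvTable) -> pd.DataFrame:
    """Per-sample proportions; rows sum to 1."""
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"zero-total sample(s): {list(zero.index)}")
    return table.counts.div(totals, axis=0)


class TaxonomyTable:
    """Per-ASV lineage at the fixed ranks phylum..genus."""

    def __init__(self, assignments: pd.DataFrame):
        missing = [r for r in RANKS if r not in assignments.columns]
        if missing:
            raise ValidationError(f"taxonomy table missing ranks: {missing}")
        if assignments.index.has_duplicates:
            raise ValidationError("duplicate ASV ids in taxonomy")
        self.assignments = assignments[list(RANKS)].fillna(UNKNOWN).astype(str)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.assignments.index)

    @classmethod
    def read_tsv(cls, path) -> "TaxonomyTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.assignments.to_csv(path, sep="\t")

    def check_covers(self, table: AsvTable) -> None:
        absent = sorted(set(table.feature_ids) - set(self.asv_ids))
        if absent:
            raise ValidationError(f"features missing from taxonomy: {absent[:10]}")


def assign_placeholder_genus(tax: TaxonomyTable) -> TaxonomyTable:
    """Give every unknown-genus ASV its own placeholder genus.

    The placeholder has the form ``<Family>_Genus_<ASVid>``, so two
    unknown-genus ASVs of the same family remain distinct genera and no
    data are discarded in genus-level comparisons.
    """
    df = tax.assignments.copy()
    mask = df["genus"] == UNKNOWN
    df.loc[mask, "genus"] = [
        f"{df.loc[a, 'family']}_Genus_{a}" for a in df.index[mask]
    ]
    return TaxonomyTable(df)


def agglomerate(table: AsvTable, tax: TaxonomyTable, rank: str) -> AsvTable:
    """Sum member-ASV counts into one feature per distinct label at ``rank``."""
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    tax.check_covers(table)
    labels = tax.assignments.loc[table.feature_ids, rank]
    grouped = table.counts.T.groupby(labels.values, sort=True).sum().T
    grouped.columns.name = rank
    return AsvTable(grouped)


class SampleMetadata:
    """Per-sample covariates for the two-study, two-age, two-timepoint design."""

    REQUIRED = ("host_id", "age", "diet", "study", "timepoint", "il6")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        df = data.copy()
        for col, levels in (("age", AGE_LEVELS), ("diet", DIET_LEVELS),
                            ("study", STUDY_LEVELS), ("timepoint", TIMEPOINTS)):
            bad = sorted(set(df[col].astype(str)) - set(levels))
            if bad:
                raise ValidationError(f"invalid {col} level(s): {bad}")
        df["il6"] = pd.to_numeric(df["il6"], errors="coerce")
        if (df["il6"].dropna() < 0).any():
            raise ValidationError("il6 must be non-negative")
        if df.duplicated(subset=["host_id", "timepoint"]).any():
            raise ValidationError("(host_id, timepoint) pairs must be unique")
        per_host = df.groupby("host_id")[["diet", "study", "age"]].nunique()
        varying = per_host[(per_host > 1).any(axis=1)]
        if len(varying):
            raise ValidationError(
                f"diet/study/age must be constant within host: {list(varying.index)[:5]}"
            )
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @classmethod
    def read_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)])

    def check_covers(self, sample_ids) -> None:
        absent = sorted(set(sample_ids) - set(self.sample_ids))
        if absent:
            raise ValidationError(f"samples missing from metadata: {absent[:10]}")
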