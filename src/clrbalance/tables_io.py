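"""Typed I/O for count tables, sample metadata and metabolite tables.

Taxon identifiers are semicolon-delimited lineage strings (Greengenes-style
``k__``/``g__`` prefixes optional).  Two naming conventions from 16S
post-processing are understood:

* a slash joins the members of an unresolved ambiguity set, e.g.
  ``Blautia/Dorea`` (optionally parenthesised: ``(Blautia/Dorea)``);
* a trailing ``_u`` marks a taxon unclassified at that rank, inheriting its
  name from the parent rank, e.g. species ``Lactobacillus_u`` under genus
  ``Lactobacillus``; markers stack (``..._u_u``) one per unresolved rank.

Tables are stored as pandas DataFrames: count tables with taxa as rows and
samples as columns (the convention of count-table ecosystems), metadata and
metabolite tables with one row per sample.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
#: the finest unit; finer than species, no lineage arithmetic of its own
ASV_RANK = "asv"

_GG_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_PREFIX_TO_RANK = dict(zip(_GG_PREFIXES, RANKS))

#: clinical score ranges (inclusive) used by metadata validation
SCORE_RANGES = {
    "gcs": (3, 15),
    "rankin": (1, 5),
    "rivermead": (0, 15),
    "nihss": (0, 42),
}

METABOLITE_PANEL = (
    "PhLA", "PhPA", "PhAA", "p-HPhAA", "p-HPhPA", "p-HPhLA",
    "BA", "p-HBA", "HVA", "SA", "FA",
)


class ValidationError(ValueError):
    """Raised when an input table violates a declared invariant."""


class LineageParseError(ValueError):
    """Raised for malformed lineage strings; names the offending token."""


def _parse_label(raw: str) -> tuple[frozenset[str], int]:
    """Split one rank label into (ambiguity name set, unclassified depth)."""
    stem = raw
    depth = 0
    while stem.endswith("_u"):
        stem = stem[:-2]
        depth += 1
    if stem.startswith("(") and stem.endswith(")"):
        stem = stem[1:-1]
    names = frozenset(n for n in stem.split("/") if n)
    if not names:
        raise LineageParseError(f"empty rank label in token {raw!r}")
    return names, depth


@dataclass(frozen=True)
class TaxonLineage:
    """Per-rank labels from kingdom down to the deepest assigned rank.

    ``labels`` holds the raw tokens exactly as read so that serialization
    round-trips byte-for-byte; ``prefixed`` records whether Greengenes rank
    prefixes were present.
    """

    labels: tuple[str, ...]
    delimiter: str = ";"
    prefixed: bool = False

    def __post_init__(self) -> None:
        if not self.labels:
            raise LineageParseError("empty lineage")
        if len(self.labels) > len(RANKS):
            raise LineageParseError(
                f"lineage deeper than species: {self.labels[len(RANKS):]!r}"
            )
        for tok in self.labels:
            if not tok:
                raise LineageParseError(
                    f"empty rank between non-empty ranks in {self.labels!r}"
                )
            _parse_label(tok)  # validates

    @property
    def depth(self) -> int:
        return len(self.labels)

    @property
    def deepest_rank(self) -> str:
        return RANKS[self.depth - 1]

    def label_at(self, rank: str) -> str:
        i = RANKS.index(rank)
        if i >= self.depth:
            raise KeyError(f"lineage has no {rank} label: {self.serialize()!r}")
        return self.labels[i]

    def key_at(self, rank: str) -> tuple:
        """Order-insensitive grouping key for the path down to ``rank``.

        Ambiguity sets compare as sets, so ``A/B`` and ``B/A`` aggregate
        together; the unclassified depth is part of the key.
        """
        i = RANKS.index(rank)
        return tuple(_parse_label(t) for t in self.labels[: i + 1])

    def truncate(self, rank: str) -> "TaxonLineage":
        i = RANKS.index(rank)
        return replace(self, labels=self.labels[: i + 1])

    def serialize(self) -> str:
        if self.prefixed:
            toks = [p + t for p, t in zip(_GG_PREFIXES, self.labels)]
        else:
            toks = list(self.labels)
        return self.delimiter.join(toks)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


def parse_lineage(label: str, delimiter: str = ";") -> TaxonLineage:
    """Parse a delimited lineage string into a :class:`TaxonLineage`.

    Raises :class:`LineageParseError` for empty input, mid-lineage gaps, or
    Greengenes prefixes appearing out of kingdom→species order.
    """
    if not label:
        raise LineageParseError("empty lineage string")
    toks = [t.strip() for t in label.split(delimiter)]
    # drop trailing empty tokens (truncated greengenes strings like 'g__;s__')
    while toks and not re.sub(r"^[kpcofgs]__", "", toks[-1]):
        toks.pop()
    if not toks:
        raise LineageParseError(f"no assigned ranks in {label!r}")
    prefixed = any(t[:3] in _PREFIX_TO_RANK for t in toks)
    clean = []
    for i, tok in enumerate(toks):
        if prefixed:
            pref = tok[:3]
            if pref not in _PREFIX_TO_RANK:
                raise LineageParseError(f"missing rank prefix on token {tok!r}")
            if _PREFIX_TO_RANK[pref] != RANKS[i]:
                raise LineageParseError(
                    f"rank prefix out of order at token {tok!r} "
                    f"(expected {RANKS[i]})"
                )
            tok = tok[3:]
        if not tok:
            raise LineageParseError(
                f"empty rank at {RANKS[i]} inside {label!r}"
            )
        clean.append(tok)
    return TaxonLineage(tuple(clean), delimiter=delimiter, prefixed=prefixed)


# ---------------------------------------------------------------------------
# count tables


@dataclass
class CountTable:
    """Taxon-by-sample integer read counts with parsed lineages.

    ``counts``: DataFrame, taxa as the index, samples as columns, dtype int.
    ``rank``: the taxonomic rank of the rows ('asv' or one of RANKS[3:]).
    ``lineages``: taxon id -> TaxonLineage; may be empty for bare ASV tables.
    """

    counts: pd.DataFrame
    rank: str
    lineages: dict[str, TaxonLineage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon IDs: {dups}")
        if c.columns.duplicated().any():
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("counts must be integers")
            self.counts = c.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = c.index[(vals < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative counts for taxa: {bad}")
        if self.rank not in RANKS + (ASV_RANK,):
            raise ValidationError(f"unknown rank tag {self.rank!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    def drop_empty_taxa(self) -> "CountTable":
        """Remove taxa with zero total count across all samples."""
        keep = self.counts.sum(axis=1) > 0
        sub = self.counts.loc[keep]
        lin = {t: self.lineages[t] for t in sub.index if t in self.lineages}
        return CountTable(sub, rank=self.rank, lineages=lin)


def _rank_depth(rank: str) -> int:
    return len(RANKS) if rank == ASV_RANK else RANKS.index(rank) + 1


def aggregate_to_rank(table: CountTable, rank: str) -> CountTable:
    """Sum counts of taxa sharing the label path down to ``rank``.

    Per-sample totals are preserved exactly.  Ambiguity sets compare as sets.
    The target rank must be coarser than or equal to the table's rank.
    """
    if rank not in RANKS:
        raise ValueError(f"cannot aggregate to rank {rank!r}")
    if _rank_depth(rank) > _rank_depth(table.rank):
        raise ValueError(
            f"target rank {rank!r} is finer than table rank {table.rank!r}"
        )
    if rank == table.rank:
        return CountTable(table.counts.copy(), rank=rank,
                          lineages=dict(table.lineages))
    groups: dict[tuple, list[str]] = {}
    rep: dict[tuple, str] = {}
    for tid in table.taxon_ids:
        lin = table.lineages.get(tid)
        if lin is None:
            raise ValidationError(f"taxon {tid!r} has no lineage; cannot aggregate")
        if lin.depth < _rank_depth(rank):
            raise ValidationError(
                f"taxon {tid!r} lineage shallower than {rank}"
            )
        key = lin.key_at(rank)
        groups.setdefault(key, []).append(tid)
        rep.setdefault(key, lin.truncate(rank).serialize())
    rows = {}
    lineages = {}
    for key, members in groups.items():
        new_id = rep[key]
        rows[new_id] = table.counts.loc[members].sum(axis=0)
        lineages[new_id] = table.lineages[members[0]].truncate(rank)
    agg = pd.DataFrame(rows).T
    agg.index.name = table.counts.index.name
    agg = agg[table.counts.columns]
    return CountTable(agg, rank=rank, lineages=lineages)


# ---------------------------------------------------------------------------
# metadata


@dataclass
class SampleMetadata:
    """One row per sample: subject, ordered time point, cohort, covariates.

    Required columns: ``subject_id``, ``time_point``, ``cohort``.  Known
    clinical columns (gcs, rankin, rivermead, nihss) are range-checked;
    unknown columns ride along as opaque covariates.
    """

    frame: pd.DataFrame

    REQUIRED = ("subject_id", "time_point", "cohort")
    COHORTS = ("CCI", "healthy")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.frame
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"missing metadata columns: {missing}")
        bad_cohort = set(df["cohort"].dropna()) - set(self.COHORTS)
        if bad_cohort:
            raise ValidationError(f"unknown cohort labels: {sorted(bad_cohort)}")
        offenders = []
        for col, (lo, hi) in SCORE_RANGES.items():
            if col in df.columns:
                v = pd.to_numeric(df[col], errors="coerce")
                bad = df.index[(v < lo) | (v > hi)].tolist()
                offenders += [f"{col}={df.loc[s, col]} (sample {s})" for s in bad]
        if offenders:
            raise ValidationError(f"scores out of range: {offenders}")
        for subj, sub in df.groupby("subject_id"):
            tp = sub["time_point"].to_numpy()
            order = np.argsort(tp, kind="stable")
            if np.any(np.diff(tp[order]) <= 0):
                raise ValidationError(
                    f"time points not strictly increasing for subject {subj}: "
                    f"{sorted(tp)}"
                )
            if (sub["cohort"] == "healthy").any() and len(sub) != 1:
                raise ValidationError(
                    f"healthy subject {subj} has {len(sub)} time points"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def _endpoint_samples(self, which: str) -> pd.Index:
        df = self.frame
        f = {"first": "idxmin", "last": "idxmax"}[which]
        return pd.Index(
            getattr(df.groupby("subject_id")["time_point"], f)().to_numpy()
        )

    def first_timepoint_samples(self) -> pd.Index:
        """One sample per subject: the earliest time point."""
        return self._endpoint_samples("first")

    def last_timepoint_samples(self) -> pd.Index:
        """One sample per subject: the latest time point."""
        return self._endpoint_samples("last")

    def subjects_with_min_timepoints(self, k: int) -> list:
        n = self.frame.groupby("subject_id").size()
        return n.index[n >= k].tolist()


# ---------------------------------------------------------------------------
# metabolites


@dataclass
class MetaboliteTable:
    """Sample-by-metabolite concentrations in µM with below-LOD flags.

    Below-LOD entries are stored as 0 with the flag set.
    """

    concentrations: pd.DataFrame
    below_lod: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.concentrations
        if c.index.duplicated().any():
            raise ValidationError("duplicate sample IDs in metabolite table")
        if (c.to_numpy() < 0).any():
            raise ValidationError("negative metabolite concentrations")
        if c.shape != self.below_lod.shape:
            raise ValidationError("flag matrix shape mismatch")
        flagged = self.below_lod.to_numpy()
        if (c.to_numpy()[flagged] != 0).any():
            raise ValidationError("below-LOD entries must be stored as 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.concentrations.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.concentrations.columns)


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path, format: str = "tsv", rank: str = "species",
                     delimiter: str = ";") -> CountTable:
    """Read a count table.

    TSV dialect: first column the taxon ID (a lineage string), remaining
    columns one per sample, integer cells.  BIOM v2.1 is accepted where the
    ``biom`` format library is available.
    """
    if format == "biom":
        try:
            import biom  # noqa: F401
        except ImportError as e:  # pragma: no cover - environment dependent
            raise ImportError(
                "BIOM input requires the 'biom-format' package, which is not "
                "installed; use the TSV dialect instead"
            ) from e
        t = biom.load_table(str(path))  # pragma: no cover
        df = t.to_dataframe(dense=True).astype(np.int64)  # pragma: no cover
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        raise ValueError(f"unknown count-table format {format!r}")
    df.index = df.index.astype(str)
    lineages = {}
    for tid in df.index:
        try:
            lineages[tid] = parse_lineage(tid, delimiter=delimiter)
        except LineageParseError:
            if rank != ASV_RANK:
                raise
    return CountTable(df, rank=rank, lineages=lineages)


def write_count_table(table: CountTable, path) -> None:
    out = table.counts.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError("metadata TSV must have a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metabolites(path) -> MetaboliteTable:
    """Read a metabolite TSV; empty cells and ``<LOD`` mean below-LOD."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    conc = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    flags = pd.DataFrame(False, index=df.index, columns=df.columns)
    for col in df.columns:
        raw = df[col]
        lod_mask = raw.isna() | raw.str.strip().str.upper().eq("<LOD")
        vals = pd.to_numeric(raw.where(~lod_mask), errors="raise")
        conc[col] = vals.fillna(0.0)
        flags[col] = lod_mask
    return MetaboliteTable(conc, flags)


def write_metabolites(table: MetaboliteTable, path) -> None:
    out = table.concentrations.astype(object).copy()
    out[table.below_lod] = "<LOD"
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
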