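"""Reading, validation and alignment of ASV count tables, taxonomy and sample metadata.

The canonical on-disk dialect for all three inputs is plain TSV, the format QIIME2
exports reduce to. A BIOM 1.0 (JSON) reader is provided for count tables as a
convenience; TSV is the only writer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "TaxonomyTable",
    "SampleMetadata",
    "StudyBundle",
    "TableValidationError",
    "RANKS",
    "UNCLASSIFIED",
    "read_count_table",
    "read_taxonomy",
    "read_metadata",
    "align",
]

#: Silva-style ranked lineage, coarsest to finest.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Marker used for every missing rank; never silently dropped.
UNCLASSIFIED = "unclassified"

_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

_METADATA_COLUMNS = (
    "sample_id",
    "group",
    "role",
    "host_genotype",
    "transplant_event",
    "generation",
    "replicate_kind",
)


class TableValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class CountTable:
    """Integer ASV x sample read-count matrix.

    Rows are ASVs (opaque string identifiers), columns are samples. Counts are
    non-negative integers and every sample must have sequencing depth >= 1:
    the downstream normalization divides by per-sample depth, so zero-depth
    samples are rejected at construction rather than silently dropped.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate ASV ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            # locate the first offending cell for the error message
            bad = ~np.isclose(values.astype(float) % 1, 0) | ~np.isfinite(
                values.astype(float)
            )
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise TableValidationError(
                    f"non-integer count {values[i, j]!r} at "
                    f"ASV {df.index[i]!r}, sample {df.columns[j]!r}"
                )
            object.__setattr__(self, "counts", df.astype(np.int64))
            values = self.counts.to_numpy()
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise TableValidationError(
                f"negative count {values[i, j]} at "
                f"ASV {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        depths = values.sum(axis=0)
        if (depths < 1).any():
            empty = [c for c, d in zip(df.columns, depths) if d < 1]
            raise TableValidationError(f"zero-depth samples: {empty}")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: list[str]) -> "CountTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return CountTable(self.counts[list(sample_ids)])

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class TaxonomyTable:
    """ASV -> ranked lineage map (domain .. species), Silva dialect.

    Missing ranks are explicit ``unclassified`` markers. The table may cover
    only a subset of the count table's ASVs; :func:`align` fills the rest.
    """

    lineages: pd.DataFrame  # index = asv_id, columns = RANKS

    def __post_init__(self) -> None:
        if tuple(self.lineages.columns) != RANKS:
            raise TableValidationError(
                f"taxonomy columns must be {RANKS}, got {tuple(self.lineages.columns)}"
            )
        if self.lineages.index.has_duplicates:
            dups = self.lineages.index[self.lineages.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate ASV ids in taxonomy: {dups}")

    def rank_labels(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; valid ranks: {RANKS}")
        return self.lineages[rank]

    def to_tsv(self, path: str | Path) -> None:
        lineage_strings = self.lineages.apply(
            lambda row: ";".join(
                f"{p}{'' if v == UNCLASSIFIED else v}"
                for p, v in zip(_RANK_PREFIXES, row)
            ),
            axis=1,
        )
        out = pd.DataFrame({"feature_id": self.lineages.index, "lineage": lineage_strings})
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample study design: group, role, host genotype, event, generation."""

    table: pd.DataFrame  # index = sample_id

    def __post_init__(self) -> None:
        expected = set(_METADATA_COLUMNS) - {"sample_id"}
        missing = expected - set(self.table.columns)
        if missing:
            raise TableValidationError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids in metadata: {dups}")
        bad_roles = set(self.table["role"]) - {"input", "recipient"}
        if bad_roles:
            raise TableValidationError(f"invalid roles: {sorted(bad_roles)}")
        tech = self.table[self.table["replicate_kind"] == "technical"]
        non_input_tech = tech[tech["role"] != "input"]
        if len(non_input_tech):
            raise TableValidationError(
                "technical replicates are only valid for input samples; offending "
                f"samples: {list(non_input_tech.index)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_in_group(self, group: str) -> list[str]:
        hits = self.table.index[self.table["group"] == group].tolist()
        if not hits:
            raise KeyError(f"group {group!r} has no samples")
        return hits

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class StudyBundle:
    """Immutable aligned view of counts + taxonomy + metadata.

    Samples are restricted to those present in both counts and metadata,
    ordered as in the count table; ASVs lacking taxonomy are Unclassified at
    every rank.
    """

    counts: CountTable
    taxonomy: TaxonomyTable
    metadata: SampleMetadata
    extras: dict = field(default_factory=dict, compare=False)

    def samples_in_group(self, group: str) -> list[str]:
        return self.metadata.samples_in_group(group)


def read_count_table(path: str | Path, dialect: str = "tsv") -> CountTable:
    """Read a features-x-samples count table.

    ``dialect='tsv'``: first column holds ASV ids, header row holds sample ids.
    ``dialect='biom-json'``: BIOM 1.0 JSON, dense or sparse.
    File row/column order is preserved.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        try:
            numeric = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise TableValidationError(f"non-numeric count in {path}: {exc}") from exc
        return CountTable(numeric)
    if dialect == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'biom-json'")


def _read_biom_json(path: Path) -> CountTable:
    """Minimal BIOM 1.0 reader: the format is plain JSON with row/column
    descriptors and either a dense matrix or [row, col, value] triples."""
    with open(path) as fh:
        doc = json.load(fh)
    asv_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n, m = doc["shape"]
    mat = np.zeros((n, m), dtype=np.int64)
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    return CountTable(pd.DataFrame(mat, index=asv_ids, columns=sample_ids))


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a semicolon-delimited Silva-style lineage into the seven named ranks.

    Rank prefixes (``d__`` .. ``s__``) are optional; empty tokens and missing
    trailing ranks become ``unclassified``.
    """
    parsed = dict.fromkeys(RANKS, UNCLASSIFIED)
    lineage = (lineage or "").strip()
    if not lineage:
        return parsed
    tokens = [t.strip() for t in lineage.split(";")]
    if len(tokens) > len(RANKS):
        raise TableValidationError(
            f"lineage has {len(tokens)} ranks (max {len(RANKS)}): {lineage!r}"
        )
    for rank, prefix, token in zip(RANKS, _RANK_PREFIXES, tokens):
        if token.startswith(prefix):
            token = token[len(prefix):]
        if token:
            parsed[rank] = token
    return parsed


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a two-column ``feature_id<TAB>lineage`` taxonomy file."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise TableValidationError(f"taxonomy file {path} needs >= 2 columns")
    id_col, lineage_col = df.columns[0], df.columns[1]
    records = {row[id_col]: parse_lineage(row[lineage_col]) for _, row in df.iterrows()}
    table = pd.DataFrame.from_dict(records, orient="index", columns=list(RANKS))
    table = table.reindex(columns=list(RANKS))
    return TaxonomyTable(table)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata TSV with the seven canonical columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise TableValidationError(f"metadata missing columns: {sorted(missing)}")
    df = df.set_index("sample_id")
    try:
        df["generation"] = df["generation"].astype(int)
    except ValueError as exc:
        raise TableValidationError(f"non-integer generation value: {exc}") from exc
    return SampleMetadata(df)


def align(
    counts: CountTable,
    taxonomy: TaxonomyTable | None,
    metadata: SampleMetadata,
) -> StudyBundle:
    """Align the three inputs into an immutable analysis bundle.

    Every counted sample must appear in the metadata. ASVs absent from the
    taxonomy are assigned ``Unclassified`` at every rank. The result is
    invariant to the row order of taxonomy and metadata (counts order is
    canonical).
    """
    count_samples = counts.sample_ids
    meta_samples = set(metadata.sample_ids)
    orphans = [s for s in count_samples if s not in meta_samples]
    if orphans:
        raise TableValidationError(
            f"samples in counts but missing from metadata: {orphans}"
        )
    shared = [s for s in count_samples if s in meta_samples]
    if not shared:
        raise TableValidationError("no samples shared between counts and metadata")

    meta = SampleMetadata(metadata.table.loc[shared])

    if taxonomy is None:
        lineages = pd.DataFrame(index=pd.Index([], dtype=object), columns=list(RANKS))
    else:
        lineages = taxonomy.lineages
    full = lineages.reindex(counts.asv_ids).fillna("Unclassified")
    # taxonomy rows not in the count table are irrelevant downstream
    tax = TaxonomyTable(full)

    return StudyBundle(counts=counts.subset_samples(shared), taxonomy=tax, metadata=meta)
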