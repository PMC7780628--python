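"""Tabular I/O for holobiont multi-omics tables.

Every table the pipeline touches is tab-separated UTF-8 text with a header
row and no quoting.  Count matrices follow the amplicon-community
convention: features in rows, samples in columns.  Readers validate
strictly and reject malformed input rather than coercing it; writers are
deterministic byte-for-byte for a given object.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TREATMENT_LEVELS = ("control", "glyphosate", "roundup")
ANTIBIOTIC_LEVELS = ("wild_type", "germ_free")

#: Seven-rank lineage, most to least inclusive.
LINEAGE_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


class ValidationError(ValueError):
    """A table violates its declared contract."""


class AlignmentError(ValidationError):
    """Sample identifiers disagree between two tables that must align."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer feature x sample table.

    Shared container for both gene-expression counts and sOTU counts; the
    ``kind`` tag ("expression" or "sotu") is carried for provenance only.
    """

    data: pd.DataFrame
    kind: str = "generic"

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0:
            raise ValidationError("no features")
        if df.index.duplicated().any():
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise ValidationError(f"duplicate feature ids: {dups}")
        if df.columns.duplicated().any():
            dups = sorted(set(df.columns[df.columns.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dups}")
        if not all(np.issubdtype(dt, np.integer) for dt in df.dtypes):
            raise ValidationError("count matrix must hold integer counts")
        if (df.to_numpy() < 0).any():
            r, c = np.argwhere(df.to_numpy() < 0)[0]
            raise ValidationError(
                f"negative count at feature {df.index[r]!r}, sample {df.columns[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions; all-zero samples yield zero columns."""
        sums = self.data.sum(axis=0).astype(float)
        sums[sums == 0] = np.nan
        return (self.data / sums).fillna(0.0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise AlignmentError(f"samples not in matrix: {missing}")
        return CountMatrix(self.data.loc[:, list(sample_ids)], kind=self.kind)

    def subset_features(self, feature_ids) -> "CountMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise AlignmentError(f"features not in matrix: {missing}")
        return CountMatrix(self.data.loc[list(feature_ids)], kind=self.kind)

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.data.equals(other.data) and list(self.data.columns) == list(
            other.data.columns
        )


@dataclass(frozen=True)
class SampleTable:
    """Per-sample design factors: genotype, treatment, antibiotic, replicate."""

    data: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("genotype", "treatment", "antibiotic", "replicate")

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in sample table")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        bad_t = sorted(set(df["treatment"]) - set(TREATMENT_LEVELS))
        if bad_t:
            raise ValidationError(
                f"unknown treatment level(s) {bad_t}; allowed: {TREATMENT_LEVELS}"
            )
        bad_a = sorted(set(df["antibiotic"]) - set(ANTIBIOTIC_LEVELS))
        if bad_a:
            raise ValidationError(
                f"unknown antibiotic level(s) {bad_a}; allowed: {ANTIBIOTIC_LEVELS}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def align_counts(self, m: CountMatrix) -> CountMatrix:
        """Reorder a count matrix to this table's sample order.

        Alignment is by id, never by position.
        """
        mine, theirs = set(self.data.index), set(m.sample_ids)
        if mine != theirs:
            only_meta = sorted(mine - theirs)
            only_counts = sorted(theirs - mine)
            raise AlignmentError(
                "sample id mismatch between metadata and counts: "
                f"metadata-only={only_meta}, counts-only={only_counts}"
            )
        return m.subset_samples(self.sample_ids)

    def subset(self, sample_ids) -> "SampleTable":
        return SampleTable(self.data.loc[list(sample_ids)])

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, SampleTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass(frozen=True)
class TaxonomyTable:
    """sOTU id -> seven-rank lineage, individually addressable ranks.

    Missing ranks are stored as empty strings, never absent.
    """

    data: pd.DataFrame  # indexed by sotu_id; columns = LINEAGE_RANKS

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate sotu ids in taxonomy")
        missing = [c for c in LINEAGE_RANKS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"taxonomy missing rank columns: {missing}")

    def rank(self, sotu_id: str, rank: str) -> str:
        if rank not in LINEAGE_RANKS:
            raise ValidationError(f"unknown rank {rank!r}; allowed: {LINEAGE_RANKS}")
        return self.data.at[sotu_id, rank]

    def lineage(self, sotu_id: str) -> str:
        prefixes = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
        return ";".join(
            p + self.data.at[sotu_id, r] for p, r in zip(prefixes, LINEAGE_RANKS)
        )

    def check_covers(self, m: CountMatrix) -> None:
        missing = sorted(set(m.feature_ids) - set(self.data.index))
        if missing:
            raise AlignmentError(f"sOTUs without taxonomy entry: {missing}")

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, TaxonomyTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass(frozen=True)
class TraitTable:
    """Per-individual life-history and genotoxicity measurements."""

    data: pd.DataFrame

    NUMERIC = (
        "size_at_maturity",
        "age_at_maturity",
        "fecundity",
        "aborted_eggs",
        "dead_offspring",
        "live_offspring",
        "tail_intensity_pct",
    )

    def __post_init__(self) -> None:
        df = self.data
        required = ("genotype", "treatment") + self.NUMERIC
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"trait table missing columns: {missing}")
        for c in ("aborted_eggs", "dead_offspring", "live_offspring"):
            if (df[c] < 0).any():
                raise ValidationError(f"negative values in {c}")
        ti = df["tail_intensity_pct"]
        if ((ti < 0) | (ti > 100)).any():
            raise ValidationError("tail_intensity_pct outside [0, 100]")

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, TraitTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass(frozen=True)
class OrthologPathwayMap:
    """Many-to-many gene -> (ortholog, pathway) mapping.

    A host gene can hit several pathways through its ortholog; the number of
    distinct pathways a gene maps to is its multiplicity, the quantity the
    weighted enrichment test corrects for.  Genes absent from the map are
    treated downstream as unannotated background.
    """

    data: pd.DataFrame  # columns: gene_id, ortholog_id, pathway_id

    def __post_init__(self) -> None:
        missing = [
            c for c in ("gene_id", "ortholog_id", "pathway_id") if c not in self.data.columns
        ]
        if missing:
            raise ValidationError(f"ortholog map missing columns: {missing}")

    @property
    def genes(self) -> set[str]:
        return set(self.data["gene_id"])

    @property
    def pathways(self) -> set[str]:
        return set(self.data["pathway_id"])

    def pathways_of(self, gene_id: str) -> set[str]:
        sel = self.data.loc[self.data["gene_id"] == gene_id, "pathway_id"]
        return set(sel)

    def multiplicity(self, gene_id: str) -> int:
        return len(self.pathways_of(gene_id))

    def multiplicities(self) -> dict[str, int]:
        return (
            self.data.groupby("gene_id")["pathway_id"].nunique().to_dict()
        )

    def gene_pathways(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g, p in zip(self.data["gene_id"], self.data["pathway_id"]):
            out.setdefault(g, set()).add(p)
        return out

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, OrthologPathwayMap):
            return NotImplemented
        a = self.data.sort_values(list(self.data.columns)).reset_index(drop=True)
        b = other.data.sort_values(list(other.data.columns)).reset_index(drop=True)
        return a.equals(b)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_lines(path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return [ln for ln in text.split("\n") if ln != ""]


def read_count_matrix(path, expected_kind: str = "generic") -> CountMatrix:
    """Read a features-in-rows TSV count matrix with strict validation.

    First header column is the feature-id column; remaining header fields
    are sample ids.  Every cell must be an explicit non-negative integer;
    ragged rows, duplicates and malformed cells are reported with their
    line number.
    """
    lines = _read_lines(path)
    if not lines:
        raise ValidationError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}: duplicate sample ids in header")
    if len(lines) == 1:
        raise ValidationError(f"{path}: no features")
    ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValidationError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {len(header)})"
            )
        fid, cells = fields[0], fields[1:]
        row = []
        for sid, cell in zip(sample_ids, cells):
            try:
                v = int(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer count {cell!r} "
                    f"(feature {fid!r}, sample {sid!r})"
                ) from None
            if v < 0:
                raise ValidationError(
                    f"{path}:{lineno}: negative count {v} (feature {fid!r}, sample {sid!r})"
                )
            row.append(v)
        ids.append(fid)
        rows.append(row)
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path}: duplicate feature ids {dups}")
    df = pd.DataFrame(rows, index=ids, columns=sample_ids, dtype=np.int64)
    df.index.name = "feature_id"
    return CountMatrix(df, kind=expected_kind)


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing sample_id column")
    df = df.set_index("sample_id")
    return SampleTable(df)


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a rank-prefixed, semicolon-separated lineage into named ranks.

    Accepts SILVA/Greengenes-style strings like
    ``d__Bacteria;p__Proteobacteria;...;s__``; absent trailing ranks are
    filled with empty strings.
    """
    tokens = [t.strip() for t in lineage.split(";")] if lineage else []
    if len(tokens) > len(LINEAGE_RANKS):
        raise ValidationError(f"lineage has more than seven ranks: {lineage!r}")
    out = {}
    for i, rank in enumerate(LINEAGE_RANKS):
        tok = tokens[i] if i < len(tokens) else ""
        out[rank] = _RANK_PREFIX.sub("", tok)
    return out


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("sotu_id", "lineage"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    parsed = pd.DataFrame(
        [parse_lineage(ln) for ln in df["lineage"]], index=df["sotu_id"]
    )
    parsed.index.name = "sotu_id"
    return TaxonomyTable(parsed)


def read_ortholog_map(path) -> OrthologPathwayMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return OrthologPathwayMap(df.reset_index(drop=True))


def read_trait_table(path) -> TraitTable:
    df = pd.read_csv(path, sep="\t")
    return TraitTable(df)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _to_tsv(df: pd.DataFrame, path, index: bool) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def write_table(obj, path) -> None:
    """Write any pipeline table as deterministic TSV.

    Round-trip contract: ``read(write(x)) == x`` for CountMatrix,
    SampleTable, TaxonomyTable, TraitTable and OrthologPathwayMap.
    """
    if isinstance(obj, CountMatrix):
        df = obj.data.copy()
        df.index.name = "feature_id"
        _to_tsv(df, path, index=True)
    elif isinstance(obj, SampleTable):
        df = obj.data.copy()
        df.index.name = "sample_id"
        _to_tsv(df.reset_index(), path, index=False)
    elif isinstance(obj, TaxonomyTable):
        rows = [
            {"sotu_id": sid, "lineage": obj.lineage(sid)} for sid in obj.data.index
        ]
        _to_tsv(pd.DataFrame(rows), path, index=False)
    elif isinstance(obj, OrthologPathwayMap):
        _to_tsv(obj.data, path, index=False)
    elif isinstance(obj, TraitTable):
        _to_tsv(obj.data, path, index=False)
    elif isinstance(obj, pd.DataFrame):
        _to_tsv(obj, path, index=False)
    else:
        raise TypeError(f"do not know how to write {type(obj).__name__}")
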