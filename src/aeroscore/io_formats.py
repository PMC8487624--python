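"""Readers, writers and canonical in-memory containers for ASV-level data.

The canonical table orientation everywhere in the toolkit is samples-as-rows.
Taxonomy lineages are canonicalized on read: rank prefixes (``g__``) stripped,
"unclassified"-style tokens collapsed to a single ``UNASSIGNED`` sentinel, and
any named taxon below an unassigned rank truncated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = "UNASSIGNED"

#: tokens mapping to the UNASSIGNED sentinel (compared case-insensitively)
_UNASSIGNED_TOKENS = {
    "", "na", "n/a", "none", "null", "unassigned", "unclassified",
    "unidentified", "unknown", "uncultured", UNASSIGNED.lower(),
}

#: single-letter lineage prefixes -> rank names ("k__Bacteria")
_PREFIX_TO_RANK = {
    "d": "domain", "k": "domain", "p": "phylum", "c": "class",
    "o": "order", "f": "family", "g": "genus", "s": "species",
}

#: accepted column-name aliases for rank columns (case-insensitive)
_RANK_ALIASES = {
    "domain": "domain", "kingdom": "domain", "phylum": "phylum",
    "class": "class", "order": "order", "family": "family",
    "genus": "genus", "species": "species",
}

SAMPLE_TYPES = ("sample", "sampling_control", "laboratory_control", "positive_control")
NEGATIVE_CONTROL_TYPES = ("sampling_control", "laboratory_control")

_VALID_BASES = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AsvTable:
    """Samples x ASVs integer count matrix.

    ``counts`` is a pandas DataFrame whose index holds sample ids and whose
    columns hold ASV ids; validated on construction.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise FormatError("ASV table must contain at least 1 sample and 1 ASV")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate ASV ids: {dupes}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = self._first_bad_cell(lambda v: not _is_count(v))
            raise ValidationError(f"non-numeric count at (sample={bad[0]!r}, asv={bad[1]!r})")
        if np.isnan(arr.astype(float)).any():
            bad = self._first_bad_cell(lambda v: pd.isna(v))
            raise ValidationError(f"missing count at (sample={bad[0]!r}, asv={bad[1]!r})")
        if (arr < 0).any():
            bad = self._first_bad_cell(lambda v: v < 0)
            raise ValidationError(f"negative count at (sample={bad[0]!r}, asv={bad[1]!r})")
        if not np.allclose(arr, np.round(arr.astype(float))):
            bad = self._first_bad_cell(lambda v: float(v) != round(float(v)))
            raise ValidationError(f"non-integer count at (sample={bad[0]!r}, asv={bad[1]!r})")
        self.counts = df.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)
        self.counts.index.name = "sample_id"

    def _first_bad_cell(self, pred) -> tuple[str, str]:
        for s in self.counts.index:
            for a in self.counts.columns:
                v = self.counts.at[s, a]
                try:
                    if pred(v):
                        return str(s), str(a)
                except (TypeError, ValueError):
                    return str(s), str(a)
        return "?", "?"

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def asv_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized proportions; zero-read samples stay all-zero."""
        totals = self.counts.sum(axis=1).to_numpy(dtype=float)
        safe = np.where(totals > 0, totals, 1.0)
        return self.counts.div(safe, axis=0)

    def subset(self, samples: Sequence[str] | None = None,
               asvs: Sequence[str] | None = None) -> "AsvTable":
        df = self.counts
        if samples is not None:
            df = df.loc[list(samples)]
        if asvs is not None:
            df = df[list(asvs)]
        return AsvTable(df.copy())


def _is_count(v) -> bool:
    try:
        f = float(v)
    except (TypeError, ValueError):
        return False
    return f >= 0 and f == round(f)


@dataclass
class SampleMetadata:
    """Per-sample metadata: location, sample type, optional DNA concentration (ng/uL)."""

    frame: pd.DataFrame  # index: sample_id; columns: location, sample_type, dna_concentration

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        for col in ("location", "sample_type"):
            if col not in df.columns:
                raise FormatError(f"metadata missing required column {col!r}")
        bad = sorted(set(df["sample_type"]) - set(SAMPLE_TYPES))
        if bad:
            raise ValidationError(
                f"unknown sample_type value(s) {bad}; allowed: {list(SAMPLE_TYPES)}")
        if "dna_concentration" not in df.columns:
            df["dna_concentration"] = np.nan
        df["dna_concentration"] = pd.to_numeric(df["dna_concentration"], errors="coerce")
        if (df["dna_concentration"].dropna() < 0).any():
            raise ValidationError("dna_concentration must be non-negative")
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        self.frame = df[["location", "sample_type", "dna_concentration"]]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def ids_of_type(self, *types: str) -> list[str]:
        mask = self.frame["sample_type"].isin(types)
        return list(self.frame.index[mask])

    def true_samples(self) -> list[str]:
        return self.ids_of_type("sample")

    def negative_controls(self, scope: str = "all_negative") -> list[str]:
        """Negative-control sample ids for ``scope`` in
        {all_negative, sampling_only, laboratory_only}."""
        if scope == "all_negative":
            return self.ids_of_type(*NEGATIVE_CONTROL_TYPES)
        if scope == "sampling_only":
            return self.ids_of_type("sampling_control")
        if scope == "laboratory_only":
            return self.ids_of_type("laboratory_control")
        raise ValueError(f"unknown control scope {scope!r}")

    def locations(self) -> pd.Series:
        return self.frame["location"]


@dataclass
class TaxonomyTable:
    """Per-ASV ranked lineage from one reference database.

    ``assignments`` is indexed by asv_id with the columns of :data:`RANKS`
    (species column optional); every cell is either a taxon name or the
    ``UNASSIGNED`` sentinel, with no named taxon below an unassigned rank.
    """

    assignments: pd.DataFrame
    source_db: str = "db"

    def __post_init__(self) -> None:
        df = self.assignments.copy()
        if df.index.has_duplicates:
            raise FormatError(f"duplicate ASV ids in taxonomy from {self.source_db!r}")
        ranks = [r for r in RANKS if r in df.columns]
        if "genus" not in ranks:
            raise FormatError("taxonomy table must carry a genus column")
        df = df[ranks].astype(object)
        # canonicalize each cell, then truncate below the first unassigned rank
        for r in ranks:
            df[r] = [canonical_taxon(v) for v in df[r]]
        vals = df.to_numpy(dtype=object)
        unassigned = vals == UNASSIGNED
        cut = np.cumsum(unassigned, axis=1) > 0
        vals[cut] = UNASSIGNED
        self.assignments = pd.DataFrame(vals, index=df.index.astype(str), columns=ranks)
        self.assignments.index.name = "asv_id"

    @property
    def asv_ids(self) -> list[str]:
        return list(self.assignments.index)

    @property
    def ranks(self) -> list[str]:
        return list(self.assignments.columns)

    def genus(self) -> pd.Series:
        return self.assignments["genus"]

    def assigned_at_genus(self) -> pd.Series:
        return self.assignments["genus"] != UNASSIGNED

    def genus_names(self) -> set[str]:
        """Canonical set of genus names assigned by this database."""
        g = self.assignments["genus"]
        return {comparable_genus(v) for v in g[g != UNASSIGNED]}


def canonical_taxon(value) -> str:
    """Strip rank prefixes/whitespace; map sentinel-like tokens to UNASSIGNED."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNASSIGNED
    s = str(value).strip()
    if len(s) >= 3 and s[1:3] == "__" and s[0].lower() in _PREFIX_TO_RANK:
        s = s[3:].strip()
    if s.lower() in _UNASSIGNED_TOKENS:
        return UNASSIGNED
    return s


def comparable_genus(name: str) -> str:
    """Case-insensitive genus key; 'Candidatus ' prefixes stripped before comparison."""
    key = name.strip().lower()
    if key.startswith("candidatus "):
        key = key[len("candidatus "):]
    return key


# ---------------------------------------------------------------------------
# ASV table I/O
# ---------------------------------------------------------------------------

def read_asv_table(path: str | Path, dialect: str = "tsv",
                   sample_ids: Iterable[str] | None = None) -> AsvTable:
    """Read an ASV count table as TSV or dense/sparse BIOM-style JSON.

    If ``sample_ids`` (e.g. from metadata) is given, the orientation is
    resolved by intersecting row and column labels with the known sample ids;
    an ambiguous intersection is an error. Without hints, rows are samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise FormatError(f"{path}: empty ASV table")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df = _orient(df, sample_ids, path)
        return AsvTable(df)
    if dialect == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown ASV-table dialect {dialect!r}")


def _orient(df: pd.DataFrame, sample_ids, path) -> pd.DataFrame:
    if sample_ids is None:
        return df
    ids = {str(s) for s in sample_ids}
    in_rows = len(ids & set(df.index))
    in_cols = len(ids & set(df.columns))
    if in_rows and in_cols:
        raise FormatError(
            f"{path}: ambiguous orientation (sample ids appear in both rows and columns)")
    if in_cols:
        return df.T
    if in_rows:
        return df
    raise FormatError(f"{path}: no known sample ids found on either axis")


def _read_biom_json(path: Path) -> AsvTable:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        asv_ids = [r["id"] for r in doc["rows"]]        # BIOM rows = observations
        samples = [c["id"] for c in doc["columns"]]
        mtype = doc.get("matrix_type", "dense")
        shape = doc.get("shape", [len(asv_ids), len(samples)])
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: not a BIOM-style JSON table ({exc})") from exc
    mat = np.zeros((shape[0], shape[1]))
    if mtype == "dense":
        mat = np.asarray(doc["data"], dtype=float)
    elif mtype == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        raise FormatError(f"{path}: unknown matrix_type {mtype!r}")
    if mat.shape != tuple(shape):
        raise FormatError(f"{path}: data shape {mat.shape} != declared {tuple(shape)}")
    # transpose to canonical samples-as-rows
    return AsvTable(pd.DataFrame(mat.T, index=samples, columns=asv_ids))


def write_asv_table(table: AsvTable, path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        table.counts.to_csv(path, sep="\t")
    elif dialect == "biom-json":
        doc = {
            "id": "aeroscore",
            "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_asvs, table.n_samples],
            "rows": [{"id": a, "metadata": None} for a in table.asv_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.T.to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown ASV-table dialect {dialect!r}")


# ---------------------------------------------------------------------------
# taxonomy I/O
# ---------------------------------------------------------------------------

def read_taxonomy(path: str | Path, dialect: str | None = None,
                  source_db: str | None = None) -> TaxonomyTable:
    """Read a taxonomy table; ``dialect`` in {rank-columns, lineage-string} or
    auto-detected from the header."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: taxonomy table needs an asv id column plus assignments")
    cols = {c.lower().strip(): c for c in df.columns}
    id_col = next((cols[k] for k in ("asv_id", "asv", "otu_id", "feature_id", "id")
                   if k in cols), df.columns[0])
    if df[id_col].isna().any():
        raise FormatError(f"{path}: missing asv_id value(s)")
    if dialect is None:
        dialect = "lineage-string" if any(k in cols for k in ("lineage", "taxonomy", "taxon")
                                          ) else "rank-columns"
    if dialect == "lineage-string":
        lin_col = next((cols[k] for k in ("lineage", "taxonomy", "taxon") if k in cols), None)
        if lin_col is None:
            raise FormatError(f"{path}: no lineage column found")
        rows = [parse_lineage(v) for v in df[lin_col]]
        body = pd.DataFrame(rows, index=df[id_col].astype(str))
    elif dialect == "rank-columns":
        rank_cols = {}
        for low, orig in cols.items():
            if low in _RANK_ALIASES and orig != id_col:
                rank_cols[_RANK_ALIASES[low]] = orig
        if "genus" not in rank_cols:
            raise FormatError(f"{path}: no genus column among {list(df.columns)}")
        body = pd.DataFrame(
            {r: df[rank_cols[r]].to_numpy() for r in RANKS if r in rank_cols},
            index=df[id_col].astype(str))
    else:
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")
    # pad missing upper ranks so downstream always sees the full ladder
    for r in RANKS[:-1]:
        if r not in body.columns:
            body[r] = UNASSIGNED
    body = body[[r for r in RANKS if r in body.columns]]
    return TaxonomyTable(body, source_db=source_db or path.stem)


def parse_lineage(lineage) -> dict[str, str]:
    """Parse 'k__Bacteria;p__Proteobacteria;...' into a rank -> taxon map."""
    out = {r: UNASSIGNED for r in RANKS}
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        return out
    for token in str(lineage).split(";"):
        token = token.strip()
        if not token:
            continue
        if len(token) >= 3 and token[1:3] == "__":
            prefix = token[0].lower()
            rank = _PREFIX_TO_RANK.get(prefix)
            if rank is None:
                warnings.warn(f"unknown rank prefix {token[:3]!r}; treated as unassigned")
                continue
            out[rank] = canonical_taxon(token)
        else:
            warnings.warn(f"unprefixed lineage token {token!r}; treated as unassigned")
    return out


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    tax.assignments.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# metadata I/O
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    cols = {c.lower().strip(): c for c in df.columns}
    for req in ("sample_id", "sample_type"):
        if req not in cols:
            raise FormatError(f"{path}: missing required column {req!r}")
    df = df.rename(columns={v: k for k, v in cols.items()})
    if "location" not in df.columns:
        df["location"] = "unknown"
    return SampleMetadata(df.set_index("sample_id"))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sequence I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """ASV representative sequences as an id -> uppercase A/C/G/T/N string map."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        s = str(rec.seq).upper()
        if not s:
            raise ValidationError(f"{path}: empty sequence for {rec.id!r}")
        bad = set(s) - _VALID_BASES
        if bad:
            raise ValidationError(f"{path}: invalid characters {sorted(bad)} in {rec.id!r}")
        seqs[rec.id] = s
    if not seqs:
        raise FormatError(f"{path}: no sequences found")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=a, description="") for a, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------

def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize any report object exposing ``to_dict``/``to_frame``.

    JSON is the machine-readable twin; TSV is the human-facing table. Both
    carry the same values.
    """
    path = Path(path)
    if format == "json":
        payload = report.to_dict() if hasattr(report, "to_dict") else report
        if not payload:
            raise ValidationError("refusing to write an empty report")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)
    elif format == "tsv":
        frame = report.to_frame() if hasattr(report, "to_frame") else pd.DataFrame(report)
        if frame.empty:
            raise ValidationError("refusing to write an empty report")
        frame.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown report format {format!r}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
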