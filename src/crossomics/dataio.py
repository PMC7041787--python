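"""Readers and writers for every external format the pipeline touches, plus
the canonical in-memory tables.

All on-disk coordinates are 1-based inclusive (GWAS convention).  The
half-open helpers :func:`to_zero_based` / :func:`to_one_based` are the only
place arithmetic on the convention happens; everything downstream works with
whichever convention its inputs carry and never re-derives it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

GWAS_COLUMNS = ("snp", "chrom", "pos", "p")

#: Recognized pathway sources (GMT ids are prefixed e.g. "GO:", "hsa").
PATHWAY_SOURCES = ("KEGG", "GO", "BioCarta", "Reactome", "other")


# ---------------------------------------------------------------------------
# coordinate convention converters
# ---------------------------------------------------------------------------

def to_zero_based(start_1based: int, end_1based_inclusive: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open [start, end)."""
    return start_1based - 1, end_1based_inclusive


def to_one_based(start0: int, end0_exclusive: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive."""
    return start0 + 1, end0_exclusive


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LoadReport:
    """Row accounting for a reader: rows_in = rows_kept + rows_dropped."""

    rows_in: int = 0
    rows_kept: int = 0
    rows_dropped: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.rows_in != self.rows_kept + self.rows_dropped:
            raise ConsistencyError(
                f"load report does not balance: {self.rows_in} != "
                f"{self.rows_kept} + {self.rows_dropped}"
            )


@dataclass
class GwasSummary:
    """Per-phenotype SNP association table.

    ``records`` has columns ``snp, chrom, pos, p`` with unique snp ids,
    0 < p <= 1 and pos >= 1.
    """

    phenotype: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in GWAS_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"GWAS table missing column(s): {', '.join(missing)}")
        dup = df["snp"][df["snp"].duplicated()]
        if len(dup):
            raise FormatError(
                f"duplicate snp_id in phenotype {self.phenotype!r}: {dup.iloc[0]!r}"
            )
        if ((df["p"] <= 0) | (df["p"] > 1)).any():
            raise FormatError("p-values must lie in (0, 1]")
        if (df["pos"] < 1).any():
            raise FormatError("positions must be >= 1 (1-based)")
        if (df["chrom"].astype(str).str.len() == 0).any():
            raise FormatError("empty chromosome name")

    @property
    def n_snps(self) -> int:
        return len(self.records)


@dataclass
class GeneAnnotation:
    """Gene bodies: columns ``gene_id, chrom, start, end, strand``
    (1-based inclusive, strand in {+, -, unknown})."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        need = ("gene_id", "chrom", "start", "end", "strand")
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise FormatError(f"annotation missing column(s): {', '.join(missing)}")
        if df["gene_id"].duplicated().any():
            dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate gene_id: {dup!r}")
        bad = df[df["start"] > df["end"]]
        if len(bad):
            raise FormatError(
                f"gene {bad['gene_id'].iloc[0]!r} has start > end"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])


@dataclass
class Pathway:
    description: str
    source: str
    genes: frozenset[str]


@dataclass
class PathwayCollection:
    """Named gene sets; after size filtering every set has
    min_size <= |genes| <= max_size."""

    entries: dict[str, Pathway]

    def __len__(self) -> int:
        return len(self.entries)

    def genes(self, pathway_id: str) -> frozenset[str]:
        return self.entries[pathway_id].genes

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for pw in self.entries.values():
            out |= pw.genes
        return out

    def subset(self, pathway_ids) -> "PathwayCollection":
        return PathwayCollection({p: self.entries[p] for p in pathway_ids})


@dataclass
class MatrixTable:
    """Numeric matrix with row/column ids and optional metadata tables.

    Thin wrapper over a pandas DataFrame (rows = features, columns =
    samples) used as the carrier for methylation beta, genotype dosage and
    expression matrices.
    """

    values: pd.DataFrame
    row_meta: pd.DataFrame | None = None
    col_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise FormatError("duplicate row ids in matrix")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate column ids in matrix")
        if self.row_meta is not None and not self.row_meta.index.equals(
            self.values.index
        ):
            raise ConsistencyError("row_meta index does not match matrix rows")
        if self.col_meta is not None and not self.col_meta.index.equals(
            self.values.columns
        ):
            raise ConsistencyError("col_meta index does not match matrix columns")

    @property
    def row_ids(self) -> list:
        return list(self.values.index)

    @property
    def col_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# GWAS summary TSV
# ---------------------------------------------------------------------------

DEFAULT_GWAS_DIALECT = {"snp": "snp", "chrom": "chrom", "pos": "pos", "p": "p"}


def read_gwas(
    path,
    phenotype: str,
    dialect: dict[str, str] | None = None,
) -> tuple[GwasSummary, LoadReport]:
    """Read a GWAS summary TSV.

    ``dialect`` maps canonical names (snp, chrom, pos, p) to the file's
    column headers.  Rows with p outside (0, 1] are dropped and counted in
    the returned :class:`LoadReport` (the -log10 transform downstream must
    stay finite, so p = 0 cannot be clamped).
    """
    dialect = dict(DEFAULT_GWAS_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, sep="\t", dtype={dialect["chrom"]: str})
    for canon, col in dialect.items():
        if col not in df.columns:
            raise FormatError(f"GWAS file {path} missing column {col!r} (for {canon})")
    df = df.rename(columns={v: k for k, v in dialect.items()})[list(GWAS_COLUMNS)]
    report = LoadReport(rows_in=len(df))
    ok = (df["p"] > 0) & (df["p"] <= 1)
    n_bad = int((~ok).sum())
    if n_bad:
        report.reasons["p outside (0,1]"] = n_bad
    df = df[ok].reset_index(drop=True)
    report.rows_kept = len(df)
    report.rows_dropped = n_bad
    report.check()
    return GwasSummary(phenotype=phenotype, records=df), report


def write_gwas(gwas: GwasSummary, path) -> None:
    gwas.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT (Broad dialect)
# ---------------------------------------------------------------------------

def _infer_source(pathway_id: str) -> str:
    pid = pathway_id.upper()
    if pid.startswith("GO:"):
        return "GO"
    if pid.startswith("HSA") or pid.startswith("KEGG"):
        return "KEGG"
    if pid.startswith("BIOCARTA"):
        return "BioCarta"
    if pid.startswith("REACTOME") or pid.startswith("R-HSA"):
        return "Reactome"
    return "other"


def read_gmt(
    path,
    min_size: int = 10,
    max_size: int = 300,
) -> tuple[PathwayCollection, LoadReport]:
    """Read a Broad-dialect GMT file (id TAB description TAB gene TAB ...).

    Sets with deduplicated size outside [min_size, max_size] (inclusive
    bounds) are excluded and counted in the report.
    """
    entries: dict[str, Pathway] = {}
    report = LoadReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has < 3 fields")
            pid, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            report.rows_in += 1
            if not (min_size <= len(genes) <= max_size):
                report.rows_dropped += 1
                report.reasons.setdefault("size outside bounds", 0)
                report.reasons["size outside bounds"] += 1
                continue
            entries[pid] = Pathway(description=desc, source=_infer_source(pid), genes=genes)
            report.rows_kept += 1
    report.check()
    return PathwayCollection(entries), report


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for pid, pw in collection.entries.items():
            genes = "\t".join(sorted(pw.genes))
            fh.write(f"{pid}\t{pw.description}\t{genes}\n")


# ---------------------------------------------------------------------------
# numeric matrices (TSV, row-id first column)
# ---------------------------------------------------------------------------

def write_matrix(mat: MatrixTable, path, float_format=None) -> None:
    """Write matrix values with repr-exact floats so the reader round-trips
    bitwise."""
    df = mat.values
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(map(str, df.columns)) + "\n")
        values = df.to_numpy()
        for rid, row in zip(df.index, values):
            cells = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{rid}\t{cells}\n")


def read_matrix(path) -> MatrixTable:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    body = df.to_numpy()
    if not np.issubdtype(body.dtype, np.number):
        # locate first offending cell for the error message
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                rid = df.index[bad.argmax()]
                raise FormatError(
                    f"{path}: non-numeric cell at row {rid!r}, column {col!r}"
                )
        raise FormatError(f"{path}: non-numeric matrix body")
    df.index.name = None
    return MatrixTable(values=df)


# ---------------------------------------------------------------------------
# gene annotation (TSV or 6-column BED)
# ---------------------------------------------------------------------------

def read_annotation(path) -> GeneAnnotation:
    """Read a gene annotation: either a header TSV with columns
    (gene_id, chrom, start, end, strand) or a headerless 6-column BED
    (chrom, start0, end, name, score, strand), converted to 1-based."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    if "gene_id" in first:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    else:
        if len(first) < 6:
            raise FormatError(f"{path}: headerless annotation must be 6-column BED")
        bed = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start0", "end", "gene_id", "score", "strand"],
            dtype={"chrom": str},
        )
        start1, _ = zip(*(to_one_based(s, e) for s, e in zip(bed["start0"], bed["end"])))
        df = pd.DataFrame(
            {
                "gene_id": bed["gene_id"],
                "chrom": bed["chrom"],
                "start": list(start1),
                "end": bed["end"],
                "strand": bed["strand"].where(bed["strand"].isin(["+", "-"]), "unknown"),
            }
        )
    return GeneAnnotation(table=df.reset_index(drop=True))


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# undirected edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path) -> pd.DataFrame:
    """Read a TSV edge list (two id columns, optional weight).  Edges are
    canonicalized to sorted endpoint order and deduplicated, so (a,b) and
    (b,a) collapse to one undirected edge; self loops are dropped."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: edge list needs at least two columns")
    a, b = df.columns[0], df.columns[1]
    lo = df[[a, b]].min(axis=1)
    hi = df[[a, b]].max(axis=1)
    out = df.copy()
    out[a], out[b] = lo, hi
    out = out[out[a] != out[b]]
    out = out.drop_duplicates(subset=[a, b]).reset_index(drop=True)
    out = out.rename(columns={a: "node_a", b: "node_b"})
    return out


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def mvalue_to_beta(m: np.ndarray) -> np.ndarray:
    """Inverse of the M-value transform: beta = 2^M / (1 + 2^M), in (0,1)."""
    return 1.0 / (1.0 + np.exp2(-np.asarray(m, dtype=float)))


def is_close_table(a: pd.DataFrame, b: pd.DataFrame, tol: float = 0.0) -> bool:
    """Field-by-field comparison helper used by round-trip tests."""
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        x, y = a[col], b[col]
        if np.issubdtype(x.dtype, np.number):
            if tol == 0.0:
                if not (x.to_numpy() == y.to_numpy()).all():
                    return False
            elif not np.allclose(x, y, atol=tol, rtol=0):
                return False
        elif not (x.astype(str) == y.astype(str)).all():
            return False
    return True


def neglog10(p) -> np.ndarray:
    """-log10(p); input already validated to (0, 1] so the result is finite."""
    return -np.log10(np.asarray(p, dtype=float))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0,1)")
    return alpha / n_tests
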