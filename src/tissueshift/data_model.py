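"""Core typed containers and file I/O.

The pipeline operates on three kinds of objects: a gene x tissue TPM
matrix (:class:`ExpressionMatrix`), named disease gene sets
(:class:`GeneSet`), and a pattern-based tissue taxonomy
(:class:`TissueTaxonomy`) that groups tissues into CNS, heart,
muscle-skeletal and peripheral-organ compartments.

Expression matrices travel as GCT 1.2 text files (the format GTEx uses
for its median-TPM releases); gene sets as CSV/TSV exports with a
``gene`` column and an optional ``score`` column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyGeneSetError, GctFormatError, ValidationError

log = logging.getLogger(__name__)

TAXONOMY_GROUPS = ("CNS", "heart", "muscle_skeletal", "peripheral_organ")


def canonicalize(symbol: str) -> str:
    """Canonical gene symbol: whitespace-stripped, upper-case."""
    return str(symbol).strip().upper()


@dataclass
class ExpressionMatrix:
    """Non-negative gene x tissue expression table in TPM units.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``tissue_ids[j]``. Gene identifiers are canonical symbols and unique;
    tissue names are unique. All values are finite and >= 0.
    """

    gene_ids: list[str]
    tissue_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n_g, n_t = self.values.shape
        if n_g != len(self.gene_ids) or n_t != len(self.tissue_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.tissue_ids)} tissues"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.tissue_ids)) != len(self.tissue_ids):
            raise ValidationError("duplicate tissue identifiers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_ids)

    def column(self, tissue: str) -> np.ndarray:
        """Expression of every gene in one tissue (a copy)."""
        try:
            j = self.tissue_ids.index(tissue)
        except ValueError:
            raise KeyError(f"unknown tissue {tissue!r}") from None
        return self.values[:, j].copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.tissue_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.tissue_ids == other.tissue_ids
            and self.values.shape == other.values.shape
            and bool(np.array_equal(self.values, other.values))
        )


@dataclass
class GeneSet:
    """Named set of canonical gene symbols for one disease.

    ``scores`` carries optional per-gene category labels (e.g. the SFARI
    "1" / "2S" evidence tiers); they are pass-through metadata and never
    influence the computation. An empty set is legal in memory — it is
    the full-genome reference condition — but file readers reject empty
    sources.
    """

    name: str
    genes: set[str] = field(default_factory=set)
    scores: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = {canonicalize(g) for g in self.genes}
        self.scores = {canonicalize(g): str(v) for g, v in self.scores.items()}
        extra = set(self.scores) - self.genes
        if extra:
            raise ValidationError(f"scores for genes not in set: {sorted(extra)[:5]}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class AbsenceReport:
    """Genes of a set that a matrix does not contain."""

    set_name: str
    n_absent: int
    absent: list[str]


@dataclass
class TissueTaxonomy:
    """Ordered (pattern, group) rules mapping tissue names to body-system groups.

    Patterns are case-insensitive substring matches evaluated in order;
    the first hit wins. Tissues matching no pattern fall back to
    ``peripheral_organ`` with a logged warning.
    """

    rules: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for pat, grp in self.rules:
            if grp not in TAXONOMY_GROUPS:
                raise ValidationError(f"unknown taxonomy group {grp!r} for pattern {pat!r}")

    @classmethod
    def default(cls) -> "TissueTaxonomy":
        """GTEx-style defaults: brain/spinal cord -> CNS, heart -> heart,
        skeletal muscle -> muscle_skeletal, everything else peripheral.

        The final empty pattern is an explicit catch-all, so ordinary
        peripheral tissues do not trigger the unmatched-tissue warning.
        """
        return cls(
            rules=[
                ("brain", "CNS"),
                ("spinal cord", "CNS"),
                ("heart", "heart"),
                ("muscle - skeletal", "muscle_skeletal"),
                ("", "peripheral_organ"),
            ]
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TissueTaxonomy":
        """Read rules from a YAML list of ``{pattern:, group:}`` entries."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, list):
            raise ValidationError("taxonomy YAML must be a list of {pattern, group}")
        return cls(rules=[(str(e["pattern"]), str(e["group"])) for e in raw])

    @classmethod
    def from_csv(cls, path: str | Path) -> "TissueTaxonomy":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "pattern" not in cols or "group" not in cols:
            raise ValidationError("taxonomy CSV needs 'pattern' and 'group' columns")
        return cls(rules=[(str(r[cols["pattern"]]), str(r[cols["group"]])) for _, r in df.iterrows()])

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                [{"pattern": p, "group": g} for p, g in self.rules],
                fh,
                sort_keys=False,
            )

    def group_of(self, tissue: str) -> str:
        low = tissue.lower()
        for pat, grp in self.rules:
            if pat.lower() in low:
                return grp
        log.warning("tissue %r matched no taxonomy pattern; assigning peripheral_organ", tissue)
        return "peripheral_organ"

    def assign(self, em: ExpressionMatrix) -> dict[str, str]:
        return {t: self.group_of(t) for t in em.tissue_ids}


# ---------------------------------------------------------------------------
# GCT 1.2 I/O
# ---------------------------------------------------------------------------

def read_gct(path: str | Path) -> ExpressionMatrix:
    """Read a GCT 1.2 expression file into an :class:`ExpressionMatrix`.

    Gene identifiers are taken from the ``Description`` (symbol) column
    when it is non-empty for a row, falling back to ``Name`` (GTEx puts
    versioned Ensembl IDs in Name and symbols in Description). Duplicate
    symbols after canonicalization keep the first occurrence, with a
    warning.
    """
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise GctFormatError(f"expected '#1.2' version line, got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise GctFormatError("malformed dimensions line")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise GctFormatError("non-integer dimensions line") from exc
        df = pd.read_csv(
            fh, sep="\t", header=0, dtype={0: str, 1: str},
            float_precision="round_trip",
        )
    if df.shape[1] < 3 or list(df.columns[:2]) != ["Name", "Description"]:
        raise GctFormatError("header must start with Name\\tDescription")
    tissues = [str(c) for c in df.columns[2:]]
    if df.shape[0] != n_rows or len(tissues) != n_cols:
        raise GctFormatError(
            f"declared {n_rows}x{n_cols} but found {df.shape[0]}x{len(tissues)}"
        )

    desc = df["Description"].fillna("").astype(str)
    name = df["Name"].fillna("").astype(str)
    ids = np.where(desc.str.strip() != "", desc, name)
    ids = [canonicalize(g) for g in ids]

    values = df.iloc[:, 2:].to_numpy(dtype=float)
    seen: dict[str, int] = {}
    keep: list[int] = []
    for i, g in enumerate(ids):
        if g in seen:
            log.warning("duplicate gene symbol %r in %s; keeping first occurrence", g, path.name)
            continue
        seen[g] = i
        keep.append(i)
    if len(keep) != len(ids):
        values = values[keep]
        ids = [ids[i] for i in keep]
    return ExpressionMatrix(gene_ids=list(ids), tissue_ids=tissues, values=values)


def write_gct(em: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as GCT 1.2. ``read_gct`` round-trips the output bit-exactly."""
    path = Path(path)
    df = pd.DataFrame(em.values, columns=em.tissue_ids)
    df.insert(0, "Description", em.gene_ids)
    df.insert(0, "Name", em.gene_ids)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{em.n_genes}\t{em.n_tissues}\n")
        # %.17g preserves every double exactly, so read_gct round-trips
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.17g")


# ---------------------------------------------------------------------------
# Gene-set I/O and set algebra
# ---------------------------------------------------------------------------

def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a disease gene set from a CSV/TSV export.

    The file needs a ``gene`` column (case-insensitive); an optional
    ``score`` column is carried through as per-gene labels. Symbols are
    canonicalized, duplicates collapsed (first score wins), blank rows
    skipped.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.strip().lower(): c for c in df.columns}
    if "gene" not in cols:
        raise ValidationError(f"{path.name}: required column 'gene' not found")
    genes: set[str] = set()
    scores: dict[str, str] = {}
    score_col = cols.get("score")
    for _, row in df.iterrows():
        raw = row[cols["gene"]]
        if pd.isna(raw) or not str(raw).strip():
            continue
        g = canonicalize(raw)
        if g in genes:
            continue
        genes.add(g)
        if score_col is not None and not pd.isna(row[score_col]):
            scores[g] = str(row[score_col]).strip()
    if not genes:
        raise EmptyGeneSetError(f"{path.name}: no gene symbols parsed")
    return GeneSet(name=name if name is not None else path.stem, genes=genes, scores=scores)


def intersect_with_matrix(gs: GeneSet, em: ExpressionMatrix) -> tuple[GeneSet, AbsenceReport]:
    """Restrict a gene set to symbols present in the matrix.

    Disease databases list symbols that a given expression release may
    not contain; only confirmed-present genes enter the removal. Returns
    the present subset and a report of the absent symbols.
    """
    present = gs.genes & set(em.gene_ids)
    absent = sorted(gs.genes - present)
    sub = GeneSet(
        name=gs.name,
        genes=present,
        scores={g: s for g, s in gs.scores.items() if g in present},
    )
    return sub, AbsenceReport(set_name=gs.name, n_absent=len(absent), absent=absent)


def overlap_gene_sets(a: GeneSet, b: GeneSet) -> GeneSet:
    """Intersection of two gene sets, named ``a∩b``; scores inherited from ``a``."""
    genes = a.genes & b.genes
    return GeneSet(
        name=f"{a.name}∩{b.name}",
        genes=genes,
        scores={g: s for g, s in a.scores.items() if g in genes},
    )


def extract_submatrix(
    em: ExpressionMatrix, gs: GeneSet, log_transform: bool = False
) -> ExpressionMatrix:
    """Rows of ``em`` restricted to ``gs`` (which must already be intersected).

    With ``log_transform`` the values become log10(TPM + 1), the scale
    used to display expression of an overlapping gene subset across its
    most-affected tissues.
    """
    idx = [i for i, g in enumerate(em.gene_ids) if g in gs.genes]
    if not idx:
        raise EmptyGeneSetError(f"gene set {gs.name!r} selects no rows")
    vals = em.values[idx]
    if log_transform:
        vals = np.log10(vals + 1.0)
    return ExpressionMatrix(
        gene_ids=[em.gene_ids[i] for i in idx],
        tissue_ids=list(em.tissue_ids),
        values=vals,
    )
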