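"""Domain types and file IO shared by every pipeline stage.

Carries gene×sample expression matrices (dense TSV/CSV or Matrix Market
triplets), gene-set collections (GMT), antibody heavy/light chain records
(FASTA), RECIST response tables and per-cell annotations.  The canonical
expression orientation is genes in rows, samples in columns; all written
files are UTF-8 and tab-delimited with a header.

Gene-id matching throughout the package is exact, case-sensitive string
comparison; no symbol aliasing is attempted.  Missing values are rejected
at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "ResponseTable",
    "AntibodyRecord",
    "CellAnnotationTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sparse_counts",
    "recist_to_binary",
    "zscore_normalize",
    "read_gene_sets",
    "write_gene_sets",
    "read_chain_sequences",
    "read_response_table",
    "write_response_table",
    "read_cell_annotations",
    "write_cell_annotations",
]

RECIST_CATEGORIES = ("CR", "PR", "SD", "PD")
RESPONDER_CATEGORIES = frozenset({"CR", "PR"})
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: the 12 major tumor-microenvironment cell types used by the single-cell
#: branch's default vocabulary
DEFAULT_CELL_TYPES = (
    "B", "Plasma", "CD4T", "CD8T_Tex", "CD8T_Teff", "Tregs",
    "NK", "Mac_M1like", "Mac_M2like", "Mo", "DC", "Mast",
)


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes×samples real matrix with ordered, unique id lists."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, list(sample_ids),
                                self.values[:, cols])


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"genes in set {self.name!r}")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self):
        _check_unique([s.name for s in self.sets], "gene-set names")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sets:
            for g in s.genes:
                seen.setdefault(g, None)
        return list(seen)


@dataclass
class ResponseTable:
    """RECIST category per sample plus the derived binary responder label."""

    categories: dict[str, str]
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        bad = {s: c for s, c in self.categories.items()
               if c not in RECIST_CATEGORIES}
        if bad:
            raise ValidationError(f"unknown RECIST categories: {bad}")
        if not self.labels:
            self.labels = {s: int(c in RESPONDER_CATEGORIES)
                           for s, c in self.categories.items()}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.categories)

    def label_vector(self, sample_ids: list[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise ValidationError(f"samples without labels: {missing[:5]}")
        return np.array([self.labels[s] for s in sample_ids], dtype=np.int64)


@dataclass(frozen=True)
class AntibodyRecord:
    """An ICI antibody: drug name plus heavy- and light-chain sequences."""

    drug_name: str
    heavy_chain: str
    light_chain: str

    def __post_init__(self):
        for role, seq in (("heavy", self.heavy_chain),
                          ("light", self.light_chain)):
            if not seq:
                raise ValidationError(
                    f"{self.drug_name}: empty {role} chain")
            bad = set(seq.upper()) - AA_ALPHABET
            if bad:
                raise ValidationError(
                    f"{self.drug_name}: invalid residues {sorted(bad)} "
                    f"in {role} chain")


@dataclass
class CellAnnotationTable:
    """cell_id → (sample_id, cell type), type labels from a closed vocabulary."""

    cells: dict[str, tuple[str, str]]
    vocabulary: tuple[str, ...] = DEFAULT_CELL_TYPES

    def __post_init__(self):
        vocab = set(self.vocabulary)
        bad = {c: st for c, st in self.cells.items() if st[1] not in vocab}
        if bad:
            some = dict(list(bad.items())[:5])
            raise ValidationError(f"cell types outside vocabulary: {some}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.cells)

    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s, _ in self.cells.values():
            seen.setdefault(s, None)
        return list(seen)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path, orientation: str = "genes_in_rows",
                           sep: str | None = None) -> ExpressionMatrix:
    """Read a dense delimited expression table.

    ``orientation`` selects whether rows are genes (canonical) or samples;
    the returned matrix is always genes×samples.  Non-numeric cells and NA
    tokens are rejected with the offending row/column named.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False, na_values=[])
    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric value {raw!r} at row {df.index[i]!r}, "
                    f"column {col!r} in {path}") from None
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if orientation == "samples_in_rows":
        rows, cols, values = cols, rows, values.T
    return ExpressionMatrix(rows, cols, values)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids,
                      columns=matrix.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_sparse_counts(mtx_path, genes_path, cells_path,
                       densify: bool = True) -> ExpressionMatrix:
    """Read Matrix Market counts plus one-id-per-line gene/cell label files."""
    mat = scipy.io.mmread(mtx_path)
    with open(genes_path) as fh:
        genes = [ln.strip() for ln in fh if ln.strip()]
    with open(cells_path) as fh:
        cells = [ln.strip() for ln in fh if ln.strip()]
    if mat.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"matrix header {mat.shape} does not match label files "
            f"({len(genes)} genes, {len(cells)} cells)")
    values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                        dtype=np.float64)
    return ExpressionMatrix(genes, cells, values)


def write_sparse_counts(matrix: ExpressionMatrix, mtx_path, genes_path,
                        cells_path) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(matrix.values))
    with open(genes_path, "w") as fh:
        fh.write("\n".join(matrix.gene_ids) + "\n")
    with open(cells_path, "w") as fh:
        fh.write("\n".join(matrix.sample_ids) + "\n")


def recist_to_binary(categories: dict[str, str]) -> ResponseTable:
    """Map RECIST categories to binary labels: CR/PR → 1, SD/PD → 0.

    Categories are parsed case-insensitively; anything outside the four
    codes raises, naming the offending samples.
    """
    normalized = {}
    bad = {}
    for s, c in categories.items():
        cu = str(c).strip().upper()
        if cu in RECIST_CATEGORIES:
            normalized[s] = cu
        else:
            bad[s] = c
    if bad:
        raise ValidationError(f"unknown RECIST categories: {bad}")
    return ResponseTable(normalized)


def read_response_table(path) -> ResponseTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected sample_id + RECIST columns")
    return recist_to_binary(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_response_table(table: ResponseTable, path) -> None:
    df = pd.DataFrame({"sample_id": list(table.categories),
                       "recist": list(table.categories.values())})
    df.to_csv(path, sep="\t", index=False)


def zscore_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each sample column across its genes (ddof=1).

    A zero-variance column maps to all zeros; a single-gene matrix errors
    because the n−1 divisor is undefined.
    """
    if matrix.n_genes < 2:
        raise ValidationError(
            "z-scoring needs at least 2 genes (sample-sd divisor is n-1)")
    mu = matrix.values.mean(axis=0, keepdims=True)
    sd = matrix.values.std(axis=0, ddof=1, keepdims=True)
    out = np.zeros_like(matrix.values)
    nz = sd[0] > 0
    out[:, nz] = (matrix.values[:, nz] - mu[:, nz]) / sd[:, nz]
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), out)


def read_gene_sets(gmt_path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then tab-separated genes.

    Within-set duplicate genes are collapsed (order preserved); a line with
    fewer than three fields errors.
    """
    sets: list[GeneSet] = []
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{gmt_path}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}")
            name, desc = fields[0], fields[1]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets.append(GeneSet(name, tuple(genes), desc))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_chain_sequences(fasta_path) -> list[AntibodyRecord]:
    """Read paired heavy/light chains from FASTA.

    Headers must encode drug name and chain role as ``>DRUG|heavy`` or
    ``>DRUG|light``; a drug with only one chain errors.
    """
    chains: dict[str, dict[str, str]] = {}
    order: list[str] = []
    name = role = None
    seq_parts: list[str] = []

    def flush():
        if name is None:
            return
        chains.setdefault(name, {})
        if role in chains[name]:
            raise ValidationError(f"{name}: duplicate {role} chain")
        chains[name][role] = "".join(seq_parts)

    with open(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                parts = header.split("|")
                if len(parts) < 2 or parts[1].lower() not in ("heavy", "light"):
                    raise ValidationError(
                        f"FASTA header {header!r} must be 'drug|heavy' or "
                        f"'drug|light'")
                name, role = parts[0], parts[1].lower()
                if name not in chains:
                    order.append(name)
                seq_parts = []
            else:
                seq_parts.append(line)
    flush()
    records = []
    for drug in order:
        got = chains[drug]
        if set(got) != {"heavy", "light"}:
            raise ValidationError(
                f"{drug}: need both heavy and light chains, got {sorted(got)}")
        records.append(AntibodyRecord(drug, got["heavy"], got["light"]))
    return records


def write_chain_sequences(records: list[AntibodyRecord], path,
                          width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            for role, seq in (("heavy", rec.heavy_chain),
                              ("light", rec.light_chain)):
                fh.write(f">{rec.drug_name}|{role}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def read_cell_annotations(path, vocabulary=DEFAULT_CELL_TYPES
                          ) -> CellAnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_id", "sample_id", "cell_type"}.issubset(df.columns):
        raise ValidationError(
            f"{path}: need columns cell_id, sample_id, cell_type")
    _check_unique(list(df["cell_id"]), "cell ids")
    cells = {r.cell_id: (r.sample_id, r.cell_type)
             for r in df.itertuples(index=False)}
    return CellAnnotationTable(cells, tuple(vocabulary))


def write_cell_annotations(table: CellAnnotationTable, path) -> None:
    df = pd.DataFrame(
        [(c, s, t) for c, (s, t) in table.cells.items()],
        columns=["cell_id", "sample_id", "cell_type"])
    df.to_csv(path, sep="\t", index=False)
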