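"""Readers, writers and shared container types.

Expression data is held in a light-weight :class:`ExpressionMatrix` (cells ×
genes, dense ndarray or scipy sparse, plus ordered identifiers).  Ligand–
receptor interactions come from a CellChatDB-style CSV with columns
``ligand,receptor,pathway`` where multi-subunit units join gene symbols with
``"_"`` (e.g. ``Itga6_Itgb4``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

RAW_COUNTS = "raw_counts"
LOGNORM = "lognorm"


class FormatError(ValueError):
    """Malformed or inconsistent input file(s)."""


class ValidationError(ValueError):
    """Input parses but violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Cells × genes expression values with aligned identifiers.

    ``values`` may be a dense ndarray or any scipy sparse matrix; sparse
    input stays sparse (memory proportional to the number of nonzeros).
    ``layer_tag`` records whether the values are raw counts or
    log-normalized.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    layer_tag: str = RAW_COUNTS

    def __post_init__(self) -> None:
        if self.layer_tag not in (RAW_COUNTS, LOGNORM):
            raise ValidationError(f"unknown layer_tag {self.layer_tag!r}")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids):
            raise FormatError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise FormatError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell ids")
        mn = self.values.min() if not sp.issparse(self.values) else self.values.data.min(initial=0.0)
        if mn < 0:
            raise ValidationError("negative expression entries")

    # -- convenience ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def column(self, gene: str) -> np.ndarray:
        j = self.gene_index()[gene]
        col = self.values[:, j]
        if sp.issparse(col):
            return np.asarray(col.todense(), dtype=float).ravel()
        return np.asarray(col, dtype=float).ravel()


@dataclass(frozen=True)
class LRInteraction:
    ligand: str
    receptor: str
    pathway: str

    @property
    def ligand_subunits(self) -> tuple[str, ...]:
        return tuple(self.ligand.split("_"))

    @property
    def receptor_subunits(self) -> tuple[str, ...]:
        return tuple(self.receptor.split("_"))

    @property
    def name(self) -> str:
        return f"{self.ligand}-{self.receptor}"


@dataclass
class LRDatabase:
    interactions: list[LRInteraction]

    def __post_init__(self) -> None:
        seen = set()
        for it in self.interactions:
            for side in (it.ligand, it.receptor):
                if not side or any(s == "" for s in side.split("_")):
                    raise ValidationError(f"empty unit or subunit in {it}")
            key = (it.ligand, it.receptor)
            if key in seen:
                raise ValidationError(f"duplicate interaction {key}")
            seen.add(key)

    @property
    def ligand_units(self) -> list[str]:
        out, seen = [], set()
        for it in self.interactions:
            if it.ligand not in seen:
                seen.add(it.ligand)
                out.append(it.ligand)
        return out

    @property
    def receptor_units(self) -> list[str]:
        out, seen = [], set()
        for it in self.interactions:
            if it.receptor not in seen:
                seen.add(it.receptor)
                out.append(it.receptor)
        return out

    def genes(self) -> set[str]:
        g: set[str] = set()
        for it in self.interactions:
            g.update(it.ligand_subunits)
            g.update(it.receptor_subunits)
        return g

    def pathways(self) -> list[str]:
        out, seen = [], set()
        for it in self.interactions:
            if it.pathway not in seen:
                seen.add(it.pathway)
                out.append(it.pathway)
        return out


@dataclass
class SpatialCoords:
    cell_ids: list[str]
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (len(self.cell_ids), 2):
            raise FormatError("coordinates must be one (x, y) pair per cell")
        if not np.all(np.isfinite(self.xy)):
            raise ValidationError("non-finite coordinates")


@dataclass
class CellLabels:
    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.cell_ids) != len(self.labels):
            raise FormatError("one label per cell required")

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.labels))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(
    path_or_triplet: str | Path | Sequence[str | Path],
    layer_tag: str = RAW_COUNTS,
    *,
    sep: str | None = None,
    genes_are_rows: bool | None = None,
) -> ExpressionMatrix:
    """Read a dense CSV/TSV (cells as rows, gene header, first column cell
    ids) or a 10x-style triplet ``(matrix.mtx, genes.tsv, barcodes.tsv)``.

    Triplet orientation (gene-major vs cell-major) is auto-detected by
    matching the id-list lengths against the matrix shape; a square matrix
    is ambiguous and requires ``genes_are_rows``.
    """
    if isinstance(path_or_triplet, (str, Path)):
        p = Path(path_or_triplet)
        if sep is None:
            sep = "\t" if p.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(p, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        if np.any(values < 0):
            raise ValidationError(f"negative entries in {p}")
        return ExpressionMatrix(
            values=values,
            gene_ids=[str(g) for g in df.columns],
            cell_ids=[str(c) for c in df.index],
            layer_tag=layer_tag,
        )

    mtx_path, genes_path, barcodes_path = (Path(p) for p in path_or_triplet)
    mat = sp.csr_matrix(mmread(mtx_path))
    genes = _read_single_column(genes_path)
    barcodes = _read_single_column(barcodes_path)
    n_r, n_c = mat.shape
    if genes_are_rows is None:
        if n_r == n_c and len(genes) == len(barcodes) == n_r:
            raise FormatError(
                f"{mtx_path} is square with matching id lists; pass genes_are_rows"
            )
        if n_r == len(genes) and n_c == len(barcodes):
            genes_are_rows = True
        elif n_r == len(barcodes) and n_c == len(genes):
            genes_are_rows = False
        else:
            raise FormatError(
                f"{mtx_path} shape {mat.shape} matches neither {genes_path} "
                f"({len(genes)} genes) nor {barcodes_path} ({len(barcodes)} barcodes)"
            )
    if genes_are_rows:
        mat = mat.T.tocsr()
    if mat.shape != (len(barcodes), len(genes)):
        raise FormatError(
            f"{mtx_path} shape {mat.shape} inconsistent with id lists"
        )
    if mat.nnz and mat.data.min() < 0:
        raise ValidationError(f"negative entries in {mtx_path}")
    return ExpressionMatrix(mat, genes, barcodes, layer_tag)


def _read_single_column(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]


def write_expression(em: ExpressionMatrix, dest: str | Path, *, triplet: bool = False) -> None:
    """Write dense CSV (default) or a 10x-style triplet into directory ``dest``."""
    dest = Path(dest)
    if triplet:
        dest.mkdir(parents=True, exist_ok=True)
        mat = em.values if sp.issparse(em.values) else sp.csr_matrix(em.values)
        mmwrite(dest / "matrix.mtx", sp.coo_matrix(mat.T))  # gene-major, 10x style
        (dest / "genes.tsv").write_text("\n".join(em.gene_ids) + "\n")
        (dest / "barcodes.tsv").write_text("\n".join(em.cell_ids) + "\n")
    else:
        pd.DataFrame(em.dense(), index=em.cell_ids, columns=em.gene_ids).to_csv(dest)


def read_lr_database(path: str | Path, *, case_insensitive: bool = False) -> LRDatabase:
    """Read a ligand/receptor interaction CSV with columns ligand, receptor, pathway."""
    df = pd.read_csv(path)
    for col in ("ligand", "receptor", "pathway"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    rows: list[LRInteraction] = []
    seen = set()
    dupes = 0
    for lig, rec, pw in zip(df["ligand"], df["receptor"], df["pathway"]):
        if pd.isna(lig) or pd.isna(rec) or str(lig) == "" or str(rec) == "":
            raise ValidationError(f"{path}: empty ligand or receptor field")
        lig, rec = str(lig), str(rec)
        if case_insensitive:
            lig, rec = lig.capitalize(), rec.capitalize()
        key = (lig, rec)
        if key in seen:
            dupes += 1
            continue
        seen.add(key)
        rows.append(LRInteraction(lig, rec, str(pw)))
    if dupes:
        logger.warning("%s: collapsed %d duplicated interaction rows", path, dupes)
    return LRDatabase(rows)


def read_coords(path: str | Path) -> SpatialCoords:
    df = pd.read_csv(path)
    for col in ("cell_id", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return SpatialCoords(
        cell_ids=[str(c) for c in df["cell_id"]],
        xy=df[["x", "y"]].to_numpy(dtype=float),
    )


def read_labels(path: str | Path) -> CellLabels:
    df = pd.read_csv(path)
    for col in ("cell_id", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return CellLabels([str(c) for c in df["cell_id"]], [str(l) for l in df["label"]])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def drop_empty_cells(em: ExpressionMatrix) -> ExpressionMatrix:
    """Remove cells with zero total count (warned), leaving others untouched."""
    totals = np.asarray(em.values.sum(axis=1)).ravel()
    keep = totals > 0
    if keep.all():
        return em
    dropped = [c for c, k in zip(em.cell_ids, keep) if not k]
    warnings.warn(f"dropping {len(dropped)} zero-count cells: {dropped[:5]}...")
    vals = em.values[keep] if not sp.issparse(em.values) else em.values[np.where(keep)[0]]
    return ExpressionMatrix(
        vals, em.gene_ids, [c for c, k in zip(em.cell_ids, keep) if k], em.layer_tag
    )


def lognormalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell to the median total count, then apply log1p.

    Every output entry equals ``log1p(raw * median_total / cell_total)``.
    """
    if em.layer_tag != RAW_COUNTS:
        raise ValidationError("lognormalize expects raw counts")
    totals = np.asarray(em.values.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = [c for c, t in zip(em.cell_ids, totals) if t == 0]
        raise ValidationError(f"cells with zero total count: {bad}")
    median_total = float(np.median(totals))
    factors = median_total / totals
    if sp.issparse(em.values):
        out = sp.csr_matrix(em.values, dtype=float, copy=True)
        out = sp.diags(factors) @ out
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(em.values * factors[:, None])
    return ExpressionMatrix(out, list(em.gene_ids), list(em.cell_ids), LOGNORM)
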