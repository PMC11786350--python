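"""Readers and writers for the plain-text formats the pipeline exchanges.

Count matrices travel as Matrix Market (.mtx) with `<stem>_genes.txt` /
`<stem>_spots.txt` identifier sidecars, or as dense CSV/TSV with gene ids
in the first column and spot ids in the header. Orientation is fixed:
genes in rows, spots in columns (a transpose flag covers the other
dialect). Coordinate tables are CSV/TSV with columns ``spot_id, x, y`` and
optional ``pixel_row, pixel_col``. Graphs are three-column edge lists with
metadata in '#' comment lines.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .geometry import SpotGeometry
from .graph import SpatialGraph
from .solver import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts",
    "read_coords",
    "read_image",
    "read_graph",
    "write_graph",
    "select_variable_genes",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_counts(
    path,
    fmt: str | None = None,
    transpose: bool = False,
    drop_empty: bool = True,
) -> ExpressionMatrix:
    """Read a genes-by-spots count matrix.

    ``fmt`` is one of ``matrix-market``, ``csv``, ``tsv``; when ``None`` it
    is inferred from the suffix. All-zero rows/columns are dropped with a
    logged count; negative entries are an error naming the offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"counts file not found: {path}")
    if fmt is None:
        fmt = {
            ".mtx": "matrix-market",
            ".csv": "csv",
            ".tsv": "tsv",
        }.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer counts format from {path.name!r}")

    if fmt == "matrix-market":
        mat = scipy.io.mmread(path)
        X = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
        stem = path.with_suffix("")
        gene_file = Path(f"{stem}_genes.txt")
        spot_file = Path(f"{stem}_spots.txt")
        for f in (gene_file, spot_file):
            if not f.exists():
                raise FileNotFoundError(f"missing sidecar file: {f}")
        gene_ids = np.loadtxt(gene_file, dtype=str, ndmin=1)
        spot_ids = np.loadtxt(spot_file, dtype=str, ndmin=1)
    else:
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        X = df.to_numpy(dtype=float)
        gene_ids = df.index.to_numpy(dtype=str)
        spot_ids = df.columns.to_numpy(dtype=str)

    if transpose:
        X = X.T
        gene_ids, spot_ids = spot_ids, gene_ids
    if X.shape != (len(gene_ids), len(spot_ids)):
        raise ValueError(
            f"sidecar mismatch: matrix {X.shape}, {len(gene_ids)} genes, "
            f"{len(spot_ids)} spots"
        )
    em = ExpressionMatrix(X, gene_ids, spot_ids)
    return em.drop_empty() if drop_empty else em


def write_counts(path, em: ExpressionMatrix, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = {".mtx": "matrix-market", ".csv": "csv", ".tsv": "tsv"}.get(
            path.suffix.lower()
        )
        if fmt is None:
            raise ValueError(f"cannot infer counts format from {path.name!r}")
    if fmt == "matrix-market":
        scipy.io.mmwrite(path, sp.coo_matrix(em.X))
        stem = path.with_suffix("")
        np.savetxt(f"{stem}_genes.txt", em.gene_ids, fmt="%s")
        np.savetxt(f"{stem}_spots.txt", em.spot_ids, fmt="%s")
    else:
        sep = "\t" if fmt == "tsv" else ","
        pd.DataFrame(em.X, index=em.gene_ids, columns=em.spot_ids).to_csv(
            path, sep=sep
        )


def read_coords(path) -> tuple[SpotGeometry, np.ndarray | None]:
    """Read a spot coordinate table.

    Returns the geometry (intensity unset) and, when ``pixel_row`` /
    ``pixel_col`` columns are present, the per-spot pixel centres for
    histology intensity extraction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"coordinates file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"spot_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coordinate table missing columns: {sorted(missing)}")
    geom = SpotGeometry(
        spot_ids=df["spot_id"].to_numpy(dtype=str),
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
    )
    centers = None
    if {"pixel_row", "pixel_col"} <= set(df.columns):
        centers = df[["pixel_row", "pixel_col"]].to_numpy(dtype=int)
    return geom, centers


def read_image(path) -> np.ndarray:
    """Load a histology image as a 2-D grey-scale array.

    RGB(A) images are converted by the standard luminance weighting
    0.2126 R + 0.7152 G + 0.0722 B; the native integer dtype is preserved
    for grey input so downstream rescaling can use the dtype maximum.
    """
    import imageio.v3 as iio

    img = iio.imread(Path(path))
    if img.ndim == 3:
        rgb = np.asarray(img[..., :3], dtype=float)
        grey = rgb @ np.array([0.2126, 0.7152, 0.0722])
        if np.issubdtype(img.dtype, np.integer):
            grey = grey / float(np.iinfo(img.dtype).max)
        return grey
    return np.asarray(img)


def write_graph(path, graph: SpatialGraph, spot_ids=None) -> None:
    """Write a graph as an edge-list TSV (``.mtx`` writes Matrix Market)."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        scipy.io.mmwrite(path, graph.G.tocoo())
        return
    coo = sp.triu(graph.G, k=1).tocoo()
    ids = (
        np.asarray(spot_ids)
        if spot_ids is not None
        else np.arange(graph.n_spots).astype(str)
    )
    with open(path, "w") as fh:
        fh.write(f"# k={graph.k}\n# beta={graph.beta!r}\n# n_spots={graph.n_spots}\n")
        fh.write("spot_i\tspot_j\tweight\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{ids[i]}\t{ids[j]}\t{float(w)!r}\n")


def read_graph(path, spot_ids=None) -> SpatialGraph:
    """Read a graph written by :func:`write_graph` and rebuild D and L."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        G = sp.csr_matrix(scipy.io.mmread(path))
        meta = {}
    else:
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        rows = []
        for line in lines:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif not line.startswith("spot_i"):
                rows.append(line.rstrip("\n").split("\t"))
        n = int(meta["n_spots"])
        ids = (
            list(np.asarray(spot_ids, dtype=str))
            if spot_ids is not None
            else [str(i) for i in range(n)]
        )
        index = {s: i for i, s in enumerate(ids)}
        ii = [index[r[0]] for r in rows]
        jj = [index[r[1]] for r in rows]
        ww = [float(r[2]) for r in rows]
        G = sp.csr_matrix((ww + ww, (ii + jj, jj + ii)), shape=(n, n))
    deg = np.asarray(G.sum(axis=1)).ravel()
    D = sp.diags(deg, format="csr")
    return SpatialGraph(
        G=G,
        D=D,
        L=(D - G).tocsr(),
        k=int(meta.get("k", 0)),
        beta=float(meta.get("beta", 0.0)),
    )


def select_variable_genes(em: ExpressionMatrix, n: int) -> np.ndarray:
    """Indices of the ``n`` most variable genes by standardized log-dispersion.

    Dispersion (variance / mean) is computed per gene, log-transformed and
    z-scored within 20 equal-frequency bins of mean expression, so highly
    expressed genes do not dominate the ranking. Deterministic; ties keep
    the original gene order.
    """
    if n > em.n_genes:
        raise ValueError(f"requested {n} genes but matrix has {em.n_genes}")
    X = em.X
    mean = X.mean(axis=1)
    var = X.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
        log_disp = np.where(disp > 0, np.log(disp), -np.inf)

    # ~20 genes per bin; small panels fall back to a single global bin
    n_bins = min(20, max(1, em.n_genes // 20))
    quantiles = np.quantile(mean, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(quantiles, mean, side="right") - 1, 0, n_bins - 1)
    score = np.full(em.n_genes, -np.inf)
    for b in range(n_bins):
        mask = (bins == b) & np.isfinite(log_disp)
        if not mask.any():
            continue
        mu, sd = log_disp[mask].mean(), log_disp[mask].std()
        score[mask] = (log_disp[mask] - mu) / sd if sd > 0 else 0.0
    order = np.argsort(-score, kind="stable")
    return np.sort(order[:n])
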