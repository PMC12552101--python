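"""Reading, writing and preprocessing of spliced/unspliced expression data.

The central container is :class:`OmicsDataset`: aligned cell-by-gene
spliced (S) and unspliced (U) matrices, optionally a second modality
(O, e.g. chromatin accessibility) measured on the same cells, plus
identifiers, labels and a 2-D embedding.  Three on-disk formats are
supported: AnnData ``.h5ad``, loom, and a MatrixMarket directory
(CellRanger-style genes x cells orientation on disk).

Preprocessing follows the convention of velocity tooling: per-cell
size-factor normalization of each layer to the median total, selection
of the most variable genes by spliced dispersion, and first-order
moment smoothing of S and U over a KNN graph built on principal
components of the normalized, log1p spliced matrix.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite
from scipy.spatial.distance import cdist

from .errors import ConfigError, DataError

__all__ = [
    "OmicsDataset",
    "PreprocessConfig",
    "read_dataset",
    "write_dataset",
    "preprocess",
]


def _densify(M) -> np.ndarray:
    if sparse.issparse(M):
        M = M.toarray()
    return np.asarray(M, dtype=np.float64)


@dataclass
class OmicsDataset:
    """Aligned spliced/unspliced (and optional second-modality) matrices.

    S and U are n_cells x n_genes and share cell and gene ordering; O
    (if present) is n_cells x n_features on the same cells.  All
    entries must be nonnegative.
    """

    S: np.ndarray
    U: np.ndarray
    cell_ids: list
    gene_ids: list
    O: Optional[np.ndarray] = None
    cell_labels: Optional[list] = None
    embedding: Optional[np.ndarray] = None

    def __post_init__(self):
        self.S = _densify(self.S)
        self.U = _densify(self.U)
        if self.O is not None:
            self.O = _densify(self.O)
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.cell_labels is not None:
            self.cell_labels = [str(c) for c in self.cell_labels]
        self.validate()

    # ------------------------------------------------------------------
    def validate(self):
        if self.S.shape != self.U.shape:
            raise DataError(
                f"shape-mismatch: S {self.S.shape} vs U {self.U.shape}")
        n, p = self.S.shape
        if len(self.cell_ids) != n:
            raise DataError("shape-mismatch: cell_ids length != n_cells")
        if len(self.gene_ids) != p:
            raise DataError("shape-mismatch: gene_ids length != n_genes")
        if self.O is not None and self.O.shape[0] != n:
            raise DataError("shape-mismatch: O cell dimension != n_cells")
        if self.cell_labels is not None and len(self.cell_labels) != n:
            raise DataError("shape-mismatch: cell_labels length != n_cells")
        if self.embedding is not None and self.embedding.shape[0] != n:
            raise DataError("shape-mismatch: embedding rows != n_cells")
        for name, M in (("S", self.S), ("U", self.U), ("O", self.O)):
            if M is not None and np.any(M < 0):
                raise DataError(f"negative-entries in {name}")

    @property
    def n_cells(self) -> int:
        return self.S.shape[0]

    @property
    def n_genes(self) -> int:
        return self.S.shape[1]

    @property
    def n_features(self) -> int:
        """Total model input width m = 2p (+h when O is present)."""
        h = 0 if self.O is None else self.O.shape[1]
        return 2 * self.n_genes + h

    @property
    def X(self) -> np.ndarray:
        """Concatenated input matrix (S, U) or (S, U, O), n x m."""
        parts = [self.S, self.U]
        if self.O is not None:
            parts.append(self.O)
        return np.concatenate(parts, axis=1)

    def subset_cells(self, idx) -> "OmicsDataset":
        idx = np.asarray(idx)
        return OmicsDataset(
            S=self.S[idx],
            U=self.U[idx],
            O=None if self.O is None else self.O[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            cell_labels=None if self.cell_labels is None
            else [self.cell_labels[i] for i in idx],
            embedding=None if self.embedding is None else self.embedding[idx],
        )

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.S.copy(),
            layers={"spliced": self.S.copy(), "unspliced": self.U.copy()},
        )
        adata.obs_names = list(self.cell_ids)
        adata.var_names = list(self.gene_ids)
        if self.cell_labels is not None:
            adata.obs["cell_type"] = pd.Categorical(self.cell_labels)
        if self.embedding is not None:
            adata.obsm["X_emb"] = self.embedding.copy()
        if self.O is not None:
            adata.obsm["X_modality"] = self.O.copy()
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "OmicsDataset":
        layers = adata.layers
        for name in ("spliced", "unspliced"):
            if name not in layers:
                raise DataError(f"layer-missing: {name}")
        S = _densify(layers["spliced"])
        U = _densify(layers["unspliced"])
        if S.shape != U.shape:
            raise DataError(
                f"shape-mismatch: spliced {S.shape} vs unspliced {U.shape}")
        return cls(
            S=S,
            U=U,
            O=_densify(adata.obsm["X_modality"])
            if "X_modality" in adata.obsm else None,
            cell_ids=list(adata.obs_names),
            gene_ids=list(adata.var_names),
            cell_labels=list(adata.obs["cell_type"])
            if "cell_type" in adata.obs else None,
            embedding=np.asarray(adata.obsm["X_emb"], dtype=np.float64)
            if "X_emb" in adata.obsm else None,
        )


@dataclass
class PreprocessConfig:
    n_top_genes: int = 2000
    knn_k: int = 30
    normalize: bool = True
    log1p_modality_O: bool = True
    n_pcs: int = 30

    def __post_init__(self):
        if self.n_top_genes < 2:
            raise ConfigError("n_top_genes must be >= 2")
        if self.knn_k < 1:
            raise ConfigError("knn_k must be >= 1")


# ======================================================================
# Format IO
# ======================================================================

def read_dataset(path: str, format: Optional[str] = None) -> OmicsDataset:
    """Read a dataset from h5ad, loom or an MTX directory.

    When `format` is omitted it is inferred from the path.
    """
    fmt = format or _infer_format(path)
    if fmt == "h5ad":
        return _read_h5ad(path)
    if fmt == "loom":
        return _read_loom(path)
    if fmt == "mtx_dir":
        return _read_mtx_dir(path)
    raise ConfigError(f"unknown-format: {fmt}")


def write_dataset(ds: OmicsDataset, path: str, format: Optional[str] = None):
    fmt = format or _infer_format(path)
    if ds.n_cells == 0:
        raise DataError("empty-dataset")
    if fmt == "h5ad":
        ds.to_anndata().write_h5ad(path)
    elif fmt == "loom":
        _write_loom(ds, path)
    elif fmt == "mtx_dir":
        _write_mtx_dir(ds, path)
    else:
        raise ConfigError(f"unknown-format: {fmt}")


def _infer_format(path: str) -> str:
    if str(path).endswith(".h5ad"):
        return "h5ad"
    if str(path).endswith(".loom"):
        return "loom"
    return "mtx_dir"


def _read_h5ad(path: str) -> OmicsDataset:
    import anndata as ad

    return OmicsDataset.from_anndata(ad.read_h5ad(path))


# Loom files are HDF5 with a fixed layout (genes are rows on disk);
# read/written directly through h5py.
def _read_loom(path: str) -> OmicsDataset:
    import h5py

    with h5py.File(path, "r") as f:
        if "layers" not in f or "spliced" not in f["layers"]:
            raise DataError("layer-missing: spliced")
        if "unspliced" not in f["layers"]:
            raise DataError("layer-missing: unspliced")
        S = np.asarray(f["layers/spliced"], dtype=np.float64).T
        U = np.asarray(f["layers/unspliced"], dtype=np.float64).T
        if S.shape != U.shape:
            raise DataError(
                f"shape-mismatch: spliced {S.T.shape} vs unspliced {U.T.shape}")
        gene_ids = [g.decode() if isinstance(g, bytes) else str(g)
                    for g in f["row_attrs/Gene"][:]]
        cell_ids = [c.decode() if isinstance(c, bytes) else str(c)
                    for c in f["col_attrs/CellID"][:]]
        labels = None
        if "col_attrs" in f and "ClusterName" in f["col_attrs"]:
            labels = [c.decode() if isinstance(c, bytes) else str(c)
                      for c in f["col_attrs/ClusterName"][:]]
        O = None
        if "modality" in f:
            O = np.asarray(f["modality/matrix"], dtype=np.float64).T
        embedding = None
        if "col_attrs" in f and "Embedding" in f["col_attrs"]:
            embedding = np.asarray(f["col_attrs/Embedding"], dtype=np.float64)
    return OmicsDataset(S=S, U=U, O=O, cell_ids=cell_ids, gene_ids=gene_ids,
                        cell_labels=labels, embedding=embedding)


def _write_loom(ds: OmicsDataset, path: str):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=ds.S.T)
        f.create_dataset("layers/spliced", data=ds.S.T)
        f.create_dataset("layers/unspliced", data=ds.U.T)
        str_dt = h5py.string_dtype()
        f.create_dataset("row_attrs/Gene",
                         data=np.array(ds.gene_ids, dtype=object), dtype=str_dt)
        f.create_dataset("col_attrs/CellID",
                         data=np.array(ds.cell_ids, dtype=object), dtype=str_dt)
        if ds.cell_labels is not None:
            f.create_dataset("col_attrs/ClusterName",
                             data=np.array(ds.cell_labels, dtype=object),
                             dtype=str_dt)
        if ds.embedding is not None:
            f.create_dataset("col_attrs/Embedding", data=ds.embedding)
        if ds.O is not None:
            f.create_dataset("modality/matrix", data=ds.O.T)


def _read_mtx_dir(path: str) -> OmicsDataset:
    sp = os.path.join(path, "spliced.mtx")
    up = os.path.join(path, "unspliced.mtx")
    if not os.path.exists(sp):
        raise DataError("layer-missing: spliced")
    if not os.path.exists(up):
        raise DataError("layer-missing: unspliced")
    # genes x cells on disk (CellRanger convention), transposed on read
    S = _densify(mmread(sp)).T
    U = _densify(mmread(up)).T
    if S.shape != U.shape:
        raise DataError(
            f"shape-mismatch: spliced {S.shape} vs unspliced {U.shape}")
    genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", header=None)
    barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t",
                           header=None)
    labels = (list(barcodes[1].astype(str))
              if barcodes.shape[1] > 1 else None)
    O = None
    mp = os.path.join(path, "modality.mtx")
    if os.path.exists(mp):
        O = _densify(mmread(mp)).T
    embedding = None
    ep = os.path.join(path, "embedding.tsv")
    if os.path.exists(ep):
        embedding = pd.read_csv(ep, sep="\t", header=None).to_numpy(float)
    return OmicsDataset(S=S, U=U, O=O,
                        cell_ids=list(barcodes[0].astype(str)),
                        gene_ids=list(genes[0].astype(str)),
                        cell_labels=labels, embedding=embedding)


def _write_mtx_dir(ds: OmicsDataset, path: str):
    os.makedirs(path, exist_ok=True)
    mmwrite(os.path.join(path, "spliced.mtx"), sparse.coo_matrix(ds.S.T))
    mmwrite(os.path.join(path, "unspliced.mtx"), sparse.coo_matrix(ds.U.T))
    pd.DataFrame({0: ds.gene_ids}).to_csv(
        os.path.join(path, "genes.tsv"), sep="\t", header=False, index=False)
    bc = {0: ds.cell_ids}
    if ds.cell_labels is not None:
        bc[1] = ds.cell_labels
    pd.DataFrame(bc).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False)
    if ds.O is not None:
        mmwrite(os.path.join(path, "modality.mtx"), sparse.coo_matrix(ds.O.T))
        pd.DataFrame({0: [f"feat_{j}" for j in range(ds.O.shape[1])]}).to_csv(
            os.path.join(path, "features.tsv"), sep="\t", header=False,
            index=False)
    if ds.embedding is not None:
        pd.DataFrame(ds.embedding).to_csv(
            os.path.join(path, "embedding.tsv"), sep="\t", header=False,
            index=False)


# ======================================================================
# Preprocessing
# ======================================================================

def _size_factor_normalize(M: np.ndarray) -> np.ndarray:
    """Scale each cell so its total matches the median total."""
    totals = M.sum(axis=1)
    median = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    sf = np.where(totals > 0, totals / median, 1.0)
    return M / sf[:, None]


def knn_indices(X: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest cells (including self), deterministic.

    Euclidean metric; ties are broken by cell index (stable sort), so
    the graph is reproducible regardless of backend threading.
    """
    D = cdist(X, X)
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]


def _pca(X: np.ndarray, n_comps: int) -> np.ndarray:
    Xc = X - X.mean(axis=0, keepdims=True)
    # deterministic full SVD; scale is small (<= a few thousand cells)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return U[:, :n_comps] * s[:n_comps]


def preprocess(ds: OmicsDataset, cfg: PreprocessConfig | None = None
               ) -> OmicsDataset:
    """Normalize, select variable genes and KNN-smooth S and U.

    Steps (each switchable through `cfg`):

    1. per-cell size-factor normalization of S and U to the median total;
    2. restriction to the `n_top_genes` most variable genes by spliced
       dispersion (variance/mean on the normalized spliced matrix);
    3. first-order moment smoothing: S and U replaced by the mean over
       each cell's `knn_k` nearest neighbors (self included) on a PCA/
       Euclidean graph of the normalized, log1p spliced matrix;
    4. O normalized and log1p-transformed.

    Fully deterministic: no randomized solver is involved.
    """
    cfg = cfg or PreprocessConfig()
    n, p = ds.S.shape
    if cfg.knn_k >= n:
        raise ConfigError(f"knn-too-large: knn_k={cfg.knn_k} >= n={n}")

    S = _size_factor_normalize(ds.S) if cfg.normalize else ds.S.copy()
    U = _size_factor_normalize(ds.U) if cfg.normalize else ds.U.copy()

    # variable-gene selection by spliced dispersion
    gene_idx = np.arange(p)
    if cfg.n_top_genes < p:
        mean = S.mean(axis=0)
        var = S.var(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            dispersion = np.where(mean > 0, var / mean, -np.inf)
        gene_idx = np.sort(
            np.argsort(-dispersion, kind="stable")[: cfg.n_top_genes])
    else:
        if cfg.n_top_genes > p:
            warnings.warn(
                f"n_top_genes={cfg.n_top_genes} exceeds the {p} available "
                "genes; keeping all genes")
    S = S[:, gene_idx]
    U = U[:, gene_idx]

    # KNN moment smoothing on PCA of log1p spliced expression
    n_comps = min(cfg.n_pcs, n - 1, S.shape[1])
    pcs = _pca(np.log1p(S), n_comps)
    nbrs = knn_indices(pcs, cfg.knn_k)
    S_smooth = S[nbrs].mean(axis=1)
    U_smooth = U[nbrs].mean(axis=1)

    O = ds.O
    if O is not None:
        O = _size_factor_normalize(O) if cfg.normalize else O.copy()
        if cfg.log1p_modality_O:
            O = np.log1p(O)

    return OmicsDataset(
        S=S_smooth,
        U=U_smooth,
        O=O,
        cell_ids=list(ds.cell_ids),
        gene_ids=[ds.gene_ids[j] for j in gene_idx],
        cell_labels=None if ds.cell_labels is None else list(ds.cell_labels),
        embedding=None if ds.embedding is None else ds.embedding.copy(),
    )
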