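"""Loading, normalization and gene filtering for spliced/unspliced datasets.

The canonical in-memory container is :class:`VelocityDataset`: paired
unspliced (U) and spliced (S) cell×gene matrices with optional 2-D tissue
coordinates and per-cell labels.  Supported on-disk formats are AnnData
``.h5ad`` (layers ``"spliced"``/``"unspliced"``, coordinates in
``obsm["spatial"]``) and Matrix Market pairs with CSV sidecars.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class MissingLayerError(KeyError):
    """A required count layer is absent from the input file."""


class ShapeMismatchError(ValueError):
    """U and S (or a sidecar) disagree in shape."""


@dataclasses.dataclass
class VelocityDataset:
    """Paired unspliced/spliced abundances with optional spatial context."""

    U: np.ndarray
    S: np.ndarray
    gene_names: np.ndarray
    cell_ids: np.ndarray
    spatial_coords: np.ndarray | None = None
    cell_labels: np.ndarray | None = None

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=np.float64)
        self.S = np.asarray(self.S, dtype=np.float64)
        self.gene_names = np.asarray(self.gene_names)
        self.cell_ids = np.asarray(self.cell_ids)
        self.validate()

    # -- invariants -----------------------------------------------------------
    def validate(self):
        if self.U.shape != self.S.shape:
            raise ShapeMismatchError(
                f"U {self.U.shape} and S {self.S.shape} must have identical shape"
            )
        if not (np.all(np.isfinite(self.U)) and np.all(np.isfinite(self.S))):
            raise ValueError("U and S must be finite")
        if (self.U < 0).any() or (self.S < 0).any():
            raise ValueError("U and S must be non-negative")
        n, g = self.U.shape
        if len(self.gene_names) != g:
            raise ShapeMismatchError("gene_names length must match gene dimension")
        if len(self.cell_ids) != n:
            raise ShapeMismatchError("cell_ids length must match cell dimension")
        if len(set(map(str, self.gene_names))) != g:
            raise ValueError("gene_names must be unique")
        if len(set(map(str, self.cell_ids))) != n:
            raise ValueError("cell_ids must be unique")
        if self.spatial_coords is not None:
            self.spatial_coords = np.asarray(self.spatial_coords, dtype=np.float64)
            if self.spatial_coords.shape != (n, 2):
                raise ShapeMismatchError("spatial_coords must be cells×2")
        if self.cell_labels is not None:
            self.cell_labels = np.asarray(self.cell_labels)
            if len(self.cell_labels) != n:
                raise ShapeMismatchError("cell_labels length must match cells")

    @property
    def n_cells(self) -> int:
        return self.U.shape[0]

    @property
    def n_genes(self) -> int:
        return self.U.shape[1]

    def subset_genes(self, idx) -> "VelocityDataset":
        idx = np.asarray(idx)
        return VelocityDataset(
            U=self.U[:, idx],
            S=self.S[:, idx],
            gene_names=self.gene_names[idx],
            cell_ids=self.cell_ids,
            spatial_coords=self.spatial_coords,
            cell_labels=self.cell_labels,
        )


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def load_dataset(path, format: str = "h5ad") -> VelocityDataset:
    """Load a dataset from ``.h5ad`` or an MTX+CSV directory.

    For ``format="mtx+csv"``, ``path`` is a directory containing
    ``unspliced.mtx``, ``spliced.mtx``, ``cells.csv`` (column ``cell_id``,
    optional ``x``/``y``/``label``) and ``genes.csv`` (column ``gene_name``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        for layer in ("spliced", "unspliced"):
            if layer not in adata.layers:
                raise MissingLayerError(f"missing-layer: '{layer}' not in {path.name}")
        coords = None
        if "spatial" in adata.obsm:
            coords = np.asarray(adata.obsm["spatial"])[:, :2]
        labels = None
        for key in ("cell_type", "labels", "label"):
            if key in adata.obs:
                labels = adata.obs[key].to_numpy()
                break
        return VelocityDataset(
            U=_dense(adata.layers["unspliced"]),
            S=_dense(adata.layers["spliced"]),
            gene_names=adata.var_names.to_numpy(),
            cell_ids=adata.obs_names.to_numpy(),
            spatial_coords=coords,
            cell_labels=labels,
        )
    if format == "mtx+csv":
        U = _dense(scipy.io.mmread(path / "unspliced.mtx"))
        S = _dense(scipy.io.mmread(path / "spliced.mtx"))
        if U.shape != S.shape:
            raise ShapeMismatchError(
                f"shape-mismatch: unspliced {U.shape} vs spliced {S.shape}"
            )
        cells = pd.read_csv(path / "cells.csv")
        genes = pd.read_csv(path / "genes.csv")
        coords = None
        if {"x", "y"}.issubset(cells.columns):
            coords = cells[["x", "y"]].to_numpy(dtype=float)
        labels = cells["label"].to_numpy() if "label" in cells.columns else None
        return VelocityDataset(
            U=U,
            S=S,
            gene_names=genes["gene_name"].to_numpy(),
            cell_ids=cells["cell_id"].to_numpy(),
            spatial_coords=coords,
            cell_labels=labels,
        )
    raise ValueError(f"unknown format {format!r}")


def save_dataset(data: VelocityDataset, path, format: str = "h5ad") -> None:
    """Write a dataset in either supported format (inverse of load_dataset)."""
    path = Path(path)
    if format == "h5ad":
        to_anndata(data).write_h5ad(path)
        return
    if format == "mtx+csv":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "unspliced.mtx"), sp.coo_matrix(data.U))
        scipy.io.mmwrite(str(path / "spliced.mtx"), sp.coo_matrix(data.S))
        cells = pd.DataFrame({"cell_id": data.cell_ids})
        if data.spatial_coords is not None:
            cells["x"] = data.spatial_coords[:, 0]
            cells["y"] = data.spatial_coords[:, 1]
        if data.cell_labels is not None:
            cells["label"] = data.cell_labels
        cells.to_csv(path / "cells.csv", index=False)
        pd.DataFrame({"gene_name": data.gene_names}).to_csv(
            path / "genes.csv", index=False
        )
        return
    raise ValueError(f"unknown format {format!r}")


def to_anndata(data: VelocityDataset):
    import anndata

    adata = anndata.AnnData(
        X=data.S.copy(),
        layers={"spliced": data.S.copy(), "unspliced": data.U.copy()},
    )
    adata.obs_names = pd.Index(data.cell_ids.astype(str))
    adata.var_names = pd.Index(data.gene_names.astype(str))
    if data.spatial_coords is not None:
        adata.obsm["spatial"] = data.spatial_coords.copy()
    if data.cell_labels is not None:
        adata.obs["cell_type"] = pd.Categorical(data.cell_labels.astype(str))
    return adata


def normalize_dataset(data: VelocityDataset, mode: str = "size_factor"):
    """Per-cell median size-factor normalization of U and S jointly.

    The factor for cell i is median(total) / total_i where total is the sum
    of U and S counts; both layers are multiplied by the factor, bringing
    every cell to the median depth while staying on an approximately
    count-scale axis.  Cells with zero total get factor 1 and are reported.

    Returns
    -------
    (normalized dataset, per-cell factors, list of zero-count cell indices)
    """
    if mode == "none":
        return data, np.ones(data.n_cells), []
    if mode != "size_factor":
        raise ValueError(f"unknown mode {mode!r}")
    totals = data.U.sum(axis=1) + data.S.sum(axis=1)
    zero_cells = np.nonzero(totals == 0)[0].tolist()
    median = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    factors = np.where(totals > 0, median / np.maximum(totals, 1e-300), 1.0)
    out = VelocityDataset(
        U=data.U * factors[:, None],
        S=data.S * factors[:, None],
        gene_names=data.gene_names,
        cell_ids=data.cell_ids,
        spatial_coords=data.spatial_coords,
        cell_labels=data.cell_labels,
    )
    return out, factors, zero_cells


def log_features(data: VelocityDataset, genes=None) -> np.ndarray:
    """log1p(U)‖log1p(S) node-feature matrix over a gene subset."""
    U, S = data.U, data.S
    if genes is not None:
        genes = np.asarray(genes)
        U, S = U[:, genes], S[:, genes]
    return np.concatenate([np.log1p(U), np.log1p(S)], axis=1)


def select_hvg(data: VelocityDataset, n_top: int) -> np.ndarray:
    """Top genes by dispersion (variance/mean of log1p S); ties and rank by
    descending dispersion then ascending gene index, so selection is
    deterministic."""
    g = data.n_genes
    if n_top > g:
        raise ValueError(f"n_top={n_top} exceeds number of genes {g}")
    logS = np.log1p(data.S)
    mean = logS.mean(axis=0)
    var = logS.var(axis=0)
    dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.lexsort((np.arange(g), -dispersion))
    return np.sort(order[:n_top])


def filter_informative_genes(
    data: VelocityDataset,
    coarse_groups=None,
    min_cells_frac: float = 0.03,
    min_u: float = 10.0,
    r_min: float = 0.1,
) -> np.ndarray:
    """Keep genes with usable splicing signal.

    A gene passes if it is expressed (S>0) in at least ``min_cells_frac`` of
    cells, has total unspliced count ≥ ``min_u``, has nonzero variance in
    both U and S, and |Pearson r(U, S)| across cells ≥ ``r_min``.
    ``coarse_groups`` is accepted for API symmetry (the stage-1 grouping is
    what makes the filtered set regime-agnostic) but the filters themselves
    pool all cells.
    """
    n = data.n_cells
    min_cells = max(1, int(np.ceil(min_cells_frac * n)))
    expressed = (data.S > 0).sum(axis=0) >= min_cells
    enough_u = data.U.sum(axis=0) >= min_u
    var_ok = (data.U.var(axis=0) > 0) & (data.S.var(axis=0) > 0)
    keep = expressed & enough_u & var_ok
    # Pearson correlation only where variances are positive
    r = np.zeros(data.n_genes)
    if keep.any():
        Uc = data.U[:, keep] - data.U[:, keep].mean(axis=0)
        Sc = data.S[:, keep] - data.S[:, keep].mean(axis=0)
        num = (Uc * Sc).sum(axis=0)
        den = np.sqrt((Uc ** 2).sum(axis=0) * (Sc ** 2).sum(axis=0))
        r[keep] = num / np.maximum(den, 1e-300)
    keep &= np.abs(r) >= r_min
    idx = np.nonzero(keep)[0]
    if idx.size == 0:
        raise ValueError(
            "no genes survive the informative-gene filters; relax min_cells_frac, "
            "min_u or r_min"
        )
    return idx
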