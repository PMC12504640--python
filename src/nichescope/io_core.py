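"""Cell tables: loading, saving, quality control, and train/test splitting.

The central container is :class:`CellTable` — per-cell 2D coordinates in
microns, a tissue-section identifier, an optional animal identifier, a
categorical cell-type label, and a sparse cell-by-gene raw count matrix.
Three on-disk representations are supported: MatrixMarket + TSV metadata,
an h5ad single-cell container (via :mod:`anndata`), and flat CSV/Parquet
tables with a wide count layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "CellTable",
    "QCConfig",
    "QCReport",
    "load_cell_table",
    "write_cell_table",
    "filter_qc",
    "split_train_test",
]

_META_COLUMNS = ("cell_id", "x", "y", "section_id", "cell_type")


@dataclass
class CellTable:
    """Validated per-cell table backing every stage of the pipeline.

    ``cell_type`` holds 1-based integer codes into ``type_labels``; ``counts``
    is an ``N x g`` sparse matrix of raw non-negative integer counts.
    ``log_counts`` is materialized lazily as natural log1p of counts when not
    supplied by the source (the transform used is recorded in ``metadata``).
    """

    cell_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    section_id: np.ndarray
    cell_type: np.ndarray
    type_labels: list[str]
    counts: sparse.csr_matrix
    gene_names: list[str]
    animal_id: np.ndarray | None = None
    ccf_xyz: np.ndarray | None = None
    _log_counts: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cell_id = np.asarray(self.cell_id, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.section_id = np.asarray(self.section_id, dtype=object)
        self.cell_type = np.asarray(self.cell_type, dtype=np.int64)
        self.counts = sparse.csr_matrix(self.counts)
        if self.animal_id is not None:
            self.animal_id = np.asarray(self.animal_id, dtype=object)
        self.validate()

    # -- contracts -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.cell_id)
        for name in ("x", "y", "section_id", "cell_type"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column '{name}' has {len(getattr(self, name))} rows, expected {n}")
        if self.counts.shape[0] != n:
            raise ValueError(f"count matrix has {self.counts.shape[0]} rows, metadata has {n}")
        if self.counts.shape[1] != len(self.gene_names):
            raise ValueError("gene_names length does not match count matrix width")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            bad = int(np.flatnonzero(~(np.isfinite(self.x) & np.isfinite(self.y)))[0])
            raise ValueError(f"non-finite coordinates for cell {self.cell_id[bad]!r}")
        data = self.counts.data
        if data.size and (data.min() < 0 or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")
        c = len(self.type_labels)
        if self.cell_type.size and (self.cell_type.min() < 1 or self.cell_type.max() > c):
            raise ValueError("cell_type codes outside the 1..C vocabulary")
        if self.animal_id is not None and len(self.animal_id) != n:
            raise ValueError("animal_id length mismatch")
        if self.ccf_xyz is not None and self.ccf_xyz.shape != (n, 3):
            raise ValueError("ccf_xyz must be N x 3")

    @property
    def n_cells(self) -> int:
        return len(self.cell_id)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_types(self) -> int:
        return len(self.type_labels)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def log_counts(self) -> np.ndarray:
        """Natural log1p of raw counts (dense), computed once on demand."""
        if self._log_counts is None:
            self._log_counts = np.log1p(np.asarray(self.counts.todense(), dtype=float))
            self.metadata.setdefault("log_transform", "log1p")
        return self._log_counts

    def subset_cells(self, idx: np.ndarray) -> "CellTable":
        idx = np.asarray(idx)
        return CellTable(
            cell_id=self.cell_id[idx],
            x=self.x[idx],
            y=self.y[idx],
            section_id=self.section_id[idx],
            cell_type=self.cell_type[idx],
            type_labels=list(self.type_labels),
            counts=self.counts[idx],
            gene_names=list(self.gene_names),
            animal_id=None if self.animal_id is None else self.animal_id[idx],
            ccf_xyz=None if self.ccf_xyz is None else self.ccf_xyz[idx],
            metadata=dict(self.metadata),
        )

    def subset_genes(self, gene_idx: np.ndarray) -> "CellTable":
        gene_idx = np.asarray(gene_idx)
        return replace(
            self,
            counts=sparse.csr_matrix(self.counts[:, gene_idx]),
            gene_names=[self.gene_names[i] for i in gene_idx],
            _log_counts=None,
        )

    # -- AnnData bridge --------------------------------------------------
    def to_anndata(self) -> ad.AnnData:
        obs = pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "section_id": pd.Categorical(self.section_id.astype(str)),
                "cell_type": pd.Categorical.from_codes(
                    self.cell_type - 1, categories=self.type_labels
                ),
            },
            index=pd.Index(self.cell_id.astype(str), name="cell_id"),
        )
        if self.animal_id is not None:
            obs["animal_id"] = pd.Categorical(self.animal_id.astype(str))
        adata = ad.AnnData(X=self.counts.copy(), obs=obs)
        adata.var_names = list(self.gene_names)
        adata.uns["coordinate_units"] = "micron"
        adata.uns["nichescope"] = {k: str(v) for k, v in self.metadata.items()}
        if self.ccf_xyz is not None:
            adata.obsm["ccf_xyz"] = self.ccf_xyz.copy()
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData) -> "CellTable":
        for col in ("x", "y", "section_id", "cell_type"):
            if col not in adata.obs:
                raise ValueError(f"missing required obs column '{col}'")
        ct = adata.obs["cell_type"]
        if ct.dtype.name != "category":
            ct = ct.astype("category")
        scale = _unit_scale(str(adata.uns.get("coordinate_units", "micron")))
        X = adata.X
        counts = sparse.csr_matrix(X if sparse.issparse(X) else np.asarray(X))
        return cls(
            cell_id=np.asarray(adata.obs_names, dtype=object),
            x=adata.obs["x"].to_numpy(float) * scale,
            y=adata.obs["y"].to_numpy(float) * scale,
            section_id=np.asarray(adata.obs["section_id"].astype(str), dtype=object),
            cell_type=ct.cat.codes.to_numpy() + 1,
            type_labels=[str(c) for c in ct.cat.categories],
            counts=counts,
            gene_names=[str(v) for v in adata.var_names],
            animal_id=(
                np.asarray(adata.obs["animal_id"].astype(str), dtype=object)
                if "animal_id" in adata.obs
                else None
            ),
            ccf_xyz=np.asarray(adata.obsm["ccf_xyz"], float) if "ccf_xyz" in adata.obsm else None,
            metadata=dict(adata.uns.get("nichescope", {})),
        )


def _unit_scale(units: str) -> float:
    units = units.lower()
    if units in ("micron", "microns", "um", "µm"):
        return 1.0
    if units in ("mm", "millimeter", "millimeters"):
        return 1000.0
    raise ValueError(f"unrecognized coordinate units {units!r}")


# -- loading / writing ----------------------------------------------------

def load_cell_table(path: str | Path, format: str) -> CellTable:
    """Load a :class:`CellTable` from ``path``.

    format: ``"mtx"`` (directory with matrix.mtx, genes.tsv, metadata.tsv),
    ``"h5ad"``, or ``"tabular"`` (wide CSV/Parquet). Coordinates declared in
    millimeters by the source metadata are converted to microns.
    """
    path = Path(path)
    if format == "h5ad":
        return CellTable.from_anndata(ad.read_h5ad(path))
    if format == "mtx":
        return _load_mtx(path)
    if format == "tabular":
        return _load_tabular(path)
    raise ValueError(f"unknown format {format!r}")


def _read_meta_frame(df: pd.DataFrame) -> dict:
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column '{col}'")
    units = "micron"
    if "coordinate_units" in df.columns:
        units = str(df["coordinate_units"].iloc[0])
    scale = _unit_scale(units)
    ct = df["cell_type"].astype("category")
    out = dict(
        cell_id=df["cell_id"].to_numpy(object),
        x=df["x"].to_numpy(float) * scale,
        y=df["y"].to_numpy(float) * scale,
        section_id=df["section_id"].astype(str).to_numpy(object),
        cell_type=ct.cat.codes.to_numpy() + 1,
        type_labels=[str(c) for c in ct.cat.categories],
    )
    if "animal_id" in df.columns:
        out["animal_id"] = df["animal_id"].astype(str).to_numpy(object)
    return out


def _load_mtx(path: Path) -> CellTable:
    mtx = path / "matrix.mtx"
    meta = path / "metadata.tsv"
    genes = path / "genes.tsv"
    for f in (mtx, meta, genes):
        if not f.exists():
            raise FileNotFoundError(f)
    counts = sparse.csr_matrix(mmread(mtx))
    df = pd.read_csv(meta, sep="\t")
    gene_names = pd.read_csv(genes, sep="\t", header=None)[0].tolist()
    if counts.shape[0] != len(df):
        raise ValueError(
            f"matrix has {counts.shape[0]} rows but metadata has {len(df)} rows"
        )
    attrs = {}
    attr_file = path / "attrs.json"
    if attr_file.exists():
        attrs = json.loads(attr_file.read_text())
    fields = _read_meta_frame(df)
    return CellTable(counts=counts, gene_names=gene_names, metadata=attrs, **fields)


def _load_tabular(path: Path) -> CellTable:
    df = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
    meta_cols = [c for c in df.columns if c in _META_COLUMNS + ("animal_id", "coordinate_units")]
    gene_cols = [c for c in df.columns if c not in meta_cols]
    fields = _read_meta_frame(df[meta_cols])
    counts = sparse.csr_matrix(df[gene_cols].to_numpy(float))
    return CellTable(counts=counts, gene_names=list(gene_cols), **fields)


def write_cell_table(table: CellTable, path: str | Path, format: str) -> None:
    path = Path(path)
    if format == "h5ad":
        table.to_anndata().write_h5ad(path)
        return
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(path / "matrix.mtx", sparse.coo_matrix(table.counts), field="integer")
        pd.Series(table.gene_names).to_csv(path / "genes.tsv", sep="\t", index=False, header=False)
        _meta_frame(table).to_csv(path / "metadata.tsv", sep="\t", index=False)
        if table.metadata:
            (path / "attrs.json").write_text(json.dumps({k: str(v) for k, v in table.metadata.items()}))
        return
    if format == "tabular":
        df = _meta_frame(table)
        wide = pd.DataFrame(
            np.asarray(table.counts.todense(), dtype=np.int64),
            columns=table.gene_names,
            index=df.index,
        )
        out = pd.concat([df, wide], axis=1)
        if path.suffix == ".parquet":
            out.to_parquet(path, index=False)
        else:
            out.to_csv(path, index=False)
        return
    raise ValueError(f"unknown format {format!r}")


def _meta_frame(table: CellTable) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "cell_id": table.cell_id,
            "x": table.x,
            "y": table.y,
            "section_id": table.section_id,
            "cell_type": [table.type_labels[c - 1] for c in table.cell_type],
        }
    )
    if table.animal_id is not None:
        df["animal_id"] = table.animal_id
    return df


# -- quality control ------------------------------------------------------

@dataclass
class QCConfig:
    """Dataset QC thresholds.

    Defaults follow whole-brain Slide-seqV2 practice: drop cells with >20%
    mitochondrial counts or within the lowest 10% of per-section read depth,
    and keep only genes expressed in >10% of cells.
    """

    mito_fraction_max: float = 0.20
    depth_percentile_min: float = 10.0
    gene_prevalence_min: float = 0.10
    mito_gene_set: tuple[str, ...] = ()

    def __post_init__(self):
        if not (0.0 <= self.mito_fraction_max <= 1.0 and 0.0 <= self.gene_prevalence_min <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 <= self.depth_percentile_min <= 100.0:
            raise ValueError("depth percentile must lie in [0, 100]")


@dataclass
class QCReport:
    removed_cell_ids: list
    removed_gene_names: list
    depth_cutoffs: dict


def filter_qc(table: CellTable, cfg: QCConfig | None = None) -> tuple[CellTable, QCReport]:
    """Apply gene and cell QC filters; returns the filtered table and a report.

    Gene filters (mitochondrial-name removal and prevalence) are applied
    first; per-section depth percentiles are then computed on the filtered
    matrix. Mitochondrial fractions are computed on the unfiltered matrix.
    The depth cutoff is inclusive: depth <= the percentile value is removed.
    """
    cfg = cfg or QCConfig()
    counts = table.counts.tocsc()
    n = table.n_cells

    mito_mask = np.isin(np.asarray(table.gene_names, dtype=object), list(cfg.mito_gene_set))
    depth_all = np.asarray(table.counts.sum(axis=1)).ravel()
    mito_frac = np.zeros(n)
    if mito_mask.any():
        mito_counts = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore"):
            mito_frac = np.where(depth_all > 0, mito_counts / np.maximum(depth_all, 1), 0.0)

    prevalence = np.asarray((counts > 0).sum(axis=0)).ravel() / max(n, 1)
    gene_keep = (prevalence > cfg.gene_prevalence_min) & ~mito_mask
    removed_genes = [g for g, k in zip(table.gene_names, gene_keep) if not k]

    filtered = table.subset_genes(np.flatnonzero(gene_keep))
    depth = np.asarray(filtered.counts.sum(axis=1)).ravel()

    cell_keep = mito_frac <= cfg.mito_fraction_max
    cutoffs: dict = {}
    if cfg.depth_percentile_min > 0:  # percentile 0 removes nothing
        for sec in pd.unique(table.section_id):
            in_sec = table.section_id == sec
            cut = float(np.percentile(depth[in_sec], cfg.depth_percentile_min))
            cutoffs[str(sec)] = cut
            cell_keep &= ~(in_sec & (depth <= cut))

    if not cell_keep.any():
        raise ValueError("QC removed every cell; relax the thresholds")

    report = QCReport(
        removed_cell_ids=list(table.cell_id[~cell_keep]),
        removed_gene_names=removed_genes,
        depth_cutoffs=cutoffs,
    )
    return filtered.subset_cells(np.flatnonzero(cell_keep)), report


def split_train_test(
    table: CellTable, train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/test index sets over the whole dataset."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = table.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.clip(round(n * train_fraction), 1, n - 1))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
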