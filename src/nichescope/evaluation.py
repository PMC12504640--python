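"""Parcellation quality metrics.

Spatial homogeneity (fraction of a cell's spatial nearest neighbors sharing
its domain label), discreteness against a reference parcellation's
per-domain smoothness percentile, cell-type composition matching (best
non-exclusive match and exclusive linear-sum assignment), NMI/ARI, linear
probing of embeddings, the spatial-contribution baseline comparison,
per-domain marker genes, and cross-animal domain consistency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .io_core import CellTable
from .model_core import CellTransformer
from .neighborhoods import NeighborhoodIndex, batch_neighborhoods

__all__ = [
    "HomogeneityResult",
    "CompositionMatrix",
    "spatial_homogeneity",
    "discreteness",
    "composition_matrix",
    "match_compositions",
    "clustering_agreement",
    "linear_probe",
    "spatial_contribution",
    "prediction_correlation_report",
    "rank_domain_markers",
    "cross_animal_consistency",
]


def _label_array(labels) -> np.ndarray:
    return np.asarray(getattr(labels, "labels", labels))


# -- spatial homogeneity --------------------------------------------------

@dataclass
class HomogeneityResult:
    per_cell: np.ndarray
    dataset_mean: float
    per_domain_mean: dict
    n_neighbors: int


def spatial_homogeneity(table: CellTable, labels, n_neighbors: int = 100) -> HomogeneityResult:
    """Per cell: fraction of its spatial nearest neighbors (same section,
    self excluded) that share its domain label."""
    lab = _label_array(labels)
    if len(lab) != table.n_cells:
        raise ValueError("labels misaligned with cell table")
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    per_cell = np.empty(table.n_cells)
    coords = table.coords
    for sec in np.unique(table.section_id.astype(str)):
        idx = np.flatnonzero(table.section_id.astype(str) == sec)
        n_sec = min(n_neighbors, len(idx) - 1)
        if n_sec < n_neighbors:
            warnings.warn(f"section {sec}: clamped neighbors to {n_sec}", stacklevel=2)
        if n_sec == 0:
            per_cell[idx] = 1.0
            continue
        tree = cKDTree(coords[idx])
        _, nn = tree.query(coords[idx], k=n_sec + 1)
        neigh = idx[nn[:, 1:]]
        per_cell[idx] = (lab[neigh] == lab[idx][:, None]).mean(axis=1)
    per_domain = {int(d): float(per_cell[lab == d].mean()) for d in np.unique(lab)}
    return HomogeneityResult(
        per_cell=per_cell,
        dataset_mean=float(per_cell.mean()),
        per_domain_mean=per_domain,
        n_neighbors=n_neighbors,
    )


def discreteness(per_domain_mean, per_domain_mean_ref, percentile: float = 20.0):
    """Flag method domains whose mean smoothness reaches the reference
    parcellation's given percentile; returns (fraction discrete, flags)."""
    method = np.asarray(list(per_domain_mean.values()) if isinstance(per_domain_mean, dict) else per_domain_mean, float)
    ref = np.asarray(list(per_domain_mean_ref.values()) if isinstance(per_domain_mean_ref, dict) else per_domain_mean_ref, float)
    if method.size == 0 or ref.size == 0:
        raise ValueError("empty per-domain vectors")
    threshold = float(np.percentile(ref, percentile))
    flags = method >= threshold
    return float(flags.mean()), flags


# -- composition ----------------------------------------------------------

@dataclass
class CompositionMatrix:
    """Domain-by-cell-type abundance; rows sum to 1."""

    values: np.ndarray
    domain_ids: list
    type_labels: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if (v < 0).any() or not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must be non-negative and sum to 1")
        self.values = v


def composition_matrix(labels, table: CellTable, type_level: list[str] | None = None) -> CompositionMatrix:
    lab = _label_array(labels)
    if len(lab) != table.n_cells:
        raise ValueError("labels misaligned with cell table")
    types = table.cell_type
    vocab = type_level or list(table.type_labels)
    t_count = len(vocab)
    domains = np.unique(lab)
    rows, kept = [], []
    for d in domains:
        mask = lab == d
        if not mask.any():
            continue
        counts = np.bincount(types[mask] - 1, minlength=t_count).astype(float)
        total = counts.sum()
        if total == 0:
            warnings.warn(f"domain {d} empty; dropped", stacklevel=2)
            continue
        rows.append(counts / total)
        kept.append(int(d))
    return CompositionMatrix(values=np.vstack(rows), domain_ids=kept, type_labels=vocab)


def _standardized_rows(M: np.ndarray, domain_ids, tag: str) -> np.ndarray:
    Mc = M - M.mean(axis=1, keepdims=True)
    sd = Mc.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if len(bad):
        raise ValueError(f"domain {domain_ids[bad[0]]} of {tag} has constant composition")
    return Mc / sd[:, None]


@dataclass
class MatchResult:
    mean_r: float
    pairs: list[tuple]
    per_domain_r: np.ndarray


def match_compositions(A: CompositionMatrix, B: CompositionMatrix, mode: str = "max") -> MatchResult:
    """Mean Pearson r between two composition matrices.

    mode="max": each row of A matches its best row of B (non-exclusive).
    mode="assignment": exclusive one-to-one pairing maximizing total r
    (rectangular inputs are matched over min(K) pairs).
    """
    if A.type_labels != B.type_labels:
        raise ValueError("composition matrices use different type vocabularies")
    Za = _standardized_rows(A.values, A.domain_ids, "A")
    Zb = _standardized_rows(B.values, B.domain_ids, "B")
    R = (Za @ Zb.T) / len(A.type_labels)
    if mode == "max":
        per = R.max(axis=1)
        pairs = [(A.domain_ids[i], B.domain_ids[int(j)]) for i, j in enumerate(R.argmax(axis=1))]
    elif mode == "assignment":
        if R.shape[0] != R.shape[1]:
            warnings.warn("rectangular assignment over min(K) pairs", stacklevel=2)
        ri, ci = linear_sum_assignment(R, maximize=True)
        per = R[ri, ci]
        pairs = [(A.domain_ids[i], B.domain_ids[j]) for i, j in zip(ri, ci)]
    else:
        raise ValueError("mode must be 'max' or 'assignment'")
    return MatchResult(mean_r=float(per.mean()), pairs=pairs, per_domain_r=per)


def clustering_agreement(labels_a, labels_b) -> tuple[float, float]:
    """(NMI with arithmetic normalization, ARI) of two aligned labelings."""
    a, b = _label_array(labels_a), _label_array(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors have different lengths")
    return (
        float(normalized_mutual_info_score(a, b, average_method="arithmetic")),
        float(adjusted_rand_score(a, b)),
    )


# -- linear probing -------------------------------------------------------

@dataclass
class ProbeResult:
    target: str
    median_abs_error: float | None = None
    mean_abs_error: float | None = None
    per_group_error: dict = field(default_factory=dict)
    accuracy: float | None = None
    per_group_accuracy: dict = field(default_factory=dict)
    coefficients: np.ndarray | None = None


def linear_probe(emb, table: CellTable, target: str = "coordinates") -> ProbeResult:
    """Fit a simple linear (coordinates) or logistic (donor) read-out.

    Coordinates use the registered 3D positions when available, otherwise
    the section-plane (x, y); fitting is ordinary least squares through an
    orthogonal (SVD) decomposition, minimum-norm under rank deficiency.
    Errors are per-cell Euclidean distances; both the median and the mean
    are reported.
    """
    X = emb.values if hasattr(emb, "values") else np.asarray(emb, float)
    if X.shape[0] != table.n_cells:
        raise ValueError("embedding rows misaligned with cell table")
    if target == "coordinates":
        Y = table.ccf_xyz if table.ccf_xyz is not None else table.coords
        design = np.column_stack([X, np.ones(len(X))])
        coef, _, rank, _ = np.linalg.lstsq(design, Y, rcond=None)
        if rank < design.shape[1]:
            warnings.warn("rank-deficient design; minimum-norm solution used", stacklevel=2)
        err = np.linalg.norm(design @ coef - Y, axis=1)
        per_group = {}
        if table.animal_id is not None:
            per_group = {
                str(a): float(np.median(err[table.animal_id == a]))
                for a in np.unique(table.animal_id.astype(str))
            }
        return ProbeResult(
            target=target,
            median_abs_error=float(np.median(err)),
            mean_abs_error=float(err.mean()),
            per_group_error=per_group,
            coefficients=coef,
        )
    if target == "donor":
        if table.animal_id is None:
            raise ValueError("donor probe requires animal_id")
        y = table.animal_id.astype(str)
        clf = LogisticRegression(max_iter=2000).fit(X, y)
        pred = clf.predict(X)
        per = {str(a): float((pred[y == a] == a).mean()) for a in np.unique(y)}
        return ProbeResult(
            target=target,
            accuracy=float((pred == y).mean()),
            per_group_accuracy=per,
            coefficients=clf.coef_,
        )
    raise ValueError("target must be 'coordinates' or 'donor'")


# -- spatial contribution -------------------------------------------------

def prediction_correlation_report(observed, predicted, baseline, types) -> pd.DataFrame:
    """Per-type mean Pearson r of observed counts against two predictors
    and their difference (model minus baseline); zero-variance observations
    are skipped and counted."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    baseline = np.asarray(baseline, float)
    types = np.asarray(types)
    if baseline.ndim == 1:
        baseline = np.broadcast_to(baseline, observed.shape)

    def row_r(a, b):
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (ac * bc).sum(axis=1) / denom, np.nan)

    ok = observed.std(axis=1) > 0
    r_model = row_r(observed, predicted)
    r_base = row_r(observed, baseline)
    rows = []
    for t in np.unique(types):
        sel = (types == t) & ok
        rows.append(
            {
                "cell_type": t,
                "n_cells": int(sel.sum()),
                "n_skipped": int(((types == t) & ~ok).sum()),
                "r_model": float(np.nanmean(r_model[sel])) if sel.any() else np.nan,
                "r_baseline": float(np.nanmean(r_base[sel])) if sel.any() else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df["delta_r"] = df["r_model"] - df["r_baseline"]
    return df


def spatial_contribution(
    model: CellTransformer,
    table: CellTable,
    index: NeighborhoodIndex,
    batch_size: int = 512,
) -> pd.DataFrame:
    """Per-type gain in expression-prediction correlation of the context
    model over a dataset-mean baseline."""
    counts = np.asarray(table.counts.todense(), dtype=float)
    tokens = model.encode_cell_tokens(table.log_counts, table.cell_type)
    preds = []
    for lo in range(0, table.n_cells, batch_size):
        refs = np.arange(lo, min(lo + batch_size, table.n_cells))
        batch = batch_neighborhoods(index, refs, table)
        preds.append(model.predict_mu(batch, tokens))
    predicted = np.vstack(preds)
    return prediction_correlation_report(counts, predicted, counts.mean(axis=0), table.cell_type)


# -- markers and cross-animal consistency ---------------------------------

def rank_domain_markers(
    table: CellTable, labels, min_log2fc: float = 1.0, pseudocount: float = 1.0
) -> dict[int, pd.DataFrame]:
    """Per domain: genes with log2 fold change (pseudocounted mean counts
    inside vs outside the domain) of at least ``min_log2fc``, best first."""
    lab = _label_array(labels)
    domains = np.unique(lab)
    if len(domains) < 2:
        raise ValueError("need at least 2 domains for marker ranking")
    counts = np.asarray(table.counts.todense(), dtype=float)
    out = {}
    for d in domains:
        inside = counts[lab == d].mean(axis=0)
        outside = counts[lab != d].mean(axis=0)
        lfc = np.log2((inside + pseudocount) / (outside + pseudocount))
        sel = np.flatnonzero(lfc >= min_log2fc)
        order = sel[np.argsort(-lfc[sel])]
        out[int(d)] = pd.DataFrame(
            {"gene": [table.gene_names[i] for i in order], "log2fc": lfc[order]}
        )
    return out


def cross_animal_consistency(labels, animal_ids, min_cells: int = 10):
    """Fraction of domains present (>= min_cells) in every animal, plus the
    per-domain presence table."""
    lab = _label_array(labels)
    animals = np.asarray(animal_ids).astype(str)
    uniq_animals = np.unique(animals)
    if len(uniq_animals) < 2:
        raise ValueError("need at least 2 animals")
    domains = np.unique(lab)
    presence = pd.DataFrame(index=domains, columns=uniq_animals, dtype=bool)
    for a in uniq_animals:
        counts = {d: int(((lab == d) & (animals == a)).sum()) for d in domains}
        presence[a] = [counts[d] >= min_cells for d in domains]
    fraction = float(presence.all(axis=1).mean())
    return fraction, presence
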