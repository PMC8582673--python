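"""Batch self-organizing map (SOM) with K-means / Davies–Bouldin patterning.

A Kohonen SOM condenses the (log-transformed, rare-filtered) site × taxon
matrix onto a small two-dimensional lattice of prototype ("codebook")
vectors. Training is the batch algorithm: each epoch assigns every sample to
its best-matching unit (BMU, nearest codebook vector in Euclidean distance),
then replaces each codebook vector by the neighborhood-kernel-weighted mean
of the data, with a Gaussian kernel on lattice distance whose radius shrinks
linearly through a rough and a fine phase. The trained units are then
clustered by K-means, with the number of clusters K chosen by minimizing the
Davies–Bouldin index; samples inherit the cluster of their BMU.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import CommunityMatrix

__all__ = [
    "GridSpec",
    "SomModel",
    "ClusterPartition",
    "target_unit_count",
    "map_size",
    "train_som",
    "quantization_error",
    "davies_bouldin_index",
    "cluster_units",
]


@dataclass(frozen=True)
class GridSpec:
    """SOM output-lattice geometry."""

    n_rows: int
    n_cols: int
    lattice: str = "hexagonal"

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols < 2:
            raise ValueError("lattice needs at least 2 units")
        if self.lattice not in ("hexagonal", "rectangular"):
            raise ValueError(f"unknown lattice {self.lattice!r}")

    @property
    def n_units(self) -> int:
        return self.n_rows * self.n_cols


def grid_coordinates(grid: GridSpec) -> np.ndarray:
    """(units × 2) lattice coordinates, row-major unit ordering.

    Hexagonal lattices offset odd rows by half a unit and compress row
    spacing to √3/2, so immediate neighbors are all at distance 1.
    """
    rr, cc = np.meshgrid(
        np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij"
    )
    x = cc.astype(float)
    y = rr.astype(float)
    if grid.lattice == "hexagonal":
        x = x + 0.5 * (rr % 2)
        y = y * (math.sqrt(3.0) / 2.0)
    return np.column_stack([y.ravel(), x.ravel()])


def target_unit_count(n_samples: int) -> int:
    """The ``ceil(5·√n)`` heuristic for the number of SOM output units."""
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    return math.ceil(5.0 * math.sqrt(n_samples))


def map_size(
    n_samples: int,
    data: CommunityMatrix | np.ndarray | None = None,
    override: GridSpec | None = None,
) -> GridSpec:
    """Choose the SOM lattice size from the ``5·√n`` heuristic.

    Target unit count u = ceil(5·√n_samples). The rows:cols split follows the
    ratio of the two leading data covariance eigenvalues when data are given
    (the SOM-toolbox convention), otherwise the squarest factorization with
    rows·cols ≥ u. An explicit ``override`` always wins.
    """
    if override is not None:
        return override
    if n_samples < 4:
        raise ValueError("need at least 4 samples to size a map")
    u = target_unit_count(n_samples)

    ratio = 1.0
    if data is not None:
        X = data.counts if isinstance(data, CommunityMatrix) else np.asarray(data, float)
        if X.shape[0] > 2 and X.shape[1] > 1:
            cov = np.cov(X, rowvar=False)
            ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
            if ev[1] > 1e-12:
                ratio = math.sqrt(ev[0] / ev[1])

    best = None
    for rows in range(1, u + 1):
        cols = math.ceil(u / rows)
        key = (abs(rows / cols - ratio), rows * cols, rows)
        if best is None or key < best[0]:
            best = (key, GridSpec(rows, cols))
    return best[1]


@dataclass(frozen=True)
class SomModel:
    """A trained SOM: lattice, codebook, training trace and BMU assignments."""

    grid: GridSpec
    codebook: np.ndarray                # units × taxa
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    bmu: np.ndarray                     # sample index -> unit index
    training_log: tuple[float, ...]     # per-epoch quantization error

    def bmu_of(self, sample_id: str) -> int:
        return int(self.bmu[self.sample_ids.index(sample_id)])


def _bmus(X: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _linear_init(X: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Codebook spanning the first two principal components (deterministic).

    SVD signs are fixed by making the largest-magnitude loading of each
    component positive.
    """
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    n_comp = min(2, vt.shape[0])
    comps = vt[:n_comp]
    for i in range(n_comp):
        j = np.abs(comps[i]).argmax()
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    scale = s[:n_comp] / math.sqrt(max(X.shape[0] - 1, 1))

    rows = np.repeat(np.arange(grid.n_rows), grid.n_cols)
    cols = np.tile(np.arange(grid.n_cols), grid.n_rows)

    def axis(vals, k):
        return np.zeros_like(vals, dtype=float) if k <= 1 else 2.0 * vals / (k - 1) - 1.0

    a = axis(rows, grid.n_rows)
    b = axis(cols, grid.n_cols)
    # the longer lattice side carries the leading principal component
    if grid.n_cols >= grid.n_rows:
        a, b = b, a
    code = np.tile(mean, (grid.n_units, 1))
    code += np.outer(a * scale[0], comps[0])
    if n_comp > 1:
        code += np.outer(b * scale[1], comps[1])
    return code


def train_som(
    data: CommunityMatrix | np.ndarray,
    grid: GridSpec,
    init: str = "linear",
    rough_epochs: int = 50,
    fine_epochs: int = 100,
    radius_start: float | None = None,
    radius_end: float = 0.5,
    seed: int = 0,
) -> SomModel:
    """Train a batch Kohonen SOM; deterministic given parameters (and seed,
    for random initialization).

    The neighborhood radius decreases linearly from ``radius_start``
    (default max(grid)/4) to 1.5 over the rough phase, then from 1.5 to
    ``radius_end`` over the fine phase.
    """
    if isinstance(data, CommunityMatrix):
        if not data.transformed:
            warnings.warn(
                "training on untransformed abundances; log-transform is "
                "recommended first",
                stacklevel=2,
            )
        X = data.counts
        sample_ids = tuple(data.sample_ids)
        feature_ids = tuple(data.taxon_ids)
    else:
        X = np.asarray(data, dtype=float)
        sample_ids = tuple(f"s{i}" for i in range(X.shape[0]))
        feature_ids = tuple(f"f{j}" for j in range(X.shape[1]))
    if X.size == 0:
        raise ValueError("empty training data")
    if grid.n_units > 10 * X.shape[0]:
        warnings.warn(
            f"lattice of {grid.n_units} units is large for {X.shape[0]} samples",
            stacklevel=2,
        )

    if init == "linear":
        codebook = _linear_init(X, grid)
    elif init == "random":
        rng = np.random.default_rng(seed)
        lo, hi = X.min(axis=0), X.max(axis=0)
        codebook = rng.uniform(lo, hi, size=(grid.n_units, X.shape[1]))
    else:
        raise ValueError(f"unknown init {init!r}")

    coords = grid_coordinates(grid)
    lat_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)

    if radius_start is None:
        radius_start = max(grid.n_rows, grid.n_cols) / 4.0
    mid = 1.5
    if radius_start >= mid >= radius_end:
        # standard two-phase schedule: rough (start -> 1.5), fine (1.5 -> end)
        radii = np.concatenate(
            [
                np.linspace(radius_start, mid, max(rough_epochs, 1)),
                np.linspace(mid, radius_end, max(fine_epochs, 1)),
            ]
        )
        if rough_epochs == 0:
            radii = radii[1:]
        if fine_epochs == 0:
            radii = radii[:-1]
    else:
        # custom start/end not bracketing the midpoint: single linear phase
        radii = np.linspace(radius_start, radius_end,
                            max(rough_epochs + fine_epochs, 1))

    log = []
    bmu = _bmus(X, codebook)
    for sigma in radii:
        sigma = max(float(sigma), 1e-6)
        bmu = _bmus(X, codebook)
        log.append(float(np.sqrt(((X - codebook[bmu]) ** 2).sum(axis=1)).mean()))
        h = np.exp(-lat_d2 / (2.0 * sigma**2))  # units × units
        w = h[:, bmu]                            # units × samples
        denom = w.sum(axis=1)
        numer = w @ X
        nonzero = denom > 1e-300
        codebook = codebook.copy()
        codebook[nonzero] = numer[nonzero] / denom[nonzero, None]
    bmu = _bmus(X, codebook)
    log.append(float(np.sqrt(((X - codebook[bmu]) ** 2).sum(axis=1)).mean()))

    return SomModel(
        grid=grid,
        codebook=codebook,
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        bmu=bmu,
        training_log=tuple(log),
    )


def quantization_error(model: SomModel, data: CommunityMatrix | np.ndarray) -> float:
    """Mean Euclidean distance from each sample to its BMU codebook vector."""
    X = data.counts if isinstance(data, CommunityMatrix) else np.asarray(data, float)
    bmu = _bmus(X, model.codebook)
    return float(np.sqrt(((X - model.codebook[bmu]) ** 2).sum(axis=1)).mean())


def davies_bouldin_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Davies–Bouldin cluster-validity score (lower is better).

    DB = (1/K)·Σᵢ maxⱼ≠ᵢ (Sᵢ + Sⱼ)/Mᵢⱼ, where Sᵢ is the mean Euclidean
    distance of cluster i's members to their centroid and Mᵢⱼ the distance
    between centroids i and j.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("Davies–Bouldin needs at least 2 clusters")
    cents = np.stack([X[labels == u].mean(axis=0) for u in uniq])
    S = np.array(
        [
            np.sqrt(((X[labels == u] - cents[i]) ** 2).sum(axis=1)).mean()
            for i, u in enumerate(uniq)
        ]
    )
    M = np.sqrt(((cents[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2))
    ratios = np.full((k, k), -np.inf)
    for i in range(k):
        for j in range(k):
            if i != j:
                if M[i, j] == 0:
                    return float("inf")
                ratios[i, j] = (S[i] + S[j]) / M[i, j]
    return float(ratios.max(axis=1).mean())


@dataclass(frozen=True)
class ClusterPartition:
    """Unit- and sample-level cluster labels with the DB model-selection trace."""

    unit_labels: np.ndarray             # unit index -> cluster in 1..k
    sample_labels: pd.Series            # sample_id -> cluster in 1..k
    k: int
    db_by_k: dict[int, float] = field(default_factory=dict)


def cluster_units(
    model: SomModel,
    k_range=None,
    restarts: int = 100,
    seed: int = 0,
) -> ClusterPartition:
    """K-means over codebook vectors with Davies–Bouldin selection of K.

    For each K in ``k_range`` (default 2..min(10, units−1)) the best of
    ``restarts`` k-means++ runs is scored by the Davies–Bouldin index; the
    K minimizing it is chosen (ties to the smaller K). Every SOM unit —
    including units that are no sample's BMU — participates through its
    codebook vector, so unit clusters tile the whole map. Samples inherit
    the cluster of their BMU.
    """
    units = model.grid.n_units
    if k_range is None:
        k_range = range(2, min(10, units - 1) + 1)
    k_range = [k for k in k_range]
    if not k_range or max(k_range) >= units:
        raise ValueError("k_range must be non-empty with max(k) < number of units")

    n_distinct = np.unique(model.codebook, axis=0).shape[0]
    db_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        if k > n_distinct:
            warnings.warn(f"K={k} exceeds distinct codebook vectors; skipped",
                          stacklevel=2)
            continue
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        lab = km.fit_predict(model.codebook)
        if len(np.unique(lab)) < k:
            warnings.warn(f"K={k} produced an empty cluster; skipped", stacklevel=2)
            continue
        db_by_k[k] = davies_bouldin_index(model.codebook, lab)
        labels_by_k[k] = lab
    if not db_by_k:
        raise ValueError("no K in k_range produced a valid partition")

    chosen = min(sorted(db_by_k), key=lambda k: db_by_k[k])
    unit_labels = labels_by_k[chosen] + 1  # clusters numbered 1..K
    sample_labels = pd.Series(
        unit_labels[model.bmu], index=list(model.sample_ids), name="cluster"
    )
    assert (sample_labels.to_numpy() == unit_labels[model.bmu]).all()
    return ClusterPartition(
        unit_labels=unit_labels,
        sample_labels=sample_labels,
        k=chosen,
        db_by_k=db_by_k,
    )
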