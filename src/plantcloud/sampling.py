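"""Down-sampling strategies for plant point clouds.

Point-level segmentation networks take fixed-size inputs, so dense scans
(tens of thousands of points) must be reduced to a target count ``n``
(conventionally 4096). Five strategies are implemented:

* **FPS** — farthest point sampling: greedy max–min selection where each new
  point maximises its minimum distance to the already-selected set. O(Mn)
  with the incremental nearest-selected-distance update.
* **RS** — sequential random sampling: a one-pass scan that draws random
  skip counts from the distribution of uniform sampling without
  replacement (Vitter's Algorithm S), O(M).
* **UVS** — voxelise, keep per occupied voxel the real point nearest the
  voxel's geometric centre, then FPS down to ``n``.
* **VFPS** — voxelise, emit per occupied voxel the gravity centroid of its
  members (synthetic points), then FPS down to ``n``.
* **3DEPS** — edge-preserving sampling: split the cloud into edge and
  internal points with a surface-boundary filter (SBF), FPS each part, and
  recombine at a user-set edge ratio.

All strategies are deterministic given their integer seed, return exactly
``n`` points, and carry semantic/instance labels from the source cloud
(VFPS assigns each centroid the majority label of its voxel's members).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .cloudio import LabeledPointCloud, _as_cloud

__all__ = [
    "VoxelSpec",
    "SampleResult",
    "EdgeMask",
    "fps",
    "fps_indices",
    "rs",
    "rs_indices",
    "voxelize",
    "uvs",
    "vfps",
    "sbf",
    "threedeps",
    "auto_voxel_size",
    "rs_then_fps",
    "sample",
    "STRATEGIES",
]


@dataclass(frozen=True)
class VoxelSpec:
    """Axis-aligned voxel grid: positive edge lengths and an origin.

    ``origin=None`` anchors the grid at the per-axis minimum of the cloud.
    Cells are half-open, ``[low, low + l)``, so every point falls in exactly
    one voxel.
    """

    lx: float
    ly: float
    lz: float
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if min(self.lx, self.ly, self.lz) <= 0:
            raise ValueError("voxel edge lengths must be positive")

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=np.float64)


@dataclass
class SampleResult:
    """Outcome of one down-sampling run.

    ``indices`` are positions into the source cloud (absent for VFPS, whose
    output points are synthetic centroids). ``sem``/``ins`` are carried from
    the source when it is labeled.
    """

    coords: np.ndarray
    strategy: str
    params: dict = field(default_factory=dict)
    indices: np.ndarray | None = None
    sem: np.ndarray | None = None
    ins: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def to_cloud(self) -> LabeledPointCloud:
        return LabeledPointCloud(
            coords=self.coords, sem=self.sem, ins=self.ins
        )


@dataclass
class EdgeMask:
    """Per-point edge/internal split produced by :func:`sbf`.

    ``flags`` is boolean with ``True`` = edge point; the edge set and the
    internal set partition the cloud.
    """

    flags: np.ndarray
    k: int
    tau: float

    @property
    def edge_indices(self) -> np.ndarray:
        return np.flatnonzero(self.flags)

    @property
    def internal_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.flags)


def _check_n(n: int, N: int) -> None:
    if N < 1:
        raise ValueError("empty point cloud")
    if not (1 <= n <= N):
        raise ValueError(f"target count n={n} outside [1, {N}]")


def _result(cloud: LabeledPointCloud, idx: np.ndarray, strategy: str,
            params: dict) -> SampleResult:
    return SampleResult(
        coords=cloud.coords[idx],
        indices=idx,
        sem=None if cloud.sem is None else cloud.sem[idx],
        ins=None if cloud.ins is None else cloud.ins[idx],
        strategy=strategy,
        params=params,
    )


# ---------------------------------------------------------------------------
# FPS
# ---------------------------------------------------------------------------

def fps_indices(
    coords: np.ndarray,
    n: int,
    seed: int = 0,
    start: int | None = None,
) -> np.ndarray:
    """Greedy max–min farthest point sampling; returns selection order.

    The first point is ``start`` or, when ``start`` is None, chosen
    uniformly at random from the seed. Every subsequent point maximises its
    minimum Euclidean distance to the points selected so far; distance
    ties break to the lowest index. Cost is one distance pass per selected
    point, i.e. O(Mn).
    """
    coords = np.asarray(coords, dtype=np.float64)
    N = coords.shape[0]
    _check_n(n, N)
    if start is None:
        start = int(np.random.default_rng(seed).integers(N))
    elif not (0 <= start < N):
        raise ValueError(f"start index {start} outside [0, {N})")
    selected = np.empty(n, dtype=np.int64)
    selected[0] = start
    # squared min-distance from each point to the selected set
    d2 = np.einsum("ij,ij->i", coords - coords[start], coords - coords[start])
    for i in range(1, n):
        nxt = int(np.argmax(d2))
        selected[i] = nxt
        diff = coords - coords[nxt]
        np.minimum(d2, np.einsum("ij,ij->i", diff, diff), out=d2)
    return selected


def fps(
    cloud,
    n: int,
    seed: int = 0,
    start: int | None = None,
) -> SampleResult:
    """Farthest point sampling of a (possibly labeled) cloud."""
    c = _as_cloud(cloud)
    idx = fps_indices(c.coords, n, seed=seed, start=start)
    return _result(c, idx, "FPS", {"n": n, "seed": seed, "start": start})


# ---------------------------------------------------------------------------
# RS
# ---------------------------------------------------------------------------

def rs_indices(N: int, n: int, seed: int = 0) -> np.ndarray:
    """Sequential random sampling without replacement; strictly increasing.

    One-pass skip sampling: with ``m`` points still to take out of ``N'``
    unvisited, the skip count ``S`` follows
    ``P(S <= s) = 1 - A(N'-m, s+1) / A(N', s+1)`` where ``A(x, r)`` is the
    falling factorial. A single uniform draw per selected point finds the
    smallest ``s`` with ``A(N'-m, s+1) <= A(N', s+1) * V``; the permutation
    ratio is evaluated as an incremental product of ``(N'-m-j)/(N'-j)``
    factors, never as factorials. The ``(S+1)``-th unvisited point is taken.

    The resulting index sets are uniform over all ``n``-subsets of
    ``range(N)``.
    """
    _check_n(n, N)
    rng = np.random.default_rng(seed)
    out = np.empty(n, dtype=np.int64)
    pos = 0          # next unvisited index
    remaining = N    # N', points not yet visited
    for i in range(n):
        m = n - i
        if m == remaining:
            # only exactly-enough points left: take them all
            out[i] = pos
            pos += 1
            remaining -= 1
            continue
        v = rng.random()
        s = 0
        ratio = (remaining - m) / remaining
        while ratio > v:
            s += 1
            ratio *= (remaining - m - s) / (remaining - s)
        out[i] = pos + s
        pos += s + 1
        remaining -= s + 1
    return out


def rs(cloud, n: int, seed: int = 0) -> SampleResult:
    """Sequential random sampling of a cloud; indices strictly increasing."""
    c = _as_cloud(cloud)
    idx = rs_indices(c.n_points, n, seed=seed)
    return _result(c, idx, "RS", {"n": n, "seed": seed})


# ---------------------------------------------------------------------------
# voxel grids
# ---------------------------------------------------------------------------

def _voxel_cells(coords: np.ndarray, spec: VoxelSpec):
    origin = (
        coords.min(axis=0)
        if spec.origin is None
        else np.asarray(spec.origin, dtype=np.float64)
    )
    cells = np.floor((coords - origin) / spec.edges).astype(np.int64)
    return cells, origin


def voxelize(coords: np.ndarray, spec: VoxelSpec) -> dict:
    """Assign each point to its half-open voxel cell.

    Returns a mapping from integer cell key ``(ix, iy, iz)`` to the sorted
    array of member point indices; the member lists partition the cloud.
    """
    coords = np.asarray(coords, dtype=np.float64)
    cells, _ = _voxel_cells(coords, spec)
    keys, inverse = np.unique(cells, axis=0, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    bounds = np.searchsorted(inverse[order], np.arange(len(keys) + 1))
    return {
        tuple(keys[j]): order[bounds[j]:bounds[j + 1]]
        for j in range(len(keys))
    }


def _voxel_stage(coords: np.ndarray, spec: VoxelSpec):
    """Shared grouping for UVS/VFPS: cells, origin, group index arrays."""
    cells, origin = _voxel_cells(coords, spec)
    keys, inverse = np.unique(cells, axis=0, return_inverse=True)
    return keys, inverse, origin


def uvs(cloud, n: int, spec: VoxelSpec, seed: int = 0) -> SampleResult:
    """Uniformly voxelised sampling.

    Per occupied voxel keep the real member point nearest the voxel's
    geometric centre (ties to the lowest point index), then FPS the kept
    points down to ``n``. Output indices are a subset of the source.
    """
    c = _as_cloud(cloud)
    coords = c.coords
    keys, inverse, origin = _voxel_stage(coords, spec)
    n_occ = len(keys)
    if n_occ < n:
        raise ValueError(
            f"only {n_occ} occupied voxels for n={n}; use a smaller voxel "
            "size or auto_voxel_size"
        )
    centers = origin + (keys + 0.5) * spec.edges
    d2 = np.einsum(
        "ij,ij->i", coords - centers[inverse], coords - centers[inverse]
    )
    # per-voxel argmin of distance-to-centre; lexsort makes ties go to the
    # lowest point index
    order = np.lexsort((np.arange(len(coords)), d2, inverse))
    first = np.searchsorted(inverse[order], np.arange(n_occ))
    kept = np.sort(order[first])
    sub = fps_indices(coords[kept], n, seed=seed)
    idx = kept[sub]
    return _result(
        c, idx, "UVS",
        {"n": n, "seed": seed, "voxel": (spec.lx, spec.ly, spec.lz)},
    )


def _majority(values: np.ndarray) -> int:
    """Most frequent value; ties break to the smallest value."""
    uniq, counts = np.unique(values, return_counts=True)
    return int(uniq[np.argmax(counts)])


def vfps(cloud, n: int, spec: VoxelSpec, seed: int = 0) -> SampleResult:
    """Voxelised farthest point sampling.

    Per occupied voxel emit the gravity centroid of its members (a synthetic
    point lying inside the cell), then FPS the centroids down to ``n``.
    Labels are transferred by per-voxel majority vote (ties to the smallest
    label id); ``indices`` is None because output points are synthetic.
    """
    c = _as_cloud(cloud)
    coords = c.coords
    keys, inverse, origin = _voxel_stage(coords, spec)
    n_occ = len(keys)
    if n_occ < n:
        raise ValueError(
            f"only {n_occ} occupied voxels for n={n}; use a smaller voxel "
            "size or auto_voxel_size"
        )
    counts = np.bincount(inverse, minlength=n_occ).astype(np.float64)
    centroids = np.empty((n_occ, 3))
    for ax in range(3):
        centroids[:, ax] = (
            np.bincount(inverse, weights=coords[:, ax], minlength=n_occ)
            / counts
        )
    sub = fps_indices(centroids, n, seed=seed)
    sem = ins = None
    if c.sem is not None or c.ins is not None:
        order = np.argsort(inverse, kind="stable")
        bounds = np.searchsorted(inverse[order], np.arange(n_occ + 1))
        members = [order[bounds[j]:bounds[j + 1]] for j in sub]
        if c.sem is not None:
            sem = np.array([_majority(c.sem[m]) for m in members])
        if c.ins is not None:
            ins = np.array([_majority(c.ins[m]) for m in members])
    return SampleResult(
        coords=centroids[sub],
        indices=None,
        sem=sem,
        ins=ins,
        strategy="VFPS",
        params={"n": n, "seed": seed, "voxel": (spec.lx, spec.ly, spec.lz)},
    )


# ---------------------------------------------------------------------------
# SBF + 3DEPS
# ---------------------------------------------------------------------------

def sbf(coords: np.ndarray, k: int = 20, tau: float = 0.5) -> EdgeMask:
    """Surface boundary filter: flag edge points by k-NN centroid shift.

    For each point take its ``k`` nearest neighbours, compute the
    displacement ``d`` of the neighbourhood centroid from the point and the
    mean neighbour distance ``r``; the point is an edge point iff
    ``d / r > tau``. On a locally symmetric (interior) neighbourhood the
    centroid shift vanishes, while at an organ boundary the neighbours lie
    to one side and the normalised shift approaches 1.
    """
    coords = np.asarray(coords, dtype=np.float64)
    N = coords.shape[0]
    if k < 3:
        raise ValueError("sbf requires k >= 3")
    if N <= k:
        raise ValueError(f"sbf requires more than k={k} points, got {N}")
    tree = cKDTree(coords)
    dist, nbr = tree.query(coords, k=k + 1)
    dist, nbr = dist[:, 1:], nbr[:, 1:]   # drop self
    centroid = coords[nbr].mean(axis=1)
    d = np.linalg.norm(centroid - coords, axis=1)
    rbar = dist.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(rbar > 0, d / np.where(rbar > 0, rbar, 1.0), 0.0)
    return EdgeMask(flags=score > tau, k=k, tau=tau)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def threedeps(
    cloud,
    n: int,
    ratio: float = 0.2,
    k: int = 20,
    tau: float = 0.5,
    seed: int = 0,
) -> SampleResult:
    """3D edge-preserving sampling.

    SBF splits the cloud into edge set B and internal set C; the target is
    ``n_e = round(ratio * n)`` edge points and ``n - n_e`` internal points.
    If either part is smaller than its target the whole part is taken and
    the deficit spills to the other part. FPS (independently seeded) runs
    on each part; the concatenated result has exactly ``n`` unique source
    indices. Practical ratios are 0.1–0.5; larger values over-represent
    silhouettes.
    """
    c = _as_cloud(cloud)
    N = c.n_points
    _check_n(n, N)
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("ratio must lie in [0, 1]")
    mask = sbf(c.coords, k=k, tau=tau)
    edge_idx = mask.edge_indices
    int_idx = mask.internal_indices
    n_e = min(_round_half_away(ratio * n), n)
    n_c = n - n_e
    # deficit spill: a part smaller than its target contributes all it has
    if len(edge_idx) < n_e:
        n_e = len(edge_idx)
        n_c = n - n_e
    if len(int_idx) < n_c:
        n_c = len(int_idx)
        n_e = n - n_c
    seed_e, seed_c = _derive_seeds(seed, 2)
    parts = []
    if n_e > 0:
        sub = fps_indices(c.coords[edge_idx], n_e, seed=seed_e)
        parts.append(edge_idx[sub])
    if n_c > 0:
        sub = fps_indices(c.coords[int_idx], n_c, seed=seed_c)
        parts.append(int_idx[sub])
    idx = np.concatenate(parts)
    return _result(
        c, idx, "3DEPS",
        {"n": n, "ratio": ratio, "k": k, "tau": tau, "seed": seed},
    )


def _derive_seeds(seed: int, count: int) -> list[int]:
    """Deterministic child seeds below 2**31 from one base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(count)]


# ---------------------------------------------------------------------------
# helpers: voxel auto-tuning, RS→FPS hybrid
# ---------------------------------------------------------------------------

def auto_voxel_size(
    coords: np.ndarray, n_target: int, isotropy: bool = False
) -> VoxelSpec:
    """Find a voxel size whose occupied-voxel count is in [n, 2n].

    Tuning voxel edges by hand is slow; this bisects a single scale factor
    applied to the bounding-box extents (``isotropy=True`` uses cubic
    voxels scaled from the largest extent) until the occupied count lands
    in ``[n_target, 2 * n_target]``. Deterministic; at most 60 iterations.
    """
    coords = np.asarray(coords, dtype=np.float64)
    N = coords.shape[0]
    if n_target > N:
        raise ValueError(f"n_target={n_target} exceeds point count {N}")
    n_unique = len(np.unique(coords, axis=0))
    if n_unique < n_target:
        raise ValueError(
            f"cloud has only {n_unique} unique points; cannot reach "
            f"{n_target} occupied voxels"
        )
    extent = coords.max(axis=0) - coords.min(axis=0)
    extent = np.maximum(extent, 1e-12)
    if isotropy:
        extent = np.full(3, extent.max())

    def occupied(scale: float) -> int:
        spec = VoxelSpec(*(extent * scale))
        cells, _ = _voxel_cells(coords, spec)
        return len(np.unique(cells, axis=0))

    hi = 1.001  # whole box in one voxel
    lo = hi
    for _ in range(60):
        if occupied(lo) >= n_target:
            break
        lo /= 2.0
    else:
        raise ValueError("could not bracket the requested voxel count")
    for _ in range(60):
        occ = occupied(lo)
        if n_target <= occ <= 2 * n_target:
            return VoxelSpec(*(extent * lo))
        mid = (lo + hi) / 2.0
        if occupied(mid) >= n_target:
            lo, hi = mid, hi
        else:
            hi = mid
    occ = occupied(lo)
    if n_target <= occ <= 2 * n_target:
        return VoxelSpec(*(extent * lo))
    raise ValueError(
        "voxel-size bisection failed to land in the requested bracket "
        "(degenerate point distribution)"
    )


def rs_then_fps(
    cloud, n: int, intermediate: int = 1_000_000, seed: int = 0
) -> SampleResult:
    """RS to an intermediate size, then FPS to ``n``.

    For very dense clouds FPS alone is slow; thinning first with RS to at
    most ``intermediate`` points (skipped when the cloud is already that
    small) keeps FPS tractable. Returned indices point into the original
    cloud.
    """
    c = _as_cloud(cloud)
    N = c.n_points
    if n > intermediate:
        raise ValueError(f"n={n} exceeds intermediate={intermediate}")
    _check_n(n, N)
    seed_rs, seed_fps = _derive_seeds(seed, 2)
    if intermediate >= N:
        idx = fps_indices(c.coords, n, seed=seed_fps)
    else:
        stage1 = rs_indices(N, intermediate, seed=seed_rs)
        sub = fps_indices(c.coords[stage1], n, seed=seed_fps)
        idx = stage1[sub]
    return _result(
        c, idx, "RS+FPS",
        {"n": n, "intermediate": intermediate, "seed": seed},
    )


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

STRATEGIES = ("fps", "rs", "uvs", "vfps", "3deps", "rsfps")


def sample(
    cloud,
    strategy: str,
    n: int,
    seed: int = 0,
    *,
    ratio: float = 0.2,
    voxel: VoxelSpec | None = None,
    sbf_k: int = 20,
    sbf_tau: float = 0.5,
    intermediate: int = 1_000_000,
) -> SampleResult:
    """Run one strategy by name (see :data:`STRATEGIES`).

    UVS/VFPS fall back to :func:`auto_voxel_size` when ``voxel`` is None.
    """
    c = _as_cloud(cloud)
    key = strategy.lower()
    if key == "fps":
        return fps(c, n, seed=seed)
    if key == "rs":
        return rs(c, n, seed=seed)
    if key in ("uvs", "vfps"):
        spec = voxel if voxel is not None else auto_voxel_size(c.coords, n)
        fn = uvs if key == "uvs" else vfps
        return fn(c, n, spec, seed=seed)
    if key == "3deps":
        return threedeps(c, n, ratio=ratio, k=sbf_k, tau=sbf_tau, seed=seed)
    if key == "rsfps":
        return rs_then_fps(c, n, intermediate=intermediate, seed=seed)
    raise ValueError(f"unknown strategy {strategy!r}; choose from "
                     f"{STRATEGIES}")
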