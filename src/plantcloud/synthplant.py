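"""Synthetic labeled plant point clouds and degraded predictions.

Single-plant clouds in the 10,000–100,000-point regime typical of
close-range plant scans, with two semantic classes — the connected stem
system (class 0, no instances) and leaves (class 1, one instance per
leaf) — in two morphologies:

* **dicot** — broad deformed-ellipse leaf blades on short petioles
  (tomato/tobacco-like);
* **monocot** — long slender arched blades sheathing directly from the
  stem, blade length at least 5× its width (sorghum-like).

Points are spread over parametric organ surfaces proportionally to surface
area (floor of 100 points per organ) and jittered with Gaussian noise.
The generator is a test fixture for samplers and metrics: it reproduces
plausible organ geometry, connectivity and label structure, not scanner
artefacts, occlusion or biological variation.

``perturb_prediction`` degrades the ground-truth labels the way real
segmentation networks fail — semantic flips concentrated at organ
boundaries (leaf edges, stem–leaf junctions) plus instance splits and
merges — so metric code can be exercised across the full quality range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloudio import LabeledPointCloud
from .sampling import SampleResult, _derive_seeds, sample

__all__ = [
    "PlantSpec",
    "PerturbSpec",
    "gen_plant",
    "perturb_prediction",
    "augment",
    "split_train_test",
]

logger = logging.getLogger(__name__)

STEM_CLASS = 0
LEAF_CLASS = 1


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of one synthetic plant.

    Lengths are in mm. ``n_points`` must be at least ``100 * (n_leaves+1)``
    so every organ gets a non-degenerate point allocation.
    """

    morphology: str = "dicot"
    n_leaves: int = 6
    n_points: int = 20_000
    stem_height: float = 300.0
    leaf_scale: float = 80.0
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.morphology not in ("dicot", "monocot"):
            raise ValueError("morphology must be 'dicot' or 'monocot'")
        if self.n_leaves < 0:
            raise ValueError("n_leaves must be >= 0")
        if self.n_points < 100 * (self.n_leaves + 1):
            raise ValueError(
                f"n_points={self.n_points} too small for "
                f"{self.n_leaves} leaves; need >= {100 * (self.n_leaves + 1)}"
            )
        if min(self.stem_height, self.leaf_scale) <= 0:
            raise ValueError("stem_height and leaf_scale must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class PerturbSpec:
    """Error rates for degrading a ground-truth labeling.

    ``boundary_flip_rate`` — fraction of boundary points (k-NN
    neighbourhood containing two or more semantic classes) whose predicted
    semantic label is flipped. ``split_prob`` / ``merge_prob`` —
    per-instance probabilities of cutting one leaf in two by a random
    plane, or of merging a leaf with its nearest-centroid neighbour.
    """

    boundary_flip_rate: float = 0.0
    split_prob: float = 0.0
    merge_prob: float = 0.0
    knn: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("boundary_flip_rate", "split_prob", "merge_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _stem_axis(t: np.ndarray, height: float) -> np.ndarray:
    """Slightly curved vertical stem centreline, t in [0, 1]."""
    sway = 0.03 * height
    return np.column_stack([
        sway * np.sin(2.2 * t),
        0.5 * sway * np.sin(1.3 * t + 0.7),
        t * height,
    ])


def _tube_points(rng, n, height, radius, t_lo=0.0, t_hi=1.0):
    t = rng.uniform(t_lo, t_hi, n)
    theta = rng.uniform(0, 2 * np.pi, n)
    axis = _stem_axis(t, height)
    offset = np.column_stack([
        radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)
    ])
    return axis + offset


def _leaf_frame(azimuth: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal frame: outward direction, lateral, up."""
    out = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
    lat = np.array([-np.sin(azimuth), np.cos(azimuth), 0.0])
    up = np.array([0.0, 0.0, 1.0])
    return out, lat, up


def _dicot_leaf(rng, n, base, azimuth, length, elevation):
    """Broad elliptical blade: u along the midrib, v across, drooping tip."""
    out, lat, up = _leaf_frame(azimuth)
    width = 0.55 * length
    u = rng.uniform(0, 1, n)
    v = rng.uniform(-1, 1, n)
    half = width * np.sqrt(np.maximum(u * (1 - u), 0.0))
    along = u * length
    rise = np.sin(elevation) * along - 0.45 * length * u ** 2
    reach = np.cos(elevation) * along
    return (
        base
        + reach[:, None] * out
        + (v * half)[:, None] * lat
        + rise[:, None] * up
    )


def _monocot_leaf(rng, n, base, azimuth, length, _elevation):
    """Long slender arched blade, length >= 5x width."""
    out, lat, up = _leaf_frame(azimuth)
    width = length / 6.0
    u = rng.uniform(0, 1, n)
    v = rng.uniform(-0.5, 0.5, n)
    taper = 1.0 - 0.8 * u
    reach = u * length
    rise = 0.5 * length * np.sin(np.pi * 0.75 * u) * (1 - 0.4 * u)
    return (
        base
        + reach[:, None] * out
        + (v * width * taper)[:, None] * lat
        + rise[:, None] * up
    )


def _petiole(rng, n, base, azimuth, length, elevation):
    """Thin cylinder from the stem to a dicot leaf base."""
    out, _, up = _leaf_frame(azimuth)
    direction = np.cos(elevation) * out + np.sin(elevation) * up
    t = rng.uniform(0, 1, n)
    theta = rng.uniform(0, 2 * np.pi, n)
    perp1 = np.cross(direction, up)
    perp1 /= np.linalg.norm(perp1)
    perp2 = np.cross(direction, perp1)
    r = 0.02 * length
    return (
        base
        + (t * length)[:, None] * direction
        + (r * np.cos(theta))[:, None] * perp1
        + (r * np.sin(theta))[:, None] * perp2
    )


def gen_plant(spec: PlantSpec) -> LabeledPointCloud:
    """Generate one labeled plant; bit-identical for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    H, L = spec.stem_height, spec.leaf_scale
    stem_radius = max(0.012 * H, 1.0)
    golden = np.deg2rad(137.5)

    # organ layout: one stem tube (+ petioles for dicot), n_leaves blades
    leaf_len = L if spec.morphology == "dicot" else 2.8 * L
    organs = []  # (kind, area, sampler)
    stem_area = 2 * np.pi * stem_radius * H
    organs.append(("stem", stem_area, None))
    attach = []
    for i in range(spec.n_leaves):
        t_i = 0.25 + 0.7 * (i / max(spec.n_leaves, 1))
        azimuth = i * golden
        elevation = np.deg2rad(35.0 - 15.0 * (i / max(spec.n_leaves, 1)))
        attach.append((t_i, azimuth, elevation))
        if spec.morphology == "dicot":
            blade_area = np.pi * leaf_len * 0.55 * leaf_len / 4
            organs.append(("petiole", 2 * np.pi * 0.02 * 0.4 * L * 0.4 * L,
                           None))
        else:
            blade_area = leaf_len * leaf_len / 6.0
        organs.append(("leaf", blade_area, None))

    # proportional allocation with a 100-point floor per organ
    areas = np.array([a for _, a, _ in organs])
    alloc = np.maximum(
        100, np.round(spec.n_points * areas / areas.sum()).astype(int)
    )
    # trim/pad the largest organ (the stem) so totals match exactly
    alloc[0] += spec.n_points - alloc.sum()
    if alloc[0] < 100:  # pathological allocation; rebalance from leaves
        deficit = 100 - alloc[0]
        alloc[0] = 100
        alloc[np.argmax(alloc)] -= deficit

    coords_parts, sem_parts, ins_parts = [], [], []
    organ_iter = iter(range(len(organs)))
    k = next(organ_iter)
    coords_parts.append(_tube_points(rng, alloc[k], H, stem_radius))
    sem_parts.append(np.full(alloc[k], STEM_CLASS))
    ins_parts.append(np.full(alloc[k], -1))

    for leaf_id, (t_i, azimuth, elevation) in enumerate(attach):
        stem_pt = _stem_axis(np.array([t_i]), H)[0]
        out, _, up = _leaf_frame(azimuth)
        if spec.morphology == "dicot":
            k = next(organ_iter)
            pet_len = 0.4 * L
            coords_parts.append(
                _petiole(rng, alloc[k], stem_pt + stem_radius * out,
                         azimuth, pet_len, elevation)
            )
            sem_parts.append(np.full(alloc[k], STEM_CLASS))
            ins_parts.append(np.full(alloc[k], -1))
            base = (
                stem_pt + stem_radius * out
                + pet_len * (np.cos(elevation) * out + np.sin(elevation) * up)
            )
            maker = _dicot_leaf
        else:
            base = stem_pt + stem_radius * out
            maker = _monocot_leaf
        k = next(organ_iter)
        coords_parts.append(
            maker(rng, alloc[k], base, azimuth, leaf_len, elevation)
        )
        sem_parts.append(np.full(alloc[k], LEAF_CLASS))
        ins_parts.append(np.full(alloc[k], leaf_id))

    coords = np.concatenate(coords_parts)
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0, spec.noise_sigma, coords.shape)
    return LabeledPointCloud(
        coords=coords,
        sem=np.concatenate(sem_parts),
        ins=np.concatenate(ins_parts),
        species=spec.morphology,
        n_classes=2,
    )


# ---------------------------------------------------------------------------
# prediction degradation
# ---------------------------------------------------------------------------

def perturb_prediction(
    cloud: LabeledPointCloud, pspec: PerturbSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Degrade ground-truth labels into a plausible network prediction.

    Returns ``(pred_sem, pred_ins)``. Semantic flips hit only boundary
    points (those whose ``knn`` nearest neighbours span at least two
    semantic classes); splits cut an instance by a random plane through its
    centroid; merges relabel an instance to its nearest-centroid
    neighbour. Splits or merges requested with too few instances are
    skipped with a log message.
    """
    if cloud.sem is None or cloud.ins is None:
        raise ValueError("perturb_prediction requires a fully labeled cloud")
    rng = np.random.default_rng(pspec.seed)
    pred_sem = cloud.sem.copy()
    pred_ins = cloud.ins.copy()

    if pspec.boundary_flip_rate > 0:
        tree = cKDTree(cloud.coords)
        _, nbr = tree.query(cloud.coords, k=pspec.knn + 1)
        nbr_sem = cloud.sem[nbr]
        boundary = (nbr_sem != nbr_sem[:, :1]).any(axis=1)
        flip = boundary & (rng.random(cloud.n_points)
                           < pspec.boundary_flip_rate)
        for i in np.flatnonzero(flip):
            others = nbr_sem[i][nbr_sem[i] != cloud.sem[i]]
            vals, cnt = np.unique(others, return_counts=True)
            pred_sem[i] = vals[np.argmax(cnt)]

    gt_ids = sorted(int(g) for g in np.unique(cloud.ins) if g >= 0)
    next_id = (max(gt_ids) + 1) if gt_ids else 0

    if pspec.split_prob > 0:
        for gid in gt_ids:
            if rng.random() >= pspec.split_prob:
                continue
            idx = np.flatnonzero(pred_ins == gid)
            if len(idx) < 2:
                logger.info("split of instance %d skipped: too few points",
                            gid)
                continue
            normal = rng.normal(size=3)
            normal /= np.linalg.norm(normal)
            side = (cloud.coords[idx] - cloud.coords[idx].mean(0)) @ normal
            moved = idx[side > 0]
            if 0 < len(moved) < len(idx):
                pred_ins[moved] = next_id
                next_id += 1

    if pspec.merge_prob > 0:
        ids = sorted(int(g) for g in np.unique(pred_ins) if g >= 0)
        if len(ids) < 2:
            logger.info("merge skipped: fewer than two instances")
        else:
            centroids = {
                g: cloud.coords[pred_ins == g].mean(0) for g in ids
            }
            for gid in ids:
                if rng.random() >= pspec.merge_prob:
                    continue
                current = sorted(int(g) for g in np.unique(pred_ins)
                                 if g >= 0)
                if gid not in current or len(current) < 2:
                    continue
                others = [g for g in current if g != gid]
                nearest = min(
                    others,
                    key=lambda g: float(
                        np.linalg.norm(centroids[g] - centroids[gid])
                    ),
                )
                pred_ins[pred_ins == gid] = nearest

    return pred_sem, pred_ins


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def augment(
    cloud: LabeledPointCloud,
    strategy: str,
    n: int = 4096,
    times: int = 10,
    seed: int = 0,
    **params,
) -> list[SampleResult]:
    """``times`` independent seeded runs of one strategy (default 10×4096).

    Random-start FPS (and the seeded randomness of the other strategies)
    makes each run a distinct cloud, which is the usual augmentation for
    training point-level networks. Child seeds derive deterministically
    from ``seed``.
    """
    seeds = _derive_seeds(seed, times)
    return [
        sample(cloud, strategy, n, seed=s, **params) for s in seeds
    ]


def split_train_test(
    clouds: list, ratio: tuple[int, int] = (2, 1), seed: int = 0
) -> tuple[list, list]:
    """Seeded shuffle then split; |train| = round(K * ratio0 / sum(ratio))."""
    k = len(clouds)
    if k < 3:
        raise ValueError("need at least 3 clouds to split")
    n_train = round(k * ratio[0] / (ratio[0] + ratio[1]))
    order = np.random.default_rng(seed).permutation(k)
    train = [clouds[i] for i in order[:n_train]]
    test = [clouds[i] for i in order[n_train:]]
    return train, test
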