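"""Point-cloud containers and file I/O.

The central container is :class:`LabeledPointCloud`: an ``(N, 3)`` coordinate
array with optional per-point semantic labels (organ classes, ``0..C-1``) and
instance labels (individual leaves; ``-1`` marks points that belong to no
instance, i.e. the stem system).

Three interchange formats are supported:

* labeled-XYZ text — one point per line, ``x y z [sem [ins]]``, ``#`` comments;
* PLY (ASCII and binary little-endian) with optional integer vertex
  properties ``sem``/``label`` and ``ins``/``instance``;
* HDF5 batches of equally sized clouds (datasets ``data``, ``sem``, ``ins``),
  the layout point-level segmentation networks train on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError, ParseError

__all__ = [
    "LabeledPointCloud",
    "BatchFile",
    "read_labeled_xyz",
    "write_labeled_xyz",
    "read_ply",
    "write_ply",
    "read_h5_batch",
    "write_h5_batch",
    "normalize_cloud",
]


@dataclass
class LabeledPointCloud:
    """A single plant point cloud with optional per-point labels.

    Parameters
    ----------
    coords
        ``(N, 3)`` float array, arbitrary length units (typically mm).
    sem
        Optional length-``N`` integer semantic labels in ``[0, C)``.
    ins
        Optional length-``N`` integer instance labels; ``-1`` = no instance.
    species
        Optional free-text tag (e.g. ``"tomato"``).
    n_classes
        Number of semantic classes ``C``; inferred as ``max(sem) + 1`` when
        labels are present and no explicit value is given.
    """

    coords: np.ndarray
    sem: np.ndarray | None = None
    ins: np.ndarray | None = None
    species: str | None = None
    n_classes: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("a point cloud needs at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        n = self.coords.shape[0]
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=np.int64)
            if self.sem.shape != (n,):
                raise ValueError("sem must have one label per point")
            if self.sem.min() < 0:
                raise ValueError("semantic labels must be non-negative")
            if self.n_classes is None:
                self.n_classes = int(self.sem.max()) + 1
            elif self.sem.max() >= self.n_classes:
                raise ValueError(
                    f"semantic label {int(self.sem.max())} outside [0, "
                    f"{self.n_classes})"
                )
        if self.ins is not None:
            self.ins = np.asarray(self.ins, dtype=np.int64)
            if self.ins.shape != (n,):
                raise ValueError("ins must have one label per point")
            if self.ins.min() < -1:
                raise ValueError("instance labels must be >= -1")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def take(self, indices: np.ndarray) -> "LabeledPointCloud":
        """Sub-cloud at ``indices``, labels carried over."""
        idx = np.asarray(indices)
        return replace(
            self,
            coords=self.coords[idx],
            sem=None if self.sem is None else self.sem[idx],
            ins=None if self.ins is None else self.ins[idx],
        )


@dataclass
class BatchFile:
    """A list of clouds sharing a fixed per-cloud point count (default 4096)."""

    clouds: list[LabeledPointCloud] = field(default_factory=list)
    n_fixed: int = 4096

    def __post_init__(self) -> None:
        for c in self.clouds:
            if c.n_points != self.n_fixed:
                raise ValueError(
                    f"cloud with {c.n_points} points in a batch fixed at "
                    f"{self.n_fixed}; down-sample it first"
                )


def _as_cloud(obj) -> LabeledPointCloud:
    if isinstance(obj, LabeledPointCloud):
        return obj
    return LabeledPointCloud(coords=np.asarray(obj, dtype=np.float64))


# ---------------------------------------------------------------------------
# labeled-XYZ text
# ---------------------------------------------------------------------------

def read_labeled_xyz(path: str | Path) -> LabeledPointCloud:
    """Read a whitespace-separated ``x y z [sem [ins]]`` text file.

    Labels are present in the returned cloud iff the corresponding columns
    exist on every data line. Lines starting with ``#`` (and inline ``#``
    comments) are ignored.
    """
    coords: list[tuple[float, float, float]] = []
    sems: list[int] = []
    inss: list[int] = []
    ncols: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) not in (3, 4, 5):
                raise ParseError(
                    f"{path}:{lineno}: expected 3, 4 or 5 fields, got "
                    f"{len(fields)}"
                )
            if ncols is None:
                ncols = len(fields)
            elif len(fields) != ncols:
                raise ParseError(
                    f"{path}:{lineno}: inconsistent field count "
                    f"({len(fields)} vs {ncols})"
                )
            try:
                coords.append(
                    (float(fields[0]), float(fields[1]), float(fields[2]))
                )
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric coordinate"
                ) from exc
            try:
                if ncols >= 4:
                    sems.append(int(fields[3]))
                if ncols == 5:
                    inss.append(int(fields[4]))
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer label"
                ) from exc
    if not coords:
        raise ParseError(f"{path}: no points found")
    return LabeledPointCloud(
        coords=np.asarray(coords, dtype=np.float64),
        sem=np.asarray(sems, dtype=np.int64) if sems else None,
        ins=np.asarray(inss, dtype=np.int64) if inss else None,
    )


def write_labeled_xyz(cloud: LabeledPointCloud, path: str | Path) -> None:
    """Write ``%.6f %.6f %.6f [sem [ins]]`` lines; labels only if present."""
    with open(path, "w") as fh:
        for i in range(cloud.n_points):
            x, y, z = cloud.coords[i]
            parts = [f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"]
            if cloud.sem is not None:
                parts.append(str(int(cloud.sem[i])))
                if cloud.ins is not None:
                    parts.append(str(int(cloud.ins[i])))
            fh.write(" ".join(parts) + "\n")


# ---------------------------------------------------------------------------
# PLY — minimal vertex-only codec (ASCII + binary little-endian)
# ---------------------------------------------------------------------------

_PLY_SCALARS = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}

_SEM_NAMES = ("sem", "label")
_INS_NAMES = ("ins", "instance")


def read_ply(path: str | Path) -> LabeledPointCloud:
    """Read a PLY point cloud (ASCII or binary little-endian).

    The ``vertex`` element must carry ``x``/``y``/``z``; integer properties
    named ``sem``/``label`` and ``ins``/``instance`` become labels.
    """
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise FormatError(f"{path}: not a PLY file")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        while True:
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: unterminated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if not elements:
                    raise FormatError(f"{path}: property before element")
                if tokens[1] == "list":
                    elements[-1][2].append((tokens[-1], "list"))
                else:
                    elements[-1][2].append((tokens[-1], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise FormatError(f"{path}: unsupported PLY format {fmt!r}")
        names = [name for name, _, _ in elements]
        if "vertex" not in names:
            raise FormatError(f"{path}: PLY has no vertex element")
        if names.index("vertex") != 0:
            raise FormatError(f"{path}: vertex must be the first element")
        vname, count, props = elements[0]
        for p, t in props:
            if t == "list":
                raise FormatError(f"{path}: list property {p!r} on vertices")
        dtype = np.dtype(
            [(p, "<" + _PLY_SCALARS[t]) for p, t in props]
        )
        if fmt == "ascii":
            rows = []
            while len(rows) < count:
                line = fh.readline()
                if not line:
                    raise FormatError(f"{path}: truncated vertex data")
                fields = line.split()
                if not fields:
                    continue
                rows.append(tuple(float(v) for v in fields))
            data = np.array(rows, dtype=dtype)
        else:
            buf = fh.read(dtype.itemsize * count)
            if len(buf) != dtype.itemsize * count:
                raise FormatError(f"{path}: truncated vertex data")
            data = np.frombuffer(buf, dtype=dtype)
    for ax in ("x", "y", "z"):
        if ax not in data.dtype.names:
            raise FormatError(f"{path}: vertex lacks coordinate {ax!r}")
    coords = np.column_stack(
        [data["x"], data["y"], data["z"]]
    ).astype(np.float64)
    sem = ins = None
    for name in _SEM_NAMES:
        if name in data.dtype.names:
            sem = data[name].astype(np.int64)
            break
    for name in _INS_NAMES:
        if name in data.dtype.names:
            ins = data[name].astype(np.int64)
            break
    return LabeledPointCloud(coords=coords, sem=sem, ins=ins)


def write_ply(
    cloud: LabeledPointCloud, path: str | Path, ascii: bool = False
) -> None:
    """Write a PLY point cloud, binary little-endian by default.

    Coordinates are stored as float32 (the format's customary precision),
    labels as int32 properties ``sem`` and ``ins``.
    """
    props = [("x", "float"), ("y", "float"), ("z", "float")]
    if cloud.sem is not None:
        props.append(("sem", "int"))
    if cloud.ins is not None:
        props.append(("ins", "int"))
    dtype = np.dtype([(p, "<" + _PLY_SCALARS[t]) for p, t in props])
    data = np.empty(cloud.n_points, dtype=dtype)
    data["x"], data["y"], data["z"] = cloud.coords.T.astype(np.float32)
    if cloud.sem is not None:
        data["sem"] = cloud.sem
    if cloud.ins is not None:
        data["ins"] = cloud.ins
    fmt = "ascii" if ascii else "binary_little_endian"
    header = ["ply", f"format {fmt} 1.0",
              f"element vertex {cloud.n_points}"]
    header += [f"property {t} {p}" for p, t in props]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if ascii:
            for row in data:
                fields = []
                for p, t in props:
                    v = row[p]
                    fields.append(
                        f"{float(v):.9g}" if t == "float" else str(int(v))
                    )
                fh.write((" ".join(fields) + "\n").encode("ascii"))
        else:
            fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# HDF5 batches
# ---------------------------------------------------------------------------

def write_h5_batch(batch: BatchFile, path: str | Path) -> None:
    """Write a batch as HDF5: ``data`` (B, n, 3) float32, ``sem``/``ins``
    (B, n) int64 when every member cloud carries that label."""
    b = len(batch.clouds)
    if b == 0:
        raise ValueError("cannot write an empty batch")
    data = np.stack([c.coords for c in batch.clouds]).astype(np.float32)
    have_sem = all(c.sem is not None for c in batch.clouds)
    have_ins = all(c.ins is not None for c in batch.clouds)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=data)
        if have_sem:
            fh.create_dataset(
                "sem", data=np.stack([c.sem for c in batch.clouds])
            )
        if have_ins:
            fh.create_dataset(
                "ins", data=np.stack([c.ins for c in batch.clouds])
            )


def read_h5_batch(path: str | Path) -> BatchFile:
    with h5py.File(path, "r") as fh:
        if "data" not in fh:
            raise FormatError(f"{path}: missing 'data' dataset")
        data = np.asarray(fh["data"], dtype=np.float64)
        if data.ndim != 3 or data.shape[2] != 3:
            raise FormatError(
                f"{path}: 'data' must be (B, n, 3), got {data.shape}"
            )
        sem = np.asarray(fh["sem"]) if "sem" in fh else None
        ins = np.asarray(fh["ins"]) if "ins" in fh else None
    clouds = [
        LabeledPointCloud(
            coords=data[i],
            sem=None if sem is None else sem[i],
            ins=None if ins is None else ins[i],
        )
        for i in range(data.shape[0])
    ]
    return BatchFile(clouds=clouds, n_fixed=data.shape[1])


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def normalize_cloud(cloud: LabeledPointCloud) -> LabeledPointCloud:
    """Translate to zero centroid and scale the max radius to 1.

    Makes distance-parameterised steps (voxel sizes, SBF thresholds)
    comparable across acquisitions. A zero-extent cloud is translated only.
    Idempotent.
    """
    centered = cloud.coords - cloud.coords.mean(axis=0)
    radius = np.linalg.norm(centered, axis=1).max()
    if radius > 0:
        centered = centered / radius
    return replace(cloud, coords=centered)
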