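"""Published benchmark tables for the scoring harness.

Metric values (in %) from a published cross-network benchmark comparing
the five down-sampling strategies (FPS, RS, UVS, VFPS, 3DEPS) on five
point-cloud segmentation networks, on a three-species crop dataset
(tomato / tobacco / sorghum) and on a multi-view soybean dataset. The
single-function networks (PointNet++, DGCNN) report the four semantic
metrics; the dual-function networks (ASIS, PlantNet, PSegNet) additionally
report the four instance metrics.

These matrices are inputs to :mod:`plantcloud.ranking`: feeding them to
:func:`~plantcloud.ranking.score_table` reproduces the benchmark's
published Score ranking.
"""

from __future__ import annotations

from .ranking import StrategyMetricsTable

__all__ = ["BENCHMARK_TABLES", "benchmark_table"]

_STRATEGIES = ("FPS", "RS", "UVS", "VFPS", "3DEPS")

_RAW = {
    # network: {strategy: [Precision, Recall, F1, IoU(, Cov, WCov, mPrec, mRec)]}
    "pointnet2": {
        "FPS": [85.38, 84.62, 84.96, 75.77],
        "RS": [85.29, 84.81, 85.01, 76.00],
        "UVS": [86.07, 86.15, 85.90, 77.03],
        "VFPS": [85.55, 84.95, 85.08, 75.91],
        "3DEPS": [85.64, 86.05, 85.74, 76.80],
    },
    "dgcnn": {
        "FPS": [92.03, 90.50, 91.22, 84.85],
        "RS": [93.23, 92.09, 92.64, 87.04],
        "UVS": [92.53, 91.75, 92.13, 86.25],
        "VFPS": [91.98, 92.10, 92.04, 86.11],
        "3DEPS": [92.67, 92.56, 92.60, 86.93],
    },
    "asis": {
        "FPS": [79.77, 81.44, 79.62, 67.24, 63.46, 70.37, 69.58, 58.41],
        "RS": [82.67, 82.09, 82.04, 70.28, 62.85, 70.34, 67.73, 53.56],
        "UVS": [83.97, 81.09, 81.93, 70.18, 61.29, 69.10, 68.73, 52.15],
        "VFPS": [84.33, 81.03, 82.08, 70.66, 62.20, 69.88, 67.90, 51.73],
        "3DEPS": [83.33, 82.48, 82.34, 70.24, 64.01, 71.92, 71.45, 54.62],
    },
    "plantnet": {
        "FPS": [91.83, 89.56, 90.63, 83.22, 77.27, 83.23, 81.89, 76.19],
        "RS": [93.38, 91.87, 92.60, 86.66, 79.38, 86.25, 85.43, 75.97],
        "UVS": [93.66, 92.35, 92.99, 87.21, 79.72, 86.44, 84.83, 75.17],
        "VFPS": [93.67, 91.84, 92.77, 86.88, 77.90, 85.55, 81.61, 73.70],
        "3DEPS": [93.61, 92.45, 93.02, 87.29, 79.22, 86.25, 85.10, 75.60],
    },
    "psegnet": {
        "FPS": [90.03, 89.38, 89.68, 81.90, 79.63, 85.50, 84.30, 78.18],
        "RS": [91.71, 91.04, 91.35, 84.62, 78.79, 85.67, 83.54, 72.80],
        "UVS": [93.10, 92.62, 92.67, 86.78, 80.12, 86.77, 85.37, 74.99],
        "VFPS": [92.26, 92.14, 92.18, 85.99, 78.21, 85.67, 85.05, 72.27],
        "3DEPS": [92.24, 91.86, 92.04, 85.74, 79.03, 85.92, 84.37, 73.48],
    },
    "pointnet2-soybean": {
        "FPS": [72.42, 70.18, 71.33, 58.91],
        "RS": [73.82, 69.85, 70.31, 42.63],
        "UVS": [73.11, 73.27, 72.98, 60.44],
        "VFPS": [71.19, 68.66, 69.56, 57.42],
        "3DEPS": [70.04, 66.63, 67.62, 53.26],
    },
    "dgcnn-soybean": {
        "FPS": [90.93, 88.58, 89.68, 82.00],
        "RS": [91.51, 91.68, 91.59, 84.62],
        "UVS": [90.95, 89.03, 89.93, 82.36],
        "VFPS": [91.08, 86.93, 88.83, 80.77],
        "3DEPS": [92.13, 92.20, 92.16, 85.63],
    },
    "asis-soybean": {
        "FPS": [91.47, 85.05, 87.81, 79.27, 28.83, 35.12, 37.79, 10.69],
        "RS": [89.66, 85.27, 86.95, 77.32, 33.07, 33.25, 35.74, 11.72],
        "UVS": [89.30, 85.04, 86.94, 77.97, 28.22, 33.85, 37.21, 10.29],
        "VFPS": [88.36, 80.29, 83.53, 73.49, 27.02, 34.06, 36.64, 10.38],
        "3DEPS": [89.32, 88.83, 89.06, 80.60, 28.52, 29.34, 31.72, 9.06],
    },
    "plantnet-soybean": {
        "FPS": [86.79, 87.30, 87.03, 78.04, 45.06, 51.52, 51.27, 27.08],
        "RS": [88.95, 88.89, 88.92, 80.27, 45.54, 45.75, 46.32, 24.70],
        "UVS": [86.23, 86.87, 86.54, 77.31, 43.56, 50.93, 49.82, 25.03],
        "VFPS": [86.80, 86.55, 86.69, 77.61, 38.95, 46.35, 45.41, 19.89],
        "3DEPS": [89.61, 89.36, 89.48, 81.26, 45.37, 46.21, 44.36, 24.70],
    },
    "psegnet-soybean": {
        "FPS": [86.75, 86.76, 86.75, 77.65, 45.40, 51.19, 48.76, 26.65],
        "RS": [89.13, 89.01, 89.06, 80.50, 46.40, 46.54, 47.33, 27.31],
        "UVS": [85.82, 86.81, 86.30, 76.96, 44.01, 50.93, 49.17, 25.14],
        "VFPS": [85.13, 86.16, 85.61, 76.08, 38.68, 45.52, 43.67, 20.10],
        "3DEPS": [88.64, 88.31, 88.47, 79.67, 47.99, 48.96, 50.27, 29.64],
    },
}

BENCHMARK_TABLES: dict[str, StrategyMetricsTable] = {
    name: StrategyMetricsTable.from_dict(
        {s: rows[s] for s in _STRATEGIES}
    )
    for name, rows in _RAW.items()
}


def benchmark_table(name: str) -> StrategyMetricsTable:
    """Fetch one published table by key (e.g. ``"pointnet2"``, ``"asis"``)."""
    try:
        return BENCHMARK_TABLES[name]
    except KeyError:
        raise KeyError(
            f"unknown benchmark {name!r}; available: "
            f"{sorted(BENCHMARK_TABLES)}"
        ) from None
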