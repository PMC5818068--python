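"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, direct definitions)
and independent of the library code paths it checks.
"""

from __future__ import annotations

import numpy as np


def pair_count_auc(values, labels) -> float:
    """Mann-Whitney AUC by O(n^2) pair counting, ties worth 0.5, folded."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = values[labels]
    neg = values[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    auc = wins / (len(pos) * len(neg))
    return max(auc, 1.0 - auc)


def slab_average_loops(data: np.ndarray, ratio: int) -> np.ndarray:
    """Slice-group averaging by explicit voxel loops (double precision)."""
    nx, ny, nz = data.shape
    n_out = nz // ratio
    out = np.zeros((nx, ny, n_out), dtype=np.float64)
    for i in range(nx):
        for j in range(ny):
            for k in range(n_out):
                acc = 0.0
                for r in range(ratio):
                    acc += float(data[i, j, k * ratio + r])
                out[i, j, k] = acc / ratio
    return out


def lce_sliding_window(data: np.ndarray, window: int) -> np.ndarray:
    """In-plane local standardization by an explicit double loop with
    reflect padding; epsilon 1 matches the enhancement definition."""
    half = window // 2
    out = np.zeros_like(data, dtype=np.float64)
    padded = np.pad(data.astype(np.float64), ((half, half), (half, half), (0, 0)),
                    mode="symmetric")  # edge-repeating reflection
    nx, ny, nz = data.shape
    for i in range(nx):
        for j in range(ny):
            patch = padded[i : i + window, j : j + window, :]
            mean = patch.mean(axis=(0, 1))
            std = patch.std(axis=(0, 1))
            out[i, j, :] = (data[i, j, :] - mean) / (std + 1.0)
    return out


def sphere_fill_fraction(center_mm, radius_mm, voxel_indices, spacing, origin,
                         supersample: int = 10) -> float:
    """Mean occupancy of a sphere over the listed voxels, by analytic
    inside-tests on a ``supersample``^3 subgrid per voxel."""
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    center = np.asarray(center_mm, dtype=float)
    steps = (np.arange(supersample) + 0.5) / supersample - 0.5
    offsets = np.stack(
        np.meshgrid(*[steps * s for s in spacing], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    fracs = []
    for idx in voxel_indices:
        voxel_center = origin + np.asarray(idx) * spacing
        pts = voxel_center + offsets
        inside = np.sum((pts - center) ** 2, axis=1) <= radius_mm**2
        fracs.append(inside.mean())
    return float(np.mean(fracs))


def froc_resweep(scores, target_ids, n_cases, n_targets):
    """Direct threshold re-sweep: for each distinct score threshold compute
    (FP/case, sensitivity) from scratch."""
    scores = np.asarray(scores, dtype=float)
    target_ids = np.asarray(target_ids, dtype=int)
    points = []
    for t in sorted(set(scores), reverse=True):
        sel = scores >= t
        hits = {int(x) for x in target_ids[sel] if x >= 0}
        fps = int(np.sum(sel & (target_ids < 0)))
        points.append((fps / n_cases, len(hits) / n_targets))
    return points


def step_auc_0_10(points) -> float:
    """Integrate a right-continuous step curve over [0, 10] directly."""

    def sens_at(f):
        best = 0.0
        for fp, s in points:
            if fp <= f:
                best = max(best, s)
        return best

    breaks = sorted({0.0, 10.0, *[min(fp, 10.0) for fp, _ in points]})
    area = 0.0
    for a, b in zip(breaks, breaks[1:]):
        area += sens_at(a) * (b - a)
    return area


def step_anode(points) -> float:
    rates = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

    def sens_at(f):
        best = 0.0
        for fp, s in points:
            if fp <= f:
                best = max(best, s)
        return best

    return float(np.mean([sens_at(r) for r in rates]))
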