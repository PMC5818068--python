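"""Per-candidate feature catalog: geometry, intensity, gradient, position.

Each candidate is described by a fixed-order vector of real features
computed from the raw HU volume and two local-contrast-enhanced (LCE)
substrates, obtained by standardizing every voxel against its in-plane
window mean and std (windows 11 and 51).  Intensity statistics are taken
inside the candidate mask and over a surrounding shell (a 3-voxel
dilation band clipped to the lung), gradient statistics over the mask
interior, its boundary ("perimeter") and the shell, and positional
features relate the candidate to the lung field as a whole.

Numbered variants of separation-type statistics are realized on three
mask variants — eroded by one voxel, original, dilated by one voxel —
which probes how sharply a statistic changes across the candidate's rim.
Degenerate denominators are floored so every feature is finite; a
candidate whose shell is empty gets zeros for shell-dependent features
and a raised flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter as skimage_perimeter

from .volume_io import CTVolume

EPS_STD = 1.0  # HU floor on the LCE local std
EPS_FISHER = 1e-6
SHELL_DILATION_VOXELS = 3
BOTTOM_SHADOW_DEPTH_MM = 30.0
BOTTOM_SHADOW_THRESHOLD_HU = -500.0

__all__ = [
    "FeatureVector",
    "CaseContext",
    "FEATURE_NAMES",
    "local_contrast_enhance",
    "build_case_context",
    "compute_feature_vector",
    "featurize_case",
    "fisher_ratio",
]


def local_contrast_enhance(vol, window: int) -> np.ndarray:
    """Standardize each voxel against its in-plane window: (v - mean)/(std + 1).

    The window is ``window x window`` within the axial plane (reflect
    boundary); the 1-HU epsilon keeps flat regions at exactly zero.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"LCE window must be odd and >= 3, got {window}")
    data = vol.data if isinstance(vol, CTVolume) else vol
    data = np.asarray(data, dtype=np.float64)
    size = (window, window, 1)
    mean = ndimage.uniform_filter(data, size=size, mode="reflect")
    sq = ndimage.uniform_filter(data * data, size=size, mode="reflect")
    std = np.sqrt(np.maximum(sq - mean * mean, 0.0))
    return ((data - mean) / (std + EPS_STD)).astype(np.float32)


def fisher_ratio(inside, outside) -> float:
    """Class-separation score (mu_in - mu_out)^2 / (var_in + var_out + 1e-6)."""
    inside = np.asarray(inside, dtype=float)
    outside = np.asarray(outside, dtype=float)
    if inside.size == 0 or outside.size == 0:
        raise ValueError("fisher_ratio requires nonempty samples")
    num = (inside.mean() - outside.mean()) ** 2
    return float(num / (inside.var() + outside.var() + EPS_FISHER))


@dataclass
class CaseContext:
    """Per-case substrates shared by all candidates of one volume."""

    volume: CTVolume
    raw: np.ndarray
    lce1: np.ndarray
    lce2: np.ndarray
    lung_mask: np.ndarray
    lung_centroid_mm: np.ndarray
    lung_bbox_mm: tuple[np.ndarray, np.ndarray]  # (lo, hi) world mm
    lung_edt_mm: np.ndarray  # distance to lung boundary, inside the lung
    gradients: tuple[np.ndarray, np.ndarray, np.ndarray]
    gradients_lce1: tuple[np.ndarray, np.ndarray, np.ndarray]


def build_case_context(
    vol: CTVolume, lung_mask: np.ndarray, windows: tuple[int, int] = (11, 51)
) -> CaseContext:
    raw = vol.data.astype(np.float32)
    lce1 = local_contrast_enhance(vol, windows[0])
    lce2 = local_contrast_enhance(vol, windows[1])
    spacing = np.asarray(vol.spacing)
    origin = np.asarray(vol.origin)
    if lung_mask.any():
        idx = np.argwhere(lung_mask)
        centroid = origin + idx.mean(axis=0) * spacing
        lo = origin + idx.min(axis=0) * spacing
        hi = origin + idx.max(axis=0) * spacing
        edt = ndimage.distance_transform_edt(lung_mask, sampling=vol.spacing)
    else:
        centroid = origin + (np.asarray(vol.shape) - 1) / 2.0 * spacing
        lo, hi = origin, origin + (np.asarray(vol.shape) - 1) * spacing
        edt = np.zeros(vol.shape, dtype=float)
    grads = np.gradient(raw.astype(np.float64), *vol.spacing)
    grads_l1 = np.gradient(lce1.astype(np.float64), *vol.spacing)
    return CaseContext(
        volume=vol,
        raw=raw,
        lce1=lce1,
        lce2=lce2,
        lung_mask=lung_mask,
        lung_centroid_mm=centroid,
        lung_bbox_mm=(lo, hi),
        lung_edt_mm=edt,
        gradients=tuple(g.astype(np.float32) for g in grads),
        gradients_lce1=tuple(g.astype(np.float32) for g in grads_l1),
    )


def _build_names() -> tuple[str, ...]:
    names = [
        "n_slices",
        "equivalent_diameter_mm",
        "circularity",
        "elongation",
        "compactness_bbox",
        "area_outside_mm2",
        "periapsis_mm",
        "dist_center_projection_mm",
        "x_fraction_global",
        "bottom_shadow_fraction",
        "std_voxel_below_raw",
        "std_voxel_below_lce1",
        "contrast_z",
        "fisher_ratio_z",
    ]
    for sub in ("raw", "lce1", "lce2"):
        names += [
            f"mean_inside_{sub}",
            f"std_inside_{sub}",
            f"min_inside_{sub}",
            f"max_inside_{sub}",
            f"mean_outside_{sub}",
            f"std_outside_{sub}",
            f"contrast_{sub}",
            f"std_separation_{sub}",
            f"fisher_ratio_{sub}",
        ]
    names += [
        "fisher_ratio_raw_eroded",
        "fisher_ratio_raw_dilated",
        "std_separation_raw_eroded",
        "std_separation_raw_dilated",
        "grad_mag_mean_inside",
        "grad_mag_mean_outside",
        "surface_gradient",
        "surface_gradient_lce1",
    ]
    for stat in ("radial_grad", "radial_dev"):
        for region in ("inside", "perimeter", "outside"):
            names += [f"{stat}_mean_{region}", f"{stat}_std_{region}"]
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = _build_names()


@dataclass
class FeatureVector:
    names: tuple[str, ...]
    values: np.ndarray
    shell_empty: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def _safe_mean(values: np.ndarray) -> float:
    return float(values.mean()) if values.size else 0.0


def _safe_std(values: np.ndarray) -> float:
    return float(values.std()) if values.size else 0.0


def compute_feature_vector(candidate, ctx: CaseContext) -> FeatureVector:
    """Compute the full catalog for one candidate.

    ``candidate`` needs ``indices`` (voxel index array) and ``centroid_mm``.
    Shell-dependent features are zeroed (and ``shell_empty`` raised) when
    the 3-voxel dilation band around the candidate contains no lung voxel.
    """
    vol = ctx.volume
    spacing = np.asarray(vol.spacing)
    origin = np.asarray(vol.origin)
    idx = np.asarray(candidate.indices)
    centroid_mm = np.asarray(candidate.centroid_mm, dtype=float)
    shape = np.asarray(vol.shape)

    # local crop with room for the shell band
    margin = SHELL_DILATION_VOXELS + 2
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    local_idx = idx - lo

    mask = np.zeros(tuple(hi - lo), dtype=bool)
    mask[local_idx[:, 0], local_idx[:, 1], local_idx[:, 2]] = True
    eroded = ndimage.binary_erosion(mask)
    if not eroded.any():
        eroded = mask
    dilated = ndimage.binary_dilation(mask)
    dilate3 = ndimage.binary_dilation(mask, iterations=SHELL_DILATION_VOXELS)
    lung_local = ctx.lung_mask[sl]
    shell = dilate3 & ~mask & lung_local
    shell_empty = not shell.any()
    perim = mask & ~ndimage.binary_erosion(mask)
    if not perim.any():
        perim = mask

    raw_l = ctx.raw[sl]
    lce1_l = ctx.lce1[sl]
    lce2_l = ctx.lce2[sl]
    subs = {"raw": raw_l, "lce1": lce1_l, "lce2": lce2_l}

    feats: dict[str, float] = {}
    n_vox = idx.shape[0]
    voxel_mm3 = float(np.prod(spacing))
    volume_mm3 = n_vox * voxel_mm3

    # --- geometric ---
    z_vals = np.unique(idx[:, 2])
    feats["n_slices"] = float(z_vals.size)
    feats["equivalent_diameter_mm"] = float((6.0 * volume_mm3 / np.pi) ** (1.0 / 3.0))

    slice_counts = np.bincount(idx[:, 2] - idx[:, 2].min())
    best_z = int(np.argmax(slice_counts)) + int(idx[:, 2].min())
    mask2d = mask[:, :, best_z - int(lo[2])]
    area = mask2d.sum() * spacing[0] * spacing[1]
    in_plane = float(np.sqrt(spacing[0] * spacing[1]))
    per = skimage_perimeter(mask2d) * in_plane
    feats["circularity"] = float(4.0 * np.pi * area / (per**2)) if per > 0 else 1.0

    pos_mm = origin + idx * spacing
    if n_vox >= 2:
        cov = np.cov(pos_mm.T)
        eigs = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
        feats["elongation"] = (
            float(np.sqrt(eigs[-1] / eigs[0])) if eigs[0] > 1e-9 else float(np.sqrt(eigs[-1] / 1e-9))
        )
    else:
        feats["elongation"] = 1.0

    extent = idx.max(axis=0) - idx.min(axis=0) + 1
    feats["compactness_bbox"] = float(n_vox / np.prod(extent))
    feats["area_outside_mm2"] = float(shell.sum() * spacing[0] * spacing[1])

    cvox = np.clip(np.rint((centroid_mm - origin) / spacing).astype(int), 0, shape - 1)
    feats["periapsis_mm"] = float(ctx.lung_edt_mm[tuple(cvox)])

    # --- positional ---
    feats["dist_center_projection_mm"] = float(
        np.linalg.norm((centroid_mm - ctx.lung_centroid_mm)[:2])
    )
    blo, bhi = ctx.lung_bbox_mm
    span = max(bhi[0] - blo[0], 1e-6)
    feats["x_fraction_global"] = float(np.clip((centroid_mm[0] - blo[0]) / span, 0.0, 1.0))

    # column "below" the candidate = +y direction, depth 30 mm
    depth_vox = int(round(BOTTOM_SHADOW_DEPTH_MM / spacing[1]))
    y0 = int(cvox[1]) + 1
    y1 = min(y0 + depth_vox, shape[1])
    col = (int(cvox[0]), slice(y0, y1), int(cvox[2]))
    col_lung = ctx.lung_mask[col]
    col_raw = ctx.raw[col][col_lung]
    feats["bottom_shadow_fraction"] = (
        float((col_raw > BOTTOM_SHADOW_THRESHOLD_HU).mean()) if col_raw.size else 0.0
    )
    feats["std_voxel_below_raw"] = _safe_std(col_raw)
    feats["std_voxel_below_lce1"] = _safe_std(ctx.lce1[col][col_lung])

    # --- z-profile contrast through the centroid ---
    zlo, zhi = int(idx[:, 2].min()), int(idx[:, 2].max())
    profile = ctx.raw[int(cvox[0]), int(cvox[1]), :]
    inside_z = profile[zlo : zhi + 1]
    out_parts = [
        profile[max(zlo - SHELL_DILATION_VOXELS, 0) : zlo],
        profile[zhi + 1 : min(zhi + 1 + SHELL_DILATION_VOXELS, shape[2])],
    ]
    outside_z = np.concatenate([p for p in out_parts if p.size]) if any(
        p.size for p in out_parts
    ) else np.zeros(0)
    if outside_z.size:
        feats["contrast_z"] = float(inside_z.mean() - outside_z.mean())
        feats["fisher_ratio_z"] = fisher_ratio(inside_z, outside_z)
    else:
        feats["contrast_z"] = 0.0
        feats["fisher_ratio_z"] = 0.0

    # --- intensity statistics per substrate ---
    for name, arr in subs.items():
        inside = arr[mask].astype(np.float64)
        out = arr[shell].astype(np.float64)
        feats[f"mean_inside_{name}"] = float(inside.mean())
        feats[f"std_inside_{name}"] = float(inside.std())
        feats[f"min_inside_{name}"] = float(inside.min())
        feats[f"max_inside_{name}"] = float(inside.max())
        feats[f"mean_outside_{name}"] = _safe_mean(out)
        feats[f"std_outside_{name}"] = _safe_std(out)
        if shell_empty:
            feats[f"contrast_{name}"] = 0.0
            feats[f"std_separation_{name}"] = 0.0
            feats[f"fisher_ratio_{name}"] = 0.0
        else:
            feats[f"contrast_{name}"] = float(inside.mean() - out.mean())
            feats[f"std_separation_{name}"] = float(inside.std() - out.std())
            feats[f"fisher_ratio_{name}"] = fisher_ratio(inside, out)

    # --- rim-variant separations (eroded / dilated inside masks) ---
    for vname, vmask in (("eroded", eroded), ("dilated", dilated)):
        inside = raw_l[vmask].astype(np.float64)
        out_mask = shell & ~vmask
        out = raw_l[out_mask].astype(np.float64)
        if inside.size == 0 or out.size == 0:
            feats[f"fisher_ratio_raw_{vname}"] = 0.0
            feats[f"std_separation_raw_{vname}"] = 0.0
        else:
            feats[f"fisher_ratio_raw_{vname}"] = fisher_ratio(inside, out)
            feats[f"std_separation_raw_{vname}"] = float(inside.std() - out.std())

    # --- gradient statistics ---
    g = [ctx.gradients[i][sl].astype(np.float64) for i in range(3)]
    gmag = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
    feats["grad_mag_mean_inside"] = _safe_mean(gmag[mask])
    feats["grad_mag_mean_outside"] = _safe_mean(gmag[shell]) if not shell_empty else 0.0
    feats["surface_gradient"] = _safe_mean(gmag[perim])
    gl1 = [ctx.gradients_lce1[i][sl].astype(np.float64) for i in range(3)]
    gmag_l1 = np.sqrt(gl1[0] ** 2 + gl1[1] ** 2 + gl1[2] ** 2)
    feats["surface_gradient_lce1"] = _safe_mean(gmag_l1[perim])

    # radial direction from the candidate centroid, evaluated only on the
    # union of the regions any statistic needs
    need = mask | perim | shell
    pts = np.argwhere(need)
    world = origin + (pts + lo) * spacing
    rvec = world - centroid_mm
    rnorm = np.linalg.norm(rvec, axis=1)
    runit = np.where(rnorm[:, None] > 1e-9, rvec / np.maximum(rnorm, 1e-9)[:, None], 0.0)
    gv = np.stack([g[i][need] for i in range(3)], axis=1)
    gvnorm = np.linalg.norm(gv, axis=1)
    radial_grad = np.einsum("ij,ij->i", gv, runit)
    cosang = np.where(
        (gvnorm > 1e-9) & (rnorm > 1e-9),
        np.clip(radial_grad / np.maximum(gvnorm, 1e-9), -1.0, 1.0),
        1.0,
    )
    radial_dev = np.degrees(np.arccos(cosang))
    flat_mask = mask[pts[:, 0], pts[:, 1], pts[:, 2]]
    flat_perim = perim[pts[:, 0], pts[:, 1], pts[:, 2]]
    flat_shell = shell[pts[:, 0], pts[:, 1], pts[:, 2]]
    for stat_name, values in (("radial_grad", radial_grad), ("radial_dev", radial_dev)):
        for region, flat in (
            ("inside", flat_mask),
            ("perimeter", flat_perim),
            ("outside", flat_shell),
        ):
            vals = values[flat]
            if region == "outside" and shell_empty:
                feats[f"{stat_name}_mean_{region}"] = 0.0
                feats[f"{stat_name}_std_{region}"] = 0.0
            else:
                feats[f"{stat_name}_mean_{region}"] = _safe_mean(vals)
                feats[f"{stat_name}_std_{region}"] = _safe_std(vals)

    values = np.array([feats[n] for n in FEATURE_NAMES], dtype=float)
    if not np.all(np.isfinite(values)):
        bad = [n for n, v in zip(FEATURE_NAMES, values) if not np.isfinite(v)]
        raise AssertionError(f"non-finite features {bad}")
    return FeatureVector(FEATURE_NAMES, values, shell_empty=shell_empty)


def featurize_case(case_id: str, vol: CTVolume, lung_mask, candidates,
                   windows: tuple[int, int] = (11, 51)):
    """Feature matrix for all candidates of one case as a pandas DataFrame.

    Columns: ``seriesuid``, ``ordinal``, centroid coordinates, then the
    catalog in registry order.
    """
    import pandas as pd

    ctx = build_case_context(vol, lung_mask, windows)
    rows = []
    for k, cand in enumerate(candidates):
        fv = compute_feature_vector(cand, ctx)
        cand.features = fv
        row = {
            "seriesuid": case_id,
            "ordinal": k,
            "coordX": cand.centroid_mm[0],
            "coordY": cand.centroid_mm[1],
            "coordZ": cand.centroid_mm[2],
        }
        row.update(fv.as_dict())
        rows.append(row)
    columns = ["seriesuid", "ordinal", "coordX", "coordY", "coordZ", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=columns)
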