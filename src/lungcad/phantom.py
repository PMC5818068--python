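"""Synthetic thoracic CT phantoms with known nodule ground truth.

A phantom case is a small thorax rendered in Hounsfield units: background
air (-1000 HU), a soft-tissue body cylinder (0 HU), two ellipsoidal lung
fields (-850 HU), bright random-walk vessel tubes (~+900 HU above lung,
with occasional junction bulges that act as compact false-positive
sources), and spherical soft-tissue nodules brighter than parenchyma.
Every structure is rendered with partial volume: occupancy fractions are
computed by 3x supersampling voxels straddling an object boundary, objects
are alpha-composited in paint order, the volume is Gaussian-smoothed and
white Gaussian HU noise is added.  Ground-truth lung and nodule masks are
the pre-noise, pre-smoothing occupancy > 0.5 regions, so detector and
feature contracts can be tested against exact truth without external data.

Cohorts emulate a screening dataset: MetaImage volume pairs at 1.25-mm
slice spacing plus a single annotations CSV in the LUNA16 dialect
(``seriesuid,coordX,coordY,coordZ,diameter_mm``, world mm).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, nearest_voxel, write_metaimage

__all__ = [
    "NoduleSpec",
    "NoduleAnnotation",
    "PhantomSpec",
    "PhantomCase",
    "NodulePlacementError",
    "generate_phantom",
    "generate_cohort",
    "read_annotations_csv",
    "write_annotations_csv",
    "ANNOTATION_HEADER",
]

ANNOTATION_HEADER = ("seriesuid", "coordX", "coordY", "coordZ", "diameter_mm")


class NodulePlacementError(ValueError):
    """A requested nodule center falls outside the lung fields."""


@dataclass(frozen=True)
class NoduleSpec:
    """One spherical nodule: center (world mm), diameter, HU above lung."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    contrast_hu: float = 500.0


@dataclass(frozen=True)
class NoduleAnnotation:
    """A radiologist-style cue point in the LUNA16 CSV dialect."""

    seriesuid: str
    center_mm: tuple[float, float, float]
    diameter_mm: float


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom thorax.

    The lung fields are two ellipsoids inside an elliptical body cylinder;
    their geometry is derived from the volume extent so any shape/spacing
    yields a proportioned thorax.  ``edge_smoothing_mm`` is the Gaussian
    sigma applied after compositing (0 disables smoothing); noise is
    additive white Gaussian in HU.
    """

    shape: tuple[int, int, int] = (128, 128, 64)
    spacing: tuple[float, float, float] = (0.7, 0.7, 1.25)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_hu: float = -1000.0
    body_hu: float = 0.0
    lung_hu: float = -850.0
    nodules: tuple[NoduleSpec, ...] = ()
    vessel_count: int = 6
    vessel_radius_mm: tuple[float, float] = (0.8, 1.8)
    vessel_contrast_hu: float = 900.0
    noise_sigma_hu: float = 20.0
    edge_smoothing_mm: float = 0.7

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        for nod in self.nodules:
            if nod.diameter_mm <= 3.0:
                raise ValueError(
                    f"nodule at {nod.center_mm}: diameter must exceed 3 mm "
                    f"(got {nod.diameter_mm})"
                )
            if nod.contrast_hu <= 0:
                raise ValueError("nodule contrast must be positive (brighter than lung)")
            if not self._inside_lung(nod.center_mm, margin_mm=nod.diameter_mm / 2.0):
                raise NodulePlacementError(
                    f"nodule at {nod.center_mm} (d={nod.diameter_mm} mm) does not "
                    "fit inside the lung fields"
                )

    # --- derived thorax geometry -------------------------------------------------
    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)

    @property
    def center_mm(self) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.spacing
        )

    @property
    def body_semiaxes_mm(self) -> tuple[float, float]:
        ex, ey, _ = self.extent_mm
        return (0.47 * ex, 0.45 * ey)

    def lung_ellipsoids(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(center, semiaxes) of the two lung fields, world mm."""
        ex, ey, ez = self.extent_mm
        c = self.center_mm
        semi = np.array([0.16 * ex, 0.30 * ey, 0.40 * ez])
        out = []
        for side in (-1.0, 1.0):
            out.append((c + np.array([side * 0.22 * ex, 0.0, 0.0]), semi.copy()))
        return out

    def _inside_lung(self, point_mm, margin_mm: float = 0.0) -> bool:
        p = np.asarray(point_mm, dtype=float)
        for center, semi in self.lung_ellipsoids():
            shrunk = semi - margin_mm
            if np.any(shrunk <= 0):
                continue
            if np.sum(((p - center) / shrunk) ** 2) <= 1.0:
                return True
        return False


@dataclass
class PhantomCase:
    """A rendered phantom: HU volume, cue points, and ground-truth masks."""

    case_id: str
    volume: CTVolume
    annotations: list[NoduleAnnotation]
    lung_mask: np.ndarray
    nodule_mask: np.ndarray
    spec: PhantomSpec = field(repr=False, default=None)  # type: ignore[assignment]


# --- occupancy rendering ---------------------------------------------------------

_SUPERSAMPLE = 3


def _grid_axes(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(
        np.asarray(spec.origin)[i] + np.arange(spec.shape[i]) * spec.spacing[i]
        for i in range(3)
    )


def _subvoxel_offsets(spacing, n: int = _SUPERSAMPLE) -> np.ndarray:
    """n x n x n sub-sample offsets (mm) covering a voxel cell."""
    steps = (np.arange(n) + 0.5) / n - 0.5
    offs = np.stack(np.meshgrid(*[steps * s for s in spacing], indexing="ij"), axis=-1)
    return offs.reshape(-1, 3)


def _occupancy(inside_fn, spec: PhantomSpec) -> np.ndarray:
    """Occupancy fraction per voxel: exact 0/1 away from the boundary,
    3x3x3 supersampled mean on the boundary band."""
    xs, ys, zs = _grid_axes(spec)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    inside = inside_fn(X, Y, Z)
    band = ndimage.binary_dilation(inside) ^ ndimage.binary_erosion(inside)
    alpha = inside.astype(np.float32)
    if band.any():
        pts = np.stack([X[band], Y[band], Z[band]], axis=-1)
        acc = np.zeros(pts.shape[0], dtype=np.float32)
        for off in _subvoxel_offsets(spec.spacing):
            q = pts + off
            acc += inside_fn(q[:, 0], q[:, 1], q[:, 2]).astype(np.float32)
        alpha[band] = acc / (_SUPERSAMPLE**3)
    return alpha


def _sphere_occupancy_patch(spec: PhantomSpec, center, radius, supersample: int = 5):
    """Supersampled occupancy of a sphere over its voxel bounding box.

    Spheres use a denser subgrid than the large structures (5x vs 3x):
    the patches are tiny, and the finer sampling keeps the quantization
    bias of the interior fill fraction well below the HU noise floor.
    Returns (slices, alpha_patch) in volume index space, or None if the
    sphere misses the grid.
    """
    center = np.asarray(center, dtype=float)
    lo_idx, hi_idx = [], []
    for i in range(3):
        lo = int(np.floor((center[i] - radius - spec.origin[i]) / spec.spacing[i])) - 1
        hi = int(np.ceil((center[i] + radius - spec.origin[i]) / spec.spacing[i])) + 2
        lo, hi = max(lo, 0), min(hi, spec.shape[i])
        if hi <= lo:
            return None
        lo_idx.append(lo)
        hi_idx.append(hi)
    axes = [
        spec.origin[i] + np.arange(lo_idx[i], hi_idx[i]) * spec.spacing[i]
        for i in range(3)
    ]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    acc = np.zeros(X.shape, dtype=np.float32)
    for off in _subvoxel_offsets(spec.spacing, supersample):
        d2 = (X + off[0] - center[0]) ** 2 + (Y + off[1] - center[1]) ** 2 + (
            Z + off[2] - center[2]
        ) ** 2
        acc += (d2 <= radius**2).astype(np.float32)
    sl = tuple(slice(lo_idx[i], hi_idx[i]) for i in range(3))
    return sl, acc / (supersample**3)


def _composite(hu: np.ndarray, alpha: np.ndarray, value: float) -> None:
    np.copyto(hu, alpha * value + (1.0 - alpha) * hu)


def _render_vessels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Union occupancy of random-walk vessel tubes (chains of spheres).

    Tubes stay inside the lung fields and keep their sphere centers at
    least one nodule diameter from every nodule center, so vessels can
    never contaminate nodule ground truth.  A small per-step bulge
    probability creates compact junction blobs — the phantom's main
    false-positive source.
    """
    alpha = np.zeros(spec.shape, dtype=np.float32)
    lungs = spec.lung_ellipsoids()
    nod_centers = np.array([n.center_mm for n in spec.nodules]).reshape(-1, 3)
    nod_clear = np.array([n.diameter_mm for n in spec.nodules])
    step_mm = 1.2
    for v in range(spec.vessel_count):
        center, semi = lungs[v % len(lungs)]
        # start well inside the lung
        while True:
            u = rng.uniform(-0.6, 0.6, size=3)
            if np.sum(u**2) <= 0.36:
                break
        pos = center + u * semi
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        base_r = rng.uniform(*spec.vessel_radius_mm)
        n_steps = int(rng.integers(24, 48))
        for _ in range(n_steps):
            radius = base_r * float(rng.uniform(0.85, 1.15))
            if rng.uniform() < 0.08:
                radius = float(rng.uniform(2.2, 3.2))  # junction bulge
            clear = True
            if len(nod_centers):
                d = np.linalg.norm(nod_centers - pos, axis=1)
                clear = bool(np.all(d >= nod_clear))
            if clear:
                patch = _sphere_occupancy_patch(spec, pos, radius)
                if patch is not None:
                    sl, a = patch
                    np.maximum(alpha[sl], a, out=alpha[sl])
            direction = direction + rng.normal(scale=0.35, size=3)
            direction /= np.linalg.norm(direction)
            pos = pos + direction * step_mm
            norm = np.sum(((pos - center) / semi) ** 2)
            if norm > 0.72:  # steer back toward the lung center
                direction = (center - pos) / np.linalg.norm(center - pos)
                pos = pos + direction * step_mm
    return alpha


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomCase:
    """Render one phantom case deterministically from (spec, seed)."""
    rng = np.random.default_rng(seed)
    cx, cy = spec.center_mm[0], spec.center_mm[1]
    ax, ay = spec.body_semiaxes_mm

    hu = np.full(spec.shape, float(spec.background_hu), dtype=np.float32)

    body_alpha = _occupancy(
        lambda X, Y, Z: ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 <= 1.0, spec
    )
    _composite(hu, body_alpha, spec.body_hu)

    lung_alpha = np.zeros(spec.shape, dtype=np.float32)
    for center, semi in spec.lung_ellipsoids():
        a = _occupancy(
            lambda X, Y, Z, c=center, s=semi: ((X - c[0]) / s[0]) ** 2
            + ((Y - c[1]) / s[1]) ** 2
            + ((Z - c[2]) / s[2]) ** 2
            <= 1.0,
            spec,
        )
        np.maximum(lung_alpha, a, out=lung_alpha)
    _composite(hu, lung_alpha, spec.lung_hu)
    lung_mask = lung_alpha > 0.5

    vessel_alpha = _render_vessels(spec, rng)
    _composite(hu, vessel_alpha, spec.lung_hu + spec.vessel_contrast_hu)

    nodule_mask = np.zeros(spec.shape, dtype=bool)
    for nod in spec.nodules:
        patch = _sphere_occupancy_patch(spec, nod.center_mm, nod.diameter_mm / 2.0)
        if patch is None:
            raise NodulePlacementError(f"nodule at {nod.center_mm} misses the grid")
        sl, a = patch
        sub = hu[sl]
        np.copyto(sub, a * (spec.lung_hu + nod.contrast_hu) + (1.0 - a) * sub)
        nodule_mask[sl] |= a > 0.5

    if spec.edge_smoothing_mm > 0:
        sigma = [spec.edge_smoothing_mm / s for s in spec.spacing]
        hu = ndimage.gaussian_filter(hu, sigma=sigma)
    if spec.noise_sigma_hu > 0:
        hu = hu + rng.normal(scale=spec.noise_sigma_hu, size=spec.shape)

    data = np.clip(np.rint(hu), -1024, 3071).astype(np.int16)
    volume = CTVolume(data, spec.spacing, spec.origin)

    case_id = f"phantom-{seed}"
    annotations = [
        NoduleAnnotation(case_id, tuple(float(c) for c in nod.center_mm), nod.diameter_mm)
        for nod in spec.nodules
    ]
    for ann in annotations:  # invariant: cue centers land inside truth
        idx = nearest_voxel(volume.geometry, ann.center_mm)
        if not nodule_mask[idx]:
            raise NodulePlacementError(
                f"annotation center {ann.center_mm} fell outside its rendered mask"
            )
    return PhantomCase(case_id, volume, annotations, lung_mask, nodule_mask, spec)


# --- cohorts ---------------------------------------------------------------------


def _sample_nodules(
    spec: PhantomSpec,
    rng: np.random.Generator,
    n_nodules: int,
    diameter_range_mm: tuple[float, float],
    contrast_range_hu: tuple[float, float],
) -> tuple[NoduleSpec, ...]:
    """Place nodules uniformly inside the lung fields with full clearance
    from the lung boundary and from each other."""
    lungs = spec.lung_ellipsoids()
    placed: list[NoduleSpec] = []
    for _ in range(n_nodules):
        for _attempt in range(200):
            d = float(rng.uniform(*diameter_range_mm))
            contrast = float(rng.uniform(*contrast_range_hu))
            center, semi = lungs[int(rng.integers(len(lungs)))]
            shrunk = semi - (d / 2.0 + 1.5)
            if np.any(shrunk <= 0):
                continue
            u = rng.uniform(-1.0, 1.0, size=3)
            if np.sum(u**2) > 1.0:
                continue
            pos = center + u * shrunk
            if any(
                np.linalg.norm(np.asarray(p.center_mm) - pos)
                < (p.diameter_mm + d) / 2.0 + 4.0
                for p in placed
            ):
                continue
            placed.append(NoduleSpec(tuple(float(x) for x in pos), d, contrast))
            break
        else:
            raise NodulePlacementError(
                f"could not place nodule {len(placed) + 1} of {n_nodules}"
            )
    return tuple(placed)


def generate_cohort(
    n_cases: int,
    spec_template: PhantomSpec,
    nodules_per_case: tuple[int, int],
    seed: int,
    out_dir=None,
    diameter_range_mm: tuple[float, float] = (4.0, 12.0),
    contrast_range_hu: tuple[float, float] = (300.0, 600.0),
    write_masks: bool = False,
) -> list[PhantomCase]:
    """Generate a seeded phantom cohort, optionally written to disk.

    Per-case seeds are spawned from the master seed, so cohorts are
    deterministic and byte-identical across runs.  When ``out_dir`` is
    given, each case is written as an uncompressed MetaImage pair and a
    single ``annotations.csv`` in the LUNA16 dialect collects all cue
    points.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    lo, hi = int(nodules_per_case[0]), int(nodules_per_case[1])
    if lo < 0 or hi < lo:
        raise ValueError(f"bad nodules_per_case range ({lo}, {hi})")
    master = np.random.SeedSequence(seed)
    cases: list[PhantomCase] = []
    for i, child in enumerate(master.spawn(n_cases)):
        rng = np.random.default_rng(child)
        n_nod = int(rng.integers(lo, hi + 1))
        nodules = _sample_nodules(
            spec_template, rng, n_nod, diameter_range_mm, contrast_range_hu
        )
        spec = replace(spec_template, nodules=nodules)
        render_seed = int(rng.integers(0, 2**31 - 1))
        case = generate_phantom(spec, render_seed)
        case_id = f"phantom-{seed}-{i:03d}"
        case.case_id = case_id
        case.annotations = [
            NoduleAnnotation(case_id, a.center_mm, a.diameter_mm)
            for a in case.annotations
        ]
        cases.append(case)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for case in cases:
            write_metaimage(case.volume, out_dir / f"{case.case_id}.mhd")
            if write_masks:
                geom = case.volume
                for name, mask in (
                    ("lungmask", case.lung_mask),
                    ("nodulemask", case.nodule_mask),
                ):
                    write_metaimage(
                        CTVolume(mask.astype(np.uint8), geom.spacing, geom.origin),
                        out_dir / f"{case.case_id}_{name}.mhd",
                        dtype=np.uint8,
                    )
        write_annotations_csv(
            [a for case in cases for a in case.annotations],
            out_dir / "annotations.csv",
        )
    return cases


def write_annotations_csv(annotations, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_HEADER)
        for a in annotations:
            writer.writerow(
                [a.seriesuid, a.center_mm[0], a.center_mm[1], a.center_mm[2], a.diameter_mm]
            )


def read_annotations_csv(path) -> list[NoduleAnnotation]:
    out: list[NoduleAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != ANNOTATION_HEADER:
            raise ValueError(
                f"{path}: expected header {','.join(ANNOTATION_HEADER)}"
            )
        for row in reader:
            out.append(
                NoduleAnnotation(
                    row["seriesuid"],
                    (float(row["coordX"]), float(row["coordY"]), float(row["coordZ"])),
                    float(row["diameter_mm"]),
                )
            )
    return out
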