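"""Experiment harness: training regimes, thickness studies, k-fold runs.

Three regimes for nonhomogeneous-thickness training data are supported:

* ``aggregate`` — every train-eligible case at its native thickness;
* ``homogeneous`` — only cases whose (thickness, spacing) matches the test
  set, which can legitimately fail when no such cases exist;
* ``common`` — the whole suite slab-averaged to one common thickness
  (default 2.5 mm); cases whose native spacing does not divide the common
  thickness are excluded with a warning, and test cases are resampled too
  whenever their native thickness differs.

"Thickness" is operationalized as z-spacing throughout; inventories where
slice thickness differs from slice spacing are rejected, since slab
averaging is only a faithful thickness simulation when the two coincide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import DetectorParams, detect_candidates, segment_lungs
from .evaluation import (
    HitCriterion,
    anode_score,
    auc_0_10,
    froc_from_detections,
    match_candidates,
    merge_redundant_annotations,
    subset_confidence_interval,
)
from .features import FEATURE_NAMES, build_case_context, compute_feature_vector
from .phantom import PhantomSpec, generate_cohort
from .selection import TrainingBundle, fit_fld, score_candidates, sfs_select, shortlist_features
from .volume_io import downsample_slices

logger = logging.getLogger(__name__)

__all__ = [
    "CaseRecord",
    "CaseInventory",
    "CompositionEntry",
    "TrainingComposition",
    "EmptyCompositionError",
    "compose_training",
    "kfold_split",
    "ProcessedCase",
    "process_case",
    "build_bundle",
    "train_classifier",
    "evaluate_test_set",
    "run_thickness_study",
    "run_regime_experiment",
    "run_phantom_benchmark",
    "run_small_nodule_thickness_benchmark",
]


# --------------------------------------------------------------------------- #
# inventories and training compositions
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class CaseRecord:
    """Inventory entry: identity, native geometry, and train/test role."""

    case_id: str
    thickness_mm: float
    spacing_mm: float
    role: str  # "train" or "test"
    case: object | None = None  # optional in-memory PhantomCase
    path: object | None = None

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0 or self.spacing_mm <= 0:
            raise ValueError("thickness and spacing must be positive")
        if abs(self.thickness_mm - self.spacing_mm) > 1e-9:
            raise ValueError(
                f"case {self.case_id}: thickness {self.thickness_mm} != spacing "
                f"{self.spacing_mm}; slab averaging only models contiguous slices"
            )
        if self.role not in ("train", "test"):
            raise ValueError(f"case {self.case_id}: role must be train or test")


class CaseInventory:
    """Unique-id collection of :class:`CaseRecord`."""

    def __init__(self, records) -> None:
        self.records = list(records)
        ids = [r.case_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate case ids in inventory")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def train_records(self) -> list[CaseRecord]:
        return [r for r in self.records if r.role == "train"]

    @property
    def test_records(self) -> list[CaseRecord]:
        return [r for r in self.records if r.role == "test"]


class EmptyCompositionError(RuntimeError):
    """A regime resolved to zero training cases (e.g. homogeneous with no
    thickness-matched data)."""


@dataclass(frozen=True)
class CompositionEntry:
    case_id: str
    native_thickness_mm: float
    use_at_thickness_mm: float
    resample_ratio: int | None  # None = used at native thickness


@dataclass
class TrainingComposition:
    regime: str
    entries: list[CompositionEntry]
    test_entries: list[CompositionEntry]
    common_thickness_mm: float | None = None

    def count(self, native_mm: float, resampled: bool, test: bool = False) -> int:
        pool = self.test_entries if test else self.entries
        return sum(
            1
            for e in pool
            if abs(e.native_thickness_mm - native_mm) < 1e-9
            and (e.resample_ratio is not None) == resampled
        )

    @property
    def train_case_ids(self) -> list[str]:
        return [e.case_id for e in self.entries]


def _resample_ratio(native: float, target: float) -> int | None:
    """Integer slab ratio native -> target, None if not an integer multiple."""
    ratio = target / native
    if abs(ratio - round(ratio)) > 1e-9:
        return None
    return int(round(ratio))


def compose_training(
    inventory: CaseInventory,
    regime: str,
    test_thickness_mm: float,
    common_thickness_mm: float = 2.5,
) -> TrainingComposition:
    """Resolve one training regime against an inventory.

    The composition is a pure function of the inventory: entry lists and
    their counts are deterministic, never subsampled, and exclude every
    test case by construction.
    """
    if regime not in ("aggregate", "homogeneous", "common"):
        raise ValueError(f"unknown regime {regime!r}")
    train = inventory.train_records
    tests = inventory.test_records
    if not train:
        raise EmptyCompositionError("inventory has no train-eligible cases")

    def native_entry(r: CaseRecord) -> CompositionEntry:
        return CompositionEntry(r.case_id, r.thickness_mm, r.thickness_mm, None)

    if regime == "aggregate":
        entries = [native_entry(r) for r in train]
        test_entries = [native_entry(r) for r in tests]
        common = None
    elif regime == "homogeneous":
        entries = [
            native_entry(r)
            for r in train
            if abs(r.thickness_mm - test_thickness_mm) < 1e-9
        ]
        if not entries:
            raise EmptyCompositionError(
                f"no training cases match test thickness {test_thickness_mm} mm"
            )
        test_entries = [native_entry(r) for r in tests]
        common = None
    else:  # common thickness
        common = common_thickness_mm
        entries = []
        for r in train:
            ratio = _resample_ratio(r.thickness_mm, common)
            if ratio is None or ratio < 1:
                warnings.warn(
                    f"case {r.case_id}: native {r.thickness_mm} mm does not divide "
                    f"common thickness {common} mm; excluded",
                    stacklevel=2,
                )
                continue
            entries.append(
                CompositionEntry(
                    r.case_id, r.thickness_mm, common, ratio if ratio > 1 else None
                )
            )
        if not entries:
            raise EmptyCompositionError("no training cases usable at common thickness")
        test_entries = []
        for r in tests:
            ratio = _resample_ratio(r.thickness_mm, common)
            if ratio is None or ratio < 1:
                warnings.warn(
                    f"test case {r.case_id} cannot be resampled to {common} mm",
                    stacklevel=2,
                )
                continue
            test_entries.append(
                CompositionEntry(
                    r.case_id, r.thickness_mm, common, ratio if ratio > 1 else None
                )
            )
    comp = TrainingComposition(regime, entries, test_entries, common)
    test_ids = {r.case_id for r in tests}
    leaked = test_ids.intersection(comp.train_case_ids)
    if leaked:
        raise AssertionError(f"test cases leaked into training: {sorted(leaked)}")
    logger.info(
        "regime=%s: %d training entries (%d resampled), %d test entries",
        regime,
        len(comp.entries),
        sum(e.resample_ratio is not None for e in comp.entries),
        len(comp.test_entries),
    )
    return comp


def kfold_split(case_ids, k: int = 10, seed: int = 0) -> list[list[str]]:
    """Seeded near-equal partition of case ids into k disjoint folds."""
    case_ids = list(case_ids)
    if len(case_ids) < k:
        raise ValueError(f"{len(case_ids)} cases cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(case_ids))
    return [[case_ids[i] for i in fold] for fold in np.array_split(perm, k)]


# --------------------------------------------------------------------------- #
# per-case pipeline
# --------------------------------------------------------------------------- #


@dataclass
class ProcessedCase:
    """One case pushed through detect -> featurize -> match."""

    case_id: str
    X: np.ndarray  # (n_candidates, n_features)
    target_ids: np.ndarray  # per-candidate local target id, -1 = non-hit
    n_targets: int
    detected: dict  # target id -> bool (candidate-level, pre-classifier)
    targets: list = field(default_factory=list)


def process_case(
    case_id: str,
    volume,
    annotations,
    det_params: DetectorParams | None = None,
    criterion: HitCriterion | None = None,
    lung_mask=None,
) -> ProcessedCase:
    det_params = det_params or DetectorParams()
    if lung_mask is None:
        lung_mask = segment_lungs(volume, det_params)
    candidates = detect_candidates(volume, lung_mask, det_params)
    targets = merge_redundant_annotations(annotations)
    centers = np.array([c.centroid_mm for c in candidates]).reshape(-1, 3)
    tids, detected = match_candidates(centers, targets, criterion)
    if candidates:
        ctx = build_case_context(volume, lung_mask)
        X = np.stack(
            [compute_feature_vector(c, ctx).values for c in candidates], axis=0
        )
    else:
        X = np.zeros((0, len(FEATURE_NAMES)))
    return ProcessedCase(case_id, X, tids, len(targets), detected, targets)


def candidate_sensitivity(processed) -> float:
    """Pre-classifier sensitivity: detected targets / all targets."""
    detected = sum(sum(p.detected.values()) for p in processed)
    total = sum(p.n_targets for p in processed)
    return detected / total if total else float("nan")


def build_bundle(processed) -> TrainingBundle:
    """Pool processed cases into one SFS-ready training bundle, offsetting
    per-case target ids so they are globally unique."""
    xs, tids = [], []
    offset = 0
    n_targets = 0
    for p in processed:
        xs.append(p.X)
        shifted = np.where(p.target_ids >= 0, p.target_ids + offset, -1)
        tids.append(shifted)
        offset += p.n_targets
        n_targets += p.n_targets
    X = np.concatenate(xs, axis=0) if xs else np.zeros((0, len(FEATURE_NAMES)))
    return TrainingBundle(
        X=X,
        feature_names=FEATURE_NAMES,
        target_ids=np.concatenate(tids) if tids else np.zeros(0, dtype=int),
        n_cases=len(list(processed)),
        n_targets=n_targets,
    )


def train_classifier(
    processed_train,
    shortlist_k: int = 300,
    max_features: int = 20,
    ridge: float = 1e-3,
):
    """Shortlist -> SFS -> final FLD fit on the training cases.

    Returns ``(model, trace)``; the model is fit on the SFS-chosen feature
    subset only.
    """
    bundle = build_bundle(processed_train)
    k = min(shortlist_k, bundle.X.shape[1])
    shortlist = shortlist_features(bundle.X, bundle.y, k)
    sub = TrainingBundle(
        X=bundle.X[:, shortlist],
        feature_names=tuple(FEATURE_NAMES[j] for j in shortlist),
        target_ids=bundle.target_ids,
        n_cases=bundle.n_cases,
        n_targets=bundle.n_targets,
    )
    trace = sfs_select(sub, max_features=max_features, ridge=ridge)
    chosen = trace.chosen_features
    cols = [FEATURE_NAMES.index(n) for n in chosen]
    model = fit_fld(bundle.X[:, cols], bundle.y, ridge=ridge, feature_names=chosen)
    return model, trace


def _scores_for(model, p: ProcessedCase) -> np.ndarray:
    cols = [FEATURE_NAMES.index(n) for n in model.feature_names]
    return score_candidates(model, p.X[:, cols])


def evaluate_test_set(model, processed_test, ci_subsets: int = 10, seed: int = 0):
    """Score a test set and summarize its FROC.

    Returns a dict with AUC(0-10), ANODE score, candidate sensitivity and,
    when the test set is large enough to split, the subset confidence
    half-width of the AUC.
    """
    processed_test = list(processed_test)
    by_id = {p.case_id: p for p in processed_test}

    def froc_for(case_ids):
        scores, tids = [], []
        offset = 0
        n_targets = 0
        for cid in case_ids:
            p = by_id[cid]
            scores.append(_scores_for(model, p))
            tids.append(np.where(p.target_ids >= 0, p.target_ids + offset, -1))
            offset += p.n_targets
            n_targets += p.n_targets
        return froc_from_detections(
            np.concatenate(scores) if scores else np.zeros(0),
            np.concatenate(tids) if tids else np.zeros(0, dtype=int),
            len(case_ids),
            n_targets,
        )

    froc = froc_for(list(by_id))
    result = {
        "auc_0_10": auc_0_10(froc),
        "anode": anode_score(froc),
        "candidate_sensitivity": candidate_sensitivity(processed_test),
        "froc": froc,
    }
    if len(by_id) >= ci_subsets and all(p.n_targets > 0 for p in processed_test):
        mean, half = subset_confidence_interval(
            list(by_id), lambda ids: auc_0_10(froc_for(ids)), ci_subsets, seed
        )
        result["auc_ci_mean"] = mean
        result["auc_ci_halfwidth"] = half
    else:
        result["auc_ci_mean"] = float("nan")
        result["auc_ci_halfwidth"] = float("nan")
    return result


# --------------------------------------------------------------------------- #
# studies
# --------------------------------------------------------------------------- #


def _process_cohort(cases, ratio: int, det_params, criterion):
    processed = []
    for case in cases:
        vol = case.volume if ratio == 1 else downsample_slices(case.volume, ratio)
        processed.append(
            process_case(case.case_id, vol, case.annotations, det_params, criterion)
        )
    return processed


def run_thickness_study(
    cases,
    ratios=(1, 2, 4, 8),
    test_fraction: float = 0.25,
    seed: int = 0,
    det_params: DetectorParams | None = None,
    max_features: int = 20,
    ridge: float = 1e-3,
) -> pd.DataFrame:
    """CAD performance at native and slab-averaged thicknesses.

    The same seeded train/test split is reused at every ratio, and cue
    points (world mm) are identical across thicknesses — only the volume
    geometry changes.  Returns one row per ratio with the pre-classifier
    candidate sensitivity, the SFS-chosen feature count, AUC(0-10), its
    subset confidence half-width when computable, and the ANODE score.
    """
    cases = list(cases)
    for r in ratios:
        if int(r) not in (1, 2, 4, 8):
            warnings.warn(f"non-standard thickness ratio {r}", stacklevel=2)
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_fraction * len(cases))))
    test_idx = set(rng.choice(len(cases), size=n_test, replace=False).tolist())
    det_params = det_params or DetectorParams()
    criterion = HitCriterion()
    base_z = cases[0].volume.spacing[2]

    rows = []
    for ratio in ratios:
        processed = _process_cohort(cases, int(ratio), det_params, criterion)
        train = [p for i, p in enumerate(processed) if i not in test_idx]
        test = [p for i, p in enumerate(processed) if i in test_idx]
        model, trace = train_classifier(
            train, max_features=max_features, ridge=ridge
        )
        res = evaluate_test_set(model, test, seed=seed)
        rows.append(
            {
                "ratio": int(ratio),
                "thickness_mm": base_z * int(ratio),
                "candidate_sensitivity": 100.0 * res["candidate_sensitivity"],
                "n_features_selected": trace.chosen_size,
                "auc_0_10": res["auc_0_10"],
                "auc_ci_halfwidth": res["auc_ci_halfwidth"],
                "anode": res["anode"],
            }
        )
    return pd.DataFrame(rows)


def run_regime_experiment(
    inventory: CaseInventory,
    regimes=("aggregate", "homogeneous", "common"),
    common_thickness_mm: float = 2.5,
    seed: int = 0,
    det_params: DetectorParams | None = None,
    max_features: int = 20,
    ridge: float = 1e-3,
) -> pd.DataFrame:
    """Compare training regimes on a fixed test set.

    Inventory records must carry in-memory cases.  Each regime trains on
    its resolved composition (resampling volumes where the composition says
    so) and is evaluated on the identical test cases; when a regime cannot
    be composed (homogeneous with no matching thickness) the report carries
    a documented failure row instead of aborting the study.
    """
    det_params = det_params or DetectorParams()
    criterion = HitCriterion()
    test_records = inventory.test_records
    if not test_records:
        raise ValueError("inventory has no test cases")
    test_thickness = test_records[0].thickness_mm

    records_by_id = {r.case_id: r for r in inventory}
    processed_cache: dict[tuple[str, int], ProcessedCase] = {}

    def processed_at(case_id: str, ratio: int) -> ProcessedCase:
        key = (case_id, ratio)
        if key not in processed_cache:
            rec = records_by_id[case_id]
            vol = rec.case.volume
            if ratio > 1:
                vol = downsample_slices(vol, ratio)
            processed_cache[key] = process_case(
                case_id, vol, rec.case.annotations, det_params, criterion
            )
        return processed_cache[key]

    rows = []
    for regime in regimes:
        try:
            comp = compose_training(
                inventory, regime, test_thickness, common_thickness_mm
            )
        except EmptyCompositionError as exc:
            rows.append({"regime": regime, "status": f"failed: {exc}"})
            continue
        train = [
            processed_at(e.case_id, e.resample_ratio or 1) for e in comp.entries
        ]
        test = [
            processed_at(e.case_id, e.resample_ratio or 1) for e in comp.test_entries
        ]
        model, trace = train_classifier(train, max_features=max_features, ridge=ridge)
        res = evaluate_test_set(model, test, seed=seed)
        rows.append(
            {
                "regime": regime,
                "status": "ok",
                "n_train_cases": len(comp.entries),
                "n_train_resampled": sum(
                    e.resample_ratio is not None for e in comp.entries
                ),
                "candidate_sensitivity": 100.0 * res["candidate_sensitivity"],
                "n_features_selected": trace.chosen_size,
                "auc_0_10": res["auc_0_10"],
                "auc_ci_halfwidth": res["auc_ci_halfwidth"],
                "anode": res["anode"],
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# seeded phantom benchmarks (study conditions)
# --------------------------------------------------------------------------- #


def run_phantom_benchmark(
    seed: int,
    n_cases: int = 20,
    n_test: int = 5,
    n_permutations: int = 20,
) -> dict:
    """End-to-end run on the default seeded phantom cohort.

    Generates ``n_cases`` phantoms under the default study conditions
    (1-3 nodules/case, 4-12 mm, 300-600 HU contrast, 1.25-mm slices),
    trains on all but ``n_test`` cases and evaluates on the held-out ones.
    Reports the pre-classifier candidate sensitivity restricted to large
    conspicuous nodules (>= 8 mm and >= 400 HU contrast, over the whole
    cohort), the held-out AUC(0-10)/ANODE, and the mean AUC obtained when
    the trained scores are randomly permuted among the same candidates —
    the no-information baseline the classifier must beat.
    """
    spec = PhantomSpec()
    cases = generate_cohort(n_cases, spec, (1, 3), seed)
    det_params = DetectorParams()
    criterion = HitCriterion()
    processed = _process_cohort(cases, 1, det_params, criterion)

    # candidate-level sensitivity over large, high-contrast nodules
    large_total = 0
    large_found = 0
    for case, p in zip(cases, processed):
        for t in p.targets:
            nod = min(
                case.spec.nodules,
                key=lambda n: np.linalg.norm(np.asarray(n.center_mm) - t.center_mm),
            )
            if t.diameter_mm >= 8.0 and nod.contrast_hu >= 400.0:
                large_total += 1
                large_found += bool(p.detected[t.target_id])

    train, test = processed[:-n_test], processed[-n_test:]
    model, trace = train_classifier(train)
    res = evaluate_test_set(model, test, seed=seed)

    rng = np.random.default_rng(seed + 1)
    permuted_aucs = []
    scores = [_scores_for(model, p) for p in test]
    flat = np.concatenate(scores)
    tids = []
    offset = 0
    n_targets = 0
    for p in test:
        tids.append(np.where(p.target_ids >= 0, p.target_ids + offset, -1))
        offset += p.n_targets
        n_targets += p.n_targets
    flat_tids = np.concatenate(tids)
    for _ in range(n_permutations):
        perm = rng.permutation(flat.size)
        froc = froc_from_detections(flat[perm], flat_tids, len(test), n_targets)
        permuted_aucs.append(auc_0_10(froc))

    return {
        "n_cases": n_cases,
        "n_test": n_test,
        "candidate_sensitivity_all": candidate_sensitivity(processed),
        "candidate_sensitivity_large": (
            large_found / large_total if large_total else float("nan")
        ),
        "n_large_nodules": large_total,
        "n_features_selected": trace.chosen_size,
        "auc_0_10": res["auc_0_10"],
        "anode": res["anode"],
        "auc_0_10_permuted": float(np.mean(permuted_aucs)),
    }


def run_small_nodule_thickness_benchmark(
    seed: int, n_cases: int = 12, ratios=(1, 8)
) -> dict:
    """Candidate-detector sensitivity for small nodules across thicknesses.

    Generates a cohort of exclusively small (4-5 mm) nodules at 1.25-mm
    slices and measures the pre-classifier sensitivity at each slab ratio;
    small nodules dilute into thick slabs, so sensitivity should fall with
    the ratio.
    """
    spec = PhantomSpec()
    cases = generate_cohort(
        n_cases,
        spec,
        (2, 3),
        seed,
        diameter_range_mm=(4.0, 5.0),
        contrast_range_hu=(400.0, 600.0),
    )
    det_params = DetectorParams()
    criterion = HitCriterion()
    out = {}
    for ratio in ratios:
        processed = _process_cohort(cases, int(ratio), det_params, criterion)
        out[int(ratio)] = candidate_sensitivity(processed)
    return out
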