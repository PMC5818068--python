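"""FROC scoring for nodule CAD: hit matching, AUC over 0-10 FP/case, ANODE.

A detection run is scored free-response style: every candidate carries a
score, and as the score threshold sweeps downward the operating point moves
to higher sensitivity at the cost of more false positives per case.  The
headline summaries are the area under the FROC curve restricted to 0-10
false positives per case (max 10) and the ANODE score, the mean sensitivity
at the seven reference rates 0.125, 0.25, 0.5, 1, 2, 4 and 8 FP/case.

Redundant radiologist markings of one physical nodule are merged into a
single target before scoring, so a nodule marked three times counts once.
The hit rule follows the LUNA16 convention: a candidate hits a target when
its centroid lies strictly within the target's radius (diameter/2, world
mm).  Multiple hits on one target count once for sensitivity and never as
false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ANODE_RATES = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

__all__ = [
    "ANODE_RATES",
    "FROCCurve",
    "HitCriterion",
    "merge_redundant_annotations",
    "match_candidates",
    "compute_froc",
    "froc_from_detections",
    "auc_0_10",
    "anode_score",
    "subset_confidence_interval",
]


@dataclass(frozen=True)
class HitCriterion:
    """Candidate-target matching rule: distance < scale * (diameter / 2)."""

    radius_scale: float = 1.0

    def radius(self, diameter_mm: float) -> float:
        return self.radius_scale * diameter_mm / 2.0


@dataclass
class FROCCurve:
    """Operating points (FP/case, sensitivity), one per distinct threshold.

    Points are ordered by descending score threshold, i.e. non-decreasing
    FP/case and non-decreasing sensitivity.
    """

    fp_per_case: np.ndarray
    sensitivity: np.ndarray
    n_cases: int
    n_targets: int
    thresholds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.fp_per_case = np.asarray(self.fp_per_case, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if self.fp_per_case.shape != self.sensitivity.shape:
            raise ValueError("fp_per_case and sensitivity must align")
        if np.any(np.diff(self.fp_per_case) < 0):
            raise ValueError("FP/case must be non-decreasing along the curve")
        if np.any(np.diff(self.sensitivity) < -1e-12):
            raise ValueError("sensitivity must be non-decreasing along the curve")
        if self.sensitivity.size and (
            self.sensitivity.min() < -1e-12 or self.sensitivity.max() > 1 + 1e-12
        ):
            raise ValueError("sensitivity out of [0, 1]")

    def sensitivity_at(self, fp_rate) -> np.ndarray:
        """Right-continuous step read: sensitivity of the last operating
        point with FP/case <= fp_rate, 0 below the first achieved rate."""
        fp_rate = np.atleast_1d(np.asarray(fp_rate, dtype=float))
        if self.fp_per_case.size == 0:
            return np.zeros_like(fp_rate)
        # collapse duplicate FP values to their best (latest) sensitivity
        fps, sens = _collapse(self.fp_per_case, self.sensitivity)
        idx = np.searchsorted(fps, fp_rate, side="right") - 1
        out = np.where(idx >= 0, sens[np.clip(idx, 0, None)], 0.0)
        return out


def _collapse(fps: np.ndarray, sens: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, last_index = np.unique(fps[::-1], return_index=True)
    return uniq, sens[::-1][last_index]


def merge_redundant_annotations(annotations) -> list:
    """Merge markings of one physical nodule into single targets.

    Two annotations are linked when each center lies within the other's
    radius (distance < min of the two radii); linked groups are merged via
    union-find into a target centered at the member mean with diameter equal
    to the member max.  Input items need ``center_mm`` (3-vector, world mm)
    and ``diameter_mm`` attributes; merged targets are returned as
    :class:`MergedTarget`.
    """
    anns = list(annotations)
    n = len(anns)
    if n == 0:
        return []
    centers = np.array([np.asarray(a.center_mm, dtype=float) for a in anns])
    radii = np.array([a.diameter_mm / 2.0 for a in anns])
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(centers[i] - centers[j]))
            if d < min(radii[i], radii[j]):
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    targets = []
    for k, members in enumerate(sorted(groups.values(), key=lambda m: m[0])):
        targets.append(
            MergedTarget(
                target_id=k,
                center_mm=tuple(centers[members].mean(axis=0)),
                diameter_mm=float(max(anns[m].diameter_mm for m in members)),
                n_markings=len(members),
            )
        )
    return targets


@dataclass(frozen=True)
class MergedTarget:
    target_id: int
    center_mm: tuple[float, float, float]
    diameter_mm: float
    n_markings: int = 1


def match_candidates(candidate_centers_mm, targets, criterion: HitCriterion | None = None):
    """Label candidates against merged targets of one case.

    Returns ``(target_ids, detected)`` where ``target_ids[i]`` is the id of
    the nearest target whose radius contains candidate ``i`` (or -1 for a
    non-hit) and ``detected[t]`` flags targets hit by at least one candidate.
    """
    criterion = criterion or HitCriterion()
    centers = np.atleast_2d(np.asarray(candidate_centers_mm, dtype=float)).reshape(-1, 3)
    target_ids = np.full(len(centers), -1, dtype=int)
    detected = {t.target_id: False for t in targets}
    if not targets:
        return target_ids, detected
    t_centers = np.array([t.center_mm for t in targets])
    t_radii = np.array([criterion.radius(t.diameter_mm) for t in targets])
    t_ids = np.array([t.target_id for t in targets])
    for i, c in enumerate(centers):
        dists = np.linalg.norm(t_centers - c, axis=1)
        inside = dists < t_radii  # strict: a candidate on the boundary misses
        if np.any(inside):
            j = int(np.argmin(np.where(inside, dists, np.inf)))
            target_ids[i] = int(t_ids[j])
            detected[int(t_ids[j])] = True
    return target_ids, detected


def froc_from_detections(scores, target_ids, n_cases: int, n_targets: int) -> FROCCurve:
    """Build the FROC curve from scored, pre-matched candidates.

    ``target_ids`` holds the matched target id per candidate (-1 = false
    positive); target ids must be unique across cases.  Thresholds sweep the
    distinct scores descending; tied scores enter the operating set together.
    Cases with zero candidates contribute only to the FP denominator.
    """
    if n_targets <= 0:
        raise ValueError("FROC requires at least one target nodule")
    if n_cases <= 0:
        raise ValueError("FROC requires at least one case")
    scores = np.asarray(scores, dtype=float)
    target_ids = np.asarray(target_ids, dtype=int)
    if scores.shape != target_ids.shape:
        raise ValueError("scores and target_ids must align")
    if scores.size == 0:
        return FROCCurve(np.array([0.0]), np.array([0.0]), n_cases, n_targets,
                         thresholds=np.array([]))
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    t_sorted = target_ids[order]
    # last position of each distinct score = full operating set at that threshold
    boundary = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([boundary, [scores.size - 1]])
    fp_cum = np.cumsum(t_sorted < 0)
    sens, fps = [], []
    seen: set[int] = set()
    k_prev = 0
    for k in cut:
        for t in t_sorted[k_prev : k + 1]:
            if t >= 0:
                seen.add(int(t))
        k_prev = k + 1
        sens.append(len(seen) / n_targets)
        fps.append(fp_cum[k] / n_cases)
    return FROCCurve(
        np.asarray(fps), np.asarray(sens), n_cases, n_targets, thresholds=s_sorted[cut]
    )


def compute_froc(case_detections, criterion: HitCriterion | None = None) -> FROCCurve:
    """Score a full test set.

    ``case_detections`` is an iterable of ``(candidate_centers_mm, scores,
    targets)`` triples, one per test case (cases with no candidates pass
    empty arrays).  Annotation merging is the caller's responsibility;
    ``targets`` are :class:`MergedTarget`-like objects per case.
    """
    criterion = criterion or HitCriterion()
    all_scores, all_tids = [], []
    n_cases = 0
    n_targets = 0
    offset = 0
    for centers, scores, targets in case_detections:
        n_cases += 1
        tids, _ = match_candidates(centers, targets, criterion)
        shifted = np.where(tids >= 0, tids + offset, -1)
        all_tids.append(shifted)
        all_scores.append(np.asarray(scores, dtype=float))
        offset += len(targets)
        n_targets += len(targets)
    scores = np.concatenate(all_scores) if all_scores else np.array([])
    tids = np.concatenate(all_tids) if all_tids else np.array([], dtype=int)
    return froc_from_detections(scores, tids, n_cases, n_targets)


def auc_0_10(froc: FROCCurve) -> float:
    """Area under sensitivity vs FP/case over [0, 10].

    The curve is a right-continuous step function between operating points,
    held constant at its final sensitivity beyond the last point, clipped at
    10 FP/case; the result lies in [0, 10].
    """
    breaks = np.unique(np.concatenate([[0.0, 10.0], np.clip(froc.fp_per_case, 0, 10)]))
    widths = np.diff(breaks)
    heights = froc.sensitivity_at(breaks[:-1])
    return float(np.sum(widths * heights))


def anode_score(froc: FROCCurve) -> float:
    """Mean sensitivity at the seven reference FP rates (ANODE convention)."""
    return float(np.mean(froc.sensitivity_at(np.asarray(ANODE_RATES))))


def subset_confidence_interval(case_ids, metric_fn, n_subsets: int = 10, seed: int = 0):
    """Mean and 95% half-width of a metric over random case subsets.

    Cases are partitioned into ``n_subsets`` near-equal seeded subsets;
    ``metric_fn`` maps a list of case ids to a scalar.  Returns
    ``(mean, 1.96 * std / sqrt(n_subsets))`` with the sample (ddof=1) std.
    """
    case_ids = list(case_ids)
    if len(case_ids) < n_subsets:
        raise ValueError(
            f"{len(case_ids)} cases cannot be split into {n_subsets} subsets"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(case_ids))
    subsets = np.array_split(perm, n_subsets)
    values = np.array([float(metric_fn([case_ids[i] for i in sub])) for sub in subsets])
    half_width = 1.96 * values.std(ddof=1) / np.sqrt(n_subsets)
    return float(values.mean()), float(half_width)
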