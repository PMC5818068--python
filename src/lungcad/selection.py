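"""Feature shortlisting, sequential forward selection, Fisher discriminant.

The classification stage mirrors a classic nodule-CAD recipe: a large
feature catalog is first shortlisted by ranking each feature's class
separation with the (orientation-folded) Mann-Whitney ROC AUC, then a
greedy sequential forward selection (SFS) grows a feature set one at a
time, scoring each tentative set by the free-response merit that actually
matters downstream — the area under the training-set FROC curve between 0
and 10 false positives per case.  The final classifier is a Fisher linear
discriminant (FLD) on standardized features with a small ridge on the
pooled within-class covariance, which keeps the fit well defined when the
feature count approaches the candidate count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .evaluation import auc_0_10, froc_from_detections

STD_FLOOR = 1e-6

__all__ = [
    "FLDModel",
    "SFSTrace",
    "TrainingBundle",
    "FitError",
    "roc_auc",
    "shortlist_features",
    "fit_fld",
    "score_candidates",
    "sfs_select",
]


class FitError(RuntimeError):
    """Classifier fit failed (singular scatter with no ridge)."""


def roc_auc(values, labels) -> float:
    """Orientation-folded Mann-Whitney AUC of one feature, in [0.5, 1].

    Ties count 0.5 via midranks; the raw AUC is folded to
    ``max(auc, 1 - auc)`` so anti-correlated features rank as high as
    correlated ones.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(values)
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return float(max(auc, 1.0 - auc))


def shortlist_features(X, labels, k: int) -> np.ndarray:
    """Indices of the top-k features by folded ROC AUC (stable tie order).

    Ties in AUC are broken by catalog (column) order via a stable sort, so
    the shortlist is deterministic for a fixed feature registry.
    """
    X = np.asarray(X, dtype=float)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {X.shape[1]}")
    aucs = np.array([roc_auc(X[:, j], labels) for j in range(X.shape[1])])
    order = np.argsort(-aucs, kind="stable")
    return order[:k]


@dataclass
class FLDModel:
    """Fisher linear discriminant on standardized features."""

    weights: np.ndarray
    means: np.ndarray
    stds: np.ndarray
    feature_names: tuple[str, ...]
    ridge: float

    def save(self, path) -> None:
        """Persist as a plain-text key/value + array file."""
        path = Path(path)
        lines = [
            f"ridge = {self.ridge!r}",
            "features = " + ",".join(self.feature_names),
            "weights = " + ",".join(repr(float(v)) for v in self.weights),
            "means = " + ",".join(repr(float(v)) for v in self.means),
            "stds = " + ",".join(repr(float(v)) for v in self.stds),
        ]
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "FLDModel":
        fields: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if "=" in line:
                key, value = line.split("=", 1)
                fields[key.strip()] = value.strip()
        names = tuple(n for n in fields["features"].split(",") if n)
        arr = lambda key: np.array([float(v) for v in fields[key].split(",")])
        return cls(arr("weights"), arr("means"), arr("stds"), names,
                   float(fields["ridge"]))


def fit_fld(X, y, ridge: float = 1e-3, feature_names=None) -> FLDModel:
    """Fit ``w = (S_w + ridge I)^-1 (mu1 - mu0)`` on standardized features.

    ``S_w`` is the pooled within-class covariance of the standardized
    training matrix; standardization statistics (train means, stds floored
    at 1e-6) are stored in the model and re-applied at scoring time.  With
    ``ridge = 0`` a singular pooled covariance (e.g. duplicated feature
    columns) raises :class:`FitError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if y.all() or not y.any():
        raise ValueError("fit_fld requires both classes present")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    means = X.mean(axis=0)
    stds = np.maximum(X.std(axis=0), STD_FLOOR)
    Z = (X - means) / stds
    mu0 = Z[~y].mean(axis=0)
    mu1 = Z[y].mean(axis=0)
    n0, n1 = int((~y).sum()), int(y.sum())
    S0 = (Z[~y] - mu0).T @ (Z[~y] - mu0)
    S1 = (Z[y] - mu1).T @ (Z[y] - mu1)
    denom = max(n0 + n1 - 2, 1)
    Sw = (S0 + S1) / denom + ridge * np.eye(X.shape[1])
    if ridge == 0 and np.linalg.cond(Sw) > 1e12:
        raise FitError("pooled within-class scatter is singular; use ridge > 0")
    try:
        w = np.linalg.solve(Sw, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular system in FLD fit") from exc
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"f{j}" for j in range(X.shape[1])
    )
    if len(names) != X.shape[1]:
        raise ValueError("feature_names length mismatch")
    return FLDModel(w, means, stds, names, float(ridge))


def score_candidates(model: FLDModel, X, feature_names=None) -> np.ndarray:
    """Discriminant scores (higher = more nodule-like) for a feature matrix.

    When ``X`` is a pandas DataFrame, columns are looked up by the model's
    feature names; a missing column raises ``KeyError``.
    """
    if hasattr(X, "columns"):  # DataFrame path
        missing = [n for n in model.feature_names if n not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        X = X.loc[:, list(model.feature_names)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.zeros(0)
    if feature_names is not None and tuple(feature_names) != model.feature_names:
        raise KeyError("feature columns do not match the fitted model")
    if X.shape[1] != model.weights.size:
        raise KeyError(
            f"expected {model.weights.size} features, got {X.shape[1]}"
        )
    Z = (X - model.means) / model.stds
    return Z @ model.weights


@dataclass
class TrainingBundle:
    """Everything SFS needs to evaluate a tentative feature set.

    Candidates are pooled across training cases: feature matrix, hit target
    id per candidate (-1 for non-hits, globally unique otherwise), case
    count and merged-target count so the training FROC is computable.
    """

    X: np.ndarray
    feature_names: tuple[str, ...]
    target_ids: np.ndarray
    n_cases: int
    n_targets: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.target_ids = np.asarray(self.target_ids, dtype=int)
        if self.X.shape[0] != self.target_ids.size:
            raise ValueError("X rows must align with target_ids")
        if self.n_targets <= 0:
            raise ValueError("training bundle carries no annotated targets")

    @property
    def y(self) -> np.ndarray:
        return self.target_ids >= 0


@dataclass
class SFSTrace:
    """Selected feature names in order, merit after each addition, and the
    plateau-rule stopping size."""

    features: list[str]
    merits: list[float]
    chosen_size: int

    @property
    def chosen_features(self) -> list[str]:
        return self.features[: self.chosen_size]


def _bundle_merit(bundle: TrainingBundle, cols, ridge: float) -> float:
    model = fit_fld(bundle.X[:, cols], bundle.y, ridge=ridge)
    scores = score_candidates(model, bundle.X[:, cols])
    froc = froc_from_detections(scores, bundle.target_ids,
                                bundle.n_cases, bundle.n_targets)
    return auc_0_10(froc)


def sfs_select(
    bundle: TrainingBundle,
    max_features: int = 20,
    ridge: float = 1e-3,
    plateau_tol: float = 0.05,
) -> SFSTrace:
    """Greedy sequential forward selection under the FROC AUC(0-10) merit.

    Features are added one at a time; each tentative set is scored by
    refitting the FLD on the training candidates and integrating the
    resulting training-set FROC from 0 to 10 FP/case (resubstitution merit).
    Merit ties break toward catalog order.  The chosen size is the smallest
    prefix whose merit is within ``plateau_tol`` of the best merit seen
    along the trace (deterministic plateau rule), capped at
    ``max_features``.
    """
    n_features = bundle.X.shape[1]
    if n_features < 2:
        raise ValueError("SFS needs at least 2 candidate features")
    if not bundle.y.any():
        raise ValueError("no positive candidates; FROC merit not computable")
    selected: list[int] = []
    merits: list[float] = []
    remaining = list(range(n_features))
    for _ in range(min(max_features, n_features)):
        best_j, best_merit = None, -np.inf
        for j in remaining:
            merit = _bundle_merit(bundle, selected + [j], ridge)
            if merit > best_merit:  # strict: ties keep the earlier catalog index
                best_j, best_merit = j, merit
        selected.append(best_j)  # type: ignore[arg-type]
        remaining.remove(best_j)  # type: ignore[arg-type]
        merits.append(float(best_merit))
    peak = max(merits)
    chosen_size = next(
        i + 1 for i, m in enumerate(merits) if m >= peak - plateau_tol
    )
    names = [bundle.feature_names[j] for j in selected]
    return SFSTrace(features=names, merits=merits, chosen_size=chosen_size)
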