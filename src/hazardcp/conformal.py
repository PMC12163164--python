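"""Mondrian inductive conformal prediction for binary classification.

A probabilistic base classifier (by default a random forest with library
defaults) is trained on the proper training set; a held-out calibration
set is scored with the nonconformity function ``1 - P(true class)`` and
the scores are kept *separately per class* (the Mondrian taxonomy).  For
a test compound, the p-value of each hypothesized class c is the rank of
its nonconformity score within class c's calibration scores::

    p_c = (#{s in cal_c : s >= score} + 1) / (|cal_c| + 1)

A class is included in the prediction set iff ``p_c > epsilon`` (strict),
giving one of four outcomes: a single-label prediction for either class,
*both*, or *empty*.  Under exchangeability the per-class error rate —
prediction sets that miss the true class — is at most epsilon, class-wise.

The model object follows the fit/results idiom: build a
:class:`MondrianConformalClassifier` from the split data, call
:meth:`~MondrianConformalClassifier.fit`, and use the returned
:class:`ConformalResults` for p-values, prediction sets and a summary.
"""

from __future__ import annotations

import enum
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeaturizerSpec

__all__ = [
    "Outcome",
    "ConformalError",
    "nonconformity",
    "p_value",
    "prediction_set",
    "prediction_sets",
    "MondrianConformalClassifier",
    "ConformalResults",
    "fit_icp",
    "predict_pvalues",
]


class ConformalError(ValueError):
    pass


class Outcome(enum.IntEnum):
    """The four possible conformal prediction sets for a binary task."""

    SINGLE_ACTIVE = 0    # {active}
    SINGLE_INACTIVE = 1  # {inactive}
    BOTH = 2             # {active, inactive}
    EMPTY = 3            # {}

    def contains(self, label: int) -> bool:
        """Whether the prediction set contains class ``label`` (0/1)."""
        if self is Outcome.BOTH:
            return True
        if self is Outcome.EMPTY:
            return False
        return (self is Outcome.SINGLE_ACTIVE) == (label == 1)

    @property
    def is_single(self) -> bool:
        return self in (Outcome.SINGLE_ACTIVE, Outcome.SINGLE_INACTIVE)


def nonconformity(prob_of_class) -> np.ndarray | float:
    """Nonconformity score ``1 - P(hypothesized class)``.

    Monotone decreasing in the probability; 0 for a perfectly conforming
    example, 1 for a perfectly non-conforming one.
    """
    p = np.asarray(prob_of_class, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConformalError(f"probability outside [0, 1]: {prob_of_class!r}")
    out = 1.0 - p
    return float(out) if out.ndim == 0 else out


def p_value(
    cal_scores: Sequence[float],
    test_score: float,
    smoothed: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Conformal p-value of a test score against one class's calibration scores.

    Deterministic (default): ties count toward the numerator,
    ``p = (#{s >= t} + 1) / (n + 1)``.  With ``smoothed=True`` ties are
    split uniformly at random (seeded ``rng`` required for
    reproducibility), which makes the p-values exactly rather than
    conservatively valid.
    """
    if not 0.0 <= test_score <= 1.0:
        raise ConformalError(f"test score outside [0, 1]: {test_score}")
    scores = np.asarray(cal_scores, dtype=float)
    n = scores.size
    if not smoothed:
        return (int(np.sum(scores >= test_score)) + 1) / (n + 1)
    greater = int(np.sum(scores > test_score))
    ties = int(np.sum(scores == test_score))
    u = (rng or np.random.default_rng()).uniform()
    return (greater + u * (ties + 1)) / (n + 1)


def prediction_set(p_active: float, p_inactive: float, epsilon: float) -> Outcome:
    """Map a p-value pair to one of the four outcomes at significance ``epsilon``.

    A class is included iff its p-value strictly exceeds ``epsilon``.
    """
    if not 0.0 < epsilon < 1.0:
        raise ConformalError(f"significance must be in (0, 1), got {epsilon}")
    active = p_active > epsilon
    inactive = p_inactive > epsilon
    if active and inactive:
        return Outcome.BOTH
    if active:
        return Outcome.SINGLE_ACTIVE
    if inactive:
        return Outcome.SINGLE_INACTIVE
    return Outcome.EMPTY


def prediction_sets(pvals: np.ndarray, epsilon: float) -> np.ndarray:
    """Vectorized :func:`prediction_set` over an (n, 2) [p_inactive, p_active] array."""
    pvals = np.asarray(pvals, dtype=float)
    return np.array(
        [prediction_set(pa, pi, epsilon) for pi, pa in pvals], dtype=object
    )


class MondrianConformalClassifier:
    """Mondrian ICP model specification: split data plus a base classifier.

    Parameters
    ----------
    X_train, y_train
        Proper training set for the base classifier (labels in {0, 1};
        both classes must be present).
    X_cal, y_cal
        Calibration set, disjoint from training (both classes present).
    base
        Unfitted scikit-learn style classifier with ``predict_proba``;
        default: ``RandomForestClassifier`` with library defaults, seeded.
    spec
        Optional :class:`~hazardcp.features.FeaturizerSpec` recorded with
        the model for provenance and dimension checks.
    seed
        Seeds the base classifier (and tie-splitting when smoothed
        p-values are requested at prediction time).
    """

    def __init__(
        self,
        X_train,
        y_train,
        X_cal,
        y_cal,
        base=None,
        spec: FeaturizerSpec | None = None,
        seed: int = 0,
    ):
        self.X_train = np.asarray(X_train)
        self.y_train = np.asarray(y_train, dtype=int)
        self.X_cal = np.asarray(X_cal)
        self.y_cal = np.asarray(y_cal, dtype=int)
        for name, y in (("training", self.y_train), ("calibration", self.y_cal)):
            if set(np.unique(y)) != {0, 1}:
                raise ConformalError(
                    f"{name} set must contain both classes (got labels "
                    f"{sorted(set(np.unique(y)))}); re-split the data"
                )
        self.base = base
        self.spec = spec
        self.seed = seed

    def fit(self) -> "ConformalResults":
        """Fit the base classifier and calibrate per class."""
        base = self.base
        if base is None:
            base = RandomForestClassifier(random_state=self.seed, n_jobs=1)
        base.fit(self.X_train, self.y_train)
        proba_cal = base.predict_proba(self.X_cal)
        col = {int(c): j for j, c in enumerate(base.classes_)}
        cal_scores = {}
        for cls in (0, 1):
            mask = self.y_cal == cls
            cal_scores[cls] = np.sort(nonconformity(proba_cal[mask, col[cls]]))
        return ConformalResults(self, base, cal_scores)


class ConformalResults:
    """A fitted Mondrian ICP: base model plus per-class calibration scores."""

    def __init__(self, model: MondrianConformalClassifier, base, cal_scores):
        self.model = model
        self.base_ = base
        self.cal_scores_ = cal_scores
        self.seed = model.seed
        self.spec = model.spec
        self._col = {int(c): j for j, c in enumerate(base.classes_)}

    @property
    def n_cal_(self) -> dict[int, int]:
        return {c: int(s.size) for c, s in self.cal_scores_.items()}

    def predict_p(
        self, X, smoothed: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Class-conditional p-values, shape (n, 2): columns (p_inactive, p_active)."""
        X = np.asarray(X)
        expected = self.model.X_train.shape[1]
        if X.ndim != 2 or X.shape[1] != expected:
            raise ConformalError(
                f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"model expects {expected}"
                + (f" (featurizer {self.spec.name})" if self.spec else "")
            )
        if smoothed and rng is None:
            rng = np.random.default_rng(self.seed)
        proba = self.base_.predict_proba(X)
        out = np.empty((X.shape[0], 2), dtype=float)
        for cls in (0, 1):
            scores = nonconformity(proba[:, self._col[cls]])
            cal = self.cal_scores_[cls]
            if smoothed:
                out[:, cls] = [p_value(cal, s, smoothed=True, rng=rng) for s in scores]
            else:
                # rank against the sorted calibration scores in one pass
                ge = cal.size - np.searchsorted(cal, scores, side="left")
                out[:, cls] = (ge + 1) / (cal.size + 1)
        return out

    def predict_set(self, X, epsilon: float, **kwargs) -> np.ndarray:
        """Prediction sets (array of :class:`Outcome`) at significance ``epsilon``."""
        return prediction_sets(self.predict_p(X, **kwargs), epsilon)

    def summary(self) -> str:
        lines = [
            "Mondrian inductive conformal predictor",
            "=" * 46,
            f"base classifier     {type(self.base_).__name__}",
            f"featurizer          {self.spec.name if self.spec else '-'}",
            f"seed                {self.seed}",
            f"n train             {self.model.y_train.size} "
            f"({int(self.model.y_train.sum())} active)",
        ]
        for cls, label in ((1, "active"), (0, "inactive")):
            s = self.cal_scores_[cls]
            lines.append(
                f"cal {label:<9}       n={s.size:<5d} median score={np.median(s):.3f}"
            )
        lines.append(
            f"min attainable p    active {1 / (self.n_cal_[1] + 1):.4f}, "
            f"inactive {1 / (self.n_cal_[0] + 1):.4f}"
        )
        return "\n".join(lines)

    def save(self, path) -> None:
        joblib.dump(
            {
                "base": self.base_,
                "cal_scores": self.cal_scores_,
                "spec": self.spec.to_dict() if self.spec else None,
                "seed": self.seed,
                "n_features": self.model.X_train.shape[1],
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "ConformalResults":
        bundle = joblib.load(path)
        spec = FeaturizerSpec.from_dict(bundle["spec"]) if bundle["spec"] else None
        model = MondrianConformalClassifier.__new__(MondrianConformalClassifier)
        model.X_train = np.empty((0, bundle["n_features"]))
        model.y_train = np.empty(0, dtype=int)
        model.spec = spec
        model.seed = bundle["seed"]
        res = cls.__new__(cls)
        res.model = model
        res.base_ = bundle["base"]
        res.cal_scores_ = bundle["cal_scores"]
        res.seed = bundle["seed"]
        res.spec = spec
        res._col = {int(c): j for j, c in enumerate(bundle["base"].classes_)}
        return res


def fit_icp(X_train, y_train, X_cal, y_cal, base=None,
            spec: FeaturizerSpec | None = None, seed: int = 0) -> ConformalResults:
    """Functional form: build and fit a Mondrian ICP in one call."""
    return MondrianConformalClassifier(
        X_train, y_train, X_cal, y_cal, base=base, spec=spec, seed=seed
    ).fit()


def predict_pvalues(results: ConformalResults, X, **kwargs) -> np.ndarray:
    """Functional form of :meth:`ConformalResults.predict_p`."""
    return results.predict_p(X, **kwargs)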