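"""Conformal and classical performance metrics, and the CV experiment driver.

Conformal metrics are class-conditional, matching the Mondrian guarantee:
*validity* is the fraction of prediction sets containing the true class
(*both* always correct, *empty* always erroneous) among compounds whose
true label is that class; *efficiency* is the fraction of single-label
prediction sets among the same compounds, regardless of correctness.

Classical metrics (accuracy, balanced accuracy, sensitivity, specificity,
Matthews correlation) are computed on the single-label predictions only,
and a ROC AUC is computed over all compounds from the per-compound score
``p_active - p_inactive``.

Metrics with an empty denominator are reported as ``None`` (serialized as
nulls), never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conformal import Outcome, fit_icp, prediction_sets
from .consensus import ConsensusConfig, consensus_cls, consensus_pvals, resolve_model_set
from .data import MoleculeRecord, make_folds, standardize_records
from .features import featurize_dataset, get_featurizer

__all__ = [
    "validity",
    "efficiency",
    "single_label_metrics",
    "roc_auc_from_pvalue_diff",
    "compute_metrics",
    "run_cv_experiment",
    "CVResults",
    "DEFAULT_EPSILONS",
]

DEFAULT_EPSILONS = (0.1, 0.15, 0.2, 0.25, 0.3)


def _class_mask(true_labels, class_c) -> np.ndarray:
    return np.asarray(true_labels, dtype=int) == int(class_c)


def validity(outcomes: Sequence[Outcome], true_labels, class_c: int) -> float | None:
    """Fraction of prediction sets containing the true class, among
    compounds of true class ``class_c``.  ``None`` if no such compound."""
    mask = _class_mask(true_labels, class_c)
    if not mask.any():
        return None
    hits = [Outcome(o).contains(class_c) for o, m in zip(outcomes, mask) if m]
    return float(np.mean(hits))


def efficiency(outcomes: Sequence[Outcome], true_labels, class_c: int) -> float | None:
    """Fraction of single-label prediction sets (either label, correct or
    not) among compounds of true class ``class_c``."""
    mask = _class_mask(true_labels, class_c)
    if not mask.any():
        return None
    singles = [Outcome(o).is_single for o, m in zip(outcomes, mask) if m]
    return float(np.mean(singles))


def single_label_metrics(
    outcomes: Sequence[Outcome], true_labels
) -> dict[str, float] | None:
    """Acc, BA, SE, SP and MCC over the single-label predictions.

    Predictions are restricted to singleton outcomes; the 2x2 table is
    active-prediction vs true label.  MCC is 0 when a marginal is zero.
    ``None`` when there is no singleton at all; SE/SP are ``None`` when
    their own class is absent among the singletons.
    """
    y = np.asarray(true_labels, dtype=int)
    single = np.array([Outcome(o).is_single for o in outcomes], dtype=bool)
    if not single.any():
        return None
    pred_active = np.array(
        [Outcome(o) is Outcome.SINGLE_ACTIVE for o in outcomes], dtype=bool
    )[single]
    truth = y[single] == 1
    tp = int(np.sum(pred_active & truth))
    fn = int(np.sum(~pred_active & truth))
    tn = int(np.sum(~pred_active & ~truth))
    fp = int(np.sum(pred_active & ~truth))
    n = tp + fn + tn + fp
    se = tp / (tp + fn) if (tp + fn) else None
    sp = tn / (tn + fp) if (tn + fp) else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return {
        "acc": (tp + tn) / n,
        "ba": (se + sp) / 2 if se is not None and sp is not None else None,
        "se": se,
        "sp": sp,
        "mcc": mcc,
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


def roc_auc_from_pvalue_diff(pvals: np.ndarray, true_labels) -> float | None:
    """ROC AUC of the ranking score ``p_active - p_inactive``.

    Mann-Whitney formulation: the probability that a random active scores
    above a random inactive, ties credited 0.5.  ``None`` if either class
    is absent.
    """
    pvals = np.asarray(pvals, dtype=float)
    y = np.asarray(true_labels, dtype=int)
    scores = pvals[:, 1] - pvals[:, 0]
    pos, neg = scores[y == 1], scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        return None
    # rank-sum form: O(n log n)
    order = np.argsort(np.concatenate([pos, neg]), kind="mergesort")
    ranks = np.empty(order.size, dtype=float)
    combined = np.concatenate([pos, neg])[order]
    i = 0
    rank = np.empty(order.size)
    while i < combined.size:
        j = i
        while j + 1 < combined.size and combined[j + 1] == combined[i]:
            j += 1
        rank[i : j + 1] = (i + j) / 2 + 1  # mid-rank for ties
        i = j + 1
    ranks[order] = rank
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def compute_metrics(
    outcomes: Sequence[Outcome],
    true_labels,
    pvals: np.ndarray | None = None,
) -> dict[str, float | int | None]:
    """All metrics for one model at one significance level."""
    y = np.asarray(true_labels, dtype=int)
    outcomes = [Outcome(o) for o in outcomes]
    counts = {o: 0 for o in Outcome}
    for o in outcomes:
        counts[o] += 1
    metrics: dict[str, float | int | None] = {
        "validity_active": validity(outcomes, y, 1),
        "validity_inactive": validity(outcomes, y, 0),
        "efficiency_active": efficiency(outcomes, y, 1),
        "efficiency_inactive": efficiency(outcomes, y, 0),
        "efficiency_overall": (
            float(np.mean([o.is_single for o in outcomes])) if outcomes else None
        ),
        "n_single_active": counts[Outcome.SINGLE_ACTIVE],
        "n_single_inactive": counts[Outcome.SINGLE_INACTIVE],
        "n_both": counts[Outcome.BOTH],
        "n_empty": counts[Outcome.EMPTY],
        "n_evaluated": len(outcomes),
    }
    slm = single_label_metrics(outcomes, y)
    for key in ("acc", "ba", "se", "sp", "mcc"):
        metrics[key] = slm[key] if slm else None
    metrics["roc_auc"] = (
        roc_auc_from_pvalue_diff(pvals, y) if pvals is not None else None
    )
    return metrics


@dataclass
class CVResults:
    """Pooled cross-validated predictions plus the tidy metrics report.

    ``pvalues`` maps a model name to an (n, 2) array of pooled test-fold
    p-values (columns p_inactive, p_active; NaN where the model could not
    featurize the compound).  ``report`` is tidy: one row per
    (model, epsilon, metric).
    """

    ids: list[str]
    labels: np.ndarray
    pvalues: dict[str, np.ndarray]
    report: pd.DataFrame
    epsilons: tuple[float, ...]
    seed: int
    fold_of: np.ndarray
    consensus_outcomes: dict[str, dict[float, np.ndarray]] = field(default_factory=dict)

    def metric(self, model: str, epsilon: float, name: str):
        rows = self.report[
            (self.report["model"] == model)
            & (np.isclose(self.report["epsilon"], epsilon))
            & (self.report["metric"] == name)
        ]
        if rows.empty:
            raise KeyError(f"no metric {name!r} for {model!r} at epsilon {epsilon}")
        value = rows["value"].iloc[0]
        return None if pd.isna(value) else float(value)

    def outcomes(self, model: str, epsilon: float) -> np.ndarray:
        """Prediction sets for one model at one significance (NaN rows -> EMPTY
        excluded: entries are None where the model has no p-values)."""
        if model in self.consensus_outcomes:
            return self.consensus_outcomes[model][epsilon]
        pv = self.pvalues[model]
        out = np.empty(len(self.ids), dtype=object)
        ok = ~np.isnan(pv).any(axis=1)
        out[ok] = prediction_sets(pv[ok], epsilon)
        out[~ok] = None
        return out

    def predictions_frame(self, epsilon: float) -> pd.DataFrame:
        """Per-compound table: id, label and each model's p-values/outcome."""
        data: dict[str, object] = {"id": self.ids, "label": self.labels,
                                   "fold": self.fold_of}
        for name, pv in self.pvalues.items():
            data[f"p_inactive[{name}]"] = pv[:, 0]
            data[f"p_active[{name}]"] = pv[:, 1]
            data[f"outcome[{name}]"] = [
                o.name if o is not None else "" for o in self.outcomes(name, epsilon)
            ]
        for name in self.consensus_outcomes:
            data[f"outcome[{name}]"] = [
                o.name if o is not None else "" for o in self.outcomes(name, epsilon)
            ]
        return pd.DataFrame(data)

    def summary(self, epsilon: float = 0.2) -> str:
        models = list(dict.fromkeys(self.report["model"]))
        lines = [
            f"10-fold CV conformal prediction report (epsilon={epsilon})",
            "=" * 78,
            f"{'model':<28}{'val_act':>8}{'val_ina':>8}{'eff_act':>8}"
            f"{'eff_ina':>8}{'BA':>8}{'MCC':>8}",
            "-" * 78,
        ]
        for m in models:
            def g(name):
                v = self.metric(m, epsilon, name)
                return f"{v:8.3f}" if v is not None else f"{'--':>8}"
            lines.append(
                f"{m:<28}" + g("validity_active") + g("validity_inactive")
                + g("efficiency_active") + g("efficiency_inactive")
                + g("ba") + g("mcc")
            )
        return "\n".join(lines)


def run_cv_experiment(
    records: Sequence[MoleculeRecord],
    featurizer_names: Sequence[str],
    epsilons: Sequence[float] = DEFAULT_EPSILONS,
    consensus_configs: Sequence[ConsensusConfig] = (),
    k: int = 10,
    cal_frac: float = 0.2,
    seed: int = 0,
    shuffle: bool = True,
    dataset_name: str = "dataset",
) -> CVResults:
    """Run the full cross-validated experiment grid.

    For each fold: split into proper-train / calibration / test, featurize
    per descriptor, fit the Mondrian ICP, and predict test p-values; test
    predictions are pooled over folds (the test sets partition the data)
    and every metric is computed per descriptor and per consensus
    configuration at each significance level.  Fully deterministic given
    ``seed``.
    """
    records = list(records)
    if any(not r.valid and r.smiles_std is None for r in records):
        records = standardize_records(records)
    n = len(records)
    y = np.array([r.label for r in records], dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("dataset must contain both classes")

    folds = make_folds(n, k=k, cal_frac=cal_frac, seed=seed, shuffle=shuffle)
    fold_of = np.empty(n, dtype=int)
    for fs in folds:
        fold_of[fs.test_idx] = fs.fold_index

    pvalues: dict[str, np.ndarray] = {}
    for spec_name in featurizer_names:
        featurizer = get_featurizer(spec_name)
        X, row_index, failures = featurize_dataset(records, featurizer)
        row_of = {int(pos): i for i, pos in enumerate(row_index)}
        pv = np.full((n, 2), np.nan)
        for fs in folds:
            tr = [i for i in fs.train_idx if i in row_of]
            ca = [i for i in fs.cal_idx if i in row_of]
            te = [i for i in fs.test_idx if i in row_of]
            if not te:
                continue
            res = fit_icp(
                X[[row_of[i] for i in tr]], y[tr],
                X[[row_of[i] for i in ca]], y[ca],
                spec=featurizer.spec, seed=seed + fs.fold_index,
            )
            pv[te] = res.predict_p(X[[row_of[i] for i in te]])
        pvalues[spec_name] = pv

    rows: list[tuple] = []

    def add(model_name: str, eps: float, metrics: Mapping[str, object]) -> None:
        for metric_name, value in metrics.items():
            rows.append((dataset_name, model_name, eps, metric_name,
                         np.nan if value is None else value))

    for name, pv in pvalues.items():
        ok = ~np.isnan(pv).any(axis=1)
        for eps in epsilons:
            outcomes = prediction_sets(pv[ok], eps)
            add(name, eps, compute_metrics(outcomes, y[ok], pvals=pv[ok]))

    consensus_outcomes: dict[str, dict[float, np.ndarray]] = {}
    for config in consensus_configs:
        members = resolve_model_set(config.model_set, list(pvalues))
        member_pv = [pvalues[m] for m in members]
        ok = ~np.all([np.isnan(pv).any(axis=1) for pv in member_pv], axis=0)
        per_eps: dict[float, np.ndarray] = {}
        for eps in epsilons:
            if config.mode == "pvals":
                stacked = np.stack([pv[ok] for pv in member_pv])
                median = np.nanmedian(stacked, axis=0)
                outcomes = prediction_sets(median, eps)
                metrics = compute_metrics(outcomes, y[ok], pvals=median)
            else:
                idx = np.flatnonzero(ok)
                missing = {
                    m: [j for j, i in enumerate(idx) if np.isnan(pv[i]).any()]
                    for m, pv in enumerate(member_pv)
                }
                per_model = [
                    prediction_sets(np.nan_to_num(pv[ok], nan=1.0), eps)
                    for pv in member_pv
                ]
                outcomes = consensus_cls(per_model, eps, missing=missing)
                metrics = compute_metrics(outcomes, y[ok])
            full = np.empty(n, dtype=object)
            full[ok] = outcomes
            full[~ok] = None
            per_eps[eps] = full
            add(config.name, eps, metrics)
        consensus_outcomes[config.name] = per_eps

    report = pd.DataFrame(rows, columns=["dataset", "model", "epsilon", "metric", "value"])
    return CVResults(
        ids=[r.id for r in records],
        labels=y,
        pvalues=pvalues,
        report=report,
        epsilons=tuple(epsilons),
        seed=seed,
        fold_of=fold_of,
        consensus_outcomes=consensus_outcomes,
    )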