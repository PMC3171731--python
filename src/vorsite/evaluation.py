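"""Performance statistics: R, P, MCC, Q2, F1, ROC/AUC, AUC comparison.

Definitions are the standard ones for binary classification of interface
vs non-interface residues: recall R = TP/(TP+FN), precision
P = TP/(TP+FP), two-class accuracy Q2 = (TP+TN)/N, F1 = 2PR/(P+R), and
the Matthews correlation coefficient, taken as 0 whenever a marginal of
the confusion table is 0.  AUC is the area under the ROC step curve,
identical to the tie-corrected Mann-Whitney rank statistic.

Displayed metric values are truncated (not rounded) to two decimals;
full precision is always kept internally.

Two score sets over the same residues are compared with a paired,
class-stratified bootstrap of the AUC difference (replaces an external
ROC-comparison program; assumption-light and seed-deterministic).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ConsistencyError, EvaluationError
from .structure import ResidueKey


def truncate2(x: float) -> float:
    """Two-decimal truncation used for displayed metric values."""
    return math.floor(x * 100.0 + 1e-9) / 100.0


def f1_from_precision_recall(precision: float, recall: float) -> float:
    if precision + recall <= 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    counts: ConfusionCounts
    recall: float
    precision: float
    mcc: float
    q2: float
    f1: float
    threshold: float
    precision_defined: bool = True
    roc: np.ndarray | None = None  # (fpr, tpr) points
    auc: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "recall": self.recall,
            "precision": self.precision,
            "precision_defined": self.precision_defined,
            "mcc": self.mcc,
            "q2": self.q2,
            "f1": self.f1,
            "auc": self.auc,
            "threshold": self.threshold,
        }

    def display(self) -> dict:
        """Two-decimal truncated view of the headline metrics."""
        out = {}
        for name in ("recall", "precision", "mcc", "q2", "f1"):
            out[name] = truncate2(getattr(self, name))
        if self.auc is not None:
            out["auc"] = truncate2(self.auc)
        return out


def _aligned(
    scores: Mapping[ResidueKey, float], labels: Mapping[ResidueKey, bool]
) -> tuple[np.ndarray, np.ndarray]:
    missing = [k for k in scores if k not in labels]
    if missing:
        raise ConsistencyError(f"scored residues without labels: {missing[:5]}")
    keys = sorted(scores)
    y = np.array([bool(labels[k]) for k in keys], dtype=int)
    s = np.array([float(scores[k]) for k in keys])
    return s, y


def confusion_and_rates(
    scores: Mapping[ResidueKey, float],
    labels: Mapping[ResidueKey, bool],
    threshold: float = 0.5,
) -> EvalReport:
    """Confusion counts and threshold metrics; ROC/AUC when both classes."""
    s, y = _aligned(scores, labels)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)

    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else 0.0
    q2 = (tp + tn) / counts.total if counts.total else 0.0
    f1 = f1_from_precision_recall(precision, recall)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0

    roc = auc = None
    if len(np.unique(y)) == 2:
        roc, auc = roc_auc(scores, labels)
    return EvalReport(
        counts=counts,
        recall=recall,
        precision=precision,
        precision_defined=precision_defined,
        mcc=mcc,
        q2=q2,
        f1=f1,
        threshold=threshold,
        roc=roc,
        auc=auc,
    )


def roc_auc(
    scores: Mapping[ResidueKey, float], labels: Mapping[ResidueKey, bool]
) -> tuple[np.ndarray, float]:
    """ROC step-curve points and AUC (tie-corrected rank formulation)."""
    s, y = _aligned(scores, labels)
    if len(np.unique(y)) < 2:
        raise EvaluationError("both classes required for a ROC curve")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    delta: float  # auc_a - auc_b
    p_value: float
    ci_low: float
    ci_high: float
    n_boot: int


def compare_auc(
    scores_a: Mapping[ResidueKey, float],
    scores_b: Mapping[ResidueKey, float],
    labels: Mapping[ResidueKey, bool],
    n_boot: int = 2000,
    seed: int = 0,
) -> AucComparison:
    """Paired bootstrap test for a difference in AUC.

    Residues are resampled with replacement within each class (keeping
    both classes present in every replicate) and both AUCs are recomputed
    on the same resample; the two-sided p-value tests delta AUC = 0.
    """
    if set(scores_a) != set(scores_b):
        raise ConsistencyError("the two score sets cover different residues")
    keys = sorted(scores_a)
    y = np.array([bool(labels.get(k, False)) for k in keys], dtype=int)
    missing = [k for k in keys if k not in labels]
    if missing:
        raise ConsistencyError(f"scored residues without labels: {missing[:5]}")
    sa = np.array([scores_a[k] for k in keys])
    sb = np.array([scores_b[k] for k in keys])
    if len(np.unique(y)) < 2:
        raise EvaluationError("both classes required to compare AUCs")

    auc_a = float(roc_auc_score(y, sa))
    auc_b = float(roc_auc_score(y, sb))
    delta = auc_a - auc_b

    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        yb = y[idx]
        deltas[b] = roc_auc_score(yb, sa[idx]) - roc_auc_score(yb, sb[idx])
    # two-sided bootstrap p-value for delta = 0
    p = 2.0 * min(np.mean(deltas <= 0.0), np.mean(deltas >= 0.0))
    p = float(min(1.0, max(p, 1.0 / n_boot)))
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return AucComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        delta=delta,
        p_value=p,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# experiment matrix

def _structure_folds(n_structures: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic shuffled fold assignment over structures."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_structures)
    return [order[f::n_folds] for f in range(n_folds)]


def cross_validated_scores(
    structures: Sequence,
    msas: Sequence | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    groups: Sequence[int] | None = None,
    **predictor_params,
) -> tuple[dict[tuple[int, ResidueKey], float], dict[tuple[int, ResidueKey], float], dict[tuple[int, ResidueKey], bool]]:
    """Pooled held-out first/final scores and labels, folds by structure.

    ``groups`` optionally assigns structures to units that must stay in
    one fold (e.g. the two chains of one complex, whose interfaces mirror
    each other); by default every structure is its own unit.  Result keys
    are ``(structure_index, residue_key)`` so identical chain ids in
    different structures never collide.
    """
    from .model import TwoStepInterfacePredictor  # deferred to avoid cycle

    n = len(structures)
    if msas is None:
        msas = [None] * n
    group_ids = list(groups) if groups is not None else list(range(n))
    if len(group_ids) != n:
        raise EvaluationError("groups must align with structures")
    units = sorted(set(group_ids))
    n_folds = min(cv_folds, len(units))
    if n_folds < 2:
        raise EvaluationError("cross-validation needs at least two structure groups")
    first: dict[tuple[int, ResidueKey], float] = {}
    final: dict[tuple[int, ResidueKey], float] = {}
    labels: dict[tuple[int, ResidueKey], bool] = {}
    for fold in _structure_folds(len(units), n_folds, seed):
        test_units = {units[int(i)] for i in fold}
        test_set = {i for i in range(n) if group_ids[i] in test_units}
        train_idx = [i for i in range(n) if i not in test_set]
        model = TwoStepInterfacePredictor(random_state=seed, **predictor_params)
        model.fit(
            [structures[i] for i in train_idx],
            msas=[msas[i] for i in train_idx],
        )
        for i in test_set:
            ss = model.score_structure(structures[i], msa=msas[i])
            for key, s in ss.first_scores().items():
                first[(i, key)] = s
            for key, s in ss.final_scores().items():
                final[(i, key)] = s
                lab = structures[i].get(key).interface_label
                if lab is None:
                    raise EvaluationError(f"unlabelled residue {key}")
                labels[(i, key)] = bool(lab)
    return first, final, labels


def run_experiment_matrix(
    structures: Sequence,
    feature_subsets: Iterable[Iterable[str]],
    env_modes: Iterable[str],
    msas: Sequence | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
    groups: Sequence[int] | None = None,
    **predictor_params,
) -> pd.DataFrame:
    """Cross-validated metrics for every feature-subset x environment cell.

    Cells that cannot be computed from the provided inputs (conservation
    without alignments) are marked unavailable and the run continues.
    """
    rows = []
    for subset_groups, mode in itertools.product(
        [tuple(g) for g in feature_subsets], list(env_modes)
    ):
        label = "+".join(subset_groups)
        cell = {"features": label, "env_mode": mode, "available": True}
        if "c" in subset_groups and msas is None:
            cell.update(
                available=False, auc=np.nan, mcc=np.nan, recall=np.nan,
                precision=np.nan, f1=np.nan,
            )
            rows.append(cell)
            continue
        _, final, labels = cross_validated_scores(
            structures,
            msas=msas,
            cv_folds=cv_folds,
            seed=seed,
            groups=groups,
            feature_groups=subset_groups,
            env_mode=mode,
            **predictor_params,
        )
        report = confusion_and_rates(final, labels, threshold=threshold)
        cell.update(
            auc=report.auc,
            mcc=report.mcc,
            recall=report.recall,
            precision=report.precision,
            f1=report.f1,
        )
        rows.append(cell)
    return pd.DataFrame(rows)


def write_report(report: EvalReport, out_dir: str | Path, stem: str = "eval") -> None:
    """Emit a report as JSON + TSV (+ ROC points when present)."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"{stem}.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    pd.DataFrame([report.to_dict()]).to_csv(out / f"{stem}.tsv", sep="\t", index=False)
    if report.roc is not None:
        np.savetxt(
            out / f"{stem}.roc.tsv",
            report.roc,
            delimiter="\t",
            header="fpr\ttpr",
            comments="",
        )
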