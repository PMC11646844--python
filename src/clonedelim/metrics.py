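"""Per-sequence evaluation of inferred clonal-family partitions.

For each focal sequence x_i, every *other* sequence is classified by
(same/different true family) x (same/different inferred family):

* TP — same true family, same inferred family
* FN — same true family, different inferred family
* FP — different true family, same inferred family
* TN — different true family, different inferred family

Precision, recall, specificity and F1 are computed per focal sequence and
averaged over all evaluated sequences, yielding one value per repertoire.
Inferred singletons can be removed before evaluation (the convention used
throughout the benchmarking, since singletons are disregarded in practice);
sequences a method failed to return can be re-classified as singletons to
keep the id universe comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .partition import Partition


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int


@dataclass
class MetricsReport:
    mean_precision: float
    mean_recall: float
    mean_specificity: float
    mean_f1: float
    n_true_families: int
    n_inferred_families: int
    true_median_size: float
    inferred_median_size: float
    n_sequences_evaluated: int
    empty: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


#: conventions for 0/0 ratios (configurable per call)
DEFAULT_ZERO_CONVENTIONS = {
    "precision": 1.0,  # nothing wrongly merged
    "recall": 1.0,  # true singleton focal: nothing to recover
    "specificity": 1.0,  # nothing from other families present
    "f1": 1.0,
}


def confusion_counts(truth: Partition, inferred: Partition, focal: str) -> ConfusionCounts:
    """Confusion counts for one focal sequence (the focal itself is excluded)."""
    if truth.ids() != inferred.ids():
        raise ValueError("truth and inferred partitions cover different id sets")
    if focal not in truth.assignment:
        raise KeyError(f"focal id {focal!r} not in partitions")
    t_lab = truth.assignment[focal]
    i_lab = inferred.assignment[focal]
    tp = tn = fp = fn = 0
    for sid, t in truth.assignment.items():
        if sid == focal:
            continue
        same_true = t == t_lab
        same_inferred = inferred.assignment[sid] == i_lab
        if same_true and same_inferred:
            tp += 1
        elif same_true:
            fn += 1
        elif same_inferred:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float, convention: float) -> float:
    return num / den if den > 0 else convention


def per_sequence_metrics(
    c: ConfusionCounts, zero_conventions: dict | None = None
) -> tuple[float, float, float, float]:
    """(precision, recall, specificity, f1) for one focal sequence."""
    conv = DEFAULT_ZERO_CONVENTIONS if zero_conventions is None else zero_conventions
    precision = _ratio(c.tp, c.tp + c.fp, conv["precision"])
    recall = _ratio(c.tp, c.tp + c.fn, conv["recall"])
    specificity = _ratio(c.tn, c.tn + c.fp, conv["specificity"])
    f1 = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, conv["f1"])
    return precision, recall, specificity, f1


def remove_singletons(p: Partition) -> Partition:
    """Drop families of size 1; the result covers only the surviving ids."""
    clusters = p.clusters()
    keep = {lab: members for lab, members in clusters.items() if len(members) > 1}
    return Partition.from_clusters(keep)


def classify_missing_as_singletons(inferred: Partition, full_id_set) -> Partition:
    """Ids missing from the inferred partition become their own singleton families."""
    full = set(full_id_set)
    extra = inferred.ids() - full
    if extra:
        raise ValueError(f"inferred partition contains unknown ids: {sorted(extra)[:5]}")
    assignment = dict(inferred.assignment)
    for i, sid in enumerate(sorted(full - inferred.ids())):
        assignment[sid] = f"missing_singleton_{i + 1}"
    return Partition(assignment)


def _metrics_frame(truth: Partition, inferred: Partition) -> pd.DataFrame:
    """Vectorized per-focal confusion counts via label-pair contingency.

    For focal i with true family size a, inferred cluster size b and m ids
    sharing both labels: tp = m - 1, fn = a - m, fp = b - m,
    tn = N - a - b + m.
    """
    ids = sorted(truth.ids())
    t = pd.Series([truth.assignment[i] for i in ids], index=ids)
    g = pd.Series([inferred.assignment[i] for i in ids], index=ids)
    n = len(ids)
    a = t.map(t.value_counts())
    b = g.map(g.value_counts())
    pair = pd.Series(list(zip(t, g)), index=ids)
    m = pair.map(pair.value_counts())
    df = pd.DataFrame({"tp": m - 1, "fn": a - m, "fp": b - m, "tn": n - a - b + m})
    return df


def repertoire_metrics(
    truth: Partition,
    inferred: Partition,
    drop_singletons: bool = True,
    zero_conventions: dict | None = None,
) -> MetricsReport:
    """Average per-sequence metrics over a repertoire.

    With ``drop_singletons``, inferred singleton families are removed and
    both partitions are restricted to the surviving ids, so the averages
    run over a common universe. Family counts and median sizes are taken on
    the (optionally singleton-free) partitions. An evaluation with no
    surviving sequences is flagged ``empty`` (means are NaN, not zero).
    """
    if truth.ids() != inferred.ids():
        raise ValueError(
            "truth and inferred partitions cover different id sets; "
            "use classify_missing_as_singletons first"
        )
    truth_eval, inferred_eval = truth, inferred
    if drop_singletons:
        inferred_eval = remove_singletons(inferred)
        ids = inferred_eval.ids()
        truth_eval = truth.restrict(ids)
    n_eval = len(truth_eval)
    if n_eval == 0:
        return MetricsReport(
            mean_precision=float("nan"),
            mean_recall=float("nan"),
            mean_specificity=float("nan"),
            mean_f1=float("nan"),
            n_true_families=0,
            n_inferred_families=0,
            true_median_size=float("nan"),
            inferred_median_size=float("nan"),
            n_sequences_evaluated=0,
            empty=True,
        )
    conv = DEFAULT_ZERO_CONVENTIONS if zero_conventions is None else zero_conventions
    df = _metrics_frame(truth_eval, inferred_eval)
    precision = np.where(df.tp + df.fp > 0, df.tp / (df.tp + df.fp), conv["precision"])
    recall = np.where(df.tp + df.fn > 0, df.tp / (df.tp + df.fn), conv["recall"])
    specificity = np.where(df.tn + df.fp > 0, df.tn / (df.tn + df.fp), conv["specificity"])
    denom = 2 * df.tp + df.fp + df.fn
    f1 = np.where(denom > 0, 2 * df.tp / denom, conv["f1"])
    return MetricsReport(
        mean_precision=float(precision.mean()),
        mean_recall=float(recall.mean()),
        mean_specificity=float(specificity.mean()),
        mean_f1=float(f1.mean()),
        n_true_families=truth_eval.n_families,
        n_inferred_families=inferred_eval.n_families,
        true_median_size=truth_eval.median_size(),
        inferred_median_size=inferred_eval.median_size(),
        n_sequences_evaluated=n_eval,
    )


def median_size_mse(reports: list[MetricsReport]) -> float:
    """Mean squared error of inferred vs true median family size across repertoires."""
    if not reports:
        raise ValueError("no reports given")
    diffs = [
        (r.inferred_median_size - r.true_median_size) ** 2 for r in reports if not r.empty
    ]
    if not diffs:
        raise ValueError("all reports are empty evaluations")
    return float(np.mean(diffs))
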