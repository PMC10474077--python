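"""Metrics and experiment harnesses.

Per-class sensitivity and specificity are one-vs-rest rates at the argmax
decision; "average" means the unweighted (macro) mean over classes observed
in the test set (a class-frequency-weighted mean is available behind a flag).
The overall score is the micro-average ROC/AUC: every (record, class)
one-vs-rest decision is pooled into a single binary problem before the
threshold sweep, so heavily imbalanced classes do not dominate.

Two harnesses cover the comparisons that matter in a multi-site setting:
Experiment 1 compares each station's individual model with the combined
(federated) model on that
station's own test split; Experiment 2 compares centralized training on the
pooled data with federated training on per-station slices of the same train
partition — under count pooling the two are provably identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from fedbn.federation import StationNode, run_federation
from fedbn.schema import (
    DatasetSchema,
    StationDataset,
    harmonize_schemas,
    observed_schema,
    split_indices,
    split_train_test,
)
from fedbn.tan import TANModel, predict_proba, train_tan

logger = logging.getLogger("fedbn")


@dataclass
class ConfusionMatrix:
    """Observed (rows) x predicted (columns) counts over a fixed class order."""

    classes: tuple[str, ...]
    matrix: np.ndarray

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


@dataclass
class ROCCurve:
    """Micro-average ROC: monotone (FPR, TPR) points from (0,0) to (1,1)."""

    points: list[tuple[float, float]]
    auc: float


@dataclass
class EvaluationReport:
    """One model evaluated on one test set."""

    auc: float
    average_sensitivity: float
    average_specificity: float
    per_class_sensitivity: dict[str, float]
    per_class_specificity: dict[str, float]
    confusion: ConfusionMatrix
    roc: ROCCurve
    n_test: int
    model_id: str = ""
    test_set_id: str = ""
    unobserved_classes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "test_set_id": self.test_set_id,
            "n_test": self.n_test,
            "auc": self.auc,
            "average_sensitivity": self.average_sensitivity,
            "average_specificity": self.average_specificity,
            "per_class_sensitivity": self.per_class_sensitivity,
            "per_class_specificity": self.per_class_specificity,
            "unobserved_classes": list(self.unobserved_classes),
            "confusion": {
                "classes": list(self.confusion.classes),
                "matrix": self.confusion.matrix.tolist(),
            },
        }


def confusion_and_rates(
    observed: list[str],
    predicted: list[str],
    classes: tuple[str, ...],
) -> tuple[ConfusionMatrix, dict[str, float], dict[str, float]]:
    """Confusion matrix plus one-vs-rest sensitivity/specificity per class.

    sensitivity_c = TP_c / (TP_c + FN_c);  specificity_c = TN_c / (TN_c + FP_c).
    A class never observed has undefined sensitivity (NaN) and is excluded
    from downstream averages.
    """
    if not observed:
        raise ValueError("cannot evaluate an empty label vector")
    if len(observed) != len(predicted):
        raise ValueError("observed and predicted must have equal length")
    idx = {c: i for i, c in enumerate(classes)}
    for lab in set(observed) | set(predicted):
        if lab not in idx:
            raise ValueError(f"label {lab!r} not in the declared class order")
    m = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for o, p in zip(observed, predicted):
        m[idx[o], idx[p]] += 1
    n = m.sum()
    sens: dict[str, float] = {}
    spec: dict[str, float] = {}
    for c, i in idx.items():
        tp = m[i, i]
        fn = m[i, :].sum() - tp
        fp = m[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens[c] = float(tp / (tp + fn)) if (tp + fn) > 0 else float("nan")
        spec[c] = float(tn / (tn + fp)) if (tn + fp) > 0 else float("nan")
    return ConfusionMatrix(tuple(classes), m), sens, spec


def micro_average_roc(
    observed: list[str],
    scores: np.ndarray,
    classes: tuple[str, ...],
) -> ROCCurve:
    """Micro-average ROC curve with trapezoidal AUC.

    Every (record, class) pair becomes one binary decision (positive iff the
    record's observed class is that class) scored by the record's posterior
    for that class; thresholds sweep the distinct pooled scores in descending
    order with ties grouped, so a constant score yields the chance diagonal
    (AUC 0.5).
    """
    scores = np.asarray(scores, dtype=float)
    n, C = scores.shape
    if len(observed) != n:
        raise ValueError("scores and observed must align")
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("score rows must sum to 1")
    idx = {c: i for i, c in enumerate(classes)}
    y = np.zeros((n, C), dtype=bool)
    for r, lab in enumerate(observed):
        if lab not in idx:
            raise ValueError(f"label {lab!r} not in the declared class order")
        y[r, idx[lab]] = True
    return binary_roc(y.ravel(), scores.ravel())


def binary_roc(y: np.ndarray, s: np.ndarray) -> ROCCurve:
    """ROC of one pooled binary problem; thresholds at distinct scores, ties grouped.

    Invariant under any strictly increasing transformation of the scores
    (only their ordering enters).
    """
    y = np.asarray(y, dtype=bool)
    s = np.asarray(s, dtype=float)
    P = int(y.sum())
    N = y.size - P
    if P == 0 or N == 0:
        raise ValueError("pooled binarization has no positives or no negatives")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # keep only the last index of each tied-score group
    last_of_group = np.append(np.diff(s_sorted) != 0, True)
    tpr = np.concatenate([[0.0], tp[last_of_group] / P, [1.0]])
    fpr = np.concatenate([[0.0], fp[last_of_group] / N, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return ROCCurve(points, auc)


def _macro(values: dict[str, float], weights: dict[str, float] | None = None) -> float:
    defined = {c: v for c, v in values.items() if not np.isnan(v)}
    if not defined:
        return float("nan")
    if weights is None:
        return float(np.mean(list(defined.values())))
    w = np.array([weights.get(c, 0.0) for c in defined])
    v = np.array(list(defined.values()))
    return float(np.average(v, weights=w)) if w.sum() > 0 else float(np.mean(v))


def conform_dataset(data: StationDataset, schema: DatasetSchema) -> StationDataset:
    """Re-express ``data`` under ``schema``, dropping records with unseen states.

    A test record carrying a state no training record exhibited cannot be
    scored by a model over that state space; such records are dropped with a
    logged count (mirroring the complete-data ingestion contract).
    """
    order = [data.schema.index_of(n) for n in schema.variable_names]
    kept, dropped = [], 0
    for rec in data.records:
        out = tuple(rec[i] for i in order)
        if all(v in spec.states for spec, v in zip(schema.variables, out)):
            kept.append(out)
        else:
            dropped += 1
    if dropped:
        logger.warning(
            "%s: dropped %d test record(s) with states unseen in training",
            data.station_id, dropped,
        )
    return StationDataset(data.station_id, schema, kept, data.provenance, n_rejected=dropped)


def evaluate_model(
    model: TANModel,
    test: StationDataset,
    weighted: bool = False,
    model_id: str = "",
) -> EvaluationReport:
    """Score a model on a test set: confusion, rates, micro-average ROC/AUC.

    The ROC binarization uses the model's full class space; a class in the
    model's space never observed in the test labels contributes negatives
    only (and is excluded from the sensitivity/specificity averages).
    """
    if len(test) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    test = test.with_schema(model.schema) if test.schema is not model.schema else test
    classes = model.schema.class_var.states
    observed = test.class_labels()
    scores = predict_proba(model, test)
    predicted = [classes[int(i)] for i in np.argmax(scores, axis=1)]
    cm, sens, spec = confusion_and_rates(observed, predicted, classes)
    roc = micro_average_roc(observed, scores, classes)
    counts = {c: observed.count(c) for c in classes}
    weights = {c: counts[c] / len(observed) for c in classes} if weighted else None
    unobserved = tuple(c for c in classes if counts[c] == 0)
    if unobserved:
        logger.info("classes never observed in test (excluded from averages): %s", unobserved)
    return EvaluationReport(
        auc=roc.auc,
        average_sensitivity=_macro(sens, weights),
        average_specificity=_macro({c: v for c, v in spec.items() if counts[c] > 0}, weights),
        per_class_sensitivity=sens,
        per_class_specificity=spec,
        confusion=cm,
        roc=roc,
        n_test=len(test),
        model_id=model_id,
        test_set_id=test.station_id,
        unobserved_classes=unobserved,
    )


def run_experiment_1(
    stations: list[StationDataset],
    seed: int = 0,
    fraction: float = 0.8,
    iss: float = 1.0,
    stratify: bool = True,
    combine: str = "pool-stats",
) -> dict[str, dict[str, EvaluationReport]]:
    """Individual vs combined model, evaluated per station.

    Each station gets a seeded (default stratified) train/test split.  The
    individual model is trained on the station's own train partition (over
    the harmonized schema, so its class space matches the combined model's);
    the combined model is trained by federation over all stations' train
    partitions.  Both are evaluated on that station's local test partition.
    """
    if len(stations) < 2:
        raise ValueError("experiment 1 needs at least 2 stations")
    splits = {}
    for k, ds in enumerate(stations):
        if len(ds) < 2:
            logger.warning("station %s too small to split; excluded", ds.station_id)
            continue
        splits[ds.station_id] = split_train_test(
            ds, fraction=fraction, seed=seed + k, stratify=stratify
        )
    combined, _audit = run_federation(
        [StationNode(sid, sp.train) for sid, sp in splits.items()],
        iss=iss,
        combine=combine,
    )
    # individual models share the combined model's harmonized state space, so
    # a station lacking a class still predicts over the full class space
    # (through the Dirichlet prior alone)
    harmonized = combined.schema
    results: dict[str, dict[str, EvaluationReport]] = {}
    for sid, sp in splits.items():
        individual = train_tan(sp.train.with_schema(harmonized), iss=iss)
        test = conform_dataset(sp.test, harmonized)
        if len(test) == 0:
            logger.warning("station %s has no evaluable test records; excluded", sid)
            continue
        results[sid] = {
            "individual": evaluate_model(individual, test, model_id=f"individual:{sid}"),
            "combined": evaluate_model(combined, test, model_id="combined"),
        }
    return results


def run_experiment_2(
    stations: list[StationDataset],
    seed: int = 0,
    fraction: float = 0.8,
    iss: float = 1.0,
    combine: str = "pool-stats",
) -> dict[str, EvaluationReport]:
    """Centralized vs federated training on the identical pooled train partition.

    The pooled dataset gets one unstratified random split.  The centralized
    model trains directly on the pooled train records; the federated model
    trains by federation over the per-station slices of that same partition.
    Under count pooling the two models are mathematically identical, so their
    metric rows coincide exactly — a stronger statement than approximate
    agreement between separately split runs.
    """
    declared = harmonize_schemas([d.schema for d in stations])
    pooled_records = []
    origin = []
    for ds in stations:
        for rec in ds.with_schema(declared).records:
            pooled_records.append(rec)
            origin.append(ds.station_id)
    n = len(pooled_records)
    if n < 5:
        raise ValueError("experiment 2 needs a pooled dataset of at least 5 records")
    train_idx, test_idx = split_indices(n, fraction, seed)
    train = StationDataset("POOLED-TRAIN", declared, [pooled_records[i] for i in train_idx])
    slices = {}
    for i in train_idx:
        slices.setdefault(origin[i], []).append(pooled_records[i])
    nodes = [
        StationNode(sid, StationDataset(sid, declared, recs))
        for sid, recs in slices.items()
    ]
    # both routes see exactly the states observed in the pooled train data:
    # that is what a centralized analyst pooling the raw records would infer,
    # and what the federation handshake harmonizes to
    schema = observed_schema(train)
    centralized = train_tan(train.with_schema(schema), iss=iss)
    federated, _audit = run_federation(nodes, iss=iss, combine=combine)
    test = conform_dataset(
        StationDataset("POOLED-TEST", declared, [pooled_records[i] for i in test_idx]),
        schema,
    )
    return {
        "centralized": evaluate_model(centralized, test, model_id="centralized"),
        "federated": evaluate_model(federated, test.with_schema(federated.schema), model_id="federated"),
    }


def report_table(results: dict, metrics: tuple[str, ...] = ("auc", "average_sensitivity", "average_specificity")) -> str:
    """Render experiment results as a markdown table."""

    def fmt(r: EvaluationReport) -> list[str]:
        return [f"{getattr(r, m):.3f}" for m in metrics]

    lines = []
    first = next(iter(results.values()))
    if isinstance(first, dict):  # experiment 1 layout
        cols = list(first.keys())
        header = ["station"] + [f"{c} {m}" for c in cols for m in metrics]
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))
        for sid, row in results.items():
            cells = [sid]
            for c in cols:
                cells += fmt(row[c])
            lines.append("| " + " | ".join(cells) + " |")
    else:  # experiment 2 layout
        header = ["model"] + list(metrics)
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))
        for mid, rep in results.items():
            lines.append("| " + " | ".join([mid] + fmt(rep)) + " |")
    return "\n".join(lines)


def plot_roc(curves: dict[str, ROCCurve], path) -> None:
    """Optional PNG plot of micro-average ROC curves (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, curve in curves.items():
        xs, ys = zip(*curve.points)
        ax.plot(xs, ys, label=f"{label} (area = {curve.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title("Micro-average ROC")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
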