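"""Histological severity: truth rule, baseline sweep, and classifiers.

Severity ground truth follows the remission rule: a slide is histologically
severe (not in remission) when PEC >= 15 **or** the EoEHSS total exceeds 3.
Two conventions for "EoEHSS total" are supported: ``"separate"`` (default)
sums the eight grade scores and the eight stage scores separately and fires
when either sum exceeds the cut; ``"combined"`` sums all sixteen scores
into one total.

Three classifier families predict severity from the four whole-slide AI
scores (PEC, SEC, PBZ, SBZ): a support vector machine, linear discriminant
analysis, and a multi-layer perceptron.  Training follows a repeated
stratified 80/20 split protocol (default 20 repeats, median reported).
The windowed multi-classifier routes slides whose PEC lies within +-Delta
of the clinical cutoff 15 to a dedicated inner classifier C_in and all
others to C_out,

    C_in  if 15 - Delta <= PEC <= 15 + Delta   (inclusive bounds)
    C_out otherwise,

with each region contributing to the 80/20 split proportionally to its
size.  Delta = 9 reproduces the (6, 24) inner window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "HSS_FEATURES",
    "FEATURES",
    "EvalProtocol",
    "MultiClassifierSpec",
    "ClassificationMetrics",
    "MetricsSummary",
    "severity_truth",
    "severity_truth_row",
    "hss_total_from_row",
    "evaluate",
    "confusion_metrics",
    "baseline_sweep",
    "best_baseline_threshold",
    "make_classifier",
    "train_feature_classifier",
    "train_multi_classifier",
    "sweep_delta",
    "route_window",
    "predict_multi",
]

#: The eight EoEHSS histologic features, each scored 0..3 for grade
#: (severity) and stage (extent): eosinophilic inflammation, basal zone
#: hyperplasia, dilated intercellular spaces, eosinophilic abscess,
#: surface layering, surface epithelial alteration, dyskeratotic
#: epithelial cells, lamina propria fibrosis.
HSS_FEATURES = ("ei", "bzh", "dis", "ea", "sl", "sea", "dec", "lpf")

#: Default classifier feature set: the four whole-slide AI scores.
FEATURES = ("pec", "sec", "pbz", "sbz")


# --------------------------------------------------------------------------
# Ground-truth severity rule
# --------------------------------------------------------------------------

def _hss_sums(row: Mapping) -> tuple[int, int]:
    try:
        g = sum(int(row[f"{f}_grade"]) for f in HSS_FEATURES)
        s = sum(int(row[f"{f}_stage"]) for f in HSS_FEATURES)
    except (KeyError, TypeError) as exc:
        raise ValueError(
            "severity truth requires all 16 EoEHSS grade/stage fields "
            f"({exc}); the truth rule cannot default missing scores"
        ) from exc
    return g, s


def hss_total_from_row(row: Mapping, convention: str = "separate") -> int:
    """The EoEHSS total entering the severity rule.

    Under the ``"separate"`` convention the rule compares the grade sum and
    the stage sum each against the cut, which is equivalent to comparing
    their maximum; that maximum is returned.  ``"combined"`` returns the
    single sum of all sixteen scores.
    """
    g, s = _hss_sums(row)
    if convention == "separate":
        return max(g, s)
    if convention == "combined":
        return g + s
    raise ValueError("convention must be 'separate' or 'combined'")


def severity_truth_row(
    row: Mapping,
    pec_cut: int = 15,
    hss_cut: int = 3,
    convention: str = "separate",
) -> bool:
    """Severity rule on a mapping with ``pec`` and the 16 EoEHSS fields."""
    if "pec" not in row:
        raise ValueError("severity truth requires a 'pec' field")
    total = hss_total_from_row(row, convention)
    return bool(int(row["pec"]) >= pec_cut or total > hss_cut)


def severity_truth(
    record,
    pec_cut: int = 15,
    hss_cut: int = 3,
    convention: str = "separate",
) -> bool:
    """Severity rule: severe iff PEC >= pec_cut or EoEHSS total > hss_cut.

    ``record`` may be a mapping / pandas row with ``pec`` and the sixteen
    ``<feature>_grade`` / ``<feature>_stage`` fields.  The "total > 3"
    comparison is strict: a total of exactly 3 is not severe on its own.
    """
    return severity_truth_row(record, pec_cut=pec_cut, hss_cut=hss_cut, convention=convention)


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion-derived metrics on the severe-positive convention."""

    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def miss_rate(self) -> float:
        return 1.0 - self.sensitivity

    @property
    def false_alarm_rate(self) -> float:
        return 1.0 - self.specificity

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "miss_rate": self.miss_rate,
            "false_alarm_rate": self.false_alarm_rate,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ClassificationMetrics:
    """Metrics from raw confusion counts; one-class inputs yield NaN rates."""
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty evaluation: no records")
    acc = (tp + tn) / total
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return ClassificationMetrics(
        accuracy=acc, sensitivity=sens, specificity=spec, tp=tp, fp=fp, tn=tn, fn=fn
    )


def evaluate(y_true: Sequence, y_pred: Sequence) -> ClassificationMetrics:
    """Evaluate boolean predictions against boolean truth."""
    yt = np.asarray(y_true, dtype=bool)
    yp = np.asarray(y_pred, dtype=bool)
    if yt.shape != yp.shape:
        raise ValueError("truth and prediction lengths differ")
    if yt.size == 0:
        raise ValueError("empty evaluation: no records")
    tp = int(np.count_nonzero(yp & yt))
    fp = int(np.count_nonzero(yp & ~yt))
    tn = int(np.count_nonzero(~yp & ~yt))
    fn = int(np.count_nonzero(~yp & yt))
    return confusion_metrics(tp, fp, tn, fn)


# --------------------------------------------------------------------------
# PEC-threshold baseline
# --------------------------------------------------------------------------

def baseline_sweep(records: pd.DataFrame, thresholds: Sequence[int]) -> pd.DataFrame:
    """Sweep PEC thresholds as a baseline severity classifier.

    For each threshold ``t`` the rule "severe iff PEC >= t" is evaluated
    against the truth labels over all records.  Returns one row per
    threshold with accuracy, sensitivity and specificity; the best
    threshold is the accuracy argmax (ties broken toward the smallest
    threshold, the row order).  Single-class truth leaves the undefined
    rate as NaN without crashing.
    """
    thresholds = list(thresholds)
    rows = []
    if thresholds and len(records) < 2:
        raise ValueError("baseline sweep needs at least 2 records")
    y = records["severe"].to_numpy(dtype=bool) if len(records) else np.array([], bool)
    pec = records["pec"].to_numpy() if len(records) else np.array([])
    if thresholds and (y.all() or (~y).all()):
        warnings.warn("baseline sweep on single-class truth: some metrics undefined")
    for t in thresholds:
        m = evaluate(y, pec >= t)
        rows.append(
            {
                "threshold": t,
                "accuracy": m.accuracy,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
            }
        )
    return pd.DataFrame(rows, columns=["threshold", "accuracy", "sensitivity", "specificity"])


def best_baseline_threshold(sweep: pd.DataFrame) -> tuple[int, float]:
    """Argmax-accuracy threshold of a sweep table; ties -> smallest."""
    if len(sweep) == 0:
        raise ValueError("empty sweep table")
    i = int(np.argmax(sweep["accuracy"].to_numpy()))  # first max = smallest t
    return int(sweep["threshold"].iloc[i]), float(sweep["accuracy"].iloc[i])


# --------------------------------------------------------------------------
# Feature classifiers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalProtocol:
    """Repeated stratified random-split training protocol."""

    train_fraction: float = 0.8
    n_repeats: int = 20
    base_seed: int = 0
    group_by_patient: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @property
    def seeds(self) -> list[int]:
        return [self.base_seed + i for i in range(self.n_repeats)]


@dataclass(frozen=True)
class MetricsSummary:
    """Median (and spread) of repeat metrics under a protocol."""

    median: ClassificationMetrics
    spread: dict
    n_valid_repeats: int
    per_repeat: tuple[ClassificationMetrics, ...] = field(repr=False, default=())

    @property
    def median_accuracy(self) -> float:
        return self.median.accuracy


def _summarize(repeats: list[ClassificationMetrics]) -> MetricsSummary:
    if not repeats:
        raise ValueError("no valid repeats to summarize")
    arr = {
        k: np.array([getattr(m, k) for m in repeats])
        for k in ("accuracy", "sensitivity", "specificity")
    }
    med = {k: float(np.nanmedian(v)) for k, v in arr.items()}
    spread = {k: float(np.nanstd(v)) for k, v in arr.items()}
    totals = {
        k: int(np.median([getattr(m, k) for m in repeats])) for k in ("tp", "fp", "tn", "fn")
    }
    median = ClassificationMetrics(
        accuracy=med["accuracy"],
        sensitivity=med["sensitivity"],
        specificity=med["specificity"],
        **totals,
    )
    return MetricsSummary(
        median=median,
        spread=spread,
        n_valid_repeats=len(repeats),
        per_repeat=tuple(repeats),
    )


def make_classifier(model_kind: str, arch: Sequence[int] = (20, 50, 100), seed: int = 0):
    """Build an untrained classifier pipeline with train-fold scaling.

    ``model_kind`` is one of ``"svm"``, ``"lda"``, ``"mlp"``.  ``arch`` is
    the MLP hidden-layer widths (default 20-50-100).  Features are
    standardized inside the pipeline, so scaling statistics always come
    from the training fold only.
    """
    if model_kind == "svm":
        clf = SVC(random_state=seed)
    elif model_kind == "lda":
        clf = LinearDiscriminantAnalysis()
    elif model_kind == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=tuple(arch), max_iter=300, random_state=seed
        )
    else:
        raise ValueError("model_kind must be 'svm', 'lda' or 'mlp'")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _split_indices(
    records: pd.DataFrame, protocol: EvalProtocol, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One stratified (or patient-grouped) train/test index split."""
    idx = np.arange(len(records))
    y = records["severe"].to_numpy(dtype=bool)
    if protocol.group_by_patient:
        rng = np.random.default_rng(seed)
        patients = records["patient_id"].to_numpy()
        uniq = np.unique(patients)
        perm = rng.permutation(uniq)
        n_train = max(1, int(round(protocol.train_fraction * len(uniq))))
        train_p = set(perm[:n_train])
        train_mask = np.array([p in train_p for p in patients])
        return idx[train_mask], idx[~train_mask]
    return train_test_split(
        idx, train_size=protocol.train_fraction, random_state=seed, stratify=y
    )


def train_feature_classifier(
    records: pd.DataFrame,
    model_kind: str = "mlp",
    arch: Sequence[int] = (20, 50, 100),
    protocol: EvalProtocol = EvalProtocol(),
    features: Sequence[str] = FEATURES,
):
    """Train a severity classifier on the AI scores under the protocol.

    For each repeat seed the records are split stratified 80/20, the model
    is fit on the training fold and evaluated on the held-out fold; the
    summary reports the median (and spread) over repeats.  Repeats whose
    training fold is single-class are skipped with a warning; at least half
    the repeats must remain valid.  The returned model handle is refit on
    all records with the first repeat seed.
    """
    features = list(features)
    X = records[features].to_numpy(dtype=float)
    y = records["severe"].to_numpy(dtype=bool)
    repeats: list[ClassificationMetrics] = []
    for seed in protocol.seeds:
        tr, te = _split_indices(records, protocol, seed)
        if len(np.unique(y[tr])) < 2 or len(te) == 0:
            warnings.warn(f"repeat seed {seed}: degenerate training fold, skipped")
            continue
        model = make_classifier(model_kind, arch, seed)
        model.fit(X[tr], y[tr])
        repeats.append(evaluate(y[te], model.predict(X[te])))
    if len(repeats) < (protocol.n_repeats + 1) // 2:
        raise ValueError(
            f"only {len(repeats)}/{protocol.n_repeats} repeats had a valid "
            "training fold; cohort too degenerate to train"
        )
    summary = _summarize(repeats)
    final = make_classifier(model_kind, arch, protocol.seeds[0])
    final.fit(X, y)
    return final, summary


# --------------------------------------------------------------------------
# Windowed multi-classifier
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MultiClassifierSpec:
    """The windowed multi-classifier: C_in inside PEC in [center - delta,
    center + delta] (inclusive), C_out elsewhere."""

    delta: int = 9
    center: int = 15
    model_kind_in: str = "mlp"
    model_kind_out: str = "mlp"
    arch_in: tuple[int, ...] = (100, 20, 100)
    arch_out: tuple[int, ...] = (100, 20, 100)
    features: tuple[str, ...] = FEATURES

    def __post_init__(self) -> None:
        if not 1 <= self.delta <= 12:
            raise ValueError("delta must lie in [1, 12]")


def route_window(pec, center: int = 15, delta: int = 9) -> np.ndarray:
    """Boolean routing mask: True -> C_in (inclusive window), False -> C_out.

    Every record is routed to exactly one region for every delta (the
    partition is exhaustive and disjoint by construction).
    """
    pec = np.asarray(pec)
    return (pec >= center - delta) & (pec <= center + delta)


def predict_multi(
    records: pd.DataFrame,
    model_in,
    model_out,
    delta: int,
    center: int = 15,
    features: Sequence[str] = FEATURES,
) -> np.ndarray:
    """Predict with the windowed pair: route each record, apply its model."""
    X = records[list(features)].to_numpy(dtype=float)
    inside = route_window(records["pec"].to_numpy(), center, delta)
    pred = np.zeros(len(records), dtype=bool)
    if inside.any():
        pred[inside] = np.asarray(model_in.predict(X[inside]), dtype=bool)
    if (~inside).any():
        pred[~inside] = np.asarray(model_out.predict(X[~inside]), dtype=bool)
    return pred


def train_multi_classifier(
    records: pd.DataFrame,
    spec: MultiClassifierSpec = MultiClassifierSpec(),
    protocol: EvalProtocol = EvalProtocol(),
):
    """Train the windowed multi-classifier pair under the protocol.

    Each repeat splits *each region* stratified 80/20 so both regions
    contribute to training and validation proportionally to their size;
    the two region models are fit on their region's training fold, and the
    combined held-out predictions are evaluated together.  Raises when a
    region is empty for the chosen delta.  Returns
    ``((model_in, model_out), summary)`` with the final pair refit on all
    records.
    """
    inside = route_window(records["pec"].to_numpy(), spec.center, spec.delta)
    if not inside.any() or inside.all():
        raise ValueError(
            f"delta={spec.delta} leaves a region empty "
            f"({int(inside.sum())} inside / {int((~inside).sum())} outside)"
        )
    rec_in = records[inside].reset_index(drop=True)
    rec_out = records[~inside].reset_index(drop=True)
    X_in = rec_in[list(spec.features)].to_numpy(dtype=float)
    X_out = rec_out[list(spec.features)].to_numpy(dtype=float)
    y_in = rec_in["severe"].to_numpy(dtype=bool)
    y_out = rec_out["severe"].to_numpy(dtype=bool)

    def split_region(rec: pd.DataFrame, y: np.ndarray, seed: int):
        idx = np.arange(len(rec))
        if len(rec) < 5 or len(np.unique(y)) < 2:
            # tiny or single-class region: plain random split
            rng = np.random.default_rng(seed)
            perm = rng.permutation(idx)
            n_tr = max(1, int(round(protocol.train_fraction * len(idx))))
            n_tr = min(n_tr, len(idx) - 1) if len(idx) > 1 else n_tr
            return perm[:n_tr], perm[n_tr:]
        return train_test_split(
            idx, train_size=protocol.train_fraction, random_state=seed, stratify=y
        )

    repeats: list[ClassificationMetrics] = []
    for seed in protocol.seeds:
        tr_i, te_i = split_region(rec_in, y_in, seed)
        tr_o, te_o = split_region(rec_out, y_out, seed)
        if len(np.unique(y_in[tr_i])) < 2 or len(np.unique(y_out[tr_o])) < 2:
            warnings.warn(f"repeat seed {seed}: degenerate region training fold, skipped")
            continue
        m_in = make_classifier(spec.model_kind_in, spec.arch_in, seed)
        m_out = make_classifier(spec.model_kind_out, spec.arch_out, seed)
        m_in.fit(X_in[tr_i], y_in[tr_i])
        m_out.fit(X_out[tr_o], y_out[tr_o])
        y_true = np.concatenate([y_in[te_i], y_out[te_o]])
        y_pred = np.concatenate(
            [
                np.asarray(m_in.predict(X_in[te_i]), dtype=bool) if len(te_i) else np.array([], bool),
                np.asarray(m_out.predict(X_out[te_o]), dtype=bool) if len(te_o) else np.array([], bool),
            ]
        )
        repeats.append(evaluate(y_true, y_pred))
    if len(repeats) < (protocol.n_repeats + 1) // 2:
        raise ValueError(
            f"only {len(repeats)}/{protocol.n_repeats} repeats valid for "
            f"delta={spec.delta}"
        )
    summary = _summarize(repeats)
    final_in = make_classifier(spec.model_kind_in, spec.arch_in, protocol.seeds[0])
    final_out = make_classifier(spec.model_kind_out, spec.arch_out, protocol.seeds[0])
    final_in.fit(X_in, y_in)
    final_out.fit(X_out, y_out)
    return (final_in, final_out), summary


def sweep_delta(
    records: pd.DataFrame,
    deltas: Sequence[int] = range(1, 13),
    spec: MultiClassifierSpec = MultiClassifierSpec(),
    protocol: EvalProtocol = EvalProtocol(),
) -> tuple[int, dict[int, MetricsSummary]]:
    """Sweep the window half-width and pick the median-accuracy argmax.

    Deltas whose window leaves a region empty (or too degenerate to train)
    are skipped.  Ties break toward the smallest delta.
    """
    results: dict[int, MetricsSummary] = {}
    for d in deltas:
        try:
            _, summary = train_multi_classifier(
                records,
                MultiClassifierSpec(
                    delta=d,
                    center=spec.center,
                    model_kind_in=spec.model_kind_in,
                    model_kind_out=spec.model_kind_out,
                    arch_in=spec.arch_in,
                    arch_out=spec.arch_out,
                    features=spec.features,
                ),
                protocol,
            )
        except ValueError:
            continue
        results[d] = summary
    if not results:
        raise ValueError("no delta admitted a trainable two-region partition")
    best = max(sorted(results), key=lambda d: results[d].median_accuracy)
    return best, results
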