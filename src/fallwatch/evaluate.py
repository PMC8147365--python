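"""Point-level evaluation: confusion counts, metrics, and event-level CV.

The binary collapse follows the platform's alarm semantics: transition
and falling samples form the positive class (they should raise an
alarm), normal motion the negative class.  Metrics are

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)

with zero denominators flagged as undefined rather than silently zeroed.
Cross-validation splits by event (never by point): the normalization and
the fall map are refitted on each training fold, so no test-point
statistic leaks into training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import fall_model, fusion
from .errors import ParameterError

POSITIVE_STAGES = frozenset({"transition", "fall"})


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)

    def to_dict(self) -> dict:
        return {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN}


def confusion(predicted, truth) -> ConfusionCounts:
    """Binary confusion counts over aligned state/stage sequences."""
    predicted = np.asarray(predicted, dtype=str)
    truth = np.asarray(truth, dtype=str)
    if predicted.shape != truth.shape:
        raise ParameterError("predicted and true sequences differ in length")
    if predicted.size == 0:
        warnings.warn("empty input: all confusion counts are zero",
                      stacklevel=2)
        return ConfusionCounts()
    pred_pos = np.isin(predicted, list(POSITIVE_STAGES))
    true_pos = np.isin(truth, list(POSITIVE_STAGES))
    return ConfusionCounts(
        TP=int(np.sum(pred_pos & true_pos)),
        TN=int(np.sum(~pred_pos & ~true_pos)),
        FP=int(np.sum(pred_pos & ~true_pos)),
        FN=int(np.sum(~pred_pos & true_pos)),
    )


@dataclass
class MetricReport:
    """Accuracy / sensitivity / precision with undefined-metric flags."""

    accuracy: float | None
    sensitivity: float | None
    precision: float | None
    counts: ConfusionCounts
    undefined: list[str] = field(default_factory=list)
    per_fold: list["MetricReport"] = field(default_factory=list)
    macro: dict | None = None

    def rounded(self, ndigits: int = 2) -> dict:
        return {k: (None if v is None else round(v, ndigits))
                for k, v in [("accuracy", self.accuracy),
                             ("sensitivity", self.sensitivity),
                             ("precision", self.precision)]}

    def to_dict(self) -> dict:
        d = {"counts": self.counts.to_dict(),
             "accuracy": self.accuracy,
             "sensitivity": self.sensitivity,
             "precision": self.precision,
             "undefined": list(self.undefined),
             "rounded": self.rounded()}
        if self.per_fold:
            d["per_fold"] = [f.to_dict() for f in self.per_fold]
        if self.macro is not None:
            d["macro"] = self.macro
        return d


def metrics(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity and precision from confusion counts."""
    undefined = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    acc = ratio(counts.TP + counts.TN, counts.n, "accuracy")
    sens = ratio(counts.TP, counts.TP + counts.FN, "sensitivity")
    prec = ratio(counts.TP, counts.TP + counts.FP, "precision")
    return MetricReport(accuracy=acc, sensitivity=sens, precision=prec,
                        counts=counts, undefined=undefined)


def _fold_assignments(n_events: int, k: int, rng: np.random.Generator,
                      ) -> list[np.ndarray]:
    order = rng.permutation(n_events)
    return [np.sort(part) for part in np.array_split(order, k)]


def _run_fold(train_events, test_events, seed: int, projection,
              K_max: int, eps: float, sd_multiplier: float,
              compute_boundary: bool, grid_resolution: int):
    train_feats = fusion.feature_matrix(train_events)
    starts = np.stack([ev[list(fusion.FEATURE_NAMES)].to_numpy(dtype=float)[0]
                       for ev in train_events])
    fmap = fall_model.build_fall_map(
        train_feats, projection=projection, seed=seed,
        K_max=K_max, eps=eps, sd_multiplier=sd_multiplier,
        compute_boundary=compute_boundary, grid_resolution=grid_resolution,
        event_start_features=starts)

    counts = ConfusionCounts()
    event_results = []
    for ev in test_events:
        feats = ev[list(fusion.FEATURE_NAMES)].to_numpy(dtype=float)
        pred = fall_model.classify_features(fmap, feats)
        counts = counts + confusion(pred, ev["stage"].to_numpy())
        truth = ev["stage"].to_numpy()
        onset_idx = np.flatnonzero(truth == "fall")
        event_results.append({
            "times": ev["t"].to_numpy(dtype=float),
            "classified": pred,
            "fall_onset_t": (float(ev["t"].iloc[onset_idx[0]])
                             if onset_idx.size else None),
        })
    return counts, event_results, fmap


@dataclass
class CVReport:
    """Cross-validation result: pooled + per-fold metrics, lead times."""

    pooled: MetricReport
    lead_times: fall_model.LeadTimeReport
    fold_events: list[np.ndarray]

    def to_dict(self) -> dict:
        return {
            "pooled": self.pooled.to_dict(),
            "lead_time_mean_s": self.lead_times.mean,
            "lead_times_s": self.lead_times.per_event,
            "n_late_alarms": self.lead_times.n_late,
            "n_no_alarm": self.lead_times.n_no_alarm,
            "fold_events": [f.tolist() for f in self.fold_events],
        }


def kfold_cv(events: list, k: int = 10, seed: int = 0,
             projection=fall_model.DEFAULT_PROJECTION, K_max: int = 6,
             eps: float = 0.05,
             sd_multiplier: float = fall_model.SD_MULTIPLIER,
             repeated_cv: bool = False, repetitions: int = 10,
             test_events_per_rep: int = 10,
             compute_boundary: bool = False,
             grid_resolution: int = 80) -> CVReport:
    """Event-stratified cross-validation of the full pipeline.

    ``events`` are windowed per-event trajectories (see
    :func:`fallwatch.fusion.dataset_trajectories`).  Default: a k-fold
    partition of events, each tested exactly once.  With ``repeated_cv``,
    ``repetitions`` rounds each draw ``test_events_per_rep`` random test
    events and train on the rest (events may repeat across rounds).
    Pooled metrics micro-average the counts; a macro average over folds
    is attached for reference.
    """
    n = len(events)
    if repeated_cv:
        if test_events_per_rep >= n:
            raise ParameterError("test_events_per_rep must be < n_events")
        rng = np.random.default_rng(seed)
        folds = [np.sort(rng.choice(n, size=test_events_per_rep,
                                    replace=False))
                 for _ in range(repetitions)]
    else:
        if k > n:
            raise ParameterError(f"k={k} exceeds the {n} available events")
        folds = _fold_assignments(n, k, np.random.default_rng(seed))

    pooled = ConfusionCounts()
    fold_reports, all_event_results = [], []
    for test_idx in folds:
        test_set = set(int(i) for i in test_idx)
        train = [ev for i, ev in enumerate(events) if i not in test_set]
        test = [events[i] for i in test_idx]
        counts, ev_results, _ = _run_fold(
            train, test, seed, projection, K_max, eps, sd_multiplier,
            compute_boundary, grid_resolution)
        pooled = pooled + counts
        fold_reports.append(metrics(counts))
        all_event_results.extend(ev_results)

    report = metrics(pooled)
    report.per_fold = fold_reports
    defined = lambda vals: [v for v in vals if v is not None]
    report.macro = {
        name: (float(np.mean(vs)) if (vs := defined(
            [getattr(f, name) for f in fold_reports])) else None)
        for name in ("accuracy", "sensitivity", "precision")
    }
    leads = fall_model.alarm_lead_time(all_event_results)
    return CVReport(pooled=report, lead_times=leads, fold_events=folds)
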