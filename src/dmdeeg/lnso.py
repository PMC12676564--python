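"""Subject-wise leave-N-subjects-out (LNSO) evaluation.

The full protocol builds five independent "batches"; each batch splits every
diagnostic group into five near-equal partitions after a seeded shuffle, and
each of the five folds holds out one partition per group (so every subject is
tested exactly once per batch, and all of a test subject's epochs are excluded
from training).  Model learning is repeated five times per fold; one task is
therefore 5 x 5 x 5 training runs.

Metrics come from the cumulative confusion matrix over all scored test epochs;
"Total" rows are unweighted macro averages of the per-class values.  Batch-level
accuracies feed a t-based 95% confidence interval, and the delta-band ablation
is assessed with a paired t-test over (batch, fold) accuracy pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

#: binary tasks: class 0 is the dementia-side class, class 1 the control class
TASKS = {
    "AD/CN": {"AD": "AD", "CN": "CN"},
    "FTD/CN": {"FTD": "FTD", "CN": "CN"},
    "(AD+FTD)/CN": {"AD": "AD+FTD", "FTD": "AD+FTD", "CN": "CN"},
}

#: epoch indices kept for the over-represented side of the combined task
BALANCED_EPOCH_INDICES = (0, 2, 4, 6, 8)


def round2(x: float) -> float:
    """Round to two decimals, half away from zero (table convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def task_classes(task: str):
    """(group -> class name) mapping and ordered class-name list for a task."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {list(TASKS)}")
    mapping = TASKS[task]
    classes = []
    for cls in mapping.values():
        if cls not in classes:
            classes.append(cls)
    return mapping, classes


@dataclass
class LNSOPlan:
    """Partition schedule: ``batches[b][group]`` is a list of ``n_partitions``
    subject-id lists; fold f of batch b holds out partition f of every group."""

    batches: list
    n_partitions: int
    seed: int

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    def fold_split(self, batch: int, fold: int):
        """(train_ids, test_ids) for one fold; subject-disjoint by construction."""
        parts = self.batches[batch]
        test, train = [], []
        for group_parts in parts.values():
            for i, part in enumerate(group_parts):
                (test if i == fold else train).extend(part)
        assert not set(train) & set(test), "subject leakage between train and test"
        return train, test


def make_lnso_plan(groups: Mapping[str, str], n_partitions: int = 5,
                   n_batches: int = 5, seed: int = 0) -> LNSOPlan:
    """Build the batch/partition schedule from ``{subject_id: group}``.

    Each batch independently shuffles every group's subjects (seeded from the
    master seed) and deals them into ``n_partitions`` near-equal parts, with
    remainder subjects going to the earliest partitions.
    """
    by_group: dict = {}
    for sid, grp in groups.items():
        by_group.setdefault(grp, []).append(sid)
    for grp, sids in by_group.items():
        if len(sids) < n_partitions:
            raise ValueError(
                f"group {grp} has {len(sids)} subjects; need >= {n_partitions}")
    rng = np.random.default_rng(seed)
    batches = []
    for _b in range(n_batches):
        parts = {}
        for grp in sorted(by_group):
            sids = sorted(by_group[grp])
            order = rng.permutation(len(sids))
            shuffled = [sids[i] for i in order]
            base, rem = divmod(len(shuffled), n_partitions)
            sizes = [base + (1 if i < rem else 0) for i in range(n_partitions)]
            out, pos = [], 0
            for sz in sizes:
                out.append(shuffled[pos:pos + sz])
                pos += sz
            parts[grp] = out
        batches.append(parts)
    return LNSOPlan(batches, n_partitions, seed)


def balance_epochs(features: Mapping[str, dict], task: str) -> dict:
    """Apply the class-balancing rule to a feature set.

    ``features`` maps subject_id to ``{"group": ..., "tensors": [(epoch_index,
    tensor), ...]}``.  For the combined (AD+FTD)/CN task, AD and FTD subjects
    keep only epochs 0, 2, 4, 6, 8 (halving the majority side deterministically
    while spreading retained epochs over the recording); other tasks pass
    through unchanged.
    """
    mapping, _ = task_classes(task)
    if task != "(AD+FTD)/CN":
        return dict(features)
    out = {}
    for sid, entry in features.items():
        if entry["group"] in ("AD", "FTD"):
            kept = [(i, t) for i, t in entry["tensors"]
                    if i in BALANCED_EPOCH_INDICES]
            out[sid] = {**entry, "tensors": kept}
        else:
            out[sid] = entry
    return out


def run_protocol(plan: LNSOPlan, features: Mapping[str, dict], task: str,
                 model_cfg=None, train_cfg=None, n_repetitions: int = 5,
                 batches: Sequence[int] | None = None,
                 folds: Sequence[int] | None = None) -> list:
    """Train/evaluate the CNN over the planned batches, folds, and repetitions.

    ``features`` is keyed by subject_id as in :func:`balance_epochs` (call that
    first for the combined task).  Subjects whose group is outside the task are
    ignored; planned subjects with no feature tensors abort before any
    training.  Returns one prediction record per scored test epoch per run:
    dicts with batch, fold, repetition, subject_id, epoch_index, y_true, y_pred
    and class probabilities.
    """
    from .nn import CNN3D, ModelConfig, TrainConfig

    mapping, classes = task_classes(task)
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    batches = list(range(plan.n_batches)) if batches is None else list(batches)
    folds = list(range(plan.n_partitions)) if folds is None else list(folds)

    in_task = {sid for sid, entry in features.items()
               if entry["group"] in mapping}
    planned = set()
    for b in batches:
        for grp, parts in plan.batches[b].items():
            if grp in mapping:
                planned.update(sid for part in parts for sid in part)
    missing = sorted(planned - in_task) + sorted(
        sid for sid in planned & in_task if not features[sid]["tensors"])
    if missing:
        raise ValueError(f"missing features for planned subject(s): {missing}")

    def xy(sids):
        X, y, info = [], [], []
        for sid in sids:
            if sid not in in_task:
                continue
            cls = classes.index(mapping[features[sid]["group"]])
            for ep, tensor in features[sid]["tensors"]:
                X.append(tensor)
                y.append(cls)
                info.append((sid, ep))
        return np.stack(X), np.array(y), info

    records = []
    master = np.random.default_rng(train_cfg.seed)
    run_seeds = master.integers(2 ** 31, size=(plan.n_batches,
                                               plan.n_partitions,
                                               n_repetitions))
    for b in batches:
        for f in folds:
            train_ids, test_ids = plan.fold_split(b, f)
            assert not set(train_ids) & set(test_ids)
            Xtr, ytr, _ = xy(train_ids)
            Xte, yte, te_info = xy(test_ids)
            for rep in range(n_repetitions):
                seed = int(run_seeds[b, f, rep])
                model = CNN3D(model_cfg, seed=seed)
                cfg = TrainConfig(max_epochs=train_cfg.max_epochs,
                                  batch_size=train_cfg.batch_size,
                                  learning_rate=train_cfg.learning_rate,
                                  seed=seed)
                model.fit(Xtr, ytr, cfg)
                probs = model.predict_proba(Xte)
                preds = probs.argmax(axis=1)
                for (sid, ep), yt, yp, pr in zip(te_info, yte, preds, probs):
                    records.append({
                        "task": task, "batch": b, "fold": f, "repetition": rep,
                        "subject_id": sid, "epoch_index": ep,
                        "y_true": int(yt), "y_pred": int(yp),
                        "probs": pr.tolist(),
                    })
    return records


@dataclass
class MetricsReport:
    """Cumulative-confusion metrics for one task (percentages, two decimals)."""

    class_names: list
    confusion: np.ndarray            # rows: true class, cols: predicted
    accuracy: float
    per_class: dict                  # metric -> {class: value}
    totals: dict                     # metric -> unweighted macro average
    batch_accuracies: dict = field(default_factory=dict)
    ci: tuple | None = None          # (mean, std, moe, lower, upper)


def macro_total(per_class_values: Sequence[float]) -> float:
    """Unweighted macro average of per-class percentages, in exact decimal
    arithmetic with table rounding (so printed cells reproduce exactly)."""
    vals = [Decimal(repr(float(v))) for v in per_class_values]
    mean = sum(vals) / len(vals)
    return float(mean.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def aggregate_metrics(records: Sequence[dict], class_names=None) -> MetricsReport:
    """Cumulative confusion matrix and derived metrics over all scored epochs.

    Per-class precision/recall/F1 come from the pooled confusion matrix;
    "Total" values are unweighted macro averages; per-batch accuracy is
    epoch-weighted (cumulative over that batch's scored samples).  A class with
    no scored test sample yields NaN for its undefined metrics.
    """
    if not records:
        raise ValueError("no prediction records to aggregate")
    if class_names is None:
        _, class_names = task_classes(records[0]["task"])
    k = len(class_names)
    conf = np.zeros((k, k), dtype=np.int64)
    for r in records:
        conf[r["y_true"], r["y_pred"]] += 1
    total = conf.sum()
    accuracy = 100.0 * conf.trace() / total
    per_class = {"precision": {}, "recall": {}, "f1": {}}
    for i, cls in enumerate(class_names):
        tp = conf[i, i]
        pred_i, true_i = conf[:, i].sum(), conf[i, :].sum()
        prec = 100.0 * tp / pred_i if pred_i else np.nan
        rec = 100.0 * tp / true_i if true_i else np.nan
        f1 = (2 * prec * rec / (prec + rec)
              if np.isfinite(prec) and np.isfinite(rec) and (prec + rec) > 0
              else np.nan)
        per_class["precision"][cls] = round2(prec) if np.isfinite(prec) else np.nan
        per_class["recall"][cls] = round2(rec) if np.isfinite(rec) else np.nan
        per_class["f1"][cls] = round2(f1) if np.isfinite(f1) else np.nan
    totals = {m: macro_total(list(v.values()))
              if all(np.isfinite(list(v.values()))) else np.nan
              for m, v in per_class.items()}
    batch_acc = {}
    for b in sorted({r["batch"] for r in records}):
        rows = [r for r in records if r["batch"] == b]
        batch_acc[b] = round2(
            100.0 * sum(r["y_true"] == r["y_pred"] for r in rows) / len(rows))
    ci = confidence_interval(list(batch_acc.values())) if len(batch_acc) >= 2 else None
    return MetricsReport(list(class_names), conf, round2(accuracy),
                         per_class, totals, batch_acc, ci)


def confidence_interval(values: Sequence[float]):
    """t-based 95% CI of a small sample of batch accuracies.

    Returns ``(mean, sample std, margin of error, lower, upper)`` with
    ``MoE = t_{0.975, n-1} * std / sqrt(n)``.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    mean = values.mean()
    std = values.std(ddof=1)
    moe = scipy.stats.t.ppf(0.975, n - 1) * std / np.sqrt(n)
    return mean, std, moe, mean - moe, mean + moe


def paired_ttest(acc_a: Sequence[float], acc_b: Sequence[float]):
    """Two-sided paired t-test with Cohen's d on fold-level accuracy pairs.

    Pairs are matched by (batch, fold); with the full 5x5 protocol the test has
    24 degrees of freedom.  ``d = mean(diff) / std(diff, ddof=1)``; for
    zero-variance differences t and d are 0 by convention.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired accuracy vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        return 0.0, n - 1, 1.0, 0.0
    t, p = scipy.stats.ttest_rel(a, b)
    d = diff.mean() / sd
    return float(t), n - 1, float(p), float(d)
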