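"""Cross-validated evaluation: K-fold CV, confusion-matrix metrics,
accuracy-vs-PC-count curves with plateau selection, sub-range analysis,
and class-mean difference spectra.

Fold confusion counts are summed over folds before metrics are computed;
the reported dispersion is the standard deviation of per-fold accuracies.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import BinaryTask, lda_fit, lda_predict, pca_fit, pca_project
from .preprocess import cut_to_range
from .spectra_io import CLASS_LABELS, SITES, DatabaseEntry

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "CVConfig",
    "PCCurve",
    "SubrangeSpec",
    "DEFAULT_SUBRANGES",
    "CVResult",
    "compute_metrics",
    "kfold_split",
    "run_cv",
    "accuracy_vs_pcs",
    "select_n_pcs",
    "subrange_analysis",
    "difference_spectra",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fn + other.fn,
            self.fp + other.fp,
            self.tn + other.tn,
        )


@dataclass
class Metrics:
    """ACC/SE/SP/PPV/NPV in percent; None marks an undefined (0-denominator)
    value; acc_std is the fold-wise standard deviation of accuracy."""

    acc: float
    se: float | None
    sp: float | None
    ppv: float | None
    npv: float | None
    acc_std: float | None = None


def _ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """ACC=(TP+TN)/total, SE=TP/(TP+FN), SP=TN/(TN+FP), PPV=TP/(TP+FP),
    NPV=TN/(TN+FN); each as a percentage; undefined denominators -> None."""
    if cm.total == 0:
        raise ValueError("all-zero confusion matrix")
    return Metrics(
        acc=100.0 * (cm.tp + cm.tn) / cm.total,
        se=_ratio(cm.tp, cm.tp + cm.fn),
        sp=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
    )


@dataclass(frozen=True)
class CVConfig:
    k: int = 5
    n_repeats: int = 1
    seed: int = 0
    stratified: bool = True
    group_by_cell: bool = True

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def kfold_split(entries, config: CVConfig, repeat: int = 0) -> list:
    """Partition entry indices into k disjoint folds.

    ``entries`` is a sequence of (cell_id, label) pairs (extra trailing
    elements, e.g. a DatabaseEntry's spectrum, are ignored).  Entries
    sharing a cell_id stay in one fold when ``group_by_cell``; folds are
    stratified by label so per-class sizes differ by at most 1.  The
    shuffle is seeded: identical (seed, repeat) -> identical folds.
    """
    pairs = [(e[0], e[1]) for e in entries]
    rng = np.random.default_rng((config.seed, repeat))
    if config.group_by_cell:
        groups: dict = {}
        for i, (cid, lab) in enumerate(pairs):
            groups.setdefault(cid, (lab, []))[1].append(i)
        units = [(lab, idxs) for lab, idxs in groups.values()]
    else:
        units = [(lab, [i]) for i, (_, lab) in enumerate(pairs)]
    folds = [[] for _ in range(config.k)]
    if config.stratified:
        strata: dict = {}
        for lab, idxs in units:
            strata.setdefault(lab, []).append(idxs)
        offset = 0
        for lab in sorted(strata, key=str):
            stratum = strata[lab]
            if len(stratum) < config.k:
                raise ValueError(
                    f"class {lab!r} has {len(stratum)} group(s); needs >= "
                    f"k={config.k} for stratified folds"
                )
            perm = rng.permutation(len(stratum))
            for j, u in enumerate(perm):
                folds[(j + offset) % config.k].extend(stratum[u])
            offset += len(stratum) % config.k  # balance remainders across folds
    else:
        perm = rng.permutation(len(units))
        for j, u in enumerate(perm):
            folds[j % config.k].extend(units[u][1])
    return [sorted(f) for f in folds]


def fold_hash(folds) -> str:
    blob = ";".join(",".join(map(str, f)) for f in folds)
    return hashlib.sha1(blob.encode()).hexdigest()[:16]


@dataclass
class CVResult:
    confusion: ConfusionMatrix
    metrics: Metrics
    fold_accuracies: np.ndarray
    fold_hash: str
    n_pcs: int
    fold_confusions: list = field(default_factory=list)


def _task_arrays(entries, task: BinaryTask):
    """Filter database entries to the task's classes; return X, y, ids."""
    X, y, ids = [], [], []
    excluded = 0
    for e in entries:
        m = task.membership(e.class_label)
        if m is None:
            excluded += 1
            continue
        X.append(e.spectrum.intensities)
        y.append(m)
        ids.append(e.cell_id)
    if not X:
        raise ValueError(f"no entries match task {task.task_id!r}")
    return np.asarray(X), np.asarray(y), ids, excluded


def _confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def run_cv(entries, task: BinaryTask, n_pcs: int,
           cv: CVConfig | None = None, regularization: float | None = None,
           folds: list | None = None) -> CVResult:
    """Grouped stratified K-fold CV of the PCA->LDA classifier.

    Per fold: PCA is fit on the training spectra only, train and test are
    projected onto the first ``n_pcs`` components, LDA is fit on the train
    features and evaluated on the test fold.  Confusion counts are summed
    over folds; ``acc_std`` is the standard deviation (ddof=1) of the
    per-fold accuracies.
    """
    cv = cv or CVConfig()
    X, y, ids, _ = _task_arrays(entries, task)
    if folds is None:
        folds = kfold_split(list(zip(ids, y)), cv)
    total = ConfusionMatrix()
    fold_accs = []
    fold_cms = []
    for test_idx in folds:
        test = np.asarray(test_idx, dtype=int)
        train = np.setdiff1d(np.arange(len(y)), test)
        basis = pca_fit(X[train])
        Ftr = pca_project(basis, X[train], n_pcs)
        Fte = pca_project(basis, X[test], n_pcs)
        model = lda_fit(Ftr, y[train], regularization=regularization)
        pred, _ = lda_predict(model, Fte)
        cm = _confusion_from_predictions(y[test], pred)
        fold_cms.append(cm)
        total = total + cm
        fold_accs.append(100.0 * (cm.tp + cm.tn) / cm.total)
    fold_accs = np.asarray(fold_accs)
    metrics = compute_metrics(total)
    metrics.acc_std = float(np.std(fold_accs, ddof=1)) if len(fold_accs) > 1 else 0.0
    return CVResult(total, metrics, fold_accs, fold_hash(folds), n_pcs, fold_cms)


@dataclass
class PCCurve:
    """Pooled CV accuracy (percent) as a function of the PC count.

    ``mean_accuracy[i]`` is the accuracy from fold-summed confusion counts
    at ``n_pcs_values[i]``; ``std`` is the fold-wise accuracy dispersion.
    """

    n_pcs_values: np.ndarray
    mean_accuracy: np.ndarray
    std: np.ndarray
    fold_hash: str = ""


def accuracy_vs_pcs(entries, task: BinaryTask, cv: CVConfig | None = None,
                    max_pcs: int = 25,
                    regularization: float | None = None) -> PCCurve:
    """Sweep n_pcs = 1..max_pcs over identical folds per seeded split.

    Each fold's PCA is fit once with ``max_pcs`` components and truncated
    per sweep point, which is identical to refitting at each n_pcs.  With
    ``cv.n_repeats > 1`` the whole sweep is repeated on fresh seeded fold
    splits and the pooled accuracies are averaged across repeats, giving a
    smoother curve for plateau selection; every repeat still uses one fold
    assignment across all n_pcs.
    """
    cv = cv or CVConfig()
    X, y, ids, _ = _task_arrays(entries, task)
    n_vals = np.arange(1, max_pcs + 1)
    repeat_acc = []
    all_fold_acc = []
    all_folds = []
    for repeat in range(cv.n_repeats):
        folds = kfold_split(list(zip(ids, y)), cv, repeat=repeat)
        all_folds.extend(folds)
        min_train = min(len(y) - len(f) for f in folds)
        if max_pcs > min_train - 2:
            raise ValueError(
                f"max_pcs={max_pcs} exceeds the smallest fold training size "
                f"minus 2 ({min_train - 2})"
            )
        per_fold_cm = np.empty((len(folds), max_pcs, 4), dtype=int)
        for fi, test_idx in enumerate(folds):
            test = np.asarray(test_idx, dtype=int)
            train = np.setdiff1d(np.arange(len(y)), test)
            basis = pca_fit(X[train])
            Ftr = pca_project(basis, X[train], max_pcs)
            Fte = pca_project(basis, X[test], max_pcs)
            for j, n in enumerate(n_vals):
                model = lda_fit(Ftr[:, :n], y[train], regularization=regularization)
                pred, _ = lda_predict(model, Fte[:, :n])
                cm = _confusion_from_predictions(y[test], pred)
                per_fold_cm[fi, j] = (cm.tp, cm.fn, cm.fp, cm.tn)
        summed = per_fold_cm.sum(axis=0)
        repeat_acc.append(
            100.0 * (summed[:, 0] + summed[:, 3]) / summed.sum(axis=1)
        )
        fold_correct = per_fold_cm[:, :, 0] + per_fold_cm[:, :, 3]
        fold_total = per_fold_cm.sum(axis=2)
        all_fold_acc.append(100.0 * fold_correct / fold_total)
    acc = np.mean(repeat_acc, axis=0)
    std = np.std(np.concatenate(all_fold_acc, axis=0), axis=0, ddof=1)
    return PCCurve(n_vals, acc, std, fold_hash(all_folds))


def select_n_pcs(curve: PCCurve, tolerance: float = 0.5) -> int:
    """Smallest n with accuracy within ``tolerance`` points of the maximum."""
    acc = np.asarray(curve.mean_accuracy, dtype=float)
    if acc.size == 0:
        raise ValueError("empty accuracy curve")
    threshold = acc.max() - tolerance
    i = int(np.argmax(acc >= threshold))
    return int(curve.n_pcs_values[i])


@dataclass(frozen=True)
class SubrangeSpec:
    name: str
    low: float
    high: float


#: biomolecular sub-ranges of the working 1800-600 cm^-1 region
DEFAULT_SUBRANGES = (
    SubrangeSpec("carbohydrates", 600.0, 1195.0),
    SubrangeSpec("proteins(amideIII)+lipids", 1196.0, 1380.0),
    SubrangeSpec("nucleic acids", 1381.0, 1520.0),
    SubrangeSpec("proteins(amideI+II)", 1521.0, 1728.0),
)


def _cut_entries(entries, low: float, high: float):
    return [
        DatabaseEntry(e.cell_id, e.class_label, cut_to_range(e.spectrum, low, high))
        for e in entries
    ]


def subrange_analysis(entries, tasks, ranges=DEFAULT_SUBRANGES,
                      cv: CVConfig | None = None, tolerance: float = 0.5,
                      max_pcs: int = 25,
                      regularization: float | None = None) -> pd.DataFrame:
    """PC sweep + plateau selection per (task, wavenumber range).

    Spectra are cut (only — preprocessing is not redone) to each range;
    for every task x range cell the accuracy-vs-PCs curve is swept, the
    plateau PC count selected, and the metrics at that count reported.
    Returns a DataFrame with one row per (task, range).
    """
    cv = cv or CVConfig()
    rows = []
    for task in tasks:
        for rng_spec in ranges:
            sub = _cut_entries(entries, rng_spec.low, rng_spec.high)
            curve = accuracy_vs_pcs(sub, task, cv, max_pcs, regularization)
            n_sel = select_n_pcs(curve, tolerance)
            res = run_cv(sub, task, n_sel, cv, regularization)
            rows.append(
                {
                    "task": task.task_id,
                    "range": rng_spec.name,
                    "low": rng_spec.low,
                    "high": rng_spec.high,
                    "n_pcs": n_sel,
                    "acc": res.metrics.acc,
                    "acc_std": res.metrics.acc_std,
                    "se": res.metrics.se,
                    "sp": res.metrics.sp,
                    "ppv": res.metrics.ppv,
                    "npv": res.metrics.npv,
                    "tp": res.confusion.tp,
                    "fn": res.confusion.fn,
                    "fp": res.confusion.fp,
                    "tn": res.confusion.tn,
                }
            )
    return pd.DataFrame(rows)


def difference_spectra(manifest):
    """Per-site class means, pointwise std, and pairwise mean differences.

    Expects a (preprocessed) DatasetManifest.  Returns
    ``{site: {"mean": {class: arr}, "std": {class: arr}, "n": {class: int},
    "diff": {(a, b): mean_a - mean_b}}}`` for every site where all three
    classes are present; raises if a class is missing at a site.
    """
    out = {}
    for site in SITES:
        per_class: dict = {c: [] for c in CLASS_LABELS}
        for rec in manifest.records:
            if site in rec.site_spectra:
                per_class[rec.class_label].append(
                    rec.site_spectra[site].intensities
                )
        missing = [c for c, v in per_class.items() if not v]
        if missing:
            raise ValueError(f"site {site!r} missing class(es): {missing}")
        means = {c: np.mean(np.stack(v), axis=0) for c, v in per_class.items()}
        stds = {c: np.std(np.stack(v), axis=0, ddof=1) for c, v in per_class.items()}
        ns = {c: len(v) for c, v in per_class.items()}
        diffs = {}
        for a in CLASS_LABELS:
            for b in CLASS_LABELS:
                if a != b:
                    diffs[(a, b)] = means[a] - means[b]
        out[site] = {"mean": means, "std": stds, "n": ns, "diff": diffs}
    return out
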