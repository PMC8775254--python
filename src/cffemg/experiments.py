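"""Training loops, cross-validation, paired statistics, and the comparison
experiments between the plain RCNN and the CFF-RCNN.

The optimizer is SGD with momentum 0.95, learning rate 0.002, weight decay
0.0005 and minibatches of 20; the loss is the cross-entropy form
``-[y log p + (1-y) log(1-p)]`` over the softmax output.  Model pairs are
compared with the Wilcoxon matched-pairs signed-ranks test at α = 0.05, exact
for small sample counts.

Splits: ``random_window`` shuffles windows into train/val/test fractions
(0.8/0.1/0.1, stratified); ``by_repetition`` assigns whole movement
repetitions to one side only, which is the leakage-free protocol when
consecutive windows overlap.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import models, nn
from .windowing import WindowConfig, frame_dataset, one_hot, standardize
from . import synthetic as synth
from . import features as feat


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    epochs: int = 10
    learning_rate: float = 0.002
    momentum: float = 0.95
    weight_decay: float = 0.0005
    batch_size: int = 20
    loss: str = "bernoulli"  # -[y log p + (1-y) log(1-p)] over softmax
    seed: int = 0
    split: str = "random_window"  # or 'by_repetition'
    fractions: tuple = (0.8, 0.1, 0.1)
    k_folds: int = 5

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class History:
    """Per-epoch training curves; wall-clock seconds are informational only
    (hardware-dependent, never asserted)."""

    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    epoch_seconds: list = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)


@dataclass
class ComparisonResult:
    acc_a: np.ndarray
    acc_b: np.ndarray
    statistic: float  # W+ = sum of positive-difference ranks (a - b)
    p_value: float
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < self.alpha


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_random_window(labels, fractions=(0.8, 0.1, 0.1), seed=0):
    """Stratified window-level split; returns (train_idx, val_idx, test_idx)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    tr, va, te = [], [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        n = idx.size
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        tr.extend(idx[:n_tr])
        va.extend(idx[n_tr : n_tr + n_va])
        te.extend(idx[n_tr + n_va :])
    return (np.sort(np.array(tr, dtype=int)),
            np.sort(np.array(va, dtype=int)),
            np.sort(np.array(te, dtype=int)))


def split_by_repetition(labels, repetitions, fractions=(0.8, 0.1, 0.1), seed=0):
    """Assign whole (label, repetition) groups to one partition each, so no
    repetition contributes windows to two sides."""
    labels = np.asarray(labels)
    repetitions = np.asarray(repetitions)
    rng = np.random.default_rng(seed)
    tr, va, te = [], [], []
    for cls in np.unique(labels):
        cls_idx = np.flatnonzero(labels == cls)
        reps = np.unique(repetitions[cls_idx])
        reps = rng.permutation(reps)
        n = reps.size
        # every nonzero fraction gets at least one whole repetition
        n_va = max(int(round(fractions[1] * n)), 1 if fractions[1] > 0 else 0)
        n_te = max(int(round(fractions[2] * n)), 1 if fractions[2] > 0 else 0)
        n_tr = max(n - n_va - n_te, 1)
        groups = {"tr": reps[:n_tr], "va": reps[n_tr : n_tr + n_va],
                  "te": reps[n_tr + n_va :]}
        for name, out in (("tr", tr), ("va", va), ("te", te)):
            mask = np.isin(repetitions[cls_idx], groups[name])
            out.extend(cls_idx[mask])
    return (np.sort(np.array(tr, dtype=int)),
            np.sort(np.array(va, dtype=int)),
            np.sort(np.array(te, dtype=int)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(model, X, y, cfg: TrainConfig, X_val=None, y_val=None):
    """Train in place; returns a :class:`History`.

    ``X`` is ``(n, W, H, C)`` or ``(n, T, W, H, C)``; ``y`` integer labels.
    Aborts with a diagnostic on non-finite loss.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 4:
        X = X[:, None]
    if X.shape[0] == 0:
        raise TrainingError("empty training split")
    G = model.head.params["W"].shape[1]
    y1h = one_hot(y, G)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.SGDM(lr=cfg.learning_rate, momentum=cfg.momentum,
                  weight_decay=cfg.weight_decay)
    hist = History()
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            loss, probs = model.forward_backward(X[idx], y1h[idx], cfg.loss)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, step {i // cfg.batch_size}")
            opt.step(model.layers)
            losses.append(loss * idx.size)
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
        hist.train_loss.append(float(np.sum(losses) / n))
        hist.train_acc.append(correct / n)
        if X_val is not None and len(X_val):
            vl, va = evaluate(model, X_val, y_val, loss_kind=cfg.loss)
            hist.val_loss.append(vl)
            hist.val_acc.append(va)
        hist.epoch_seconds.append(time.perf_counter() - t0)
    return hist


def evaluate(model, X, y, loss_kind="bernoulli"):
    """(loss, accuracy) on a held-out set, inference mode."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 4:
        X = X[:, None]
    y = np.asarray(y)
    G = model.head.params["W"].shape[1]
    probs = model.predict_proba(X)
    loss, _ = nn.cross_entropy(probs, one_hot(y, G), kind=loss_kind)
    return float(loss), float(np.mean(probs.argmax(axis=1) == y))


def kfold_cv(X, y, fit_predict, k: int = 5, seed: int = 0):
    """Stratified k-fold cross-validation.

    ``fit_predict(X_train, y_train, X_test) -> predicted labels``.  Returns
    ``(per-fold accuracies, mean, sd)``.  Folds partition the data; every
    class must appear in every training fold.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    accs = []
    for i in range(k):
        te = np.sort(np.array(folds[i], dtype=int))
        tr = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]).astype(int))
        if np.unique(y[tr]).size < np.unique(y).size:
            raise ValueError(f"class missing from training fold {i}")
        pred = fit_predict(X[tr], y[tr], X[te])
        accs.append(float(np.mean(pred == y[te])))
    accs = np.asarray(accs)
    return accs, float(accs.mean()), float(accs.std())


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed-ranks test
# ---------------------------------------------------------------------------

def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p for the positive-rank sum, allowing midranks.

    Doubling makes every rank an integer; the null distribution of the doubled
    positive-rank sum is built by dynamic programming over the 2^n equally
    likely sign assignments, then ``p = 2 min(P(W <= w), P(W >= w))``.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def wilcoxon_compare(acc_a, acc_b, alpha: float = 0.05,
                     exact_max_n: int = 25) -> ComparisonResult:
    """Wilcoxon matched-pairs signed-ranks test on paired accuracies.

    Zero differences are dropped; tied magnitudes take midranks.  The p-value
    is exact (full sign-assignment distribution) for up to ``exact_max_n``
    nonzero pairs and a tie-corrected normal approximation beyond.  All
    differences zero is reported as degenerate with p = 1.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D with equal length")
    d = a - b
    nz = d != 0
    if not nz.any():
        return ComparisonResult(a, b, statistic=0.0, p_value=1.0,
                                alpha=alpha, degenerate=True)
    d = d[nz]
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if d.size <= exact_max_n:
        p = _exact_signed_rank_p(w_plus, ranks)
    else:
        p = float(sps.wilcoxon(d, alternative="two-sided",
                               method="approx").pvalue)
    return ComparisonResult(a, b, statistic=w_plus, p_value=p, alpha=alpha)


# ---------------------------------------------------------------------------
# efficiency and robustness reports
# ---------------------------------------------------------------------------

NOT_REACHED = "not reached"


def efficiency_report(histories: dict, thresholds) -> list[dict]:
    """Epochs-to-threshold (and cumulative seconds, informational) per model.

    For each accuracy threshold and each named :class:`History`, the first
    epoch (1-based) whose validation accuracy reaches the threshold, or the
    ``NOT_REACHED`` sentinel.  Wall-clock columns are hardware-dependent and
    must not be asserted against.
    """
    rows = []
    for thr in thresholds:
        for name, hist in histories.items():
            accs = hist.val_acc if hist.val_acc else hist.train_acc
            reached = next((e + 1 for e, a in enumerate(accs) if a >= thr), None)
            secs = (float(np.sum(hist.epoch_seconds[:reached]))
                    if reached is not None else None)
            rows.append({
                "threshold": thr,
                "model": name,
                "epochs_to_threshold": reached if reached is not None else NOT_REACHED,
                "seconds_to_threshold": secs,
            })
    return rows


# ---------------------------------------------------------------------------
# end-to-end experiment drivers
# ---------------------------------------------------------------------------

def _grouped_cv_accuracy(X, y, groups, seed=0, method="lda_knn"):
    """Leave-one-repetition-out accuracy of a shallow baseline: every window
    gets an out-of-repetition prediction, pooled into one accuracy."""
    groups = np.asarray(groups)
    correct = 0
    for g in np.unique(groups):
        te = groups == g
        tr = ~te
        pred_acc = feat.baseline_classify(X[tr], y[tr], X[te], y[te],
                                          method, seed=seed)
        correct += pred_acc * te.sum()
    return float(correct / len(y))

def run_confusable_comparison(seeds, *, epochs=20, split="by_repetition",
                              wcfg=None, spec_kw=None, train_kw=None):
    """Train RCNN and CFF-RCNN on the order-confusable two-class dataset.

    For each seed: generate a fresh confusable-pair recording, segment and
    standardize it, train both variants from matched initializations, and
    record final validation accuracy plus an amplitude-only (per-channel MAV
    feature + LDA/KNN) baseline accuracy on the same split.

    The split is repetition-disjoint by default: consecutive windows overlap
    by 80%, so a window-level random split leaks most of the validation set
    into training and both models saturate; holding out whole repetitions
    measures generalization to unseen executions, where the temporal
    information the fusion block preserves actually matters.

    Returns a dict with per-seed accuracies and the trained histories.
    """
    spec_kw = spec_kw or {}
    train_kw = dict(train_kw or {})
    train_kw.setdefault("split", split)
    results = {"seed": [], "rcnn": [], "cff_rcnn": [], "mav_baseline": [],
               "histories": []}
    for seed in seeds:
        sspec = synth.make_confusable_pair(
            synth.SyntheticSpec(seed=int(seed), **spec_kw))
        rec = synth.generate(sspec)
        wc = wcfg or WindowConfig(W=5, H=10, c_out=None)
        cfg = TrainConfig(epochs=epochs, seed=int(seed), **train_kw)
        frames, labels, _, reps = frame_dataset(rec, wc, drop_rest=True)
        labels = labels - labels.min()
        if cfg.split == "by_repetition":
            tr, va, te = split_by_repetition(labels, reps, cfg.fractions, cfg.seed)
        else:
            tr, va, te = split_random_window(labels, cfg.fractions, cfg.seed)
        Xtr, Xva, Xte, _ = standardize(frames[tr], frames[va], frames[te])
        ytr, yva, yte = labels[tr], labels[va], labels[te]
        W, H, C = Xtr.shape[1:]
        accs = {}
        hists = {}
        for variant in ("rcnn", "cff_rcnn"):
            spec = models.ModelSpec(variant=variant, input_shape=(W, H, C),
                                    num_classes=2)
            model = models.build_model(spec, seed=int(seed))
            hists[variant] = train(model, Xtr, ytr, cfg, Xva, yva)
            accs[variant] = hists[variant].val_acc[-1]
        # amplitude-only control: per-channel MAV is the feature a pure
        # pooling/amplitude detector sees; chance here is the point.
        # Estimated by repetition-grouped CV over all movement windows so the
        # estimate is not dominated by the shared noise of one held-out block.
        mav = np.abs(frames).mean(axis=(1, 2))
        mav_acc = _grouped_cv_accuracy(mav, labels, reps, seed=int(seed))
        results["seed"].append(int(seed))
        results["rcnn"].append(accs["rcnn"])
        results["cff_rcnn"].append(accs["cff_rcnn"])
        results["mav_baseline"].append(mav_acc)
        results["histories"].append(hists)
    return results


def robustness_run(n_subjects: int, *, epochs=8, seed=0, jitter=0.2,
                   spec_kw=None, train_kw=None, subject_disjoint=False):
    """Pooled multi-subject comparison of the two variants.

    ``n_subjects`` synthetic subjects are generated from the confusable-pair
    spec with per-subject envelope jitter, pooled, split (window-level by
    default, subject-disjoint when requested), and both models are trained on
    the pooled training data.  Returns test accuracies per model.
    """
    spec_kw = spec_kw or {}
    train_kw = train_kw or {}
    base = synth.make_confusable_pair(synth.SyntheticSpec(seed=seed, **spec_kw))
    wc = WindowConfig(W=5, H=10)
    all_frames, all_labels, all_subj = [], [], []
    for s in range(1, n_subjects + 1):
        rec = synth.generate(synth.perturb_subject(base, s, jitter=jitter, seed=seed + s))
        frames, labels, _, _ = frame_dataset(rec, wc, drop_rest=True)
        all_frames.append(frames)
        all_labels.append(labels - 1)
        all_subj.append(np.full(len(labels), s))
    X = np.concatenate(all_frames)
    y = np.concatenate(all_labels)
    subj = np.concatenate(all_subj)
    cfg = TrainConfig(epochs=epochs, seed=seed, **train_kw)
    if subject_disjoint:
        test_subject = n_subjects
        te = np.flatnonzero(subj == test_subject)
        pool = np.flatnonzero(subj != test_subject)
        rng = np.random.default_rng(seed)
        pool = rng.permutation(pool)
        n_va = max(int(0.1 * pool.size), 1)
        va, tr = np.sort(pool[:n_va]), np.sort(pool[n_va:])
    else:
        tr, va, te = split_random_window(y, cfg.fractions, seed)
    Xtr, Xva, Xte, _ = standardize(X[tr], X[va], X[te])
    out = {"subject_disjoint": subject_disjoint, "n_subjects": n_subjects}
    W, H, C = Xtr.shape[1:]
    for variant in ("rcnn", "cff_rcnn"):
        spec = models.ModelSpec(variant=variant, input_shape=(W, H, C),
                                num_classes=int(y.max()) + 1)
        model = models.build_model(spec, seed=seed)
        train(model, Xtr, y[tr], cfg, Xva, y[va])
        _, acc = evaluate(model, Xte, y[te], cfg.loss)
        out[variant] = acc
    return out
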