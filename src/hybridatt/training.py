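"""Training protocol, subject-independent cross-validation, metrics.

Optimisation uses adadelta (decay rho = 0.95, eps = 1e-6) with an L2
penalty of 0.001 added to the cost and dropout 0.5 in training mode.
Cross-validation is subject-independent: the k test sets partition the
cohort at subject level, and the remaining subjects split 0.7/0.1 (of
the total) into train/validation, so no subject's epochs leak across
sets. Evaluation reports accuracy, macro-/micro-F1, and macro
one-vs-rest AUC-PR / AUC-ROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (accuracy_score, average_precision_score, f1_score,
                             roc_auc_score)

from .model import HybridAttModel
from .preprocessing import EpochSequence
from .stages import N_STAGES


@dataclass
class TrainConfig:
    rho: float = 0.95            # adadelta decay (the stated "momentum")
    eps: float = 1e-6
    l2_coeff: float = 0.001
    dropout: float = 0.5
    epochs: int = 50
    batch: int = 8               # windows per update
    window: int = 25             # epochs per attention window
    patience: int = 10           # early stop on validation-accuracy plateau
    seed: int = 0

    def validate(self) -> None:
        if self.l2_coeff < 0:
            raise ValueError("l2_coeff must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


class Adadelta:
    """Adadelta with L2 weight penalty folded into the gradient."""

    def __init__(self, params: dict, rho: float = 0.95, eps: float = 1e-6,
                 l2: float = 0.0):
        self.params = params
        self.rho, self.eps, self.l2 = rho, eps, l2
        self._eg = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._ed = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.l2 * p.data
            eg = self._eg[k] = self.rho * self._eg[k] + (1 - self.rho) * g * g
            dx = -np.sqrt((self._ed[k] + self.eps) / (eg + self.eps)) * g
            self._ed[k] = self.rho * self._ed[k] + (1 - self.rho) * dx * dx
            p.data += dx


@dataclass
class FoldSplit:
    fold_id: int
    train_subjects: tuple
    val_subjects: tuple
    test_subjects: tuple

    def validate(self) -> None:
        tr, va, te = map(set, (self.train_subjects, self.val_subjects,
                               self.test_subjects))
        if tr & va or tr & te or va & te:
            raise ValueError(f"fold {self.fold_id}: overlapping subject sets")


def subject_folds(subject_ids, k: int, ratios=(0.7, 0.1, 0.2),
                  seed: int = 0) -> list:
    """k subject-level folds: the test sets partition the cohort; the
    remainder is split into train/validation at the given ratios of the
    total (validation size floored, remainder to train)."""
    ids = sorted(set(subject_ids))
    n = len(ids)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} subjects")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    if k == 1:
        # single split at the stated ratios
        n_test = max(1, int(round(ratios[2] * n)))
        test_chunks = [order[:n_test]]
    else:
        test_chunks = [list(c) for c in np.array_split(np.array(order), k)]
    n_val = int(np.floor(ratios[1] * n))
    folds = []
    for f in range(k):
        test = sorted(test_chunks[f])
        rest = [s for s in order if s not in test]
        rest = [rest[i] for i in rng.permutation(len(rest))]
        val = sorted(rest[:n_val])
        train = sorted(rest[n_val:])
        split = FoldSplit(fold_id=f, train_subjects=tuple(train),
                          val_subjects=tuple(val), test_subjects=tuple(test))
        split.validate()
        folds.append(split)
    return folds


def make_windows(seq: EpochSequence, window: int) -> list:
    """Chunk one record into (X, y) windows of at most `window` epochs;
    the trailing remainder is kept as a shorter window."""
    mats = seq.matrices()
    labels = seq.labels
    out = []
    for a in range(0, len(labels), window):
        out.append((mats[a:a + window], labels[a:a + window]))
    return out


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    best_epoch: int = -1


def _subject_windows(cohort: dict, subjects, window: int) -> list:
    wins = []
    for sid in subjects:
        wins.extend(make_windows(cohort[sid], window))
    return wins


def _accuracy_on_windows(model: HybridAttModel, wins) -> float:
    correct = total = 0
    for X, y in wins:
        pred = model.predict(X)
        correct += int((pred == y).sum())
        total += len(y)
    return correct / total if total else float("nan")


def train(model: HybridAttModel, cohort: dict, split: FoldSplit,
          cfg: TrainConfig) -> TrainHistory:
    """Fit `model` on the split's training subjects, selecting the best
    checkpoint by validation accuracy. `cohort` maps subject_id to its
    EpochSequence. Fully reproducible from cfg.seed."""
    cfg.validate()
    split.validate()
    missing = [s for s in (split.train_subjects + split.val_subjects)
               if s not in cohort]
    if missing:
        raise ValueError(f"cohort missing subjects {missing}")
    if not split.train_subjects:
        raise ValueError("empty training set")
    train_wins = _subject_windows(cohort, split.train_subjects, cfg.window)
    val_wins = _subject_windows(cohort, split.val_subjects, cfg.window)
    model.dropout = cfg.dropout
    opt = Adadelta(model.parameters(), rho=cfg.rho, eps=cfg.eps, l2=cfg.l2_coeff)
    rng = np.random.default_rng(cfg.seed)
    hist = TrainHistory()
    best_acc, best_state, stall = -np.inf, None, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_wins))
        losses = []
        for a in range(0, len(order), cfg.batch):
            batch = [train_wins[i] for i in order[a:a + cfg.batch]]
            opt.zero_grad()
            loss = model.batch_forward_loss([w[0] for w in batch],
                                            [w[1] for w in batch],
                                            train=True, rng=rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        hist.train_loss.append(float(np.mean(losses)))
        val_acc = (_accuracy_on_windows(model, val_wins) if val_wins
                   else _accuracy_on_windows(model, train_wins))
        hist.val_accuracy.append(val_acc)
        if val_acc > best_acc:
            best_acc, best_state, stall = val_acc, model.state_dict(), 0
            hist.best_epoch = epoch
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return hist


# -- metrics ---------------------------------------------------------


@dataclass
class Metrics:
    accuracy: float
    macro_f1: float
    micro_f1: float
    auc_pr_macro: float
    auc_roc_macro: float

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "macro_f1": self.macro_f1,
                "micro_f1": self.micro_f1, "auc_pr_macro": self.auc_pr_macro,
                "auc_roc_macro": self.auc_roc_macro}


def compute_metrics(y_true, probs, n_classes: int = N_STAGES) -> Metrics:
    """The five evaluation measurements from labels and posteriors.

    Macro-F1 averages per-class F1 over all n_classes (absent classes
    contribute 0); micro-F1 comes from pooled counts and equals accuracy
    for single-label multiclass. AUCs are one-vs-rest, macro-averaged
    over classes present in y_true; with a single-class truth they are
    undefined and reported as nan with a warning."""
    y_true = np.asarray(y_true, dtype=int)
    probs = np.asarray(probs, dtype=float)
    y_pred = probs.argmax(axis=1)
    labels = list(range(n_classes))
    acc = accuracy_score(y_true, y_pred)
    macro = f1_score(y_true, y_pred, labels=labels, average="macro",
                     zero_division=0)
    micro = f1_score(y_true, y_pred, labels=labels, average="micro",
                     zero_division=0)
    present = [c for c in labels if np.any(y_true == c)]
    aucs_roc, aucs_pr = [], []
    if len(present) < 2:
        warnings.warn("single-class test set: AUCs undefined", stacklevel=2)
        roc = pr = float("nan")
    else:
        for c in present:
            y_bin = (y_true == c).astype(int)
            if 0 < y_bin.sum() < len(y_bin):
                aucs_roc.append(roc_auc_score(y_bin, probs[:, c]))
                aucs_pr.append(average_precision_score(y_bin, probs[:, c]))
        roc = float(np.mean(aucs_roc)) if aucs_roc else float("nan")
        pr = float(np.mean(aucs_pr)) if aucs_pr else float("nan")
    return Metrics(accuracy=float(acc), macro_f1=float(macro),
                   micro_f1=float(micro), auc_pr_macro=pr, auc_roc_macro=roc)


def evaluate(model: HybridAttModel, cohort: dict, subjects,
             window: int = 25) -> Metrics:
    """Metrics over all epochs of the given subjects (dropout off)."""
    wins = _subject_windows(cohort, subjects, window)
    if not wins:
        raise ValueError("empty evaluation set")
    y_true = np.concatenate([y for _, y in wins])
    probs = np.concatenate([model.predict_proba(X) for X, _ in wins])
    return compute_metrics(y_true, probs, model.n_classes)


@dataclass
class CVResult:
    per_fold: list                 # Metrics per fold
    histories: list

    def summary(self) -> dict:
        """mu +/- sigma per metric across folds (Tables-style row)."""
        keys = ["accuracy", "macro_f1", "micro_f1", "auc_pr_macro",
                "auc_roc_macro"]
        out = {}
        for k in keys:
            vals = np.array([m.as_dict()[k] for m in self.per_fold])
            out[k] = {"mean": float(np.nanmean(vals)),
                      "std": float(np.nanstd(vals))}
        return out

    def table(self):
        import pandas as pd

        rows = [m.as_dict() for m in self.per_fold]
        df = pd.DataFrame(rows)
        df.index.name = "fold"
        summ = {k: f"{v['mean']:.4f} ±{v['std']:.4f}"
                for k, v in self.summary().items()}
        return df, summ


def cross_validate(cohort: dict, k: int, cfg: TrainConfig,
                   model_factory) -> CVResult:
    """k-fold subject-independent CV: train+evaluate per fold with a
    fresh model from `model_factory(fold_seed)`."""
    folds = subject_folds(list(cohort.keys()), k, seed=cfg.seed)
    per_fold, histories = [], []
    for split in folds:
        model = model_factory(cfg.seed + split.fold_id)
        hist = train(model, cohort, split, cfg)
        per_fold.append(evaluate(model, cohort, split.test_subjects,
                                 window=cfg.window))
        histories.append(hist)
    return CVResult(per_fold=per_fold, histories=histories)
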