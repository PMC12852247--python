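"""Permuted discriminant function analysis (pDFA) with a restriction factor.

Calls are classified to individuals by linear discriminant functions fitted
on balanced training subsets; significance is assessed by permuting the
individual labels only *within* blocks of a restriction factor (behavioural
context), so the null preserves the context composition of the data.

The observed statistic is the mean correct-classification rate over
``n_selections`` random balanced train/test splits, for both the training
calls (re-classified by the fitted functions) and the held-out calls
("cross-classified"). Each permuted dataset is scored by the identical
procedure (same number of selections), keeping observed and null
exchangeable, which is what makes the permutation p-value valid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from . import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "PDFAConfig",
    "PDFAResult",
    "balanced_split",
    "permute_within_blocks",
    "fit_and_classify",
    "run_pdfa",
    "relative_cross_classification",
]


@dataclass
class PDFAConfig:
    test_factor: str = "individual"
    restriction_factor: str = "context"
    feature_columns: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))
    n_permutations: int = 1000
    n_selections: int = 100
    n_train_per_cell: int | None = None  # default: smallest usable cell size - 1
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.n_selections < 1:
            raise ValueError("n_selections must be >= 1")
        if self.n_train_per_cell is not None and self.n_train_per_cell < 1:
            raise ValueError("n_train_per_cell must be >= 1")


@dataclass
class PDFAResult:
    """One model's classification summary (one column of the results table)."""

    n_context_categories: int
    n_calls: int
    pct_correct: float
    chance_correct: float
    p_correct: float
    pct_cross: float
    chance_cross: float
    relative_cross: float
    p_cross: float
    n_train_per_cell: int
    n_dropped_cells: int

    def to_dict(self) -> dict:
        return {
            "n_context_categories": self.n_context_categories,
            "n_calls": self.n_calls,
            "pct_correct": self.pct_correct,
            "chance_correct": self.chance_correct,
            "p_correct": self.p_correct,
            "pct_cross": self.pct_cross,
            "chance_cross": self.chance_cross,
            "relative_cross": self.relative_cross,
            "p_cross": self.p_cross,
            "n_train_per_cell": self.n_train_per_cell,
            "n_dropped_cells": self.n_dropped_cells,
        }


def relative_cross_classification(pct_cross: float, chance_cross: float) -> float:
    """Cross-classified accuracy divided by its chance level, to 2 decimals."""
    if chance_cross <= 0:
        raise ValueError("chance_cross must be > 0")
    return round(pct_cross / chance_cross, 2)


def permute_within_blocks(
    labels: np.ndarray, blocks: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly permute ``labels`` within each level of ``blocks``.

    The label multiset of every block is conserved; nothing crosses blocks.
    """
    labels = np.asarray(labels)
    blocks = np.asarray(blocks)
    if labels.shape != blocks.shape:
        raise ValueError("labels and blocks must have equal length")
    out = labels.copy()
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        out[idx] = labels[idx[rng.permutation(idx.size)]]
    return out


def _split_indices(
    y: np.ndarray, blocks: np.ndarray, n_train: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    """Balanced train/test index split over (y x block) cells.

    Cells with fewer than ``n_train + 1`` members are dropped. Returns
    (train_idx, test_idx, n_dropped_cells); raises if no cell survives or
    fewer than two classes remain.
    """
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    kept_classes: set = set()
    n_dropped = 0
    y_codes = pd.factorize(y)[0]
    b_codes = pd.factorize(blocks)[0]
    cell = y_codes.astype(np.int64) * (b_codes.max() + 1) + b_codes
    for c in np.unique(cell):
        idx = np.flatnonzero(cell == c)
        yv = y[idx[0]]
        if idx.size < n_train + 1:
            n_dropped += 1
            continue
        pick = rng.permutation(idx.size)
        train.append(idx[pick[:n_train]])
        test.append(idx[pick[n_train:]])
        kept_classes.add(yv)
    if not train:
        raise ValueError("no individual x context cell has enough calls for the split")
    if len(kept_classes) < 2:
        raise ValueError("fewer than two classes remain after dropping small cells")
    return np.concatenate(train), np.concatenate(test), n_dropped


def balanced_split(
    calls: pd.DataFrame,
    test_factor: str,
    restriction_factor: str,
    n_train_per_cell: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random balanced train/test split of a call table.

    Train holds exactly ``n_train_per_cell`` calls per retained
    test-factor x restriction-factor cell (sampled without replacement);
    test holds the remaining calls of retained cells. Under-filled cells are
    dropped with a logged warning.
    """
    y = calls[test_factor].to_numpy()
    b = calls[restriction_factor].to_numpy()
    tr, te, n_dropped = _split_indices(y, b, n_train_per_cell, rng)
    if n_dropped:
        logger.warning(
            "balanced_split: dropped %d cell(s) with < %d calls",
            n_dropped,
            n_train_per_cell + 1,
        )
    return calls.iloc[tr], calls.iloc[te]


def _lda_accuracy(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, y_test: np.ndarray
) -> tuple[float, float]:
    """Fit linear discriminant functions on train; return (% correct on the
    training calls re-classified, % correct on test).

    Features are standardised by train mean/SD. A near-singular pooled
    within-class covariance is ridge-regularised (1e-6 x mean diagonal).
    """
    classes, y_idx = np.unique(y_train, return_inverse=True)
    k = classes.size
    if k < 2:
        raise ValueError("need at least two classes in the training set")
    if X_test.shape[0] == 0:
        raise ValueError("test set is empty")
    n, p = X_train.shape
    if n <= p:
        warnings.warn(
            f"only {n} training calls for {p} features; discriminant functions "
            "may be unstable",
            stacklevel=2,
        )

    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    Xtr = (X_train - mu) / sd
    Xte = (X_test - mu) / sd

    means = np.empty((k, p))
    for j in range(k):
        means[j] = Xtr[y_idx == j].mean(axis=0)
    resid = Xtr - means[y_idx]
    dof = max(n - k, 1)
    cov = resid.T @ resid / dof

    ridge = 1e-6 * np.trace(cov) / p
    for attempt in range(2):
        try:
            chol = linalg.cho_factor(cov, lower=True)
            break
        except linalg.LinAlgError:
            if attempt == 1:
                raise linalg.LinAlgError(
                    "within-class covariance singular even after ridge regularisation"
                )
            logger.info("singular within-class covariance; adding ridge %.3g", ridge)
            cov = cov + max(ridge, 1e-12) * np.eye(p)

    W = linalg.cho_solve(chol, means.T)  # (p, k)
    priors = np.bincount(y_idx, minlength=k) / n
    const = -0.5 * np.einsum("kp,pk->k", means, W) + np.log(priors)

    pred_train = classes[np.argmax(Xtr @ W + const, axis=1)]
    pred_test = classes[np.argmax(Xte @ W + const, axis=1)]
    acc_train = 100.0 * np.mean(pred_train == y_train)
    acc_test = 100.0 * np.mean(pred_test == y_test)
    return float(acc_train), float(acc_test)


def fit_and_classify(
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_columns: list[str],
    test_factor: str,
) -> tuple[float, float]:
    """Linear DFA on the train table; percentages of correctly classified
    training and test calls."""
    Xtr = train[feature_columns].to_numpy(dtype=np.float64)
    Xte = test[feature_columns].to_numpy(dtype=np.float64)
    if not (np.all(np.isfinite(Xtr)) and np.all(np.isfinite(Xte))):
        raise ValueError("features must be finite")
    return _lda_accuracy(
        Xtr, train[test_factor].to_numpy(), Xte, test[test_factor].to_numpy()
    )


def _procedure_statistic(
    X: np.ndarray,
    y: np.ndarray,
    blocks: np.ndarray,
    n_train: int,
    n_selections: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Mean (train %, cross %) over ``n_selections`` balanced splits."""
    acc_tr = np.empty(n_selections)
    acc_te = np.empty(n_selections)
    for s in range(n_selections):
        tr, te, _ = _split_indices(y, blocks, n_train, rng)
        acc_tr[s], acc_te[s] = _lda_accuracy(X[tr], y[tr], X[te], y[te])
    return float(acc_tr.mean()), float(acc_te.mean())


def run_pdfa(calls: pd.DataFrame, config: PDFAConfig) -> PDFAResult:
    """Run one permuted DFA model on a call table.

    Observed rates average over ``config.n_selections`` balanced splits; the
    null distribution applies the identical procedure to labels permuted
    within restriction-factor blocks. Chance levels are null means and
    p-values use the add-one convention (b + 1)/(m + 1), so the smallest
    attainable p with 1000 permutations is 1/1001.
    """
    rng = np.random.default_rng(config.seed)
    X = calls[config.feature_columns].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    y = calls[config.test_factor].to_numpy()
    blocks = calls[config.restriction_factor].to_numpy()

    cell_sizes = (
        pd.Series(1, index=pd.MultiIndex.from_arrays([y, blocks])).groupby(level=[0, 1]).sum()
    )
    usable = cell_sizes[cell_sizes >= 2]
    if usable.empty:
        raise ValueError("no individual x context cell has at least 2 calls")
    n_train = (
        config.n_train_per_cell
        if config.n_train_per_cell is not None
        else max(1, int(usable.min()) - 1)
    )
    _, _, n_dropped = _split_indices(y, blocks, n_train, rng=np.random.default_rng(0))
    if n_dropped:
        logger.warning("run_pdfa: %d cell(s) too small for n_train_per_cell=%d", n_dropped, n_train)

    obs_correct, obs_cross = _procedure_statistic(
        X, y, blocks, n_train, config.n_selections, rng
    )

    null_correct = np.empty(config.n_permutations)
    null_cross = np.empty(config.n_permutations)
    for m in range(config.n_permutations):
        for _attempt in range(100):
            y_perm = permute_within_blocks(y, blocks, rng)
            try:
                null_correct[m], null_cross[m] = _procedure_statistic(
                    X, y_perm, blocks, n_train, config.n_selections, rng
                )
                break
            except ValueError:
                continue  # degenerate permuted labelling; redraw
        else:
            raise RuntimeError("could not find a usable permutation in 100 attempts")

    eps = 1e-9
    p_correct = (np.sum(null_correct >= obs_correct - eps) + 1) / (config.n_permutations + 1)
    p_cross = (np.sum(null_cross >= obs_cross - eps) + 1) / (config.n_permutations + 1)
    chance_correct = float(null_correct.mean())
    chance_cross = float(null_cross.mean())

    return PDFAResult(
        n_context_categories=int(pd.unique(blocks).size),
        n_calls=int(len(calls)),
        pct_correct=obs_correct,
        chance_correct=chance_correct,
        p_correct=float(p_correct),
        pct_cross=obs_cross,
        chance_cross=chance_cross,
        relative_cross=relative_cross_classification(obs_cross, chance_cross),
        p_cross=float(p_cross),
        n_train_per_cell=n_train,
        n_dropped_cells=int(n_dropped),
    )
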