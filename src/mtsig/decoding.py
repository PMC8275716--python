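"""Odor-pair discriminability: scalar auROC and cross-validated logistic decoding.

Two complementary readouts of how well a signal separates two odors:

* ``pair_auroc`` reduces each trial to a baseline-subtracted evoked-window
  mean and computes the auROC between the two odors' scalar distributions,
  folded to [0.5, 1] so it reads as a magnitude of difference;
* ``decode_pair`` / ``decoding_curve`` train L2 logistic-regression
  classifiers on concatenated, standardized 50-ms-binned features over
  cumulative windows (0, t] up to 5 s, scored by stratified 10-fold
  cross-validation and averaged over all 28 unordered odor pairs.

Standardization parameters are always fit on the training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io import ValidationError
from .preprocess import TrialMatrix
from .response import auroc

__all__ = [
    "PairDiscrimination",
    "DecodingCurve",
    "pair_auroc",
    "build_features",
    "decode_pair",
    "decoding_curve",
]


@dataclass(frozen=True)
class PairDiscrimination:
    """Folded auROC (>= 0.5) between two odors' per-trial response scalars."""

    odor_pair: tuple
    signal_kind: str
    auroc_raw: float
    auroc_folded: float


@dataclass
class DecodingCurve:
    """Mean 28-pair classification accuracy at each cumulative feature window."""

    t_end: np.ndarray            # right edges of the cumulative windows (s)
    accuracy: np.ndarray         # mean over pairs, in [0, 1]
    signal_kind: str
    seed: int


def _evoked_scalars(tm: TrialMatrix, evoked_window: float = 2.0) -> np.ndarray:
    """Per-trial baseline-subtracted mean over the evoked window (0-2 s)."""
    pre, _ = tm.window
    i_on = int(round(pre / tm.bin_width))
    ne = int(round(evoked_window / tm.bin_width))
    return tm.values[:, i_on: i_on + ne].mean(axis=1) - tm.baseline_means()


def pair_auroc(tm_a: TrialMatrix, tm_b: TrialMatrix,
               evoked_window: float = 2.0) -> PairDiscrimination:
    """Discriminability of two odors from per-trial evoked response scalars."""
    if tm_a.signal_kind != tm_b.signal_kind or tm_a.source != tm_b.source:
        raise ValidationError("pair_auroc requires the same signal and source")
    if tm_a.values.shape[1] != tm_b.values.shape[1] or tm_a.window != tm_b.window:
        raise ValidationError("pair_auroc requires matching trial-matrix grids")
    a = _evoked_scalars(tm_a, evoked_window)
    b = _evoked_scalars(tm_b, evoked_window)
    raw = auroc(a, b)
    return PairDiscrimination((tm_a.odor_id, tm_b.odor_id), tm_a.signal_kind,
                              raw, max(raw, 1.0 - raw))


def build_features(tms: list[TrialMatrix], t_end: float) -> np.ndarray:
    """Per-trial feature vectors: baseline-mean-subtracted values of all bins
    in (0, t_end], concatenated across channels (one TrialMatrix per channel:
    the population trace for calcium/band power, one per unit for spikes).

    Standardization is *not* applied here; it belongs to the training fold
    (see :func:`decode_pair`).
    """
    if not tms:
        raise ValidationError("build_features needs at least one channel")
    pre, post = tms[0].window
    if t_end > post + 1e-9:
        raise ValidationError(f"t_end={t_end}s exceeds the {post}s post-onset window")
    k = t_end / tms[0].bin_width
    if abs(k - round(k)) > 1e-9:
        raise ValidationError(f"t_end={t_end}s is not on the {tms[0].bin_width}s bin grid")
    i_on = int(round(pre / tms[0].bin_width))
    k = int(round(k))
    blocks = []
    for tm in tms:
        if tm.window != tms[0].window or tm.values.shape != tms[0].values.shape:
            raise ValidationError("all channels must share one trial-matrix grid")
        blocks.append(tm.values[:, i_on: i_on + k] - tm.baseline_means()[:, None])
    return np.concatenate(blocks, axis=1)


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both folds with the training fold's mean/SD (no leakage)."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def decode_pair(features_a: np.ndarray, features_b: np.ndarray,
                folds: int = 10, seed: int = 0, C: float = 1.0,
                tol: float = 1e-6) -> float:
    """Stratified k-fold CV accuracy of an L2 logistic regression on two classes.

    Per fold, features are standardized with the training fold's mean/SD and
    the same transform is applied to the held-out trials.
    """
    na, nb = len(features_a), len(features_b)
    if min(na, nb) < folds:
        raise ValidationError(
            f"each class needs >= {folds} trials for {folds}-fold CV "
            f"(got {na}/{nb}); reduce the fold count"
        )
    X = np.concatenate([features_a, features_b])
    y = np.concatenate([np.zeros(na), np.ones(nb)])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        X_tr, X_te = _standardize(X[tr], X[te])
        # default penalty is L2; C is the inverse regularization strength
        clf = LogisticRegression(C=C, tol=tol, max_iter=1000)
        clf.fit(X_tr, y[tr])
        accs.append(clf.score(X_te, y[te]))
    return float(np.mean(accs))


def decoding_curve(tms_by_odor: dict[int, list[TrialMatrix]], signal_kind: str,
                   feature_end: float = 5.0, bin_width: float = 0.05,
                   folds: int = 10, seed: int = 0, C: float = 1.0,
                   tol: float = 1e-6, t_grid: np.ndarray | None = None) -> DecodingCurve:
    """Cumulative-window decoding: for each t_end on the 50-ms grid up to
    ``feature_end``, the mean :func:`decode_pair` accuracy over all unordered
    odor pairs (28 with the full 8-odor design)."""
    odors = sorted(tms_by_odor)
    if len(odors) < 2:
        raise ValidationError("decoding_curve needs >= 2 odors")
    if t_grid is None:
        n_steps = int(round(feature_end / bin_width))
        t_grid = bin_width * np.arange(1, n_steps + 1)
    t_grid = np.asarray(t_grid, float)
    full = {o: build_features(tms_by_odor[o], float(t_grid[-1])) for o in odors}
    n_ch = len(tms_by_odor[odors[0]])
    bins_per_ch = full[odors[0]].shape[1] // n_ch
    acc = np.zeros(t_grid.size)
    pairs = list(combinations(odors, 2))
    rng = np.random.default_rng(seed)
    pair_seeds = rng.integers(0, 2 ** 31 - 1, len(pairs))
    for j, t_end in enumerate(t_grid):
        k = int(round(t_end / bin_width))
        cols = np.concatenate([np.arange(c * bins_per_ch, c * bins_per_ch + k)
                               for c in range(n_ch)])
        vals = []
        for (a, b), ps in zip(pairs, pair_seeds):
            vals.append(decode_pair(full[a][:, cols], full[b][:, cols],
                                    folds=folds, seed=int(ps), C=C, tol=tol))
        acc[j] = np.mean(vals)
    return DecodingCurve(t_grid, acc, signal_kind, seed)
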