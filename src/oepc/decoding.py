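"""Exploration vs non-exploration decoding at angular positions.

Each behavioral bout is one observation labeled +1 (exploration) or -1
(non-exploration). At a given bin relative to the object, the predictors
are either the simultaneously recorded oePC activities at that bin (one
feature per cell) or the mean radial position rho there (the behavioral
control). A linear-kernel SVM (C = 1, features standardized per training
fold) is evaluated by leave-one-out: accuracy = (1/k) sum_i I(y_i = yhat_i).
Significance compares the observed accuracy to the 95th percentile of 100
label-permutation accuracies. The off-track exclusion variant removes
masked frames before bin-averaging, dropping bouts whose bin empties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .trajectory import EXPLORATION, NON_EXPLORATION, PolarTrajectory

FEATURE_OEPC = "oepc_activity"
FEATURE_RHO = "rho"


@dataclass
class DecodingResult:
    object_id: int
    rel_bin: int              # bins relative to the object bin
    feature_set: str
    exclusion: str            # "none" | "offtrack_excluded"
    k: int                    # bouts decoded
    accuracy: float
    chance_p95: float
    significant: bool


def build_design(activity, traj: PolarTrajectory, bouts, object_id: int,
                 target_bin: int, feature_set: str = FEATURE_OEPC,
                 cell_ids=None, exclude_offtrack: bool = False):
    """Design matrix (bouts x features) and labels at one angular bin.

    Feature per bout: the mean over the bout's frames falling in
    ``target_bin`` of each selected cell's activity, or of rho. With
    exclusion, off-track/indeterminate frames are removed first; bouts
    whose bin empties are dropped.
    """
    rows, labels = [], []
    for b in bouts:
        if b.object_id != object_id or b.label not in (EXPLORATION,
                                                       NON_EXPLORATION):
            continue
        f = b.valid_frames(traj, exclude_offtrack=exclude_offtrack)
        f = f[traj.bin[f] == target_bin]
        if len(f) == 0:
            continue
        if feature_set == FEATURE_RHO:
            rows.append([float(traj.rho[f].mean())])
        elif feature_set == FEATURE_OEPC:
            act = np.asarray(activity, dtype=float)
            ids = range(act.shape[0]) if cell_ids is None else cell_ids
            rows.append([float(act[c, f].mean()) for c in ids])
        else:
            raise ValueError(f"unknown feature_set {feature_set!r}")
        labels.append(1 if b.label == EXPLORATION else -1)
    X = np.asarray(rows, dtype=float)
    y = np.asarray(labels, dtype=int)
    return X, y


def prediction_accuracy(y, y_hat) -> float:
    """Fraction of correct predictions: (1/k) sum_i I(y_i = yhat_i)."""
    y = np.asarray(y)
    y_hat = np.asarray(y_hat)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("label and prediction vectors must match")
    return float(np.mean(y == y_hat))


def loo_accuracy(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> float:
    """Leave-one-out accuracy of a linear-kernel SVM.

    Features are standardized on each training fold. A fold whose
    training set contains a single class predicts that class. Accuracy is
    the fraction of held-out bouts predicted correctly.
    """
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 bouts")
    preds = np.empty(n, dtype=int)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        ytr = y[tr]
        if len(np.unique(ytr)) < 2:
            preds[i] = int(np.sign(ytr.sum())) or 1
        else:
            scaler = StandardScaler()
            Xtr = scaler.fit_transform(X[tr])
            clf = SVC(kernel="linear", C=C)
            clf.fit(Xtr, ytr)
            preds[i] = int(clf.predict(scaler.transform(X[i:i + 1]))[0])
    return prediction_accuracy(y, preds)


def permutation_significance(X: np.ndarray, y: np.ndarray,
                             n_perm: int = 100, rng=None, C: float = 1.0,
                             percentile: float = 95.0):
    """Observed LOO accuracy vs a label-permutation chance distribution.

    Permutations shuffle labels without replacement (class counts are
    preserved). Significant iff the observed accuracy strictly exceeds
    the ``percentile``-th percentile of the chance accuracies.

    Returns (accuracy, chance, significant).
    """
    rng = np.random.default_rng(rng)
    acc = loo_accuracy(X, y, C)
    chance = np.array([loo_accuracy(X, rng.permutation(y), C)
                       for _ in range(n_perm)])
    threshold = float(np.percentile(chance, percentile))
    return acc, chance, bool(acc > threshold)


def decode_profile(activity, traj: PolarTrajectory, bouts, object_id: int,
                   object_bin: int, cell_ids=None,
                   feature_set: str = FEATURE_OEPC,
                   exclude_offtrack: bool = False,
                   rel_bins=range(-3, 3), n_perm: int = 100,
                   rng=None, min_bouts: int = 3) -> pd.DataFrame:
    """Decoding accuracy/significance per bin across the bout window.

    ``rel_bins`` are offsets from the object bin (negative = before the
    object in running direction). Bins with fewer than ``min_bouts``
    bouts of either class are reported undecodable (NaN accuracy).
    """
    rng = np.random.default_rng(rng)
    n_bins = traj.n_bins
    rows = []
    for rb in rel_bins:
        tb = (object_bin + rb) % n_bins
        X, y = build_design(activity, traj, bouts, object_id, tb,
                            feature_set, cell_ids, exclude_offtrack)
        n_pos = int((y == 1).sum())
        n_neg = int((y == -1).sum())
        if min(n_pos, n_neg) < min_bouts:
            rows.append(dict(object_id=object_id, rel_bin=rb,
                             feature_set=feature_set,
                             exclusion="offtrack_excluded"
                             if exclude_offtrack else "none",
                             k=len(y), accuracy=np.nan, chance_p95=np.nan,
                             significant=False))
            continue
        acc, chance, sig = permutation_significance(X, y, n_perm, rng)
        rows.append(dict(object_id=object_id, rel_bin=rb,
                         feature_set=feature_set,
                         exclusion="offtrack_excluded"
                         if exclude_offtrack else "none",
                         k=len(y), accuracy=acc,
                         chance_p95=float(np.percentile(chance, 95)),
                         significant=sig))
    return pd.DataFrame(rows)
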