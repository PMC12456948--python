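"""Decoding the behavioral reversal trial and residual subspace coupling.

A linear discriminant decoder reads the behavioral reversal trial out of
reversal-probability activity: for each block, the 2*dk+1 trials around the
reversal each contribute a short time window of the projection around a
probe time t0, labeled by their relative-trial identity. A test block's
predicted reversal is the trial whose window scores highest for the
relative-trial-0 class; chance is 1/(2*dk+1).

Residual analyses relate single-block deviations from the block-averaged
activity between the reversal-probability and choice subspaces, via an OLS
slope across blocks at each relative trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .reversal import AlignedSubspaceActivity

__all__ = [
    "DecoderDataset",
    "build_decoder_dataset",
    "decode_reversal",
    "residual_activity",
    "residual_slope",
]


@dataclass
class DecoderDataset:
    """Per-block windows of reversal-probability activity around time t0.

    ``X[block, class, bin]`` with one class per relative trial (-dk..dk) and
    ``T_dec = 2*dt/dh + 1`` time bins; the one-hot target marks relative
    trial 0 (the behavioral reversal).
    """

    X: np.ndarray
    classes: np.ndarray  # relative trials, length 2*dk+1
    t0: float
    n_excluded: int

    @property
    def n_blocks(self) -> int:
        return self.X.shape[0]

    @property
    def n_classes(self) -> int:
        return self.X.shape[1]

    def one_hot_target(self) -> np.ndarray:
        y = np.zeros(self.n_classes)
        y[int(np.flatnonzero(self.classes == 0)[0])] = 1.0
        return y


def build_decoder_dataset(
    aligned: AlignedSubspaceActivity,
    t0: float,
    dk: int = 10,
    dt: float = 160.0,
    dh: float = 20.0,
) -> DecoderDataset:
    """Extract (2*dk+1) class-labeled time windows per block.

    The window spans t0 +/- dt sampled every dh on the aligned time axis
    (2*dt/dh + 1 bins). Blocks missing any of the 2*dk+1 trials or any
    window sample are excluded and counted.
    """
    taxis = aligned.time_axis
    want = np.arange(t0 - dt, t0 + dt + dh / 2, dh)
    if want[0] < taxis.min() - 1e-9 or want[-1] > taxis.max() + 1e-9:
        raise ValueError(f"window around t0={t0} falls outside the trial span")
    idx = []
    for w in want:
        j = int(np.argmin(np.abs(taxis - w)))
        if abs(taxis[j] - w) > dh / 2:
            raise ValueError("aligned time axis does not sample the decoder grid")
        idx.append(j)
    idx = np.asarray(idx)
    rel = aligned.rel_trials
    sel_rel = np.flatnonzero(np.abs(rel) <= dk)
    if len(sel_rel) != 2 * dk + 1:
        raise ValueError(f"aligned window narrower than dk={dk}")
    rows, kept = [], 0
    n_excl = 0
    for b in range(aligned.n_blocks):
        if not aligned.valid[b, sel_rel].all():
            n_excl += 1
            continue
        rows.append(aligned.x[b][np.ix_(sel_rel, idx)])
    if not rows:
        raise ValueError("no complete blocks for the decoder")
    return DecoderDataset(
        X=np.asarray(rows), classes=rel[sel_rel], t0=t0, n_excluded=n_excl
    )


def decode_reversal(
    dataset: DecoderDataset,
    train_fraction: float = 0.9,
    n_repeats: int = 20,
    rng: Optional[np.random.Generator] = None,
    shuffle_labels: bool = False,
    shrinkage: str | float | None = "auto",
) -> pd.DataFrame:
    """Linear discriminant decoding of the reversal trial, repeated splits.

    Trial windows are samples labeled by relative-trial identity; a test
    block's predicted reversal is the trial with the highest posterior for
    the relative-trial-0 class (posteriors normalized within each trial's
    window, so a monotone code cannot win by sheer magnitude). Accuracy per
    repeat is the fraction of test blocks predicted correctly (chance =
    1/n_classes). ``shuffle_labels`` permutes the trial/class association
    within every block — training and test alike — which makes the data
    exchangeable with respect to the labels, so accuracy sits at chance.
    The discriminant pools covariance with shrinkage toward identity, which
    regularizes the window-by-window covariance when blocks are few.
    """
    rng = np.random.default_rng() if rng is None else rng
    nb, nc, nt = dataset.X.shape
    if nb < 3:
        raise ValueError("need at least 3 blocks to decode")
    n_train = max(2, int(round(train_fraction * nb)))
    if n_train >= nb:
        n_train = nb - 1
    zero_class = int(np.flatnonzero(dataset.classes == 0)[0])
    rows = []
    for rep in range(n_repeats):
        X = dataset.X
        if shuffle_labels:
            X = np.stack([X[b][rng.permutation(nc)] for b in range(nb)])
        perm = rng.permutation(nb)
        tr, te = perm[:n_train], perm[n_train:]
        Xtr = X[tr].reshape(-1, nt)
        ytr = np.tile(np.arange(nc), len(tr))
        counts = np.bincount(ytr, minlength=nc)
        if counts.min() < 2:
            rows.append({"repeat": rep, "t0": dataset.t0, "accuracy": np.nan,
                         "n_test": len(te), "skipped": True})
            continue
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
        lda.fit(Xtr, ytr)
        correct = 0
        for b in te:
            proba = lda.predict_proba(X[b])  # (nc trials, nc classes)
            pred_trial = int(np.argmax(proba[:, zero_class]))
            correct += pred_trial == zero_class
        rows.append({"repeat": rep, "t0": dataset.t0,
                     "accuracy": correct / len(te), "n_test": len(te),
                     "skipped": False})
    return pd.DataFrame(rows)


def residual_activity(x_blocks: np.ndarray) -> np.ndarray:
    """Deviation of each block's activity from the across-block mean.

    ``x_blocks`` is (blocks, ...) at fixed relative trial; residuals sum to
    zero across blocks at every remaining coordinate.
    """
    x = np.asarray(x_blocks, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 blocks for residuals")
    return x - x.mean(axis=0, keepdims=True)


def residual_slope(
    aligned_rev: AlignedSubspaceActivity,
    aligned_choice: AlignedSubspaceActivity,
    window: tuple[float, float] = (0.0, 500.0),
) -> pd.DataFrame:
    """OLS slope of choice residuals on reversal-probability residuals.

    Per relative trial, each block's residual activity is time-averaged over
    ``window`` (ms on the aligned axis), and the slope of the choice
    residual against the reversal-probability residual is fit across blocks
    (closed form cov/var). Zero-variance regressors yield NaN.
    """
    t = aligned_rev.time_axis
    sel = (t >= window[0]) & (t <= window[1])
    rows = []
    for j, rel in enumerate(aligned_rev.rel_trials):
        ok = aligned_rev.valid[:, j] & aligned_choice.valid[:, j]
        if ok.sum() < 3:
            rows.append({"rel_trial": int(rel), "slope": np.nan,
                         "stderr": np.nan, "n_blocks": int(ok.sum())})
            continue
        xr = aligned_rev.x[ok, j][:, sel].mean(axis=1)
        xc = aligned_choice.x[ok, j][:, sel].mean(axis=1)
        xr_res = xr - xr.mean()
        xc_res = xc - xc.mean()
        var = float(np.dot(xr_res, xr_res))
        if var == 0:
            slope, se = np.nan, np.nan
        else:
            slope = float(np.dot(xr_res, xc_res)) / var
            resid = xc_res - slope * xr_res
            dof = max(1, ok.sum() - 2)
            se = float(np.sqrt(resid @ resid / dof / var))
        rows.append({"rel_trial": int(rel), "slope": slope,
                     "stderr": se, "n_blocks": int(ok.sum())})
    return pd.DataFrame(rows)
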