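"""Targeted dimensionality reduction (TDR) of population activity.

Per neuron and per time bin, activity is regressed across trials onto task
variables (ordinary least squares with an intercept). The coefficient
vectors across neurons form a time-indexed population vector per variable;
the task vector is taken at the time where its L2 norm across neurons peaks,
the set of task vectors is orthogonalized by QR (order preserving, reversal
probability first), and activity is projected onto the orthonormal vectors
to yield the task-variable activity x^v_t(k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityTensor",
    "TaskVectors",
    "bin_spike_counts",
    "regress_activity",
    "select_task_vector",
    "orthogonalize",
    "project",
]


@dataclass
class ActivityTensor:
    """Population activity: ``values[neuron, time, trial]`` plus a trial table.

    ``time_axis`` holds bin centers in ms (trial-relative, strictly
    increasing); ``source`` records whether values are RNN firing rates or
    binned spike counts. ``trial_table`` carries the per-trial task variables
    (one row per trial, aligned with the last axis).
    """

    values: np.ndarray
    time_axis: np.ndarray
    source: str = "rnn_rates"
    trial_table: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (neurons, time, trials)")
        if len(self.time_axis) != self.values.shape[1]:
            raise ValueError("time_axis length must match the time dimension")
        if np.any(np.diff(self.time_axis) <= 0):
            raise ValueError("time_axis must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity tensor contains non-finite values")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]


@dataclass
class TaskVectors:
    """Raw regression coefficients and orthogonalized task vectors.

    ``coef[neuron, time, variable]`` are the OLS coefficients; ``t_max`` maps
    each variable to the time-bin index of its maximal population-vector
    norm; ``raw`` and ``ortho`` are (neurons x variables) matrices of the
    selected vectors before/after QR orthogonalization, in the configured
    variable order (reversal probability first by convention).
    """

    variables: list[str]
    coef: np.ndarray
    bias: np.ndarray
    t_max: dict[str, int]
    raw: np.ndarray
    ortho: np.ndarray
    zscored: bool = True

    def vector(self, variable: str, orthogonal: bool = True) -> np.ndarray:
        j = self.variables.index(variable)
        return (self.ortho if orthogonal else self.raw)[:, j]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, v in enumerate(self.variables):
            for i in range(self.raw.shape[0]):
                rows.append(
                    {"neuron": i, "variable": v,
                     "weight_raw": self.raw[i, j], "weight_ortho": self.ortho[i, j]}
                )
        return pd.DataFrame(rows)


def bin_spike_counts(
    spike_times: Sequence[Sequence[np.ndarray]],
    span: tuple[float, float],
    window: float = 300.0,
    step: float = 20.0,
) -> ActivityTensor:
    """Count spikes in a sliding window stepped along the trial.

    ``spike_times[i][k]`` holds the spike times (ms) of neuron ``i`` on trial
    ``k`` within ``span``. A ``window``-wide interval centered on each bin
    center is slid in ``step`` increments; bin centers run from
    ``span[0] + window/2`` to ``span[1] - window/2`` so every window lies
    inside the span.
    """
    lo, hi = span
    if hi - lo < window:
        raise ValueError("span shorter than one window")
    centers = np.arange(lo + window / 2, hi - window / 2 + step / 2, step)
    n_neurons = len(spike_times)
    n_trials = len(spike_times[0])
    out = np.zeros((n_neurons, len(centers), n_trials))
    for i in range(n_neurons):
        for k in range(n_trials):
            st = np.sort(np.asarray(spike_times[i][k], dtype=float))
            left = np.searchsorted(st, centers - window / 2, side="left")
            right = np.searchsorted(st, centers + window / 2, side="right")
            out[i, :, k] = right - left
    return ActivityTensor(values=out, time_axis=centers, source="spike_counts")


def _zscore_tensor(values: np.ndarray) -> np.ndarray:
    """Z-score each neuron over all (time, trial) samples; silent neurons stay 0."""
    mu = values.mean(axis=(1, 2), keepdims=True)
    sd = values.std(axis=(1, 2), keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mu) / sd


def regress_activity(
    tensor: ActivityTensor,
    regressors: pd.DataFrame,
    zscore: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """OLS of activity on task variables, per (neuron, time).

    ``regressors`` has one row per trial and one column per task variable.
    Returns ``(coef[neuron, time, variable], bias[neuron, time], variables)``.
    Activity is z-scored per neuron beforehand by default (switchable).
    Constant regressors (which would alias the intercept) and rank-deficient
    designs raise with the offending variables named.
    """
    variables = list(regressors.columns)
    Z = regressors.to_numpy(dtype=float)
    K, V = Z.shape
    if tensor.n_trials != K:
        raise ValueError("regressor table and tensor disagree on trial count")
    if K < V + 2:
        raise ValueError(f"need at least {V + 2} trials to fit {V} variables")
    const = [v for v, col in zip(variables, Z.T) if np.ptp(col) == 0]
    if const:
        raise ValueError(f"constant regressor(s) would alias the intercept: {const}")
    X = np.column_stack([Z, np.ones(K)])
    if np.linalg.matrix_rank(X) < V + 1:
        # identify collinear columns by rank-1 deflation
        bad = [
            v for j, v in enumerate(variables)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"rank-deficient design; collinear variables: {bad}")
    values = _zscore_tensor(tensor.values) if zscore else tensor.values
    N, M, _ = values.shape
    Y = values.reshape(N * M, K).T  # (K, N*M)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    coef = beta[:V].T.reshape(N, M, V)
    bias = beta[V].reshape(N, M)
    return coef, bias, variables


def select_task_vector(
    coef: np.ndarray, variables: Sequence[str], variable: str
) -> tuple[np.ndarray, int]:
    """Coefficient population vector at the time of maximal L2 norm.

    Ties in the norm resolve to the earliest time bin.
    """
    j = list(variables).index(variable)
    norms = np.linalg.norm(coef[:, :, j], axis=0)
    t_max = int(np.argmax(norms))  # first max -> earliest time
    return coef[:, t_max, j].copy(), t_max


def orthogonalize(
    coef: np.ndarray,
    bias: np.ndarray,
    variables: Sequence[str],
    order: Optional[Sequence[str]] = None,
    zscored: bool = True,
) -> TaskVectors:
    """Select per-variable max-norm vectors and orthogonalize them by QR.

    ``order`` fixes the QR column order (default: the regression order);
    by convention the reversal-probability vector comes first so it is
    preserved up to normalization. Near-dependent vector sets (condition
    number above 1e8) raise.
    """
    variables = list(variables)
    order = variables if order is None else list(order)
    raw = np.empty((coef.shape[0], len(order)))
    t_max: dict[str, int] = {}
    for j, v in enumerate(order):
        raw[:, j], t_max[v] = select_task_vector(coef, variables, v)
    if np.linalg.cond(raw) > 1e8:
        raise ValueError("task vectors are nearly linearly dependent")
    Q, R = np.linalg.qr(raw)
    # fix signs so each orthonormal vector correlates positively with its raw one
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    return TaskVectors(
        variables=order, coef=coef, bias=bias, t_max=t_max,
        raw=raw, ortho=Q, zscored=zscored,
    )


def project(tensor_or_values, vector: np.ndarray) -> np.ndarray:
    """Project population activity onto a task vector: x_t(k) = w . y_t(k).

    Accepts an ActivityTensor or a raw (neurons, time, trials) array and
    returns a (time, trials) matrix.
    """
    values = (
        tensor_or_values.values
        if isinstance(tensor_or_values, ActivityTensor)
        else np.asarray(tensor_or_values, dtype=float)
    )
    w = np.asarray(vector, dtype=float)
    if values.shape[0] != len(w):
        raise ValueError("vector length must equal the neuron count")
    return np.tensordot(w, values, axes=(0, 0))
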