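"""File-format contracts: HDF5 activity containers and CSV tables.

Activity tensors and network bundles round-trip through HDF5; tabular
outputs (block records, posteriors, task vectors, analysis tables) are tidy
CSV with fixed column schemas. Pipeline stages communicate only through
these files plus the resolved configuration written next to them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .rnn import RNNBundle, StimulusBank
from .tdr import ActivityTensor, TaskVectors

__all__ = [
    "save_activity",
    "load_activity",
    "save_bundle",
    "load_bundle",
    "posterior_to_frame",
    "task_vectors_to_csv",
]


def save_activity(path, tensor: ActivityTensor, readout: Optional[np.ndarray] = None) -> None:
    """Write an activity tensor (and optional readout traces) to HDF5.

    Datasets: ``rates[N, time, trials]``, ``time_axis``, optional
    ``readout[time, trials]``; the trial table is stored alongside as
    ``<path>.trials.csv``.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=tensor.values, compression="gzip")
        f.create_dataset("time_axis", data=tensor.time_axis)
        f.attrs["source"] = tensor.source
        if readout is not None:
            f.create_dataset("readout", data=readout)
    if tensor.trial_table is not None:
        tensor.trial_table.to_csv(path.with_suffix(path.suffix + ".trials.csv"), index=False)


def load_activity(path) -> tuple[ActivityTensor, Optional[np.ndarray]]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        values = f["rates"][...]
        time_axis = f["time_axis"][...]
        source = f.attrs.get("source", "rnn_rates")
        readout = f["readout"][...] if "readout" in f else None
    trials_csv = path.with_suffix(path.suffix + ".trials.csv")
    table = pd.read_csv(trials_csv) if trials_csv.exists() else None
    return ActivityTensor(values=values, time_axis=time_axis, source=str(source),
                          trial_table=table), readout


def save_bundle(path, bundle: RNNBundle, stimuli: Optional[StimulusBank] = None,
                seed: Optional[int] = None, extra: Optional[dict] = None) -> None:
    """Serialize network parameters (and the frozen stimulus bank) for reload."""
    with h5py.File(path, "w") as f:
        f.create_dataset("W_rec", data=bundle.W_rec)
        f.create_dataset("w_out", data=bundle.w_out)
        if bundle.mask is not None:
            f.create_dataset("mask", data=bundle.mask)
        f.attrs["tau"] = bundle.tau
        f.attrs["act_a"] = bundle.act_a
        f.attrs["act_b"] = bundle.act_b
        if seed is not None:
            f.attrs["seed"] = seed
        if extra:
            f.attrs["extra"] = json.dumps(extra, default=float)
        if stimuli is not None:
            g = f.create_group("stimuli")
            g.create_dataset("I_base", data=stimuli.I_base)
            g.create_dataset("I_cue", data=stimuli.I_cue)
            for k, v in stimuli.I_feedback.items():
                g.create_dataset(f"I_feedback_{k}", data=v)


def load_bundle(path) -> tuple[RNNBundle, Optional[StimulusBank]]:
    with h5py.File(path, "r") as f:
        bundle = RNNBundle(
            W_rec=f["W_rec"][...],
            w_out=f["w_out"][...],
            tau=float(f.attrs["tau"]),
            act_a=float(f.attrs["act_a"]),
            act_b=float(f.attrs["act_b"]),
            mask=f["mask"][...] if "mask" in f else None,
        )
        stimuli = None
        if "stimuli" in f:
            g = f["stimuli"]
            stimuli = StimulusBank(
                I_base=g["I_base"][...],
                I_cue=g["I_cue"][...],
                I_feedback={
                    k.removeprefix("I_feedback_"): g[k][...]
                    for k in g if k.startswith("I_feedback_")
                },
            )
    return bundle, stimuli


def posterior_to_frame(tables) -> pd.DataFrame:
    """Tidy frame (t, r, prob, model) from PosteriorTable objects."""
    rows = []
    for tab in tables:
        for r, prob in enumerate(tab.probs, start=1):
            rows.append({"t": tab.upto_trial, "r": r, "prob": prob, "model": tab.model})
    return pd.DataFrame(rows)


def task_vectors_to_csv(path, tv: TaskVectors) -> None:
    """Task vectors as CSV plus a JSON sidecar with t_max/order/z-scoring."""
    path = Path(path)
    tv.to_frame().to_csv(path, index=False)
    sidecar = {
        "order": tv.variables,
        "t_max": {k: int(v) for k, v in tv.t_max.items()},
        "zscored": tv.zscored,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
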