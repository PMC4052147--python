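"""Plain-text I/O: spike event tables, kinematics, counts and model files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .binning import SpikeTrainSet, bin_spikes
from .tuning import KinematicSeries

__all__ = [
    "write_spikes_tsv",
    "read_spikes_tsv",
    "write_kinematics_tsv",
    "read_kinematics_tsv",
    "write_counts_tsv",
]

_KIN_COLS = ["pos_x", "pos_y", "vel_x", "vel_y", "acc_x", "acc_y"]


def write_spikes_tsv(path, spikes: SpikeTrainSet) -> None:
    """Event table with columns neuron_id (0-based) and time_s."""
    ids = np.concatenate(
        [np.full(t.size, j, dtype=int) for j, t in enumerate(spikes.spike_times)]
    ) if any(t.size for t in spikes.spike_times) else np.empty(0, dtype=int)
    times = np.concatenate([t for t in spikes.spike_times]) if ids.size else np.empty(0)
    df = pd.DataFrame({"neuron_id": ids, "time_s": times})
    df.sort_values(["neuron_id", "time_s"], inplace=True, kind="mergesort")
    with open(path, "w") as fh:
        fh.write(f"# bin_width_s={spikes.bin_width!r}\tduration_s={spikes.duration!r}"
                 f"\tn_neurons={spikes.n_neurons}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_spikes_tsv(path) -> SpikeTrainSet:
    header = Path(path).open().readline()
    meta = dict(kv.split("=") for kv in header.lstrip("# ").strip().split("\t"))
    dt = float(meta["bin_width_s"])
    T = float(meta["duration_s"])
    C = int(meta["n_neurons"])
    df = pd.read_csv(path, sep="\t", comment="#")
    per_neuron = [
        np.sort(df.loc[df["neuron_id"] == j, "time_s"].to_numpy()) for j in range(C)
    ]
    return bin_spikes(per_neuron, dt, T)


def write_kinematics_tsv(path, kin: KinematicSeries) -> None:
    df = pd.DataFrame(kin.x, columns=_KIN_COLS)
    df.insert(0, "t", kin.t)
    df.to_csv(path, sep="\t", index=False, float_format="%.8f")


def read_kinematics_tsv(path) -> KinematicSeries:
    df = pd.read_csv(path, sep="\t")
    return KinematicSeries(
        t=df["t"].to_numpy(), x=df[_KIN_COLS].to_numpy()
    )


def write_counts_tsv(path, spikes: SpikeTrainSet) -> None:
    """Binned count matrix with a one-line header recording Δ and T."""
    with open(path, "w") as fh:
        fh.write(f"# bin_width_s={spikes.bin_width!r}\tduration_s={spikes.duration!r}\n")
        np.savetxt(fh, spikes.counts, fmt="%d", delimiter="\t")
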