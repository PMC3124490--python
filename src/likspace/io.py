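"""Plain-text formats for spike trains, intensities, projections, and configs.

Everything is delimited text (CSV) or YAML so datasets survive version
control and diffing; an adapter layer for binary electrophysiology formats is
an extension point, not a dependency.  Formats:

* spike table — one row per spike: ``trial_id, neuron_id, stimulus_id,
  spike_time_s`` (lossless round-trip; times kept to full float precision);
* intensity table — ``bin_start_s, lambda_hz``;
* likelihood-vector table — ``trial_id, true_stimulus, coord_1..coord_P``;
* dissimilarity matrix — square CSV with header labels;
* population recording — ``time_s, neuron_id``;
* run config — YAML mapping.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import IntensityModel, SpikeTrain
from .geometry import DissimilarityMatrix
from .population import PopulationRecording

__all__ = [
    "write_spike_table",
    "read_spike_table",
    "trains_to_frame",
    "frame_to_trains",
    "write_intensity_table",
    "read_intensity_table",
    "write_likelihood_table",
    "read_likelihood_table",
    "write_dissimilarity",
    "read_dissimilarity",
    "write_population_recording",
    "read_population_recording",
    "write_config",
    "read_config",
]

SPIKE_COLUMNS = ["trial_id", "neuron_id", "stimulus_id", "spike_time_s"]


def trains_to_frame(trains, interval=None) -> pd.DataFrame:
    """Flatten spike trains into the one-row-per-spike table."""
    rows = []
    for tr in trains:
        for t in tr.times:
            rows.append(
                {
                    "trial_id": tr.trial_id,
                    "neuron_id": tr.neuron_id,
                    "stimulus_id": tr.stimulus_id,
                    "spike_time_s": t,
                }
            )
    return pd.DataFrame(rows, columns=SPIKE_COLUMNS)


def frame_to_trains(df: pd.DataFrame, interval: tuple[float, float]) -> list:
    """Group a spike table into SpikeTrain objects on a common interval.

    One train per (trial_id, neuron_id, stimulus_id) combination; trains with
    zero spikes in the table are necessarily absent (the format has no row
    for them).
    """
    trains = []
    for (trial, neuron, stim), g in df.groupby(
        ["trial_id", "neuron_id", "stimulus_id"], sort=True, dropna=False
    ):
        trains.append(
            SpikeTrain(
                times=np.sort(g["spike_time_s"].to_numpy(dtype=float)),
                interval=interval,
                neuron_id=neuron,
                trial_id=trial,
                stimulus_id=stim,
            )
        )
    return trains


def write_spike_table(trains_or_frame, path) -> None:
    df = (
        trains_or_frame
        if isinstance(trains_or_frame, pd.DataFrame)
        else trains_to_frame(trains_or_frame)
    )
    df.to_csv(path, index=False)


def read_spike_table(path) -> pd.DataFrame:
    """Read and validate a spike table; errors name the offending line."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty; returning an empty table", stacklevel=2)
        return pd.DataFrame(columns=SPIKE_COLUMNS)
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        warnings.warn(f"{path} holds no spikes", stacklevel=2)
        return df[SPIKE_COLUMNS]
    times = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = times.isna()
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: malformed spike_time_s at line {line}")
    df = df.copy()
    df["spike_time_s"] = times
    return df[SPIKE_COLUMNS]


def write_intensity_table(model: IntensityModel, path) -> None:
    t0 = model.t_start
    df = pd.DataFrame(
        {
            "bin_start_s": t0 + np.arange(model.J) * model.delta,
            "lambda_hz": model.lambda_per_bin,
        }
    )
    df.to_csv(path, index=False)


def read_intensity_table(path) -> IntensityModel:
    df = pd.read_csv(path)
    starts = df["bin_start_s"].to_numpy(dtype=float)
    lam = df["lambda_hz"].to_numpy(dtype=float)
    if len(starts) < 2:
        raise ValueError(f"{path}: need at least two bins to infer delta")
    deltas = np.diff(starts)
    delta = float(deltas[0])
    if not np.allclose(deltas, delta, rtol=1e-6):
        raise ValueError(f"{path}: bins are not uniformly spaced")
    return IntensityModel(
        lambda_per_bin=lam,
        delta=delta,
        interval=(float(starts[0]), float(starts[0] + len(lam) * delta)),
    )


def write_likelihood_table(coords: np.ndarray, path, trial_ids=None, true_stimuli=None):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    m, p = coords.shape
    df = pd.DataFrame(coords, columns=[f"coord_{i + 1}" for i in range(p)])
    df.insert(0, "true_stimulus", true_stimuli if true_stimuli is not None else [None] * m)
    df.insert(0, "trial_id", trial_ids if trial_ids is not None else np.arange(m))
    df.to_csv(path, index=False)


def read_likelihood_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_dissimilarity(d: DissimilarityMatrix, path) -> None:
    pd.DataFrame(d.matrix, index=list(d.labels), columns=list(d.labels)).to_csv(path)


def read_dissimilarity(path) -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return DissimilarityMatrix(df.to_numpy(dtype=float), labels=tuple(df.columns))


def write_population_recording(rec: PopulationRecording, path) -> None:
    pd.DataFrame({"time_s": rec.times, "neuron_id": rec.marks}).to_csv(path, index=False)


def read_population_recording(
    path, n_neurons: int, interval: tuple[float, float]
) -> PopulationRecording:
    df = pd.read_csv(path)
    return PopulationRecording(
        times=df["time_s"].to_numpy(dtype=float),
        marks=df["neuron_id"].to_numpy(dtype=int),
        n_neurons=n_neurons,
        interval=interval,
    )


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}
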