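"""File formats: estimate tables (CSV), the epochs container (HDF5), and
continuous-EEG ingestion from EDF+/BrainVision via MNE."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet
from .montage import CHANNELS_30

ESTIMATE_COLUMNS = ["participant", "block", "condition", "numerosity",
                    "hemifield", "estimate"]


def write_estimates(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=ESTIMATE_COLUMNS)


def read_estimates(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(ESTIMATE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"estimate table missing columns: {sorted(missing)}")
    return table


# --------------------------------------------------------------------------
# epochs container
# --------------------------------------------------------------------------
# Layout (one file per participant x condition):
#   /data          float64 (n_trials, n_channels, n_times)  [microvolts]
#   /time_ms       float64 (n_times,)
#   /channel_names UTF-8 strings (n_channels,)
#   /channel_positions float64 (n_channels, 3)   [optional]
#   attrs: fs, condition, participant

def write_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time_ms", data=epochs.time_ms)
        f.create_dataset("channel_names",
                         data=np.array(epochs.channel_names, dtype="S16"))
        if epochs.channel_positions is not None:
            f.create_dataset("channel_positions", data=epochs.channel_positions)
        f.attrs["fs"] = epochs.fs
        f.attrs["condition"] = epochs.condition
        f.attrs["participant"] = str(epochs.participant)


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        names = tuple(n.decode() for n in f["channel_names"][()])
        pos = f["channel_positions"][()] if "channel_positions" in f else None
        return EpochSet(
            data=f["data"][()], fs=float(f.attrs["fs"]),
            time_ms=f["time_ms"][()], channel_names=names,
            channel_positions=pos,
            condition=str(f.attrs.get("condition", "")),
            participant=str(f.attrs.get("participant", "")),
        )


def validate_container(path) -> list:
    """Check a stored epochs file against the container invariants.

    Returns a list of violation strings (empty when the file is valid);
    I/O-level failures propagate as exceptions.
    """
    problems = []
    with h5py.File(path, "r") as f:
        for ds in ("data", "time_ms", "channel_names"):
            if ds not in f:
                problems.append(f"missing dataset {ds!r}")
        if problems:
            return problems
        data = f["data"]
        time_ms = f["time_ms"][()]
        names = [n.decode() for n in f["channel_names"][()]]
        if data.ndim != 3:
            problems.append(f"data must be 3D (trials x channels x time), "
                            f"got {data.ndim}D")
        else:
            if data.shape[1] != len(names):
                problems.append(f"channel axis {data.shape[1]} != "
                                f"{len(names)} channel names")
            if data.shape[2] != time_ms.size:
                problems.append(f"time axis {data.shape[2]} != "
                                f"{time_ms.size} time points")
        if len(set(names)) != len(names):
            problems.append("duplicate channel names")
        unknown = [n for n in names if n not in CHANNELS_30]
        if unknown:
            problems.append(f"channels outside the 30-channel montage: {unknown}")
        if "fs" not in f.attrs:
            problems.append("missing fs attribute")
        else:
            fs = float(f.attrs["fs"])
            if time_ms.size > 1 and not np.allclose(np.diff(time_ms),
                                                    1000.0 / fs, atol=1e-6):
                problems.append("time axis not uniform at 1/fs")
    return problems


# --------------------------------------------------------------------------
# continuous EEG readers
# --------------------------------------------------------------------------

def read_continuous(path):
    """Read continuous EEG from EDF+ (.edf) or BrainVision (.vhdr).

    Returns (data_uV (n_channels, n_samples), fs, channel_names).
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="ERROR")
    else:
        raise ValueError(f"unsupported continuous format: {path.suffix}")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


def read_events(path) -> pd.DataFrame:
    """Event table CSV with columns sample, condition."""
    events = pd.read_csv(path)
    missing = {"sample", "condition"} - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return events
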