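"""Reading and writing the on-disk formats: LFP HDF5 container and events TSV.

HDF5 layout::

    /data           float32, channels x samples
    /fs             scalar
    /channels/name, /channels/site, /channels/hemisphere, /channels/contact
    /artifact_mask  bool, per sample

Events TSV columns (BIDS-events-like): trial_index, block, onset_go_ms,
trial_kind {go, stop}, ssd_ms (empty for go trials), staircase_ssd_ms,
rt_ms (empty for omissions / successful stops), hand {left, right},
pressed (side pressed, empty when no press), outcome.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from burstpipe.containers import LfpRecording

EVENTS_COLUMNS = [
    "trial_index",
    "block",
    "onset_go_ms",
    "trial_kind",
    "ssd_ms",
    "staircase_ssd_ms",
    "rt_ms",
    "hand",
    "pressed",
    "outcome",
]


def save_lfp_h5(rec: LfpRecording, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype(np.float32))
        f.create_dataset("fs", data=float(rec.fs))
        g = f.create_group("channels")
        for col in ("name", "site", "hemisphere"):
            g.create_dataset(
                col, data=np.asarray(rec.channels[col].astype(str).tolist(), dtype="S")
            )
        g.create_dataset("contact", data=rec.channels["contact"].to_numpy(dtype=int))
        f.create_dataset("artifact_mask", data=rec.artifact_mask)


def load_lfp_h5(path) -> LfpRecording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f["fs"][()])
        ch = pd.DataFrame(
            {
                "name": [s.decode() for s in f["channels/name"][()]],
                "site": [s.decode() for s in f["channels/site"][()]],
                "hemisphere": [s.decode() for s in f["channels/hemisphere"][()]],
                "contact": f["channels/contact"][()],
            }
        )
        mask = f["artifact_mask"][()].astype(bool)
    return LfpRecording(data=data, fs=fs, channels=ch, artifact_mask=mask)


def save_events_tsv(trials: pd.DataFrame, path) -> None:
    cols = [c for c in EVENTS_COLUMNS if c in trials.columns]
    trials[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"trial_kind": str, "hand": str, "pressed": str, "outcome": str},
    )
    for col in ("pressed", "outcome"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df
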