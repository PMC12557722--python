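"""Reading and writing photon streams and tabular stage outputs.

Photon streams are stored in a Photon-HDF5-style HDF5 layout
(``photon_data/timestamps``, ``photon_data/detectors``,
``photon_data/timestamps_specs/timestamps_unit``, plus ``setup`` and
optional ground-truth groups), written directly with h5py.  Detector codes
follow the three-channel enumeration of :mod:`alexfret.simkit`.  Tables
(bursts, BVA, state models) are exchanged as TSV / JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simkit import PhotonStream


def write_photon_hdf5(stream: PhotonStream, path, metadata: dict | None = None):
    """Write a :class:`PhotonStream` to a Photon-HDF5-style file."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=stream.timestamps, dtype=np.int64)
        g.create_dataset("detectors", data=stream.channels, dtype=np.int8)
        spec = g.create_group("timestamps_specs")
        spec.create_dataset("timestamps_unit", data=stream.clock_period_s)
        setup = f.create_group("setup")
        setup.create_dataset("num_spectral_ch", data=2)
        setup.create_dataset("alex", data=True)
        f.create_dataset("acquisition_duration", data=stream.duration_s)
        if stream.truth_state is not None:
            f.create_dataset(
                "ground_truth/state", data=stream.truth_state, dtype=np.int64
            )
        if stream.truth_bursts is not None:
            tg = f.create_group("ground_truth/bursts")
            tb = stream.truth_bursts
            tg.create_dataset(
                "species",
                data=np.array([s.encode() for s in tb["species"]], dtype="S8"),
            )
            for col in ("start_s", "stop_s", "n_photons"):
                tg.create_dataset(col, data=tb[col].to_numpy())
        if metadata:
            f.attrs["metadata_json"] = json.dumps(metadata, sort_keys=True)
    return path


def read_photon_hdf5(path) -> PhotonStream:
    """Read a stream previously written by :func:`write_photon_hdf5`."""
    with h5py.File(path, "r") as f:
        ts = f["photon_data/timestamps"][()]
        det = f["photon_data/detectors"][()]
        unit = float(f["photon_data/timestamps_specs/timestamps_unit"][()])
        dur = float(f["acquisition_duration"][()])
        truth = None
        tb = None
        if "ground_truth" in f:
            if "state" in f["ground_truth"]:
                truth = f["ground_truth/state"][()]
            if "bursts" in f["ground_truth"]:
                g = f["ground_truth/bursts"]
                tb = pd.DataFrame(
                    {
                        "species": [s.decode() for s in g["species"][()]],
                        "start_s": g["start_s"][()],
                        "stop_s": g["stop_s"][()],
                        "n_photons": g["n_photons"][()],
                    }
                )
    return PhotonStream(
        timestamps=ts,
        channels=det,
        clock_period_s=unit,
        duration_s=dur,
        truth_state=truth,
        truth_bursts=tb,
    )


def write_stream_tsv(stream: PhotonStream, path):
    """Plain-text debug dump: one photon per line (tick, channel[, truth])."""
    df = pd.DataFrame(
        {"timestamp_tick": stream.timestamps, "channel": stream.channels}
    )
    if stream.truth_state is not None:
        df["truth_state"] = stream.truth_state
    df.to_csv(path, sep="\t", index=False)
    return path


def write_table(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonify)
    return path


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
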