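"""Plain-text readers and writers for every exchange format.

Point clouds are ``x y z`` triples (mm, ``#`` comments allowed); montages
use an sfp-like ``NAME x y z`` dialect; signals are CSV with a leading
``time_ms`` column; spike trains are two-column ``channel time_ms`` text;
weight snapshots are sparse ``i j w`` triplets with hex-float weights so a
round-trip is bitwise exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .encoding import ContinuousSignal, SpikeTrain
from .errors import ValidationError
from .geometry import ElectrodeMontage, HeadPointCloud
from .plasticity import WeightMatrix


def read_point_cloud(path, source_tag=None):
    pts = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValidationError(f"expected 'x y z', got {line!r}")
            pts.append([float(x) for x in parts])
    return HeadPointCloud(np.array(pts), source_tag or str(path))


def write_point_cloud(path, cloud):
    with open(path, "w") as fh:
        fh.write(f"# {cloud.source_tag}\n")
        for x, y, z in cloud.points:
            fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_montage(path):
    names, pos = [], []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValidationError(f"expected 'NAME x y z', got {line!r}")
            names.append(parts[0])
            pos.append([float(x) for x in parts[1:]])
    return ElectrodeMontage(names, np.array(pos))


def write_montage(path, montage):
    with open(path, "w") as fh:
        for name, (x, y, z) in zip(montage.names, montage.positions):
            fh.write(f"{name} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def write_layout(path, layout):
    df = pd.DataFrame({
        "id": np.arange(layout.n_neurons),
        "x": layout.positions[:, 0],
        "y": layout.positions[:, 1],
        "z": layout.positions[:, 2],
        "role": ["hidden"] * layout.n_neurons,
        "channel": [""] * layout.n_neurons,
        "inhibitory": layout.is_inhibitory,
    })
    for name, nid in layout.observed_index.items():
        df.loc[nid, "role"] = "observed"
        df.loc[nid, "channel"] = name
    df.to_csv(path, index=False)
    return df


def read_signal_csv(path, ts_ms=None):
    df = pd.read_csv(path)
    if df.columns[0] != "time_ms":
        raise ValidationError("first column must be time_ms")
    t = df["time_ms"].to_numpy(dtype=float)
    if ts_ms is None:
        ts_ms = float(np.median(np.diff(t))) if t.size > 1 else 8.0
    return ContinuousSignal(df.iloc[:, 1:].to_numpy(dtype=float), ts_ms,
                            list(df.columns[1:]))


def write_signal_csv(path, signal):
    df = pd.DataFrame(signal.values, columns=signal.channel_names)
    df.insert(0, "time_ms", signal.times_ms)
    df.to_csv(path, index=False)


def read_spike_trains(path):
    trains = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            name, t = line.split()
            trains.setdefault(name, []).append(float(t))
    return SpikeTrain({k: np.sort(np.asarray(v)) for k, v in trains.items()})


def write_spike_trains(path, spikes):
    with open(path, "w") as fh:
        fh.write("# channel time_ms\n")
        for name, times in spikes.spike_times.items():
            for t in times:
                fh.write(f"{name} {float(t)!r}\n")


def write_weights(path, W, step=-1, mode=""):
    """Sparse triplet dump; hex floats give a bitwise-exact round-trip."""
    with open(path, "w") as fh:
        fh.write(f"# n={W.n} step={step} mode={mode}\n")
        ii, jj = np.nonzero(W.mask)
        for i, j in zip(ii, jj):
            fh.write(f"{i} {j} {float(W.values[i, j]).hex()}\n")


def read_weights(path):
    n = None
    entries = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("n="):
                        n = int(tok[2:])
                continue
            i, j, w = line.split()
            entries.append((int(i), int(j), float.fromhex(w)))
    if n is None:
        raise ValidationError("weight file lacks an n= header")
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i, j, w in entries:
        values[i, j] = w
        mask[i, j] = True
    return WeightMatrix(values, mask)


def read_edf(path):
    """Multichannel EEG from an EDF file (requires the optional mne extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires mne (pip install mrisnn[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    ts_ms = 1000.0 / raw.info["sfreq"]
    return ContinuousSignal(raw.get_data().T * 1e3, ts_ms, list(raw.ch_names))
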