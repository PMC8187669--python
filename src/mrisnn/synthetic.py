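"""Synthetic fixtures: head geometry, montages, EEG-like signals, spikes.

These generators emulate the statistical structure the method relies on —
a head-shaped candidate volume, electrodes at standard scalp positions, and
multichannel signals that share a small number of latent oscillatory
sources (so reconstructing an unrecorded channel from its neighbours is
possible in principle).  They make no claim of physiological realism (no
1/f background, no forward head model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import ContinuousSignal, SpikeTrain
from .errors import ValidationError
from .geometry import ElectrodeMontage, HeadPointCloud

#: channels examined in the first recording of the study protocol
CASE1_CHANNELS = ["PO7", "M2", "P9", "Oz", "Pz", "Fz", "Cz", "F8", "F7",
                  "A2", "A1", "T4", "T3", "T5", "T6"]
#: channels examined in the second recording
CASE2_CHANNELS = ["A1", "A2", "O1", "O2", "T3", "T4", "T5", "T6", "P3",
                  "Pz", "P4", "C3", "Cz", "C4", "F8"]
#: standard positions used as unmonitored (virtual) read-out locations
VIRTUAL_CHANNELS = ["O2", "O1", "P4", "P3", "C4", "C3", "F3", "F4", "Fp1", "Fp2"]

MONTAGE_PRESETS = {"case1": CASE1_CHANNELS, "case2": CASE2_CHANNELS,
                   "virtual": VIRTUAL_CHANNELS}


def _unit(incl_deg, az_deg):
    """Unit vector at inclination from vertex and azimuth from nasion.

    x points right, y to the nasion (front), z up; positive azimuth turns
    toward +x.
    """
    th = np.deg2rad(incl_deg)
    ph = np.deg2rad(az_deg)
    return np.array([np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)])


def _slerp(p, q, t):
    p = p / np.linalg.norm(p)
    q = q / np.linalg.norm(q)
    ang = np.arccos(np.clip(p @ q, -1.0, 1.0))
    if ang == 0:
        return p
    return (np.sin((1 - t) * ang) * p + np.sin(t * ang) * q) / np.sin(ang)


def _build_unit_positions():
    """Idealised spherical 10-20/10-10 positions (unit sphere).

    Midline electrodes sit on the nasion-inion arc at 10% (18 deg) steps;
    the outer ring at 72 deg inclination carries Fp1/2 ... O1/2 at 36 deg
    azimuth steps (18 deg for the 10-10 intermediates such as PO7); interior
    electrodes are great-circle midpoints of their meridian neighbours
    (e.g. C3 midway Cz-T3).  P9/P10 sit one 10% step below P7/P8; earlobe
    (A) and mastoid (M) references are idealised just below the ear.
    """
    pos = {}
    midline = {"Fpz": -72, "AFz": -54, "Fz": -36, "FCz": -18, "Cz": 0,
               "CPz": 18, "Pz": 36, "POz": 54, "Oz": 72}
    for name, back in midline.items():
        pos[name] = _unit(abs(back), 0.0 if back <= 0 else 180.0)
    # outer (10%) ring: azimuth from nasion, negative = left hemisphere
    ring = {"Fp1": -18, "AF7": -36, "F7": -54, "FT7": -72, "T3": -90,
            "TP7": -108, "T5": -126, "PO7": -144, "O1": -162}
    for name, az in ring.items():
        pos[name] = _unit(72.0, az)
        right = {"Fp1": "Fp2", "AF7": "AF8", "F7": "F8", "FT7": "FT8",
                 "T3": "T4", "TP7": "TP8", "T5": "T6", "PO7": "PO8",
                 "O1": "O2"}[name]
        pos[right] = _unit(72.0, -az)
    # interior 10-20 electrodes: arc midpoints
    for mid, out, name in [("Cz", "T3", "C3"), ("Cz", "T4", "C4"),
                           ("Fz", "F7", "F3"), ("Fz", "F8", "F4"),
                           ("Pz", "T5", "P3"), ("Pz", "T6", "P4"),
                           ("POz", "PO7", "PO3"), ("POz", "PO8", "PO4")]:
        pos[name] = _slerp(pos[mid], pos[out], 0.5)
    # below the ring: P9/P10 one 10% step (18 deg) further down from P7/P8
    pos["P9"] = _unit(90.0, -126.0)
    pos["P10"] = _unit(90.0, 126.0)
    # idealised earlobes and mastoids (below the ear line)
    pos["A1"] = _unit(100.0, -90.0)
    pos["A2"] = _unit(100.0, 90.0)
    pos["M1"] = _unit(100.0, -108.0)
    pos["M2"] = _unit(100.0, 108.0)
    return pos


_UNIT_POSITIONS = _build_unit_positions()
#: modern 10-10 aliases for the classical temporal labels
LABEL_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}


def gen_montage_1020(subset="case1", head_radius=85.0):
    """Standard spherical 10-20/10-10 electrode positions scaled to a head.

    ``subset`` is a preset name (``case1``, ``case2``, ``virtual``) or an
    explicit list of labels.  Unknown labels raise.
    """
    if isinstance(subset, str):
        try:
            names = MONTAGE_PRESETS[subset]
        except KeyError:
            raise ValidationError(f"unknown montage preset {subset!r}") from None
    else:
        names = list(subset)
    positions = []
    for name in names:
        key = LABEL_ALIASES.get(name, name)
        if key not in _UNIT_POSITIONS:
            raise ValidationError(f"unknown 10-20/10-10 label {name!r}")
        positions.append(_UNIT_POSITIONS[key] * head_radius)
    return ElectrodeMontage(list(names), np.array(positions))


def gen_head_cloud(n_points, shape="sphere", radius=85.0, seed=0, axes=None):
    """Quasi-uniform candidate positions filling a sphere or ellipsoid.

    Concentric Fibonacci-sphere shells with shell counts proportional to
    the shell surface give near-constant nearest-neighbour spacing; the
    construction is deterministic (the seed is accepted for interface
    uniformity).
    """
    if n_points < 50:
        raise ValidationError("need at least 50 points")
    if shape not in ("sphere", "ellipsoid"):
        raise ValidationError("shape must be 'sphere' or 'ellipsoid'")
    if axes is None:
        axes = (1.0, 1.0, 1.0) if shape == "sphere" else (1.0, 1.2, 0.9)
    n_shells = max(1, int(round((3.0 * n_points / (4.0 * np.pi)) ** (1.0 / 3.0))))
    weights = np.arange(1, n_shells + 1) ** 2
    counts = np.maximum(1, np.round(n_points * weights / weights.sum()).astype(int))
    while counts.sum() != n_points:  # fix rounding drift on the outer shell
        counts[-1] += 1 if counts.sum() < n_points else -1
    golden = np.pi * (3.0 - np.sqrt(5.0))
    pts = []
    for k, m in enumerate(counts, start=1):
        r = radius * k / n_shells
        i = np.arange(m)
        z = 1.0 - 2.0 * (i + 0.5) / m
        rho = np.sqrt(np.maximum(0.0, 1.0 - z ** 2))
        # offset successive shells so points do not stack along one meridian
        phi = golden * i + 2.0 * np.pi * k / n_shells
        pts.append(r * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z]))
    points = np.vstack(pts) * np.asarray(axes)[None, :]
    return HeadPointCloud(points, source_tag=f"synthetic-{shape}-r{radius:g}")


@dataclass
class SyntheticEEGSpec:
    """Low-rank oscillatory multichannel signal specification.

    Channels are linear mixtures of ``n_sources`` latent sources, each a sum
    of sinusoidal band components with random phases, plus white noise.
    Defaults follow the study conditions: 15 channels, 500 samples at 8 ms,
    alpha (10 Hz, amplitude 1.0) and beta (20 Hz, amplitude 0.5) components,
    two shared sources, noise SD 0.1.
    """

    n_channels: int = 15
    n_samples: int = 500
    ts_ms: float = 8.0
    bands: list = field(default_factory=lambda: [(10.0, 1.0), (20.0, 0.5)])
    n_sources: int = 2
    mixing: np.ndarray = None  # channels x sources; random if None
    noise_sd: float = 0.1
    seed: int = 0
    channel_names: list = None

    def __post_init__(self):
        nyq = 500.0 / self.ts_ms
        for f, _ in self.bands:
            if f >= nyq:
                raise ValidationError(f"band {f} Hz is at/above Nyquist {nyq} Hz")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=float)
            if not np.all(np.isfinite(self.mixing)):
                raise ValidationError("mixing must be finite")
            if self.mixing.shape != (self.n_channels, self.n_sources):
                raise ValidationError("mixing must be (n_channels, n_sources)")


def gen_synthetic_eeg(spec):
    """Generate the signal; returns (signal, sources, mixing)."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_samples) * spec.ts_ms / 1000.0
    sources = np.zeros((spec.n_samples, spec.n_sources))
    for s in range(spec.n_sources):
        for f, amp in spec.bands:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            sources[:, s] += amp * np.sin(2.0 * np.pi * f * t + phase)
    mixing = spec.mixing
    if mixing is None:
        mixing = rng.normal(0.0, 1.0, size=(spec.n_channels, spec.n_sources))
        mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
    values = sources @ mixing.T
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    sig = ContinuousSignal(values, spec.ts_ms, spec.channel_names)
    return sig, sources, mixing


def spatial_mixing(montage, source_positions, length_scale=80.0):
    """Distance-decaying source-to-channel gains.

    Gain of source s at electrode p is exp(-|p - q_s|^2 / (2 L^2)): nearby
    electrodes receive correlated signals, which is the structure that makes
    unmonitored-channel reconstruction meaningful.
    """
    q = np.asarray(source_positions, dtype=float)
    d2 = ((montage.positions[:, None, :] - q[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * length_scale ** 2))


def gen_spike_fixture(n_channels, rate_hz, duration_ms, seed=0):
    """Homogeneous Poisson spike trains per channel."""
    if rate_hz <= 0:
        raise ValidationError("rate must be positive")
    rng = np.random.default_rng(seed)
    trains = {}
    for k in range(n_channels):
        n_exp = rate_hz * duration_ms / 1000.0
        n_spk = rng.poisson(n_exp)
        times = np.sort(rng.uniform(0.0, duration_ms, size=n_spk))
        times = np.unique(times)  # enforce strict increase
        trains[f"ch{k}"] = times
    return SpikeTrain(trains)
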