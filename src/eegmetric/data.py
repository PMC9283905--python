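"""Continuous EEG recordings: synthetic generation and MAT-dialect file I/O.

A :class:`Recording` is a continuous multichannel scalp EEG trace (fixed
21-channel 10/20 layout, 200 Hz) with keypress onsets and binary class
labels (1 = "d" key, 2 = "l" key) read off a synchronized marker channel.

The synthetic generator emulates a self-paced binary keypress session:
~700 freely-timed onsets with jittered inter-trial intervals, a slow
readiness-potential-like negative deflection on frontal channels before each
onset, a lateralized movement deflection on the central motor channels after
it, and broadband background noise (white plus 1/f). Effects are additive
raised-cosine templates, so the planted class structure is analytically
known and recoverable by the downstream pipeline.

Files are read and written in the dialect of the published FreeForm
sessions: a MATLAB struct ``o`` with fields ``data`` (T x 21), ``marker``
(T,), ``sampFreq``, ``nS``, ``chnames`` and ``id``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import loadmat, savemat

__all__ = [
    "CHANNELS_1020",
    "Recording",
    "SynthConfig",
    "generate_recording",
    "read_freeform_mat",
    "write_freeform_mat",
]

#: Fixed channel order: 19 scalp electrodes of the 10/20 system plus the two
#: ear electrodes A1/A2.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "C3", "C4", "Cz", "T3", "T4", "T5", "T6",
    "P3", "P4", "Pz", "O1", "O2", "A1", "A2",
)

FS = 200  # Hz, sampling rate of the recording format


@dataclass
class Recording:
    """Continuous EEG with event markers.

    Attributes
    ----------
    signals : (21, T) float array, microvolts, rows ordered as CHANNELS_1020
    fs : sampling rate in Hz (always 200 for this format)
    onsets : strictly increasing sample indices of keypress onsets
    labels : class per onset, 1 ("d") or 2 ("l")
    """

    signals: np.ndarray
    onsets: np.ndarray
    labels: np.ndarray
    fs: int = FS
    channels: tuple[str, ...] = CHANNELS_1020
    session_id: str = "synthetic"

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.signals.ndim != 2 or self.signals.shape[0] != len(self.channels):
            raise ValueError(
                f"signals must be ({len(self.channels)}, T), got {self.signals.shape}"
            )
        if self.fs != FS:
            raise ValueError(f"sampling rate must be {FS} Hz, got {self.fs}")
        if self.onsets.size != self.labels.size:
            raise ValueError("onsets and labels must have equal length")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


@dataclass
class SynthConfig:
    """Parameters of the synthetic self-paced keypress session.

    Defaults mirror the published recording conditions: ~700 trials at
    200 Hz with balanced classes and free (jittered) timing. Effect
    amplitudes are in microvolts on the scale of real slow cortical
    potentials; the pre-onset deflection sits on frontal channels and the
    post-onset one on the motor strip, lateralized by class.
    """

    n_trials: int = 700
    fs: int = FS
    iti_mean: float = 2.5       # s, mean inter-trial interval
    iti_jitter: float = 0.5     # s, half-width of uniform jitter
    effect_channels_pre: tuple[str, ...] = ("F3", "F4", "Fz")
    effect_channels_move: tuple[str, ...] = ("C3", "C4")
    effect_band: tuple[float, float] = (0.5, 4.0)  # Hz, template bandwidth
    effect_amplitude: float = 3.0  # microvolts
    lateralization: float = 0.6    # signed class weighting of C3 vs C4
    noise_white: float = 1.0       # microvolts RMS
    noise_pink: float = 1.0        # 1/f amplitude scale
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 20:
            raise ValueError("n_trials must be at least 20")
        if self.effect_amplitude < 0 or self.noise_white < 0 or self.noise_pink < 0:
            raise ValueError("amplitudes must be non-negative")
        for name in self.effect_channels_pre + self.effect_channels_move:
            if name not in CHANNELS_1020:
                raise ValueError(
                    f"unknown channel {name!r}; valid names: {CHANNELS_1020}"
                )


def _raised_cosine(n: int, f0: float, fs: int) -> np.ndarray:
    """Unit-amplitude raised-cosine bump of duration ``n`` samples.

    The bump is a half period of a cosine squared whose fundamental lies at
    ``f0`` when the duration equals half the period; for the default window
    the energy is concentrated well below 5 Hz.
    """
    t = np.arange(n) / fs
    T = n / fs
    env = np.sin(np.pi * t / T) ** 2
    # slow carrier keeps the spectral content inside the effect band
    return env * np.cos(2.0 * np.pi * f0 * t / 2.0)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f noise via spectral shaping, unit variance."""
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def generate_recording(cfg: SynthConfig) -> Recording:
    """Simulate one continuous session; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    win = int(round(0.85 * fs))

    # freely-timed onsets: jittered inter-trial intervals, padding at both ends
    itis = cfg.iti_mean + cfg.iti_jitter * rng.uniform(-1, 1, size=cfg.n_trials)
    itis = np.maximum(itis, 2 * 0.85 + 0.1)
    onsets = (np.cumsum(itis) * fs).astype(int) + win
    T = int(onsets[-1] + win + fs)

    # balanced classes in random order
    labels = np.empty(cfg.n_trials, dtype=int)
    half = cfg.n_trials // 2
    labels[:half] = 1
    labels[half:] = 2
    rng.shuffle(labels)

    n_ch = len(CHANNELS_1020)
    signals = np.zeros((n_ch, T))
    if cfg.noise_white > 0:
        signals += cfg.noise_white * rng.standard_normal((n_ch, T))
    if cfg.noise_pink > 0:
        for c in range(n_ch):
            signals[c] += cfg.noise_pink * _pink_noise(T, rng)

    f0 = 0.5 * (cfg.effect_band[0] + cfg.effect_band[1])
    template = _raised_cosine(win, f0, fs)
    idx = {name: i for i, name in enumerate(CHANNELS_1020)}

    if cfg.effect_amplitude > 0:
        amp = cfg.effect_amplitude
        lat = cfg.lateralization
        for onset, lab in zip(onsets, labels):
            sign = 1.0 if lab == 1 else -1.0
            # readiness-potential-like negative ramp before the onset,
            # class-dependent sign modulation on the frontal channels
            pre = -amp * template[::-1] * (1.0 + 0.5 * sign)
            for name in cfg.effect_channels_pre:
                signals[idx[name], onset - win : onset] += pre
            # lateralized movement deflection after the onset
            w = {}
            if "C3" in cfg.effect_channels_move and "C4" in cfg.effect_channels_move:
                w["C3"] = 1.0 + sign * lat
                w["C4"] = 1.0 - sign * lat
            for name in cfg.effect_channels_move:
                weight = w.get(name, 1.0 + 0.3 * sign)
                signals[idx[name], onset : onset + win] += amp * weight * template

    return Recording(signals=signals, onsets=onsets, labels=labels, fs=fs)


# ---------------------------------------------------------------------------
# MAT-dialect I/O
# ---------------------------------------------------------------------------


def write_freeform_mat(rec: Recording, path) -> None:
    """Write a recording in the published FreeForm session dialect."""
    marker = np.zeros(rec.n_samples)
    marker[rec.onsets] = rec.labels
    o = {
        "id": rec.session_id,
        "sampFreq": float(rec.fs),
        "nS": float(rec.n_samples),
        "marker": marker[:, None],
        "data": rec.signals.T,
        "chnames": np.array(
            [np.array([c], dtype=object) for c in rec.channels], dtype=object
        )[:, None],
    }
    savemat(str(path), {"o": o})


def _field(o, name):
    if not hasattr(o, name):
        raise ValueError(f"MAT file is missing required field {name!r}")
    return getattr(o, name)


def read_freeform_mat(path) -> Recording:
    """Read a FreeForm-dialect session file into a :class:`Recording`.

    Onsets are the rising edges of the marker channel; labels are the marker
    values at those samples (1 = "d", 2 = "l"). Channels are reordered to
    the fixed 21-name list if needed.
    """
    try:
        mat = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    except Exception as exc:  # scipy raises several types for bad files
        raise ValueError(f"could not parse MAT file {path}: {exc}") from exc
    if "o" not in mat:
        raise ValueError("MAT file is missing the session struct 'o'")
    o = mat["o"]
    data = np.atleast_2d(np.asarray(_field(o, "data"), dtype=float))
    marker = np.asarray(_field(o, "marker"), dtype=float).ravel()
    fs = int(_field(o, "sampFreq"))
    raw_names = _field(o, "chnames")
    names = [str(np.asarray(c).ravel()[0]) for c in np.asarray(raw_names).ravel()]

    if data.shape[0] == len(marker) and data.shape[1] == len(names):
        data = data.T  # stored samples-major
    if data.shape[0] != len(names):
        raise ValueError(
            f"data shape {data.shape} inconsistent with {len(names)} channels"
        )
    if sorted(names) != sorted(CHANNELS_1020):
        unknown = sorted(set(names) - set(CHANNELS_1020))
        raise ValueError(
            f"unknown channel set (unexpected: {unknown}); expected the 21 "
            f"names {CHANNELS_1020}"
        )
    order = [names.index(c) for c in CHANNELS_1020]
    data = data[order]

    # rising edges: first sample of each nonzero marker run
    nz = marker > 0
    rising = nz & ~np.concatenate(([False], nz[:-1]))
    onsets = np.flatnonzero(rising)
    if onsets.size == 0:
        raise ValueError("marker channel contains no events")
    labels = marker[onsets].astype(int)
    session_id = str(_field(o, "id")) if hasattr(o, "id") else "unknown"
    return Recording(
        signals=data, onsets=onsets, labels=labels, fs=fs, session_id=session_id
    )
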