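"""Loading speech segments, ingesting GCI marks, and cutting pitch periods.

The analysis operates on a steady-state vowel segmented into n pitch periods
{d_1..d_n} by glottal closing instants (GCIs).  Periods are half-open sample
ranges [tau_i, tau_{i+1}) with GCI times rounded to the nearest sample, and
the whole selection is normalized by one shared max-abs scale so that model
amplitudes are of order one.  A GCI-perturbation sampler reproduces the
segmentation-error experiment: perturbed period lengths are drawn lognormally
around the true ones and each GCI is shifted by the resulting length error.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

__all__ = [
    "SpeechSegment",
    "GCISequence",
    "PitchPeriodSet",
    "PerturbationSpec",
    "load_segment",
    "write_wav",
    "read_gci_file",
    "write_gci_file",
    "segment_periods",
    "perturb_gcis",
]

_MIN_PERIOD_SAMPLES = 8


@dataclass
class SpeechSegment:
    samples: np.ndarray
    fs: float
    origin: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")


@dataclass
class GCISequence:
    """Strictly increasing glottal closing instants tau_1..tau_{n+1} (seconds)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least two GCI times")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("GCI times must be strictly increasing")

    @property
    def periods(self) -> np.ndarray:
        """Pitch period durations T_i = tau_{i+1} - tau_i."""
        return np.diff(self.times)

    @property
    def n(self) -> int:
        return len(self.times) - 1


@dataclass
class PitchPeriodSet:
    """The n data vectors {d_i}, normalized, with a shared sampling rate.

    Sample times inside each period are the dimensionless grid 0..N_i-1.
    """

    periods: list[np.ndarray]
    fs: float
    norm_scale: float

    def __post_init__(self) -> None:
        if len(self.periods) < 1:
            raise ValueError("need at least one period")
        self.periods = [np.asarray(p, dtype=float) for p in self.periods]

    @property
    def n(self) -> int:
        return len(self.periods)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(p) for p in self.periods])

    @property
    def N(self) -> int:
        return int(self.lengths.sum())

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for p in self.periods:
            h.update(p.tobytes())
        h.update(np.float64(self.fs).tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class PerturbationSpec:
    eps: float
    n_draws: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.eps <= 1.0):
            raise ValueError("eps must lie in [0, 1]")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def load_segment(
    path: str | Path,
    t_start: float | None = None,
    t_end: float | None = None,
    fs_target: float | None = None,
) -> SpeechSegment:
    """Read a mono segment from a PCM WAV file, optionally resampled.

    Multichannel input is averaged to mono.  Integer PCM is scaled to
    [-1, 1] by the positive full-scale value (32767 for 16-bit).
    Resampling is polyphase with built-in antialiasing.
    """
    fs_in, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        x = data.astype(float) / 32767.0
    elif data.dtype == np.int32:  # 24/32-bit containers
        x = data.astype(float) / 2147483647.0
    else:
        x = data.astype(float)

    t0 = 0.0 if t_start is None else t_start
    t1 = len(x) / fs_in if t_end is None else t_end
    if not t0 < t1:
        raise ValueError("t_start must be < t_end")
    i0, i1 = int(round(t0 * fs_in)), int(round(t1 * fs_in))
    x = x[max(i0, 0) : min(i1, len(x))]
    if len(x) == 0:
        raise ValueError("empty selection")

    fs = float(fs_in)
    if fs_target is not None and fs_target != fs:
        frac = Fraction(int(round(fs_target)), int(round(fs))).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
        fs = float(fs_target)
    return SpeechSegment(samples=x, fs=fs, origin=f"{path}[{t0:.6g}s..{t1:.6g}s]")


def write_wav(path: str | Path, samples: np.ndarray, fs: float) -> None:
    """Write 16-bit PCM mono, peak-normalized to full scale."""
    x = np.asarray(samples, dtype=float)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    q = np.round(np.clip(x, -1.0, 1.0) * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(round(fs)), q)


def read_gci_file(path: str | Path) -> GCISequence:
    """Plain-text GCI marks: one float (seconds) per line; '#' comments allowed."""
    times = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            times.append(float(line))
    return GCISequence(times=np.array(times))


def write_gci_file(path: str | Path, gcis: GCISequence) -> None:
    Path(path).write_text("".join(f"{t:.9f}\n" for t in gcis.times))


def segment_periods(seg: SpeechSegment, gcis: GCISequence) -> PitchPeriodSet:
    """Cut the segment into n = len(gcis)-1 periods and normalize.

    Each period is the half-open sample range [round(tau_i*fs),
    round(tau_{i+1}*fs)); all samples are divided by the global max-abs over
    the selection, recorded as ``norm_scale``.
    """
    idx = np.round(gcis.times * seg.fs).astype(int)
    if idx[0] < 0 or idx[-1] > len(seg.samples):
        raise ValueError("GCI outside segment")
    if np.any(np.diff(idx) < _MIN_PERIOD_SAMPLES):
        raise ValueError(f"period shorter than {_MIN_PERIOD_SAMPLES} samples")
    chunk = seg.samples[idx[0] : idx[-1]]
    scale = float(np.max(np.abs(chunk)))
    if scale == 0.0:
        raise ValueError("segment is identically zero")
    periods = [
        seg.samples[a:b] / scale for a, b in zip(idx[:-1], idx[1:])
    ]
    return PitchPeriodSet(periods=periods, fs=seg.fs, norm_scale=scale)


def perturb_gcis(
    gcis: GCISequence, p: PerturbationSpec, skip_invalid: bool = False
) -> list[GCISequence]:
    """Simulate segmentation error: draw log T_i(eps) ~ N(log T_i, eps) and
    shift tau_i -> tau_i + [T_i - T_i(eps)].

    Each of the n interior GCIs moves by its own period-length error; the
    final GCI is kept fixed.  Returns one perturbed sequence per draw,
    deterministic given the seed.  At large eps a draw can put the GCIs out
    of order; by default that raises, with ``skip_invalid`` such draws are
    dropped (the draw stream is unaffected, so the remaining draws are the
    same either way).
    """
    rng = np.random.default_rng(p.seed)
    T = gcis.periods
    out = []
    for _ in range(p.n_draws):
        T_eps = np.exp(np.log(T) + p.eps * rng.standard_normal(len(T)))
        tau = gcis.times.copy()
        tau[:-1] = tau[:-1] + (T - T_eps)
        try:
            out.append(GCISequence(times=tau))
        except ValueError:
            if not skip_invalid:
                raise
    return out
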