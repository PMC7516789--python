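"""Synthetic steady-state vowels with known ground truth.

A vowel is synthesized source-filter style: the glottal flow derivative
u'(t) is generated cycle by cycle with the Liljencrants-Fant (LF) model,
passed through an all-pole vocal-tract filter (one conjugate pole pair per
formant), and downsampled with a zero-phase antialiasing filter.  Glottal
closing instants (GCIs) — the negative excitation spikes of the LF pulses —
are laid out with multiplicative lognormal jitter on the period lengths,
and each pulse carries a lognormal shimmer factor on its excitation
amplitude.  The generator records the exact GCI times and the source signal
itself, so downstream formant estimates can be scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import brentq

__all__ = [
    "LFParams",
    "VowelSynthesisSpec",
    "SyntheticVowel",
    "lf_pulse",
    "allpole_filter",
    "synthesize_vowel",
]


@dataclass(frozen=True)
class LFParams:
    """Timing and amplitude parameters of one LF glottal-flow-derivative pulse.

    ``tp``, ``te`` and ``ta`` are fractions of the period: the zero crossing
    of u', the main (negative-spike) excitation instant — the glottal closing
    instant — and the return-phase time constant.  ``Ee`` is the magnitude of
    the negative spike at closure.
    """

    period_s: float
    Ee: float = 1.0
    tp: float = 0.45
    te: float = 0.60
    ta: float = 0.03

    def __post_init__(self) -> None:
        if not (0.0 < self.tp < self.te < 1.0):
            raise ValueError(f"need 0 < tp < te < 1, got tp={self.tp}, te={self.te}")
        # the spike must fall in the falling half-cycle of the open phase,
        # strictly before the sinusoid's second zero crossing at 2*tp
        if not self.te < 2.0 * self.tp:
            raise ValueError(f"need te < 2*tp, got tp={self.tp}, te={self.te}")
        if not (0.0 < self.ta < 1.0 - self.te):
            raise ValueError(f"need 0 < ta < 1 - te, got ta={self.ta}, te={self.te}")
        if self.Ee < 0:
            raise ValueError("Ee must be nonnegative")
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")


@dataclass(frozen=True)
class VowelSynthesisSpec:
    """Recipe for one synthetic steady-state vowel."""

    f0_hz: float
    formants: tuple[tuple[float, float], ...]  # (bandwidth_hz, frequency_hz) pairs
    fs_synth: float = 16000.0
    fs_out: float = 8000.0
    n_periods_total: int = 12
    n_periods_out: int = 3
    jitter_rel: float = 0.005
    shimmer_rel: float = 0.02
    seed: int = 0
    lf: LFParams | None = None  # timing template; period_s is ignored

    def __post_init__(self) -> None:
        if self.fs_synth < 2 * self.fs_out:
            raise ValueError("fs_synth must be at least 2*fs_out")
        for b, f in self.formants:
            if not f < self.fs_out / 2:
                raise ValueError(f"formant frequency {f} Hz >= output Nyquist")
            if b <= 0:
                raise ValueError("formant bandwidths must be positive")
        if self.jitter_rel < 0 or self.shimmer_rel < 0:
            raise ValueError("jitter_rel and shimmer_rel must be nonnegative")
        if self.n_periods_out + 1 > self.n_periods_total:
            raise ValueError("n_periods_total too small for requested output periods")


@dataclass
class SyntheticVowel:
    """A synthesized vowel segment with its ground truth.

    ``waveform`` and ``source_deriv`` are sampled at ``spec.fs_out`` and span
    the selected central periods; ``gci_times`` are exact (not quantized to
    the output rate), relative to the start of ``waveform``.
    """

    waveform: np.ndarray
    gci_times: np.ndarray
    source_deriv: np.ndarray
    spec: VowelSynthesisSpec
    true_bandwidths_hz: tuple[float, ...] = field(default_factory=tuple)
    true_frequencies_hz: tuple[float, ...] = field(default_factory=tuple)


def _solve_lf(params: LFParams) -> tuple[float, float, float, float]:
    """Solve the LF shape constraints: (wg, eps, a, E0).

    The open phase is E0*exp(a*t)*sin(wg*t) with wg = pi/tp (so u' crosses
    zero at tp) and value -Ee at te.  The return phase is an offset
    exponential with rate eps chosen so u' vanishes exactly at the period
    end.  The growth rate a enforces zero net area (flow closure).
    """
    T0 = params.period_s
    tp_abs, te_abs, ta_abs = params.tp * T0, params.te * T0, params.ta * T0
    wg = np.pi / tp_abs
    tc = T0

    def eps_eq(e: float) -> float:
        return e * ta_abs - (1.0 - np.exp(-e * (tc - te_abs)))

    eps = brentq(eps_eq, 1e-9 / ta_abs, 50.0 / ta_abs, xtol=1e-12 / ta_abs)

    K = np.exp(-eps * (tc - te_abs))
    area_ret = -(params.Ee / (eps * ta_abs)) * ((1.0 - K) / eps - (tc - te_abs) * K)

    def total_area(a: float) -> float:
        E0 = -params.Ee / (np.exp(a * te_abs) * np.sin(wg * te_abs))
        num = np.exp(a * te_abs) * (
            a * np.sin(wg * te_abs) - wg * np.cos(wg * te_abs)
        ) + wg
        return E0 * num / (a * a + wg * wg) + area_ret

    lo, hi = -2.0 / T0, 2.0 / T0
    flo, fhi = total_area(lo), total_area(hi)
    tries = 0
    while flo * fhi > 0 and tries < 60:
        lo -= 2.0 / T0
        hi += 2.0 / T0
        flo, fhi = total_area(lo), total_area(hi)
        tries += 1
    if flo * fhi > 0:
        raise RuntimeError("could not bracket the LF area-balance root")
    a = brentq(total_area, lo, hi, xtol=1e-9 / T0)
    E0 = -params.Ee / (np.exp(a * te_abs) * np.sin(wg * te_abs))
    return wg, eps, a, E0


def _lf_eval(t: np.ndarray, params: LFParams, sol=None) -> np.ndarray:
    """Evaluate u'(t) for t in [0, period); zero outside."""
    if params.Ee == 0.0:
        return np.zeros_like(t)
    wg, eps, a, E0 = sol if sol is not None else _solve_lf(params)
    T0 = params.period_s
    te_abs, ta_abs = params.te * T0, params.ta * T0
    out = np.zeros_like(t)
    opn = (t >= 0) & (t < te_abs)
    ret = (t >= te_abs) & (t < T0)
    out[opn] = E0 * np.exp(a * t[opn]) * np.sin(wg * t[opn])
    K = np.exp(-eps * (T0 - te_abs))
    out[ret] = -(params.Ee / (eps * ta_abs)) * (np.exp(-eps * (t[ret] - te_abs)) - K)
    return out


def lf_pulse(params: LFParams, fs: float) -> np.ndarray:
    """One period of the LF glottal flow derivative u'(t), sampled at ``fs``.

    Returns round(fs*period) samples starting at the glottal opening; the
    minimum (-Ee) falls at the sample nearest te*period.  The growth rate of
    the open phase is solved so the pulse has zero net area: the glottal
    flow u returns to its starting value at the period end.
    """
    n = int(round(fs * params.period_s))
    if n < 8:
        raise ValueError(f"period too short for fs={fs}: only {n} samples")
    if params.Ee == 0.0:
        return np.zeros(n)
    t = np.arange(n) / fs
    wg, eps, a0, _ = _solve_lf(params)
    T0 = params.period_s
    te_abs, ta_abs = params.te * T0, params.ta * T0
    K = np.exp(-eps * (T0 - te_abs))
    ret = t >= te_abs
    ret_vals = -(params.Ee / (eps * ta_abs)) * (np.exp(-eps * (t[ret] - te_abs)) - K)
    ret_sum = ret_vals.sum()

    def disc_area(a: float) -> float:
        # refine the flow-closure balance on the sampled grid itself
        E0 = -params.Ee / (np.exp(a * te_abs) * np.sin(wg * te_abs))
        return E0 * (np.exp(a * t[~ret]) * np.sin(wg * t[~ret])).sum() + ret_sum

    da = 2.0 / T0
    lo, hi = a0 - da, a0 + da
    tries = 0
    while disc_area(lo) * disc_area(hi) > 0 and tries < 40:
        lo -= da
        hi += da
        tries += 1
    a = brentq(disc_area, lo, hi, xtol=1e-10 / T0)
    E0 = -params.Ee / (np.exp(a * te_abs) * np.sin(wg * te_abs))
    out = np.empty(n)
    out[~ret] = E0 * np.exp(a * t[~ret]) * np.sin(wg * t[~ret])
    out[ret] = ret_vals
    return out


def allpole_filter(
    source: np.ndarray, formants: list[tuple[float, float]], fs: float
) -> np.ndarray:
    """Cascade of second-order all-pole resonators (one per formant).

    Each (B, F) pair in Hz maps to the conjugate pole pair
    z = exp((-pi*B +/- i*2*pi*F)/fs) (impulse invariance), so the impulse
    response of a single section decays as exp(-pi*B*t).
    """
    out = np.asarray(source, dtype=float)
    for b_hz, f_hz in formants:
        if f_hz >= fs / 2:
            raise ValueError(f"formant frequency {f_hz} Hz >= Nyquist {fs / 2} Hz")
        if b_hz <= 0:
            raise ValueError("bandwidth must be positive")
        r = np.exp(-np.pi * b_hz / fs)
        c = np.cos(2 * np.pi * f_hz / fs)
        # (1 - p z^-1)(1 - conj(p) z^-1) = 1 - 2 r cos(w) z^-1 + r^2 z^-2
        out = sps.lfilter([1.0], [1.0, -2.0 * r * c, r * r], out)
    return out


def _decimate_zero_phase(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Zero-phase FIR antialias (cutoff 0.45*fs_out) then integer decimation."""
    ratio = fs_in / fs_out
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError("fs_synth must be an integer multiple of fs_out")
    if q == 1:
        return x.copy()
    taps = sps.firwin(255, 0.45 * fs_out, fs=fs_in)
    y = sps.filtfilt(taps, [1.0], x, padlen=min(3 * 255, len(x) - 1))
    return y[::q]


def synthesize_vowel(spec: VowelSynthesisSpec) -> SyntheticVowel:
    """Synthesize a steady-state vowel and return its central pitch periods.

    Pitch periods (GCI to GCI) have durations T0 * lognormal(jitter_rel);
    each LF pulse is placed so its excitation spike lands exactly on its
    GCI, and carries a lognormal(shimmer_rel) amplitude factor.  The source
    is filtered at ``fs_synth``, then both the speech wave and the source
    are decimated to ``fs_out`` with the same zero-phase antialiasing filter
    so they stay time aligned.  Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_gci = spec.n_periods_total  # spikes; n_gci - 1 periods between them
    T0 = 1.0 / spec.f0_hz
    fs = spec.fs_synth

    T = T0 * np.exp(rng.standard_normal(n_gci - 1) * spec.jitter_rel)
    ees = np.exp(rng.standard_normal(n_gci) * spec.shimmer_rel)
    lf_template = spec.lf if spec.lf is not None else LFParams(period_s=T0)

    # spike (GCI) times; lead-in so the first pulse's open phase fits
    tau = np.concatenate([[1.5 * T0], 1.5 * T0 + np.cumsum(T)])

    total_s = tau[-1] + 1.5 * T0
    n_samp = int(np.ceil(total_s * fs))
    source = np.zeros(n_samp)
    # each pulse spans [tau_i - te*T_i, tau_i + (1-te)*T_i); cycle duration
    # follows the period *ending* at its spike so consecutive pulses abut
    durs = np.concatenate([[T[0]], T])
    for tau_i, dur, ee in zip(tau, durs, ees):
        p = LFParams(
            period_s=float(dur),
            Ee=float(ee),
            tp=lf_template.tp,
            te=lf_template.te,
            ta=lf_template.ta,
        )
        t_start = tau_i - p.te * dur
        j0 = max(int(np.ceil(t_start * fs)), 0)
        j1 = min(int(np.ceil((t_start + dur) * fs)), n_samp)
        tloc = np.arange(j0, j1) / fs - t_start
        source[j0:j1] += _lf_eval(tloc, p)

    speech = allpole_filter(source, list(spec.formants), fs)

    wav8 = _decimate_zero_phase(speech, fs, spec.fs_out)
    src8 = _decimate_zero_phase(source, fs, spec.fs_out)

    # central run of n_out periods: centered on period ceil(n/2) (1-based)
    n_periods = n_gci - 1
    n_out = spec.n_periods_out
    center = int(np.ceil(n_periods / 2)) - 1
    first = min(max(center - (n_out - 1) // 2, 0), n_periods - n_out)
    t_a = tau[first]
    t_b = tau[first + n_out]
    i_a = int(round(t_a * spec.fs_out))
    i_b = int(round(t_b * spec.fs_out))

    return SyntheticVowel(
        waveform=wav8[i_a:i_b],
        gci_times=tau[first : first + n_out + 1] - i_a / spec.fs_out,
        source_deriv=src8[i_a:i_b],
        spec=spec,
        true_bandwidths_hz=tuple(b for b, _ in spec.formants),
        true_frequencies_hz=tuple(f for _, f in spec.formants),
    )
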