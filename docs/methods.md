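# Methods

## The model

A steady-state vowel is a quasi-periodic string of pitch periods, each
delimited by glottal closing instants (GCIs).  Within one period the speech
wave is modeled as the vocal tract's free ring-down triggered by the GCI —
one exponentially decaying sinusoid per formant — superimposed on a smooth
*trend* that carries the low-frequency imprint of the glottal pulse (the
weak excitation around the glottal opening).  For period *i* of length
`N_i` samples, on the dimensionless grid `j = 0..N_i-1`:

    d_ij = sum_{k=1..P} b_ik L_k(j)
         + sum_{l=1..Q} [c_il cos(j w_l) + s_il sin(j w_l)] exp(-j a_l)
         + e_ij,            e_ij ~ N(0, sigma^2)

* `L_k` — polynomials of degree `0..P-1`, orthonormalized on the discrete
  grid (see below);
* `(a_l, w_l)` — per-sample decay rate and angular frequency of formant
  *l*; in physical units `B_l = a_l fs / pi` (bandwidth, Hz, the 3 dB full
  width) and `F_l = w_l fs / 2 pi` (center frequency, Hz);
* `n` periods share the formant parameters `theta = (a, w)` and the noise
  scale `sigma` but keep private amplitudes — the trend's shape and the
  ring-down's intensity and phase may vary from period to period.

`(P, Q)` are model orders, unknown a priori, handled by Bayesian model
averaging.

## Priors and marginalization

Amplitudes carry independent `N(0, delta^2)` priors with `delta = 1`: the
data are normalized to unit maximum amplitude, and every basis column of
the trend block has unit norm by construction, so order-one amplitudes are
the right scale.  `theta` and `sigma` carry bounded Jeffreys (log-uniform)
priors; the `sigma` bounds (defaults `1e-6`, `1`) only enter through a
constant that cancels in model averaging.

Both the `n·m` amplitudes (`m = P + 2Q`) and `sigma` are marginalized
analytically.  The amplitude integral drops the prior's `+I/delta^2` term
from the posterior precision `g_i/sigma^2 + I/delta^2`; this is valid when
each basis column's integrated power dominates the noise power,
`[g_i]_jj delta^2 / sigma^2 >> 1`.  The implementation tracks the minimum
of this ratio and logs a warning below a threshold of 10 (the approximation
degrades smoothly, so this is a diagnostic, not an error).  The `sigma`
integral is concentrated at `sigma_hat = sqrt(sum chi2_i / (N - nm + 1))`
and evaluated as a gamma integral.  The result is the integrated
likelihood

    L_I(P,Q,theta) = C(P,Q) [sum_i chi2_i]^((nm-N)/2)
                     prod_i |det g_i|^(-1/2) exp(-sum_i bhat_i^T bhat_i / 2)

with `C(P,Q) = (1/2) [log(sigma_hi/sigma_lo)]^(-1) pi^((nm-N)/2)
Gamma((N-nm)/2) (2 pi delta^2)^(-nm/2)`.  Everything is carried in log
space (`Gamma` via `lgamma`; `N - nm` is ~150 in practice, so the linear
scale would overflow).  The test suite checks the closed form against an
independent oracle that performs the exact Gaussian marginalization
(keeping `+I/delta^2`) and integrates `sigma` by quadrature; agreement is
required to 0.1 nats.

Per-period least squares is solved by QR factorization, never by normal
equations; `chi2` is computed both as the residual sum of squares and as
`d^T d - fhat^T fhat` and the two must agree to `1e-8` relative.  A
rank-deficient design (e.g. two coincident frequencies) raises an error
naming the offending columns rather than falling back to a pseudo-inverse:
the ordered prior boxes exclude exact degeneracies, so a singular fit
indicates a configuration mistake the user should see.

## Nested sampling and model averaging

The evidence `Z(P,Q) = int L_I(theta) p(theta) dtheta` is a 2Q-dimensional
integral — independent of `n` and `P` (for the typical `n=3, P=5, Q=3` the
marginalization shrinks the space from 40 to 6 dimensions).  It is
computed by a static nested sampler written for this package: live-point
replacement uses an adaptive random walk in the unit cube (or rejection
sampling in the enlarged live-point bounding box for dimension <= 2),
prior volumes shrink as `exp(-k/n_live)`, and the run stops when the
estimated remaining contribution falls below `dlogz = 0.1`.  Defaults:
`n_live = 250`, walk length `max(20, 4*dim)`, evidence uncertainty
`sqrt(H/n_live)`.  The sampler is validated against 2-D tensor-grid
quadrature of `L_I * prior` on a toy problem.

Draws whose frequencies are not strictly increasing get zero likelihood,
which fixes the formant labeling when adjacent prior ranges overlap.

Model-order posteriors are `p(P,Q|d) = Z(P,Q)/sum Z` under a uniform
model-order prior.  Formant estimates are model-averaged first moments of
the pooled samples reweighted by `w -> w * Z/sum Z`; error bars come from
first and second moments and are reported at three standard deviations.
Models of different `Q` are combined per formant: formant *k* is averaged
over models with `Q >= k` (weights renormalized within that support), and
`p(formant k exists) = sum_{Q>=k} p(Q)` is reported alongside.

## The synthetic-vowel generator

The generator emulates a steady-state vowel the way a source-filter
synthesizer would produce one:

* **Source** — the Liljencrants–Fant (LF) glottal flow derivative, one
  pulse per glottal cycle.  Timing defaults `tp = 0.45`, `te = 0.60`,
  `ta = 0.03` (fractions of the period) describe a modal male voice; the
  open-phase growth rate is solved numerically so each pulse has zero net
  area (the glottal flow closes on itself), and `te < 2 tp` is enforced so
  the closure spike falls in the falling half-cycle of the open phase.
* **Filter** — a cascade of second-order all-pole resonators, poles
  `z = exp((-pi B + 2 pi i F)/fs)` (impulse invariance), defaults
  `B = (54, 22, 19)` Hz, `F = (430, 1088, 2142)` Hz.
* **Perturbations** — period durations and pulse amplitudes carry
  multiplicative lognormal jitter (0.5%) and shimmer (2%).  Jitter is
  applied directly to the GCI-to-GCI intervals and each pulse is placed so
  its excitation spike lands exactly on its GCI (pulses vanish at both
  ends, so additive placement is seamless); the recorded GCI ground truth
  is therefore exact and the jitter statistic of the output periods equals
  the nominal value by construction.
* **Rates** — synthesis at 16 kHz, zero-phase FIR antialiasing (cutoff
  `0.45 fs_out`) and decimation to 8 kHz; the source signal is decimated
  through the same filter so it stays aligned with the waveform.
* **Selection** — 12 cycles are synthesized (11 periods) and the 3 central
  periods are returned; the lead-in lets the filter and the period
  sequence reach steady state.

What the generator does *not* emulate: aspiration noise, subglottal
coupling (open-phase bandwidth widening), microphone/room coloration, or
amplitude drift.  Passing tests on this data demonstrate the correctness
of the inference machinery and the method's behavior under its own model
assumptions plus realistic jitter/shimmer — not performance on real
recordings, where the LPC-style preprocessing and GCI detection introduce
errors of their own (the GCI-perturbation experiment probes exactly that
failure mode).

## Numerical and design choices

* **Discrete orthonormal trend.**  Legendre polynomials evaluated on the
  period's sample grid are re-orthonormalized by QR with a positive
  diagonal.  Continuous-Legendre normalization would leave column norms
  dependent on `N_i`, breaking the `delta = 1` prior scale.
* **Sample grid starts at zero.**  `j = 0..N-1`, so the first row of the
  cos/sin blocks is `(1, ..., 1, 0, ..., 0)`.
* **Periods are half-open** `[tau_i, tau_{i+1})` with GCI times rounded to
  the nearest sample; concatenating the periods reproduces the selection
  exactly.
* **Normalization** divides all selected samples by one shared max-abs
  scale (recorded in the period set); per-period scaling would break the
  comparability of amplitudes across the chained fits.
* **GCI perturbation** draws `log T_i(eps) ~ N(log T_i, eps)` and shifts
  `tau_i -> tau_i + [T_i - T_i(eps)]` for the n interior GCIs, keeping the
  final GCI fixed (each GCI has exactly one following period to take its
  error from).
* **Grid sweeps** derive one seed per `(P, Q)` cell from the master seed,
  so cells are order-independent and could run in parallel; cells with
  `N <= n m` are skipped with a logged reason.
* **Averaged transfer magnitude** is the geometric mean of per-period
  magnitudes: periods share poles but not gains or zeros.
* **Flow proxy** integrates the fitted trend by cumulative summation and
  is left with an arbitrary offset and scale.

## Problem sizes in tests

The test suite and the acceptance script run the full pipeline at sizes a
laptop handles in minutes: the model-order grid uses `P in {4,5,6}`,
`Q in {1,2,3}` with 250 live points (the neighborhood of the most probable
cell; wider `P` ranges change none of the conclusions but cost
proportionally more), single-model fits use `(P,Q) = (6,2)`, the high-F0
comparison averages over `P in {4..7}` at `Q = 2` with 120 live points,
and the segmentation-robustness experiment uses 6 perturbation draws per
error level with 100 live points.

## Known limitations

* The method is reliable for fundamental frequencies below roughly 150 Hz
  (male voices): at higher F0 the ring-down of one period spills into the
  next and the trend-plus-ring-down decomposition breaks down.  The test
  suite asserts this failure mode rather than hiding it.
* The trend polynomial only approximates the response to the open-phase
  excitation.  Because the vocal-tract gain rises steeply between 0 Hz and
  F1, that response contains content just below F1 that a low-order
  polynomial cannot fully absorb; the residual couples into the formant
  columns and can bias F1 estimates by a few Hz while the posterior (which
  assumes the model is exact) stays much sharper than that.  On very clean
  synthetic data — high SNR after an easy fit — the truth can therefore
  fall outside the formal three-standard-deviation band even though the
  point estimate is accurate to well under one percent.  Error bars should
  be read as conditional on the model.
* Bandwidth estimates above F2 are weakly constrained at an 8 kHz rate
  with three periods; their error bars grow quickly with formant index.
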