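# Methods

## The measurement and the analysis problem

A lensed optical-fiber tip focuses a 980 nm laser to trap (or, for ~100 nm
extracellular vesicles, merely illuminate) a single particle and collects
the light scattered back into the fiber. The photodetector voltage is
recorded at 5 kHz while the source is modulated with a 1 kHz sinusoid, so
the useful signal sits well above slow disturbances (50 Hz mains, drift).
The analysis question is whether *phase-spectral* descriptions of these
recordings carry enough structure to separate particle classes that are
nearly identical in size, refractive index and chemistry — e.g. two gastric
cancer cell lines, or their derived extracellular vesicles, differing only
in surface glycosylation.

`oftphase` implements the full screening pipeline: preprocessing, three
phase representations per 2-s epoch, 46 features per representation, and
per-feature nonparametric hypothesis tests, plus a seeded synthetic-signal
generator that stands in for the (request-only) laboratory recordings.

## Pipeline

1. **High-pass filter.** Second-order Butterworth, cutoff 500 Hz, applied
   zero-phase by default (forward-backward). Zero-phase application is the
   package's choice: the entire downstream analysis is phase-based, and a
   causal pass would add the filter's own phase response to every
   representation; the causal mode remains available
   (`filter_mode="causal"`). Zero-phase squares the magnitude response
   (50 Hz is attenuated by ~1e-4 rather than ~1e-2). The realized digital
   (bilinear) filter matches the analog Butterworth form closely but not
   exactly away from the cutoff: |H| at 1 kHz is 0.944 digitally vs 0.970
   for the analog prototype; the −3 dB point is 500 Hz for both.
2. **Epoching.** Consecutive non-overlapping 2-s windows
   (`floor(duration / 2 s)` epochs; remainder discarded).
3. **Artifact rejection.** Per-epoch z-scores; an epoch is rejected iff
   max |z| strictly exceeds 5 ("exceeds" is a strict inequality — a
   boundary epoch is retained). Retained epochs are returned standardized.
   The z-score basis is per-epoch by default; a pooled per-acquisition
   basis is switchable (`z_basis="per_acquisition"`) because the protocol
   text order (z-score, then segmentation) is ambiguous about the basis.
   Constant epochs are rejected with reason `"degenerate"`.
4. **Phase representations.** Per retained epoch, three unwrapped
   representations (see below).
5. **Features.** Per representation: 6 descriptive statistics + the 40
   coefficient features, i.e. 46 features per (epoch, method).
6. **Statistics.** Per (feature, method): Shapiro–Wilk/Levene assumption
   checks, a Kruskal–Wallis omnibus test across all classes, and
   Mann–Whitney tests over every class pair, all at α = 0.05, with no
   multiple-testing correction by default (each feature is evaluated
   individually; Holm correction within a feature's pairwise family is
   available and labeled).

## Phase representations

**DFT phase** — the principal argument of the one-sided DFT, bins 0..N/2.
A time shift by d samples adds the linear ramp −2πkd/N.

**Hilbert phase (spectral minimum phase, default)** — the phase spectrum a
minimum-phase system with the epoch's magnitude spectrum would have,
obtained through the Hilbert-transform relation between log-magnitude and
phase. Implemented exactly by real-cepstrum folding: c = IDFT(ln|X|), the
causal fold doubles positive quefrencies, and the imaginary part of the
DFT of the folded cepstrum is the phase. Because it is a function of |X|
alone, this representation is *identical* for an epoch and any delayed
copy of it — the operational content of "removing the linear delay
component". The alternative reading of the method — the instantaneous
phase arg a[n] of the analytic signal — is implemented as
`hilbert_mode="analytic_time"`; both are first-class and the feature table
records which was used.

Magnitude bins below 1e-6 of the spectral peak are floored before the log.
The floor is a numerical-conditioning choice: behind a zero-phase
second-order 500 Hz high-pass, stopband bins sit 12+ decades below the
passband, where double-precision FFT/filter round-off dominates; a 1e-12
floor would keep those garbage values, a 1e-6 floor clamps them
deterministically while leaving all physically meaningful bins untouched.

**Hilbert phase slope** — principal-value first differences of the wrapped
Hilbert phase (the phase of each point relative to its predecessor along
the axis), then unwrapped like any other representation. Slope before
unwrap is deliberate: differencing first exposes point-to-point reflection
structure; unwrapping then integrates it into a continuous profile.

**Unwrapping** adds the multiples of 2π that make successive differences
principal values; the first value anchors the sequence, and wrapping the
output recovers the input exactly.

## Features

Per unwrapped representation:

| group | features | conventions |
|---|---|---|
| descriptive | STD, RMS, KURT, IQR, SKEW, ENT | population (biased) STD; RMS = √(mean of squares); Fisher–Pearson g₁ skewness; excess kurtosis g₂; IQR with linear-interpolation (type-7) quantiles; ENT = Shannon entropy in bits of a 64-bin equal-width histogram over the representation's own [min, max] |
| coefficients | Coeff_1 … Coeff_40 | the unwrapped phase at positions 1..40 of the method's axis; position 0 (DC bin) is excluded because it is degenerate for a high-pass-filtered, standardized epoch |

The entropy definition (undefined in the protocol) was fixed for
determinism and scale invariance; the moment conventions are recorded in
the feature table's metadata so results are comparable across runs. For a
constant representation, SKEW/KURT are emitted as NaN and the epoch is
excluded from screening for those features.

## Statistics

Mann–Whitney U counts the first sample's wins (#(a > b) + ties/2). The
p-value is exact by enumeration for tie-free samples with n₁+n₂ ≤ 12 and a
tie-corrected normal approximation with continuity correction otherwise;
Kruskal–Wallis uses the tie-corrected H with the χ²(k−1) approximation.
Screening runs at the epoch level by default — epochs from one trapped
particle are pseudo-replicates, so the report can instead aggregate to
per-acquisition medians (`level="acquisition_median"`); both levels are
first-class and per-class retained-epoch counts are logged to surface the
issue.

## Surrogate validation

Phase-randomized surrogates keep each epoch's amplitude spectrum bin-wise
(hence total power) and draw fresh Fourier phases under conjugate
symmetry; IAAFT surrogates additionally preserve the amplitude
distribution. Re-running phase → feature → test on surrogate datasets
builds an empirical null for the original p-value; the verdict is
"structure-driven" iff the original p falls below the null's α-quantile.

A structural caveat, asserted by a test rather than hidden: features
computed from the spectral minimum phase are functions of |X| only and are
therefore *invariant* under amplitude-preserving surrogates — the
surrogate null can interrogate only Fourier-phase-sensitive features (DFT
phase, analytic-time instantaneous phase), and only differences beyond
second-order structure (e.g. coherent envelope modulation) can be flagged.
Class differences that live entirely in the magnitude spectrum, such as
echo-delay structure, survive phase randomization by construction.
The negative control (two white-noise classes) flags at the nominal ~α
rate by design; tests assert over replicates accordingly.

## Synthetic acquisition model

No generative model for the laboratory signals is published, so the
generator is a minimal physically-motivated stand-in with the statistical
structure the pipeline assumes:

```
base    = carrier_amp · sin(2π·1000·t + φ₀) · (1 + brownian(t)) + scatter(t)
signal  = base + Σᵢ gainᵢ · jitterᵢ(base delayed by τᵢ)
          + mains_amp · sin(2π·50·t + φ) + detector noise + spikes
```

* **Scatter** (std `noise_sd`, default 0.3) models the broadband
  back-scattered speckle field. By default its *magnitude spectrum is
  deterministic* (flat) and only its Fourier phases are random
  (`scatter_mode="fixed_magnitude"`): the particle's spectral signature is
  stable from epoch to epoch while the waveform decorrelates. This is the
  regime in which magnitude-derived (minimum-phase) structure is
  repeatable; with plain white Gaussian scatter
  (`scatter_mode="gaussian"`, available), the log-periodogram of every
  epoch carries O(1) per-bin noise regardless of SNR and phase-spectral
  features carry no recoverable class information at desk scale.
* **Echoes** are delayed, attenuated, optionally phase-jittered copies of
  the whole base field (not the carrier alone — a delayed pure tone is
  just a phase-shifted tone and its delay would be unidentifiable).
  Delays are seconds; circular mode supports fractional-sample delays via
  exact spectral shifts. Two observable channels result: the spectral
  ripple of period 1/τ across the band, and an interferometric channel —
  the echo phase at the carrier, θ = 2π·f₀·τ, sets how constructively the
  echo adds to the carrier line, so the whole log-magnitude landscape
  (and with it the global minimum-phase curve) responds to τ with period
  fs/f₀ = 5 samples.
* **Brownian envelope**: a random walk low-passed below 10 Hz scaling the
  carrier — largely (correctly) removed by the 500 Hz high-pass, its
  residual influence entering through echo phase jitter.
* **Artifacts**: Poisson-placed single-sample spikes with standardized
  magnitude uniform in [6, 12], so they trip the |z| > 5 rejection.
* **`period_s`** makes the whole signature periodic with the epoch length
  (requires circular echoes and frozen slow components): any aligned
  epoch-length window then realizes its designed magnitude spectrum
  exactly. The Monte-Carlo studies simulate three epoch-lengths per
  acquisition and use only the interior epoch, so the zero-phase filter's
  edge transients never touch an analyzed epoch.

The bundled 4-class study (`four_class_design`) mirrors a small
trapped-particle campaign: Mock (15 acquisitions), HST6 (15), polystyrene
control (10) and a no-particle blank (13), at 5 kHz for 60 s each, with
class-specific echo and jitter parameters. All template defaults are
package choices, not measured values; the generator makes no attempt to
match real cell or vesicle signal statistics quantitatively.

## Monte-Carlo studies (the calibration evidence)

* **Type-I error** (`null_rejection_rate`): 1000 replicate two-group
  studies (15 independent 2-s epochs per group) from one fixed jitter-free
  single-echo template with artifacts disabled; full pipeline; Mann–Whitney
  on the slope-representation STD feature at α = 0.05. Each epoch is its
  own acquisition — epochs cut from one long acquisition share its carrier
  phase and Brownian path, and that pseudo-replication measurably inflates
  the rejection rate.
* **Separation power** (`separation_power_study`): three classes whose
  echo delays are 2000, 2000+s, 2000+2s samples for s ∈ {0.7, 1.0, 1.25};
  15 epochs per class, 200 replicates; Kruskal–Wallis omnibus p for each
  of the 40 coefficient features under the DFT and slope methods. The
  separations are confined to the monotone branch of the interferometric
  response (all pairwise Δθ ≤ π; larger separations alias with period 5
  samples). Expected and observed: DFT coefficient medians stay near 0.5
  (after high-pass filtering, bins 1–40 of the DFT phase are stopband
  noise), slope medians fall from ~0.3 to ~0.01 as the separation grows.
* **Carrier recovery** (`carrier_peak_khz`): the post-filter spectral
  argmax of a default synthetic epoch, at 0.5 Hz resolution — 1.0 kHz.

Problem sizes (epochs per group, replicate counts) are the package's
standard desk-scale study design; `scripts/acceptance.py` re-runs the
type-I and carrier studies from scratch with a caller-supplied seed.

## What passing tests do and do not show

The generator expresses the structures the pipeline claims to exploit
(stable magnitude signatures, echo delays, mains, artifacts, Brownian
modulation) and omits much of real data: no Mie scattering physics, no
trap dynamics, no instrument drift, no inter-acquisition variability
beyond template randomness, and echo delays far longer than optical path
lengths (they stand for slow multi-path/trap-dynamics correlation at the
tens-of-milliseconds scale the coefficient features probe). Green tests
therefore certify the *pipeline arithmetic and its statistical
calibration*, not biological discriminability; the headline biological
findings require the original recordings.

## Numerical choices

* Wrapping convention: (−π, π], with π mapping to +π; unwrap is the exact
  inverse given the first value.
* Magnitude floor 1e-6 (relative) before log-magnitude, as argued above.
* Exact Mann–Whitney switch at n₁+n₂ ≤ 12 without ties.
* All randomness flows through `numpy.random.Generator`; dataset
  simulation spawns one child generator per acquisition, so runs are
  byte-reproducible under a fixed seed.
* Text exports use 12 significant digits; write → read → write is
  byte-identical.

## Known limitations

* The analytic-time Hilbert mode inherits analytic-signal edge effects;
  tone-based assertions trim 5% per edge.
* Surrogate validation cannot falsify magnitude-derived features (see
  above) — a property of amplitude-preserving surrogates, not a bug.
* With `scatter_mode="gaussian"` the coefficient features are
  uninformative at realistic epoch counts; this mode exists to make that
  comparison explicit.
* The pairwise stage applies no multiplicity correction by default (each
  feature is reported individually); Holm is available and labeled.
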