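"""Seeded generator of back-scattering-like acquisitions.

The generator emulates the statistical structure the analysis pipeline
assumes in a recording from a lensed-fiber trap-and-sense setup:

* a 1 kHz sinusoidal modulation carrier sampled at 5 kHz, amplitude-
  modulated by a slow Brownian-motion envelope (random walk low-passed
  below 10 Hz, so the 500 Hz high-pass removes most of it);
* a broadband scatter component (flat spectrum, std ``noise_sd``) that,
  together with the carrier, forms the back-scattered base field. By default
  (``scatter_mode="fixed_magnitude"``) its magnitude spectrum is
  deterministic and only its Fourier phases are random: the particle's
  spectral signature is stable from epoch to epoch while the waveform
  decorrelates, the regime in which magnitude-derived (minimum-phase)
  structure is repeatable. ``scatter_mode="gaussian"`` gives plain white
  noise instead;
* class-dependent bounce-back echoes: delayed, attenuated, optionally
  phase-jittered copies of the base field. Because the scatter component is
  broadband, an echo at delay d imprints a spectral ripple of period 1/d on
  the whole band, and the echo phase at the carrier (2*pi*f0*d) sets how
  constructively the echo adds to the carrier line — both make echo
  structure identifiable and discriminable downstream. ``echo_mode``
  selects zero-filled ("linear") or wrap-around ("circular", steady-state)
  delays; circular delays may be fractional;
* residual 50 Hz mains contamination;
* detector noise (white, 0.1 x ``noise_sd``, added after the echoes);
* occasional large artifacts: Poisson-placed single-sample spikes with
  standardized magnitude drawn uniformly in [6, 12], so they trip the
  |z| > 5 epoch rejection.

Setting ``period_s`` makes the whole signature periodic with that period
(scatter tiled from one period-length draw; requires circular echoes and no
Brownian/jitter components): any aligned window of one period then realizes
the designed magnitude spectrum exactly, which the Monte-Carlo studies use.

All randomness flows through a :class:`numpy.random.Generator`; a fixed
seed makes every sample path reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .exceptions import ConfigurationError
from .io import Acquisition, Dataset

__all__ = [
    "ClassTemplate",
    "StudyDesign",
    "simulate_acquisition",
    "simulate_dataset",
    "four_class_design",
]

DETECTOR_NOISE_FRACTION = 0.1
BROWNIAN_CUTOFF_HZ = 10.0
ARTIFACT_Z_RANGE = (6.0, 12.0)


@dataclass
class ClassTemplate:
    """Generative parameters of one particle class.

    Units: ``carrier_freq`` Hz, ``echo_delays`` seconds, ``phase_jitter_sd``
    radians, ``artifact_rate`` spikes per second; amplitudes share the
    (arbitrary) voltage unit of the carrier.
    """

    carrier_freq: float = 1000.0
    carrier_amp: float = 1.0
    echo_delays: tuple[float, ...] = (0.002,)
    echo_gains: tuple[float, ...] = (0.4,)
    phase_jitter_sd: float = 0.1
    brownian_sd: float = 0.05
    mains_amp: float = 0.05
    noise_sd: float = 0.3
    artifact_rate: float = 0.05
    scatter_mode: str = "fixed_magnitude"
    echo_mode: str = "linear"
    period_s: float | None = None

    def __post_init__(self) -> None:
        self.echo_delays = tuple(float(d) for d in self.echo_delays)
        self.echo_gains = tuple(float(g) for g in self.echo_gains)
        if len(self.echo_delays) != len(self.echo_gains):
            raise ConfigurationError("echo_delays and echo_gains differ in length")
        if any(g < 0 for g in self.echo_gains):
            raise ConfigurationError("echo gains must be non-negative")
        if any(d < 0 for d in self.echo_delays):
            raise ConfigurationError("echo delays must be non-negative")
        if self.scatter_mode not in ("fixed_magnitude", "gaussian"):
            raise ConfigurationError(f"unknown scatter_mode: {self.scatter_mode!r}")
        if self.echo_mode not in ("linear", "circular"):
            raise ConfigurationError(f"unknown echo_mode: {self.echo_mode!r}")
        if self.period_s is not None:
            # a periodic signature requires every component to share the period
            if self.brownian_sd != 0 or self.phase_jitter_sd != 0:
                raise ConfigurationError(
                    "period_s requires brownian_sd == 0 and phase_jitter_sd == 0"
                )
            if self.echo_mode != "circular":
                raise ConfigurationError("period_s requires echo_mode='circular'")


@dataclass
class StudyDesign:
    """A multi-class acquisition campaign."""

    classes: list[tuple[str, ClassTemplate, int]] = field(default_factory=list)
    fs: float = 5000.0
    duration: float = 60.0
    include_no_particle: bool = False
    n_no_particle: int = 13
    medium: str = "synthetic"

    def __post_init__(self) -> None:
        labels = [label for label, _, _ in self.classes]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("class labels must be unique")
        if any(n < 1 for _, _, n in self.classes):
            raise ConfigurationError("each class needs at least 1 acquisition")


def _slow_process(rng: np.random.Generator, n: int, fs: float,
                  target_sd: float) -> np.ndarray:
    """Low-passed random walk scaled to a target standard deviation."""
    walk = np.cumsum(rng.standard_normal(n))
    cutoff = min(BROWNIAN_CUTOFF_HZ, 0.45 * fs)
    sos = _signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    slow = _signal.sosfiltfilt(sos, walk)
    sd = slow.std()
    return slow * (target_sd / sd) if sd > 0 else np.zeros(n)


def _delayed(x: np.ndarray, d: float, mode: str) -> np.ndarray:
    """Delay ``x`` by ``d`` samples.

    Circular mode supports fractional delays (exact spectral phase shift);
    linear mode shifts by the nearest whole sample and zero-fills the head.
    """
    if mode == "circular":
        if float(d).is_integer():
            return np.roll(x, int(d))
        spectrum = np.fft.rfft(x)
        k = np.arange(len(spectrum))
        return np.fft.irfft(
            spectrum * np.exp(-2j * np.pi * k * d / len(x)), n=len(x)
        )
    d = int(round(d))
    out = np.zeros_like(x)
    if d < len(x):
        out[d:] = x[: len(x) - d]
    return out


def _scatter(rng: np.random.Generator, n: int, sd: float, mode: str) -> np.ndarray:
    """Broadband scatter component of the back-scattered field.

    ``fixed_magnitude`` (default): flat deterministic magnitude spectrum with
    iid uniform Fourier phases — the particle's spectral signature is stable
    from epoch to epoch while the waveform decorrelates, which is the regime
    in which magnitude-derived (minimum-phase) structure is repeatable.
    ``gaussian``: plain white Gaussian noise (fully stochastic spectrum).
    """
    if mode == "gaussian":
        return rng.normal(0.0, sd, n)
    n_bins = n // 2 + 1
    spectrum = np.zeros(n_bins, dtype=complex)
    phases = rng.uniform(0.0, 2 * np.pi, n_bins - 2)
    spectrum[1:-1] = np.exp(1j * phases)
    spectrum[-1] = rng.choice([-1.0, 1.0])
    x = np.fft.irfft(spectrum, n=n)
    return x * (sd / x.std())


def simulate_acquisition(
    template: ClassTemplate,
    fs: float = 5000.0,
    duration: float = 60.0,
    seed=None,
    class_label: str = "",
    medium: str = "synthetic",
    acquisition_id: str = "",
    settle: float = 0.0,
) -> Acquisition:
    """Draw one acquisition from a class template (see module docstring).

    ``settle`` seconds are simulated before the recording window and
    discarded, so the returned samples are in echo steady state (no echo
    onset transient at the start of the record).
    """
    if not template.carrier_freq < fs / 2:
        raise ConfigurationError(
            f"carrier {template.carrier_freq} Hz not below Nyquist {fs / 2} Hz"
        )
    if any(d >= duration for d in template.echo_delays):
        raise ConfigurationError("echo delay exceeds the acquisition duration")
    rng = np.random.default_rng(seed)
    n_settle = round(fs * settle)
    n = round(fs * duration) + n_settle
    t = np.arange(n) / fs

    envelope = 1.0
    if template.brownian_sd > 0:
        envelope = 1.0 + _slow_process(rng, n, fs, template.brownian_sd)
    phi0 = rng.uniform(0, 2 * np.pi)
    carrier = template.carrier_amp * np.sin(
        2 * np.pi * template.carrier_freq * t + phi0
    )
    if template.noise_sd > 0:
        if template.period_s is not None:
            n_period = round(fs * template.period_s)
            one = _scatter(rng, n_period, template.noise_sd,
                           template.scatter_mode)
            reps = int(np.ceil(n / n_period))
            scatter = np.tile(one, reps)[:n]
        else:
            scatter = _scatter(rng, n, template.noise_sd, template.scatter_mode)
    else:
        scatter = np.zeros(n)
    base = carrier * envelope + scatter

    samples = base.copy()
    base_quad = None
    for delay, gain in zip(template.echo_delays, template.echo_gains):
        if gain == 0.0:
            continue
        d = delay * fs if template.echo_mode == "circular" else round(delay * fs)
        echo = _delayed(base, d, template.echo_mode)
        if template.phase_jitter_sd > 0:
            if base_quad is None:
                base_quad = np.imag(_signal.hilbert(base))
            theta = _slow_process(rng, n, fs, template.phase_jitter_sd)
            quad = _delayed(base_quad, d, template.echo_mode)
            echo = echo * np.cos(theta) - quad * np.sin(theta)
        samples += gain * echo

    if template.mains_amp > 0:
        samples += template.mains_amp * np.sin(
            2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
        )
    if template.noise_sd > 0:
        samples += rng.normal(0.0, DETECTOR_NOISE_FRACTION * template.noise_sd, n)

    if template.artifact_rate > 0:
        n_spikes = rng.poisson(template.artifact_rate * duration)
        if n_spikes:
            pos = rng.integers(n_settle, n, n_spikes)
            mag = rng.uniform(*ARTIFACT_Z_RANGE, n_spikes)
            sign = rng.choice([-1.0, 1.0], n_spikes)
            samples[pos] += sign * mag * samples.std()

    samples = samples[n_settle:]
    return Acquisition(
        samples=samples, fs=fs, class_label=class_label, medium=medium,
        acquisition_id=acquisition_id or f"{class_label or 'acq'}_{rng.integers(1 << 30):08x}",
        provenance=f"synthetic seed={seed}",
    )


def simulate_dataset(design: StudyDesign, seed=None) -> Dataset:
    """Simulate a full study: every class, every acquisition, one seed."""
    rng = np.random.default_rng(seed)
    classes = list(design.classes)
    if design.include_no_particle:
        base_noise = classes[0][1].noise_sd if classes else 0.3
        classes.append((
            "NoParticle",
            ClassTemplate(echo_delays=(), echo_gains=(), phase_jitter_sd=0.0,
                          brownian_sd=0.0, mains_amp=0.05,
                          noise_sd=base_noise, artifact_rate=0.05),
            design.n_no_particle,
        ))
    acqs = []
    for label, template, n_acq in classes:
        for i in range(n_acq):
            child = rng.spawn(1)[0]
            acqs.append(
                simulate_acquisition(
                    template, fs=design.fs, duration=design.duration,
                    seed=child, class_label=label, medium=design.medium,
                    acquisition_id=f"{label}_{i:03d}",
                )
            )
    manifest = {
        a.acquisition_id: {"path": "", "class_label": a.class_label,
                           "medium": a.medium}
        for a in acqs
    }
    return Dataset(acquisitions=acqs, manifest=manifest)


def four_class_design(duration: float = 60.0, fs: float = 5000.0) -> StudyDesign:
    """The bundled 4-class synthetic study (three particle classes + blank).

    Class templates differ in echo delay/gain structure and phase jitter —
    the signal properties the pipeline is meant to resolve. Acquisition
    counts mirror a small trapped-particle campaign (15/15/10 plus 13
    blanks).
    """
    mock = ClassTemplate(echo_delays=(0.0024, 0.0050), echo_gains=(0.5, 0.25),
                         phase_jitter_sd=0.15)
    hst6 = ClassTemplate(echo_delays=(0.0028, 0.0056), echo_gains=(0.5, 0.25),
                         phase_jitter_sd=0.2)
    ps = ClassTemplate(echo_delays=(0.0016,), echo_gains=(0.6,),
                       phase_jitter_sd=0.05)
    return StudyDesign(
        classes=[("Mock", mock, 15), ("HST6", hst6, 15), ("PS", ps, 10)],
        fs=fs, duration=duration, include_no_particle=True,
    )
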