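"""Phase representations of back-scattering epochs.

Three representations are computed per epoch:

``DFT_PHASE``
    Principal argument of the one-sided DFT coefficients, bins 0..N/2.
    Carries the linear-delay ramp -2*pi*k*d/N of any time shift d.
``HILBERT_PHASE``
    Default mode ``spectral_minimum_phase``: the minimum-phase spectrum
    implied by the epoch's log-magnitude spectrum through the Hilbert
    relation between log-magnitude and phase of a minimum-phase system.
    This removes the linear-delay component entirely — two epochs differing
    only by a delay share the same magnitude spectrum, hence the same
    minimum-phase representation. Mode ``analytic_time`` instead returns the
    instantaneous phase arg(a[n]) of the analytic signal.
``HILBERT_PHASE_SLOPE``
    Principal-value first difference of the wrapped Hilbert phase — the
    phase of each point relative to its predecessor along the axis — which
    exposes bounce-back reflection patterns between adjacent points; the
    slope sequence is subsequently unwrapped like any other representation.

The minimum-phase spectrum is realized by the real-cepstrum folding
construction: c = IDFT(ln|X|), the causal fold (doubling positive
quefrencies) yields the complex cepstrum of the minimum-phase system, and
the imaginary part of its DFT is the phase. This is the exact discrete form
of "minus the Hilbert transform of the log-magnitude".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as _signal

from .exceptions import ConfigurationError, DataError
from .io import Epoch, PhaseMethod, PhaseRepresentation

__all__ = [
    "AnalyticSignal",
    "wrap",
    "dft_phase",
    "analytic_signal",
    "hilbert_phase",
    "phase_slope",
    "unwrap",
    "extract_representation",
]

#: relative floor applied to |X(k)| before taking logs. With a zero-phase
#: second-order 500 Hz high-pass ahead of the spectrum, stopband bins sit many
#: decades below the passband, where double-precision FFT/filter noise
#: dominates; flooring at 1e-6 of the peak keeps ln|X| determined by actual
#: signal content rather than rounding error.
MAGNITUDE_FLOOR = 1e-6


def wrap(values: np.ndarray) -> np.ndarray:
    """Wrap phase values into the principal interval (-pi, pi]."""
    values = np.asarray(values, dtype=float)
    return values - 2 * np.pi * np.ceil((values - np.pi) / (2 * np.pi))


def _principal_diff(values: np.ndarray) -> np.ndarray:
    return wrap(np.diff(values))


@dataclass
class AnalyticSignal:
    """Complex analytic extension of an epoch.

    The real part equals the source samples; the imaginary part is the
    discrete Hilbert transform (one-sided-spectrum construction); the
    modulus is the envelope.
    """

    values: np.ndarray
    source_epoch: str = ""

    @property
    def envelope(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def instantaneous_phase(self) -> np.ndarray:
        return np.angle(self.values)


def _check_finite(epoch: Epoch) -> np.ndarray:
    x = np.asarray(epoch.samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError(f"epoch {epoch.epoch_id} contains non-finite samples")
    return x


def dft_phase(epoch: Epoch) -> PhaseRepresentation:
    """Wrapped phase of the one-sided DFT, bins 0..N/2."""
    x = _check_finite(epoch)
    values = np.angle(np.fft.rfft(x))
    return PhaseRepresentation(
        values=values, method=PhaseMethod.DFT_PHASE, axis="frequency_bins",
        wrapped=True, source_epoch=epoch.epoch_id,
    )


def analytic_signal(epoch: Epoch) -> AnalyticSignal:
    """Analytic signal via the one-sided-spectrum construction."""
    x = _check_finite(epoch)
    if len(x) < 2:
        raise DataError("analytic signal requires at least 2 samples")
    return AnalyticSignal(values=_signal.hilbert(x), source_epoch=epoch.epoch_id)


def _minimum_phase_spectrum(x: np.ndarray, magnitude_floor: float = None) -> np.ndarray:
    """One-sided minimum-phase spectrum (radians) of ``x`` via the cepstrum."""
    n = len(x)
    mag = np.abs(np.fft.fft(x))
    if magnitude_floor is None:
        magnitude_floor = MAGNITUDE_FLOOR
    floor = magnitude_floor * mag.max()
    if floor == 0.0:
        raise DataError("all-zero epoch has no defined phase spectrum")
    log_mag = np.log(np.maximum(mag, floor))
    cepstrum = np.fft.ifft(log_mag).real
    fold = np.zeros(n)
    fold[0] = 1.0
    if n % 2 == 0:
        fold[n // 2] = 1.0
        fold[1 : n // 2] = 2.0
    else:
        fold[1 : (n + 1) // 2] = 2.0
    phase_full = np.fft.fft(cepstrum * fold).imag
    return phase_full[: n // 2 + 1]


def hilbert_phase(
    epoch: Epoch,
    mode: Literal["spectral_minimum_phase", "analytic_time"] = "spectral_minimum_phase",
) -> PhaseRepresentation:
    """Hilbert-transform-derived phase representation (wrapped).

    See the module docstring for the two modes. The spectral mode floors
    magnitude bins below ``MAGNITUDE_FLOOR * max|X|`` so the log stays
    finite on near-silent bins.
    """
    x = _check_finite(epoch)
    if mode == "spectral_minimum_phase":
        values = wrap(_minimum_phase_spectrum(x))
        axis = "frequency_bins"
    elif mode == "analytic_time":
        values = np.angle(_signal.hilbert(x))
        axis = "time_samples"
    else:
        raise ConfigurationError(f"unknown Hilbert mode: {mode!r}")
    return PhaseRepresentation(
        values=values, method=PhaseMethod.HILBERT_PHASE, axis=axis,
        wrapped=True, source_epoch=epoch.epoch_id,
    )


def phase_slope(phase: PhaseRepresentation) -> PhaseRepresentation:
    """Point-to-point principal-value phase difference (wrapped slope).

    Input must be a wrapped representation; output has length - 1 and is
    itself wrapped, to be unwrapped downstream.
    """
    if not phase.wrapped:
        raise ConfigurationError("phase_slope expects a wrapped representation")
    if len(phase) < 2:
        raise DataError("phase_slope requires at least 2 phase values")
    return PhaseRepresentation(
        values=_principal_diff(phase.values),
        method=PhaseMethod.HILBERT_PHASE_SLOPE, axis=phase.axis,
        wrapped=True, source_epoch=phase.source_epoch,
    )


def unwrap(phase: PhaseRepresentation) -> PhaseRepresentation:
    """Unwrap a representation: cumulative sum of principal-value differences.

    The first output value equals the first input value; wrapping the output
    back to (-pi, pi] recovers the input.
    """
    if not phase.wrapped:
        raise ConfigurationError("representation is already unwrapped")
    values = phase.values
    if len(values) == 0:
        unwrapped = values.copy()
    else:
        unwrapped = np.concatenate(
            [[values[0]], values[0] + np.cumsum(_principal_diff(values))]
        )
    return PhaseRepresentation(
        values=unwrapped, method=phase.method, axis=phase.axis,
        wrapped=False, source_epoch=phase.source_epoch,
    )


def extract_representation(
    epoch: Epoch,
    method: PhaseMethod,
    hilbert_mode: str = "spectral_minimum_phase",
) -> PhaseRepresentation:
    """Unwrapped representation for one epoch and one method."""
    method = PhaseMethod(method)
    if method is PhaseMethod.DFT_PHASE:
        return unwrap(dft_phase(epoch))
    if method is PhaseMethod.HILBERT_PHASE:
        return unwrap(hilbert_phase(epoch, mode=hilbert_mode))
    if method is PhaseMethod.HILBERT_PHASE_SLOPE:
        return unwrap(phase_slope(hilbert_phase(epoch, mode=hilbert_mode)))
    raise ConfigurationError(f"unknown phase method: {method!r}")
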