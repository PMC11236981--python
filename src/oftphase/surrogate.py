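"""Surrogate-data validation of feature significance.

Phase-randomized surrogates keep each epoch's amplitude spectrum bin-for-bin
(hence its total power, by Parseval) while replacing the Fourier phases with
independent uniform draws under conjugate symmetry, so the surrogate is real
and shares the original's linear (second-order) structure but none of its
phase structure. Re-running the phase -> feature -> test pipeline on
surrogate datasets builds an empirical null for the original p-value: if the
original significance survives only because of linear/noise structure, it
re-appears in the surrogates; if it is driven by phase structure, the
original p-value falls below the null's lower quantile.

Caveat (by construction, not a defect): features computed from the spectral
minimum phase are functions of the magnitude spectrum only and are therefore
invariant under phase randomization — this surrogate can only interrogate
Fourier-phase-sensitive features (DFT phase, analytic-time instantaneous
phase). The IAAFT variant additionally preserves the amplitude distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError, DataError
from .features import build_feature_table
from .io import Epoch, PhaseMethod
from .stats import kruskal_wallis, mann_whitney

__all__ = [
    "SurrogateReport",
    "phase_randomized_surrogate",
    "iaaft_surrogate",
    "surrogate_validation",
]

MIN_SURROGATES = 19


def _randomized_spectrum(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(x)
    if n % 2:
        x = x[:-1]  # truncate one sample so the Nyquist bin is well defined
        n -= 1
    spectrum = np.fft.rfft(x)
    phases = rng.uniform(0.0, 2 * np.pi, len(spectrum) - 2)
    randomized = spectrum.copy()
    # DC and Nyquist stay untouched (real); interior bins keep |X| exactly
    randomized[1:-1] = np.abs(spectrum[1:-1]) * np.exp(1j * phases)
    return np.fft.irfft(randomized, n=n)


def phase_randomized_surrogate(epoch: Epoch, seed=None) -> Epoch:
    """Fourier phase-randomized surrogate of one epoch.

    Preserves the amplitude spectrum bin-wise (DC included, so the mean is
    unchanged) and draws new phases; odd-length epochs are truncated by one
    sample. ``seed`` may be an int or a :class:`numpy.random.Generator`.
    """
    rng = np.random.default_rng(seed)
    return replace(epoch, samples=_randomized_spectrum(epoch.samples, rng))


def iaaft_surrogate(epoch: Epoch, seed=None, n_iter: int = 100) -> Epoch:
    """Iterative amplitude-adjusted Fourier-transform surrogate.

    Alternates spectrum matching and rank-ordering until the surrogate has
    (approximately) the original amplitude spectrum and exactly the original
    amplitude distribution.
    """
    rng = np.random.default_rng(seed)
    x = epoch.samples
    if len(x) % 2:
        x = x[:-1]
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    s = rng.permutation(x)
    for _ in range(n_iter):
        spec = np.fft.rfft(s)
        mag = np.abs(spec)
        mag[mag == 0] = 1.0
        s = np.fft.irfft(target_amp * spec / mag, n=len(x))
        ranks = np.argsort(np.argsort(s))
        s_new = sorted_x[ranks]
        if np.array_equal(s_new, s):
            break
        s = s_new
    return replace(epoch, samples=s)


@dataclass
class SurrogateReport:
    """Outcome of one surrogate-validation run."""

    feature: str
    method: str
    algorithm: str
    original_p: float
    surrogate_p: np.ndarray
    alpha: float

    @property
    def n_surrogates(self) -> int:
        return len(self.surrogate_p)

    @property
    def quantile(self) -> float:
        """Empirical quantile of the original p within the surrogate null."""
        return float(
            (1 + np.sum(self.surrogate_p <= self.original_p))
            / (self.n_surrogates + 1)
        )

    @property
    def structure_driven(self) -> bool:
        """True iff the original p-value undercuts the null's alpha-quantile."""
        return bool(
            self.original_p < np.quantile(self.surrogate_p, self.alpha)
        )

    def to_row(self) -> dict:
        return {
            "feature": self.feature, "method": self.method,
            "algorithm": self.algorithm, "original_p": self.original_p,
            "surrogate_p_median": float(np.median(self.surrogate_p)),
            "quantile": self.quantile, "n_surrogates": self.n_surrogates,
            "structure_driven": self.structure_driven, "alpha": self.alpha,
        }


def _feature_pvalue(
    epochs: Sequence[Epoch], feature: str, method: PhaseMethod,
    hilbert_mode: str, alpha: float,
) -> float:
    table = build_feature_table(epochs, methods=[method],
                                hilbert_mode=hilbert_mode)
    groups = {
        str(lbl): sub[feature].to_numpy()
        for lbl, sub in table.groupby("class_label")
    }
    if len(groups) < 2:
        raise DataError("surrogate validation needs at least 2 classes")
    if len(groups) == 2:
        (la, va), (lb, vb) = sorted(groups.items())
        return mann_whitney(va, vb, labels=(la, lb), alpha=alpha).p_value
    return kruskal_wallis(groups, alpha=alpha).p_value


def surrogate_validation(
    epochs: Sequence[Epoch],
    feature: str,
    method: PhaseMethod | str = PhaseMethod.DFT_PHASE,
    n_surrogates: int = 99,
    seed=None,
    algorithm: str = "phase_randomized",
    hilbert_mode: str = "spectral_minimum_phase",
    alpha: float = 0.05,
) -> SurrogateReport:
    """Re-run phase -> feature -> test on surrogate datasets.

    Each surrogate dataset replaces every (preprocessed, retained) epoch with
    an independent surrogate; the class labels are untouched, so the null
    retains the design but destroys within-epoch phase structure.
    """
    if n_surrogates < MIN_SURROGATES:
        raise ConfigurationError(
            f"n_surrogates must be >= {MIN_SURROGATES}, got {n_surrogates}"
        )
    make = {"phase_randomized": phase_randomized_surrogate,
            "iaaft": iaaft_surrogate}.get(algorithm)
    if make is None:
        raise ConfigurationError(f"unknown surrogate algorithm: {algorithm!r}")
    method = PhaseMethod(method)
    rng = np.random.default_rng(seed)
    original_p = _feature_pvalue(list(epochs), feature, method,
                                 hilbert_mode, alpha)
    surrogate_p = np.empty(n_surrogates)
    for i in range(n_surrogates):
        surrogates = [make(e, seed=rng) for e in epochs]
        surrogate_p[i] = _feature_pvalue(surrogates, feature, method,
                                         hilbert_mode, alpha)
    return SurrogateReport(
        feature=feature, method=method.value, algorithm=algorithm,
        original_p=original_p, surrogate_p=surrogate_p, alpha=alpha,
    )
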