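"""Phase-derived features: 6 descriptive statistics + 40 coefficients.

Per (epoch, phase method) a 46-value feature vector is computed from the
unwrapped representation:

* subset 1 — STD, RMS, KURT, IQR, SKEW, ENT over the whole representation;
* subset 2 — Coeff_1 .. Coeff_40, the unwrapped phase at positions 1..40 of
  the method's axis (the DC bin / position 0 is excluded: for a high-pass
  filtered, standardized epoch it is degenerate).

Estimator conventions (recorded in the table attrs so runs are comparable):
population (biased) standard deviation, Fisher-Pearson skewness g1, excess
kurtosis g2, linear-interpolation quantiles for the IQR, and Shannon entropy
in bits of a 64-bin equal-width histogram over the representation's own
[min, max] — deterministic and invariant under positive rescaling.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .exceptions import DataError
from .io import Epoch, PhaseMethod, PhaseRepresentation
from .phase import extract_representation

__all__ = [
    "DESCRIPTIVE_FEATURES",
    "COEFFICIENT_FEATURES",
    "FEATURE_COLUMNS",
    "META_COLUMNS",
    "descriptive_features",
    "coefficient_features",
    "build_feature_table",
]

N_COEFFICIENTS = 40
ENTROPY_BINS = 64

DESCRIPTIVE_FEATURES = ["STD", "RMS", "KURT", "IQR", "SKEW", "ENT"]
COEFFICIENT_FEATURES = [f"Coeff_{i}" for i in range(1, N_COEFFICIENTS + 1)]
FEATURE_COLUMNS = DESCRIPTIVE_FEATURES + COEFFICIENT_FEATURES
META_COLUMNS = ["epoch_id", "parent_id", "class_label", "medium", "method"]


def _shannon_entropy(values: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(values, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def descriptive_features(phase: PhaseRepresentation) -> dict[str, float]:
    """Subset-1 statistics of an unwrapped representation.

    A constant representation has STD = IQR = 0 and ENT = 0 but undefined
    skewness/kurtosis; those are emitted as NaN so downstream screening can
    exclude the epoch for these features.
    """
    if phase.wrapped:
        raise DataError("descriptive features are defined on unwrapped phase")
    v = phase.values
    if len(v) < 4:
        raise DataError("descriptive features require at least 4 phase values")
    std = float(np.std(v))
    if std == 0.0:
        skew = kurt = float("nan")
    else:
        skew = float(_stats.skew(v, bias=True))
        kurt = float(_stats.kurtosis(v, fisher=True, bias=True))
    return {
        "STD": std,
        "RMS": float(np.sqrt(np.mean(v**2))),
        "KURT": kurt,
        "IQR": float(np.percentile(v, 75) - np.percentile(v, 25)),
        "SKEW": skew,
        "ENT": _shannon_entropy(v),
    }


def coefficient_features(
    phase: PhaseRepresentation, n_coeff: int = N_COEFFICIENTS
) -> dict[str, float]:
    """Subset-2 features: unwrapped phase at positions 1..n_coeff."""
    if phase.wrapped:
        raise DataError("coefficient features are defined on unwrapped phase")
    if len(phase.values) < n_coeff + 1:
        raise DataError(
            f"representation has {len(phase.values)} values; "
            f"{n_coeff + 1} required for {n_coeff} coefficients"
        )
    coeffs = phase.values[1 : n_coeff + 1]
    if not np.all(np.isfinite(coeffs)):
        raise DataError("non-finite coefficient encountered")
    return {f"Coeff_{i + 1}": float(c) for i, c in enumerate(coeffs)}


def feature_vector(
    epoch: Epoch, method: PhaseMethod, hilbert_mode: str = "spectral_minimum_phase"
) -> dict[str, float]:
    """The 46 features of one epoch under one phase method."""
    rep = extract_representation(epoch, method, hilbert_mode=hilbert_mode)
    row = descriptive_features(rep)
    row.update(coefficient_features(rep))
    return row


def build_feature_table(
    epochs: Sequence[Epoch],
    methods: Iterable[PhaseMethod | str] = tuple(PhaseMethod),
    hilbert_mode: str = "spectral_minimum_phase",
) -> pd.DataFrame:
    """Assemble the epochs x features table.

    One row per (epoch, method); columns are the metadata columns followed by
    the 46 feature columns in a fixed order. Deterministic given its inputs.
    """
    epochs = list(epochs)
    if not epochs:
        raise DataError("no epochs to featurize")
    methods = [PhaseMethod(m) for m in methods]
    rows = []
    for epoch in epochs:
        for method in methods:
            row = {
                "epoch_id": epoch.epoch_id,
                "parent_id": epoch.parent_id,
                "class_label": epoch.class_label,
                "medium": epoch.medium,
                "method": method.value,
            }
            row.update(feature_vector(epoch, method, hilbert_mode=hilbert_mode))
            rows.append(row)
    table = pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_COLUMNS)
    table.attrs["hilbert_mode"] = hilbert_mode
    table.attrs["conventions"] = (
        "population STD; Fisher-Pearson g1 skew; excess kurtosis g2; "
        "type-7 quantile IQR; Shannon entropy (bits), 64 equal-width bins"
    )
    return table
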