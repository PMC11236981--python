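"""Data model and on-disk formats.

An :class:`Acquisition` is one raw back-scattering voltage series recorded by
the photodetector of a fiber-tweezers setup (arbitrary units, sampling rate
``fs``), tagged with the particle class and suspension medium. Acquisitions
are segmented into fixed-duration :class:`Epoch` objects, the unit of feature
extraction. A :class:`Dataset` bundles acquisitions with a manifest.

Two acquisition dialects are supported:

* ``tsv`` — two columns (time_s, voltage) preceded by ``# key=value`` header
  lines (``fs`` is mandatory);
* ``binary`` — raw little-endian float64 samples with a JSON sidecar
  (``<path>.json``) carrying the metadata.

Voltages are never rescaled on read; normalization is an explicit
preprocessing step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError

__all__ = [
    "Acquisition",
    "Epoch",
    "Dataset",
    "PhaseMethod",
    "PhaseRepresentation",
    "read_acquisition",
    "write_acquisition",
    "write_results",
    "read_feature_table",
]

#: significant digits used for all text exports; round-trip is lossless at
#: this precision and re-export is byte-stable.
TEXT_PRECISION = 12
_FLOAT_FMT = f"%.{TEXT_PRECISION}g"


@dataclass
class Acquisition:
    """One raw back-scattering voltage series with its metadata."""

    samples: np.ndarray
    fs: float
    class_label: str = ""
    medium: str = ""
    acquisition_id: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise FormatError("acquisition samples must be a 1-D series")
        if not self.fs > 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        """Duration in seconds implied by the sample count."""
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class Epoch:
    """A fixed-duration segment of an acquisition.

    Epochs from one parent are non-overlapping and ordered by ``index``.
    ``normalized`` flags that the samples have been standardized (zero mean,
    unit standard deviation) by the artifact-rejection stage.
    """

    samples: np.ndarray
    fs: float
    parent_id: str = ""
    index: int = 0
    class_label: str = ""
    medium: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def epoch_len(self) -> float:
        return len(self.samples) / self.fs

    @property
    def epoch_id(self) -> str:
        return f"{self.parent_id}:{self.index:04d}"

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class Dataset:
    """A collection of acquisitions plus the manifest that locates them."""

    acquisitions: list[Acquisition] = field(default_factory=list)
    manifest: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.acquisition_id for a in self.acquisitions]
        if len(set(ids)) != len(ids):
            raise FormatError("acquisition_ids must be unique within a dataset")

    def __len__(self) -> int:
        return len(self.acquisitions)

    def __iter__(self):
        return iter(self.acquisitions)

    @property
    def class_labels(self) -> list[str]:
        return sorted({a.class_label for a in self.acquisitions})


class PhaseMethod(str, Enum):
    """The three phase-extraction methods."""

    DFT_PHASE = "dft"
    HILBERT_PHASE = "hilbert"
    HILBERT_PHASE_SLOPE = "hilbert_slope"


@dataclass
class PhaseRepresentation:
    """A 1-D phase sequence (radians) tagged with its provenance.

    ``axis`` is ``"frequency_bins"`` for spectral representations (one-sided,
    bins 0..N/2, spacing fs/N) or ``"time_samples"`` for the analytic-signal
    instantaneous phase. Wrapped values lie in (-pi, pi]; unwrapped values
    have successive differences of magnitude <= pi.
    """

    values: np.ndarray
    method: PhaseMethod
    axis: str = "frequency_bins"
    wrapped: bool = True
    source_epoch: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# acquisition I/O


def _parse_header(path: Path) -> tuple[dict, int]:
    meta: dict = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta, n_header


def read_acquisition(
    path: str | Path,
    format: str = "tsv",
    meta: Mapping | None = None,
) -> Acquisition:
    """Read one acquisition from disk.

    ``meta`` supplies or overrides metadata absent from the file header;
    ``fs`` must be available from one of the two sources. A declared
    ``duration`` that disagrees with the sample count raises
    :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "tsv":
        header, n_header = _parse_header(path)
        data = np.loadtxt(path, skiprows=n_header, ndmin=2)
        samples = data[:, -1]  # last column is voltage; first may be time_s
    elif format == "binary":
        sidecar = path.with_suffix(path.suffix + ".json")
        header = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        samples = np.fromfile(path, dtype="<f8")
        n_header = 0
    else:
        raise ConfigurationError(f"unknown acquisition format: {format!r}")

    merged = dict(header)
    if meta:
        merged.update(meta)
    if "fs" not in merged:
        raise ConfigurationError(f"sampling rate 'fs' missing for {path}")
    fs = float(merged["fs"])
    if "duration" in merged:
        declared = round(fs * float(merged["duration"]))
        if declared != len(samples):
            raise FormatError(
                f"{path}: {len(samples)} samples but declared duration "
                f"{merged['duration']} s at fs={fs} implies {declared}"
            )
    return Acquisition(
        samples=samples,
        fs=fs,
        class_label=str(merged.get("class_label", "")),
        medium=str(merged.get("medium", "")),
        acquisition_id=str(merged.get("acquisition_id", path.stem)),
        provenance=str(merged.get("provenance", f"file:{path.name}")),
    )


def write_acquisition(acq: Acquisition, path: str | Path, format: str = "tsv") -> None:
    """Write one acquisition; inverse of :func:`read_acquisition`."""
    path = Path(path)
    meta = {
        "fs": repr(float(acq.fs)),
        "class_label": acq.class_label,
        "medium": acq.medium,
        "acquisition_id": acq.acquisition_id,
        "provenance": acq.provenance,
    }
    if format == "tsv":
        t = np.arange(len(acq.samples)) / acq.fs
        with open(path, "w") as fh:
            for key, val in meta.items():
                fh.write(f"# {key}={val}\n")
            np.savetxt(fh, np.column_stack([t, acq.samples]),
                       fmt=_FLOAT_FMT, delimiter="\t")
    elif format == "binary":
        acq.samples.astype("<f8").tofile(path)
        meta["fs"] = float(acq.fs)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    else:
        raise ConfigurationError(f"unknown acquisition format: {format!r}")


def load_manifest(path: str | Path) -> Dataset:
    """Load a dataset from a manifest TSV.

    Columns: acquisition_id, path, class_label, medium. Paths are resolved
    relative to the manifest location. Row order does not matter: the dataset
    is sorted by acquisition_id.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such manifest: {path}")
    rows = pd.read_csv(path, sep="\t", dtype=str)
    required = {"acquisition_id", "path", "class_label", "medium"}
    if not required.issubset(rows.columns):
        raise FormatError(f"manifest must have columns {sorted(required)}")
    rows = rows.sort_values("acquisition_id")
    acqs, manifest = [], {}
    for _, row in rows.iterrows():
        fpath = path.parent / row["path"]
        fmt = "binary" if fpath.suffix in (".raw", ".bin", ".f64") else "tsv"
        acq = read_acquisition(
            fpath, format=fmt,
            meta={"acquisition_id": row["acquisition_id"],
                  "class_label": row["class_label"], "medium": row["medium"]},
        )
        acqs.append(acq)
        manifest[row["acquisition_id"]] = {
            "path": str(fpath), "class_label": row["class_label"],
            "medium": row["medium"],
        }
    return Dataset(acquisitions=acqs, manifest=manifest)


def write_manifest(dataset: Dataset, out_dir: str | Path, format: str = "tsv") -> Path:
    """Write every acquisition of ``dataset`` plus a manifest TSV; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".tsv" if format == "tsv" else ".raw"
    records = []
    for acq in dataset:
        fname = f"{acq.acquisition_id}{ext}"
        write_acquisition(acq, out_dir / fname, format=format)
        records.append(
            {"acquisition_id": acq.acquisition_id, "path": fname,
             "class_label": acq.class_label, "medium": acq.medium}
        )
    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(records).to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


# ---------------------------------------------------------------------------
# result I/O


def write_results(obj, path: str | Path, format: str = "tsv") -> None:
    """Write a feature table or a statistics report.

    Accepts a :class:`pandas.DataFrame` (feature table, flattened report) or
    any object exposing ``to_frame()``. Numeric values are written with
    :data:`TEXT_PRECISION` significant digits so a write -> read -> write
    cycle is byte-identical.
    """
    frame = obj.to_frame() if hasattr(obj, "to_frame") else obj
    if not isinstance(frame, pd.DataFrame):
        raise ConfigurationError(f"cannot serialize object of type {type(obj)}")
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    elif format == "json":
        text = frame.to_json(orient="records", double_precision=15, indent=1)
        path.write_text(text)
    else:
        raise ConfigurationError(f"unknown results format: {format!r}")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read back a feature table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


def concat_epochs(epochs: Iterable[Epoch]) -> np.ndarray:
    """Concatenate ordered epochs back into one sample vector."""
    return np.concatenate([e.samples for e in epochs]) if epochs else np.empty(0)
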