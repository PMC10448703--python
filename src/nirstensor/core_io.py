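"""Data model, readers/writers, configuration and logging for the pipeline.

The in-memory objects here are shared by every stage: a continuous
:class:`FNIRSRecording` (channels x samples of HbO concentration change),
the :class:`EpochDefinition` that slices it into trials, the 2x2
:class:`DesignInfo`, and the trial-averaged :class:`SubjectHRF`.

Two on-disk formats are supported for recordings:

* **SNIRF** (HDF5, ``.snirf``) — the field's standard container, written
  through :mod:`h5py` using the v1.0 layout (``/nirs/data1/dataTimeSeries``,
  ``measurementList``, ``stim`` groups, ``metaDataTags``).
* **CSV** — a long-format table (``subject, channel, time_s, hbo``) with a
  JSON sidecar carrying sampling rate, trial onsets and the
  channel-to-hemisphere map; chosen for diffability.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DesignInfo",
    "EpochDefinition",
    "FNIRSRecording",
    "SubjectHRF",
    "PipelineConfig",
    "load_config",
    "read_recording",
    "write_recording",
    "default_hemisphere_map",
    "get_logger",
]

LOG_FORMAT = "%(asctime)s %(name)s [%(levelname)s] %(message)s"


def get_logger(name: str = "nirstensor", logfile: str | Path | None = None) -> logging.Logger:
    """Structured logger writing to stderr (and optionally a file)."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter(LOG_FORMAT))
        logger.addHandler(fh)
    return logger


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ConfigurationError(ValueError):
    """A configuration value is missing, unknown, or inconsistent."""


class DataError(ValueError):
    """Input data violate a contract (missing condition, bad epoch, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

Scope = str  # {"between", "within"}
_SCOPES = ("between", "within")


@dataclass(frozen=True)
class DesignInfo:
    """A 2x2 factorial design, fully between-subjects or mixed.

    ``subject_assignments`` maps each subject id to its ``(level_a, level_b)``
    cell; for a within factor the corresponding entry names the *levels the
    subject contributes* and every subject provides one HRF per level.
    """

    factor_a_name: str = "entity_type"
    factor_b_name: str = "action_sequence"
    factor_a_scope: Scope = "between"
    factor_b_scope: Scope = "between"
    levels_a: tuple[str, str] = ("a1", "a2")
    levels_b: tuple[str, str] = ("b1", "b2")
    subject_assignments: Mapping[str, tuple[str, str]] = field(default_factory=dict)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.factor_a_scope not in _SCOPES or self.factor_b_scope not in _SCOPES:
            raise ConfigurationError("factor scopes must be 'between' or 'within'")
        if self.factor_a_scope == "within" and self.factor_b_scope == "within":
            raise ConfigurationError("at most one within-subjects factor is supported")
        if len(set(self.levels_a)) != 2 or len(set(self.levels_b)) != 2:
            raise ConfigurationError("exactly two distinct levels per factor")
        for sid, cell in self.subject_assignments.items():
            la, lb = cell
            if self.factor_a_scope == "between" and la not in self.levels_a:
                raise ConfigurationError(f"subject {sid}: unknown level_a {la!r}")
            if self.factor_b_scope == "between" and lb not in self.levels_b:
                raise ConfigurationError(f"subject {sid}: unknown level_b {lb!r}")

    @property
    def is_mixed(self) -> bool:
        return "within" in (self.factor_a_scope, self.factor_b_scope)

    @property
    def within_factor(self) -> str | None:
        if self.factor_a_scope == "within":
            return "a"
        if self.factor_b_scope == "within":
            return "b"
        return None

    def cell_of(self, subject_id: str) -> tuple[str, str]:
        try:
            return tuple(self.subject_assignments[subject_id])  # type: ignore[return-value]
        except KeyError:
            raise DataError(f"subject {subject_id!r} has no design assignment") from None


@dataclass(frozen=True)
class EpochDefinition:
    """Trial epoch geometry: baseline, stimulus, post-stimulus (seconds).

    Sample counts follow the inclusive-endpoint convention:
    ``n_samples = round(total_s * fs) + 1``, with time 0 at stimulus onset,
    so a 2 + 15 + 10 s epoch at 50 Hz yields 1351 samples.
    """

    baseline_s: float = 2.0
    stimulus_s: float = 15.0
    post_s: float = 10.0
    fs: float = 50.0

    def __post_init__(self) -> None:
        for name in ("baseline_s", "stimulus_s", "post_s", "fs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"EpochDefinition.{name} must be > 0")

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.stimulus_s + self.post_s

    @property
    def n_samples(self) -> int:
        return int(round(self.total_s * self.fs)) + 1

    @property
    def n_baseline(self) -> int:
        """Samples strictly before stimulus onset (half-open [start, onset))."""
        return int(round(self.baseline_s * self.fs))

    def times(self) -> np.ndarray:
        """Time axis in seconds, 0 at stimulus onset."""
        return np.arange(self.n_samples) / self.fs - self.baseline_s


@dataclass
class FNIRSRecording:
    """Continuous HbO recording for one subject.

    ``hbo`` is channels x samples in micromolar concentration change;
    ``trial_onsets`` holds 0-based sample indices paired with condition
    labels of the form ``"level_a|level_b"`` (or a single level for mixed
    designs where the other factor is between).
    """

    subject_id: str
    hbo: np.ndarray
    fs: float
    trial_onsets: list[tuple[int, str]]
    channel_ids: list[str]
    hemisphere_map: dict[str, str]

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        if self.hbo.ndim != 2:
            raise FormatError("hbo must be a channels x samples matrix")
        if len(self.channel_ids) != self.hbo.shape[0]:
            raise FormatError(
                f"channel_ids ({len(self.channel_ids)}) do not match hbo rows ({self.hbo.shape[0]})"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise FormatError("channel_ids must be unique")
        for ch in self.channel_ids:
            hemi = self.hemisphere_map.get(ch)
            if hemi not in ("left", "right"):
                raise ConfigurationError(f"channel {ch!r} lacks a left/right hemisphere mapping")

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def validate_epochs(self, epoch: EpochDefinition) -> None:
        """Reject onsets whose epoch window would fall outside the data."""
        for onset, label in self.trial_onsets:
            start = onset - epoch.n_baseline
            stop = start + epoch.n_samples
            if start < 0 or stop > self.n_samples:
                raise DataError(
                    f"subject {self.subject_id}: onset {onset} ({label}) does not leave room "
                    f"for a full epoch of {epoch.n_samples} samples"
                )


@dataclass
class SubjectHRF:
    """Trial-averaged hemodynamic response for one subject and condition."""

    subject_id: str
    condition: tuple[str, str]
    hrf: np.ndarray  # time x channel, micromolar
    epoch: EpochDefinition
    channel_ids: list[str]
    n_trials_averaged: int = 1

    def __post_init__(self) -> None:
        self.hrf = np.asarray(self.hrf, dtype=float)
        if self.hrf.shape[0] != self.epoch.n_samples:
            raise DataError(
                f"HRF rows ({self.hrf.shape[0]}) do not match epoch samples ({self.epoch.n_samples})"
            )
        if self.hrf.shape[1] != len(self.channel_ids):
            raise DataError("HRF columns do not match channel_ids")
        if self.n_trials_averaged < 1:
            raise DataError("n_trials_averaged must be >= 1")


def default_hemisphere_map(channel_ids: Sequence[str]) -> dict[str, str]:
    """First half of the channel list -> left, second half -> right.

    Matches the conventional numbering where channels 1-10 cover the left
    and 11-20 the right temporal cortex.
    """
    n = len(channel_ids)
    half = n // 2
    return {ch: ("left" if i < half else "right") for i, ch in enumerate(channel_ids)}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with its published default."""

    # decomposition
    error_threshold: float = 0.10     # rank accepted when rel. error < 10%
    n_runs: int = 10                  # CPD restarts to cover nonuniqueness
    cpd_max_rank: int = 15
    cpd_rank: int | None = None       # fixed rank; None -> automatic selection
    td_ranks: tuple[int, int] | None = None  # fixed (Rt, Rc); None -> automatic
    cpd_max_iter: int = 500
    cpd_tol: float = 1e-8
    td_max_iter: int = 200
    td_tol: float = 1e-8
    # screening
    temporal_threshold: float = 0.01  # mean |value| in [onset+2 s, offset)
    spectral_cutoff_hz: float = 0.1   # hemodynamics live below this
    consensus_r: float = 0.5          # cross-run matching r threshold
    spectral_statistic: str = "argmax"  # or "centroid"
    consensus_mode: str = "both"      # temporal AND spatial match ("either" optional)
    # inference
    alpha: float = 0.05
    fdr_correction: bool = False
    toi_half_width_s: float = 1.0
    toi_post_fraction: float = 0.5    # within-stimulus peak must reach this
    roi_fraction: float = 0.5         # channels >= fraction * max enter the ROI
    bayes_prior_scale: float = 0.707  # Cauchy scale of the JZS prior
    # tensorisation
    stft_window_s: float = 10.0
    stft_overlap: float = 0.75
    # preprocessing
    baseline_correct: bool = True
    resample_method: str = "linear"   # or "polyphase"
    # grand averaging (must be supplied explicitly to run that branch)
    grandavg_toi: tuple[float, float] | None = None
    grandavg_roi: list[str] | None = None
    # orchestration
    hemispheres: tuple[str, ...] = ("left", "right")
    method: str = "both"              # {"cpd", "td", "both"}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_TUPLE_FIELDS = {"td_ranks", "grandavg_toi", "hemispheres"}


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> PipelineConfig:
    """Load a YAML/JSON pipeline configuration; absent keys take defaults.

    Unknown keys raise :class:`ConfigurationError` listing the offenders.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config root must be a mapping, got {type(loaded).__name__}")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {', '.join(unknown)}")
    for key in _TUPLE_FIELDS & set(data):
        if isinstance(data[key], list):
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".snirf":
        return "snirf"
    if suffix == ".csv":
        return "csv"
    raise FormatError(f"cannot infer format from {path.name!r}; pass format explicitly")


def write_recording(recording: FNIRSRecording, path: str | Path, format: str | None = None) -> Path:
    """Persist a recording as SNIRF or long-format CSV (+ JSON sidecar)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "snirf":
        _write_snirf(recording, path)
    elif fmt == "csv":
        _write_csv(recording, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    return path


def read_recording(path: str | Path, format: str | None = None) -> FNIRSRecording:
    """Read a recording previously written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "snirf":
        return _read_snirf(path)
    if fmt == "csv":
        return _read_csv(path)
    raise FormatError(f"unknown format {fmt!r}")


# -- CSV ---------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_csv(rec: FNIRSRecording, path: Path) -> None:
    n_ch, n_s = rec.hbo.shape
    times = np.arange(n_s) / rec.fs
    frame = pd.DataFrame(
        {
            "subject": rec.subject_id,
            "channel": np.repeat(rec.channel_ids, n_s),
            "time_s": np.tile(times, n_ch),
            "hbo": rec.hbo.reshape(-1),
        }
    )
    frame.to_csv(path, index=False, float_format="%.12g")
    sidecar = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "channel_ids": list(rec.channel_ids),
        "hemisphere_map": dict(rec.hemisphere_map),
        "trial_onsets": [[int(i), str(lbl)] for i, lbl in rec.trial_onsets],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _read_csv(path: Path) -> FNIRSRecording:
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise ConfigurationError(f"missing sidecar {sidecar_file.name} (carries the hemisphere map)")
    meta = json.loads(sidecar_file.read_text())
    for key in ("subject_id", "fs", "channel_ids", "hemisphere_map", "trial_onsets"):
        if key not in meta:
            raise FormatError(f"sidecar is missing field {key!r}")
    frame = pd.read_csv(path)
    for col in ("subject", "channel", "time_s", "hbo"):
        if col not in frame.columns:
            raise FormatError(f"CSV is missing column {col!r}")
    channel_ids = [str(c) for c in meta["channel_ids"]]
    frame["channel"] = frame["channel"].astype(str)
    wide = frame.pivot_table(index="time_s", columns="channel", values="hbo", sort=True)
    missing = [c for c in channel_ids if c not in wide.columns]
    if missing:
        raise FormatError(f"CSV lacks data for channels {missing}")
    hbo = wide[channel_ids].to_numpy().T  # preserve sidecar channel order
    return FNIRSRecording(
        subject_id=str(meta["subject_id"]),
        hbo=hbo,
        fs=float(meta["fs"]),
        trial_onsets=[(int(i), str(lbl)) for i, lbl in meta["trial_onsets"]],
        channel_ids=channel_ids,
        hemisphere_map={str(k): str(v) for k, v in meta["hemisphere_map"].items()},
    )


# -- SNIRF -------------------------------------------------------------------

_HBO_DATATYPE = 99999  # "processed" per the SNIRF spec; label carries "HbO"


def _write_snirf(rec: FNIRSRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("hemisphereMap", data=json.dumps(rec.hemisphere_map))
        meta.create_dataset("channelIDs", data=json.dumps(list(rec.channel_ids)))

        data1 = nirs.create_group("data1")
        data1.create_dataset("dataTimeSeries", data=rec.hbo.T)  # time x measurement
        data1.create_dataset("time", data=np.array([0.0, 1.0 / rec.fs]))
        for i, ch in enumerate(rec.channel_ids, start=1):
            ml = data1.create_group(f"measurementList{i}")
            ml.create_dataset("sourceIndex", data=i)
            ml.create_dataset("detectorIndex", data=i)
            ml.create_dataset("wavelengthIndex", data=1)
            ml.create_dataset("dataType", data=_HBO_DATATYPE)
            ml.create_dataset("dataTypeLabel", data="HbO")
            ml.create_dataset("dataTypeIndex", data=1)

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array([760.0, 850.0]))

        by_label: dict[str, list[int]] = {}
        for onset, label in rec.trial_onsets:
            by_label.setdefault(label, []).append(onset)
        for j, (label, onsets) in enumerate(sorted(by_label.items()), start=1):
            stim = nirs.create_group(f"stim{j}")
            stim.create_dataset("name", data=label)
            rows = [[onset / rec.fs, 0.0, 1.0] for onset in onsets]
            stim.create_dataset("data", data=np.array(rows))


def _read_str(ds) -> str:
    value = ds[()]
    return value.decode() if isinstance(value, bytes) else str(value)


def _read_snirf(path: Path) -> FNIRSRecording:
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise FormatError("SNIRF file lacks the /nirs group")
        nirs = f["nirs"]
        meta = nirs.get("metaDataTags")
        if meta is None or "hemisphereMap" not in meta:
            raise ConfigurationError("SNIRF file carries no hemisphereMap metaDataTag")
        subject_id = _read_str(meta["SubjectID"]) if "SubjectID" in meta else path.stem
        hemisphere_map = json.loads(_read_str(meta["hemisphereMap"]))
        channel_ids = json.loads(_read_str(meta["channelIDs"]))
        data1 = nirs.get("data1")
        if data1 is None or "dataTimeSeries" not in data1:
            raise FormatError("SNIRF file lacks /nirs/data1/dataTimeSeries")
        series = np.asarray(data1["dataTimeSeries"])
        time = np.asarray(data1["time"])
        if time.size == 2:  # [start, dt] convention
            fs = 1.0 / float(time[1])
        elif time.size > 2:
            fs = 1.0 / float(np.mean(np.diff(time)))
        else:
            raise FormatError("SNIRF /nirs/data1/time must hold [start, dt] or a full axis")
        onsets: list[tuple[int, str]] = []
        for key in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim = nirs[key]
            label = _read_str(stim["name"])
            rows = np.atleast_2d(np.asarray(stim["data"]))
            for row in rows:
                onsets.append((int(round(row[0] * fs)), label))
        onsets.sort()
    return FNIRSRecording(
        subject_id=subject_id,
        hbo=series.T,
        fs=fs,
        trial_onsets=onsets,
        channel_ids=[str(c) for c in channel_ids],
        hemisphere_map={str(k): str(v) for k, v in hemisphere_map.items()},
    )
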