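"""Data model and I/O for two-module MEA recordings.

Canonical units: spike times are seconds from recording start, voltages are
microvolts.  Time intervals are half-open ``[onset, offset)`` and all binning
is half-open with bin 0 starting at t = 0.

On-disk formats are deliberately plain: spike tables are CSV
(``electrode_id,time_s``) or an HDF5 container with one dataset of times per
electrode; electrode maps are CSV (``electrode_id,module``); analysis results
are JSON documents that round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

MODULE_LABELS = ("source", "target", "channel", "excluded")

__all__ = [
    "MODULE_LABELS",
    "SpikeTrainSet",
    "ElectrodeMap",
    "RawRecording",
    "read_spike_table",
    "write_spike_table",
    "read_electrode_map",
    "write_electrode_map",
    "read_raw_recording",
    "write_raw_recording",
    "write_report",
    "read_report",
    "register_report_type",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike timestamps for one recording.

    Parameters
    ----------
    spikes
        Mapping electrode id -> strictly increasing spike times in seconds.
    duration_s
        Recording duration in seconds; every spike time lies in
        ``[0, duration_s]``.
    sample_rate_hz
        Acquisition sample rate, or ``None`` when only spike times are known.
    """

    spikes: Dict[str, np.ndarray]
    duration_s: float
    sample_rate_hz: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.duration_s > 0):
            raise ValidationError(f"duration_s must be positive, got {self.duration_s}")
        if self.sample_rate_hz is not None and not (self.sample_rate_hz > 0):
            raise ValidationError("sample_rate_hz must be positive when given")
        clean: Dict[str, np.ndarray] = {}
        for eid, times in self.spikes.items():
            t = np.asarray(times, dtype=float)
            if t.ndim != 1:
                raise ValidationError(f"electrode {eid}: spike times must be 1-D")
            if t.size and (t[0] < 0 or t[-1] > self.duration_s):
                raise ValidationError(
                    f"electrode {eid}: spike times outside [0, {self.duration_s}]"
                )
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValidationError(f"electrode {eid}: spike times not strictly increasing")
            clean[str(eid)] = t
        self.spikes = clean

    @property
    def electrode_ids(self) -> List[str]:
        return list(self.spikes.keys())

    def n_spikes(self, electrodes: Optional[Iterable[str]] = None) -> int:
        ids = self.electrode_ids if electrodes is None else list(electrodes)
        return int(sum(self.spikes[e].size for e in ids if e in self.spikes))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrainSet):
            return NotImplemented
        if self.duration_s != other.duration_s or self.sample_rate_hz != other.sample_rate_hz:
            return False
        if set(self.spikes) != set(other.spikes):
            return False
        return all(np.array_equal(self.spikes[e], other.spikes[e]) for e in self.spikes)


@dataclass
class ElectrodeMap:
    """Assignment of each electrode to source / target / channel / excluded.

    The chip never prints its own wiring; the map is always supplied by the
    user.  Electrodes labeled ``channel`` sit inside the microchannels and are
    excluded from module-level burst statistics by default.
    """

    assignment: Dict[str, str]

    def __post_init__(self) -> None:
        clean = {}
        for eid, label in self.assignment.items():
            if label not in MODULE_LABELS:
                raise ValidationError(
                    f"electrode {eid}: unknown module label {label!r}; "
                    f"expected one of {MODULE_LABELS}"
                )
            clean[str(eid)] = label
        self.assignment = clean

    def electrodes(self, module: str) -> List[str]:
        if module not in MODULE_LABELS:
            raise ValidationError(f"unknown module label {module!r}")
        return [e for e, m in self.assignment.items() if m == module]

    def require_coverage(self, sts: SpikeTrainSet) -> None:
        missing = [e for e in sts.electrode_ids if e not in self.assignment]
        if missing:
            raise ValidationError(f"electrodes without module assignment: {missing}")


@dataclass
class RawRecording:
    """Uniformly sampled multichannel voltage traces (microvolts)."""

    traces: Dict[str, np.ndarray]
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if not (self.sample_rate_hz > 0):
            raise ValidationError("sample_rate_hz must be positive")
        clean = {}
        n = None
        for eid, x in self.traces.items():
            a = np.asarray(x, dtype=float)
            if a.ndim != 1:
                raise ValidationError(f"electrode {eid}: trace must be 1-D")
            if n is None:
                n = a.size
            elif a.size != n:
                raise ValidationError("all traces must have equal length")
            clean[str(eid)] = a
        self.traces = clean

    @property
    def n_samples(self) -> int:
        return next(iter(self.traces.values())).size if self.traces else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


# ---------------------------------------------------------------------------
# spike tables and electrode maps
# ---------------------------------------------------------------------------

_H5_SUFFIXES = {".h5", ".hdf5", ".hdf"}


def read_spike_table(
    path: str | Path,
    duration_s: Optional[float] = None,
    sample_rate_hz: Optional[float] = None,
) -> SpikeTrainSet:
    """Read a spike table from CSV or HDF5.

    CSV requires columns ``electrode_id`` and ``time_s`` and an explicit
    ``duration_s``; times are sorted per electrode and duplicate
    (electrode, time) rows collapsed.  HDF5 containers carry ``duration_s``
    and ``sample_rate_hz`` as root attributes (explicit arguments override).
    """
    path = Path(path)
    if path.suffix.lower() in _H5_SUFFIXES:
        import h5py

        with h5py.File(path, "r") as f:
            dur = duration_s if duration_s is not None else f.attrs.get("duration_s")
            sr = sample_rate_hz if sample_rate_hz is not None else f.attrs.get("sample_rate_hz")
            if dur is None:
                raise FormatError(f"{path}: missing duration_s attribute")
            grp = f["spikes"] if "spikes" in f else f
            spikes = {str(k): np.asarray(grp[k][()], dtype=float) for k in grp}
        return SpikeTrainSet(spikes, float(dur), None if sr is None else float(sr))

    if duration_s is None:
        raise ValidationError("duration_s is required for CSV spike tables")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file (expected header electrode_id,time_s)") from exc
    for col in ("electrode_id", "time_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    if times.isna().any():
        raise FormatError(f"{path}: non-numeric time_s values")
    if len(times) and (times.min() < 0 or times.max() > duration_s):
        raise ValidationError(
            f"{path}: spike times outside [0, {duration_s}]"
        )
    spikes: Dict[str, np.ndarray] = {}
    for eid, group in df.assign(time_s=times).groupby("electrode_id", sort=True):
        spikes[str(eid)] = np.unique(group["time_s"].to_numpy(dtype=float))
    return SpikeTrainSet(spikes, float(duration_s), sample_rate_hz)


def write_spike_table(sts: SpikeTrainSet, path: str | Path) -> None:
    """Write a spike table as CSV or (by file suffix) HDF5."""
    path = Path(path)
    if path.suffix.lower() in _H5_SUFFIXES:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["duration_s"] = sts.duration_s
            if sts.sample_rate_hz is not None:
                f.attrs["sample_rate_hz"] = sts.sample_rate_hz
            grp = f.create_group("spikes")
            for eid, t in sts.spikes.items():
                grp.create_dataset(eid, data=t)
        return
    rows = [
        {"electrode_id": eid, "time_s": t}
        for eid in sorted(sts.spikes)
        for t in sts.spikes[eid]
    ]
    pd.DataFrame(rows, columns=["electrode_id", "time_s"]).to_csv(path, index=False)


def read_electrode_map(path: str | Path) -> ElectrodeMap:
    """Read a CSV electrode map with columns ``electrode_id,module``."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file (expected header electrode_id,module)") from exc
    for col in ("electrode_id", "module"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    assignment = {
        str(eid): str(mod).strip() for eid, mod in zip(df["electrode_id"], df["module"])
    }
    return ElectrodeMap(assignment)


def write_electrode_map(emap: ElectrodeMap, path: str | Path) -> None:
    pd.DataFrame(
        [{"electrode_id": e, "module": m} for e, m in emap.assignment.items()],
        columns=["electrode_id", "module"],
    ).to_csv(path, index=False)


def read_raw_recording(path: str | Path) -> RawRecording:
    """Read raw traces from an HDF5 container (group ``traces``)."""
    import h5py

    with h5py.File(path, "r") as f:
        sr = f.attrs.get("sample_rate_hz")
        if sr is None:
            raise FormatError(f"{path}: missing sample_rate_hz attribute")
        grp = f["traces"] if "traces" in f else f
        traces = {str(k): np.asarray(grp[k][()], dtype=float) for k in grp}
    return RawRecording(traces, float(sr))


def write_raw_recording(rec: RawRecording, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["sample_rate_hz"] = rec.sample_rate_hz
        grp = f.create_group("traces")
        for eid, x in rec.traces.items():
            grp.create_dataset(eid, data=x)


# ---------------------------------------------------------------------------
# JSON result reports
# ---------------------------------------------------------------------------

_REPORT_REGISTRY: Dict[str, type] = {}


def register_report_type(cls: type) -> type:
    """Class decorator: make a result dataclass JSON round-trippable."""
    _REPORT_REGISTRY[cls.__name__] = cls
    return cls


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        name = type(obj).__name__
        if name not in _REPORT_REGISTRY:
            raise ValidationError(f"{name} is not a registered report type")
        out: Dict[str, Any] = {"__type__": name}
        for f in dataclasses.fields(obj):
            out[f.name] = _to_jsonable(getattr(obj, f.name))
        return out
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    raise ValidationError(f"cannot serialize object of type {type(obj).__name__}")


def _from_jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        if "__type__" in obj:
            name = obj["__type__"]
            if name not in _REPORT_REGISTRY:
                raise FormatError(f"unknown report type {name!r}")
            cls = _REPORT_REGISTRY[name]
            kwargs = {k: _from_jsonable(v) for k, v in obj.items() if k != "__type__"}
            return cls(**kwargs)
        return {k: _from_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_from_jsonable(v) for v in obj]
    return obj


def write_report(result: Any, path: str | Path) -> None:
    """Serialize a result object to JSON, losslessly for all numeric fields."""
    payload = _to_jsonable(result)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> Any:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON") from exc
    return _from_jsonable(payload)
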