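"""Domain types and plain-text I/O for intracellular recordings.

Conventions
-----------
* Voltages are millivolts, times are seconds, angles are degrees.
* Grid maps are stored row-major with the top-left corner first, matching
  a left-to-right / top-to-bottom scan: azimuth increases with column
  index, elevation decreases with row index (top row = highest elevation).
  Stimulus epoch ``k`` therefore maps to position ``(k // n_cols, k % n_cols)``.
* Polarizer angles are axial quantities, reported modulo 180 degrees.

File formats
------------
Traces are CSV files with header ``time_s,voltage_mV`` plus a JSON sidecar
(`<stem>.json`) holding ``sampling_rate``, ``t0`` and the stimulus markers.
Grid maps are CSV matrices (``n_rows`` lines of ``n_cols`` floats) plus a
JSON sidecar with the stage and angular coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np

from .errors import DataError, FormatError, InputError

MAP_STAGES = ("raw", "smoothed", "sensitivity")
SPECIES = ("Apis", "Bombus")
EYE_REGIONS = ("main_retina", "marginal_DRA", "DRA")

#: allowed jitter (s) when checking for a uniform time axis
TIME_JITTER_S = 1e-6


@dataclass(frozen=True)
class Marker:
    """A stimulus event: flash onset, polarizer angle or intensity step."""

    time_s: float
    kind: str
    payload: dict = field(default_factory=dict)


@dataclass
class RecordingTrace:
    """A uniformly sampled membrane-potential time series.

    Parameters
    ----------
    samples : array of float
        Membrane potential in mV.
    sampling_rate : float
        Samples per second; must be positive.
    t0 : float
        Time of the first sample in seconds.
    markers : list of Marker
        Stimulus events, sorted by time, all within the trace duration.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InputError("samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise InputError("sampling_rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise DataError("samples contain non-finite values")
        times = [m.time_s for m in self.markers]
        if any(b < a for a, b in zip(times, times[1:])):
            raise DataError("markers are not sorted by time")
        end = self.t0 + self.duration_s
        if any(not (self.t0 <= t <= end) for t in times):
            raise DataError("marker outside trace duration")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def sample_index(self, time_s: float) -> int:
        """Index of the sample closest to ``time_s``."""
        return int(round((time_s - self.t0) * self.sampling_rate))


@dataclass(frozen=True)
class GridScanProtocol:
    """Parameters of the flashing grid scan used for RF mapping.

    The scan visits ``n_rows * n_cols`` positions row-major, left to right
    then top to bottom, one flash per position.
    """

    extent_deg: float = 20.0
    step_deg: float = 1.0
    flash_ms: float = 20.0
    period_ms: float = 145.0
    stim_size_deg: float = 0.9
    az_center_deg: float = 0.0
    el_center_deg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("extent_deg", "step_deg", "flash_ms", "period_ms", "stim_size_deg"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be positive")
        if not self.flash_ms < self.period_ms:
            raise InputError("flash_ms must be shorter than period_ms")

    @property
    def n_cols(self) -> int:
        return int(math.floor(self.extent_deg / self.step_deg)) + 1

    @property
    def n_rows(self) -> int:
        return self.n_cols

    @property
    def n_positions(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def az_deg(self) -> np.ndarray:
        """Per-column azimuth, increasing rightward."""
        left = self.az_center_deg - self.extent_deg / 2
        return left + self.step_deg * np.arange(self.n_cols)

    @property
    def el_deg(self) -> np.ndarray:
        """Per-row elevation, decreasing with row index."""
        top = self.el_center_deg + self.extent_deg / 2
        return top - self.step_deg * np.arange(self.n_rows)

    def position(self, epoch: int) -> tuple[float, float]:
        """(azimuth, elevation) of stimulus epoch ``epoch`` (row-major)."""
        if not 0 <= epoch < self.n_positions:
            raise InputError(f"epoch {epoch} outside 0..{self.n_positions - 1}")
        r, c = divmod(epoch, self.n_cols)
        return float(self.az_deg[c]), float(self.el_deg[r])

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised (az, el) for all epochs in scan order."""
        az = np.tile(self.az_deg, self.n_rows)
        el = np.repeat(self.el_deg, self.n_cols)
        return az, el

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GridScanProtocol":
        return cls(**d)


@dataclass
class SpatialSensitivityMap:
    """Per-position response/sensitivity values of a grid scan.

    ``stage`` tracks the processing state: ``raw`` (max-minus-min voltage per
    epoch), ``smoothed`` (Gaussian-filtered raw) or ``sensitivity``
    (inverse-Hill transformed and rescaled so the maximum is 1).
    """

    stage: str
    values: np.ndarray
    az_deg: np.ndarray
    el_deg: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.az_deg = np.asarray(self.az_deg, dtype=float)
        self.el_deg = np.asarray(self.el_deg, dtype=float)
        if self.stage not in MAP_STAGES:
            raise InputError(f"stage must be one of {MAP_STAGES}")
        if self.values.ndim != 2:
            raise InputError("values must be a 2-D matrix")
        if self.values.shape != (self.el_deg.size, self.az_deg.size):
            raise DataError(
                f"values shape {self.values.shape} does not match coordinates "
                f"({self.el_deg.size} rows x {self.az_deg.size} cols)"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("map contains non-finite values")
        if np.any(self.values < 0):
            raise DataError("map values must be nonnegative")
        if self.stage == "sensitivity":
            if not np.isclose(self.values.max(), 1.0, rtol=0, atol=1e-9):
                raise DataError("sensitivity maps must have maximum 1")

    @property
    def n_rows(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_cols(self) -> int:
        return int(self.values.shape[1])


@dataclass
class CellRecord:
    """One cell's derived profile, a row of the group-statistics table."""

    cell_id: str
    species: str
    eye_region: str
    ps: float | None = None
    phi_max: float | None = None
    fwhm_circ: float | None = None
    coupled: bool = False
    ps_excluded: bool = False
    hill: Any = None
    lambda_max: float | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise InputError(f"species must be one of {SPECIES}")
        if self.eye_region not in EYE_REGIONS:
            raise InputError(f"eye_region must be one of {EYE_REGIONS}")
        if self.ps is not None and self.ps < 1:
            raise DataError("ps must be >= 1")
        if self.fwhm_circ is not None and not self.fwhm_circ > 0:
            raise DataError("fwhm_circ must be positive")
        if self.phi_max is not None:
            self.phi_max = float(self.phi_max) % 180.0


def epoch_slices(trace: RecordingTrace, kind: str | None = None
                 ) -> list[tuple[Marker, slice]]:
    """Per-marker sample windows: each epoch runs from its marker to the
    next marker of any kind (or the end of the trace)."""
    sel = [m for m in trace.markers if kind is None or m.kind == kind]
    if not sel:
        raise InputError("trace has no markers" + (f" of kind {kind!r}" if kind else ""))
    all_times = [m.time_s for m in trace.markers]
    out = []
    for m in sel:
        start = trace.sample_index(m.time_s)
        later = [t for t in all_times if t > m.time_s]
        stop = trace.sample_index(later[0]) if later else trace.n_samples
        out.append((m, slice(start, stop)))
    return out


def epoch_responses(trace: RecordingTrace, kind: str | None = None) -> np.ndarray:
    """Max-minus-min voltage per marker epoch (baseline-invariant response)."""
    vals = []
    for _m, sl in epoch_slices(trace, kind):
        seg = trace.samples[sl]
        if seg.size == 0:
            raise DataError("empty epoch window")
        vals.append(float(seg.max() - seg.min()))
    return np.asarray(vals)


def epoch_amplitudes(trace: RecordingTrace, kind: str | None = None, *,
                     template_smooth_ms: float = 3.0) -> np.ndarray:
    """Per-epoch response amplitudes via a data-derived matched filter.

    All epochs of a step series share one waveform shape up to amplitude,
    so an amplitude-weighted mean epoch serves as a template and each
    epoch's amplitude is its least-squares projection onto it.  Unlike the
    max-minus-min statistic the projection is unbiased under additive
    zero-mean noise; weighting and light template smoothing keep the
    template's own noise from biasing its normalization.  The template is
    scaled so that amplitudes come out in max-minus-min units (mV).
    """
    from scipy.ndimage import gaussian_filter1d

    slices = epoch_slices(trace, kind)
    n_ep = min(sl.stop - sl.start for _m, sl in slices)
    segs = np.stack([trace.samples[sl.start:sl.start + n_ep] for _m, sl in slices])
    segs = segs - segs.mean(axis=1, keepdims=True)
    weights = np.ptp(segs, axis=1)
    total = weights.sum()
    if total <= 0:
        return np.zeros(len(slices))
    template = (weights[:, None] * segs).sum(axis=0) / total
    if template_smooth_ms > 0:
        template = gaussian_filter1d(
            template, template_smooth_ms * trace.sampling_rate / 1000.0,
            mode="nearest")
    span = template.max() - template.min()
    if span <= 0:
        return np.zeros(len(slices))
    template = template / span  # unit max-minus-min
    denom = float(np.dot(template, template))
    amps = segs @ template / denom
    return np.maximum(amps, 0.0)


# ---------------------------------------------------------------------------
# trace I/O


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace_csv(trace: RecordingTrace, path: str | Path) -> None:
    """Write a trace as ``time_s,voltage_mV`` CSV plus a JSON sidecar."""
    path = Path(path)
    t = trace.times
    with open(path, "w") as fh:
        fh.write("time_s,voltage_mV\n")
        for ti, vi in zip(t, trace.samples):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")
    meta = {
        "sampling_rate": trace.sampling_rate,
        "t0": trace.t0,
        "markers": [
            {"time_s": m.time_s, "kind": m.kind, "payload": m.payload}
            for m in trace.markers
        ],
    }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_trace_csv(path: str | Path) -> RecordingTrace:
    """Read a trace CSV (+ optional sidecar with markers).

    Raises
    ------
    FormatError
        Missing/extra columns or an empty file.
    DataError
        Non-monotone time axis, or time steps deviating from uniform
        sampling by more than 1e-6 s.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "time_s,voltage_mV":
            raise FormatError(
                f"{path}: expected header 'time_s,voltage_mV', got {header!r}"
            )
        times, volts = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                times.append(float(parts[0]))
                volts.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
    if not times:
        raise FormatError(f"{path}: no data rows")
    t = np.asarray(times)
    v = np.asarray(volts)
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError(f"{path}: time axis is not strictly increasing")
        if dt.max() - dt.min() > TIME_JITTER_S:
            raise DataError(f"{path}: non-uniform sampling beyond {TIME_JITTER_S} s")
        rate = 1.0 / float(np.median(dt))
    else:
        rate = 1.0

    markers: list[Marker] = []
    t0 = float(t[0])
    sc = _sidecar(path)
    if sc.exists():
        with open(sc) as fh:
            meta = json.load(fh)
        rate = float(meta.get("sampling_rate", rate))
        t0 = float(meta.get("t0", t0))
        markers = [
            Marker(float(m["time_s"]), str(m["kind"]), dict(m.get("payload", {})))
            for m in meta.get("markers", [])
        ]
    return RecordingTrace(samples=v, sampling_rate=rate, t0=t0, markers=markers)


# ---------------------------------------------------------------------------
# map I/O


def write_map_csv(smap: SpatialSensitivityMap, path: str | Path) -> None:
    """Write a map matrix (top row first) plus JSON sidecar, lossless to
    better than 12 significant digits (floats are written with ``repr``)."""
    path = Path(path)
    with open(path, "w") as fh:
        for row in smap.values:
            fh.write(",".join(repr(float(x)) for x in row) + "\n")
    meta = {
        "stage": smap.stage,
        "az_deg": [float(a) for a in smap.az_deg],
        "el_deg": [float(e) for e in smap.el_deg],
        "n_rows": smap.n_rows,
        "n_cols": smap.n_cols,
    }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_map_csv(path: str | Path) -> SpatialSensitivityMap:
    """Inverse of :func:`write_map_csv`; validates shape and invariants."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append([float(x) for x in line.split(",")])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
    if not rows:
        raise FormatError(f"{path}: empty map file")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FormatError(f"{path}: ragged rows")
    values = np.asarray(rows, dtype=float)

    sc = _sidecar(path)
    if not sc.exists():
        raise FormatError(f"{path}: missing JSON sidecar {sc.name}")
    with open(sc) as fh:
        meta = json.load(fh)
    if (meta.get("n_rows"), meta.get("n_cols")) != values.shape:
        if tuple(values.shape) != (meta.get("n_rows"), meta.get("n_cols")):
            raise FormatError(
                f"{path}: matrix is {values.shape} but sidecar declares "
                f"({meta.get('n_rows')}, {meta.get('n_cols')})"
            )
    return SpatialSensitivityMap(
        stage=str(meta["stage"]),
        values=values,
        az_deg=np.asarray(meta["az_deg"], dtype=float),
        el_deg=np.asarray(meta["el_deg"], dtype=float),
    )
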