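"""Receptive-field reconstruction and weighted multi-Gaussian decomposition.

Pipeline for one grid-scan recording::

    trace -> extract_raw_map -> smooth_map -> to_sensitivity -> fit_rf
                                          -> detect_coupling, delay_difference

The raw map takes max-minus-min voltage per flash epoch (the subtraction
removes the per-epoch baseline).  The raw grid is Gaussian-smoothed
(default sigma 1 deg), normalized by the cell's maximum response and
passed through the inverse Hill transformation, then rescaled so the map
maximum is 1.  RF size and shape come from a bounded least-squares fit of
an offset plus up to three weighted elliptical Gaussians, with the
component count chosen by BIC.  Coupling between photoreceptors shows up
as multiple high-sensitivity lobes separated by a low-sensitivity valley.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .errors import DataError, InputError, NotEstimableError
from .recording import (
    GridScanProtocol,
    RecordingTrace,
    SpatialSensitivityMap,
    epoch_slices,
)
from .response import HillFit, inverse_hill, R_CAP

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

# Coupled cells show multiple lobes of high relative sensitivity separated
# by low-sensitivity regions.  The peak threshold sits below the canonical
# "half of maximum" so that genuinely coupled secondaries with relative
# amplitude down to ~0.4 are still detected; the valley threshold applies
# to the smoothed sensitivity map, where the 1-deg filter raises the
# observed dip well above the underlying profile valley.  Both are config.
PEAK_THRESHOLD_DEFAULT = 0.35    # lobes must exceed this fraction of map max
VALLEY_THRESHOLD_DEFAULT = 0.45  # and be separated by a dip below this
QUALITY_PEAK_OVER_MEDIAN = 5.0   # quality=high criterion
NO_RF_FACTOR = 3.0               # peak must exceed this multiple of the median

_SIGMA_BOUNDS = (0.3, 15.0)      # deg; prevents degenerate fits
_CENTER_MARGIN = 2.0             # centres may sit this far outside the grid
_RSS_FLOOR = 1e-18
_MAX_DELAY_LAG_SAMPLES = 20      # latency offsets are physiologically small


@dataclass
class RFComponent:
    """One fitted elliptical-Gaussian receptive-field lobe."""

    center_az: float
    center_el: float
    sigma_major: float
    sigma_minor: float
    orientation: float  # deg in [0, 180)
    amplitude: float
    weight: float = 1.0  # amplitude / largest component amplitude
    role: str = "main"   # "main" or "coupled"
    t_max_ms: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_major < self.sigma_minor:
            self.sigma_major, self.sigma_minor = self.sigma_minor, self.sigma_major
            self.orientation += 90.0
        self.orientation = float(self.orientation) % 180.0

    @property
    def fwhm_major(self) -> float:
        return FWHM_FACTOR * self.sigma_major

    @property
    def fwhm_minor(self) -> float:
        return FWHM_FACTOR * self.sigma_minor

    @property
    def fwhm_circ(self) -> float:
        """Diameter of the circle with the same area as the half-max ellipse."""
        return float(np.sqrt(self.fwhm_major * self.fwhm_minor))

    def evaluate(self, az, el):
        th = np.deg2rad(self.orientation)
        da = np.asarray(az, float) - self.center_az
        de = np.asarray(el, float) - self.center_el
        u = np.cos(th) * da + np.sin(th) * de
        v = -np.sin(th) * da + np.cos(th) * de
        q = (u / self.sigma_major) ** 2 + (v / self.sigma_minor) ** 2
        return self.amplitude * np.exp(-q / 2.0)

    def to_dict(self) -> dict:
        return {
            "center_az_deg": self.center_az,
            "center_el_deg": self.center_el,
            "sigma_major_deg": self.sigma_major,
            "sigma_minor_deg": self.sigma_minor,
            "orientation_deg": self.orientation,
            "amplitude": self.amplitude,
            "weight": self.weight,
            "fwhm_major_deg": self.fwhm_major,
            "fwhm_minor_deg": self.fwhm_minor,
            "fwhm_circ_deg": self.fwhm_circ,
            "role": self.role,
            "t_max_ms": self.t_max_ms,
        }


@dataclass
class RFModel:
    """Offset plus 1-3 weighted elliptical Gaussian components."""

    components: list[RFComponent]
    offset: float
    rss: float
    n_points: int = 0
    quality: str = "high"

    def __post_init__(self) -> None:
        self.components = sorted(self.components, key=lambda c: -c.amplitude)
        if self.components:
            a0 = self.components[0].amplitude
            for i, c in enumerate(self.components):
                c.weight = c.amplitude / a0 if a0 > 0 else 0.0
                c.role = "main" if i == 0 else "coupled"

    @property
    def main(self) -> RFComponent:
        return self.components[0]

    @property
    def coupled_components(self) -> list[RFComponent]:
        return self.components[1:]

    def evaluate(self, az, el):
        out = np.full(np.broadcast(np.asarray(az, float),
                                   np.asarray(el, float)).shape, self.offset)
        for c in self.components:
            out = out + c.evaluate(az, el)
        return out

    def to_dict(self) -> dict:
        return {
            "offset": self.offset,
            "rss": self.rss,
            "n_points": self.n_points,
            "quality": self.quality,
            "components": [c.to_dict() for c in self.components],
        }


# ---------------------------------------------------------------------------
# map construction


def extract_raw_map(trace: RecordingTrace,
                    protocol: GridScanProtocol) -> SpatialSensitivityMap:
    """Build the raw response grid: max minus min voltage per flash epoch.

    The trace markers must cover all ``n_rows * n_cols`` grid positions
    (marker payloads carry ``row``/``col`` or an ``epoch`` index).
    """
    n_rows, n_cols = protocol.n_rows, protocol.n_cols
    values = np.full((n_rows, n_cols), np.nan)
    for m, sl in epoch_slices(trace, kind="flash"):
        if "row" in m.payload and "col" in m.payload:
            r, c = int(m.payload["row"]), int(m.payload["col"])
        elif "epoch" in m.payload:
            r, c = divmod(int(m.payload["epoch"]), n_cols)
        else:
            raise InputError("flash marker lacks row/col or epoch payload")
        seg = trace.samples[sl]
        values[r, c] = float(seg.max() - seg.min())
    if np.isnan(values).any():
        missing = [(int(r), int(c)) for r, c in zip(*np.where(np.isnan(values)))]
        raise InputError(f"missing epochs for positions {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    return SpatialSensitivityMap(stage="raw", values=values,
                                 az_deg=protocol.az_deg, el_deg=protocol.el_deg)


def smooth_map(raw_map: SpatialSensitivityMap, sigma_deg: float = 1.0,
               mode: str = "reflect") -> SpatialSensitivityMap:
    """Gaussian-filter the raw grid (kernel sd ``sigma_deg`` in map units)."""
    if raw_map.stage != "raw":
        raise InputError("smooth_map expects a stage='raw' map")
    if not sigma_deg > 0:
        raise InputError("sigma_deg must be positive")
    step = float(abs(raw_map.az_deg[1] - raw_map.az_deg[0])) \
        if raw_map.n_cols > 1 else 1.0
    smoothed = ndimage.gaussian_filter(raw_map.values, sigma=sigma_deg / step,
                                       mode=mode)
    smoothed = np.maximum(smoothed, 0.0)
    return SpatialSensitivityMap(stage="smoothed", values=smoothed,
                                 az_deg=raw_map.az_deg, el_deg=raw_map.el_deg)


def to_sensitivity(smap: SpatialSensitivityMap, hill: HillFit, *,
                   baseline: str = "min", r_cap: float = R_CAP
                   ) -> SpatialSensitivityMap:
    """Inverse-Hill transform a voltage map into relative sensitivities.

    Values are divided by the cell's fitted ``v_max``, passed through the
    inverse Hill function and rescaled so the map maximum is 1.  With
    ``baseline='min'`` (the default used by the pipeline) the map minimum —
    a residual noise pedestal left by the max-minus-min epoch statistic —
    is subtracted first; ``baseline='none'`` disables this.
    """
    if smap.stage not in ("raw", "smoothed"):
        raise InputError("to_sensitivity expects a raw or smoothed map")
    if baseline not in ("min", "none"):
        raise InputError("baseline must be 'min' or 'none'")
    v = smap.values.copy()
    if baseline == "min":
        v = v - v.min()
    if not v.max() > 0:
        raise DataError("map is all zero; cannot form a sensitivity map")
    r = v / hill.v_max
    s = inverse_hill(r, hill, r_cap=r_cap)
    s = s / s.max()
    return SpatialSensitivityMap(stage="sensitivity", values=s,
                                 az_deg=smap.az_deg, el_deg=smap.el_deg)


# ---------------------------------------------------------------------------
# Gaussian decomposition


def _local_maxima(values: np.ndarray, step: float, nms_radius_deg: float
                  ) -> list[tuple[int, int]]:
    """Grid indices of local maxima, strongest first, with non-maximum
    suppression at ``nms_radius_deg``."""
    size = max(3, 2 * int(round(nms_radius_deg / step)) + 1)
    filt = ndimage.maximum_filter(values, size=size, mode="nearest")
    cand = np.argwhere((values >= filt) & (values > 0))
    cand = sorted(map(tuple, cand), key=lambda rc: -values[rc])
    kept: list[tuple[int, int]] = []
    r_px = nms_radius_deg / step
    for rc in cand:
        if all((rc[0] - k[0]) ** 2 + (rc[1] - k[1]) ** 2 >= r_px ** 2 for k in kept):
            kept.append(rc)
    return kept


def _pack(offset: float, comps: list[list[float]]) -> np.ndarray:
    return np.concatenate([[offset]] + [np.asarray(c) for c in comps])


def _model_values(params: np.ndarray, az: np.ndarray, el: np.ndarray,
                  k: int) -> np.ndarray:
    out = np.full(az.shape, params[0])
    for j in range(k):
        A, a0, e0, sx, sy, th = params[1 + 6 * j: 7 + 6 * j]
        u = np.cos(th) * (az - a0) + np.sin(th) * (el - e0)
        v = -np.sin(th) * (az - a0) + np.cos(th) * (el - e0)
        out = out + A * np.exp(-((u / sx) ** 2 + (v / sy) ** 2) / 2.0)
    return out


def _fit_k_components(values: np.ndarray, az2: np.ndarray, el2: np.ndarray,
                      peaks: list[tuple[int, int]], k: int,
                      az_deg: np.ndarray, el_deg: np.ndarray) -> tuple:
    offset0 = float(np.median(values))
    x0, lo, hi = [offset0], [0.0], [1.0]
    az_lo, az_hi = az_deg.min() - _CENTER_MARGIN, az_deg.max() + _CENTER_MARGIN
    el_lo, el_hi = el_deg.min() - _CENTER_MARGIN, el_deg.max() + _CENTER_MARGIN
    for j in range(k):
        r, c = peaks[j] if j < len(peaks) else peaks[-1]
        amp0 = max(float(values[r, c]) - offset0, 0.05)
        x0 += [amp0, float(az_deg[c]), float(el_deg[r]), 1.5, 1.5, 0.0]
        lo += [0.0, az_lo, el_lo, _SIGMA_BOUNDS[0], _SIGMA_BOUNDS[0], -np.pi]
        hi += [1.5, az_hi, el_hi, _SIGMA_BOUNDS[1], _SIGMA_BOUNDS[1], np.pi]
    res = least_squares(
        lambda p: _model_values(p, az2, el2, k).ravel() - values.ravel(),
        x0=np.asarray(x0), bounds=(np.asarray(lo), np.asarray(hi)),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=4000,
    )
    rss = float(2.0 * res.cost)
    return res.x, rss


def _min_center_distance(params: np.ndarray, k: int) -> float:
    centers = [(params[2 + 6 * j], params[3 + 6 * j]) for j in range(k)]
    return min(
        float(np.hypot(a[0] - b[0], a[1] - b[1]))
        for i, a in enumerate(centers) for b in centers[i + 1:]
    )


def fit_rf(sens_map: SpatialSensitivityMap, max_components: int = 3, *,
           nms_radius_deg: float = 2.0,
           quality_ratio: float = QUALITY_PEAK_OVER_MEDIAN) -> RFModel:
    """Fit offset + up to ``max_components`` elliptical Gaussians by bounded
    least squares; the component count is selected by BIC.

    Initialization uses the strongest local maxima after non-maximum
    suppression (radius 2 deg).  The largest-amplitude component is the
    main cell (weight 1); the rest are candidate coupled cells.

    Raises
    ------
    NotEstimableError
        No local maximum exceeds ``NO_RF_FACTOR`` times the map median.
    """
    if sens_map.stage != "sensitivity":
        raise InputError("fit_rf expects a stage='sensitivity' map")
    values = sens_map.values
    step = float(abs(sens_map.az_deg[1] - sens_map.az_deg[0])) \
        if sens_map.n_cols > 1 else 1.0
    bg = float(np.median(values))
    peaks = _local_maxima(values, step, nms_radius_deg)
    peaks = [p for p in peaks if values[p] > NO_RF_FACTOR * bg] or peaks[:0]
    if not peaks:
        raise NotEstimableError(
            f"no local maximum above {NO_RF_FACTOR}x the map median")

    az2, el2 = np.meshgrid(sens_map.az_deg, sens_map.el_deg)
    m = values.size
    best = None
    k_cap = min(max_components, len(peaks))
    for k in range(1, k_cap + 1):
        params, rss = _fit_k_components(values, az2, el2, peaks, k,
                                        sens_map.az_deg, sens_map.el_deg)
        if k > 1 and _min_center_distance(params, k) < nms_radius_deg:
            continue  # redundant decomposition of a single lobe
        n_par = 1 + 6 * k
        bic = m * np.log(max(rss, _RSS_FLOOR) / m) + n_par * np.log(m)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, k, params, rss)
    _, k, params, rss = best
    comps = []
    for j in range(k):
        A, a0, e0, sx, sy, th = params[1 + 6 * j: 7 + 6 * j]
        if A <= 1e-6:  # vanished component
            continue
        comps.append(RFComponent(
            center_az=float(a0), center_el=float(e0),
            sigma_major=float(sx), sigma_minor=float(sy),
            orientation=float(np.rad2deg(th)), amplitude=float(A),
        ))
    if not comps:
        raise NotEstimableError("all fitted components vanished")
    quality = "high" if values.max() >= quality_ratio * bg else "low"
    return RFModel(components=comps, offset=float(params[0]), rss=rss,
                   n_points=m, quality=quality)


# ---------------------------------------------------------------------------
# coupling and delay


@dataclass
class CouplingResult:
    coupled: bool
    pairs: list[dict] = field(default_factory=list)

    def __bool__(self) -> bool:  # allows `if detect_coupling(...)`
        return self.coupled

    def to_dict(self) -> dict:
        return {"coupled": self.coupled, "pairs": self.pairs}


def _map_value_at(smap: SpatialSensitivityMap, az: float, el: float) -> float:
    step_az = float(smap.az_deg[1] - smap.az_deg[0])
    step_el = float(smap.el_deg[1] - smap.el_deg[0])  # negative (top first)
    col = (az - smap.az_deg[0]) / step_az
    row = (el - smap.el_deg[0]) / step_el
    return float(ndimage.map_coordinates(smap.values, [[row], [col]],
                                         order=1, mode="nearest")[0])


def _line_profile(smap: SpatialSensitivityMap, p0, p1, n: int = 64) -> np.ndarray:
    step_az = float(smap.az_deg[1] - smap.az_deg[0])
    step_el = float(smap.el_deg[1] - smap.el_deg[0])
    t = np.linspace(0.0, 1.0, n)
    az = p0[0] + t * (p1[0] - p0[0])
    el = p0[1] + t * (p1[1] - p0[1])
    cols = (az - smap.az_deg[0]) / step_az
    rows = (el - smap.el_deg[0]) / step_el
    return ndimage.map_coordinates(smap.values, [rows, cols], order=1,
                                   mode="nearest")


def detect_coupling(model: RFModel, sens_map: SpatialSensitivityMap, *,
                    peak_threshold: float = PEAK_THRESHOLD_DEFAULT,
                    valley_threshold: float = VALLEY_THRESHOLD_DEFAULT
                    ) -> CouplingResult:
    """Coupling test: at least two components whose centres each exceed
    ``peak_threshold`` of the map maximum, separated along the straight
    line between centres by a dip below ``valley_threshold`` of the map
    maximum.  Diagnostics include the along-line sensitivity profile."""
    if not model.components:
        raise InputError("model has no components")
    if len(model.components) < 2:
        return CouplingResult(coupled=False)
    vmax = float(sens_map.values.max())
    main = model.main
    result = CouplingResult(coupled=False)
    for comp in model.coupled_components:
        peak_a = _map_value_at(sens_map, main.center_az, main.center_el)
        peak_b = _map_value_at(sens_map, comp.center_az, comp.center_el)
        profile = _line_profile(sens_map, (main.center_az, main.center_el),
                                (comp.center_az, comp.center_el))
        valley = float(profile.min())
        ok = (peak_a > peak_threshold * vmax
              and peak_b > peak_threshold * vmax
              and valley < valley_threshold * vmax)
        result.pairs.append({
            "main_peak": peak_a, "secondary_peak": peak_b,
            "valley": valley, "profile": profile.tolist(), "coupled": ok,
        })
        result.coupled = result.coupled or ok
    return result


def delay_difference(trace: RecordingTrace, protocol: GridScanProtocol,
                     model: RFModel, *, n_strongest: int = 5
                     ) -> list[float | None]:
    """Per-coupled-component response-delay differences, in ms.

    For each component, the grid positions it dominates form its territory;
    ``t_max`` is the median, over the territory's ``n_strongest`` epochs,
    of (time of epoch peak - flash onset).  The epoch peak is located by
    cross-correlating the epoch against a common waveform template (the
    normalized mean of the strongest epochs), with 3-point parabolic lag
    refinement: on noiseless data this coincides with the raw argmax, and
    under noise it exploits the steep response flanks instead of the flat
    top.  The template choice is common to all components and cancels in
    the difference.  Returns ``t_max(main) - t_max(secondary)`` per coupled
    component; ``None`` where a territory has no epoch above the noise
    floor.
    """
    if len(model.components) < 2:
        raise InputError("delay_difference needs a model with >= 2 components")
    slices = epoch_slices(trace, kind="flash")
    az, el = protocol.positions()
    contrib = np.stack([c.evaluate(az, el) for c in model.components])
    territory = np.argmax(contrib, axis=0)

    amps = np.array([float(trace.samples[sl].max() - trace.samples[sl].min())
                     for _m, sl in slices])
    floor = NO_RF_FACTOR * float(np.median(amps))

    def epoch_index(m) -> int:
        if "epoch" in m.payload:
            return int(m.payload["epoch"])
        return int(m.payload["row"]) * protocol.n_cols + int(m.payload["col"])

    n_ep = min(sl.stop - sl.start for _m, sl in slices)
    order = np.argsort(-amps)
    template = np.zeros(n_ep)
    for i in order[:n_strongest]:
        seg = trace.samples[slices[i][1]][:n_ep]
        template += seg - seg.mean()
    if template.max() <= 0:
        return [None] * (len(model.components) - 1)
    template /= np.abs(template).max()
    t_tpl_peak = int(np.argmax(template))

    max_lag = min(_MAX_DELAY_LAG_SAMPLES, (n_ep - 1) // 3)

    def refined_peak_ms(seg: np.ndarray) -> float:
        # normalized correlation over a fixed window: at the true lag the
        # segment window and template slice are exactly proportional, so
        # the cosine similarity peaks there regardless of edge effects
        window = seg[max_lag:n_ep - max_lag]
        window = window - window.mean()
        wnorm = float(np.linalg.norm(window)) or 1.0
        lags = np.arange(-max_lag, max_lag + 1)
        corr = np.empty(lags.size)
        for i, l in enumerate(lags):
            tpl = template[max_lag - l:n_ep - max_lag - l]
            tpl = tpl - tpl.mean()
            tnorm = float(np.linalg.norm(tpl)) or 1.0
            corr[i] = float(np.dot(window, tpl)) / (wnorm * tnorm)
        j = int(np.argmax(corr))
        lag = int(lags[j])
        frac = 0.0
        # cosine similarity 1 means an exact on-sample match: no refinement
        if 0 < j < corr.size - 1 and corr[j] < 1.0 - 1e-9:
            y0, y1, y2 = corr[j - 1], corr[j], corr[j + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                frac = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
        return (lag + frac + t_tpl_peak) * 1000.0 / trace.sampling_rate

    def t_max_for(comp_idx: int) -> float | None:
        idx = [i for i, (m, _sl) in enumerate(slices)
               if territory[epoch_index(m)] == comp_idx and amps[i] > floor]
        if not idx:
            return None
        idx = sorted(idx, key=lambda i: -amps[i])[:n_strongest]
        # averaging the strongest epochs before locating the peak beats the
        # per-epoch median: single-epoch peak times jitter by several ms at
        # realistic noise because the response top is flat
        mean_seg = np.mean([trace.samples[slices[i][1]][:n_ep] for i in idx],
                           axis=0)
        return refined_peak_ms(mean_seg)

    t_main = t_max_for(0)
    out: list[float | None] = []
    for j in range(1, len(model.components)):
        t_sec = t_max_for(j)
        out.append(None if t_main is None or t_sec is None else t_main - t_sec)
    return out


def average_fwhm(models: list[RFModel]) -> float:
    """Mean circular FWHM of the main component over quality=high models."""
    good = [m.main.fwhm_circ for m in models if m.quality == "high"]
    if not good:
        raise NotEstimableError("no high-quality recordings")
    return float(np.mean(good))
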