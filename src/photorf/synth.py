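"""Ground-truth cell models and simulated intracellular recordings.

Every downstream estimator in this package is validated by parameter
recovery against cells generated here.  A :class:`GroundTruthCell` carries
the true receptive-field components (weighted elliptical Gaussians with
per-component response latencies), a Hill intensity-response nonlinearity,
cos^2-type polarization tuning and a UV pigment template; the ``simulate_*``
functions render membrane-voltage traces for the three stimulus protocols
(grid scan, V-log(I) series, polarizer series).

Noise model: additive Gaussian, low-pass filtered to a configurable
correlation time (membrane + amplifier filtering makes physiological noise
band-limited; unfiltered white noise at 1 kHz would make the max-minus-min
epoch statistic meaninglessly biased).  The filtered noise is rescaled to
the requested standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import InputError
from .recording import GridScanProtocol, Marker, RecordingTrace
from .response import hill_response, spectral_template  # noqa: F401  (re-export)

DEFAULT_SAMPLING_RATE = 1000.0  # Hz
DEFAULT_T_PEAK_MS = 30.0
DEFAULT_KERNEL_SHAPE = 3.0
DEFAULT_NOISE_CORR_MS = 5.0
#: flash intensity in Hill units relative to the cell's half-max intensity
DEFAULT_I0_FACTOR = 3.0


@dataclass(frozen=True)
class RFComponentTruth:
    """One true receptive-field lobe (elliptical Gaussian)."""

    az_deg: float
    el_deg: float
    sigma_major_deg: float
    sigma_minor_deg: float
    orientation_deg: float = 0.0
    weight: float = 1.0  # relative amplitude in (0, 1]
    latency_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma_major_deg > 0 and self.sigma_minor_deg > 0):
            raise InputError("sigmas must be positive")
        if not 0 < self.weight <= 1:
            raise InputError("weight must be in (0, 1]")


@dataclass
class GroundTruthCell:
    """A simulated photoreceptor with known parameters."""

    cell_id: str
    components: list[RFComponentTruth]
    v_max_mv: float
    k_half: float
    hill_n: float
    ps_true: float = 1.0
    phi_max_true_deg: float = 0.0
    lambda_max_nm: float = 340.0
    noise_sd_mv: float = 0.0
    species: str = "Apis"
    eye_region: str = "DRA"

    def __post_init__(self) -> None:
        if not self.components:
            raise InputError("cell needs at least one RF component")
        n_main = sum(1 for c in self.components if c.weight == 1.0)
        if n_main != 1:
            raise InputError("exactly one component must have weight 1 (the main cell)")
        if self.ps_true < 1:
            raise InputError("ps_true must be >= 1")
        self.phi_max_true_deg = float(self.phi_max_true_deg) % 180.0

    @property
    def main_component(self) -> RFComponentTruth:
        return max(self.components, key=lambda c: c.weight)

    @property
    def is_coupled(self) -> bool:
        return len(self.components) > 1

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthCell":
        d = dict(d)
        d["components"] = [RFComponentTruth(**c) for c in d["components"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# forward models


def _component_quadform(comp: RFComponentTruth, az, el):
    th = np.deg2rad(comp.orientation_deg)
    da = np.asarray(az, dtype=float) - comp.az_deg
    de = np.asarray(el, dtype=float) - comp.el_deg
    u = np.cos(th) * da + np.sin(th) * de
    v = -np.sin(th) * da + np.cos(th) * de
    return (u / comp.sigma_major_deg) ** 2 + (v / comp.sigma_minor_deg) ** 2


def spatial_profile(cell: GroundTruthCell, az, el):
    """Relative sensitivity of the cell at (az, el), in [0, 1].

    Sum over components of ``w_k * exp(-q_k / 2)`` with ``q_k`` the rotated
    anisotropic quadratic form, clipped at 1.
    """
    out = np.zeros(np.broadcast(np.asarray(az, float), np.asarray(el, float)).shape)
    for comp in cell.components:
        out = out + comp.weight * np.exp(-_component_quadform(comp, az, el) / 2.0)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def dominant_component(cell: GroundTruthCell, az, el) -> int:
    """Index of the component contributing most at (az, el)."""
    contrib = [
        c.weight * np.exp(-_component_quadform(c, az, el) / 2.0)
        for c in cell.components
    ]
    return int(np.argmax(contrib))


def polarization_factor(cell: GroundTruthCell, phi_deg):
    """Multiplicative sensitivity factor for e-vector angle ``phi_deg``.

    ``f(phi) = 1/PS + (1 - 1/PS) * cos^2(phi - phi_max)``; the max/min ratio
    over angles equals ``ps_true`` exactly.
    """
    ps = cell.ps_true
    d = np.deg2rad(np.asarray(phi_deg, dtype=float) - cell.phi_max_true_deg)
    f = 1.0 / ps + (1.0 - 1.0 / ps) * np.cos(d) ** 2
    return f if f.ndim else float(f)


def gamma_kernel(t_ms, t_peak_ms: float = DEFAULT_T_PEAK_MS,
                 shape: float = DEFAULT_KERNEL_SHAPE):
    """Smooth unimodal response waveform, peak value 1 at ``t_peak_ms``.

    ``k(t) = (t/tp)**(s-1) * exp((s-1) * (1 - t/tp))`` for t > 0, else 0.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / t_peak_ms
    out[pos] = x ** (shape - 1.0) * np.exp((shape - 1.0) * (1.0 - x))
    return out if out.ndim else float(out)


def _make_noise(n: int, sd_mv: float, rng: np.random.Generator,
                sampling_rate: float, corr_ms: float) -> np.ndarray:
    if sd_mv <= 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sigma_samples = corr_ms * sampling_rate / 1000.0
    if sigma_samples > 0:
        filt = gaussian_filter1d(white, sigma_samples, mode="reflect")
    else:
        filt = white
    std = filt.std()
    if std == 0:
        return np.zeros(n)
    return filt * (sd_mv / std)


# ---------------------------------------------------------------------------
# protocol simulators


def _epoch_waveforms(cell: GroundTruthCell, n_ep: int, sampling_rate: float,
                     t_peak_ms: float, kernel_shape: float) -> list[np.ndarray]:
    """Unit-amplitude waveform per component (latency applied, truncated to
    one epoch so epochs are exactly independent)."""
    t_ms = np.arange(n_ep) * 1000.0 / sampling_rate
    return [
        gamma_kernel(t_ms - c.latency_ms, t_peak_ms, kernel_shape)
        for c in cell.components
    ]


def simulate_grid_scan(
    cell: GroundTruthCell,
    protocol: GridScanProtocol | None = None,
    seed: int | None = 0,
    *,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    i0_factor: float = DEFAULT_I0_FACTOR,
    t_peak_ms: float = DEFAULT_T_PEAK_MS,
    kernel_shape: float = DEFAULT_KERNEL_SHAPE,
    noise_corr_ms: float = DEFAULT_NOISE_CORR_MS,
) -> RecordingTrace:
    """Render a full grid-scan trace: one flash per position, row-major.

    For epoch ``k`` at position ``p_k`` the depolarization amplitude is
    ``Hill(I0 * spatial_profile(p_k))`` with ``I0 = i0_factor * k_half``;
    the waveform is the gamma kernel delayed by the latency of the
    component dominating ``p_k``.  Markers record every flash onset with
    its epoch index and grid position.
    """
    protocol = protocol or GridScanProtocol()
    rng = np.random.default_rng(seed)
    n_ep = int(round(protocol.period_ms * sampling_rate / 1000.0))
    az, el = protocol.positions()
    i0 = i0_factor * cell.k_half
    amps = hill_response(
        i0 * spatial_profile(cell, az, el), cell.v_max_mv, cell.k_half, cell.hill_n
    )
    waves = _epoch_waveforms(cell, n_ep, sampling_rate, t_peak_ms, kernel_shape)
    dom = (
        np.zeros(protocol.n_positions, dtype=int)
        if len(cell.components) == 1
        else np.array([dominant_component(cell, a, e) for a, e in zip(az, el)])
    )

    samples = np.empty(protocol.n_positions * n_ep)
    markers = []
    period_s = n_ep / sampling_rate
    for k in range(protocol.n_positions):
        samples[k * n_ep:(k + 1) * n_ep] = amps[k] * waves[dom[k]]
        r, c = divmod(k, protocol.n_cols)
        markers.append(
            Marker(
                time_s=k * period_s,
                kind="flash",
                payload={
                    "epoch": k,
                    "row": r,
                    "col": c,
                    "az_deg": float(az[k]),
                    "el_deg": float(el[k]),
                },
            )
        )
    samples += _make_noise(samples.size, cell.noise_sd_mv, rng, sampling_rate,
                           noise_corr_ms)
    return RecordingTrace(samples=samples, sampling_rate=sampling_rate,
                          markers=markers)


def _step_series_trace(
    cell: GroundTruthCell,
    amplitudes: np.ndarray,
    marker_kind: str,
    marker_values: list,
    seed,
    sampling_rate: float,
    period_ms: float,
    t_peak_ms: float,
    kernel_shape: float,
    noise_corr_ms: float,
) -> RecordingTrace:
    rng = np.random.default_rng(seed)
    n_ep = int(round(period_ms * sampling_rate / 1000.0))
    wave = gamma_kernel(np.arange(n_ep) * 1000.0 / sampling_rate,
                        t_peak_ms, kernel_shape)
    n_steps = len(amplitudes)
    samples = (np.asarray(amplitudes)[:, None] * wave[None, :]).ravel()
    samples = samples + _make_noise(samples.size, cell.noise_sd_mv, rng,
                                    sampling_rate, noise_corr_ms)
    period_s = n_ep / sampling_rate
    markers = [
        Marker(time_s=k * period_s, kind=marker_kind,
               payload={"step": k, marker_kind: float(marker_values[k])})
        for k in range(n_steps)
    ]
    return RecordingTrace(samples=samples, sampling_rate=sampling_rate,
                          markers=markers)


def simulate_vlogi(
    cell: GroundTruthCell,
    intensities,
    seed: int | None = 0,
    *,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    period_ms: float = 145.0,
    t_peak_ms: float = DEFAULT_T_PEAK_MS,
    kernel_shape: float = DEFAULT_KERNEL_SHAPE,
    noise_corr_ms: float = DEFAULT_NOISE_CORR_MS,
) -> RecordingTrace:
    """Graded-intensity flash series; per-step peak follows the Hill curve."""
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size < 5:
        raise InputError("need at least 5 intensity steps")
    amps = hill_response(intensities, cell.v_max_mv, cell.k_half, cell.hill_n)
    return _step_series_trace(cell, amps, "intensity", list(intensities), seed,
                              sampling_rate, period_ms, t_peak_ms, kernel_shape,
                              noise_corr_ms)


def simulate_pol_series(
    cell: GroundTruthCell,
    angles_deg,
    seed: int | None = 0,
    *,
    i0_factor: float = DEFAULT_I0_FACTOR,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    period_ms: float = 145.0,
    t_peak_ms: float = DEFAULT_T_PEAK_MS,
    kernel_shape: float = DEFAULT_KERNEL_SHAPE,
    noise_corr_ms: float = DEFAULT_NOISE_CORR_MS,
) -> RecordingTrace:
    """Polarizer-angle flash series at fixed wavelength.

    Per-step peak amplitude is ``Hill(I0 * polarization_factor(angle))``.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size < 8:
        raise InputError("need at least 8 polarizer angles")
    i0 = i0_factor * cell.k_half
    amps = hill_response(i0 * polarization_factor(cell, angles),
                         cell.v_max_mv, cell.k_half, cell.hill_n)
    return _step_series_trace(cell, amps, "angle", list(angles), seed,
                              sampling_rate, period_ms, t_peak_ms, kernel_shape,
                              noise_corr_ms)


# ---------------------------------------------------------------------------
# population generation

#: per-region parameter ranges used when drawing random cells.  These are
#: free simulator parameters chosen so that each region's cells are
#: qualitatively distinct (RF size, polarization sensitivity, absolute
#: sensitivity); coupled cells get compact, well-separated lobes.
REGION_DEFAULTS: dict[str, dict] = {
    "main_retina": {
        "fwhm_range": (2.0, 4.0),
        "ps_range": (1.2, 3.0),
        "k_range": (0.05, 0.2),
        "n_range": (0.7, 0.95),
        "coupling_prob": 0.0,
    },
    "marginal_DRA": {
        "fwhm_range": (4.5, 6.5),
        "ps_range": (4.0, 9.0),
        "k_range": (0.08, 0.3),
        "n_range": (0.8, 1.1),
        "coupling_prob": 0.0,
    },
    "DRA": {
        "fwhm_range": (5.5, 8.5),
        "ps_range": (5.0, 12.0),
        "k_range": (0.5, 2.0),
        "n_range": (0.9, 1.2),
        "coupling_prob": 0.25,
    },
}

_COUPLED_DEFAULTS = {
    "coupled_fwhm_range": (2.4, 3.6),
    "secondary_weight_range": (0.4, 0.8),
    "separation_range": (6.0, 9.0),
    "latency_offset_range": (0.0, 5.0),
    # secondary centres stay inside the mapped area; a lobe cut off by the
    # grid edge cannot be decomposed reliably
    "max_center_deg": 8.0,
}

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SimulationConfig:
    """Reproducible specification of a simulated cell population.

    ``counts`` maps ``species -> {eye_region -> n_cells}``.  Identical seed
    and config produce bit-identical populations and traces.
    """

    seed: int = 0
    counts: dict = field(default_factory=lambda: {
        "Apis": {"main_retina": 2, "marginal_DRA": 2, "DRA": 2},
        "Bombus": {"main_retina": 2, "marginal_DRA": 2, "DRA": 2},
    })
    v_max_range: tuple = (15.0, 25.0)
    noise_frac_v_max: float = 0.05
    aspect_ratio_range: tuple = (1.0, 1.5)
    center_jitter_deg: float = 2.0
    region_params: dict = field(default_factory=lambda: {
        r: dict(p) for r, p in REGION_DEFAULTS.items()
    })
    coupled_params: dict = field(default_factory=lambda: dict(_COUPLED_DEFAULTS))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("v_max_range", "aspect_ratio_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _draw_component(rng, fwhm, aspect_range, jitter, center=(0.0, 0.0),
                    weight=1.0, latency=0.0) -> RFComponentTruth:
    sigma_geo = fwhm / FWHM_FACTOR
    aspect = rng.uniform(*aspect_range)
    # geometric mean of the axes equals sigma_geo -> circular FWHM is exact
    s_major = sigma_geo * np.sqrt(aspect)
    s_minor = sigma_geo / np.sqrt(aspect)
    return RFComponentTruth(
        az_deg=center[0] + rng.uniform(-jitter, jitter),
        el_deg=center[1] + rng.uniform(-jitter, jitter),
        sigma_major_deg=float(s_major),
        sigma_minor_deg=float(s_minor),
        orientation_deg=float(rng.uniform(0.0, 180.0)),
        weight=float(weight),
        latency_ms=float(latency),
    )


def draw_cell(
    rng: np.random.Generator,
    species: str,
    eye_region: str,
    cell_id: str,
    config: SimulationConfig,
    *,
    force_coupled: bool | None = None,
) -> GroundTruthCell:
    """Draw one random ground-truth cell for the given region."""
    p = config.region_params[eye_region]
    cp = config.coupled_params
    coupled = (rng.random() < p.get("coupling_prob", 0.0)
               if force_coupled is None else force_coupled)
    fwhm_range = cp["coupled_fwhm_range"] if coupled else p["fwhm_range"]
    fwhm_main = rng.uniform(*fwhm_range)
    comps = [_draw_component(rng, fwhm_main, config.aspect_ratio_range,
                             config.center_jitter_deg)]
    if coupled:
        sep = rng.uniform(*cp["separation_range"])
        main = comps[0]
        lim = cp.get("max_center_deg", 8.0)
        for _attempt in range(256):
            ang = rng.uniform(0.0, 2.0 * np.pi)
            c2 = (main.az_deg + sep * np.cos(ang), main.el_deg + sep * np.sin(ang))
            if abs(c2[0]) <= lim and abs(c2[1]) <= lim:
                break
        # coupled secondaries are homologous neighbours: similar RF size
        comps.append(
            _draw_component(
                rng, fwhm_main * rng.uniform(0.85, 1.15),
                config.aspect_ratio_range, 0.0, center=c2,
                weight=rng.uniform(*cp["secondary_weight_range"]),
                latency=rng.uniform(*cp["latency_offset_range"]),
            )
        )
    v_max = rng.uniform(*config.v_max_range)
    return GroundTruthCell(
        cell_id=cell_id,
        components=comps,
        v_max_mv=float(v_max),
        k_half=float(rng.uniform(*p["k_range"])),
        hill_n=float(rng.uniform(*p["n_range"])),
        ps_true=float(rng.uniform(*p["ps_range"])),
        phi_max_true_deg=float(rng.uniform(0.0, 180.0)),
        lambda_max_nm=340.0,
        noise_sd_mv=float(config.noise_frac_v_max * v_max),
        species=species,
        eye_region=eye_region,
    )


def generate_cells(config: SimulationConfig) -> list[GroundTruthCell]:
    """Draw the full population described by ``config`` (deterministic)."""
    rng = np.random.default_rng(config.seed)
    cells = []
    for species in sorted(config.counts):
        for region in sorted(config.counts[species]):
            for i in range(config.counts[species][region]):
                cid = f"{species}_{region}_{i:03d}"
                cells.append(draw_cell(rng, species, region, cid, config))
    return cells


def save_ground_truth(cells: list[GroundTruthCell], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in cells], fh, indent=1, sort_keys=True)


def load_ground_truth(path: str | Path) -> list[GroundTruthCell]:
    with open(path) as fh:
        return [GroundTruthCell.from_dict(d) for d in json.load(fh)]
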