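"""Intensity-response (Hill) fitting, the inverse-Hill sensitivity
transformation, and spectral-peak fitting with a visual-pigment template.

The Hill (Naka-Rushton) curve ``V(I) = V_max * I**n / (I**n + K**n)`` maps
relative stimulus intensity to peak depolarization.  Its inverse maps a
normalized response ``r = V / V_max`` back to an equivalent intensity,
``s(r) = (r / (1 - r))**(1/n)``, which is the sensitivity scale used for
receptive-field maps and polarization tuning curves.  Intensities are
handled on a linear relative scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .errors import DegenerateFitError, DomainError, InputError

#: responses above this fraction of V_max are clipped before inversion
#: (the inverse diverges as r -> 1)
R_CAP = 0.99


@dataclass(frozen=True)
class HillFit:
    """Fitted intensity-response parameters of one cell."""

    v_max: float  # mV
    k_half: float  # half-maximum intensity, linear relative units
    n: float  # Hill slope
    rss: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (self.v_max > 0 and self.k_half > 0 and self.n > 0):
            raise InputError("v_max, k_half and n must all be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HillFit":
        return cls(**{k: d[k] for k in ("v_max", "k_half", "n", "rss", "n_points")})


@dataclass(frozen=True)
class SpectralFit:
    """Fitted peak wavelength of the pigment template."""

    lambda_max: float  # nm
    rss: float

    def __post_init__(self) -> None:
        if not 300 < self.lambda_max < 700:
            raise DomainError("lambda_max must lie in (300, 700) nm")


def hill_response(intensity, v_max: float, k_half: float, n: float):
    """Forward Hill curve ``V(I)``; vectorised over ``intensity``."""
    i = np.asarray(intensity, dtype=float)
    with np.errstate(divide="ignore"):
        ip = np.power(i, n)
    return v_max * ip / (ip + k_half**n)


def fit_hill(intensities, peak_responses_mv) -> HillFit:
    """Least-squares fit of the Hill curve to (intensity, peak response) data.

    Multi-start over initial slopes n in {0.5, 1, 2}; K is initialized at the
    intensity whose response is nearest half the maximum response.

    Raises
    ------
    InputError
        Fewer than 5 points, a span of less than 2 log units, or negative
        responses.
    DegenerateFitError
        All responses equal (the curve is unidentifiable).
    """
    i = np.asarray(intensities, dtype=float)
    v = np.asarray(peak_responses_mv, dtype=float)
    if i.shape != v.shape or i.ndim != 1:
        raise InputError("intensities and responses must be matching 1-D arrays")
    if i.size < 5:
        raise InputError("need at least 5 intensity-response points")
    if np.any(i <= 0):
        raise InputError("intensities must be positive")
    if np.any(v < 0):
        raise InputError("responses must be nonnegative")
    if np.log10(i.max() / i.min()) < 2 - 1e-9:
        raise InputError("intensities must span at least 2 log units")
    if np.ptp(v) == 0:
        raise DegenerateFitError("all responses equal; Hill fit unidentifiable")

    v_max0 = float(v.max()) * 1.05 + 1e-12
    k0 = float(i[np.argmin(np.abs(v - v.max() / 2))])
    lo = [1e-9, 1e-12, 0.05]
    hi = [np.inf, np.inf, 10.0]
    best = None
    for n0 in (0.5, 1.0, 2.0):
        try:
            popt, _ = curve_fit(
                hill_response, i, v, p0=[v_max0, k0, n0], bounds=(lo, hi), maxfev=20000
            )
        except RuntimeError:
            continue
        rss = float(np.sum((hill_response(i, *popt) - v) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise DegenerateFitError("Hill fit failed to converge from all starts")
    (v_max, k_half, n), rss = best
    return HillFit(
        v_max=float(v_max), k_half=float(k_half), n=float(n), rss=rss, n_points=i.size
    )


def inverse_hill(r, hill: HillFit | None = None, *, n: float | None = None,
                 r_cap: float = R_CAP):
    """Map normalized responses ``r = V / V_max`` to equivalent intensities.

    ``s(r) = (r / (1 - r))**(1/n)``; strictly monotone, with ``s(0.5) = 1``.
    Responses above ``r_cap`` are clipped before inversion.  The caller
    rescales a whole map/series by its maximum to obtain sensitivities in
    [0, 1].

    Either a :class:`HillFit` or an explicit slope ``n`` must be given.
    """
    if n is None:
        if hill is None:
            raise InputError("either a HillFit or a slope n is required")
        n = hill.n
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InputError("normalized responses must be >= 0")
    rc = np.minimum(r, r_cap)
    s = (rc / (1.0 - rc)) ** (1.0 / n)
    return s if s.ndim else float(s)


# ---------------------------------------------------------------------------
# spectral template

# alpha-band A1 rhodopsin template coefficients (Govardovskii et al. 2000)
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104

SPECTRAL_RANGE_NM = (300.0, 700.0)


def spectral_template(lambda_nm, lambda_max: float):
    """Relative sensitivity of an A1 visual pigment peaking at ``lambda_max``.

    Normalized so the template value at ``lambda_max`` is exactly 1.
    Valid for wavelengths in [300, 700] nm.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    lo, hi = SPECTRAL_RANGE_NM
    if np.any(lam < lo) or np.any(lam > hi):
        raise DomainError(f"wavelengths must lie in [{lo}, {hi}] nm")
    if not lo < lambda_max < hi:
        raise DomainError("lambda_max outside supported range")

    def _raw(lam_arr):
        x = lambda_max / lam_arr
        a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
        return 1.0 / (
            np.exp(_A * (a - x))
            + np.exp(_B * (_b - x))
            + np.exp(_C * (_c - x))
            + _D
        )

    s = _raw(lam) / _raw(np.asarray(lambda_max))
    return s if s.ndim else float(s)


def fit_spectral_peak(wavelengths_nm, responses_mv, hill: HillFit) -> SpectralFit:
    """Fit the template's peak wavelength to a response spectrum.

    Responses (mV) are transformed to sensitivities via the inverse Hill
    function and normalized to their maximum before the one-parameter
    least-squares fit.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    v = np.asarray(responses_mv, dtype=float)
    if lam.shape != v.shape or lam.ndim != 1:
        raise InputError("wavelengths and responses must be matching 1-D arrays")
    if lam.size < 5:
        raise InputError("need at least 5 wavelengths")
    lo, hi = SPECTRAL_RANGE_NM
    if lam.max() < lo or lam.min() > hi:
        raise DomainError("data range does not overlap template support")
    if np.ptp(v) == 0:
        raise DegenerateFitError("flat spectrum; peak wavelength unidentifiable")

    s = inverse_hill(v / hill.v_max, hill)
    s = s / s.max()

    def rss(lmax: float) -> float:
        return float(np.sum((spectral_template(lam, lmax) - s) ** 2))

    # the objective is multimodal in lambda_max: coarse grid, then refine
    grid = np.arange(lo + 1.0, hi - 1.0, 2.0)
    l0 = float(grid[np.argmin([rss(g) for g in grid])])
    res = minimize_scalar(
        rss, bounds=(max(lo + 1.0, l0 - 3.0), min(hi - 1.0, l0 + 3.0)),
        method="bounded", options={"xatol": 1e-4},
    )
    return SpectralFit(lambda_max=float(res.x), rss=float(res.fun))
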