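"""Polarization sensitivity (PS) and preferred e-vector angle (phi_max).

PS is the ratio between maximum and minimum sensitivity across polarizer
angles, where sensitivities come from the inverse-Hill transformation of
the per-angle voltage responses.  When a cell was measured repeatedly, the
per-angle arithmetic mean of the raw (mV) responses is taken first.  Mean
PS values above a cap (default 20) are flagged as artefactual and excluded.

phi_max is estimated by least squares with the cos^2-with-floor tuning
model, fitted via its exact second-harmonic reparameterization
``s(phi) = a + b*cos(2*phi) + c*sin(2*phi)`` (linear least squares), which
resolves the preferred angle finer than the sampling comb.  A sampled
arg-max fallback is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .response import HillFit, inverse_hill

PS_CAP_DEFAULT = 20.0

#: second-harmonic amplitude below this fraction of the mean sensitivity is
#: treated as "no tuning" -> phi_max not estimable
_TUNING_EPS = 1e-6


@dataclass
class PSMeasurement:
    """Result of one polarization-series analysis."""

    angles_deg: np.ndarray
    sensitivities: np.ndarray
    ps: float
    phi_max: float | None  # deg mod 180; None when not estimable
    excluded: bool = False
    exclusion_reason: str | None = None
    rf_tag: str = "main"

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        if self.phi_max is not None:
            self.phi_max = float(self.phi_max) % 180.0

    def to_dict(self) -> dict:
        return {
            "angles_deg": self.angles_deg.tolist(),
            "sensitivities": self.sensitivities.tolist(),
            "ps": self.ps,
            "phi_max": self.phi_max,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
            "rf_tag": self.rf_tag,
        }


def average_repeats(repeat_series) -> tuple[np.ndarray, np.ndarray]:
    """Per-angle arithmetic mean of raw mV responses across repeats.

    ``repeat_series`` is a sequence of ``(angles_deg, responses_mv)`` pairs
    sharing the same angle comb.  Averaging happens before any
    transformation.
    """
    if not repeat_series:
        raise InputError("no repeats given")
    angles0 = np.asarray(repeat_series[0][0], dtype=float)
    stacked = []
    for angles, resp in repeat_series:
        angles = np.asarray(angles, dtype=float)
        if angles.shape != angles0.shape or not np.allclose(angles, angles0,
                                                            rtol=0, atol=1e-9):
            raise InputError("repeats do not share the same angle comb")
        resp = np.asarray(resp, dtype=float)
        if resp.shape != angles0.shape:
            raise InputError("responses do not match angles")
        stacked.append(resp)
    return angles0, np.mean(stacked, axis=0)


def _fit_phi_max(angles_deg: np.ndarray, s: np.ndarray) -> float | None:
    """phi of the cos^2-model maximum via linear second-harmonic regression."""
    phi = np.deg2rad(angles_deg)
    X = np.column_stack([np.ones_like(phi), np.cos(2 * phi), np.sin(2 * phi)])
    coef, *_ = np.linalg.lstsq(X, s, rcond=None)
    a, b, c = coef
    amp = np.hypot(b, c)
    if amp <= _TUNING_EPS * max(abs(a), 1e-300):
        return None
    return float(np.rad2deg(0.5 * np.arctan2(c, b)) % 180.0)


def compute_ps(
    angles_deg,
    responses_mv,
    hill: HillFit,
    *,
    ps_cap: float = PS_CAP_DEFAULT,
    phi_method: str = "fit",
    rf_tag: str = "main",
) -> PSMeasurement:
    """Compute PS and phi_max from a (possibly pre-averaged) angle series.

    Responses are normalized by the cell's fitted ``v_max`` and passed
    through the inverse Hill transformation; PS is max/min of the resulting
    sensitivities.  The measurement is flagged ``excluded`` when PS exceeds
    ``ps_cap`` (artefactual) or when the minimum response is non-positive
    (hyperpolarizing-minimum artefact).
    """
    angles = np.asarray(angles_deg, dtype=float)
    resp = np.asarray(responses_mv, dtype=float)
    if angles.ndim != 1 or angles.shape != resp.shape:
        raise InputError("angles and responses must be matching 1-D arrays")
    if angles.size < 8:
        raise InputError("need at least 8 polarizer angles")
    if np.ptp(angles) < 180.0 - np.ptp(angles) / angles.size - 1e-9:
        # allow combs like 0..168.75 in 16 steps (full period minus one step)
        if np.ptp(angles) < 150.0:
            raise InputError("angle comb must span (close to) 180 degrees")
    if phi_method not in ("fit", "argmax"):
        raise InputError("phi_method must be 'fit' or 'argmax'")

    if np.min(resp) <= 0:
        s = np.maximum(resp, 0.0) / hill.v_max
        return PSMeasurement(
            angles_deg=angles, sensitivities=np.zeros_like(s), ps=np.inf,
            phi_max=None, excluded=True,
            exclusion_reason="non-positive minimum", rf_tag=rf_tag,
        )

    s = inverse_hill(resp / hill.v_max, hill)
    s_min = float(np.min(s))
    if s_min <= 0:
        return PSMeasurement(
            angles_deg=angles, sensitivities=s, ps=np.inf, phi_max=None,
            excluded=True, exclusion_reason="non-positive minimum",
            rf_tag=rf_tag,
        )
    ps = float(np.max(s) / s_min)
    if phi_method == "fit":
        phi = _fit_phi_max(angles, s)
    else:
        phi = None if np.ptp(s) <= _TUNING_EPS * s.mean() \
            else float(angles[int(np.argmax(s))] % 180.0)
    excluded = ps > ps_cap
    reason = f"artefactual (PS > {ps_cap:g})" if excluded else None
    return PSMeasurement(
        angles_deg=angles, sensitivities=s, ps=ps, phi_max=phi,
        excluded=excluded, exclusion_reason=reason, rf_tag=rf_tag,
    )


def phi_max_offset(a: PSMeasurement | float, b: PSMeasurement | float) -> float:
    """Smallest angular difference between two axial angles, in [0, 90].

    Accepts either PSMeasurement objects (must have an estimable phi_max and
    not be excluded) or raw angles in degrees.
    """
    def _angle(x) -> float:
        if isinstance(x, PSMeasurement):
            if x.excluded:
                raise InputError("measurement is excluded")
            if x.phi_max is None:
                raise InputError("phi_max not estimable")
            return x.phi_max
        return float(x)

    d = abs(_angle(a) - _angle(b)) % 180.0
    return min(d, 180.0 - d)
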