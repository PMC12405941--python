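"""Eye-region classification: main retina / marginal DRA / DRA.

Recording-depth metadata, when present, decides the label (with warnings
when the numeric criteria disagree).  Otherwise the label comes from a
deterministic, order-free combination of three criteria:

* polarization sensitivity — low PS points to the main retina, high PS to
  the (marginal) DRA;
* absolute sensitivity — a low half-max intensity (high sensitivity)
  points to main retina or marginal DRA, a high one to the DRA;
* RF size — a large circular FWHM points to the DRA.

High sensitivity combined with high PS yields marginal_DRA.  The numeric
thresholds are artifact configuration, not measured cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, NotEstimableError
from .recording import EYE_REGIONS


@dataclass(frozen=True)
class ClassificationRule:
    """Thresholds for the numeric classification criteria."""

    ps_high: float = 4.0
    #: main-retina reference half-max intensity (linear relative units)
    k_half_ref: float = 0.1
    #: DRA cells are roughly this many times less sensitive than the
    #: main-retina reference; the cut sits at the geometric midpoint
    sensitivity_ratio: float = 10.0
    fwhm_large_deg: float = 5.0

    def __post_init__(self) -> None:
        for name in ("ps_high", "k_half_ref", "sensitivity_ratio", "fwhm_large_deg"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be positive")

    @property
    def k_half_cut(self) -> float:
        return self.k_half_ref * float(np.sqrt(self.sensitivity_ratio))


@dataclass
class Classification:
    eye_region: str
    rationale: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def classify(
    *,
    depth_hint: str | None = None,
    ps: float | None = None,
    k_half: float | None = None,
    fwhm_circ: float | None = None,
    rule: ClassificationRule | None = None,
) -> Classification:
    """Assign an eye region from depth metadata and/or numeric criteria.

    Raises
    ------
    NotEstimableError
        Fewer than two of {depth hint, PS, half-max intensity, FWHM} given.
    """
    rule = rule or ClassificationRule()
    if depth_hint is not None and depth_hint not in EYE_REGIONS:
        raise InputError(f"depth_hint must be one of {EYE_REGIONS}")
    available = [x for x in (depth_hint, ps, k_half, fwhm_circ) if x is not None]
    if len(available) < 2:
        raise NotEstimableError("need at least two classification criteria")

    rationale: list[str] = []
    high_ps = None if ps is None else ps >= rule.ps_high
    high_sens = None if k_half is None else k_half <= rule.k_half_cut
    large_fwhm = None if fwhm_circ is None else fwhm_circ >= rule.fwhm_large_deg
    if ps is not None:
        rationale.append(f"PS={ps:g} -> {'high' if high_ps else 'low'} "
                         f"(threshold {rule.ps_high:g})")
    if k_half is not None:
        rationale.append(
            f"k_half={k_half:g} -> {'high' if high_sens else 'low'} sensitivity "
            f"(cut {rule.k_half_cut:g})")
    if fwhm_circ is not None:
        rationale.append(
            f"FWHM={fwhm_circ:g} deg -> {'large' if large_fwhm else 'small'} "
            f"(threshold {rule.fwhm_large_deg:g} deg)")

    numeric = _numeric_label(high_ps, high_sens, large_fwhm)

    if depth_hint is not None:
        rationale.insert(0, f"depth hint = {depth_hint} (decides)")
        warnings = []
        if numeric is not None and numeric != depth_hint:
            warnings.append(
                f"numeric criteria suggest {numeric}, depth hint says {depth_hint}")
        return Classification(eye_region=depth_hint, rationale=rationale,
                              warnings=warnings)
    if numeric is None:
        raise NotEstimableError("need at least two numeric criteria")
    return Classification(eye_region=numeric, rationale=rationale, warnings=[])


def _numeric_label(high_ps, high_sens, large_fwhm) -> str | None:
    criteria = [x for x in (high_ps, high_sens, large_fwhm) if x is not None]
    if len(criteria) < 2:
        return None
    if high_sens is True and high_ps is True:
        return "marginal_DRA"
    # majority vote main_retina vs DRA; each criterion contributes one vote
    votes_dra = 0
    votes_main = 0
    if high_ps is not None:
        votes_dra += high_ps
        votes_main += not high_ps
    if high_sens is not None:
        votes_dra += not high_sens
        votes_main += high_sens
    if large_fwhm is not None:
        votes_dra += large_fwhm
        votes_main += not large_fwhm
    if votes_dra > votes_main:
        return "DRA"
    if votes_main > votes_dra:
        return "main_retina"
    # deterministic tie-break: PS first, then sensitivity
    if high_ps is not None:
        return "DRA" if high_ps else "main_retina"
    return "DRA" if high_sens is False else "main_retina"
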