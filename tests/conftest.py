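import numpy as np
import pytest

from photorf import GridScanProtocol, GroundTruthCell, HillFit, RFComponentTruth
from photorf.spatial import FWHM_FACTOR


@pytest.fixture
def protocol() -> GridScanProtocol:
    return GridScanProtocol()


def make_cell(
    *,
    az=0.0,
    el=0.0,
    sigma=2.0,
    sigma_minor=None,
    orientation=0.0,
    v_max=20.0,
    k_half=1.0,
    n=1.0,
    ps=1.0,
    phi_max=0.0,
    noise=0.0,
    components=None,
    cell_id="cell",
    **kw,
) -> GroundTruthCell:
    if components is None:
        components = [
            RFComponentTruth(
                az_deg=az, el_deg=el, sigma_major_deg=sigma,
                sigma_minor_deg=sigma if sigma_minor is None else sigma_minor,
                orientation_deg=orientation,
            )
        ]
    return GroundTruthCell(
        cell_id=cell_id, components=components, v_max_mv=v_max, k_half=k_half,
        hill_n=n, ps_true=ps, phi_max_true_deg=phi_max, noise_sd_mv=noise, **kw
    )


@pytest.fixture
def hill_unit() -> HillFit:
    return HillFit(v_max=20.0, k_half=1.0, n=1.0)


def sigma_for_fwhm(fwhm: float) -> float:
    return fwhm / FWHM_FACTOR
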