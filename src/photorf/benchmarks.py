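"""Seeded parameter-recovery benchmarks.

Each function simulates ground-truth recordings, runs the corresponding
estimators end to end, and reports recovery metrics.  They power the
acceptance suite and the ``scripts/acceptance.py`` report.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np

from . import spatial, synth
from .pipeline import PipelineConfig, analyze_cell, run_pipeline
from .polarization import compute_ps
from .recording import GridScanProtocol, epoch_amplitudes
from .response import HillFit, inverse_hill
from .spatial import FWHM_FACTOR
from .synth import GroundTruthCell, RFComponentTruth, SimulationConfig


def inverse_hill_roundtrip(n_pairs: int = 200, seed: int = 0) -> dict:
    """Max relative error of the algebraic round trip s -> r -> s."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_pairs:
        s = 10.0 ** rng.uniform(-3, 3)
        n = rng.uniform(0.5, 2.0)
        r = s**n / (s**n + 1.0)
        if r > 0.99:  # clipped by design; not part of the round-trip domain
            continue
        worst = max(worst, abs(inverse_hill(r, n=n) - s) / s)
        done += 1
    return {"max_rel_err": worst, "n": n_pairs}


def analytic_fwhm(seed: int = 0) -> dict:
    """Noiseless isotropic sigma=2 deg cell through the full map pipeline,
    plus the closed-form elliptical-to-circular FWHM conversion."""
    protocol = GridScanProtocol()
    cell = GroundTruthCell(
        "iso", [RFComponentTruth(0.3, -0.4, 2.0, 2.0)], 20.0, 1.0, 1.0)
    hill = HillFit(20.0, 1.0, 1.0)
    trace = synth.simulate_grid_scan(cell, protocol, seed=seed)
    raw = spatial.extract_raw_map(trace, protocol)
    sens = spatial.to_sensitivity(raw, hill, baseline="none")
    model = spatial.fit_rf(sens)
    comp = spatial.RFComponent(
        center_az=0.0, center_el=0.0, sigma_major=9.0 / FWHM_FACTOR,
        sigma_minor=4.0 / FWHM_FACTOR, orientation=0.0, amplitude=1.0)
    return {
        "n_components": len(model.components),
        "fwhm_circ": model.main.fwhm_circ,
        "expected_fwhm": FWHM_FACTOR * 2.0,
        "elliptical_fwhm_circ": comp.fwhm_circ,  # exact: sqrt(9 * 4) = 6
    }


def _random_single_rf_cell(rng, *, noise_frac: float) -> GroundTruthCell:
    fwhm = rng.uniform(2.5, 8.0)
    sigma = fwhm / FWHM_FACTOR
    v_max = rng.uniform(15.0, 25.0)
    return GroundTruthCell(
        "bench",
        [RFComponentTruth(rng.uniform(-2, 2), rng.uniform(-2, 2), sigma, sigma)],
        v_max_mv=v_max,
        k_half=rng.uniform(0.1, 1.0),
        hill_n=rng.uniform(0.7, 1.2),
        ps_true=rng.uniform(2.0, 12.0),
        phi_max_true_deg=rng.uniform(0.0, 180.0),
        noise_sd_mv=noise_frac * v_max,
    )


def recovery_benchmark(n_cells: int = 50, seed: int = 0,
                       noise_frac: float = 0.05) -> dict:
    """Single-RF parameter recovery through the complete analysis chain."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    config = PipelineConfig(noise_frac_v_max=noise_frac)
    children = ss.spawn(n_cells)
    fwhm_err, center_err, ps_err, phi_err = [], [], [], []
    for child in children:
        cell = _random_single_rf_cell(rng, noise_frac=noise_frac)
        res = analyze_cell(cell, config, child)
        comp = res["rf"]["components"][0]
        truth = cell.components[0]
        true_fwhm = FWHM_FACTOR * np.sqrt(
            truth.sigma_major_deg * truth.sigma_minor_deg)
        fwhm_err.append(abs(comp["fwhm_circ_deg"] - true_fwhm) / true_fwhm)
        center_err.append(float(np.hypot(comp["center_az_deg"] - truth.az_deg,
                                         comp["center_el_deg"] - truth.el_deg)))
        ps_err.append(abs(res["ps"]["ps"] - cell.ps_true) / cell.ps_true)
        d = abs(res["ps"]["phi_max"] - cell.phi_max_true_deg) % 180.0
        phi_err.append(min(d, 180.0 - d))
    return {
        "n": n_cells,
        "median_fwhm_rel_err": float(np.median(fwhm_err)),
        "median_center_err_deg": float(np.median(center_err)),
        "median_ps_rel_err": float(np.median(ps_err)),
        "median_phi_max_err_deg": float(np.median(phi_err)),
    }


def _rf_model_for(cell: GroundTruthCell, protocol, seed):
    hill = HillFit(cell.v_max_mv, cell.k_half, cell.hill_n)
    trace = synth.simulate_grid_scan(cell, protocol, seed=seed)
    raw = spatial.extract_raw_map(trace, protocol)
    sens = spatial.to_sensitivity(spatial.smooth_map(raw), hill)
    return trace, sens, spatial.fit_rf(sens)


def coupling_benchmark(n_each: int = 100, seed: int = 0) -> dict:
    """Coupling-detection sensitivity and false-positive rate."""
    protocol = GridScanProtocol()
    sim_cfg = SimulationConfig()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    hits = 0
    for i in range(n_each):
        cell = synth.draw_cell(rng, "Apis", "DRA", f"c{i}", sim_cfg,
                               force_coupled=True)
        _t, sens, model = _rf_model_for(cell, protocol, ss.spawn(1)[0])
        hits += bool(spatial.detect_coupling(model, sens).coupled)
    false_pos = 0
    for i in range(n_each):
        cell = synth.draw_cell(rng, "Apis", "DRA", f"s{i}", sim_cfg,
                               force_coupled=False)
        _t, sens, model = _rf_model_for(cell, protocol, ss.spawn(1)[0])
        false_pos += bool(spatial.detect_coupling(model, sens).coupled)
    return {"n_each": n_each,
            "sensitivity": hits / n_each,
            "false_positive_rate": false_pos / n_each}


def delay_benchmark(offsets_ms=(0, 1, 2, 3, 4, 5), n_runs: int = 20,
                    seed: int = 0, noise_frac: float = 0.01) -> dict:
    """Latency-offset recovery to within one sample at 1 kHz."""
    protocol = GridScanProtocol()
    sim_cfg = SimulationConfig()
    ss = np.random.SeedSequence(seed)
    per_offset = {}
    for offset in offsets_ms:
        ok = 0
        for _run in range(n_runs):
            geom_seed, sim_seed = ss.spawn(2)
            rng = np.random.default_rng(geom_seed)
            drawn = synth.draw_cell(rng, "Bombus", "DRA", "d", sim_cfg,
                                    force_coupled=True)
            comps = [
                RFComponentTruth(
                    c.az_deg, c.el_deg, c.sigma_major_deg, c.sigma_minor_deg,
                    c.orientation_deg, c.weight,
                    0.0 if c.weight == 1.0 else float(offset))
                for c in drawn.components
            ]
            cell = GroundTruthCell(
                "d", comps, drawn.v_max_mv, drawn.k_half, drawn.hill_n,
                noise_sd_mv=noise_frac * drawn.v_max_mv)
            trace, _sens, model = _rf_model_for(cell, protocol, sim_seed)
            if len(model.components) < 2:
                continue
            delta = spatial.delay_difference(trace, protocol, model)[0]
            if delta is not None and abs(delta - (-offset)) <= 1.0:
                ok += 1
        per_offset[str(offset)] = ok / n_runs
    return {"n_runs_per_offset": n_runs,
            "fraction_within_1_sample": per_offset,
            "min_fraction": min(per_offset.values())}


def exclusion_benchmark(seed: int = 0, caps=(2.0, 5.0, 10.0, 20.0, 50.0)) -> dict:
    """PS-cap exclusion rule on simulated cells, including PS_true > 20."""
    rng = np.random.default_rng(seed)
    angles = np.arange(0.0, 180.0, 15.0)
    cells = []
    for i in range(12):
        ps_true = rng.uniform(1.5, 30.0) if i % 3 else rng.uniform(21.0, 40.0)
        v_max = rng.uniform(15.0, 25.0)
        cells.append(GroundTruthCell(
            f"e{i}", [RFComponentTruth(0, 0, 2, 2)], v_max, 0.5, 1.0,
            ps_true=ps_true,
            phi_max_true_deg=float(rng.integers(0, 12) * 15),
            noise_sd_mv=0.0))
    measurements = []
    for i, cell in enumerate(cells):
        hill = HillFit(cell.v_max_mv, cell.k_half, cell.hill_n)
        trace = synth.simulate_pol_series(cell, angles, seed=1000 * seed + i)
        resp = epoch_amplitudes(trace, kind="angle")
        measurements.append((cell, angles, resp, hill))
    counts = {}
    for cap in caps:
        counts[str(cap)] = sum(
            compute_ps(a, r, h, ps_cap=cap).excluded
            for _c, a, r, h in measurements)
    above_cap_flagged = all(
        compute_ps(a, r, h, ps_cap=20.0).excluded
        for c, a, r, h in measurements if c.ps_true > 20.0)
    vals = [counts[str(c)] for c in caps]
    return {
        "n_cells": len(cells),
        "excluded_by_cap": counts,
        "all_above_20_flagged": bool(above_cap_flagged),
        "monotone_nonincreasing": all(a >= b for a, b in zip(vals, vals[1:])),
    }


def determinism_benchmark(seed: int = 0, workdir: str | Path = ".") -> dict:
    """Byte-identity of two full 12-cell pipeline runs with the same seed."""
    workdir = Path(workdir)
    dirs = [workdir / "run_a", workdir / "run_b"]
    for d in dirs:
        run_pipeline(PipelineConfig(seed=seed), d)
    names = sorted(p.name for p in dirs[0].iterdir())
    identical = all(
        filecmp.cmp(dirs[0] / n, dirs[1] / n, shallow=False) for n in names)
    return {"n_files": len(names), "byte_identical": bool(identical)}
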