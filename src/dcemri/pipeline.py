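"""End-to-end voxelwise analysis: signal in, parameter maps out.

Stages: (optional) multiflip R1/S0 mapping -> dynamic signal inversion ->
concentration conversion -> voxel selection (user mask or SER auto-mask)
-> per-voxel model fitting -> reduced-chi-square model selection -> clamping.
"""

from __future__ import annotations

import logging
import time

import numpy as np

from .core import PKMaps
from .fitting import fit_voxels_parallel
from .masking import auto_mask, clamp_params, compute_ser, select_best_model
from .matio import InputBundle
from .pharmacokinetics import MODELS_BY_BIT, derive_ve, models_from_bitmask
from .relaxometry import fit_r1_maps, invert_spgr, r1_to_concentration

log = logging.getLogger(__name__)


def run_pipeline(bundle: InputBundle, n_workers: int = 1) -> dict:
    """Run the full analysis on one input bundle; returns the output maps."""
    t0 = time.perf_counter()
    series = bundle.series
    if bundle.multiflip is not None:
        t1series, flips = bundle.multiflip
        t1acq = type(bundle.acq)(tr=bundle.acq.tr, flip_deg=flips)
        maps = fit_r1_maps(t1series, t1acq)
        log.info("R1 mapping: %d voxels fitted in %.2f s",
                 int(maps.fitted_mask.sum()), time.perf_counter() - t0)
    else:
        maps = bundle.maps

    rel = invert_spgr(series, maps, bundle.acq)
    conc = r1_to_concentration(rel, maps, series.t, relaxivity=bundle.relaxivity)

    sermap = compute_ser(series)
    if bundle.mask is not None:
        mask = bundle.mask.astype(bool)
        source = "user_supplied"
    else:
        pm = auto_mask(sermap, cutoff=bundle.ser_cutoff)
        mask = pm.mask & maps.fitted_mask
        source = pm.source
    log.info("mask (%s): %d of %d voxels selected", source,
             int(mask.sum()), mask.size)

    spatial = series.spatial_shape
    flat_mask = mask.ravel()
    curves = conc.ct.reshape(series.n_time, -1)[:, flat_mask].T
    model_list = models_from_bitmask(bundle.models)
    fits = {m.bit: fit_voxels_parallel(curves, m, conc.t_min, bundle.aif.cp,
                                       n_workers=n_workers)
            for m in model_list}
    modelmap_sel, winners = select_best_model(fits)

    n_sel = curves.shape[0]
    est = PKMaps(*(np.zeros(n_sel) for _ in range(5)),
                 modelmap_sel.astype(float))
    for v, (bit, res) in enumerate(zip(modelmap_sel, winners)):
        if bit == 0 or res.skipped:
            continue
        p = dict(zip(MODELS_BY_BIT[bit].param_names, res.params))
        est.ktrans[v] = p.get("ktrans", 0.0)
        est.kep[v] = p.get("kep", 0.0)
        est.vp[v] = p.get("vp", 0.0)
        est.ve[v] = derive_ve(max(p.get("ktrans", 0.0), 0.0),
                              max(p.get("kep", 0.0), 0.0))
        est.resid[v] = res.ssr
    est = clamp_params(est)

    def scatter(vec, fill=0.0):
        full = np.full(flat_mask.size, fill)
        full[flat_mask] = vec
        return full.reshape(spatial)

    out = {
        "Ktrans": scatter(est.ktrans),
        "kep": scatter(est.kep),
        "ve": scatter(est.ve),
        "vp": scatter(est.vp),
        "resid": scatter(est.resid),
        "modelmap": scatter(est.modelmap),
        "R10": maps.r10,
        "S0": maps.s0,
        "SER": sermap.ser,
        "mask": mask.astype(np.uint8),
    }
    elapsed = time.perf_counter() - t0
    rate = n_sel / elapsed if elapsed > 0 else float("inf")
    log.info("pipeline: %d voxels fitted in %.2f s (%.1f voxels/s)",
             n_sel, elapsed, rate)
    return out
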