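"""Accuracy metrics and the end-to-end phantom validation driver.

The driver reruns the whole analysis chain on a digital reference object
-- AIF extraction from the vessel strip, signal inversion, concentration
conversion, voxelwise model fitting, clamping -- and scores the fitted
parameter maps against the known truth with three agreement measures:

* RMS percent error: 100 * sqrt(mean(((est - truth)/truth)^2)),
* maximum percent error: 100 * max|est - truth|/truth,
* Lin's concordance correlation coefficient (CCC), which measures
  agreement with the identity line (1 = perfect concordance).

Truth values of exactly zero are rejected rather than silently skipped:
regions with Ktrans = 0 violate the two-compartment model assumptions and
must be excluded by the caller, as is done for the extended-layout runs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import AIF, PKMaps, RelaxationMaps
from .fitting import FitOptions, fit_voxels_parallel
from .masking import clamp_params, select_best_model
from .pharmacokinetics import (
    MODEL_EXTENDED,
    MODEL_STANDARD,
    MODELS_BY_BIT,
    derive_ve,
    models_from_bitmask,
)
from .phantoms import (
    NoiseSpec,
    PhantomSpec,
    SyntheticPhantom,
    add_rician_noise,
    extract_aif,
    generate_phantom,
    load_qiba_dicom,
)
from .relaxometry import invert_spgr, r1_to_concentration

log = logging.getLogger(__name__)


def rms_percent_error(est: np.ndarray, truth: np.ndarray) -> float:
    """100 * RMS of the per-element relative errors (est - truth)/truth."""
    est, truth = _check_pair(est, truth)
    return float(100.0 * np.sqrt(np.mean(((est - truth) / truth) ** 2)))


def max_percent_error(est: np.ndarray, truth: np.ndarray) -> float:
    """100 * max absolute relative error."""
    est, truth = _check_pair(est, truth)
    return float(100.0 * np.max(np.abs((est - truth) / truth)))


def _check_pair(est, truth):
    est = np.asarray(est, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if est.size != truth.size:
        raise ValueError("est and truth must have equal length")
    if np.any(truth == 0):
        raise ValueError(
            "truth contains zeros; exclude zero-truth regions before scoring")
    return est, truth


def ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient, population (1/n) moments.

    ccc = 2 cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2).
    Degenerate cases: both variances zero -> 1 if the means agree else 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    mx, my = x.mean(), y.mean()
    vx = np.mean((x - mx) ** 2)
    vy = np.mean((y - my) ** 2)
    cov = np.mean((x - mx) * (y - my))
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return 1.0
    return float(2.0 * cov / denom)


@dataclass
class ValidationReport:
    """Scores and per-region error maps of one phantom validation run."""

    phantom_id: str
    params: dict[str, dict[str, float]]  # name -> {rms_pct, max_pct, ccc}
    error_maps: dict[str, np.ndarray]  # name -> per-region mean % error
    n_voxels: int
    n_regions: int
    noise_sigma: float
    fit_rate: float  # voxels per second
    elapsed_s: float

    def summary(self) -> str:
        lines = [f"phantom: {self.phantom_id}  "
                 f"(sigma={self.noise_sigma:g}, {self.n_voxels} voxels, "
                 f"{self.n_regions} regions, {self.fit_rate:.1f} voxels/s)"]
        for name, m in self.params.items():
            lines.append(
                f"  {name:>6}: RMS {m['rms_pct']:.3f}%  "
                f"max {m['max_pct']:.3f}%  CCC {m['ccc']:.4f}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [{"parameter": name, **metrics}
                for name, metrics in self.params.items()]
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_mat(self, path) -> None:
        from scipy.io import savemat

        payload = {"phantom_id": self.phantom_id,
                   "noise_sigma": self.noise_sigma,
                   "n_voxels": self.n_voxels}
        for name, m in self.params.items():
            for k, v in m.items():
                payload[f"{name}_{k}"] = v
        for name, emap in self.error_maps.items():
            payload[f"errmap_{name}"] = emap
        savemat(path, payload)

    def save_error_map_png(self, path) -> None:
        """Per-region signed percent-error maps, one panel per parameter."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        names = list(self.error_maps)
        fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3.5),
                                 squeeze=False)
        for ax, name in zip(axes[0], names):
            emap = self.error_maps[name]
            lim = np.nanmax(np.abs(emap)) or 1.0
            im = ax.imshow(emap, cmap="PiYG", vmin=-lim, vmax=lim)
            ax.set_title(f"{name} error (%)")
            fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def run_validation(
    phantom_source,
    noise: NoiseSpec | None = None,
    models: int | None = None,
    layout: PhantomSpec | None = None,
    n_workers: int = 1,
    fit_options: FitOptions | None = None,
) -> ValidationReport:
    """Run the full pipeline on a phantom and score it against truth.

    ``phantom_source`` is a :class:`PhantomSpec` (synthetic generation), an
    already-generated :class:`SyntheticPhantom`, or a path to a QIBA DICOM
    directory (which then requires ``layout`` to supply the ground-truth
    parameter grids and strip geometry).

    Noise-free runs analyse one voxel per region (all voxels in a patch
    are identical); noisy runs keep every voxel to sample the noise.  For
    extended-layout phantoms the Ktrans = 0 regions are removed before
    fitting, since zero transfer precludes estimating ve.
    """
    if isinstance(phantom_source, PhantomSpec):
        phantom = generate_phantom(phantom_source)
        phantom_id = "synthetic_extended" if phantom_source.is_extended \
            else "synthetic_standard"
    elif isinstance(phantom_source, SyntheticPhantom):
        phantom = phantom_source
        phantom_id = "synthetic_extended" if phantom.spec.is_extended \
            else "synthetic_standard"
    else:
        if layout is None:
            raise ValueError(
                "loading a DICOM phantom requires a layout spec carrying the "
                "ground-truth parameter grids")
        phantom = _phantom_from_dicom(Path(phantom_source), layout)
        phantom_id = str(phantom_source)
    spec = phantom.spec
    sigma = noise.sigma_rel if noise is not None else 0.0

    t_start = time.perf_counter()
    series = phantom.series
    if noise is not None and noise.sigma_rel > 0:
        series = add_rician_noise(series, noise, vessel_rows=phantom.vessel_rows)

    acq = spec.acq
    aif = extract_aif(series, phantom.maps, acq, phantom.vessel_rows,
                      relaxivity=spec.relaxivity)
    rel = invert_spgr(series, phantom.maps, acq)
    conc = r1_to_concentration(rel, phantom.maps, series.t,
                               relaxivity=spec.relaxivity)
    ct_tissue = conc.ct[:, phantom.tissue_rows, :]

    keep_region = np.ones(spec.n_regions, dtype=bool)
    if spec.is_extended:
        table_kt = np.array([kt for kt, _, _ in _region_table_of(spec)])
        keep_region = table_kt > 0
    noise_free = sigma == 0
    sel = keep_region[phantom.region_ids]
    if noise_free:
        sel = sel & _patch_corner_mask(phantom.region_ids, spec.patch_shape)
    sel_flat = sel.ravel()
    curves = ct_tissue.reshape(series.n_time, -1)[:, sel_flat].T
    truth = {k: phantom.truth[k].ravel()[sel_flat] for k in ("ktrans", "ve", "vp")}

    if models is None:
        models = MODEL_EXTENDED if spec.is_extended else MODEL_STANDARD
    model_list = models_from_bitmask(models)
    t_min = series.t / 60.0
    fits = {m.bit: fit_voxels_parallel(curves, m, t_min, aif.cp,
                                       opts=fit_options, n_workers=n_workers)
            for m in model_list}
    modelmap, winners = select_best_model(fits)

    n_sel = curves.shape[0]
    est = PKMaps(*(np.zeros(n_sel) for _ in range(5)), modelmap)
    for v, (bit, res) in enumerate(zip(modelmap, winners)):
        if bit == 0 or res.skipped:
            continue
        names = MODELS_BY_BIT[bit].param_names
        p = dict(zip(names, res.params))
        est.ktrans[v] = p.get("ktrans", 0.0)
        est.kep[v] = p.get("kep", 0.0)
        est.vp[v] = p.get("vp", 0.0)
        est.ve[v] = derive_ve(max(p.get("ktrans", 0.0), 0.0),
                              max(p.get("kep", 0.0), 0.0))
        est.resid[v] = res.ssr
    est = clamp_params(est)
    elapsed = time.perf_counter() - t_start
    fit_rate = n_sel / elapsed if elapsed > 0 else np.inf

    score_names = ["ktrans", "ve", "vp"] if spec.is_extended else ["ktrans", "ve"]
    params = {}
    for name in score_names:
        e, tr = getattr(est, name), truth[name]
        params[name] = {
            "rms_pct": rms_percent_error(e, tr),
            "max_pct": max_percent_error(e, tr),
            "ccc": ccc(e, tr),
        }

    error_maps = _per_region_error_maps(
        phantom, sel, est, truth, score_names, keep_region)
    report = ValidationReport(
        phantom_id=phantom_id, params=params, error_maps=error_maps,
        n_voxels=n_sel, n_regions=int(keep_region.sum()),
        noise_sigma=sigma, fit_rate=fit_rate, elapsed_s=elapsed)
    log.info("run_validation:\n%s", report.summary())
    return report


def _region_table_of(spec: PhantomSpec):
    from .phantoms import _region_table

    return _region_table(spec)


def _patch_corner_mask(region_ids: np.ndarray, patch_shape) -> np.ndarray:
    """True at the top-left voxel of each patch (one voxel per region)."""
    pr, pc = patch_shape
    mask = np.zeros_like(region_ids, dtype=bool)
    mask[::pr, ::pc] = True
    return mask


def _per_region_error_maps(phantom, sel, est: PKMaps, truth, names, keep_region):
    """Mean signed percent error per region, arranged on the region grid."""
    spec = phantom.spec
    n_cols_regions = len(spec.ve_values) * (len(spec.vp_values) or 1)
    n_rows_regions = len(spec.ktrans_values)
    region_of_sel = phantom.region_ids.ravel()[sel.ravel()]
    maps = {}
    for name in names:
        emap = np.full((n_rows_regions, n_cols_regions), np.nan)
        err = 100.0 * (getattr(est, name) - truth[name]) / truth[name]
        for rid in np.unique(region_of_sel):
            if not keep_region[rid]:
                continue
            r, c = divmod(rid, n_cols_regions)
            emap[r, c] = err[region_of_sel == rid].mean()
        maps[name] = emap
    return maps


def _phantom_from_dicom(directory: Path, layout: PhantomSpec) -> SyntheticPhantom:
    """Wrap a loaded QIBA DICOM stack in the synthetic-phantom geometry.

    The layout spec supplies the parameter grids, patch geometry, strip
    rows and pre-contrast relaxation rates; acquisition parameters come
    from the DICOM headers.
    """
    from .phantoms import _region_table

    series, acq = load_qiba_dicom(directory)
    spec = PhantomSpec(
        ktrans_values=layout.ktrans_values, ve_values=layout.ve_values,
        vp_values=layout.vp_values, patch_shape=layout.patch_shape,
        n_time=series.n_time, dt=float(np.median(np.diff(series.t)) or layout.dt),
        acq=acq, relaxivity=layout.relaxivity, r10_tissue=layout.r10_tissue,
        r10_blood=layout.r10_blood, s0=layout.s0, strip_rows=layout.strip_rows,
    )
    regions = _region_table(spec)
    pr, pc = spec.patch_shape
    n_rows = len(spec.ktrans_values) * pr
    n_cols_regions = len(spec.ve_values) * (len(spec.vp_values) or 1)
    n_cols = n_cols_regions * pc
    if series.data.shape[1] < n_rows + spec.strip_rows or series.data.shape[2] < n_cols:
        raise ValueError(
            f"DICOM frames {series.data.shape[1:]} are smaller than the "
            f"declared layout ({n_rows + spec.strip_rows} x {n_cols})")
    truth = {k: np.empty((n_rows, n_cols)) for k in ("ktrans", "ve", "vp")}
    region_ids = np.empty((n_rows, n_cols), dtype=int)
    for i, (kt, ve, vp) in enumerate(regions):
        r = (i // n_cols_regions) * pr
        c = (i % n_cols_regions) * pc
        truth["ktrans"][r:r + pr, c:c + pc] = kt
        truth["ve"][r:r + pr, c:c + pc] = ve
        truth["vp"][r:r + pr, c:c + pc] = vp
        region_ids[r:r + pr, c:c + pc] = i
    r10 = np.full(series.data.shape[1:], spec.r10_tissue)
    r10[n_rows:n_rows + spec.strip_rows, :] = spec.r10_blood
    s0 = np.zeros_like(r10)  # use pre-contrast dynamics for normalisation
    maps = RelaxationMaps(r10=r10, s0=s0, fitted_mask=np.ones_like(r10, bool))
    return SyntheticPhantom(
        series=series, truth=truth, region_ids=region_ids, maps=maps,
        aif=AIF(t=series.t, cp=np.zeros(series.n_time)),
        vessel_rows=slice(n_rows, n_rows + spec.strip_rows),
        tissue_rows=slice(0, n_rows), spec=spec)
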