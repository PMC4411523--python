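"""Spoiled-gradient-echo (SPGR) relaxometry.

The steady-state SPGR signal is

    S = S0 * sin(theta) * (1 - E1) / (1 - cos(theta) * E1),   E1 = exp(-R1 * TR)

with flip angle theta and repetition time TR.  This module provides the
forward model, variable-flip-angle (DESPOT1-initialised) fitting of
voxelwise R1(x,0)/S(x,0) maps, inversion of the dynamic signal to an
effective R1(x,t), and conversion of R1 changes to tracer concentration.

The dynamic inversion deliberately uses a form free of sin(theta): only the
signal *ratio* s(x,t) = S(x,t)/S(x,0) enters, which cancels S0 and sin(theta)
and thereby reduces sensitivity to B1 transmit inhomogeneity.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .core import (
    AcquisitionParams,
    ConcentrationSeries,
    DynamicSeries,
    InvalidParameterError,
    RelaxationMaps,
    RelaxationSeries,
)
from .fitting import FitOptions, levmar

log = logging.getLogger(__name__)

DEFAULT_RELAXIVITY = 4.5
"""Gd-DTPA longitudinal relaxivity at 3.0 T, s^-1 mM^-1."""


def spgr_signal(s0, r1, acq: AcquisitionParams):
    """Forward SPGR steady-state signal.

    Vectorizes over voxels (``s0``, ``r1`` arrays) and over flip angles when
    ``acq.flip_deg`` is a vector; a vector flip against array inputs
    broadcasts flip angles along a new leading axis.
    """
    s0 = np.asarray(s0, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    if np.any(r1 < 0):
        raise InvalidParameterError("r1 must be non-negative")
    theta = acq.flip_rad
    e1 = np.exp(-r1 * acq.tr)
    if np.ndim(theta) > 0 and (s0.ndim > 0 or r1.ndim > 0):
        theta = np.reshape(theta, (-1,) + (1,) * max(s0.ndim, r1.ndim))
    out = s0 * np.sin(theta) * (1.0 - e1) / (1.0 - np.cos(theta) * e1)
    return out if out.ndim else float(out)


def despot1_init(signals, acq: AcquisitionParams):
    """Linear (DESPOT1) estimate of (s0, r1) from multiflip SPGR signals.

    Rearranging the signal equation gives the line
    ``S/sin(theta) = E1 * S/tan(theta) + S0 (1 - E1)``, so an ordinary
    least-squares fit of S/sin against S/tan yields slope E1 and intercept
    S0(1-E1).  The slope is clamped to (0, 1) before the log so that noisy
    input still returns finite parameters.  Exact for noise-free data; used
    as the starting point for the nonlinear fit.
    """
    signals = np.asarray(signals, dtype=float).ravel()
    theta = np.atleast_1d(acq.flip_rad)
    if theta.size < 2 or np.unique(theta).size < 2:
        raise InvalidParameterError("need at least two distinct flip angles")
    if signals.size != theta.size:
        raise ValueError("signal count must match flip-angle count")
    y = signals / np.sin(theta)
    x = signals / np.tan(theta)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx <= 0:
        raise InvalidParameterError("degenerate multiflip regression (constant x)")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    eps = 1e-12
    slope = min(max(slope, eps), 1.0 - eps)
    r1 = -np.log(slope) / acq.tr
    s0 = intercept / (1.0 - slope)
    return float(s0), float(r1)


def _fit_one_voxel(signals, theta, tr, opts: FitOptions):
    """LM fit of (s0, r1) for one voxel's multiflip signals."""
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    def residual(p):
        s0, r1 = p
        e1 = np.exp(-max(r1, 0.0) * tr)
        return s0 * sin_t * (1.0 - e1) / (1.0 - cos_t * e1) - signals

    def jacobian(p):
        s0, r1 = p
        e1 = np.exp(-max(r1, 0.0) * tr)
        denom = 1.0 - cos_t * e1
        d_s0 = sin_t * (1.0 - e1) / denom
        d_r1 = s0 * sin_t * (1.0 - cos_t) * tr * e1 / denom**2
        return np.column_stack([d_s0, d_r1])

    return levmar(residual, jacobian, opts)


def fit_r1_maps(
    multiflip: DynamicSeries,
    acq: AcquisitionParams,
    intensity_frac: float = 0.10,
) -> RelaxationMaps:
    """Fit voxelwise R1(x,0) and S(x,0) maps from multiflip SPGR data.

    Voxels whose mean multiflip intensity falls below ``intensity_frac``
    times the global maximum of the mean image are dominated by noise and
    are excluded (sentinel 0, ``fitted_mask`` False).  Each remaining voxel
    is fitted by Levenberg-Marquardt starting from the DESPOT1 linear
    estimate; voxel fits are independent, so results do not depend on
    ``n_workers``.
    """
    theta = np.atleast_1d(acq.flip_rad)
    if multiflip.n_time != theta.size:
        raise ValueError(
            f"multiflip series has {multiflip.n_time} frames but acq supplies "
            f"{theta.size} flip angles"
        )
    spatial = multiflip.spatial_shape
    flat = multiflip.data.reshape(multiflip.n_time, -1)
    mean_img = flat.mean(axis=0)
    cutoff = intensity_frac * (mean_img.max() if mean_img.size else 0.0)
    mask = mean_img >= cutoff
    if not mask.any():
        warnings.warn("no voxels above the intensity cutoff; empty R1 map")

    r10 = np.zeros(mean_img.size)
    s0 = np.zeros(mean_img.size)
    idx = np.flatnonzero(mask)
    for i in idx:
        sig = flat[:, i]
        try:
            init = despot1_init(sig, acq)
        except InvalidParameterError:
            init = (max(sig.max(), 1.0), 1.0)
        opts = FitOptions(init=np.array(init))
        res = _fit_one_voxel(sig, theta, acq.tr, opts)
        s0[i] = max(res.params[0], 0.0)
        r10[i] = max(res.params[1], 0.0)
    log.info("fit_r1_maps: fitted %d/%d voxels", idx.size, mean_img.size)
    return RelaxationMaps(
        r10=r10.reshape(spatial), s0=s0.reshape(spatial),
        fitted_mask=mask.reshape(spatial),
    )


def invert_spgr(
    series: DynamicSeries,
    maps: RelaxationMaps,
    acq: AcquisitionParams,
    n_pre: int = 3,
) -> RelaxationSeries:
    """Invert the SPGR signal equation to an effective R1(x,t) series.

    The signal is first normalized to the pre-contrast signal,
    s(x,t) = S(x,t)/S(x,0).  Where the supplied S0 map is positive, S(x,0)
    is the signal equation evaluated at (S0, R1(x,0)) -- this keeps the
    normalization valid even when the first dynamic and the S0 map are on
    different scales; elsewhere it falls back to the mean of the first
    ``n_pre`` (pre-contrast) dynamics.  The inversion uses the
    sin(theta)-free form

        R1(t) = -(1/TR) * log[ (1 - s + s*E10 - E10*cos) /
                               (1 - s*cos + s*E10*cos - E10*cos) ]

    with E10 = exp(-R1(x,0)*TR).  Samples whose log argument is
    non-positive (possible for noisy, strongly enhancing voxels) become NaN
    sentinels and are counted in ``n_degenerate`` rather than raising.
    """
    if not np.isscalar(acq.flip_deg):
        raise InvalidParameterError("dynamic inversion requires a scalar flip angle")
    if maps.r10.shape != series.spatial_shape:
        raise ValueError("relaxation maps do not cover the series' spatial grid")
    flat = series.data.reshape(series.n_time, -1)
    with np.errstate(invalid="ignore"):
        s_ref = spgr_signal(maps.s0.ravel(), maps.r10.ravel(), acq)
    need_ref = ~(s_ref > 0)
    if need_ref.any():
        n_pre_eff = min(n_pre, series.n_time)
        s_ref[need_ref] = flat[:n_pre_eff, need_ref].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_norm = flat / s_ref
    cos_t = np.cos(acq.flip_rad)
    e10 = np.exp(-maps.r10.ravel() * acq.tr)
    num = 1.0 - s_norm + s_norm * e10 - e10 * cos_t
    den = 1.0 - s_norm * cos_t + s_norm * e10 * cos_t - e10 * cos_t
    # the physical branch of the inversion requires both factors positive;
    # enhancement beyond the signal-equation ceiling flips their signs
    valid = (num > 0) & (den > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = np.where(valid, num / den, 1.0)
        r1_t = np.where(valid, -np.log(arg) / acq.tr, np.nan)
    n_degenerate = int(np.sum(~valid & np.isfinite(s_norm)))
    if n_degenerate:
        log.warning("invert_spgr: %d degenerate samples set to NaN", n_degenerate)
    shape = (series.n_time,) + series.spatial_shape
    return RelaxationSeries(
        r1_t=r1_t.reshape(shape), s_norm=s_norm.reshape(shape),
        n_degenerate=n_degenerate,
    )


def r1_to_concentration(
    rel: RelaxationSeries,
    maps: RelaxationMaps,
    t: np.ndarray,
    relaxivity: float = DEFAULT_RELAXIVITY,
) -> ConcentrationSeries:
    """Convert an R1(x,t) series to tissue concentration Ct(x,t) in mM.

    Ct = (R1(x,t) - R1(x,0)) / r1 with relaxivity r1 in s^-1 mM^-1
    (default 4.5, Gd-DTPA at 3.0 T).  Negative concentrations from noise
    are preserved; NaN sentinels propagate.  ``t`` is in seconds and is
    returned converted to minutes.
    """
    if relaxivity <= 0:
        raise InvalidParameterError("relaxivity must be positive")
    r10 = maps.r10.reshape((1,) + maps.r10.shape)
    ct = (rel.r1_t - r10) / relaxivity
    return ConcentrationSeries(ct=ct, t_min=np.asarray(t, float) / 60.0,
                               relaxivity=relaxivity)
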