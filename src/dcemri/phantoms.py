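"""Digital reference objects for validating the DCE-MRI pipeline.

The QIBA virtual DCE phantoms arrange every combination of tracer-kinetic
parameter values in a grid of uniform square patches, with a vessel strip
at the bottom of the image that carries the arterial input function
encoded as SPGR signal.  This module can

* load such a phantom from a DICOM series (frames ordered by instance
  number),
* generate a synthetic phantom with the same layout from first principles
  (kinetic model -> concentration -> relaxation rate -> SPGR signal), so
  the entire validation harness runs with no downloads, and
* corrupt a phantom with Rician noise (magnitude of a complex-Gaussian-
  corrupted signal), the realistic noise model for magnitude MR images.

Ground-truth concentration curves are simulated on a finer time grid than
the acquisition grid (``oversample``), so that model fitting on the
acquisition grid faces a genuine, small discretisation mismatch -- as it
does with the real QIBA data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    AIF,
    AcquisitionParams,
    DynamicSeries,
    InvalidParameterError,
    RelaxationMaps,
)
from .relaxometry import DEFAULT_RELAXIVITY, invert_spgr, spgr_signal

# Printed QIBA parameter grids (min^-1 for Ktrans; fractions for ve, vp)
QIBA_V6_KTRANS = (0.01, 0.02, 0.05, 0.1, 0.2, 0.35)
QIBA_V6_VE = (0.01, 0.05, 0.1, 0.2, 0.5)
QIBA_V4_KTRANS = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2)
QIBA_V4_VE = (0.1, 0.2, 0.5)
QIBA_V4_VP = (0.001, 0.005, 0.01, 0.02, 0.05, 0.1)


def population_aif(t_min: np.ndarray, bolus_arrival_min: float = 0.5) -> np.ndarray:
    """Parametric population arterial input function, in mM.

    A gamma-variate first-pass bolus (peak ~5 mM about 15 s after arrival)
    plus a slowly decaying biexponential recirculation/washout tail, zero
    before bolus arrival.  This is a generic population curve for a
    standard single-dose Gd injection, not a fit to any particular cohort.
    """
    t_min = np.asarray(t_min, dtype=float)
    tau = t_min - bolus_arrival_min
    cp = np.zeros_like(tau)
    pos = tau > 0
    tp = tau[pos]
    tau_peak = 0.25  # min
    bolus = 5.0 * (tp / tau_peak) * np.exp(1.0 - tp / tau_peak)
    tail = (0.5 * np.exp(-0.13 * tp) + 0.4 * np.exp(-0.0111 * tp)) * (
        1.0 - np.exp(-tp / tau_peak))
    cp[pos] = bolus + tail
    return cp


@dataclass
class NoiseSpec:
    """Rician noise protocol: complex Gaussian of SD ``sigma_rel`` relative
    to the pre-contrast tissue baseline, followed by a magnitude operation.
    The vessel strip (AIF) is left noise-free unless ``noise_aif``."""

    sigma_rel: float = 0.2
    seed: int = 0
    noise_aif: bool = False

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise InvalidParameterError("sigma_rel must be non-negative")


@dataclass
class PhantomSpec:
    """Layout and acquisition of a synthetic QIBA-style phantom.

    The tissue block is a grid of ``patch_shape`` patches covering every
    combination of the parameter value lists: rows iterate Ktrans, columns
    iterate ve (and, for the extended layout, the (ve, vp) pairs ve-major).
    An empty ``vp_values`` selects the Standard-Tofts layout.  A vessel
    strip of ``strip_rows`` rows carrying the AIF signal is appended below
    the tissue block.
    """

    ktrans_values: Sequence[float] = QIBA_V6_KTRANS
    ve_values: Sequence[float] = QIBA_V6_VE
    vp_values: Sequence[float] = ()
    patch_shape: tuple[int, int] = (10, 10)
    n_time: int = 721
    dt: float = 0.5  # seconds between frames
    acq: AcquisitionParams = field(
        default_factory=lambda: AcquisitionParams(tr=0.005, flip_deg=30.0))
    relaxivity: float = DEFAULT_RELAXIVITY
    r10_tissue: float = 1.0  # s^-1
    r10_blood: float = 1.0 / 1.4  # s^-1
    s0: float = 1000.0
    strip_rows: int = 10
    bolus_arrival_s: float = 30.0
    oversample: int = 8

    def __post_init__(self) -> None:
        if not self.ktrans_values or not self.ve_values:
            raise InvalidParameterError("parameter value lists must be non-empty")
        for name in ("ktrans_values", "ve_values", "vp_values"):
            if any(v < 0 for v in getattr(self, name)):
                raise InvalidParameterError(f"{name} must be non-negative")
        if min(self.patch_shape) < 1:
            raise InvalidParameterError("patch_shape must be positive")

    @property
    def is_extended(self) -> bool:
        return len(self.vp_values) > 0

    @property
    def n_regions(self) -> int:
        n = len(self.ktrans_values) * len(self.ve_values)
        if self.is_extended:
            n *= len(self.vp_values)
        return n

    @property
    def t(self) -> np.ndarray:
        """Acquisition time vector, seconds."""
        return np.arange(self.n_time) * self.dt

    def aif(self) -> AIF:
        """Ground-truth AIF sampled on the acquisition grid."""
        cp = population_aif(self.t / 60.0, self.bolus_arrival_s / 60.0)
        return AIF(t=self.t, cp=cp)


def qiba_v6_layout(**overrides) -> PhantomSpec:
    """Standard-Tofts layout: 6 Ktrans x 5 ve = 30 regions."""
    return PhantomSpec(ktrans_values=QIBA_V6_KTRANS, ve_values=QIBA_V6_VE,
                       vp_values=(), **overrides)


def qiba_v4_layout(**overrides) -> PhantomSpec:
    """Extended-Tofts layout: 6 Ktrans x 3 ve x 6 vp = 108 regions."""
    return PhantomSpec(ktrans_values=QIBA_V4_KTRANS, ve_values=QIBA_V4_VE,
                       vp_values=QIBA_V4_VP, **overrides)


@dataclass
class SyntheticPhantom:
    """A generated phantom: dynamic series, ground truth, and geometry."""

    series: DynamicSeries
    truth: dict[str, np.ndarray]  # tissue-grid maps: ktrans, ve, vp
    region_ids: np.ndarray  # tissue-grid int map, one id per patch
    maps: RelaxationMaps  # full-image R10/S0 (tissue + strip)
    aif: AIF  # ground truth on the acquisition grid
    vessel_rows: slice  # rows of the vessel strip in the full image
    tissue_rows: slice
    spec: PhantomSpec


def _conv_exp_recursive(t_min: np.ndarray, cp: np.ndarray, kep: float) -> np.ndarray:
    """O(N) evaluation of the trapezoidal exponential convolution.

    First-order recurrence K_i = e^{-kep dt} K_{i-1}
    + dt/2 (cp_{i-1} e^{-kep dt} + cp_i), algebraically identical
    term-by-term to the direct trapezoid of Cp(s) e^{kep (s - t_i)}; used
    for the long fine-grid forward simulations where an N x N operator
    would be wasteful.
    """
    k = np.zeros_like(cp)
    dt = np.diff(t_min)
    e = np.exp(-kep * dt)
    for i in range(1, cp.size):
        k[i] = k[i - 1] * e[i - 1] + 0.5 * dt[i - 1] * (
            cp[i - 1] * e[i - 1] + cp[i])
    return k


def _region_table(spec: PhantomSpec) -> list[tuple[float, float, float]]:
    """(ktrans, ve, vp) per region, row-major in the tissue grid layout."""
    regions = []
    for kt in spec.ktrans_values:
        for ve in spec.ve_values:
            if spec.is_extended:
                for vp in spec.vp_values:
                    regions.append((kt, ve, vp))
            else:
                regions.append((kt, ve, 0.0))
    return regions


def generate_phantom(spec: PhantomSpec) -> SyntheticPhantom:
    """Forward-simulate a QIBA-layout phantom.

    Chain per region: Tofts-Kety concentration (trapezoid convolution on an
    ``oversample``-times finer grid, subsampled to the acquisition times)
    -> R1(t) = R10 + r1 * Ct -> SPGR signal.  The vessel strip encodes the
    AIF through the same R1/signal chain with the blood R10.  Every voxel
    within a patch is identical; ground-truth parameter maps are returned
    alongside.
    """
    t = spec.t
    os_f = max(int(spec.oversample), 1)
    n_fine = (spec.n_time - 1) * os_f + 1
    t_fine = np.arange(n_fine) * (spec.dt / os_f)
    cp_fine = population_aif(t_fine / 60.0, spec.bolus_arrival_s / 60.0)
    t_fine_min = t_fine / 60.0

    regions = _region_table(spec)
    pr, pc = spec.patch_shape
    n_rows = len(spec.ktrans_values) * pr
    n_cols_regions = len(spec.ve_values) * (len(spec.vp_values) or 1)
    n_cols = n_cols_regions * pc

    ct_region = np.empty((len(regions), spec.n_time))
    for i, (kt, ve, vp) in enumerate(regions):
        kep = kt / ve if ve > 0 else 0.0
        ct_fine = kt * _conv_exp_recursive(t_fine_min, cp_fine, kep) + vp * cp_fine
        ct_region[i] = ct_fine[::os_f]

    # region signal via the SPGR chain
    sig_region = spgr_signal(
        spec.s0, spec.r10_tissue + spec.relaxivity * ct_region, spec.acq)

    data = np.empty((spec.n_time, n_rows + spec.strip_rows, n_cols))
    truth = {k: np.empty((n_rows, n_cols)) for k in ("ktrans", "ve", "vp")}
    region_ids = np.empty((n_rows, n_cols), dtype=int)
    for i, (kt, ve, vp) in enumerate(regions):
        r = (i // n_cols_regions) * pr
        c = (i % n_cols_regions) * pc
        data[:, r:r + pr, c:c + pc] = sig_region[i][:, None, None]
        truth["ktrans"][r:r + pr, c:c + pc] = kt
        truth["ve"][r:r + pr, c:c + pc] = ve
        truth["vp"][r:r + pr, c:c + pc] = vp
        region_ids[r:r + pr, c:c + pc] = i

    aif = spec.aif()
    strip_sig = spgr_signal(
        spec.s0, spec.r10_blood + spec.relaxivity * aif.cp, spec.acq)
    data[:, n_rows:, :] = strip_sig[:, None, None]

    r10 = np.full((n_rows + spec.strip_rows, n_cols), spec.r10_tissue)
    r10[n_rows:, :] = spec.r10_blood
    s0 = np.full_like(r10, spec.s0)
    maps = RelaxationMaps(r10=r10, s0=s0, fitted_mask=np.ones_like(r10, dtype=bool))
    return SyntheticPhantom(
        series=DynamicSeries(t=t, data=data),
        truth=truth, region_ids=region_ids, maps=maps, aif=aif,
        vessel_rows=slice(n_rows, n_rows + spec.strip_rows),
        tissue_rows=slice(0, n_rows), spec=spec,
    )


def add_rician_noise(
    series: DynamicSeries,
    noise: NoiseSpec,
    vessel_rows: slice | None = None,
    n_pre: int = 3,
) -> DynamicSeries:
    """Corrupt a dynamic series with Rician noise.

    Independent real and imaginary Gaussian components of standard
    deviation ``sigma_rel`` times the pre-contrast tissue baseline (the
    global mean of the first ``n_pre`` frames, excluding the vessel strip)
    are added and the magnitude taken.  With ``noise_aif=False`` (default)
    the vessel strip rows are returned untouched.  Seeded and reproducible.
    """
    data = series.data
    if vessel_rows is not None:
        tissue = np.ones(data.shape[1], dtype=bool)
        tissue[vessel_rows] = False
    else:
        tissue = np.ones(data.shape[1], dtype=bool)
    baseline = data[:min(n_pre, data.shape[0])][:, tissue].mean()
    sigma = noise.sigma_rel * baseline
    if sigma == 0:
        return DynamicSeries(t=series.t.copy(), data=data.copy())
    rng = np.random.default_rng(noise.seed)
    nr = rng.normal(0.0, sigma, size=data.shape)
    ni = rng.normal(0.0, sigma, size=data.shape)
    noisy = np.hypot(data + nr, ni)
    if vessel_rows is not None and not noise.noise_aif:
        noisy[:, vessel_rows] = data[:, vessel_rows]
    return DynamicSeries(t=series.t.copy(), data=noisy)


def load_qiba_dicom(directory: str | os.PathLike, dt_fallback: float = 0.5):
    """Load a single-series DICOM phantom stack.

    Frames are ordered by DICOM instance number (the burned-in frame label
    in the phantom image is a visual check only); missing or duplicate
    instance numbers raise.  The time vector comes from per-frame trigger
    or acquisition times when present, else a uniform ``dt_fallback`` grid.
    Returns ``(DynamicSeries, AcquisitionParams)`` with TR converted to
    seconds.
    """
    import pydicom

    paths = sorted(
        os.path.join(directory, f) for f in os.listdir(directory)
        if not f.startswith(".") and os.path.isfile(os.path.join(directory, f)))
    frames = []
    for p in paths:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue  # non-DICOM clutter in the directory
        if not hasattr(ds, "InstanceNumber"):
            continue
        frames.append(ds)
    if not frames:
        raise FileNotFoundError(f"no DICOM frames found in {directory}")
    numbers = [int(ds.InstanceNumber) for ds in frames]
    seen = set()
    dupes = sorted({n for n in numbers if n in seen or seen.add(n)})
    if dupes:
        raise ValueError(f"duplicate instance numbers: {dupes}")
    expected = set(range(min(numbers), min(numbers) + len(numbers)))
    gaps = sorted(expected - set(numbers))
    if gaps:
        raise ValueError(f"missing instance numbers: {gaps}")
    frames.sort(key=lambda ds: int(ds.InstanceNumber))

    data = np.stack([ds.pixel_array.astype(float) for ds in frames])
    times = []
    for i, ds in enumerate(frames):
        trig = getattr(ds, "TriggerTime", None)
        if trig is not None:
            times.append(float(trig) / 1000.0)  # ms -> s
        else:
            times.append(i * dt_fallback)
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0) and len(t) > 1:
        t = np.arange(len(frames)) * dt_fallback
    tr_ms = float(getattr(frames[0], "RepetitionTime", 5.0))
    flip = float(getattr(frames[0], "FlipAngle", 30.0))
    acq = AcquisitionParams(tr=tr_ms / 1000.0, flip_deg=flip)
    return DynamicSeries(t=t, data=data), acq


def extract_aif(
    series: DynamicSeries,
    maps: RelaxationMaps,
    acq: AcquisitionParams,
    vessel_rows: slice,
    relaxivity: float = DEFAULT_RELAXIVITY,
) -> AIF:
    """Extract the AIF from the vessel strip of a phantom.

    The strip signal is averaged spatially per frame, inverted to R1(t)
    through the SPGR signal equation with the strip's (blood) R10/S0, and
    converted to concentration: Cp = (R1(t) - R10)/r1.  Small negative
    concentrations from numerical round-off are clipped to zero.
    """
    n_rows = series.data.shape[1]
    start, stop, _ = vessel_rows.indices(n_rows)
    if stop <= start:
        raise ValueError("vessel strip rows are empty or outside the image")
    strip = series.data[:, vessel_rows]
    curve = strip.reshape(series.n_time, -1).mean(axis=1)
    r10 = float(maps.r10[vessel_rows].mean())
    s0 = float(maps.s0[vessel_rows].mean())
    one_vox = DynamicSeries(t=series.t, data=curve[:, None])
    one_map = RelaxationMaps(r10=np.array([r10]), s0=np.array([s0]),
                             fitted_mask=np.array([True]))
    rel = invert_spgr(one_vox, one_map, acq)
    cp = (rel.r1_t[:, 0] - r10) / relaxivity
    return AIF(t=series.t, cp=np.maximum(cp, 0.0))
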