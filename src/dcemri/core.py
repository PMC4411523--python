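"""Shared container types for the DCE-MRI pipeline.

Unit conventions: every public boundary takes time in SI seconds and flip
angles in degrees.  Rate constants of the tracer-kinetic models (Ktrans,
kep) are expressed in min^-1, the convention of the DCE-MRI literature;
conversion from seconds to minutes happens exactly once, at the
pharmacokinetics module boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InvalidParameterError(ValueError):
    """Raised when a physical parameter is outside its valid domain."""


@dataclass
class AcquisitionParams:
    """Spoiled-gradient-echo acquisition parameters.

    Parameters
    ----------
    tr : float
        Repetition time in seconds.  Must be positive.
    flip_deg : float or array_like
        Flip angle(s) in degrees; a scalar for a dynamic series, a vector
        for a variable-flip-angle (multiflip) T1 series.  Each entry must
        lie strictly between 0 and 180.
    te : float, optional
        Echo time in seconds.  Informational only: the signal model
        neglects R2* decay on the assumption TE << 1/R2*.
    """

    tr: float
    flip_deg: float | np.ndarray
    te: float = 0.0

    def __post_init__(self) -> None:
        if not np.isscalar(self.tr) or self.tr <= 0:
            raise InvalidParameterError(f"tr must be a positive scalar, got {self.tr!r}")
        flips = np.atleast_1d(np.asarray(self.flip_deg, dtype=float))
        if np.any(flips <= 0) or np.any(flips >= 180):
            raise InvalidParameterError(
                f"flip angles must lie in (0, 180) degrees, got {flips}"
            )

    @property
    def flip_rad(self) -> np.ndarray | float:
        """Flip angle(s) converted to radians, preserving scalar-ness."""
        if np.isscalar(self.flip_deg):
            return float(np.deg2rad(self.flip_deg))
        return np.deg2rad(np.asarray(self.flip_deg, dtype=float))


@dataclass
class DynamicSeries:
    """A dynamic (or multiflip) image series with time in the first axis.

    ``data`` has shape ``(n_time, *spatial_shape)`` where the spatial grid
    may be 1-, 2- or 3-dimensional.  ``t`` is the acquisition time vector
    in seconds (for a multiflip series it indexes flip angles instead and
    is conventionally ``arange(n_flip)``).
    """

    t: np.ndarray
    data: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float).ravel()
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim < 2:
            self.data = self.data.reshape(self.data.shape[0], 1)
        if self.data.shape[0] != self.t.size:
            raise ValueError(
                f"first data dimension ({self.data.shape[0]}) must match the "
                f"time vector length ({self.t.size})"
            )
        if np.any(np.diff(self.t) < 0):
            raise ValueError("time vector must be non-decreasing")

    @property
    def n_time(self) -> int:
        return self.t.size

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]


@dataclass
class RelaxationMaps:
    """Voxelwise pre-contrast relaxation rate R1(x,0) and signal scale S(x,0).

    Unfitted voxels (below the intensity cutoff) carry a 0 sentinel and are
    excluded from ``fitted_mask``.
    """

    r10: np.ndarray
    s0: np.ndarray
    fitted_mask: np.ndarray

    def __post_init__(self) -> None:
        self.r10 = np.asarray(self.r10, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        self.fitted_mask = np.asarray(self.fitted_mask, dtype=bool)
        if not (self.r10.shape == self.s0.shape == self.fitted_mask.shape):
            raise ValueError("r10, s0 and fitted_mask must share one spatial shape")


@dataclass
class RelaxationSeries:
    """Dynamic relaxation-rate series R1(x,t) plus the normalized signal used.

    ``n_degenerate`` counts samples where the signal-equation inversion had
    a non-positive log argument; those samples are NaN sentinels.
    """

    r1_t: np.ndarray
    s_norm: np.ndarray
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        if self.r1_t.shape != self.s_norm.shape:
            raise ValueError("r1_t and s_norm must have identical shapes")


@dataclass
class ConcentrationSeries:
    """Tissue contrast-agent concentration Ct(x,t) in mM, time-first."""

    ct: np.ndarray
    t_min: np.ndarray
    relaxivity: float

    def __post_init__(self) -> None:
        if self.relaxivity <= 0:
            raise InvalidParameterError("relaxivity must be positive")
        self.t_min = np.asarray(self.t_min, dtype=float).ravel()
        if self.ct.shape[0] != self.t_min.size:
            raise ValueError("ct first dimension must match t_min length")


@dataclass
class AIF:
    """Arterial input function: plasma concentration Cp(t) in mM."""

    t: np.ndarray  # seconds
    cp: np.ndarray  # mM

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float).ravel()
        self.cp = np.asarray(self.cp, dtype=float).ravel()
        if self.t.size != self.cp.size:
            raise ValueError("t and cp must have equal length")
        if np.any(self.cp < -1e-12):
            raise ValueError("cp must be non-negative")

    @property
    def t_min(self) -> np.ndarray:
        return self.t / 60.0


@dataclass
class PKMaps:
    """Per-voxel pharmacokinetic parameter maps.

    Ktrans and kep are in min^-1; ve and vp are dimensionless fractions.
    ``resid`` holds the pre-clamp sum of squared residuals of the winning
    model and ``modelmap`` its bitmask value.
    """

    ktrans: np.ndarray
    kep: np.ndarray
    ve: np.ndarray
    vp: np.ndarray
    resid: np.ndarray
    modelmap: np.ndarray

    def copy(self) -> "PKMaps":
        return PKMaps(
            self.ktrans.copy(), self.kep.copy(), self.ve.copy(),
            self.vp.copy(), self.resid.copy(), self.modelmap.copy(),
        )
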