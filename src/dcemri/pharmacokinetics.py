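"""Tofts-Kety tracer-kinetic models.

The Extended Tofts-Kety model for the tissue concentration of a contrast
agent with arterial input Cp(t) is

    Ct(t) = Ktrans * \\int_0^t Cp(s) exp[kep (s - t)] ds + vp * Cp(t)

with the efflux rate constant kep = Ktrans / ve.  The Standard model drops
the vp term; the plasma-only (no-exchange) model drops the Ktrans term.

Fitting is parameterized in (Ktrans, kep, vp) rather than (Ktrans, ve, vp):
formulating the integral with kep decouples the exponential from the
Ktrans prefactor and produces better-conditioned fits; ve is derived
afterwards as Ktrans/kep.  The (Ktrans, ve, vp) Jacobian is retained for
conditioning analysis and as an optional parameterization.

Numerical integration uses the trapezoidal rule on the (possibly
non-uniform) acquisition grid, evaluated directly at each output time; all
exponents are non-positive so the evaluation is stable for any kep >= 0.
Time is in minutes throughout this module, so Ktrans and kep are natively
min^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InvalidParameterError

MODEL_PLASMA_ONLY = 1
MODEL_STANDARD = 2
MODEL_EXTENDED = 4


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one tracer-kinetic model and its fit parameters."""

    id: str
    bit: int
    param_names: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


PLASMA_ONLY = ModelSpec("plasma_only", MODEL_PLASMA_ONLY, ("vp",))
STANDARD_TOFTS = ModelSpec("standard_tofts", MODEL_STANDARD, ("ktrans", "kep"))
EXTENDED_TOFTS = ModelSpec("extended_tofts", MODEL_EXTENDED, ("ktrans", "kep", "vp"))

MODELS_BY_BIT = {m.bit: m for m in (PLASMA_ONLY, STANDARD_TOFTS, EXTENDED_TOFTS)}
MODELS_BY_ID = {m.id: m for m in (PLASMA_ONLY, STANDARD_TOFTS, EXTENDED_TOFTS)}


def models_from_bitmask(bitmask: int) -> list[ModelSpec]:
    """Decode a model-selection bitmask (1|2|4, OR-combinable)."""
    models = [m for bit, m in sorted(MODELS_BY_BIT.items()) if bitmask & bit]
    if not models:
        raise InvalidParameterError(f"bitmask {bitmask} selects no known model")
    return models


@dataclass
class PKParams:
    """One voxel's kinetic parameters.

    Either ``kep`` or ``ve`` may be omitted; the missing one is derived
    from Ktrans (kep = Ktrans/ve, guarding the degenerate zeros).
    """

    ktrans: float = 0.0
    kep: float | None = None
    ve: float | None = None
    vp: float = 0.0

    def __post_init__(self) -> None:
        if self.kep is None and self.ve is None:
            self.kep = 0.0
            self.ve = 0.0
        elif self.kep is None:
            self.kep = self.ktrans / self.ve if self.ve > 0 else 0.0
        elif self.ve is None:
            self.ve = derive_ve(self.ktrans, self.kep)


@dataclass
class ModelEval:
    """A model prediction and its Jacobian (one column per fit parameter)."""

    ct_pred: np.ndarray
    jac: np.ndarray


class TrapzConvolver:
    """Trapezoidal evaluation of exponential convolutions on a fixed grid.

    For a time grid t (minutes) this precomputes the lower-triangular
    matrices needed to evaluate, for any kep,

        K(t_i) = \\int_0^{t_i} Cp(s) exp[kep (s - t_i)] ds
        G(t_i) = \\int_0^{t_i} Cp(s) (s - t_i) exp[kep (s - t_i)] ds

    by the trapezoidal rule (K is the Ktrans kernel, G its kep
    derivative).  Reused across Levenberg-Marquardt iterations so the per-
    evaluation cost is one N x N exponential.
    """

    def __init__(self, t_min: np.ndarray):
        t = np.asarray(t_min, dtype=float).ravel()
        if t.size < 2:
            raise ValueError("need at least two time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time vector must be strictly increasing")
        if t[0] < 0:
            raise ValueError("time vector must start at t >= 0")
        self.t = t
        n = t.size
        # lag[i, j] = t_j - t_i (<= 0), upper triangle zeroed: those entries
        # carry zero trapezoid weight and must not overflow the exponential
        self.lag = np.minimum(t[None, :] - t[:, None], 0.0)
        # trapezoid weights for integrating node values over [t_0, t_i]
        w = np.zeros((n, n))
        dt = np.diff(t)
        for i in range(1, n):
            w[i, 0] = 0.5 * dt[0]
            w[i, 1:i] = 0.5 * (t[2:i + 1] - t[0:i - 1])
            w[i, i] = 0.5 * dt[i - 1]
        self.weights = w
        self._cache_kep: float | None = None
        self._cache_we: np.ndarray | None = None

    def _weighted_exp(self, kep: float) -> np.ndarray:
        if self._cache_kep == kep and self._cache_we is not None:
            return self._cache_we
        with np.errstate(over="ignore", under="ignore"):
            we = self.weights * np.exp(kep * self.lag)
        self._cache_kep = kep
        self._cache_we = we
        return we

    def conv(self, cp: np.ndarray, kep: float) -> np.ndarray:
        return self._weighted_exp(kep) @ cp

    def conv_dkep(self, cp: np.ndarray, kep: float) -> np.ndarray:
        return (self._weighted_exp(kep) * self.lag) @ cp


def conv_exp_trapz(t_min: np.ndarray, cp: np.ndarray, kep: float) -> np.ndarray:
    """K(t_i) = \\int_0^{t_i} Cp(s) exp[kep (s - t_i)] ds by the trapezoidal rule.

    ``t_min`` in minutes (strictly increasing, starting >= 0), ``cp`` in mM,
    ``kep`` >= 0 in min^-1.  K(t_0) = 0 by construction.
    """
    if kep < 0:
        raise InvalidParameterError("kep must be non-negative")
    cp = np.asarray(cp, dtype=float).ravel()
    conv = TrapzConvolver(t_min)
    if cp.size != conv.t.size:
        raise ValueError("cp and t_min must have equal length")
    return conv.conv(cp, kep)


def derive_ve(ktrans: float, kep: float) -> float:
    """ve = Ktrans/kep, with the kep = 0 (no measurable efflux) case -> 0."""
    if ktrans < 0 or kep < 0:
        raise InvalidParameterError("ktrans and kep must be non-negative")
    return ktrans / kep if kep > 0 else 0.0


def model_ct(
    params: PKParams,
    spec: ModelSpec,
    t_min: np.ndarray,
    cp: np.ndarray,
    conv: TrapzConvolver | None = None,
) -> np.ndarray:
    """Predicted tissue concentration Ct(t) in mM for one model."""
    cp = np.asarray(cp, dtype=float).ravel()
    if spec.id == "plasma_only":
        return params.vp * cp
    if conv is None:
        conv = TrapzConvolver(t_min)
    k = conv.conv(cp, params.kep)
    ct = params.ktrans * k
    if spec.id == "extended_tofts":
        ct = ct + params.vp * cp
    return ct


def model_jacobian(
    params: PKParams,
    spec: ModelSpec,
    t_min: np.ndarray,
    cp: np.ndarray,
    parameterization: str = "ktrans_kep_vp",
    conv: TrapzConvolver | None = None,
) -> ModelEval:
    """Analytic Jacobian of Ct with respect to the fit parameters.

    In ``ktrans_kep_vp`` the columns are (per model)

        dCt/dKtrans = K(t),  dCt/dkep = Ktrans * G(t),  dCt/dvp = Cp(t)

    while ``ktrans_ve_vp`` substitutes kep = Ktrans/ve:

        dCt/dKtrans = K(t) + (Ktrans/ve) * G(t)
        dCt/dve     = -(Ktrans^2/ve^2) * G(t)

    with K and G the convolution kernel and its kep-derivative (both by
    trapezoid on the shared grid).  dCt/dvp = Cp(t) exactly in either case.
    """
    if parameterization not in ("ktrans_kep_vp", "ktrans_ve_vp"):
        raise ValueError(f"unknown parameterization {parameterization!r}")
    cp = np.asarray(cp, dtype=float).ravel()
    if spec.id == "plasma_only":
        return ModelEval(ct_pred=params.vp * cp, jac=cp[:, None].copy())
    if conv is None:
        conv = TrapzConvolver(t_min)
    if parameterization == "ktrans_ve_vp":
        if not params.ve or params.ve <= 0:
            raise InvalidParameterError(
                "ktrans_ve_vp parameterization requires ve > 0")
        kep = params.ktrans / params.ve
    else:
        kep = params.kep
    k = conv.conv(cp, kep)
    g = conv.conv_dkep(cp, kep)
    ct = params.ktrans * k
    if parameterization == "ktrans_kep_vp":
        cols = [k, params.ktrans * g]
    else:
        cols = [
            k + (params.ktrans / params.ve) * g,
            -(params.ktrans**2 / params.ve**2) * g,
        ]
    if spec.id == "extended_tofts":
        ct = ct + params.vp * cp
        cols.append(cp.copy())
    return ModelEval(ct_pred=ct, jac=np.column_stack(cols))


def _model_and_jac_factory(spec: ModelSpec, conv: TrapzConvolver, cp, data):
    """Residual/Jacobian closures over the raw (kep-parameterized) vector.

    Used by the voxelwise fitting driver.  Trial steps with kep < 0 are
    evaluated as-is; if the exponential overflows the resulting non-finite
    cost makes the solver reject the step.
    """
    cp = np.asarray(cp, dtype=float).ravel()
    data = np.asarray(data, dtype=float).ravel()

    if spec.id == "plasma_only":
        def residual(p):
            return p[0] * cp - data

        def jacobian(p):
            return cp[:, None].copy()

        return residual, jacobian

    extended = spec.id == "extended_tofts"

    def residual(p):
        model = p[0] * conv.conv(cp, p[1])
        if extended:
            model = model + p[2] * cp
        return model - data

    def jacobian(p):
        k = conv.conv(cp, p[1])
        g = conv.conv_dkep(cp, p[1])
        cols = [k, p[0] * g]
        if extended:
            cols.append(cp.copy())
        return np.column_stack(cols)

    return residual, jacobian
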