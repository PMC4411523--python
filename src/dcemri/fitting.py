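"""In-package Levenberg-Marquardt solver and deterministic voxelwise driver.

All nonlinear least-squares fitting in this package goes through
:func:`levmar`: a classic damped-Gauss-Newton iteration with a
multiplicative lambda update (x10 on a rejected step, /10 on an accepted
one) and Marquardt diagonal scaling.  The solver is unconstrained; physical
bounds are enforced downstream by post-hoc clamping.

The voxelwise driver splits voxels into contiguous index blocks, so results
are bit-for-bit identical for any worker count.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Callable

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class FitOptions:
    """Levenberg-Marquardt hyperparameters.

    tol_g: infinity-norm gradient tolerance; tol_x: relative step-size
    tolerance; tol_f: relative cost-reduction tolerance.  Any one of them
    terminates the iteration.
    """

    init: np.ndarray
    max_iter: int = 200
    lambda0: float = 1e-3
    tol_g: float = 1e-8
    tol_x: float = 1e-8
    tol_f: float = 1e-8

    def __post_init__(self) -> None:
        self.init = np.asarray(self.init, dtype=float).ravel()
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if min(self.tol_g, self.tol_x, self.tol_f) <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class FitResult:
    """Outcome of one least-squares fit.

    ``chisq_red`` is the reduced chi-square SSR/(N-p) under unit noise
    variance, used for model selection at a fixed voxel.
    """

    params: np.ndarray
    ssr: float
    chisq_red: float
    n_iter: int
    converged: bool
    skipped: bool = False


def levmar(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    jacobian_fn: Callable[[np.ndarray], np.ndarray],
    opts: FitOptions,
) -> FitResult:
    """Minimise ||r(x)||^2 by Levenberg-Marquardt.

    ``residual_fn`` maps a parameter vector to the residual vector r and
    ``jacobian_fn`` to its N x p Jacobian.  Deterministic: identical inputs
    give identical outputs.  If ``max_iter`` is exhausted the best
    parameters so far are returned with ``converged=False``.
    """
    x = opts.init.copy()
    p = x.size
    r = np.asarray(residual_fn(x), dtype=float)
    n = r.size
    if n < p:
        raise ValueError(f"need at least as many residuals ({n}) as parameters ({p})")
    ssr = float(r @ r)
    lam = opts.lambda0
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        jac = np.asarray(jacobian_fn(x), dtype=float)
        g = jac.T @ r
        if np.max(np.abs(g)) < opts.tol_g:
            converged = True
            break
        jtj = jac.T @ jac
        diag = np.diag(jtj).copy()
        diag[diag <= 0] = np.max(diag) if np.max(diag) > 0 else 1.0
        accepted = False
        while True:
            a = jtj + lam * np.diag(diag)
            try:
                step = np.linalg.solve(a, -g)
            except np.linalg.LinAlgError:
                step = None
            if step is not None and np.all(np.isfinite(step)):
                x_new = x + step
                r_new = np.asarray(residual_fn(x_new), dtype=float)
                ssr_new = float(r_new @ r_new)
                if np.isfinite(ssr_new) and ssr_new <= ssr:
                    accepted = True
                    break
            lam *= 10.0
            if lam > 1e12:
                break
        if not accepted:
            converged = np.max(np.abs(g)) < opts.tol_g
            break
        lam = max(lam / 10.0, 1e-15)
        dx = np.linalg.norm(step)
        df = ssr - ssr_new
        x, r, ssr = x_new, r_new, ssr_new
        if dx < opts.tol_x * (1.0 + np.linalg.norm(x)):
            converged = True
            break
        if df < opts.tol_f * max(ssr, 1e-300):
            converged = True
            break
        if ssr == 0.0:
            converged = True
            break
    chisq_red = ssr / (n - p) if n > p else np.nan
    return FitResult(params=x, ssr=ssr, chisq_red=chisq_red,
                     n_iter=it, converged=converged)


def _default_init(n_params: int) -> np.ndarray:
    """Mid-range starting point for DCE fits: Ktrans=0.1, kep=0.5, vp=0.01."""
    full = np.array([0.1, 0.5, 0.01])
    if n_params == 1:  # plasma-only fits vp alone
        return np.array([0.01])
    return full[:n_params]


def _fit_chunk(curves, spec, t_min, cp, opts_template):
    # local import avoids a cycle (pharmacokinetics pulls nothing from here)
    from .pharmacokinetics import TrapzConvolver, _model_and_jac_factory

    conv = TrapzConvolver(t_min)
    results = []
    for curve in curves:
        if np.any(~np.isfinite(curve)):
            results.append(FitResult(
                params=np.full(spec.n_params, np.nan), ssr=np.nan,
                chisq_red=np.nan, n_iter=0, converged=False, skipped=True))
            continue
        residual_fn, jacobian_fn = _model_and_jac_factory(spec, conv, cp, curve)
        init = opts_template.init if opts_template is not None else _default_init(spec.n_params)
        opts = FitOptions(
            init=init,
            max_iter=opts_template.max_iter if opts_template else 200,
            lambda0=opts_template.lambda0 if opts_template else 1e-3,
            tol_g=opts_template.tol_g if opts_template else 1e-8,
            tol_x=opts_template.tol_x if opts_template else 1e-8,
            tol_f=opts_template.tol_f if opts_template else 1e-8,
        )
        results.append(levmar(residual_fn, jacobian_fn, opts))
    return results


def fit_voxels_parallel(
    curves: np.ndarray,
    spec,
    t_min: np.ndarray,
    cp: np.ndarray,
    opts: FitOptions | None = None,
    n_workers: int = 1,
) -> list[FitResult]:
    """Fit a tracer-kinetic model to each row of ``curves`` (n_voxels, n_time).

    Voxels are split into contiguous blocks and reassembled by index, so the
    output is bit-for-bit independent of ``n_workers``.  Curves containing
    NaN are skipped (``skipped=True``) without affecting their neighbours.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim == 1:
        curves = curves[None, :]
    n_vox = curves.shape[0]
    if n_vox == 0:
        return []
    if curves.shape[1] != np.asarray(t_min).size:
        raise ValueError("curves and t_min disagree on the number of time points")
    t0 = time.perf_counter()
    if n_workers <= 1 or n_vox == 1:
        results = _fit_chunk(curves, spec, t_min, cp, opts)
    else:
        from joblib import Parallel, delayed

        chunks = np.array_split(np.arange(n_vox), min(n_workers, n_vox))
        parts = Parallel(n_jobs=n_workers)(
            delayed(_fit_chunk)(curves[ix], spec, t_min, cp, opts)
            for ix in chunks if ix.size
        )
        results = [res for part in parts for res in part]
    elapsed = time.perf_counter() - t0
    if elapsed > 0:
        log.info("fit_voxels_parallel: %d voxels in %.2f s (%.1f voxels/s)",
                 n_vox, elapsed, n_vox / elapsed)
    return results
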