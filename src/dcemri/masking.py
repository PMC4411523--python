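"""Signal-enhancement-ratio masking, parameter clamping, model selection.

SER is the mean signal over the last few dynamics divided by the mean over
the first few (pre-contrast) dynamics; strongly enhancing voxels have
SER well above 1 and are worth fitting.  Clamping enforces physical ranges
after the unconstrained fit: volume fractions in [0, 1], Ktrans in
[0, 5] min^-1.  Pre-clamp residuals are kept untouched so the user can do
their own residual-based filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DynamicSeries, PKMaps
from .fitting import FitResult
from .pharmacokinetics import MODELS_BY_BIT

KTRANS_CLAMP = (0.0, 5.0)
FRACTION_CLAMP = (0.0, 1.0)
DEFAULT_SER_CUTOFF = 2.0


@dataclass
class SERMap:
    """Per-voxel signal enhancement ratio.

    ``zero_baseline`` flags voxels whose pre-contrast mean was zero; their
    SER is defined as 0.
    """

    ser: np.ndarray
    n_pre: int
    n_post: int
    zero_baseline: np.ndarray | None = None


@dataclass
class ProcessingMask:
    """Boolean map of voxels selected for model fitting."""

    mask: np.ndarray
    source: str  # "user_supplied" | "ser_auto"


def compute_ser(series: DynamicSeries, n_pre: int = 3, n_post: int = 3) -> SERMap:
    """Mean of the last ``n_post`` dynamics over the mean of the first ``n_pre``.

    Requires at least ``n_pre + n_post`` time points (i.e. at least three
    pre-contrast acquisitions under the defaults).
    """
    if series.n_time < n_pre + n_post:
        raise ValueError(
            f"need >= {n_pre + n_post} dynamics for SER, got {series.n_time}")
    lead = series.data[:n_pre].mean(axis=0)
    trail = series.data[-n_post:].mean(axis=0)
    zero = lead == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ser = np.where(zero, 0.0, trail / np.where(zero, 1.0, lead))
    return SERMap(ser=ser, n_pre=n_pre, n_post=n_post, zero_baseline=zero)


def auto_mask(sermap: SERMap, cutoff: float = DEFAULT_SER_CUTOFF) -> ProcessingMask:
    """Voxels with SER strictly above ``cutoff`` (default 2.0) are selected."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    return ProcessingMask(mask=sermap.ser > cutoff, source="ser_auto")


def clamp_params(maps: PKMaps) -> PKMaps:
    """Clamp unphysical fitted values: ve, vp to [0,1]; Ktrans to [0,5] min^-1.

    Returns a clamped copy; residuals (and kep, which is re-derived
    implicitly through Ktrans/ve elsewhere) are left untouched.
    Idempotent and order-independent across parameters.
    """
    out = maps.copy()
    out.ktrans = np.clip(out.ktrans, *KTRANS_CLAMP)
    out.ve = np.clip(out.ve, *FRACTION_CLAMP)
    out.vp = np.clip(out.vp, *FRACTION_CLAMP)
    return out


def reduced_chisq(ssr: float, n_points: int, n_params: int) -> float:
    """SSR / (N - p), the reduced chi-square under unit noise variance."""
    if n_points <= n_params:
        raise ValueError("need more data points than parameters")
    return ssr / (n_points - n_params)


def select_best_model(
    fits: dict[int, list[FitResult]],
) -> tuple[np.ndarray, list[FitResult]]:
    """Pick the per-voxel winner among models by minimum reduced chi-square.

    ``fits`` maps model bit -> per-voxel FitResult list (all the same
    length).  Ties break toward the model with fewer parameters.  Returns
    (modelmap of winning bits, winning FitResult per voxel); skipped voxels
    get bit 0.
    """
    if not fits:
        raise ValueError("no fitted models supplied")
    bits = sorted(fits)
    n_vox = len(fits[bits[0]])
    if any(len(fits[b]) != n_vox for b in bits):
        raise ValueError("per-model result lists must have equal length")
    modelmap = np.zeros(n_vox, dtype=int)
    winners: list[FitResult] = []
    for v in range(n_vox):
        candidates = [(b, fits[b][v]) for b in bits if not fits[b][v].skipped]
        if not candidates:
            modelmap[v] = 0
            winners.append(fits[bits[0]][v])
            continue
        # sort by (chisq_red, n_params, bit): ties fall to fewer parameters
        def key(item):
            b, res = item
            chi = res.chisq_red if np.isfinite(res.chisq_red) else np.inf
            return (chi, MODELS_BY_BIT[b].n_params, b)

        b_win, res_win = min(candidates, key=key)
        modelmap[v] = b_win
        winners.append(res_win)
    return modelmap, winners
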