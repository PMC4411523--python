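"""MAT v5 input/output contract.

Input and output travel as Matlab MAT v5 files (scipy.io), so the tool can
be driven from MATLAB, Octave, Python or R.  The input file must contain

* ``t``       -- imaging time points, seconds,
* ``Cp``      -- arterial input function, mM,
* ``DCEdata`` -- dynamic data, time in the first dimension,

plus either precomputed maps ``R10`` (s^-1) and ``S0``, or multiflip
T1-weighted data ``T1data`` with flip angles ``T1flip`` (degrees).  All
other variables (``mask``, ``models``, ``relaxivity``, ``TR``, ``DCEflip``,
``SERcutoff``, ``outfile``) are optional and defaulted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import loadmat, savemat

from .core import AcquisitionParams, AIF, DynamicSeries, RelaxationMaps
from .masking import DEFAULT_SER_CUTOFF
from .pharmacokinetics import MODEL_STANDARD
from .relaxometry import DEFAULT_RELAXIVITY

DEFAULT_TR = 5e-3  # s
DEFAULT_DCE_FLIP = 30.0  # degrees

REQUIRED_VARS = ("t", "Cp", "DCEdata")


@dataclass
class InputBundle:
    """Everything the pipeline needs, decoded from one input MAT file."""

    series: DynamicSeries
    aif: AIF
    maps: RelaxationMaps | None
    multiflip: tuple[DynamicSeries, np.ndarray] | None
    mask: np.ndarray | None
    models: int
    relaxivity: float
    acq: AcquisitionParams
    ser_cutoff: float
    outfile: str | None

    def __post_init__(self) -> None:
        if (self.maps is None) == (self.multiflip is None):
            raise ValueError(
                "exactly one of (R10, S0) maps or (T1data, T1flip) multiflip "
                "data must be supplied")


def _scalar(md, name, default):
    if name not in md:
        return default
    return float(np.asarray(md[name]).ravel()[0])


def read_input_mat(path) -> InputBundle:
    """Read and validate an input MAT v5 file into an :class:`InputBundle`."""
    md = loadmat(path)
    missing = [v for v in REQUIRED_VARS if v not in md]
    if missing:
        raise KeyError(f"input MAT file is missing required variable(s): "
                       f"{', '.join(missing)}")
    t = np.asarray(md["t"], dtype=float).ravel()
    cp = np.asarray(md["Cp"], dtype=float).ravel()
    data = np.asarray(md["DCEdata"], dtype=float)
    if data.shape[0] != t.size:
        raise ValueError(
            f"DCEdata first dimension ({data.shape[0]}) does not match the "
            f"length of t ({t.size})")
    if cp.size != t.size:
        raise ValueError("Cp length does not match t")
    series = DynamicSeries(t=t, data=data)
    aif = AIF(t=t, cp=np.maximum(cp, 0.0))

    maps = None
    multiflip = None
    if "R10" in md and "S0" in md:
        r10 = np.asarray(md["R10"], dtype=float)
        s0 = np.asarray(md["S0"], dtype=float)
        r10 = r10.reshape(series.spatial_shape)
        s0 = s0.reshape(series.spatial_shape)
        maps = RelaxationMaps(r10=r10, s0=s0,
                              fitted_mask=np.ones_like(r10, dtype=bool))
    elif "T1data" in md and "T1flip" in md:
        flips = np.asarray(md["T1flip"], dtype=float).ravel()
        t1data = np.asarray(md["T1data"], dtype=float)
        multiflip = (DynamicSeries(t=np.arange(flips.size, dtype=float),
                                   data=t1data), flips)
    else:
        raise KeyError(
            "input MAT file must supply either R10 and S0 maps or T1data "
            "and T1flip multiflip data")

    mask = None
    if "mask" in md:
        mask = np.asarray(md["mask"]).astype(bool).reshape(series.spatial_shape)
    tr = _scalar(md, "TR", DEFAULT_TR)
    flip = _scalar(md, "DCEflip", DEFAULT_DCE_FLIP)
    outfile = None
    if "outfile" in md:
        out = np.asarray(md["outfile"]).ravel()
        outfile = str(out[0]) if out.size else None
    return InputBundle(
        series=series, aif=aif, maps=maps, multiflip=multiflip, mask=mask,
        models=int(_scalar(md, "models", MODEL_STANDARD)),
        relaxivity=_scalar(md, "relaxivity", DEFAULT_RELAXIVITY),
        acq=AcquisitionParams(tr=tr, flip_deg=flip),
        ser_cutoff=_scalar(md, "SERcutoff", DEFAULT_SER_CUTOFF),
        outfile=outfile,
    )


def default_outfile(input_path) -> str:
    p = Path(input_path)
    return str(p.with_name(p.stem + "_results.mat"))


def write_output_mat(results: dict, path) -> None:
    """Write named result maps (Ktrans, kep, ve, vp, resid, modelmap, R10,
    S0, SER, mask, ...) to a MAT v5 file."""
    if not results:
        raise ValueError("nothing to write")
    savemat(path, {k: np.asarray(v) for k, v in results.items()})


def write_phantom_mat(phantom, path) -> None:
    """Serialise a synthetic phantom in the pipeline's input schema, so the
    generated object can be fed straight back through ``dcefit``."""
    spec = phantom.spec
    savemat(path, {
        "t": phantom.series.t,
        "Cp": phantom.aif.cp,
        "DCEdata": phantom.series.data,
        "R10": phantom.maps.r10,
        "S0": phantom.maps.s0,
        "TR": spec.acq.tr,
        "DCEflip": float(spec.acq.flip_deg),
        "relaxivity": spec.relaxivity,
        "ktrans_truth": phantom.truth["ktrans"],
        "ve_truth": phantom.truth["ve"],
        "vp_truth": phantom.truth["vp"],
    })
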