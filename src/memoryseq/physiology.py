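"""Drought-physiology indices.

Relative water content (RWC) summarizes drought severity from the weights of
control (FW), drought-treated (DW) and re-watered (RW) plants; Fv/Fm is the
maximum quantum yield of photosystem II from dark-adapted minimum (F0) and
maximum (Fm) chlorophyll fluorescence.  Out-of-range results (measurement
error) are reported with a warning, never clipped.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def relative_water_content(fw, dw, rw):
    """RWC = (FW - DW) / (RW - DW) * 100, in percent.

    Requires RW > DW; values outside [0, 100] trigger a validity warning.
    Accepts scalars or arrays.
    """
    fw = np.asarray(fw, dtype=float)
    dw = np.asarray(dw, dtype=float)
    rw = np.asarray(rw, dtype=float)
    if np.any(rw <= dw):
        raise ValueError("RWC undefined: requires RW > DW")
    rwc = (fw - dw) / (rw - dw) * 100.0
    if np.any(rwc < 0) or np.any(rwc > 100):
        warnings.warn("RWC outside [0, 100]%: check FW/DW/RW measurements")
    return rwc if rwc.ndim else float(rwc)


def fv_over_fm(f0, fm):
    """Fv/Fm = (Fm - F0) / Fm.

    Requires Fm > 0; values outside [0, 1] trigger a validity warning.
    """
    f0 = np.asarray(f0, dtype=float)
    fm = np.asarray(fm, dtype=float)
    if np.any(fm <= 0):
        raise ValueError("Fv/Fm undefined: requires Fm > 0")
    ratio = (fm - f0) / fm
    if np.any(ratio < 0) or np.any(ratio > 1):
        warnings.warn("Fv/Fm outside [0, 1]: check F0/Fm measurements")
    return ratio if ratio.ndim else float(ratio)


def compute_indices(measurements: pd.DataFrame) -> pd.DataFrame:
    """Add rwc and fv_fm columns to a measurement table.

    Expects columns FW, DW, RW, F0, Fm (Fs, if present, is carried through
    unused).
    """
    out = measurements.copy()
    out["rwc"] = relative_water_content(out["FW"], out["DW"], out["RW"])
    out["fv_fm"] = fv_over_fm(out["F0"], out["Fm"])
    return out
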