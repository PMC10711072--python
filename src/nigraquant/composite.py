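"""Composite neuromelanin-iron marker.

The composite marker is the plain product of the three best-discriminating
SN mask parameters: the NM contrast range (90th/10th percentile signal
ratio), the NM mask area surviving the high-signal threshold, and the QSM
mask area of low-susceptibility (iron-poor) voxels.  All three factors are
reduced in Parkinson's disease, so low composite values indicate disease.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["composite_marker", "add_composite", "classify_by_cutoff"]

#: Factor columns, in product order.
COMPOSITE_FACTORS = ("nm_contrast_range", "nm_size_high", "qsm_size_low")


def composite_marker(nm_contrast_range, nm_size_high, qsm_size_low):
    """Product of the three discriminant SN parameters (unitless x mm^4).

    Accepts scalars or arrays; strictly increasing in each argument while
    the others are positive.  Negative inputs are invalid features.
    """
    a = np.asarray(nm_contrast_range, dtype=float)
    b = np.asarray(nm_size_high, dtype=float)
    c = np.asarray(qsm_size_low, dtype=float)
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0):
        raise ValueError("composite factors must be nonnegative")
    out = a * b * c
    return float(out) if out.ndim == 0 else out


def add_composite(features: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a feature table with the ``composite`` column."""
    out = features.copy()
    out["composite"] = composite_marker(*(out[c] for c in COMPOSITE_FACTORS))
    return out


def classify_by_cutoff(values: Union[Sequence[float], np.ndarray],
                       cutoff: float,
                       patient_side: str = "below") -> np.ndarray:
    """Deterministic cutoff classification into control/patient labels.

    ``patient_side="below"`` labels values <= cutoff as patient (the
    composite and all three factors are lower in disease); ties at the
    cutoff go to the patient side, favouring sensitivity.
    """
    v = np.asarray(values, dtype=float)
    if patient_side == "below":
        pat = v <= cutoff
    elif patient_side == "above":
        pat = v >= cutoff
    else:
        raise ValueError("patient_side must be 'below' or 'above'")
    return np.where(pat, "patient", "control")
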