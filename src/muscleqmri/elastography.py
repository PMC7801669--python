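"""Shear-wave elastography ROI summaries and the stretch-induced
viscoelastic index.

Shear-modulus (SM) maps are acquired at 0, 40, 60 and 80 degrees of ankle
plantar flexion. The viscoelastic index SMi = (SM80 - SM0)/SM0 quantifies
the relative stiffening of the muscle from slack to stretched length; it is
scale-invariant, so probe- and depth-dependent multiplicative biases cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SWE_ANGLES_DEG", "SWEMeasurement", "roi_mean_sm", "smi"]

SWE_ANGLES_DEG = (0, 40, 60, 80)


@dataclass(frozen=True)
class SWEMeasurement:
    """Shear modulus (kPa) per ankle angle, plus the derived index."""

    sm_kpa: dict  # angle (deg) -> kPa

    def __post_init__(self):
        missing = [a for a in SWE_ANGLES_DEG if a not in self.sm_kpa]
        if missing:
            raise ValueError(f"missing shear modulus at angle(s) {missing}")
        for a, v in self.sm_kpa.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"shear modulus at {a} deg must be positive")

    @property
    def smi(self) -> float:
        return smi(self.sm_kpa[0], self.sm_kpa[80])


def roi_mean_sm(sm_map, mask) -> float:
    """Arithmetic mean shear modulus over valid (finite, >= 0) masked pixels.

    Invalid pixels inside the ROI are excluded; an ROI with no valid pixel
    yields NaN.
    """
    m = np.asarray(sm_map, dtype=float)
    roi = np.asarray(mask).astype(bool)
    if m.shape != roi.shape:
        raise ValueError("map and mask shapes must match")
    if not roi.any():
        raise ValueError("ROI mask is empty")
    vals = m[roi]
    vals = vals[np.isfinite(vals) & (vals >= 0)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def smi(sm0_kpa: float, sm80_kpa: float) -> float:
    """Viscoelastic index (SM80 - SM0)/SM0 (dimensionless)."""
    if not np.isfinite(sm0_kpa) or sm0_kpa <= 0:
        raise ValueError("SM at 0 deg must be positive")
    return (sm80_kpa - sm0_kpa) / sm0_kpa
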