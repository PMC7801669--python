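"""Sampled relaxation/decay signals and the acquisition protocols that produce them.

A :class:`RelaxationSignal` is the common currency between the synthetic
generators and the fitting routines: a strictly increasing time axis (ms),
one amplitude per time point, and a modality tag identifying the acquisition
(saturation-recovery T1, MSME, ISIS-CPMG or UTE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Saturation-recovery repetition times (ms) of the T1-mapping protocol,
#: sorted ascending (the protocol lists them in acquisition order).
T1_SR_TR_MS: tuple[float, ...] = (
    82.9, 100.0, 128.0, 171.0, 214.0, 286.0, 359.0, 602.0,
    1010.0, 1694.0, 2842.0, 4769.0, 8000.0,
)

#: MSME T2-mapping echo train: echo spacing (ms) and echo count.
MSME_ESP_MS: float = 5.15
MSME_N_ECHOES: int = 32

#: ISIS-CPMG spectroscopic echo train: echo spacing (ms) and echo count.
CPMG_ESP_MS: float = 1.0
CPMG_N_ECHOES: int = 200

#: UTE echo times (ms); the short component oscillates at 970 Hz off-resonance.
UTE_TE_MS: tuple[float, ...] = (
    0.012, 0.1, 0.25, 0.5, 0.6, 0.8, 1.0, 1.2,
    1.4, 1.6, 1.8, 2.0, 2.6, 3.0, 6.0, 8.0,
)
UTE_CHEMICAL_SHIFT_HZ: float = 970.0

MODALITIES = ("T1SR", "MSME", "CPMG", "UTE")


@dataclass(frozen=True)
class RelaxationSignal:
    """A sampled decay/recovery curve with its time axis.

    Parameters
    ----------
    times_ms
        Sample times in milliseconds, strictly increasing.
    amplitudes
        Signal amplitude (a.u.) at each time, finite.
    modality
        One of ``T1SR``, ``MSME``, ``CPMG``, ``UTE``.
    """

    times_ms: np.ndarray
    amplitudes: np.ndarray
    modality: str = field(default="CPMG")

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.ndim != 1 or a.ndim != 1 or t.size != a.size:
            raise ValueError("times and amplitudes must be 1-D and equal length")
        if t.size == 0:
            raise ValueError("signal must contain at least one sample")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("amplitudes must be finite")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "times_ms", t)
        object.__setattr__(self, "amplitudes", a)

    def __len__(self) -> int:
        return int(self.times_ms.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times_ms, "amplitude": self.amplitudes})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, modality: str = "CPMG") -> "RelaxationSignal":
        df = pd.read_csv(path)
        return cls(df["time_ms"].to_numpy(), df["amplitude"].to_numpy(), modality)
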