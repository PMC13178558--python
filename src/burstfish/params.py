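"""Parameter containers for the ZINB observation model and the telegraph process.

The zero-inflated negative binomial (ZINB) describes per-cell mRNA counts as a
mixture of a point mass at zero (weight ``omega``, the transcriptionally
repressed state) and a negative binomial NB(r, p) with pmf

    P(k) = C(k + r - 1, k) * p**k * (1 - p)**r

so that the burst size is b = p/(1-p) and the NB shape r proxies the burst
frequency (bursts per mRNA lifetime). The telegraph parameters describe the
mechanistic two-state promoter model used as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._exceptions import ParameterError

__all__ = ["ZINBParams", "TelegraphParams"]


@dataclass(frozen=True)
class ZINBParams:
    """Zero-inflated negative binomial parameters theta = [omega, r, p].

    omega : probability of the repressed (structural-zero) state, in [0, 1]
    r     : NB shape (burst-frequency proxy), > 0
    p     : NB per-trial success probability, in (0, 1)
    """

    omega: float
    r: float
    p: float

    def __post_init__(self):
        if not (0.0 <= self.omega <= 1.0):
            raise ParameterError(f"omega must lie in [0, 1], got {self.omega}")
        if not (self.r > 0.0):
            raise ParameterError(f"r must be > 0, got {self.r}")
        if not (0.0 < self.p < 1.0):
            raise ParameterError(f"p must lie in (0, 1), got {self.p}")

    def to_vector(self) -> np.ndarray:
        """Vector view theta = [omega, r, p]."""
        return np.array([self.omega, self.r, self.p], dtype=float)

    @classmethod
    def from_vector(cls, theta) -> "ZINBParams":
        omega, r, p = np.asarray(theta, dtype=float)
        return cls(omega=float(omega), r=float(r), p=float(p))

    @property
    def burst_size(self) -> float:
        """Mean mRNAs per burst, b = p / (1 - p)."""
        return self.p / (1.0 - self.p)

    @property
    def burst_frequency(self) -> float:
        """Bursts per mRNA lifetime, f = r (dimensionless)."""
        return self.r

    def mean(self) -> float:
        """Closed-form ZINB mean (1 - omega) * r * p / (1 - p)."""
        return (1.0 - self.omega) * self.r * self.p / (1.0 - self.p)

    def var(self) -> float:
        """Closed-form ZINB variance (1 - omega) * m * (1 + b + omega * m).

        Here m = r p / (1 - p) is the NB mean and b = p / (1 - p) the burst
        size; derived from the NB variance m (1 + b) by mixing in the point
        mass at zero.
        """
        m = self.r * self.p / (1.0 - self.p)
        b = self.burst_size
        return (1.0 - self.omega) * m * (1.0 + b + self.omega * m)

    def zero_fraction(self) -> float:
        """P(K = 0) = omega + (1 - omega) (1 - p)**r."""
        return self.omega + (1.0 - self.omega) * math.exp(self.r * math.log1p(-self.p))


@dataclass(frozen=True)
class TelegraphParams:
    """Two-state (ON/OFF) promoter model rates, all per unit time.

    k_on  : OFF -> ON promoter activation rate (>= 0)
    k_off : ON -> OFF inactivation rate (>= 0)
    k_tx  : transcription rate while ON (>= 0)
    k_deg : first-order mRNA degradation rate (> 0)
    """

    k_on: float
    k_off: float
    k_tx: float
    k_deg: float

    def __post_init__(self):
        for name in ("k_on", "k_off", "k_tx"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (self.k_deg > 0):
            raise ParameterError(f"k_deg must be > 0, got {self.k_deg}")
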