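"""Physical constants for amide 15N spin relaxation.

The dipolar and CSA interaction strengths that drive backbone amide
relaxation are not free parameters of the analysis; they are set by the
N-H bond length, the 15N chemical-shift anisotropy and the gyromagnetic
ratios.  The defaults here (rNH = 1.02 A, CSA = -160 ppm) are the values
conventional for classic model-free software; both are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

# CODATA gyromagnetic ratios, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8
GAMMA_N = -2.7126189e7  # 15N, negative

MU_0 = 4.0e-7 * math.pi  # vacuum permeability, T m / A
HBAR = 1.054571817e-34  # J s
K_B = 1.380649e-23  # J / K

#: gamma_H / gamma_N used when only frequency ratios are known
GAMMA_RATIO_HN = GAMMA_H / GAMMA_N  # approx -9.8619


@dataclass(frozen=True)
class SpinSystemConstants:
    """Amide 15N spin-system parameters entering the relaxation equations.

    Parameters
    ----------
    r_nh : float
        Effective N-H bond length in Angstrom.
    csa : float
        15N chemical-shift anisotropy in ppm (negative for backbone amides).
    proton_freq : float
        1H Larmor frequency of the spectrometer in MHz.
    gamma_ratio : float
        gamma_H / gamma_N (dimensionless, negative for 15N).
    """

    r_nh: float = 1.02
    csa: float = -160.0
    proton_freq: float = 600.0
    gamma_ratio: float = GAMMA_RATIO_HN

    def __post_init__(self) -> None:
        if not (0.9 <= self.r_nh <= 1.1):
            raise ValueError(f"r_nh={self.r_nh} A outside the physical 0.9-1.1 A range")
        if self.proton_freq <= 0:
            raise ValueError("proton_freq must be positive (MHz)")

    @property
    def omega_h(self) -> float:
        """1H Larmor frequency magnitude, rad/s."""
        return 2.0 * math.pi * self.proton_freq * 1e6

    @property
    def omega_n(self) -> float:
        """15N Larmor frequency magnitude, rad/s."""
        return self.omega_h * abs(1.0 / self.gamma_ratio)

    @property
    def nitrogen_freq(self) -> float:
        """15N Larmor frequency, MHz (e.g. 60.8 at a 600 MHz magnet)."""
        return self.omega_n / (2.0 * math.pi * 1e6)

    @property
    def d2(self) -> float:
        """Squared dipolar coupling constant, rad^2/s^2.

        d = (mu0/4pi) * hbar * gamma_H * gamma_N / rNH^3
        """
        r = self.r_nh * 1e-10
        d = (MU_0 / (4.0 * math.pi)) * HBAR * GAMMA_H * abs(GAMMA_N) / r**3
        return d * d

    @property
    def c2(self) -> float:
        """Squared CSA interaction constant, rad^2/s^2: c^2 = (omegaN * csa)^2 / 3."""
        return (self.omega_n * self.csa * 1e-6) ** 2 / 3.0
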