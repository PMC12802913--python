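"""Physical constants and spin-system parameters for amide 15N relaxation.

The defaults describe a backbone amide 1H-15N spin pair on a 600 MHz
(14.1 T) spectrometer: N-H bond length 1.02 Angstrom and a 15N chemical
shift anisotropy of -172 ppm, the values conventionally used in backbone
relaxation analysis.  All of them can be overridden per calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: vacuum permeability over 4*pi, T*m/A
MU0_OVER_4PI = 1.0e-7
#: reduced Planck constant, J*s
HBAR = 1.054571817e-34
#: 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H = 2.6752e8
#: 15N gyromagnetic ratio, rad s^-1 T^-1 (negative)
GAMMA_N = -2.7126e7
#: gas constant in kcal mol^-1 K^-1 (for ensemble binding free energies)
R_GAS_KCAL = 1.98720425e-3
#: 15N weighting factor in combined chemical shift perturbations
CSP_NITROGEN_WEIGHT = 0.154


@dataclass(frozen=True)
class SpinSystemConstants:
    """Constants of the 1H-15N dipolar + 15N CSA relaxation mechanism.

    Parameters
    ----------
    nu_H : float
        1H Larmor frequency in Hz (default 600.13 MHz).
    nu_N : float or None
        15N Larmor frequency in Hz.  If None it is derived from ``nu_H``
        through the gyromagnetic-ratio magnitude ratio ``|gamma_N/gamma_H|``.
    r_NH : float
        Effective N-H bond length in Angstrom.
    csa_ppm : float
        15N chemical shift anisotropy (delta_sigma) in ppm.
    gamma_H, gamma_N : float
        Gyromagnetic ratios in rad s^-1 T^-1 (gamma_N is negative).
    """

    nu_H: float = 600.13e6
    nu_N: float | None = None
    r_NH: float = 1.02
    csa_ppm: float = -172.0
    gamma_H: float = GAMMA_H
    gamma_N: float = GAMMA_N
    _nu_N: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        nu_N = self.nu_N
        if nu_N is None:
            nu_N = self.nu_H * abs(self.gamma_N / self.gamma_H)
        else:
            ratio = abs(nu_N / self.nu_H)
            expected = abs(self.gamma_N / self.gamma_H)
            if abs(ratio - expected) / expected > 0.01:
                raise ValueError(
                    f"nu_N/nu_H = {ratio:.5f} deviates more than 1% from "
                    f"|gamma_N/gamma_H| = {expected:.5f}"
                )
        object.__setattr__(self, "_nu_N", float(nu_N))

    @property
    def nu_N_hz(self) -> float:
        """15N Larmor frequency in Hz (always defined)."""
        return self._nu_N

    @property
    def omega_H(self) -> float:
        """1H angular Larmor frequency, rad/s."""
        return 2.0 * math.pi * self.nu_H

    @property
    def omega_N(self) -> float:
        """15N angular Larmor frequency (magnitude), rad/s."""
        return 2.0 * math.pi * self._nu_N

    @property
    def dipolar_constant(self) -> float:
        """d = (mu0/4pi) * hbar * gammaH * gammaN / r_NH^3, rad/s (signed)."""
        r_m = self.r_NH * 1e-10
        return MU0_OVER_4PI * HBAR * self.gamma_H * self.gamma_N / r_m**3

    @property
    def csa_constant(self) -> float:
        """c = omega_N * delta_sigma / sqrt(3), rad/s."""
        return self.omega_N * self.csa_ppm * 1e-6 / math.sqrt(3.0)
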