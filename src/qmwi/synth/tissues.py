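"""Four-pole Cole-Cole dispersion models for biological tissues.

The complex relative permittivity of a tissue is

    εeq(ω) = ε∞ + Σ_{i=1..4} Δε_i / (1 + (jωτ_i)^{1−α_i}) + σ_s/(jωε0)

returned under the ``exp(+jωt)`` convention (Im εeq ≤ 0).  Parameter sets for
the tissues used by the head phantom are the standard literature constants
(Gabriel parametrization).  The ischemic-tissue entry is a synthetic surrogate:
measured four-pole constants for ischemic brain are not tabulated in that
literature, so it is modelled as grey matter with all Δε_i, ε∞ and σ_s scaled
by 0.81, a constant chosen so that its contrast amplitude against the ε=23,
σ=0.19 S/m matching medium is ≈0.96 at 1 GHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..geometry import EPS0
from ..scene import equivalent_permittivity


@dataclass(frozen=True)
class ColeColeTissue:
    """One tissue's four-pole Cole-Cole parameters (SI units)."""

    name: str
    eps_inf: float
    delta_eps: tuple[float, float, float, float]
    tau: tuple[float, float, float, float]  # seconds
    alpha: tuple[float, float, float, float]
    sigma_s: float  # static ionic conductivity, S/m

    def __post_init__(self) -> None:
        if self.eps_inf < 1 or self.sigma_s < 0 or any(d < 0 for d in self.delta_eps):
            raise ValueError(f"nonphysical Cole-Cole parameters for {self.name!r}")
        if any(t <= 0 for t in self.tau) or any(not 0 <= a < 1 for a in self.alpha):
            raise ValueError(f"nonphysical relaxation parameters for {self.name!r}")

    def scaled(self, factor: float) -> "ColeColeTissue":
        """Uniformly scale the dispersive amplitudes and conductivity.

        Used both for inter-subject ±10% variability and for the ischemic
        surrogate.  ε∞ is scaled but floored at 1 (vacuum limit).
        """
        return replace(
            self,
            eps_inf=max(1.0, self.eps_inf * factor),
            delta_eps=tuple(d * factor for d in self.delta_eps),
            sigma_s=self.sigma_s * factor,
        )


def cole_cole_eps(tissue: ColeColeTissue, frequency: float) -> complex:
    """Evaluate εeq at one frequency; Re ≥ 1 and Im ≤ 0 for physical tissues."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * frequency
    eps = complex(tissue.eps_inf)
    for d, t, a in zip(tissue.delta_eps, tissue.tau, tissue.alpha):
        eps += d / (1.0 + (1j * omega * t) ** (1.0 - a))
    eps += tissue.sigma_s / (1j * omega * EPS0)
    return eps


def conductivity(tissue: ColeColeTissue, frequency: float) -> float:
    """Total effective conductivity σ(ω) = −ω ε0 Im(εeq)."""
    return -2.0 * np.pi * frequency * EPS0 * cole_cole_eps(tissue, frequency).imag


# Gabriel four-pole constants for the tissues the head phantom needs.
BLOOD = ColeColeTissue(
    "blood", 4.0, (56.0, 5200.0, 0.0, 0.0),
    (8.377e-12, 132.629e-9, 159.155e-6, 15.915e-3), (0.10, 0.10, 0.20, 0.00), 0.700,
)
GREY_MATTER = ColeColeTissue(
    "grey-matter", 4.0, (45.0, 400.0, 2.0e5, 4.5e7),
    (7.958e-12, 15.915e-9, 106.103e-6, 5.305e-3), (0.10, 0.15, 0.22, 0.00), 0.020,
)
WHITE_MATTER = ColeColeTissue(
    "white-matter", 4.0, (32.0, 100.0, 4.0e4, 3.5e7),
    (7.958e-12, 7.958e-9, 53.052e-6, 7.958e-3), (0.10, 0.10, 0.30, 0.02), 0.020,
)
CSF = ColeColeTissue(
    "csf", 4.0, (65.0, 40.0, 0.0, 0.0),
    (7.958e-12, 1.592e-9, 159.155e-6, 15.915e-3), (0.10, 0.00, 0.00, 0.00), 2.000,
)
SKIN_DRY = ColeColeTissue(
    "skin-dry", 4.0, (32.0, 1100.0, 0.0, 0.0),
    (7.234e-12, 32.481e-9, 159.155e-6, 15.915e-3), (0.00, 0.20, 0.20, 0.00), 0.0002,
)
BONE_CORTICAL = ColeColeTissue(
    "bone-cortical", 2.5, (10.0, 180.0, 5.0e3, 1.0e5),
    (13.263e-12, 79.577e-9, 159.155e-6, 15.915e-3), (0.20, 0.20, 0.20, 0.00), 0.020,
)
# Synthetic surrogate (see module docstring): grey matter scaled by 0.81.
ISCHEMIC = replace(GREY_MATTER.scaled(0.81), name="ischemic-surrogate")

TISSUES: dict[str, ColeColeTissue] = {
    t.name: t
    for t in (BLOOD, GREY_MATTER, WHITE_MATTER, CSF, SKIN_DRY, BONE_CORTICAL, ISCHEMIC)
}

# Matching medium surrounding the head: lossy coupling liquid.
MATCHING_EPS = 23.0
MATCHING_SIGMA = 0.19  # S/m


def matching_medium_eps(frequency: float) -> complex:
    """Equivalent complex permittivity of the matching medium at a frequency."""
    return complex(equivalent_permittivity(MATCHING_EPS, MATCHING_SIGMA, frequency))


def tissue_contrast(tissue: ColeColeTissue, frequency: float) -> complex:
    """Contrast τ = εeq/εb − 1 of a tissue against the matching medium."""
    return cole_cole_eps(tissue, frequency) / matching_medium_eps(frequency) - 1.0
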