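"""Growth-rate model, social-interaction scenarios, and closed-form maxima.

Two strains grow on the lattice: a slow one (``S``, baseline rate
``r_S0``) and a fast one (``F``, baseline rate ``r_F0``).  A cell's
division rate depends on the composition of its cubic interaction
neighborhood through the occupancy fractions ``phi_S`` and ``phi_F``:

    r_S = (r_S0 + r_SF * phi_F + r_SS * phi_S) * [1 - chi * (phi_S + phi_F)]
    r_F = (r_F0 + r_FS * phi_S + r_FF * phi_F) * [1 - chi * (phi_S + phi_F)]

The coefficient ``r_ij`` is the effect of neighbors of type ``j`` on a
cell of type ``i``; ``chi`` is the crowding/competition coefficient
(with ``chi = 1`` the rate is exactly zero in a full neighborhood).
Social scenarios (baseline competition, obligate cooperation, greenbeard
recognition, polychromatic greenbeards) are encoded purely as sparsity
patterns of the ``r_ij`` matrix.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, asdict


class CellType(enum.IntEnum):
    """The two strain identities; values match the lattice site codes."""

    SLOW = 1
    FAST = 2


class Scenario(enum.Enum):
    """Named social-interaction scenarios.

    BASELINE
        Pure competition; every ``r_ij`` is zero.
    OBLIGATE
        The slow strain cooperates and cannot restrict the benefit:
        fast "cheaters" profit equally (``r_SS = r_FS = r``).
    GREENBEARD
        The slow strain recognizes its own type and cooperates only
        with it (``r_SS = r``, everything else zero).
    TWO_GREENBEARDS
        Both strains are simple greenbeards that also benefit the other
        cooperator type (all four ``r_ij = r``).
    SLOW_POLY_FAST_GB
        The slow strain is a polychromatic greenbeard (helps only
        itself) while the fast strain is a simple greenbeard, so F
        still helps S but S does not help F (``r_FS = 0``).
    FAST_POLY_SLOW_GB
        The mirror image: the fast strain restricts, the slow strain
        does not (``r_SF = 0``).
    BOTH_POLY
        Both strains are polychromatic: each helps only its own type
        (``r_SS = r_FF = r``, cross terms zero).
    """

    BASELINE = "baseline"
    OBLIGATE = "obligate"
    GREENBEARD = "greenbeard"
    TWO_GREENBEARDS = "two_greenbeards"
    SLOW_POLY_FAST_GB = "slow_poly_fast_gb"
    FAST_POLY_SLOW_GB = "fast_poly_slow_gb"
    BOTH_POLY = "both_poly"


#: Which of (r_SS, r_SF, r_FS, r_FF) carry the cooperation strength r.
_SCENARIO_PATTERN = {
    Scenario.BASELINE: (0, 0, 0, 0),
    Scenario.OBLIGATE: (1, 0, 1, 0),
    Scenario.GREENBEARD: (1, 0, 0, 0),
    Scenario.TWO_GREENBEARDS: (1, 1, 1, 1),
    Scenario.SLOW_POLY_FAST_GB: (1, 1, 0, 1),
    Scenario.FAST_POLY_SLOW_GB: (1, 0, 1, 1),
    Scenario.BOTH_POLY: (1, 0, 0, 1),
}

#: Cooperation strengths used throughout the study sweeps.
STUDY_R_VALUES = (0.1, 0.3, 0.5, 0.7)

#: Default baseline growth rates (divisions per unit time).
DEFAULT_R_S0 = 0.05
DEFAULT_R_F0 = 0.1
DEFAULT_CHI = 1.0


@dataclass(frozen=True)
class ScenarioSpec:
    """A scenario name plus the shared cooperation strength ``r``."""

    name: Scenario
    r: float = 0.0

    def __post_init__(self):
        if not isinstance(self.name, Scenario):
            object.__setattr__(self, "name", Scenario(self.name))
        if self.r < 0:
            raise ValueError(f"cooperation strength r must be >= 0, got {self.r}")
        if self.name is Scenario.BASELINE and self.r != 0:
            raise ValueError("BASELINE forces r = 0")


@dataclass(frozen=True)
class InteractionParams:
    """The full growth/interaction parameter set.

    ``r_ij`` is the (dimensionless) rate addition that neighbors of type
    j confer on a cell of type i; ``chi`` scales crowding competition.
    """

    r_s0: float = DEFAULT_R_S0
    r_f0: float = DEFAULT_R_F0
    r_ss: float = 0.0
    r_sf: float = 0.0
    r_fs: float = 0.0
    r_ff: float = 0.0
    chi: float = DEFAULT_CHI

    def __post_init__(self):
        for name in ("r_s0", "r_f0", "r_ss", "r_sf", "r_fs", "r_ff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.chi <= 0:
            raise ValueError("chi must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Occupancy:
    """Occupancy fractions of the interaction neighborhood (center excluded)."""

    phi_s: float
    phi_f: float

    def __post_init__(self):
        if self.phi_s < 0 or self.phi_f < 0:
            raise ValueError("occupancy fractions must be >= 0")
        if self.phi_s + self.phi_f > 1 + 1e-12:
            raise ValueError("phi_s + phi_f must be <= 1")


def scenario_params(spec: ScenarioSpec,
                    r_s0: float = DEFAULT_R_S0,
                    r_f0: float = DEFAULT_R_F0,
                    chi: float = DEFAULT_CHI) -> InteractionParams:
    """Build the interaction matrix for a named social scenario.

    Parameters
    ----------
    spec
        Scenario name and cooperation strength ``r``.
    r_s0, r_f0
        Baseline growth rates of the slow and fast strain.
    chi
        Competition coefficient.
    """
    if not isinstance(spec, ScenarioSpec):
        raise TypeError("spec must be a ScenarioSpec")
    pattern = _SCENARIO_PATTERN[spec.name]
    r = spec.r
    return InteractionParams(
        r_s0=r_s0, r_f0=r_f0,
        r_ss=r * pattern[0], r_sf=r * pattern[1],
        r_fs=r * pattern[2], r_ff=r * pattern[3],
        chi=chi,
    )


def growth_rate(cell: CellType, occ: Occupancy, p: InteractionParams) -> float:
    """Division rate of a cell given its neighborhood occupancy.

    The benefit term is linear in the neighborhood composition and the
    crowding term ``1 - chi*(phi_S + phi_F)`` vanishes in a full
    neighborhood when ``chi = 1``.  The result is clamped at zero so the
    contract stays total for ``chi > 1`` parameter explorations.
    """
    crowd = 1.0 - p.chi * (occ.phi_s + occ.phi_f)
    if cell == CellType.SLOW:
        rate = (p.r_s0 + p.r_sf * occ.phi_f + p.r_ss * occ.phi_s) * crowd
    elif cell == CellType.FAST:
        rate = (p.r_f0 + p.r_fs * occ.phi_s + p.r_ff * occ.phi_f) * crowd
    else:
        raise ValueError(f"unknown cell type {cell!r}")
    return max(rate, 0.0)


def max_growth_rate(r_i0: float, r_ii: float,
                    chi: float = DEFAULT_CHI) -> tuple[float, float]:
    """Maximum rate a self-cooperating strain can reach, and where.

    Maximizing ``(r_i0 + r_ii*phi) * (1 - chi*phi)`` over the own-type
    occupancy ``phi`` (other strain absent) gives the interior optimum

        phi* = (r_ii - chi*r_i0) / (2*chi*r_ii),
        r_max = (chi*r_ii + r_i0)^2 / (4*r_ii*chi).

    For a non-cooperator (``r_ii = 0``) the rate is maximal in an empty
    neighborhood, so ``(r_i0, 0)`` is returned.  When the interior
    optimum falls outside [0, 1] (``r_ii < chi*r_i0``), ``phi*`` is
    clamped to the boundary and the rate evaluated there.

    Returns
    -------
    (r_max, phi_star)
    """
    if chi <= 0:
        raise ValueError("chi must be > 0")
    if r_i0 <= 0:
        raise ValueError("r_i0 must be > 0")
    if r_ii < 0:
        raise ValueError("r_ii must be >= 0")
    if r_ii == 0:
        return r_i0, 0.0
    phi_star = (r_ii - chi * r_i0) / (2.0 * chi * r_ii)
    phi_star = min(1.0, max(0.0, phi_star))
    r_max = (r_i0 + r_ii * phi_star) * (1.0 - chi * phi_star)
    return max(r_max, 0.0), phi_star


def max_growth_rate_closed_form(r_i0: float, r_ii: float,
                                chi: float = DEFAULT_CHI) -> float:
    """Unclamped closed form ``(chi*r_ii + r_i0)^2 / (4*r_ii*chi)``.

    Valid when the interior optimum exists (``r_ii >= chi*r_i0``);
    agrees with :func:`max_growth_rate` there.
    """
    if r_ii == 0:
        return r_i0
    return (chi * r_ii + r_i0) ** 2 / (4.0 * r_ii * chi)
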