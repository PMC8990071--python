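"""Deterministic ODE model of BCL2-family-controlled mitochondrial outer
membrane permeabilization (MOMP).

A BH3-only "stress" species S catalytically activates the effectors BAK
and BAX (S + E -> S + E*, not consumed); the anti-apoptotic proteins BCL2,
BCL(X)L and MCL1 reversibly sequester both the stress species and the
activated effectors with member-specific affinities (BCL2 prefers BAX*,
MCL1 prefers BAK*, BCL(X)L binds both); activated effectors dimerize
irreversibly into pores.  The readout is the maximal pore level as a
percent of total effector, a cell is called low-sensitivity when that
percent stays strictly below 10% at the reference stress dose (200 nM),
and the minimal dose reaching the pore threshold is found by bisection.

Units are µM and seconds internally; stress doses cross the interface in
nM.  Rate constants are configurable model parameters (see
:class:`MompParameters` for the shipped defaults).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.integrate import solve_ivp

ANTI_APOPTOTICS = ("BCL2", "BCL(X)L", "MCL1")
EFFECTORS = ("BAK", "BAX")

#: Canonical selectivity pattern: Kd (µM) of each anti-apoptotic for the
#: activated effectors.  Tight = 0.02 µM, weak = 1 µM.
DEFAULT_KD: dict[str, dict[str, float]] = {
    "BCL2": {"BAK": 1.0, "BAX": 0.02},
    "BCL(X)L": {"BAK": 0.02, "BAX": 0.02},
    "MCL1": {"BAK": 0.02, "BAX": 1.0},
}


@dataclass(frozen=True)
class MompParameters:
    """Kinetic constants, readout conventions and solver settings."""

    kd: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {a: dict(e) for a, e in DEFAULT_KD.items()}
    )
    kd_stress: Mapping[str, float] = field(
        default_factory=lambda: {a: 0.01 for a in ANTI_APOPTOTICS}
    )
    k_on: float = 1.0  # µM^-1 s^-1 association rate (all complexes)
    k_act: float = 0.1  # µM^-1 s^-1 catalytic effector activation
    k_pore: float = 0.05  # µM^-1 s^-1 effector dimerization
    t_end: float = 10800.0  # s (3 h horizon)
    reference_stress_dose_nM: float = 200.0
    pore_threshold_pct: float = 10.0
    rtol: float = 1e-7
    atol: float = 1e-10
    bracket_max_nM: float = 10000.0  # 10 µM
    bisect_tol_nM: float = 1.0

    def __post_init__(self) -> None:
        for a in ANTI_APOPTOTICS:
            for e in EFFECTORS:
                if self.kd[a][e] <= 0:
                    raise ValueError(f"non-positive Kd for {a}/{e}")
            if self.kd_stress[a] <= 0:
                raise ValueError(f"non-positive stress Kd for {a}")
        for name in ("k_on", "k_act", "k_pore", "t_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.pore_threshold_pct < 100:
            raise ValueError("pore_threshold_pct must be in (0, 100)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MompParameters":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "kd": {a: dict(e) for a, e in self.kd.items()},
            "kd_stress": dict(self.kd_stress),
            "k_on": self.k_on, "k_act": self.k_act, "k_pore": self.k_pore,
            "t_end": self.t_end,
            "reference_stress_dose_nM": self.reference_stress_dose_nM,
            "pore_threshold_pct": self.pore_threshold_pct,
            "rtol": self.rtol, "atol": self.atol,
            "bracket_max_nM": self.bracket_max_nM,
            "bisect_tol_nM": self.bisect_tol_nM,
        }))


UNREACHABLE = math.inf  # sentinel: bracket_max never reaches the threshold

# State vector layout (µM):
#  0 S        free stress
#  1 Ebak     inactive BAK        2 Ebax    inactive BAX
#  3 aBak     activated BAK       4 aBax    activated BAX
#  5..7       free BCL2, BCL(X)L, MCL1
#  8..10      anti·S complexes
# 11..13      anti·BAK* complexes
# 14..16      anti·BAX* complexes
# 17 Pbak     BAK pores           18 Pbax   BAX pores
_N_SPECIES = 19


def _make_rhs(p: MompParameters):
    k_on, k_act, k_pore = p.k_on, p.k_act, p.k_pore
    koff_s = [k_on * p.kd_stress[a] for a in ANTI_APOPTOTICS]
    koff_k = [k_on * p.kd[a]["BAK"] for a in ANTI_APOPTOTICS]
    koff_x = [k_on * p.kd[a]["BAX"] for a in ANTI_APOPTOTICS]

    def rhs(t, y):
        S = y[0]
        Ebak, Ebax, aBak, aBax = y[1], y[2], y[3], y[4]
        dy = np.zeros(_N_SPECIES)
        act_k = k_act * S * Ebak
        act_x = k_act * S * Ebax
        dim_k = k_pore * aBak * aBak
        dim_x = k_pore * aBax * aBax
        dy[1] = -act_k
        dy[2] = -act_x
        d_aBak = act_k - 2.0 * dim_k
        d_aBax = act_x - 2.0 * dim_x
        dS = 0.0
        for j in range(3):
            A = y[5 + j]
            fS = k_on * A * S - koff_s[j] * y[8 + j]
            fK = k_on * A * aBak - koff_k[j] * y[11 + j]
            fX = k_on * A * aBax - koff_x[j] * y[14 + j]
            dy[5 + j] = -(fS + fK + fX)
            dy[8 + j] = fS
            dy[11 + j] = fK
            dy[14 + j] = fX
            dS -= fS
            d_aBak -= fK
            d_aBax -= fX
        dy[0] = dS
        dy[3] = d_aBak
        dy[4] = d_aBax
        dy[17] = dim_k
        dy[18] = dim_x
        return dy

    return rhs


@dataclass(frozen=True)
class MompSimulation:
    """Trajectory and readout of one MOMP simulation."""

    times: np.ndarray
    states: np.ndarray  # (n_species, n_times)
    pore_pct: np.ndarray
    max_pore_pct: float

    def conservation_residuals(self, profile: Mapping[str, float],
                               stress_dose_nM: float) -> dict[str, float]:
        """Worst absolute drift of each conserved family over the trajectory."""
        y = self.states
        res = {}
        bak0, bax0 = profile["BAK"], profile["BAX"]
        res["BAK"] = float(np.max(np.abs(
            y[1] + y[3] + y[11] + y[12] + y[13] + 2 * y[17] - bak0)))
        res["BAX"] = float(np.max(np.abs(
            y[2] + y[4] + y[14] + y[15] + y[16] + 2 * y[18] - bax0)))
        for j, a in enumerate(ANTI_APOPTOTICS):
            res[a] = float(np.max(np.abs(
                y[5 + j] + y[8 + j] + y[11 + j] + y[14 + j] - profile[a])))
        res["stress"] = float(np.max(np.abs(
            y[0] + y[8] + y[9] + y[10] - stress_dose_nM / 1000.0)))
        return res


def simulate_momp(
    profile: Mapping[str, float],
    stress_dose_nM: float,
    params: MompParameters | None = None,
) -> MompSimulation:
    """Integrate the network from a ten-protein profile (µM) under a stress
    dose (nM); returns the trajectory and the maximal pore percentage.

    Pore % is normalized to total effector:
    ``100 * 2 * (P_BAK + P_BAX) / (BAK0 + BAX0)``.
    """
    p = params or MompParameters()
    if stress_dose_nM < 0:
        raise ValueError("stress dose must be >= 0")
    bak0, bax0 = float(profile["BAK"]), float(profile["BAX"])
    total_eff = bak0 + bax0
    if total_eff <= 0:
        raise ValueError("total effector (BAK + BAX) is zero: pore % undefined")
    for name in ("BAK", "BAX") + ANTI_APOPTOTICS:
        if profile[name] < 0:
            raise ValueError(f"negative concentration for {name}")

    y0 = np.zeros(_N_SPECIES)
    y0[0] = stress_dose_nM / 1000.0  # nM -> µM
    y0[1], y0[2] = bak0, bax0
    for j, a in enumerate(ANTI_APOPTOTICS):
        y0[5 + j] = float(profile[a])

    sol = solve_ivp(
        _make_rhs(p), (0.0, p.t_end), y0, method="LSODA",
        rtol=p.rtol, atol=p.atol,
    )
    if not sol.success:
        raise RuntimeError(f"MOMP solver failed: {sol.message}")
    pore_pct = np.clip(100.0 * 2.0 * (sol.y[17] + sol.y[18]) / total_eff, 0.0, 100.0)
    return MompSimulation(
        times=sol.t, states=sol.y, pore_pct=pore_pct,
        max_pore_pct=float(np.max(pore_pct)),
    )


def classify_momp_sensitivity(
    max_pore_pct: float, threshold_pct: float = 10.0
) -> str:
    """``low`` iff the pore percentage is strictly below the threshold."""
    if not 0.0 <= max_pore_pct <= 100.0 + 1e-9:
        raise ValueError(f"pore percentage out of range: {max_pore_pct}")
    return "low" if max_pore_pct < threshold_pct else "high"


def required_stress_dose(
    profile: Mapping[str, float],
    params: MompParameters | None = None,
) -> float:
    """Smallest stress dose (nM) whose maximal pore % reaches the threshold,
    by bisection on the monotone dose-response; :data:`UNREACHABLE` (inf)
    when even the bracket maximum fails."""
    p = params or MompParameters()

    def reaches(dose_nM: float) -> bool:
        return simulate_momp(profile, dose_nM, p).max_pore_pct >= p.pore_threshold_pct

    hi = p.bracket_max_nM
    if not reaches(hi):
        return UNREACHABLE
    lo = 0.0
    while hi - lo > p.bisect_tol_nM:
        mid = 0.5 * (lo + hi)
        if reaches(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass(frozen=True)
class MompResult:
    """Per-cell MOMP readout."""

    max_pore_pct: float
    low_sensitivity: bool
    required_stress_nM: float | None = None
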