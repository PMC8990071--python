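"""Deterministic ODE model of executioner caspase activation downstream of
MOMP.

The model premise is that MOMP has just occurred: cytochrome c is
saturating, so apoptosome formation is limited solely by APAF1 (fixed at
0.123 µM).  Apoptosomes bind procaspase-9 into the active C9 unit, which
catalytically matures procaspase-3 into caspase-3.  XIAP reversibly
inhibits both active species and degrades the caspase-3 it holds; SMAC,
fully cytosolic at t = 0, sequesters XIAP and thereby relieves the brake.
The readout is the percent of a normalized caspase-3 substrate cleaved by
the readout time (default 60 min); a cell is called high-activity when
substrate cleavage reaches the configured cutoff (default 25%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .calibration import APAF1_DEFAULT_UM


@dataclass(frozen=True)
class CaspaseParameters:
    """Kinetic constants, readout time/cutoff and solver settings.

    Defaults give switch-like substrate cleavage over the physiological
    0.01-1 µM input range; published constants drop in via YAML.
    """

    k_apop: float = 0.01       # s^-1, APAF1 -> apoptosome (cyt-c saturating)
    k_bind9: float = 1.0       # µM^-1 s^-1, apoptosome + PC9 association
    k_c9: float = 0.1          # µM^-1 s^-1, PC3 -> C3 by apoptosome-bound C9
    kd_xiap_c3: float = 0.002  # µM
    kd_xiap_c9: float = 0.002  # µM
    kd_xiap_smac: float = 0.001  # µM
    k_on_x: float = 1.0        # µM^-1 s^-1, all XIAP/SMAC associations
    k_deg3: float = 1e-3       # s^-1, XIAP-mediated C3 degradation
    k_sub: float = 1.0         # µM^-1 s^-1, substrate cleavage by C3
    t_sc: float = 3600.0       # s, readout time (60 min)
    sc_threshold_pct: float = 25.0
    rtol: float = 1e-7
    atol: float = 1e-10

    def __post_init__(self) -> None:
        for name in ("k_apop", "k_bind9", "k_c9", "kd_xiap_c3", "kd_xiap_c9",
                     "kd_xiap_smac", "k_on_x", "k_deg3", "k_sub", "t_sc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.sc_threshold_pct < 100:
            raise ValueError("sc_threshold_pct must be in (0, 100)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CaspaseParameters":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            f: getattr(self, f) for f in self.__dataclass_fields__
        }))


# State vector layout (µM):
#  0 A      free APAF1            1 Apop   free apoptosome
#  2 PC9    procaspase-9          3 AC9    apoptosome·C9 (active unit)
#  4 PC3    procaspase-3          5 C3     free caspase-3
#  6 X      free XIAP             7 XC3    XIAP·C3
#  8 XAC9   XIAP·apoptosome·C9    9 S      free SMAC
# 10 SX     SMAC·XIAP            11 C3d    degraded C3
# 12 Sub    substrate (Sub0 = 1) 13 cSub   cleaved substrate
_N_SPECIES = 14


def _make_rhs(p: CaspaseParameters):
    koff_c3 = p.k_on_x * p.kd_xiap_c3
    koff_c9 = p.k_on_x * p.kd_xiap_c9
    koff_sx = p.k_on_x * p.kd_xiap_smac

    def rhs(t, y):
        A, Apop, PC9, AC9, PC3, C3, X, XC3, XAC9, S, SX, C3d, Sub, cSub = y
        v_apop = p.k_apop * A
        v_bind9 = p.k_bind9 * Apop * PC9
        v_c9 = p.k_c9 * AC9 * PC3
        f_xc3 = p.k_on_x * X * C3 - koff_c3 * XC3
        f_xc9 = p.k_on_x * X * AC9 - koff_c9 * XAC9
        f_sx = p.k_on_x * S * X - koff_sx * SX
        v_deg = p.k_deg3 * XC3
        v_sub = p.k_sub * C3 * Sub
        return (
            -v_apop,                       # A
            v_apop - v_bind9,              # Apop
            -v_bind9,                      # PC9
            v_bind9 - f_xc9,               # AC9
            -v_c9,                         # PC3
            v_c9 - f_xc3,                  # C3
            -(f_xc3 + f_xc9 + f_sx) + v_deg,  # X (recycled on degradation)
            f_xc3 - v_deg,                 # XC3
            f_xc9,                         # XAC9
            -f_sx,                         # S
            f_sx,                          # SX
            v_deg,                         # C3d
            -v_sub,                        # Sub
            v_sub,                         # cSub
        )

    return rhs


@dataclass(frozen=True)
class CaspaseSimulation:
    """Trajectory and readout of one caspase-activation simulation."""

    times: np.ndarray
    states: np.ndarray
    substrate_cleavage_pct: float
    high_activity: bool

    def conservation_residuals(self, profile: Mapping[str, float],
                               apaf1_um: float) -> dict[str, float]:
        y = self.states
        return {
            "PC3": float(np.max(np.abs(
                y[4] + y[5] + y[7] + y[11] - profile["PRO-CASPASE 3"]))),
            "PC9": float(np.max(np.abs(
                y[2] + y[3] + y[8] - profile["PRO-CASPASE 9"]))),
            "XIAP": float(np.max(np.abs(
                y[6] + y[7] + y[8] + y[10] - profile["XIAP"]))),
            "SMAC": float(np.max(np.abs(y[9] + y[10] - profile["SMAC"]))),
            "APAF1": float(np.max(np.abs(y[0] + y[1] + y[3] + y[8] - apaf1_um))),
            "substrate": float(np.max(np.abs(y[12] + y[13] - 1.0))),
        }


def simulate_caspase(
    profile: Mapping[str, float],
    params: CaspaseParameters | None = None,
    apaf1_um: float | None = None,
) -> CaspaseSimulation:
    """Integrate the caspase network from a profile (µM of PRO-CASPASE 3,
    PRO-CASPASE 9, SMAC, XIAP, plus APAF1) to the readout time."""
    p = params or CaspaseParameters()
    apaf1 = float(profile.get("APAF1", apaf1_um if apaf1_um is not None
                              else APAF1_DEFAULT_UM))
    inputs = {m: float(profile[m]) for m in
              ("PRO-CASPASE 3", "PRO-CASPASE 9", "SMAC", "XIAP")}
    if apaf1 < 0 or any(v < 0 for v in inputs.values()):
        raise ValueError("negative concentration in caspase profile")

    y0 = np.zeros(_N_SPECIES)
    y0[0] = apaf1
    y0[2] = inputs["PRO-CASPASE 9"]
    y0[4] = inputs["PRO-CASPASE 3"]
    y0[6] = inputs["XIAP"]
    y0[9] = inputs["SMAC"]
    y0[12] = 1.0

    sol = solve_ivp(
        _make_rhs(p), (0.0, p.t_sc), y0, method="LSODA",
        rtol=p.rtol, atol=p.atol,
    )
    if not sol.success:
        raise RuntimeError(f"caspase solver failed: {sol.message}")
    sc_pct = float(np.clip(100.0 * sol.y[13, -1], 0.0, 100.0))
    return CaspaseSimulation(
        times=sol.t, states=sol.y,
        substrate_cleavage_pct=sc_pct,
        high_activity=sc_pct >= p.sc_threshold_pct,
    )


def classify_caspase_activity(sc_pct: float, threshold_pct: float = 25.0) -> str:
    """``high`` iff substrate cleavage reaches the cutoff (closed bound)."""
    if not 0.0 <= sc_pct <= 100.0 + 1e-9:
        raise ValueError(f"substrate cleavage out of range: {sc_pct}")
    return "high" if sc_pct >= threshold_pct else "low"


QUADRANTS = ("both_high", "momp_only", "caspase_only", "both_low")


def quadrant_classify(momp_high: bool, caspase_high: bool) -> str:
    """Joint pathway label from the two binary calls."""
    if momp_high and caspase_high:
        return "both_high"
    if momp_high:
        return "momp_only"
    if caspase_high:
        return "caspase_only"
    return "both_low"


@dataclass(frozen=True)
class CaspaseResult:
    """Per-cell caspase readout."""

    substrate_cleavage_pct: float
    high_activity: bool
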