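"""Chelator-buffered free-Ca2+ speciation (a MAXCHELATOR-style calculator).

[3H]ryanodine binding assays set free Ca2+ with EGTA- or BAPTA-buffered
solutions; the free concentration at a given total Ca2+ follows from 1:1
metal-chelator mass balance.  This module solves that speciation problem in
both directions: forward (totals -> free) and inverse (target free -> total
Ca2+ to add), and batches the inverse into pCa ladders for assay design.

Two operating modes:

* apparent-constants (default): the user supplies apparent dissociation
  constants valid at the assay pH/ionic strength/temperature (the numbers a
  MAXCHELATOR-style tool prints).
* absolute-constants: the user supplies the pH-independent Kd plus stepwise
  protonation pKa values, and :func:`apparent_kd` folds the pH in via the
  cumulative protonation polynomial

      Kd_app = Kd_abs * (1 + sum_j 10**(sum_{i<=j} pKa_i - j*pH)).

Ionic-strength and temperature corrections are outside the boundary of this
module: the constants file is the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model_core import CaConcentration


class ConfigurationError(ValueError):
    """The buffer description is incomplete or inconsistent."""


class SolverError(RuntimeError):
    """The mass-balance root finder could not bracket a solution."""


@dataclass
class ChelatorSpec:
    """One 1:1 chelator: totals, Ca2+ (and optional Mg2+) affinity, pKa list."""

    name: str
    total: float  # mol/L
    Kd_Ca: float  # apparent (or absolute, see BufferSystem.mode), mol/L
    Kd_Mg: float | None = None
    proton_pKas: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ConfigurationError(f"{self.name}: total must be >= 0")
        if not (self.Kd_Ca > 0):
            raise ConfigurationError(f"{self.name}: Kd_Ca must be > 0")
        if self.Kd_Mg is not None and not (self.Kd_Mg > 0):
            raise ConfigurationError(f"{self.name}: Kd_Mg must be > 0")


@dataclass
class BufferSystem:
    """A complete free-Ca2+ problem: chelators, metal totals, pH, mode."""

    chelators: list[ChelatorSpec]
    total_Ca: float
    total_Mg: float = 0.0
    pH: float = 7.0
    mode: str = "apparent-constants"  # or "absolute-constants"

    def __post_init__(self) -> None:
        if self.total_Ca < 0 or self.total_Mg < 0:
            raise ConfigurationError("metal totals must be >= 0")
        if self.mode not in ("apparent-constants", "absolute-constants"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "absolute-constants" and not (4.0 <= self.pH <= 10.0):
            raise ConfigurationError("pH must be in [4, 10] for proton correction")

    def effective_kds(self) -> list[tuple[float, float | None]]:
        """Per-chelator (Kd_Ca, Kd_Mg) at the system pH, honoring the mode."""
        out = []
        for chel in self.chelators:
            if self.mode == "absolute-constants":
                kd_ca = apparent_kd(chel, self.pH)
                kd_mg = (
                    chel.Kd_Mg * (apparent_kd(chel, self.pH) / chel.Kd_Ca)
                    if chel.Kd_Mg is not None
                    else None
                )
            else:
                kd_ca, kd_mg = chel.Kd_Ca, chel.Kd_Mg
            out.append((kd_ca, kd_mg))
        return out


def apparent_kd(chelator: ChelatorSpec, pH: float) -> float:
    """pH-corrected apparent Kd from the absolute Kd and stepwise pKa values.

    Protonation competes with metal binding, so the apparent Kd grows as the
    pH drops:  Kd_app = Kd_abs * (1 + 10^(pKa1-pH) + 10^(pKa1+pKa2-2pH) + ...).
    """
    if chelator.proton_pKas is None:
        raise ConfigurationError(f"{chelator.name}: pKa list required in absolute mode")
    poly = 1.0
    cum = 0.0
    for j, pka in enumerate(chelator.proton_pKas, start=1):
        cum += pka
        poly += 10.0 ** (cum - j * pH)
    return chelator.Kd_Ca * poly


def _bound_fraction(free_ca: float, free_mg: float, kd_ca: float,
                    kd_mg: float | None) -> float:
    """Fraction of a chelator bound to Ca2+ under Ca/Mg competition."""
    x_ca = free_ca / kd_ca
    x_mg = free_mg / kd_mg if (kd_mg is not None and free_mg > 0) else 0.0
    return x_ca / (1.0 + x_ca + x_mg)


def _solve_free_mg(system: BufferSystem, free_ca: float,
                   kds: list[tuple[float, float | None]]) -> float:
    if system.total_Mg == 0:
        return 0.0

    def residual(free_mg: float) -> float:
        bound = sum(
            chel.total
            * (free_mg / kd_mg)
            / (1.0 + free_ca / kd_ca + free_mg / kd_mg)
            for chel, (kd_ca, kd_mg) in zip(system.chelators, kds)
            if kd_mg is not None
        )
        return free_mg + bound - system.total_Mg

    if residual(system.total_Mg) < 0:  # no Mg-binding chelators
        return system.total_Mg
    return brentq(residual, 0.0, system.total_Mg, xtol=1e-300, rtol=8.9e-16)


def free_ca(system: BufferSystem) -> tuple[CaConcentration | None, float | None]:
    """Free Ca2+ (and free Mg2+ when present) from total concentrations.

    Solves the coupled mass-balance equations by bracketed monotone root
    finding; the mass-balance residual is < 1e-12 relative at the solution.
    Returns (None, ...) when total Ca is zero (free Ca below any resolution).
    """
    kds = system.effective_kds()
    if system.total_Ca == 0:
        fmg = _solve_free_mg(system, 0.0, kds) if system.total_Mg else None
        return None, fmg
    if not system.chelators:
        return CaConcentration(system.total_Ca), (system.total_Mg or None)

    def residual(fca: float) -> float:
        fmg = _solve_free_mg(system, fca, kds)
        bound = sum(
            chel.total * _bound_fraction(fca, fmg, kd_ca, kd_mg)
            for chel, (kd_ca, kd_mg) in zip(system.chelators, kds)
        )
        return fca + bound - system.total_Ca

    lo = system.total_Ca * 1e-18
    if residual(lo) > 0 or residual(system.total_Ca) < 0:
        raise SolverError(
            f"cannot bracket free Ca in [{lo:g}, {system.total_Ca:g}] "
            f"(residuals {residual(lo):g}, {residual(system.total_Ca):g})"
        )
    fca = brentq(residual, lo, system.total_Ca, xtol=1e-300, rtol=8.9e-16)
    fmg = _solve_free_mg(system, fca, kds) if system.total_Mg else None
    return CaConcentration(fca), fmg


def total_ca_for_target(system: BufferSystem, target_free: CaConcentration | float) -> float:
    """Total Ca2+ needed to reach a target free Ca2+ (closed-form inverse).

    total = free + sum_i chelator_total_i * occupancy_i(free), with the
    occupancy including Mg2+ competition when Mg is present.  Round-trips
    through :func:`free_ca` to well below 0.1%.
    """
    free = target_free.value if isinstance(target_free, CaConcentration) else float(target_free)
    if not (free > 0):
        raise ConfigurationError("target free Ca must be > 0")
    kds = system.effective_kds()
    fmg = _solve_free_mg(system, free, kds)
    bound = sum(
        chel.total * _bound_fraction(free, fmg, kd_ca, kd_mg)
        for chel, (kd_ca, kd_mg) in zip(system.chelators, kds)
    )
    return free + bound


def pca_ladder(system: BufferSystem, pca_values) -> pd.DataFrame:
    """Total Ca2+ to add for each requested pCa; one row per ladder step.

    Failures are reported per row in the status column rather than aborting
    the whole ladder.
    """
    rows = []
    for pca in pca_values:
        target = 10.0 ** (-float(pca))
        try:
            total = total_ca_for_target(system, target)
            rows.append({"pCa": float(pca), "free_Ca_M": target,
                         "total_Ca_M": total, "status": "ok"})
        except (ConfigurationError, SolverError) as exc:
            rows.append({"pCa": float(pca), "free_Ca_M": target,
                         "total_Ca_M": math.nan, "status": f"error: {exc}"})
    return pd.DataFrame(rows)
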