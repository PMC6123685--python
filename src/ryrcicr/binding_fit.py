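"""Fitting of [3H]ryanodine binding curves to the biphasic CICR model.

Workflow mirrored here: bound ryanodine (B) measured over a pCa ladder is
normalized by the maximal number of functional channels (Bmax, from Scatchard
analysis of a 3-20 nM ryanodine saturation series); B/Bmax curves are then fit
to A = Amax * fA * (1 - fI) with the Hill coefficients nA, nI held fixed, one
shared (nA, nI) pair being chosen for a whole mutant panel by maximizing the
summed R2 of the fits.  Per-genotype summaries report pCa50 (A-site
half-activation), the caffeine-induced shift delta-pCa50, and the fold change
in modeled resting activity relative to wild type.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .model_core import (
    BindingModelParams,
    InvalidParameterError,
    activity,
    fold_change_at_rest,
)

#: lost-binding rule: curves whose largest mean B/Bmax falls below this level
#: (or below 3x the replicate noise) are reported "not-determined" rather than
#: fitted — mutants that abolish binding altogether have no meaningful pCa50.
LOST_BINDING_LEVEL = 0.01

STATUS_OK = "ok"
STATUS_NOT_DETERMINED = "not-determined"
STATUS_FIT_FAILED = "fit-failed"


class DegenerateDataError(ValueError):
    """Input data cannot support the requested analysis (e.g. no saturable binding)."""


class InvalidNormalizationError(ValueError):
    """Bmax used for normalization is not positive."""


@dataclass
class BindingCurve:
    """Replicate B/Bmax observations on a pCa grid for one genotype/condition.

    `data` is long-format with columns pCa, replicate, B.  `medium` records
    the assay medium: "0.17M-NaCl-Mg" (biphasic, physiological-like salt) or
    "1M-NaCl-noMg" (high salt, no Mg2+, which removes inactivation through the
    low-affinity Ca2+/Mg2+ site and yields monophasic curves).
    """

    genotype: str
    condition: str
    data: pd.DataFrame
    medium: str = "0.17M-NaCl-Mg"

    def __post_init__(self) -> None:
        missing = {"pCa", "replicate", "B"} - set(self.data.columns)
        if missing:
            raise ValueError(f"binding curve data missing columns {sorted(missing)}")
        if self.data["pCa"].nunique() < 5:
            raise ValueError("binding curve needs >= 5 distinct pCa points")
        if (self.data["B"] < 0).any():
            raise ValueError("bound values must be >= 0")

    @classmethod
    def from_replicate_matrix(
        cls,
        genotype: str,
        condition: str,
        pca: Sequence[float],
        B: np.ndarray,
        medium: str = "0.17M-NaCl-Mg",
    ) -> "BindingCurve":
        """Build from a (n_points, n_replicates) matrix of bound values."""
        B = np.atleast_2d(np.asarray(B, dtype=float))
        rows = [
            {"pCa": p, "replicate": j, "B": B[i, j]}
            for i, p in enumerate(pca)
            for j in range(B.shape[1])
        ]
        return cls(genotype, condition, pd.DataFrame(rows), medium)

    def means(self) -> pd.DataFrame:
        """Per-pCa mean, SEM and replicate count."""
        g = self.data.groupby("pCa")["B"]
        out = g.agg(["mean", "sem", "count"]).reset_index()
        return out.sort_values("pCa", ascending=False, ignore_index=True)


@dataclass
class SaturationSeries:
    """Ryanodine saturation series (free ligand nM vs bound) for Bmax analysis."""

    free_nM: np.ndarray
    bound: np.ndarray
    medium: str = "high-salt"

    def __post_init__(self) -> None:
        self.free_nM = np.asarray(self.free_nM, dtype=float)
        self.bound = np.asarray(self.bound, dtype=float)
        if self.free_nM.size < 3 or np.unique(self.free_nM).size < 3:
            raise ValueError("saturation series needs >= 3 distinct concentrations")
        if np.any(self.free_nM <= 0):
            raise ValueError("free ryanodine concentrations must be > 0")


@dataclass
class FitResult:
    """Outcome of fitting one binding curve."""

    genotype: str
    condition: str
    params: BindingModelParams | None
    pCa50: float | None
    stderr: dict[str, float | None] = field(default_factory=dict)
    r_squared: float | None = None
    converged: bool = False
    status: str = STATUS_FIT_FAILED
    n_points: int = 0

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK and self.converged


@dataclass
class SensitizationSummary:
    genotype: str
    pCa50_control: float | None
    pCa50_caffeine: float | None
    delta_pCa50: float | None
    resting_fold_vs_wt: float | None
    status: str = STATUS_OK


def scatchard_bmax(series: SaturationSeries) -> dict[str, float]:
    """Scatchard-plot estimate of Bmax and Kd from a saturation series.

    Regresses B/F on B: for single-site binding B/F = Bmax/Kd - B/Kd, so the
    slope is -1/Kd and the x-intercept is Bmax.  Returns Bmax (units of B),
    Kd (nM) and their standard errors (delta method for Bmax).
    """
    if np.any(series.bound <= 0):
        raise DegenerateDataError("Scatchard analysis requires bound > 0 at all points")
    x = series.bound
    y = series.bound / series.free_nM
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise DegenerateDataError(
            f"non-negative Scatchard slope ({fit.slope:.3g}): no saturable binding"
        )
    kd = -1.0 / fit.slope
    bmax = -fit.intercept / fit.slope
    kd_se = kd * kd * fit.stderr
    # var(-a/b) by first-order propagation, ignoring a,b covariance
    bmax_se = abs(bmax) * math.sqrt(
        (fit.intercept_stderr / fit.intercept) ** 2 + (fit.stderr / fit.slope) ** 2
    ) if fit.intercept != 0 else float("nan")
    return {"Bmax": bmax, "Kd_nM": kd, "Bmax_se": bmax_se, "Kd_se": kd_se,
            "r_squared": fit.rvalue**2}


def normalize_to_bmax(raw_B, Bmax: float):
    """Normalize bound values to Bmax; the result is the averaged-activity scale."""
    if not (Bmax > 0):
        raise InvalidNormalizationError(f"Bmax must be > 0, got {Bmax!r}")
    return np.asarray(raw_B, dtype=float) / Bmax


def _replicate_noise(curve: BindingCurve) -> float:
    """Pooled replicate SD across pCa points (0 when single-replicate)."""
    sds = curve.data.groupby("pCa")["B"].std(ddof=1).dropna()
    if sds.empty:
        return 0.0
    return float(np.sqrt(np.mean(sds.values**2)))


def _fit_once(
    pca: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    nA: float,
    nI: float,
    inactivation: bool,
    pka0: float,
    amax0: float,
) -> lmfit.minimizer.MinimizerResult:
    params = lmfit.Parameters()
    params.add("amax", value=max(amax0, 1e-6), min=1e-9, max=10.0)
    params.add("pka", value=pka0, min=2.0, max=9.0)
    if inactivation:
        params.add("pki", value=max(pka0 - 1.0, 0.5), min=0.0, max=9.0)

    ca = 10.0 ** (-pca)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        ki = 10.0 ** (-p["pki"].value) if inactivation else math.inf
        model = activity(
            BindingModelParams(
                Amax=p["amax"].value, KA=10.0 ** (-p["pka"].value),
                KI=ki, nA=nA, nI=nI,
            ),
            ca,
        )
        return (model - y) * weights

    return lmfit.minimize(residual, params, method="least_squares",
                          nan_policy="raise")


def fit_curve(
    curve: BindingCurve,
    nA: float = 2.0,
    nI: float = 1.0,
    inactivation: bool = True,
    use_means: bool = False,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Weighted nonlinear least-squares fit of the biphasic model to one curve.

    The Hill coefficients are held fixed; free parameters are Amax, KA and
    (when ``inactivation`` is on) KI, optimized in pK space with multi-start
    initialization: KA is started at every observed pCa grid point, Amax at
    the largest observed mean, KI one decade below KA.  The best start by SSE
    wins.  ``inactivation=False`` forces fI = 0 for the monophasic high-salt,
    no-Mg2+ medium.  By default every replicate point enters the fit; with
    ``use_means`` only the per-pCa means are fitted (published-figure
    emulation).
    """
    _require = [(nA, "nA"), (nI, "nI")]
    for v, name in _require:
        if not (v > 0):
            raise InvalidParameterError(f"{name} must be > 0, got {v!r}")

    table = curve.means() if use_means else curve.data
    pca = table["pCa"].to_numpy(dtype=float) if not use_means else table["pCa"].to_numpy()
    y = (table["mean"] if use_means else table["B"]).to_numpy(dtype=float)
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.sqrt(np.asarray(weights, dtype=float))

    result = FitResult(curve.genotype, curve.condition, params=None, pCa50=None,
                       n_points=y.size)

    means = curve.means()["mean"].to_numpy()
    noise = _replicate_noise(curve)
    if means.max() < max(LOST_BINDING_LEVEL, 3.0 * noise):
        result.status = STATUS_NOT_DETERMINED
        return result

    grid = np.unique(pca)
    amax0 = float(means.max())
    best = None
    for pka0 in grid:
        if not (2.0 < pka0 < 9.0):
            continue
        try:
            res = _fit_once(pca, y, w, nA, nI, inactivation, float(pka0), amax0)
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr - 1e-14):
            best = res
    if best is None:
        result.status = STATUS_FIT_FAILED
        return result

    p = best.params
    ki = 10.0 ** (-p["pki"].value) if inactivation else math.inf
    fitted = BindingModelParams(
        Amax=p["amax"].value, KA=10.0 ** (-p["pka"].value), KI=ki, nA=nA, nI=nI
    )
    ss_res = float(np.sum((best.residual / w) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    result.params = fitted
    result.pCa50 = fitted.pKA
    result.stderr = {
        "Amax": p["amax"].stderr,
        "pKA": p["pka"].stderr,
        "pKI": p["pki"].stderr if inactivation else None,
    }
    result.r_squared = r2
    result.converged = True
    result.status = STATUS_OK
    return result


def select_hill_coefficients(
    curves: Sequence[BindingCurve],
    grid_nA: Sequence[float] = (1.0, 1.5, 2.0, 2.5, 3.0),
    grid_nI: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
    inactivation: bool = True,
) -> tuple[float, float, pd.DataFrame]:
    """Choose one shared (nA, nI) pair for a curve panel by maximizing sum(R2).

    Every curve is fitted at every candidate pair; the pair with the largest
    summed R2 across curves wins, ties broken toward the smaller coefficients.
    Returns (nA, nI, table of summed R2 per pair).
    """
    if not curves:
        raise ValueError("need at least one curve")
    if not grid_nA or not grid_nI:
        raise ValueError("candidate grids must be non-empty")
    rows = []
    best = None
    for na, ni in itertools.product(sorted(grid_nA), sorted(grid_nI)):
        total, n_ok = 0.0, 0
        for curve in curves:
            fit = fit_curve(curve, nA=na, nI=ni, inactivation=inactivation)
            if fit.ok:
                total += fit.r_squared
                n_ok += 1
        rows.append({"nA": na, "nI": ni, "sum_r2": total, "n_fitted": n_ok})
        if n_ok and (best is None or total > best[2] + 1e-12):
            best = (na, ni, total)
    if best is None:
        raise DegenerateDataError("all fits failed at every (nA, nI) grid point")
    return best[0], best[1], pd.DataFrame(rows)


def sensitization_table(
    fits: Sequence[FitResult],
    wt_label: str = "WT",
    control_label: str = "control",
    caffeine_label: str = "caffeine-10mM",
    rest_pca: float = 7.0,
) -> list[SensitizationSummary]:
    """Per-genotype caffeine-sensitization and resting-activity summary.

    delta_pCa50 = pCa50(caffeine) - pCa50(control); resting_fold_vs_wt compares
    each genotype's control fit with the wild-type control fit at pCa 7.
    Rows whose fits did not converge carry the propagated status with numeric
    fields absent (None), never a silent zero.
    """
    by_key = {(f.genotype, f.condition): f for f in fits}
    wt = by_key.get((wt_label, control_label))
    if wt is None or not wt.ok:
        raise DegenerateDataError(f"wild-type control fit ({wt_label!r}) missing or failed")

    out = []
    for genotype in dict.fromkeys(f.genotype for f in fits):
        ctrl = by_key.get((genotype, control_label))
        caf = by_key.get((genotype, caffeine_label))
        p_ctrl = ctrl.pCa50 if ctrl and ctrl.ok else None
        p_caf = caf.pCa50 if caf and caf.ok else None
        delta = p_caf - p_ctrl if (p_ctrl is not None and p_caf is not None) else None
        fold = (
            fold_change_at_rest(wt.params, ctrl.params, pCa=rest_pca)
            if ctrl and ctrl.ok
            else None
        )
        statuses = [f.status for f in (ctrl, caf) if f is not None]
        status = STATUS_OK if all(s == STATUS_OK for s in statuses) else ";".join(
            s for s in statuses if s != STATUS_OK
        )
        out.append(
            SensitizationSummary(
                genotype=genotype,
                pCa50_control=p_ctrl,
                pCa50_caffeine=p_caf,
                delta_pCa50=delta,
                resting_fold_vs_wt=fold,
                status=status or STATUS_OK,
            )
        )
    return out
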