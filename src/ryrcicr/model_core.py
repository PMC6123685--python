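"""Biphasic Ca2+-dependence model of CICR activity.

Ryanodine receptors (RyRs) open in response to cytoplasmic Ca2+ binding at a
high-affinity activating site (A-site) and close again at higher Ca2+ through
a low-affinity inactivating site (I-site).  [3H]ryanodine binding, which
reports the open channel, therefore traces a bell-shaped ("biphasic") curve
over pCa.  The model used throughout this package is

    A([Ca2+]) = Amax * fA * (1 - fI)

with Hill occupancies

    fA = [Ca2+]^nA / ([Ca2+]^nA + KA^nA)
    fI = [Ca2+]^nI / ([Ca2+]^nI + KI^nI)

where KA and KI are dissociation constants (mol/L) and nA, nI are Hill
coefficients.  All concentrations are stored in mol/L; pCa = -log10([Ca2+])
is a derived view.  Hill fractions are evaluated in log space (logistic form)
so that extreme pCa values neither overflow nor underflow.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit


class InvalidParameterError(ValueError):
    """A model parameter or concentration violates its positivity constraint."""


class DivisionUndefinedError(ZeroDivisionError):
    """A ratio against a zero reference activity was requested."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)) or np.any(np.asarray(value) <= 0):
            raise InvalidParameterError(
                f"{name} must be finite and > 0, got {value!r}"
            )


@dataclass(frozen=True)
class CaConcentration:
    """A free Ca2+ concentration in mol/L, with pCa as a derived view."""

    value: float

    def __post_init__(self) -> None:
        _require_positive(value=self.value)

    @property
    def pCa(self) -> float:
        return -math.log10(self.value)

    @classmethod
    def from_pca(cls, pca: float) -> "CaConcentration":
        return cls(10.0 ** (-pca))


@dataclass(frozen=True)
class BindingModelParams:
    """Parameter set of the biphasic activity model.

    Amax is the gain on the B/Bmax scale (dimensionless); KA and KI are the
    A-site and I-site dissociation constants in mol/L; nA and nI are the
    corresponding Hill coefficients.
    """

    Amax: float
    KA: float
    KI: float
    nA: float
    nI: float

    def __post_init__(self) -> None:
        if self.Amax < 0 or not np.isfinite(self.Amax):
            raise InvalidParameterError(f"Amax must be >= 0, got {self.Amax!r}")
        _require_positive(KA=self.KA, nA=self.nA, nI=self.nI)
        if not (self.KI > 0):  # allow KI = inf (no inactivation)
            raise InvalidParameterError(f"KI must be > 0, got {self.KI!r}")

    @property
    def pKA(self) -> float:
        return -math.log10(self.KA)

    @property
    def pKI(self) -> float:
        return -math.log10(self.KI)

    @classmethod
    def from_pk(
        cls, Amax: float, pKA: float, pKI: float, nA: float = 2.0, nI: float = 1.0
    ) -> "BindingModelParams":
        return cls(Amax=Amax, KA=10.0 ** (-pKA), KI=10.0 ** (-pKI), nA=nA, nI=nI)

    def replace(self, **changes: float) -> "BindingModelParams":
        return replace(self, **changes)

    # pK notation in files, mol/L internally
    def to_json(self) -> str:
        return json.dumps(
            {"Amax": self.Amax, "pKA": self.pKA, "pKI": self.pKI,
             "nA": self.nA, "nI": self.nI}
        )

    @classmethod
    def from_json(cls, text: str) -> "BindingModelParams":
        record = json.loads(text)
        return cls.from_pk(
            Amax=record["Amax"], pKA=record["pKA"], pKI=record["pKI"],
            nA=record["nA"], nI=record["nI"],
        )


def _ca_value(ca) -> np.ndarray | float:
    if isinstance(ca, CaConcentration):
        return ca.value
    arr = np.asarray(ca, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"[Ca2+] must be finite and > 0, got {ca!r}")
    return arr if arr.ndim else float(arr)


def hill_fraction(ca, K: float, n: float):
    """Occupied fraction ca^n / (ca^n + K^n) of a Hill binding site.

    Evaluated as the logistic expit(n * ln(ca/K)), which is exact and immune
    to overflow/underflow at extreme pCa.  `ca` may be a float, an ndarray,
    or a :class:`CaConcentration`.
    """
    _require_positive(K=K, n=n)
    c = _ca_value(ca)
    return expit(n * (np.log(c) - math.log(K)))


def activity(params: BindingModelParams, ca):
    """Model activity A = Amax * fA * (1 - fI) on the B/Bmax scale."""
    c = _ca_value(ca)
    fA = hill_fraction(c, params.KA, params.nA)
    if math.isinf(params.KI):
        one_minus_fI = 1.0
    else:
        # 1 - fI computed directly as the complementary logistic (no cancellation)
        one_minus_fI = expit(-params.nI * (np.log(c) - math.log(params.KI)))
    return params.Amax * fA * one_minus_fI


def pca50(params: BindingModelParams) -> float:
    """pCa of half-maximal activation, defined as the A-site half-point -log10(KA).

    With the Hill coefficients fixed during fitting, fA reaches 0.5 exactly at
    [Ca2+] = KA, so the fitted KA is the natural pCa50 readout.  For the
    half-point of the composite biphasic curve use :func:`pca50_composite`.
    """
    return params.pKA


def pca50_composite(params: BindingModelParams, pca_range=(12.0, 1.0)) -> float:
    """pCa at which the composite curve A reaches half of its own maximum.

    The half-point is taken on the rising (low-Ca2+) limb of the bell-shaped
    curve.  Differs slightly from -log10(KA) when KI is close to KA.
    """
    if params.Amax == 0:
        raise InvalidParameterError("composite half-point undefined for Amax = 0")
    hi, lo = pca_range
    grid = np.linspace(hi, lo, 2201)
    a = activity(params, 10.0 ** (-grid))
    imax = int(np.argmax(a))
    half = a[imax] / 2.0

    def f(pca: float) -> float:
        return activity(params, 10.0 ** (-pca)) - half

    return brentq(f, hi, grid[imax], xtol=1e-12)


def resting_activity(params: BindingModelParams, pCa: float = 7.0) -> float:
    """Model activity at resting cytoplasmic Ca2+ (default pCa 7, i.e. 100 nM)."""
    return float(activity(params, 10.0 ** (-pCa)))


def fold_change_at_rest(
    wt: BindingModelParams, mut: BindingModelParams, pCa: float = 7.0
) -> float:
    """Ratio of mutant to wild-type resting activity at the stated pCa.

    For a pure A-site affinity shift (KA_mut = KA_wt / r, all else shared) and
    resting Ca2+ far below both KA values, the ratio approaches r**nA — the
    lever by which modest sensitivity shifts produce large changes in resting
    channel leak.
    """
    denom = resting_activity(wt, pCa)
    if denom == 0:
        raise DivisionUndefinedError("wild-type resting activity is zero")
    return resting_activity(mut, pCa) / denom
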