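"""Thermodynamic identities and regressions for host-guest binding.

Energies are in kcal/mol throughout; temperatures in kelvin; heat
capacities reported in cal/(mol K), following the mixed convention
common in the calorimetry literature.  The central identities are

    dG = dH - T*dS            (stored here as dG = dH + mTdS)
    Ka = exp(-dG / (R*T))
    dCp = d(dH)/dT            (slope of a linear enthalpy model)

and the regressions implemented are the enthalpy-entropy compensation
fit (T*dS vs dH across complexes at one temperature) and the
affinity-vs-hydrogen-bond fit (dG vs net hydrogen bonds gained on
binding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "R_KCAL",
    "BindingThermo",
    "HeatCapacityFit",
    "RegressionResult",
    "AgreementMetrics",
    "free_energy_from_affinity",
    "affinity_from_free_energy",
    "entropy_term",
    "fit_heat_capacity",
    "extrapolate_thermo",
    "compensation_regression",
    "affinity_hbond_regression",
    "agreement_metrics",
]

#: Gas constant in kcal/(mol K).
R_KCAL = 1.987204e-3

_IDENTITY_TOL = 1e-9


@dataclass(frozen=True)
class BindingThermo:
    """Binding thermodynamics of one complex at one temperature.

    ``mTdS`` is the entropic term -T*dS in kcal/mol, so that
    ``dG = dH + mTdS`` holds exactly.  ``Ka`` (per molar), when given,
    must be consistent with ``dG = -R*T*ln(Ka)``.
    """

    complex_id: str
    T: float
    dG: float
    dH: float
    mTdS: float
    Ka: float | None = None
    dG_err: float | None = None
    dH_err: float | None = None
    mTdS_err: float | None = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        if abs(self.dG - (self.dH + self.mTdS)) > _IDENTITY_TOL:
            raise ValueError(
                f"dG = dH + (-TdS) violated: {self.dG} != {self.dH} + {self.mTdS}"
            )
        if self.Ka is not None:
            if self.Ka <= 0:
                raise ValueError("Ka must be positive")
            if abs(self.dG - free_energy_from_affinity(self.Ka, self.T)) > _IDENTITY_TOL:
                raise ValueError("dG inconsistent with -R*T*ln(Ka)")

    @classmethod
    def from_free_energy_and_enthalpy(
        cls, complex_id: str, T: float, dG: float, dH: float, **kw
    ) -> "BindingThermo":
        """Construct with mTdS = dG - dH (the difference convention)."""
        return cls(complex_id=complex_id, T=T, dG=dG, dH=dH, mTdS=dG - dH, **kw)

    @property
    def TdS(self) -> float:
        return -self.mTdS


@dataclass(frozen=True)
class HeatCapacityFit:
    """Linear dH(T) fit: dCp is the slope in cal/(mol K)."""

    dCp: float
    dH_ref: float
    T_ref: float
    stderr_slope: float
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("heat-capacity fit needs >= 2 temperatures")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 out of [0, 1]: {self.r2}")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    stderr_slope: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("regression needs >= 2 points")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 out of [0, 1]: {self.r2}")


@dataclass(frozen=True)
class AgreementMetrics:
    """Calculation-vs-experiment agreement with bootstrap CIs."""

    rmse: float
    mse: float
    r2: float
    ci95_rmse: tuple[float, float]
    ci95_r2: tuple[float, float]
    n_pairs: int

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")
        if self.rmse + 1e-12 < abs(self.mse):
            raise ValueError("rmse cannot be smaller than |mean signed error|")


def free_energy_from_affinity(Ka: float, T: float) -> float:
    """Binding free energy dG = -R*T*ln(Ka), kcal/mol."""
    if Ka <= 0:
        raise ValueError(f"Ka must be positive, got {Ka}")
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    return -R_KCAL * T * math.log(Ka)


def affinity_from_free_energy(dG: float, T: float) -> float:
    """Association constant Ka = exp(-dG / (R*T)), per molar."""
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    return math.exp(-dG / (R_KCAL * T))


def entropy_term(dG: float, dH: float) -> float:
    """Entropic term -T*dS = dG - dH, kcal/mol."""
    return dG - dH


def _ols(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None):
    """Weighted or ordinary least squares of y on x.

    Returns (slope, intercept, r2, stderr_slope).  r2 is the squared
    (weighted) Pearson correlation, identical to the coefficient of
    determination of the fitted line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: no variance in x")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    W = np.sum(w)
    xm, ym = np.sum(w * x) / W, np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    sxy = np.sum(w * (x - xm) * (y - ym))
    syy = np.sum(w * (y - ym) ** 2)
    slope = sxy / sxx
    intercept = ym - slope * xm
    # constant y is fit exactly by the zero-slope line: r2 := 1 by convention
    r2 = 1.0 if syy == 0 else sxy**2 / (sxx * syy)
    dof = x.size - 2
    if dof > 0:
        resid = y - slope * x - intercept
        s2 = np.sum(w * resid**2) / dof
        stderr = math.sqrt(s2 / sxx)
    else:
        stderr = float("nan")
    return slope, intercept, r2, stderr


def fit_heat_capacity(
    temps: Sequence[float],
    dH: Sequence[float],
    T_ref: float = 298.0,
    dH_err: Sequence[float] | None = None,
) -> HeatCapacityFit:
    """Fit dH(T) linearly; the slope is the heat-capacity change.

    Parameters
    ----------
    temps, dH:
        Temperatures (K) and binding enthalpies (kcal/mol) at >= 2
        distinct temperatures.
    T_ref:
        Reference temperature at which the fitted line is evaluated to
        give ``dH_ref``.
    dH_err:
        Optional per-point standard deviations; if given the fit is
        inverse-variance weighted.

    Returns
    -------
    HeatCapacityFit with ``dCp`` in cal/(mol K) (slope x 1000).
    """
    t = np.asarray(temps, dtype=float)
    h = np.asarray(dH, dtype=float)
    if t.size != h.size:
        raise ValueError("temps and dH must have equal length")
    if np.unique(t).size < 2:
        raise ValueError("need >= 2 distinct temperatures")
    w = None if dH_err is None else 1.0 / np.asarray(dH_err, dtype=float) ** 2
    slope, intercept, r2, stderr = _ols(t, h, w)
    return HeatCapacityFit(
        dCp=slope * 1000.0,
        dH_ref=slope * T_ref + intercept,
        T_ref=T_ref,
        stderr_slope=stderr * 1000.0,
        r2=min(r2, 1.0),
        n_points=int(t.size),
    )


def extrapolate_thermo(ref: BindingThermo, dCp: float, T: float) -> BindingThermo:
    """Propagate a binding-thermodynamics record to temperature T.

    Integrates dH/dT = Cp and dS/dT = Cp/T with constant dCp
    (cal/(mol K)) around the reference state:

        dH(T)  = dH_ref + dCp*(T - T_ref)
        S(T)   = S_ref + dCp*ln(T/T_ref)
        dG(T)  = dH(T) - T*S(T)
    """
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    if T == ref.T:
        return ref
    cp_kcal = dCp / 1000.0
    dH = ref.dH + cp_kcal * (T - ref.T)
    S_ref = ref.TdS / ref.T  # entropy change in kcal/(mol K)
    S = S_ref + cp_kcal * math.log(T / ref.T)
    mTdS = -T * S
    thermo = BindingThermo(
        complex_id=ref.complex_id, T=T, dG=dH + mTdS, dH=dH, mTdS=mTdS
    )
    return replace(thermo, Ka=affinity_from_free_energy(thermo.dG, T))


def compensation_regression(
    dH: Sequence[float],
    mTdS: Sequence[float],
    dH_err: Sequence[float] | None = None,
) -> RegressionResult:
    """Enthalpy-entropy compensation fit: T*dS (y) against dH (x).

    A slope near 1 with high r2 indicates near-complete compensation
    (dG nearly invariant across complexes).
    """
    x = np.asarray(dH, dtype=float)
    y = -np.asarray(mTdS, dtype=float)  # T*dS
    if x.size < 3:
        raise ValueError("compensation fit needs >= 3 complexes")
    w = None if dH_err is None else 1.0 / np.asarray(dH_err, dtype=float) ** 2
    slope, intercept, r2, stderr = _ols(x, y, w)
    return RegressionResult(slope, intercept, min(r2, 1.0), stderr, int(x.size))


def affinity_hbond_regression(
    dG: Sequence[float],
    n_hbonds: Sequence[float],
    exclude: Sequence[int] = (),
) -> RegressionResult:
    """Regress binding free energy on net hydrogen bonds gained.

    ``exclude`` lists indices dropped before fitting (used to remove
    outlier complexes).  The slope is the apparent free energy per
    added hydrogen bond, kcal/mol.
    """
    dG = np.asarray(dG, dtype=float)
    n = np.asarray(n_hbonds, dtype=float)
    if dG.size != n.size:
        raise ValueError("dG and n_hbonds must have equal length")
    keep = np.ones(dG.size, dtype=bool)
    keep[list(exclude)] = False
    if keep.sum() < 3:
        raise ValueError("need >= 3 retained points")
    slope, intercept, r2, stderr = _ols(n[keep], dG[keep])
    return RegressionResult(slope, intercept, min(r2, 1.0), stderr, int(keep.sum()))


def agreement_metrics(
    calc: Sequence[float],
    exp: Sequence[float],
    n_boot: int = 10_000,
    seed: int | None = None,
) -> AgreementMetrics:
    """RMSE, mean signed error and r2 of calculated vs experimental values.

    Confidence intervals are 95% percentile intervals from paired
    case-resampling bootstrap with ``n_boot`` replicates.  r2 is the
    squared Pearson correlation of the calc/exp scatter.
    """
    c = np.asarray(calc, dtype=float)
    e = np.asarray(exp, dtype=float)
    if c.size != e.size:
        raise ValueError("calc and exp must have equal length")
    if c.size < 2:
        raise ValueError("need >= 2 pairs")
    diff = c - e

    def _r2(a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return 1.0 if np.allclose(a - a.mean(), b - b.mean()) else 0.0
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    rmse = float(np.sqrt(np.mean(diff**2)))
    mse = float(np.mean(diff))
    r2 = _r2(c, e)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, c.size, size=(n_boot, c.size))
    boot_rmse = np.sqrt(np.mean(diff[idx] ** 2, axis=1))
    boot_r2 = np.array([_r2(c[i], e[i]) for i in idx])
    ci_rmse = tuple(np.percentile(boot_rmse, [2.5, 97.5]))
    ci_r2 = tuple(np.percentile(boot_r2, [2.5, 97.5]))
    return AgreementMetrics(rmse, mse, r2, ci_rmse, ci_r2, int(c.size))
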