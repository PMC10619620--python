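"""Single-site ITC titration modelling and fitting.

An isothermal titration calorimetry experiment injects titrant from a
syringe into a perfusion cell of fixed volume V0 and records the
differential power needed to keep cell and reference isothermal.
Integrating each injection peak gives a per-injection heat; the heat
sequence (the Wiseman isotherm for 1:1 binding) is fit for the
association constant Ka, binding enthalpy dH, stoichiometry n, and a
constant per-injection dilution heat.

Concentration bookkeeping uses the standard displacement convention
for an overfilled cell: each injection of volume dV displaces an equal
volume, diluting everything already in the cell by (1 - dV/V0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .thermo import BindingThermo, free_energy_from_affinity

__all__ = [
    "TitrationSetup",
    "Thermogram",
    "InjectionHeats",
    "ItcFit",
    "integrate_peaks",
    "predict_heats",
    "fit_titration",
]

KCAL_TO_UCAL = 1e9


@dataclass(frozen=True)
class TitrationSetup:
    """Cell/syringe composition and injection schedule.

    cell_conc is the macromolecule (host or guest) placed in the cell;
    syringe_conc is the titrant.  Volumes in litres, concentrations
    molar.
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injection_volumes: tuple[float, ...]
    T: float = 298.15
    titrand_role: Literal["host", "guest"] = "host"

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if len(self.injection_volumes) < 2:
            raise ValueError("need >= 2 injections")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be positive")
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def concentrations(self, n: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Total cell-species and titrant concentrations after each injection.

        Applies the displacement dilution factor (1 - dV/V0) to the cell
        contents; freshly injected titrant is treated as fully mixed.
        """
        V0 = self.cell_volume
        M = np.empty(self.n_injections)
        X = np.empty(self.n_injections)
        m, x = self.cell_conc, 0.0
        for i, dV in enumerate(self.injection_volumes):
            d = 1.0 - dV / V0
            m *= d
            x = x * d + self.syringe_conc * dV / V0
            M[i], X[i] = m, x
        return M, X


@dataclass(frozen=True)
class Thermogram:
    """Raw differential-power trace with injection times."""

    time: np.ndarray          # s, strictly increasing
    power: np.ndarray         # ucal/s
    injection_times: np.ndarray  # s

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.power, dtype=float)
        ti = np.asarray(self.injection_times, dtype=float)
        if t.size != p.size:
            raise ValueError("time and power must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if ti.min() < t[0] or ti.max() > t[-1]:
            raise ValueError("injection times outside the recorded trace")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "power", p)
        object.__setattr__(self, "injection_times", ti)


@dataclass(frozen=True)
class InjectionHeats:
    """Per-injection integrated heats in ucal."""

    heats: np.ndarray
    baseline: str = "model"

    def __post_init__(self) -> None:
        object.__setattr__(self, "heats", np.asarray(self.heats, dtype=float))

    def __len__(self) -> int:
        return self.heats.size


@dataclass(frozen=True)
class ItcFit:
    Ka: float
    dH: float
    n: float
    q_dil: float
    residual_norm: float
    Ka_err: float = float("nan")
    dH_err: float = float("nan")
    n_err: float = float("nan")
    q_dil_err: float = float("nan")

    def __post_init__(self) -> None:
        if self.Ka <= 0 or self.n <= 0:
            raise ValueError("Ka and n must be positive")

    def binding_thermo(self, setup: TitrationSetup, complex_id: str = "fit") -> BindingThermo:
        dG = free_energy_from_affinity(self.Ka, setup.T)
        return BindingThermo(
            complex_id=complex_id, T=setup.T, dG=dG, dH=self.dH,
            mTdS=dG - self.dH, Ka=self.Ka,
        )


def integrate_peaks(
    tg: Thermogram,
    window: float,
    baseline: Literal["linear", "median"] = "linear",
    quiescent_fraction: float = 0.2,
) -> InjectionHeats:
    """Integrate baseline-subtracted power over each injection window.

    The heat of injection i is the trapezoidal integral of
    (power - baseline) over [t_i, t_i + window].  The linear baseline
    interpolates anchor points taken as the median power over the
    quiescent tail (last ``quiescent_fraction`` of the inter-injection
    gap) preceding each injection, plus the tail after the final
    window.  If a quiescent segment contains no samples the global
    median is used instead, with a warning.
    """
    t_inj = tg.injection_times
    if np.any(np.diff(t_inj) <= window):
        raise ValueError("injection windows overlap: spacing must exceed window")
    t, p = tg.time, tg.power

    anchors_t, anchors_p = [], []
    bounds = np.concatenate([[t[0]], t_inj, [t[-1]]])
    missing = False
    for i in range(len(t_inj) + 1):
        seg_start = bounds[i] if i == 0 else bounds[i] + window
        seg_end = bounds[i + 1]
        lo = seg_end - quiescent_fraction * max(seg_end - seg_start, 0.0)
        mask = (t >= max(lo, seg_start)) & (t <= seg_end)
        if mask.sum() >= 1:
            anchors_t.append(0.5 * (max(lo, seg_start) + seg_end))
            anchors_p.append(float(np.median(p[mask])))
        else:
            missing = True
    if missing or len(anchors_t) < 2 or baseline == "median":
        if missing:
            warnings.warn(
                "missing quiescent segment; falling back to global median baseline"
            )
        base = np.full_like(p, float(np.median(p)))
    else:
        base = np.interp(t, anchors_t, anchors_p)

    heats = np.empty(len(t_inj))
    for i, ti in enumerate(t_inj):
        mask = (t >= ti) & (t <= ti + window)
        heats[i] = np.trapezoid((p - base)[mask], t[mask])
    return InjectionHeats(heats=heats, baseline=baseline)


def _bound_concentration(A: np.ndarray, B: np.ndarray, Ka: float) -> np.ndarray:
    """Exact 1:1 equilibrium bound concentration from the quadratic root."""
    s = A + B + 1.0 / Ka
    disc = s * s - 4.0 * A * B
    if np.any(disc < 0):
        raise FloatingPointError("negative discriminant in binding quadratic")
    return 0.5 * (s - np.sqrt(disc))


def predict_heats(
    setup: TitrationSetup,
    Ka: float,
    dH: float,
    n: float = 1.0,
    q_dil: float = 0.0,
) -> InjectionHeats:
    """Exact 1:1 isotherm: incremental heat per injection, ucal.

    heat_i = dH * V0 * (b_i - b_{i-1}*(1 - dV_i/V0)) + q_dil, with b the
    bound concentration from the mass-action quadratic and n scaling the
    cell-species concentration (effective binding-site concentration).
    """
    if Ka <= 0 or n <= 0:
        raise ValueError("Ka and n must be positive")
    M, X = setup.concentrations()
    b = _bound_concentration(n * M, X, Ka)
    V0 = setup.cell_volume
    d = 1.0 - np.asarray(setup.injection_volumes) / V0
    b_prev = np.concatenate([[0.0], b[:-1]])
    heats = dH * KCAL_TO_UCAL * V0 * (b - b_prev * d) + q_dil
    return InjectionHeats(heats=heats)


def c_value(setup: TitrationSetup, Ka: float, n: float = 1.0) -> float:
    """Wiseman c parameter n*Ka*[cell]; isotherms are sigmoidal for c in ~[1, 1000]."""
    return n * Ka * setup.cell_conc


def _heuristic_init(heats: np.ndarray, setup: TitrationSetup) -> np.ndarray:
    """Initial (log Ka, dH, n, q_dil) from the shape of the isotherm."""
    M, X = setup.concentrations()
    ratio = X / M
    moles = setup.syringe_conc * np.asarray(setup.injection_volumes)
    per_mole = heats / moles  # kcal/mol-scale after unit conversion
    q_dil0 = float(heats[-1]) if heats.size >= 2 else 0.0
    dh0 = float(np.mean(per_mole[:2])) / KCAL_TO_UCAL
    if dh0 == 0:
        dh0 = -1.0
    # inflection: steepest change of per-injection heat
    k = int(np.argmax(np.abs(np.diff(heats)))) + 1
    n0 = float(np.clip(ratio[k], 0.2, 5.0))
    ka0 = 10.0 / setup.cell_conc  # c ~ 10 as a generic starting sharpness
    return np.array([np.log(ka0), dh0, n0, q_dil0])


def fit_titration(
    heats: InjectionHeats | Sequence[float],
    setup: TitrationSetup,
    init: Sequence[float] | None = None,
    fix_n: float | None = None,
    discard_first: bool = True,
) -> ItcFit:
    """Nonlinear least-squares fit of the 1:1 isotherm.

    Parameters
    ----------
    heats:
        Per-injection heats (ucal), length matching the setup schedule.
    init:
        Optional explicit (Ka, dH, n, q_dil) start; otherwise a shape
        heuristic is used.
    fix_n:
        If given, the stoichiometry is held at this value.
    discard_first:
        Drop the first injection from the residuals (common practice:
        the first aliquot is corrupted by diffusion across the syringe
        tip).  The concentration bookkeeping still includes it.

    Returns an :class:`ItcFit`; standard errors come from the Jacobian
    at the solution.
    """
    q = np.asarray(heats.heats if isinstance(heats, InjectionHeats) else heats, float)
    if q.size != setup.n_injections:
        raise ValueError("number of heats does not match injection schedule")
    informative = q.size - (1 if discard_first else 0)
    if informative < 4:
        raise ValueError("need >= 4 informative injections")

    if init is not None:
        ka0, dh0, n0, qd0 = init
        x0 = np.array([np.log(ka0), dh0, n0, qd0])
    else:
        x0 = _heuristic_init(q, setup)
    if fix_n is not None:
        x0 = np.array([x0[0], x0[1], x0[3]])

    w = np.ones(q.size)
    if discard_first:
        w[0] = 0.0

    def unpack(x):
        if fix_n is not None:
            return np.exp(x[0]), x[1], fix_n, x[2]
        return np.exp(x[0]), x[1], x[2], x[3]

    def resid(x):
        Ka, dH, n, qd = unpack(x)
        model = predict_heats(setup, Ka, dH, n, qd).heats
        return w * (model - q)

    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(f"ITC fit did not converge: {sol.message}")
    Ka, dH, n, qd = unpack(sol.x)

    cv = c_value(setup, Ka, n)
    if cv < 0.1:
        warnings.warn(f"flat isotherm (c = {cv:.3g} < 0.1): Ka is unreliable")
    elif not (1.0 <= cv <= 1000.0):
        warnings.warn(f"c value {cv:.3g} outside the well-conditioned range [1, 1000]")

    # covariance from the Jacobian; delta-method for Ka = exp(logKa)
    dof = informative - sol.x.size
    errs = np.full(sol.x.size, np.nan)
    if dof > 0:
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * 2 * sol.cost / dof
            errs = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            pass
    if fix_n is not None:
        ka_err, dh_err, qd_err = errs
        n_err = 0.0
    else:
        ka_err, dh_err, n_err, qd_err = errs
    return ItcFit(
        Ka=Ka, dH=dH, n=n, q_dil=qd,
        residual_norm=float(np.sqrt(2 * sol.cost)),
        Ka_err=Ka * ka_err, dH_err=dh_err, n_err=n_err, q_dil_err=qd_err,
    )
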