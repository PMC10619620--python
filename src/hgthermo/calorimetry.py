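"""Computational calorimetry: binding enthalpy from end-state simulations.

For a liquid at 1 atm the pressure-volume work on binding is
negligible, so the binding enthalpy is the change in mean potential
energy between end states:

    dH = <U>_complex - <U>_free_host - <U>_free_guest + bulk correction

where the bulk correction balances the water counts of the four
ensembles using the mean per-water energy of a neat-water simulation.
Because the force field is pairwise additive, the same arithmetic can
be applied per labelled component, giving two exact partitions:

* molecular:  dH = dH_HG + dH_desolv, where dH_HG collects every term
  involving only host/guest atoms (H-G interaction plus intra-solute
  reorganization) and dH_desolv every term involving water;
* force-field:  dH = dH_LJ + dH_elec + dH_valence.

Fitting each channel's dH(T) across temperatures splits the binding
heat-capacity change into the same channels (OLS is linear, so the
channel slopes add up to the total slope exactly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .thermo import HeatCapacityFit, fit_heat_capacity

__all__ = [
    "GROUP_PAIRS",
    "FF_TERMS",
    "SOLUTE_PAIRS",
    "WATER_PAIRS",
    "EnergyComponentSeries",
    "EnthalpyDecomposition",
    "CpDecomposition",
    "block_mean",
    "binding_enthalpy",
    "decompose_forcefield",
    "heat_capacity_profile",
]

GROUP_PAIRS = ("H-G", "H-W", "G-W", "W-W", "intra_H", "intra_G")
FF_TERMS = ("LJ", "elec", "valence")
#: channels involving only host/guest atoms -> dH_HG
SOLUTE_PAIRS = ("H-G", "intra_H", "intra_G")
#: channels involving water -> dH_desolv
WATER_PAIRS = ("H-W", "G-W", "W-W")
ENSEMBLES = ("complex", "free_host", "free_guest", "bulk_water")


@dataclass(frozen=True)
class EnergyComponentSeries:
    """Per-frame potential-energy components of one simulation ensemble.

    ``data`` has one row per frame and one column per component,
    labelled ``"<group_pair>:<ff_term>"`` (e.g. ``"H-W:elec"``).
    Components that do not exist in an ensemble (a free guest has no
    H-W term) are simply absent.
    """

    data: pd.DataFrame
    T: float
    ensemble_id: str
    n_waters: int = 0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.ensemble_id not in ENSEMBLES:
            raise ValueError(f"unknown ensemble_id {self.ensemble_id!r}")
        for col in self.data.columns:
            pair, _, term = col.partition(":")
            if pair not in GROUP_PAIRS or term not in FF_TERMS:
                raise ValueError(f"component label {col!r} outside the vocabulary")
        if self.n_waters < 0:
            raise ValueError("n_waters must be non-negative")

    @property
    def total(self) -> pd.Series:
        """Total potential energy per frame."""
        return self.data.sum(axis=1)

    def component_means(self) -> dict[str, float]:
        return {c: float(self.data[c].mean()) for c in self.data.columns}

    @classmethod
    def from_csv(cls, path, T: float, ensemble_id: str, n_waters: int = 0):
        return cls(pd.read_csv(path), T=T, ensemble_id=ensemble_id, n_waters=n_waters)


@dataclass(frozen=True)
class EnthalpyDecomposition:
    """Binding enthalpy and its exact partitions, kcal/mol."""

    dH_total: float
    dH_HG: float
    dH_desolv: float
    ff_terms: dict[str, float | None]       # LJ / elec / valence deltas
    group_pairs: dict[str, float]           # per group-pair deltas (bulk corr in W-W)
    se_total: float
    T: float

    def __post_init__(self) -> None:
        if abs(self.dH_HG + self.dH_desolv - self.dH_total) > 1e-9:
            raise ValueError("molecular partition does not sum to the total")
        present = [v for v in self.ff_terms.values() if v is not None]
        if abs(sum(present) - self.dH_total) > 1e-9:
            raise ValueError("force-field partition does not sum to the total")


@dataclass(frozen=True)
class CpDecomposition:
    """Heat-capacity change split across decomposition channels, cal/(mol K)."""

    total: HeatCapacityFit
    channels: dict[str, HeatCapacityFit]
    dominant_channel: str

    def slopes(self) -> dict[str, float]:
        return {k: v.dCp for k, v in self.channels.items()}


def block_mean(series: Sequence[float], block_size: int) -> tuple[float, float]:
    """Mean and block-averaged standard error of a (correlated) series.

    The series is cut into non-overlapping blocks of ``block_size``
    (remainder dropped); the SE is the standard deviation of block
    means over sqrt(number of blocks), which remains valid under
    autocorrelation shorter than the block length.
    """
    x = np.asarray(series, dtype=float)
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n_blocks = x.size // block_size
    if n_blocks < 2:
        raise ValueError("need at least 2 full blocks")
    blocks = x[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)
    return float(x.mean()), float(blocks.std(ddof=1) / np.sqrt(n_blocks))


def _default_block(n: int) -> int:
    # 1% of the series, but keep >= 10 blocks
    return max(1, min(n // 100, n // 10))


def binding_enthalpy(
    complex: EnergyComponentSeries,
    free_host: EnergyComponentSeries,
    free_guest: EnergyComponentSeries,
    bulk_water: EnergyComponentSeries | None = None,
    matching: str = "bulk-correction",
) -> EnthalpyDecomposition:
    """End-state binding enthalpy with molecular and force-field partitions.

    Water bookkeeping: with ``matching="bulk-correction"`` any excess of
    waters in the free ensembles over the complex ensemble is balanced
    by adding the mean per-water energy of the bulk ensemble
    (N_excess * <u>_bulk, assigned to the W-W / desolvation channel).
    ``matching="strict"`` requires exactly balanced counts.
    """
    ensembles = {"complex": complex, "free_host": free_host, "free_guest": free_guest}
    temps = {e.T for e in ensembles.values()}
    if bulk_water is not None:
        temps.add(bulk_water.T)
    if len(temps) > 1:
        raise ValueError(f"ensembles at different temperatures: {sorted(temps)}")

    n_excess = free_host.n_waters + free_guest.n_waters - complex.n_waters
    if matching == "strict":
        if n_excess != 0:
            raise ValueError(f"unbalanced water counts (excess {n_excess}) under strict matching")
        bulk_corr = 0.0
    elif matching == "bulk-correction":
        if n_excess != 0:
            if bulk_water is None:
                raise ValueError("bulk_water ensemble required to balance water counts")
            if bulk_water.n_waters <= 0:
                raise ValueError("bulk ensemble must declare n_waters")
            u_per_water = float(bulk_water.total.mean()) / bulk_water.n_waters
            bulk_corr = n_excess * u_per_water
        else:
            bulk_corr = 0.0
    else:
        raise ValueError(f"unknown matching rule {matching!r}")

    cm = complex.component_means()
    hm = free_host.component_means()
    gm = free_guest.component_means()
    labels = sorted(set(cm) | set(hm) | set(gm))

    deltas = {lab: cm.get(lab, 0.0) - hm.get(lab, 0.0) - gm.get(lab, 0.0) for lab in labels}
    # bulk correction carries the W-W electrostatic+LJ energy of returned
    # waters; attribute it to the W-W channel as a whole (elec slot if the
    # ff split is requested and W-W columns exist there, else lumped).
    group: dict[str, float] = {}
    for lab, d in deltas.items():
        pair = lab.partition(":")[0]
        group[pair] = group.get(pair, 0.0) + d
    group["W-W"] = group.get("W-W", 0.0) + bulk_corr

    dH_HG = sum(group.get(p, 0.0) for p in SOLUTE_PAIRS)
    dH_desolv = sum(group.get(p, 0.0) for p in WATER_PAIRS)
    dH_total = dH_HG + dH_desolv

    ff: dict[str, float | None] = {}
    present_terms = {lab.partition(":")[2] for lab in labels}
    for term in FF_TERMS:
        if term not in present_terms and not (term == "elec" and bulk_corr):
            ff[term] = None
            continue
        val = sum(d for lab, d in deltas.items() if lab.partition(":")[2] == term)
        if term == "elec":
            # bulk waters interact through LJ + elec; without a per-term
            # bulk breakdown the correction is assigned to elec, the
            # dominant water-water term.
            val += bulk_corr
        ff[term] = val

    # SE: block-averaged SEs of each ensemble's total energy, in quadrature
    ses = []
    for e in ensembles.values():
        tot = e.total.to_numpy()
        try:
            _, se = block_mean(tot, _default_block(tot.size))
        except ValueError:
            se = float("nan")
        ses.append(se)
    se_total = float(np.sqrt(np.nansum(np.square(ses))))

    return EnthalpyDecomposition(
        dH_total=dH_total,
        dH_HG=dH_HG,
        dH_desolv=dH_desolv,
        ff_terms=ff,
        group_pairs=group,
        se_total=se_total,
        T=complex.T,
    )


def decompose_forcefield(decomp: EnthalpyDecomposition) -> dict[str, float | None]:
    """Force-field term split {LJ, elec, valence} of the binding enthalpy.

    Channels absent from every input ensemble are reported as None
    (absent), not zero; present channels sum to ``dH_total``.
    """
    return dict(decomp.ff_terms)


def heat_capacity_profile(
    decomps: Sequence[EnthalpyDecomposition],
    T_ref: float = 298.0,
) -> CpDecomposition:
    """Per-channel heat-capacity changes from decompositions at >= 2 T.

    Fits dH(T) for the total and for each decomposition channel
    (molecular: HG, desolv; force-field: LJ, elec, valence).  OLS
    linearity guarantees channel slopes sum to the total slope within
    each partition.
    """
    if len(decomps) < 2:
        raise ValueError("need decompositions at >= 2 temperatures")
    temps = [d.T for d in decomps]
    if len(set(temps)) < 2:
        raise ValueError("need >= 2 distinct temperatures")

    channel_values: dict[str, list[float]] = {"HG": [], "desolv": []}
    ff_present = [t for t in FF_TERMS if all(d.ff_terms.get(t) is not None for d in decomps)]
    ff_any = {t for d in decomps for t in FF_TERMS if d.ff_terms.get(t) is not None}
    if ff_any - set(ff_present):
        raise ValueError("inconsistent force-field channel sets across temperatures")
    for t in ff_present:
        channel_values[t] = []
    for d in decomps:
        channel_values["HG"].append(d.dH_HG)
        channel_values["desolv"].append(d.dH_desolv)
        for t in ff_present:
            channel_values[t].append(d.ff_terms[t])  # type: ignore[arg-type]

    total = fit_heat_capacity(temps, [d.dH_total for d in decomps], T_ref)
    channels = {k: fit_heat_capacity(temps, v, T_ref) for k, v in channel_values.items()}
    dominant = max(("HG", "desolv"), key=lambda k: abs(channels[k].dCp))
    return CpDecomposition(total=total, channels=channels, dominant_channel=dominant)
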