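"""Seeded generators for every input class the analysis consumes.

Each generator takes a :class:`ScenarioSpec` plus an integer seed and
returns both the synthetic raw data and the ground truth used to make
it, so recovery tests can close the loop.  Identical (spec, seed)
pairs give identical outputs.

The default scenario emulates the study conditions of a rigid
host-guest pair in water titrated by ITC across 278-328 K: Ka ~ 1e7
per molar at 298 K, dH ~ -12 kcal/mol, dCp ~ -100 cal/(mol K), 1:1
stoichiometry, per-injection noise at 0.5% of the largest heat.  The
simulation-side generators encode the rigid-solute picture: the
host-guest energy channel is temperature-flat and the entire
heat-capacity signal sits in the desolvation channel, localized in the
cavity water of the toy host.

The toy complex is two parallel rings of acceptor pseudo-atoms
(portals) around a cavity, a rigid cage guest with one hydroxyl, and
rigid 3-site waters (104.5 deg HOH) placed to realize exact target
hydrogen-bond counts plus a uniform bulk at density rho0.  It mimics
the *bookkeeping structure* of real simulations, not real energetics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calorimetry import EnergyComponentSeries
from .geometry import AxisSpec
from .hbonds import Frame
from .itc import InjectionHeats, Thermogram, TitrationSetup, predict_heats
from .regions import CylinderRegion, PortalSlabs
from .thermo import BindingThermo, affinity_from_free_energy, free_energy_from_affinity

__all__ = [
    "ScenarioSpec",
    "ItcDataset",
    "EnergyScenario",
    "ToyComplex",
    "make_itc_dataset",
    "make_itc_temperature_series",
    "render_thermogram",
    "make_energy_ensembles",
    "make_toy_complex",
    "make_gist_frames",
    "make_bulk_water_frames",
    "load_paper_tables",
    "PaperTables",
]

#: bulk water number density, waters per A^3 (0.997 g/mL at 298 K)
RHO0 = 0.0334

_WATER_OH = 0.9572        # A
_WATER_HOH = 104.5        # deg


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth parameters of one synthetic study.

    Defaults describe the reference scenario used throughout the test
    suite; all energies kcal/mol, temperatures K, dCp cal/(mol K).
    """

    temperatures: tuple[float, ...] = (278.0, 288.0, 298.0, 308.0, 318.0, 328.0)
    T_ref: float = 298.0
    # true binding thermodynamics at T_ref
    Ka_ref: float = 1.0e7
    dH_ref: float = -12.0
    dCp: float = -90.0
    n: float = 1.0
    #: fraction of the dH(T) change cancelled by -TdS(T) (dG drifts by the rest)
    compensation_fraction: float = 0.7
    # ITC setup
    cell_volume: float = 200e-6          # L
    cell_conc: float = 5e-5              # M
    syringe_conc: float = 5e-4           # M
    n_injections: int = 25
    injection_volume: float = 2e-6       # L
    itc_noise_frac: float = 0.005        # sigma as fraction of largest |heat|
    # energy-ensemble construction
    n_frames: int = 2000
    solute_sigma: float = 0.5            # frame-to-frame SD, solute channels
    water_sigma: float = 2.0             # frame-to-frame SD, water channels
    ar1_rho: float = 0.0                 # optional AR(1) autocorrelation
    dH_HG: float = -19.0                 # temperature-flat solute-solute term
    hg_slope: float = 0.0                # kcal/(mol K); rigid solutes -> 0
    n_waters_complex: int = 1000
    n_waters_host: int = 1005
    n_waters_guest: int = 10
    n_waters_bulk: int = 500
    u_bulk_per_water: float = -10.0
    # toy geometry
    ring_radius: float = 3.0
    portal_half_separation: float = 3.0
    n_ring_atoms: int = 8
    cavity_radius: float = 4.0
    n_cavity_waters: int = 6
    n_bulk_waters: int = 60
    box_half: float = 12.0               # bulk shell outer half-width, A
    bulk_exclusion: float = 9.0          # keep bulk waters beyond this radius
    # toy per-water energies (kcal/mol per water)
    cavity_e_sw: float = -2.0
    bulk_e_ww: float = -10.0
    # H-bond targets for the bound frame
    target_HG: int = 1
    target_GW: int = 2
    target_HW: int = 2

    @property
    def dH_desolv_ref(self) -> float:
        return self.dH_ref - self.dH_HG

    @property
    def desolv_slope(self) -> float:
        """kcal/(mol K) slope of the desolvation channel."""
        return self.dCp / 1000.0 - self.hg_slope

    @property
    def cavity_e_slope(self) -> float:
        """Per-cavity-water solvation-energy slope, kcal/(mol K).

        Chosen so that expelling the cavity waters reproduces the
        desolvation heat-capacity channel: -n_cav * slope = desolv slope.
        """
        return -self.desolv_slope / self.n_cavity_waters

    def thermo_at(self, T: float) -> BindingThermo:
        """True binding thermodynamics at temperature T.

        dH follows the linear heat-capacity model; dG drifts by
        (1 - compensation_fraction) of the dH change, the rest being
        cancelled by -TdS (enthalpy-entropy compensation).
        """
        cp = self.dCp / 1000.0
        dG_ref = free_energy_from_affinity(self.Ka_ref, self.T_ref)
        dH = self.dH_ref + cp * (T - self.T_ref)
        dG = dG_ref + (1.0 - self.compensation_fraction) * cp * (T - self.T_ref)
        return BindingThermo(
            complex_id="synthetic", T=T, dG=dG, dH=dH, mTdS=dG - dH,
            Ka=affinity_from_free_energy(dG, T),
        )


# --------------------------------------------------------------------------
# ITC


@dataclass(frozen=True)
class ItcDataset:
    setup: TitrationSetup
    heats: InjectionHeats
    truth: dict

    def thermogram(self, **kw) -> Thermogram:
        return render_thermogram(self.setup, self.heats, **kw)

    def save(self, outdir: str | Path, stem: str = "itc") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"injection": np.arange(1, len(self.heats) + 1), "heat_ucal": self.heats.heats}
        ).to_csv(outdir / f"{stem}_heats.csv", index=False)
        (outdir / f"{stem}_truth.json").write_text(json.dumps(self.truth, indent=2))


def make_itc_dataset(
    spec: ScenarioSpec, seed: int, T: float | None = None
) -> ItcDataset:
    """Noisy 1:1 titration heats with known generating parameters.

    The true Ka and dH at temperature T follow the spec's linear
    heat-capacity model; Gaussian noise with sigma = itc_noise_frac x
    max |heat| is added per injection.
    """
    T = spec.T_ref if T is None else T
    truth_thermo = spec.thermo_at(T)
    c = spec.n * truth_thermo.Ka * spec.cell_conc
    if not (0.1 <= c <= 1e4):
        raise ValueError(f"infeasible c value {c:.3g} (need 0.1 <= c <= 1e4)")
    setup = TitrationSetup(
        cell_volume=spec.cell_volume,
        cell_conc=spec.cell_conc,
        syringe_conc=spec.syringe_conc,
        injection_volumes=(spec.injection_volume,) * spec.n_injections,
        T=T,
    )
    clean = predict_heats(setup, truth_thermo.Ka, truth_thermo.dH, spec.n).heats
    rng = np.random.default_rng(seed)
    sigma = spec.itc_noise_frac * np.abs(clean).max()
    noisy = clean + rng.normal(0.0, sigma, size=clean.size)
    truth = {
        "T": T,
        "Ka": truth_thermo.Ka,
        "dH": truth_thermo.dH,
        "dG": truth_thermo.dG,
        "n": spec.n,
        "q_dil": 0.0,
        "noise_sigma_ucal": sigma,
        "c_value": c,
    }
    return ItcDataset(setup=setup, heats=InjectionHeats(noisy), truth=truth)


def make_itc_temperature_series(
    spec: ScenarioSpec, seed: int
) -> dict[float, ItcDataset]:
    """One titration per spec temperature, independently seeded."""
    return {
        T: make_itc_dataset(spec, seed + 1000 * i, T)
        for i, T in enumerate(spec.temperatures)
    }


def render_thermogram(
    setup: TitrationSetup,
    heats: InjectionHeats,
    spacing: float = 120.0,
    pulse_width: float = 4.0,
    dt: float = 0.5,
    lead_in: float = 60.0,
    drift: float = 0.0,
) -> Thermogram:
    """Render integrated heats as a power trace of Gaussian pulses.

    Each injection becomes a Gaussian pulse whose area equals its heat,
    on a flat (optionally linearly drifting) baseline.
    """
    n = len(heats)
    t_end = lead_in + n * spacing + lead_in
    t = np.arange(0.0, t_end, dt)
    inj_times = lead_in + spacing * np.arange(n)
    power = drift * t
    for ti, q in zip(inj_times, heats.heats):
        # centre 5 sigma into the window so <1e-6 of the area is truncated
        power = power + q / (pulse_width * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((t - ti - 5 * pulse_width) / pulse_width) ** 2
        )
    return Thermogram(time=t, power=power, injection_times=inj_times)


# --------------------------------------------------------------------------
# energy ensembles


@dataclass(frozen=True)
class EnergyScenario:
    """Four end-state ensembles per temperature plus the generating truth."""

    ensembles: dict  # T -> {ensemble_id: EnergyComponentSeries}
    truth: dict

    def at(self, T: float) -> dict[str, EnergyComponentSeries]:
        return self.ensembles[T]

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for T, ens in self.ensembles.items():
            for name, series in ens.items():
                series.data.to_csv(outdir / f"energies_{name}_{T:.0f}K.csv", index=False)
        (outdir / "energies_truth.json").write_text(json.dumps(self.truth, indent=2))


def _noise(rng, n, sigma, rho):
    eps = rng.normal(0.0, sigma, size=n)
    if rho:
        out = np.empty(n)
        out[0] = eps[0]
        innov = np.sqrt(1.0 - rho**2)
        for i in range(1, n):
            out[i] = rho * out[i - 1] + innov * eps[i]
        return out
    return eps


def make_energy_ensembles(spec: ScenarioSpec, seed: int) -> EnergyScenario:
    """Stationary component series whose mean arithmetic encodes the spec.

    Channel means are constructed so that the end-state differences
    give dH_HG = spec.dH_HG + hg_slope*(T - T_ref) (flat by default)
    and dH_desolv = spec.dH_desolv_ref + desolv_slope*(T - T_ref), the
    temperature dependence living entirely in the complex's
    water-water channel.  Water counts are deliberately unbalanced so
    the per-water bulk correction is exercised.
    """
    rng = np.random.default_rng(seed)
    nf = spec.n_frames
    n_excess = spec.n_waters_host + spec.n_waters_guest - spec.n_waters_complex
    bulk_total = spec.u_bulk_per_water * spec.n_waters_bulk

    # temperature-independent building blocks (absolute channel means)
    host_means = {"intra_H:valence": 4.0, "H-W:elec": -56.0, "W-W:elec": -9000.0}
    guest_means = {"intra_G:valence": 2.0, "G-W:elec": -25.0, "W-W:elec": -90.0}
    hg_lj = -14.0

    ensembles: dict[float, dict[str, EnergyComponentSeries]] = {}
    truth_t: dict[str, dict[str, float]] = {}
    for T in spec.temperatures:
        dT = T - spec.T_ref
        dH_HG = spec.dH_HG + spec.hg_slope * dT
        dH_desolv = spec.dH_desolv_ref + spec.desolv_slope * dT
        # complex channel means solving the delta equations:
        #   d(H-G) + d(intra) = dH_HG  with d(intra) fixed at +1
        #   d(H-W) = +6, d(G-W) = +5, d(W-W) + n_excess*u_bulk = rest
        cpx = {
            "H-G:LJ": hg_lj,
            "H-G:elec": dH_HG - 1.0 - hg_lj,
            "intra_H:valence": host_means["intra_H:valence"] + 0.6,
            "intra_G:valence": guest_means["intra_G:valence"] + 0.4,
            "H-W:elec": host_means["H-W:elec"] + 6.0,
            "G-W:elec": guest_means["G-W:elec"] + 5.0,
            "W-W:elec": (
                (dH_desolv - 6.0 - 5.0)
                + host_means["W-W:elec"] + guest_means["W-W:elec"]
                - n_excess * spec.u_bulk_per_water
            ),
        }

        def series(means: dict[str, float], ensemble_id: str, n_waters: int):
            cols = {}
            for label, mu in means.items():
                sigma = spec.water_sigma if "W" in label.partition(":")[0] else spec.solute_sigma
                cols[label] = mu + _noise(rng, nf, sigma, spec.ar1_rho)
            return EnergyComponentSeries(
                pd.DataFrame(cols), T=T, ensemble_id=ensemble_id, n_waters=n_waters
            )

        ensembles[T] = {
            "complex": series(cpx, "complex", spec.n_waters_complex),
            "free_host": series(host_means, "free_host", spec.n_waters_host),
            "free_guest": series(guest_means, "free_guest", spec.n_waters_guest),
            "bulk_water": series(
                {"W-W:elec": bulk_total}, "bulk_water", spec.n_waters_bulk
            ),
        }
        th = spec.thermo_at(T)
        truth_t[f"{T:g}"] = {
            "dH_total": dH_HG + dH_desolv,
            "dH_HG": dH_HG,
            "dH_desolv": dH_desolv,
            "dG": th.dG,
            "mTdS": th.dG - (dH_HG + dH_desolv),
        }
    truth = {
        "per_temperature": truth_t,
        "dCp_total": spec.dCp,
        "dCp_HG": spec.hg_slope * 1000.0,
        "dCp_desolv": spec.desolv_slope * 1000.0,
        "se_of_mean_water_channel": spec.water_sigma / np.sqrt(nf),
        "compensation_fraction": spec.compensation_fraction,
    }
    return EnergyScenario(ensembles=ensembles, truth=truth)


# --------------------------------------------------------------------------
# toy complex geometry


def _rot_to(z: np.ndarray) -> np.ndarray:
    """Rotation matrix sending (0,0,1) to the unit vector z."""
    z = z / np.linalg.norm(z)
    a = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    c = float(np.dot(a, z))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _water_coords(o_pos: np.ndarray, donate_to: np.ndarray | None, rng) -> np.ndarray:
    """Rigid 3-site water at o_pos; if donate_to is given, one O-H points there."""
    half = np.deg2rad(_WATER_HOH / 2.0)
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [_WATER_OH * np.sin(half), 0.0, _WATER_OH * np.cos(half)],
            [-_WATER_OH * np.sin(half), 0.0, _WATER_OH * np.cos(half)],
        ]
    )
    if donate_to is None:
        direction = rng.normal(size=3)
    else:
        direction = np.asarray(donate_to) - o_pos
    R = _rot_to(direction / np.linalg.norm(direction))
    # rotate so H1 (not the bisector) points along `direction`
    h1_local = local[1]
    R_align = _rot_to(h1_local / np.linalg.norm(h1_local)).T
    return o_pos + (R @ (R_align @ local.T)).T


class _FrameBuilder:
    def __init__(self) -> None:
        self.coords: list[np.ndarray] = []
        self.elements: list[str] = []
        self.labels: list[str] = []
        self.mol_ids: list[int] = []
        self.donors: list[tuple[int, int]] = []
        self.acceptors: list[int] = []
        self._next_mol = 0

    def add_atoms(self, coords, elements, label, mol_id=None,
                  donors=(), acceptors=()):
        base = len(self.coords)
        mid = self._next_mol if mol_id is None else mol_id
        if mol_id is None:
            self._next_mol += 1
        else:
            self._next_mol = max(self._next_mol, mol_id + 1)
        for c, e in zip(np.atleast_2d(coords), elements):
            self.coords.append(np.asarray(c, float))
            self.elements.append(e)
            self.labels.append(label)
            self.mol_ids.append(mid)
        self.donors.extend((base + d, base + h) for d, h in donors)
        self.acceptors.extend(base + a for a in acceptors)
        return base

    def add_water(self, coords):
        self.add_atoms(
            coords, ["O", "H", "H"], "water",
            donors=[(0, 1), (0, 2)], acceptors=[0],
        )

    def build(self, box=None) -> Frame:
        return Frame(
            coords=np.array(self.coords),
            elements=list(self.elements),
            mol_labels=list(self.labels),
            mol_ids=np.array(self.mol_ids),
            donors=list(self.donors),
            acceptors=list(self.acceptors),
            box=box,
        )


def _host_geometry(spec: ScenarioSpec) -> tuple[np.ndarray, list[int], list[int]]:
    """Two parallel rings of acceptor pseudo-atoms; returns coords and ring indices."""
    ang = 2 * np.pi * np.arange(spec.n_ring_atoms) / spec.n_ring_atoms
    ring = np.stack([spec.ring_radius * np.cos(ang), spec.ring_radius * np.sin(ang),
                     np.zeros_like(ang)], axis=1)
    top = ring + np.array([0.0, 0.0, spec.portal_half_separation])
    bot = ring - np.array([0.0, 0.0, spec.portal_half_separation])
    coords = np.vstack([top, bot])
    n = spec.n_ring_atoms
    return coords, list(range(n)), list(range(n, 2 * n))


def _sample_bulk(rng, spec: ScenarioSpec, n: int, existing: list[np.ndarray],
                 min_sep: float = 3.2) -> list[np.ndarray]:
    """Uniform bulk positions outside the exclusion radius, mutually separated
    by > min_sep so no accidental hydrogen bonds arise."""
    placed: list[np.ndarray] = []
    guard = 0
    while len(placed) < n:
        guard += 1
        if guard > 200000:
            raise RuntimeError("could not place bulk waters; box too small")
        p = rng.uniform(-spec.box_half, spec.box_half, size=3)
        if np.linalg.norm(p) < spec.bulk_exclusion:
            continue
        if any(np.linalg.norm(p - q) < min_sep for q in existing + placed):
            continue
        placed.append(p)
    return placed


@dataclass(frozen=True)
class ToyComplex:
    bound: Frame
    free_host: Frame
    free_guest: Frame
    cavity: CylinderRegion
    portal: PortalSlabs
    axis_spec: AxisSpec
    truth: dict


def make_toy_complex(spec: ScenarioSpec, seed: int) -> ToyComplex:
    """Bound/free toy configurations realizing exact hydrogen-bond targets.

    The bound frame contains host + guest (guest filling the cavity,
    no cavity waters) plus waters engineered to give exactly
    ``target_HG`` host-guest, ``target_GW`` guest-water and
    ``target_HW`` host-water bonds, and a bulk shell with no mutual
    bonds.  The free-host frame holds ``n_cavity_waters`` waters in
    the cavity; the free guest sits in pure bulk.
    """
    rng = np.random.default_rng(seed)
    host_coords, portal1, portal2 = _host_geometry(spec)
    if spec.target_HG > 1 or spec.target_HW > spec.n_ring_atoms:
        raise ValueError("unsatisfiable hydrogen-bond targets for this geometry")

    cavity = CylinderRegion(
        center=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0),
        radius=spec.cavity_radius, half_height=spec.portal_half_separation,
    )
    portal = PortalSlabs(
        center=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0),
        radius=spec.cavity_radius + 2.0,
        half_height=spec.portal_half_separation, thickness=3.0,
    )

    # ---- bound frame: host + guest + engineered waters -------------------
    b = _FrameBuilder()
    b.add_atoms(host_coords, ["O"] * len(host_coords), "host",
                acceptors=list(range(len(host_coords))))

    # guest: 4-atom cage centred in the cavity + hydroxyl pointing at a portal
    cage = np.array(
        [[0.8, 0.8, -0.6], [-0.8, 0.8, -1.2], [0.8, -0.8, -1.4], [-0.8, -0.8, -0.6]]
    )
    acceptor_target = host_coords[portal1[0]]  # one top-ring carbonyl O
    occupied = [host_coords, cage]
    if spec.target_HG:
        u = acceptor_target - cage.mean(axis=0)
        u = u / np.linalg.norm(u)
        g_o = acceptor_target - 2.8 * u
        g_h = g_o + 0.97 * u
    else:
        g_o = np.array([0.0, 0.0, 1.6])
        g_h = g_o + np.array([0.0, 0.0, 0.97])
    guest_coords = np.vstack([cage, g_o, g_h])
    b.add_atoms(guest_coords, ["C"] * 4 + ["O", "H"], "guest",
                donors=[(4, 5)], acceptors=[4])

    existing = [c for arr in (host_coords, guest_coords) for c in arr]
    # guest-water targets: waters donating to the guest hydroxyl oxygen
    # directions with a dominant +z component so the waters sit beyond the
    # portal plane, outside the cavity cylinder
    gw_dirs = [np.array([0.0, 0.0, 1.0]), np.array([0.3, -0.3, 0.95]),
               np.array([-0.3, 0.3, 0.95])]
    for k in range(spec.target_GW):
        v = gw_dirs[k % len(gw_dirs)]
        v = v / np.linalg.norm(v)
        o = g_o + 2.8 * v
        b.add_water(_water_coords(o, donate_to=g_o, rng=rng))
        existing.append(o)
    # host-water targets: waters donating to bottom-ring acceptors from outside
    for k in range(spec.target_HW):
        a = host_coords[portal2[2 * k % spec.n_ring_atoms]]
        w_dir = np.array([a[0], a[1], 0.0])
        w_dir = 0.8 * w_dir / np.linalg.norm(w_dir) + np.array([0.0, 0.0, -0.6])
        o = a + 2.8 * w_dir / np.linalg.norm(w_dir)  # outward, below the portal
        b.add_water(_water_coords(o, donate_to=a, rng=rng))
        existing.append(o)
    for p in _sample_bulk(rng, spec, spec.n_bulk_waters, existing):
        b.add_water(_water_coords(p, donate_to=None, rng=rng))
    bound = b.build()

    # ---- free host: cavity waters + bulk --------------------------------
    fh = _FrameBuilder()
    fh.add_atoms(host_coords, ["O"] * len(host_coords), "host",
                 acceptors=list(range(len(host_coords))))
    cav_positions: list[np.ndarray] = []
    guard = 0
    while len(cav_positions) < spec.n_cavity_waters:
        guard += 1
        if guard > 100000:
            raise RuntimeError("cannot place cavity waters; reduce n_cavity_waters")
        r = np.sqrt(rng.uniform(0, 1)) * (spec.cavity_radius - 1.6)
        phi = rng.uniform(0, 2 * np.pi)
        z = rng.uniform(-0.75, 0.75) * spec.portal_half_separation
        p = np.array([r * np.cos(phi), r * np.sin(phi), z])
        if any(np.linalg.norm(p - q) < 2.6 for q in cav_positions):
            continue
        cav_positions.append(p)
    for p in cav_positions:
        fh.add_water(_water_coords(p, donate_to=None, rng=rng))
    for p in _sample_bulk(rng, spec, spec.n_bulk_waters,
                          [c for c in host_coords] + cav_positions):
        fh.add_water(_water_coords(p, donate_to=None, rng=rng))
    free_host = fh.build()

    # ---- free guest in bulk ---------------------------------------------
    fg = _FrameBuilder()
    fg.add_atoms(guest_coords, ["C"] * 4 + ["O", "H"], "guest",
                 donors=[(4, 5)], acceptors=[4])
    for p in _sample_bulk(rng, spec, spec.n_bulk_waters, [c for c in guest_coords]):
        fg.add_water(_water_coords(p, donate_to=None, rng=rng))
    free_guest = fg.build()

    axis_spec = AxisSpec(
        portal1=tuple(portal1), portal2=tuple(portal2),
        guest_tail=tuple(len(host_coords) + i for i in range(4)),
        guest_head=(len(host_coords) + 4,),
    )
    truth = {
        "target_HG": spec.target_HG,
        "target_GW": spec.target_GW,
        "target_HW": spec.target_HW,
        "n_cavity_waters_free": spec.n_cavity_waters,
        "n_cavity_waters_bound": 0,
    }
    return ToyComplex(
        bound=bound, free_host=free_host, free_guest=free_guest,
        cavity=cavity, portal=portal, axis_spec=axis_spec, truth=truth,
    )


# --------------------------------------------------------------------------
# GIST scenarios


def make_gist_frames(
    spec: ScenarioSpec,
    seed: int,
    T: float,
    state: str,
    n_frames: int = 50,
    energy_noise: float = 0.0,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-frame water positions and per-water (E_sw, E_ww) energies.

    ``state="free"`` carries n_cavity_waters inside the host cavity
    whose solute-water energy varies with temperature at
    ``spec.cavity_e_slope`` per water; bulk waters are
    temperature-flat.  ``state="bound"`` has the cavity waters expelled
    (guest in the cavity), only bulk remains.  The bound-minus-free
    solvation-energy difference thus has slope desolv_slope, localized
    in the cavity.
    """
    if state not in ("bound", "free"):
        raise ValueError("state must be 'bound' or 'free'")
    rng = np.random.default_rng(seed)
    frames = []
    e_cav = spec.cavity_e_sw + spec.cavity_e_slope * (T - spec.T_ref)
    for _ in range(n_frames):
        pos, e_sw, e_ww = [], [], []
        if state == "free":
            for _ in range(spec.n_cavity_waters):
                r = np.sqrt(rng.uniform(0, 1)) * (spec.cavity_radius - 1.0)
                phi = rng.uniform(0, 2 * np.pi)
                z = rng.uniform(-0.8, 0.8) * spec.portal_half_separation
                pos.append([r * np.cos(phi), r * np.sin(phi), z])
                e_sw.append(e_cav)
                e_ww.append(spec.bulk_e_ww)
        for _ in range(spec.n_bulk_waters):
            p = rng.uniform(-spec.box_half, spec.box_half, size=3)
            while np.linalg.norm(p) < spec.bulk_exclusion:
                p = rng.uniform(-spec.box_half, spec.box_half, size=3)
            pos.append(p)
            e_sw.append(0.0)
            e_ww.append(spec.bulk_e_ww)
        e_sw = np.asarray(e_sw)
        e_ww = np.asarray(e_ww)
        if energy_noise:
            e_sw = e_sw + rng.normal(0, energy_noise, e_sw.size)
            e_ww = e_ww + rng.normal(0, energy_noise, e_ww.size)
        frames.append((np.asarray(pos), e_sw, e_ww))
    return frames


def make_bulk_water_frames(
    spec: ScenarioSpec,
    seed: int,
    n_frames: int = 50,
    n_waters: int | None = None,
    box: float = 20.0,
    energy_noise: float = 0.1,
) -> tuple[list[tuple[np.ndarray, np.ndarray, np.ndarray]], float]:
    """Homogeneous bulk-water frames for null-map checks.

    Returns the frames and the exact number density used, so that a
    normalized map should show g ~ 1 and zero excess energy everywhere.
    """
    rng = np.random.default_rng(seed)
    n = int(round(RHO0 * box**3)) if n_waters is None else n_waters
    frames = []
    for _ in range(n_frames):
        pos = rng.uniform(0.0, box, size=(n, 3))
        e_sw = np.zeros(n)
        e_ww = spec.bulk_e_ww + rng.normal(0, energy_noise, n)
        frames.append((pos, e_sw, e_ww))
    return frames, n / box**3


# --------------------------------------------------------------------------
# printed tables


_TABLE_SHA256 = {
    "table1.csv": "5062c137fa030e70f1872d9bdd9d995d0c6f271e6028bc804b0761927adcbd07",
    "table2.csv": "7a6f4af0ffcecc22a40ba40c20edfe0008584a492d2373c1ce418b3e4f692f81",
    "table3.csv": "df79bd34f317eb8498a12680d05ab239dfb23f457fc66bb0968188ebdbe58ee5",
}


@dataclass(frozen=True)
class PaperTables:
    """The published measurement tables as typed DataFrames.

    table1: measured thermodynamics of all 16 complexes at 298 K
    (dG/dH/-TdS in kcal/mol, dCp in cal/(mol K)).  table2: calculated
    vs experimental thermodynamics for the six simulated complexes.
    table3: hydrogen-bond changes on binding and cavity-water
    expulsion for the same six complexes.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame

    def host_rows(self, host: str) -> pd.DataFrame:
        return self.table1[self.table1["host"] == host]


def load_paper_tables() -> PaperTables:
    """Load the packaged printed-table fixtures, verifying checksums."""
    tables = {}
    root = resources.files("hgthermo") / "tables"
    for name, want in _TABLE_SHA256.items():
        raw = (root / name).read_bytes()
        got = hashlib.sha256(raw).hexdigest()
        if got != want:
            raise RuntimeError(f"packaging error: checksum mismatch for {name}")
    tables = {
        name.split(".")[0]: pd.read_csv(root / name) for name in _TABLE_SHA256
    }
    return PaperTables(**tables)
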