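"""Geometric hydrogen-bond detection and change-on-binding bookkeeping.

A hydrogen bond is counted when the donor-heavy-atom to
acceptor-heavy-atom distance is strictly below ``d_max`` (default
3.0 A) and the donor-hydrogen-acceptor angle strictly exceeds
``angle_min`` (default 150 deg).  Boundary values are NOT bonds.
Bonds are classified by the unordered molecule-label pair into the
four categories host-guest (H-G), host-water (H-W), guest-water (G-W)
and water-water (W-W); intra-molecular pairs are excluded (an optional
bond-separation matrix can re-admit intra-solute pairs separated by at
least three covalent bonds).

Donor/acceptor chemistry is taken from an annotation sidecar, not
perceived: donors are O/N heavy atoms with an attached hydrogen,
acceptors are O/N heavy atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .regions import CylinderRegion

__all__ = [
    "Frame",
    "HBondCriteria",
    "HBond",
    "HBondTable",
    "EnsembleHBondStats",
    "CATEGORIES",
    "detect_hbonds",
    "classify_counts",
    "delta_on_binding",
    "count_cavity_waters",
]

CATEGORIES = ("H-G", "H-W", "G-W", "W-W")
_LABELS = {"host", "guest", "water"}
_PAIR_TO_CATEGORY = {
    frozenset({"host", "guest"}): "H-G",
    frozenset({"host", "water"}): "H-W",
    frozenset({"guest", "water"}): "G-W",
    frozenset({"water"}): "W-W",
}


def _minimum_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return vec
    return vec - box * np.round(vec / box)


@dataclass(frozen=True)
class HBondCriteria:
    d_max: float = 3.0        # donor-acceptor heavy-atom distance cutoff, A
    angle_min: float = 150.0  # D-H-A angle cutoff, degrees

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0.0 < self.angle_min < 180.0):
            raise ValueError("angle_min must lie in (0, 180)")


@dataclass(frozen=True)
class HBond:
    donor: int      # donor heavy atom index
    hydrogen: int
    acceptor: int   # acceptor heavy atom index


@dataclass
class Frame:
    """One configuration with molecule labels and donor/acceptor annotations.

    ``donors`` is a sequence of (heavy, hydrogen) index pairs;
    ``acceptors`` a sequence of heavy-atom indices.  ``mol_ids``
    partition atoms into molecules; ``mol_labels`` assigns each atom
    one of host/guest/water.  ``box`` (optional) gives orthorhombic box
    lengths for minimum-image distances.
    """

    coords: np.ndarray
    elements: Sequence[str]
    mol_labels: Sequence[str]
    mol_ids: np.ndarray
    donors: Sequence[tuple[int, int]]
    acceptors: Sequence[int]
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.mol_ids = np.asarray(self.mol_ids)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
        n = self.coords.shape[0]
        if len(self.elements) != n or len(self.mol_labels) != n or self.mol_ids.size != n:
            raise ValueError("elements, mol_labels and mol_ids must cover all atoms")
        unknown = set(self.mol_labels) - _LABELS
        if unknown:
            raise ValueError(f"unknown molecule labels: {sorted(unknown)}")
        for heavy, hyd in self.donors:
            d = np.linalg.norm(
                _minimum_image(self.coords[hyd] - self.coords[heavy], self.box)
            )
            if d >= 1.2:
                raise ValueError(
                    f"donor hydrogen {hyd} is {d:.2f} A from heavy atom {heavy} (>= 1.2 A)"
                )

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def water_oxygens(self) -> np.ndarray:
        """Indices of water oxygen atoms."""
        return np.array(
            [
                i
                for i in range(self.n_atoms)
                if self.mol_labels[i] == "water" and self.elements[i] == "O"
            ],
            dtype=int,
        )


def detect_hbonds(
    frame: Frame,
    criteria: HBondCriteria = HBondCriteria(),
    bond_separation: np.ndarray | None = None,
) -> list[HBond]:
    """All donor-hydrogen-acceptor triplets passing the geometric cuts.

    Intra-molecular pairs are excluded unless ``bond_separation`` (a
    matrix of covalent-bond path lengths) shows donor and acceptor at
    least 3 bonds apart and the molecule is host or guest.  Bifurcated
    bonds (one hydrogen to several acceptors) are all counted.
    """
    if not frame.donors or not frame.acceptors:
        return []
    coords = frame.coords
    box = frame.box
    acceptors = np.asarray(frame.acceptors, dtype=int)
    acc_pos = coords[acceptors]
    if box is not None:
        tree = cKDTree(np.mod(acc_pos, box), boxsize=box)
    else:
        tree = cKDTree(acc_pos)

    cos_min = np.cos(np.deg2rad(criteria.angle_min))
    bonds: list[HBond] = []
    for heavy, hyd in frame.donors:
        dpos = np.mod(coords[heavy], box) if box is not None else coords[heavy]
        for j in tree.query_ball_point(dpos, criteria.d_max):
            acc = int(acceptors[j])
            if acc == heavy:
                continue
            same_mol = frame.mol_ids[acc] == frame.mol_ids[heavy]
            if same_mol:
                if (
                    bond_separation is None
                    or frame.mol_labels[heavy] == "water"
                    or bond_separation[heavy, acc] < 3
                ):
                    continue
            r_da = np.linalg.norm(_minimum_image(coords[acc] - coords[heavy], box))
            if not (r_da < criteria.d_max):
                continue  # strict cut (KD-tree query is inclusive at d_max)
            v_hd = _minimum_image(coords[heavy] - coords[hyd], box)
            v_ha = _minimum_image(coords[acc] - coords[hyd], box)
            denom = np.linalg.norm(v_hd) * np.linalg.norm(v_ha)
            if denom == 0:
                continue
            cos_dha = float(np.dot(v_hd, v_ha) / denom)
            # angle > angle_min  <=>  cos(angle) < cos(angle_min), strict
            if cos_dha < cos_min:
                bonds.append(HBond(donor=heavy, hydrogen=hyd, acceptor=acc))
    return bonds


def classify_counts(bonds: Sequence[HBond], frame: Frame) -> dict[str, int]:
    """Count bonds per category from the unordered molecule-label pair."""
    counts = dict.fromkeys(CATEGORIES, 0)
    for b in bonds:
        pair = frozenset({frame.mol_labels[b.donor], frame.mol_labels[b.acceptor]})
        try:
            counts[_PAIR_TO_CATEGORY[pair]] += 1
        except KeyError:
            raise ValueError(f"unclassifiable label pair {sorted(pair)}") from None
    return counts


@dataclass(frozen=True)
class EnsembleHBondStats:
    """Mean per-category hydrogen-bond counts of one ensemble."""

    counts: Mapping[str, float]
    n_waters: int

    @classmethod
    def from_frames(cls, frames: Sequence[Frame], criteria: HBondCriteria = HBondCriteria()):
        if not frames:
            raise ValueError("need at least one frame")
        acc = dict.fromkeys(CATEGORIES, 0.0)
        for f in frames:
            for k, v in classify_counts(detect_hbonds(f, criteria), f).items():
                acc[k] += v
        n = len(frames)
        return cls(
            counts={k: v / n for k, v in acc.items()},
            n_waters=int(frames[0].water_oxygens().size),
        )


@dataclass(frozen=True)
class HBondTable:
    """Change in mean hydrogen-bond counts on binding (one table row)."""

    dHG: float
    dHW: float
    dGW: float
    dWW: float
    total: float
    dN_wat: float | None = None

    def __post_init__(self) -> None:
        if abs(self.total - (self.dHG + self.dHW + self.dGW + self.dWW)) > 1e-9:
            raise ValueError("total must equal the sum of the four categories")


def delta_on_binding(
    bound: EnsembleHBondStats,
    free_host: EnsembleHBondStats,
    free_guest: EnsembleHBondStats,
    bulk_rate_per_water: float = 0.0,
    matching: str = "bulk-correction",
    dN_wat: float | None = None,
) -> HBondTable:
    """Per-category change on binding: bound - (free host + free guest).

    Waters present in the free ensembles but absent from the bound one
    are credited with the bulk per-water W-W hydrogen-bond rate
    (``matching="bulk-correction"``); ``"strict"`` demands balanced
    counts.
    """
    n_excess = free_host.n_waters + free_guest.n_waters - bound.n_waters
    if matching == "strict":
        if n_excess != 0:
            raise ValueError(f"unbalanced water counts (excess {n_excess}) under strict matching")
        ww_corr = 0.0
    elif matching == "bulk-correction":
        ww_corr = n_excess * bulk_rate_per_water
    else:
        raise ValueError(f"unknown matching rule {matching!r}")

    def delta(cat: str) -> float:
        return bound.counts.get(cat, 0.0) - free_host.counts.get(cat, 0.0) - free_guest.counts.get(cat, 0.0)

    d = {c: delta(c) for c in CATEGORIES}
    d["W-W"] += ww_corr
    total = sum(d.values())
    return HBondTable(
        dHG=d["H-G"], dHW=d["H-W"], dGW=d["G-W"], dWW=d["W-W"],
        total=total, dN_wat=dN_wat,
    )


def count_cavity_waters(frame: Frame, cavity: CylinderRegion) -> int:
    """Number of water oxygens inside the host-cavity cylinder."""
    ox = frame.water_oxygens()
    if ox.size == 0:
        return 0
    return int(np.count_nonzero(cavity.contains(frame.coords[ox])))
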