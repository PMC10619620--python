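import numpy as np
import pytest

from hgthermo.hbonds import Frame
from hgthermo.synthetic import ScenarioSpec, load_paper_tables


@pytest.fixture(scope="session")
def tables():
    return load_paper_tables()


@pytest.fixture(scope="session")
def spec():
    return ScenarioSpec()


def random_water_frame(rng, n_waters=50, box=20.0, periodic=False) -> Frame:
    """Random rigid waters in a cubic box (shared helper for oracle tests)."""
    oh = 0.9572
    half = np.deg2rad(104.5 / 2)
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [oh * np.sin(half), 0.0, oh * np.cos(half)],
            [-oh * np.sin(half), 0.0, oh * np.cos(half)],
        ]
    )
    coords, donors, acceptors, mol_ids = [], [], [], []
    for i in range(n_waters):
        # random rotation via QR of a Gaussian matrix
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        o = rng.uniform(0, box, size=3)
        w = o + local @ q.T
        base = 3 * i
        coords.append(w)
        donors += [(base, base + 1), (base, base + 2)]
        acceptors.append(base)
        mol_ids += [i, i, i]
    return Frame(
        coords=np.vstack(coords),
        elements=["O", "H", "H"] * n_waters,
        mol_labels=["water"] * (3 * n_waters),
        mol_ids=np.array(mol_ids),
        donors=donors,
        acceptors=acceptors,
        box=np.array([box] * 3) if periodic else None,
    )
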