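"""End-state binding enthalpy, its partitions, and per-channel heat capacities."""

import numpy as np
import pandas as pd
import pytest

from hgthermo.calorimetry import (
    EnergyComponentSeries,
    binding_enthalpy,
    block_mean,
    decompose_forcefield,
    heat_capacity_profile,
)
from hgthermo.synthetic import ScenarioSpec, make_energy_ensembles


def _series(means, ensemble_id, T=298.0, n_waters=0, n_frames=50, sigma=0.0, seed=0):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        {k: v + rng.normal(0, sigma, n_frames) for k, v in means.items()}
    )
    return EnergyComponentSeries(data, T=T, ensemble_id=ensemble_id, n_waters=n_waters)


class TestBlockMean:
    def test_constant_series_zero_se(self):
        mean, se = block_mean(np.full(100, 3.5), 10)
        assert mean == 3.5
        assert se == 0.0

    def test_iid_se_calibration(self):
        # CLT: SE of the mean of 1e4 iid N(0,1) samples is 0.01
        rng = np.random.default_rng(0)
        ses = [block_mean(rng.normal(size=10_000), 100)[1] for _ in range(100)]
        assert abs(np.mean(ses) - 0.01) / 0.01 < 0.3

    def test_autocorrelation_inflates_block_se(self):
        rng = np.random.default_rng(1)
        n, rho = 20_000, 0.9
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        _, block_se = block_mean(x, 200)
        naive_se = x.std(ddof=1) / np.sqrt(n)
        assert block_se > 1.5 * naive_se

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            block_mean(np.arange(10.0), 8)


class TestBindingEnthalpy:
    def test_null_binding_when_complex_is_disjoint_union(self):
        host = _series({"intra_H:valence": 4.0, "H-W:elec": -30.0, "W-W:elec": -100.0},
                       "free_host", n_waters=10)
        guest = _series({"intra_G:valence": 2.0, "G-W:elec": -20.0, "W-W:elec": -50.0},
                        "free_guest", n_waters=5)
        cpx = _series(
            {"intra_H:valence": 4.0, "intra_G:valence": 2.0, "H-W:elec": -30.0,
             "G-W:elec": -20.0, "W-W:elec": -150.0},
            "complex", n_waters=15,
        )
        d = binding_enthalpy(cpx, host, guest)
        assert d.dH_total == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_channel_arithmetic(self):
        # generator deltas: H-G=-20, dH-W=+6, dG-W=+5, dW-W=-3, dintra=+1
        host = _series({"intra_H:valence": 4.0, "H-W:elec": -56.0, "W-W:elec": -500.0},
                       "free_host", n_waters=20)
        guest = _series({"intra_G:valence": 2.0, "G-W:elec": -25.0, "W-W:elec": -30.0},
                        "free_guest", n_waters=5)
        cpx = _series(
            {"H-G:LJ": -20.0, "intra_H:valence": 4.6, "intra_G:valence": 2.4,
             "H-W:elec": -50.0, "G-W:elec": -20.0, "W-W:elec": -533.0},
            "complex", n_waters=25,
        )
        d = binding_enthalpy(cpx, host, guest)
        assert d.dH_total == pytest.approx(-11.0, abs=1e-9)
        assert d.dH_HG == pytest.approx(-19.0, abs=1e-9)
        assert d.dH_desolv == pytest.approx(8.0, abs=1e-9)

    def test_partition_identities_on_random_tables(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            labels = ["H-G:LJ", "H-G:elec", "intra_H:valence", "intra_G:valence",
                      "H-W:LJ", "H-W:elec", "G-W:elec", "W-W:elec", "W-W:LJ"]
            def rand_series(eid, labs, n_wat):
                return _series({l: rng.normal(0, 50) for l in labs}, eid,
                               n_waters=n_wat, sigma=1.0, seed=trial)
            cpx = rand_series("complex", labels, 40)
            host = rand_series("free_host", ["intra_H:valence", "H-W:LJ", "H-W:elec", "W-W:elec"], 30)
            guest = rand_series("free_guest", ["intra_G:valence", "G-W:elec", "W-W:LJ"], 15)
            bulk = rand_series("bulk_water", ["W-W:elec"], 100)
            d = binding_enthalpy(cpx, host, guest, bulk)
            assert d.dH_HG + d.dH_desolv == pytest.approx(d.dH_total, abs=1e-9)
            ff = [v for v in d.ff_terms.values() if v is not None]
            assert sum(ff) == pytest.approx(d.dH_total, abs=1e-9)

    def test_strict_matching_rejects_unbalanced_waters(self):
        host = _series({"W-W:elec": -10.0}, "free_host", n_waters=10)
        guest = _series({"G-W:elec": -5.0}, "free_guest", n_waters=5)
        cpx = _series({"W-W:elec": -12.0, "G-W:elec": -5.0}, "complex", n_waters=12)
        with pytest.raises(ValueError, match="unbalanced"):
            binding_enthalpy(cpx, host, guest, matching="strict")

    def test_temperature_mismatch_rejected(self):
        host = _series({"W-W:elec": -10.0}, "free_host", T=298.0)
        guest = _series({"G-W:elec": -5.0}, "free_guest", T=298.0)
        cpx = _series({"W-W:elec": -12.0}, "complex", T=308.0)
        with pytest.raises(ValueError, match="temperature"):
            binding_enthalpy(cpx, host, guest)


class TestForceFieldDecomposition:
    def test_absent_channel_reported_absent(self):
        host = _series({"H-W:elec": -30.0, "W-W:elec": -100.0}, "free_host", n_waters=10)
        guest = _series({"G-W:elec": -20.0}, "free_guest", n_waters=0)
        cpx = _series({"H-W:elec": -28.0, "W-W:elec": -102.0, "G-W:elec": -22.0,
                       "H-G:elec": -8.0}, "complex", n_waters=10)
        ff = decompose_forcefield(binding_enthalpy(cpx, host, guest))
        assert ff["LJ"] is None
        assert ff["valence"] is None
        # deltas: H-W +2, W-W -2, G-W -2, H-G -8 -> elec total -10
        assert ff["elec"] == pytest.approx(-10.0, abs=1e-9)

    def test_rigid_solute_valence_delta_zero(self):
        host = _series({"intra_H:valence": 7.0, "W-W:elec": -100.0}, "free_host", n_waters=10)
        guest = _series({"intra_G:valence": 3.0}, "free_guest", n_waters=0)
        cpx = _series({"intra_H:valence": 7.0, "intra_G:valence": 3.0,
                       "H-G:LJ": -15.0, "W-W:elec": -98.0}, "complex", n_waters=10)
        ff = decompose_forcefield(binding_enthalpy(cpx, host, guest))
        assert ff["valence"] == pytest.approx(0.0, abs=1e-9)


class TestHeatCapacityProfile:
    def test_scenario_attribution_to_desolvation(self, spec):
        sc = make_energy_ensembles(spec, seed=11)
        decomps = []
        for T in spec.temperatures:
            e = sc.at(T)
            decomps.append(
                binding_enthalpy(e["complex"], e["free_host"], e["free_guest"], e["bulk_water"])
            )
        cp = heat_capacity_profile(decomps)
        assert cp.channels["HG"].dCp == pytest.approx(0.0, abs=3 * cp.channels["HG"].stderr_slope)
        assert cp.channels["desolv"].dCp == pytest.approx(
            -90.0, abs=3 * cp.channels["desolv"].stderr_slope
        )
        assert cp.dominant_channel == "desolv"

    def test_all_channels_constant_gives_zero_slopes(self):
        means = {"H-G:LJ": -10.0, "W-W:elec": -50.0}
        decomps = []
        for T in (278.0, 298.0, 328.0):
            cpx = _series(means, "complex", T=T, n_waters=10)
            host = _series({"W-W:elec": -45.0}, "free_host", T=T, n_waters=10)
            guest = _series({"G-W:elec": 0.0}, "free_guest", T=T, n_waters=0)
            decomps.append(binding_enthalpy(cpx, host, guest))
        cp = heat_capacity_profile(decomps)
        assert all(abs(f.dCp) < 1e-9 for f in cp.channels.values())

    def test_channel_slopes_sum_to_total(self, spec):
        sc = make_energy_ensembles(spec, seed=5)
        decomps = []
        for T in spec.temperatures:
            e = sc.at(T)
            decomps.append(
                binding_enthalpy(e["complex"], e["free_host"], e["free_guest"], e["bulk_water"])
            )
        cp = heat_capacity_profile(decomps)
        assert cp.channels["HG"].dCp + cp.channels["desolv"].dCp == pytest.approx(
            cp.total.dCp, abs=1e-9
        )

    def test_entropy_compensation_fraction_on_default_scenario(self, spec):
        # dG(T) from the scenario is nearly flat, so the fitted -TdS(T)
        # changes should cancel roughly 70% of the dH(T) changes
        from hgthermo.thermo import fit_heat_capacity

        sc = make_energy_ensembles(spec, seed=17)
        temps, dh, mtds = [], [], []
        for T in spec.temperatures:
            e = sc.at(T)
            d = binding_enthalpy(e["complex"], e["free_host"], e["free_guest"], e["bulk_water"])
            dG = sc.truth["per_temperature"][f"{T:g}"]["dG"]
            temps.append(T)
            dh.append(d.dH_total)
            mtds.append(dG - d.dH_total)
        slope_h = fit_heat_capacity(temps, dh).dCp
        slope_mtds = fit_heat_capacity(temps, mtds).dCp
        fraction = slope_mtds / (-slope_h)
        assert 0.60 <= fraction <= 0.80
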