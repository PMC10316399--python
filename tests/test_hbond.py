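"""Hydrogen-bond detection, interaction energies and profile bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from gslnano import (
    HBondCriterion,
    MoietyMap,
    Topology,
    density_profile,
    detect_hbonds,
    energy_summary,
    headgroup_water_hbonds,
    moiety_hbond_table,
    molecular_pair_energies,
    pair_interaction_energy,
    percent_energy_change,
)
from gslnano.hbond import COULOMB_KJ_NM_E2, _block_se
from gslnano import make_membrane_fixture
from gslnano import reference

BOX = np.array([10.0, 10.0, 10.0])


def _water_pair(oo_distance, angle_deg):
    """Two waters: donor O-H aimed at the acceptor O, H tilted by angle."""
    theta = np.deg2rad(angle_deg)
    coords = np.array(
        [
            [5.0, 5.0, 5.0],                                        # donor O
            [5.0 + 0.1 * np.cos(theta), 5.0 + 0.1 * np.sin(theta), 5.0],  # H
            [4.9, 5.4, 5.0],                                        # spectator H
            [5.0 + oo_distance, 5.0, 5.0],                          # acceptor O
            [5.0 + oo_distance + 0.08, 5.06, 5.0],                  # acceptor H
            [5.0 + oo_distance + 0.08, 4.94, 5.0],                  # acceptor H
        ]
    )
    atoms = pd.DataFrame(
        {
            "element": ["O", "H", "H", "O", "H", "H"],
            "charge_e": [-0.6, 0.3, 0.3, -0.6, 0.3, 0.3],
            "sigma_nm": [0.31, 0.1, 0.1, 0.31, 0.1, 0.1],
            "epsilon_kj_mol": [0.65, 0.06, 0.06, 0.65, 0.06, 0.06],
            "mol_id": [0, 0, 0, 1, 1, 1],
            "species": ["water"] * 6,
        }
    )
    topo = Topology(atoms=atoms, bonds=np.array([[0, 1], [0, 2], [3, 4], [3, 5]]))
    return coords, topo


class TestDetectHBonds:
    @pytest.mark.parametrize(
        "oo, angle, expected",
        [
            (0.28, 5.0, 1),   # ideal geometry
            (0.40, 5.0, 0),   # beyond the 0.35 nm distance cutoff
            (0.30, 60.0, 0),  # inside the cutoff but H-D-A angle too large
        ],
    )
    def test_water_dimer_geometry(self, oo, angle, expected):
        coords, topo = _water_pair(oo, angle)
        bonds = detect_hbonds(coords, BOX, topo)
        donors = bonds[:, 0] if len(bonds) else np.array([])
        assert np.sum(donors == 0) == expected

    def test_matches_all_pairs_brute_force(self, rng):
        # 120 random three-atom molecules (O, H, O) in a periodic box
        n_mol = 120
        pos, elem, mol, bonds = [], [], [], []
        for m in range(n_mol):
            o1 = rng.uniform(0, 10, 3)
            h = o1 + rng.normal(scale=0.05, size=3)
            o2 = o1 + rng.normal(scale=0.15, size=3)
            base = len(pos)
            pos += [o1, h, o2]
            elem += ["O", "H", "O"]
            mol += [m, m, m]
            bonds.append([base, base + 1])
        atoms = pd.DataFrame(
            {
                "element": elem,
                "charge_e": np.tile([-0.6, 0.3, 0.3], n_mol),
                "sigma_nm": 0.3,
                "epsilon_kj_mol": 0.5,
                "mol_id": mol,
                "species": "water",
            }
        )
        topo = Topology(atoms=atoms, bonds=np.array(bonds))
        coords = np.array(pos)
        crit = HBondCriterion()
        got = detect_hbonds(coords, BOX, topo, crit, exclude_intramolecular=True)

        # O(N^2) oracle
        expected = []
        elements = atoms["element"].to_numpy()
        mols = atoms["mol_id"].to_numpy()
        cos_max = np.cos(np.deg2rad(crit.max_angle_deg))
        for d, h in topo.bonds:
            for a in np.flatnonzero(elements == "O"):
                if a == d or mols[a] == mols[d]:
                    continue
                da = coords[a] - coords[d]
                da -= BOX * np.round(da / BOX)
                if np.linalg.norm(da) > crit.max_donor_acceptor_nm:
                    continue
                dh = coords[h] - coords[d]
                dh -= BOX * np.round(dh / BOX)
                cosang = (da @ dh) / (np.linalg.norm(da) * np.linalg.norm(dh))
                if cosang >= cos_max:
                    expected.append((d, h, a))
        assert sorted(map(tuple, got)) == sorted(expected)

    def test_orphan_hydrogen_raises(self):
        coords, topo = _water_pair(0.28, 5.0)
        bad = Topology(atoms=topo.atoms, bonds=topo.bonds[:-1])  # drop one O-H bond
        with pytest.raises(ValueError, match="not bonded"):
            detect_hbonds(coords, BOX, bad)


class TestPairEnergy:
    def test_coulomb_constant(self):
        atoms = pd.DataFrame(
            {
                "element": ["N", "O"],
                "charge_e": [1.0, -1.0],
                "sigma_nm": [0.0, 0.0],
                "epsilon_kj_mol": [0.0, 0.0],
                "mol_id": [0, 1],
                "species": ["water", "water"],
            }
        )
        topo = Topology(atoms=atoms, bonds=np.empty((0, 2)))
        coords = np.array([[2.0, 2.0, 2.0], [3.0, 2.0, 2.0]])
        e = pair_interaction_energy(coords, BOX, topo, [0], [1])
        assert e == pytest.approx(-COULOMB_KJ_NM_E2, rel=1e-12)

    def test_symmetry_and_brute_force(self, rng):
        n = 400
        coords = rng.uniform(0, 10, (n, 3))
        atoms = pd.DataFrame(
            {
                "element": "C",
                "charge_e": 0.0,
                "sigma_nm": rng.uniform(0.25, 0.35, n),
                "epsilon_kj_mol": rng.uniform(0.1, 0.8, n),
                "mol_id": np.arange(n) // 4,
                "species": "DOPC",
            }
        )
        q = rng.uniform(-0.5, 0.5, n)
        q -= np.repeat(
            np.bincount(atoms["mol_id"], weights=q) / 4, 4
        )  # neutral molecules
        atoms["charge_e"] = q
        topo = Topology(atoms=atoms, bonds=np.empty((0, 2)))
        ga, gb = np.arange(0, 40), np.arange(40, n)
        e_ab = pair_interaction_energy(coords, BOX, topo, ga, gb, cutoff_nm=1.2)
        e_ba = pair_interaction_energy(coords, BOX, topo, gb, ga, cutoff_nm=1.2)
        assert e_ab == pytest.approx(e_ba, rel=1e-12)

        # brute force O(N^2)
        sig = atoms["sigma_nm"].to_numpy()
        eps = atoms["epsilon_kj_mol"].to_numpy()
        expected = 0.0
        for i in ga:
            for j in gb:
                d = coords[i] - coords[j]
                d -= BOX * np.round(d / BOX)
                r = np.linalg.norm(d)
                if r > 1.2:
                    continue
                sij = 0.5 * (sig[i] + sig[j])
                eij = np.sqrt(eps[i] * eps[j])
                sr6 = (sij / r) ** 6
                expected += COULOMB_KJ_NM_E2 * q[i] * q[j] / r + 4 * eij * (
                    sr6**2 - sr6
                )
        assert e_ab == pytest.approx(expected, rel=1e-10)

    def test_overlapping_atoms_rejected(self):
        atoms = pd.DataFrame(
            {
                "element": ["O", "O"],
                "charge_e": [0.0, 0.0],
                "sigma_nm": [0.3, 0.3],
                "epsilon_kj_mol": [0.5, 0.5],
                "mol_id": [0, 1],
                "species": ["water", "water"],
            }
        )
        topo = Topology(atoms=atoms, bonds=np.empty((0, 2)))
        coords = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0 + 1e-4]])
        with pytest.raises(ValueError, match="verlapping"):
            pair_interaction_energy(coords, BOX, topo, [0], [1])

    def test_disjoint_groups_required(self):
        coords, topo = _water_pair(0.28, 5.0)
        with pytest.raises(ValueError, match="disjoint"):
            pair_interaction_energy(coords, BOX, topo, [0, 1], [1, 2])


class TestPlantedFixtures:
    def test_planted_bonds_recovered_exactly(self):
        coords, topo, mmap, truth = make_membrane_fixture(
            n_gsl=2, species="GM1", planted_bonds=[("Sia3", "Sia3", 4)],
            n_water=0, box=14.0, seed=5,
        )
        bonds = detect_hbonds(coords, np.full(3, 14.0), topo)
        assert len(bonds) == 4
        assert sorted(map(tuple, bonds)) == sorted(map(tuple, truth["hbonds"]))

    def test_decoys_only_yield_nothing(self):
        coords, topo, mmap, truth = make_membrane_fixture(
            n_gsl=2, species="GM1", planted_bonds=[], n_water=4, box=14.0,
            seed=2, n_decoys=6,
        )
        assert len(detect_hbonds(coords, np.full(3, 14.0), topo)) == 0

    def test_moiety_table_attribution(self):
        # 3 Sia3-Sia3 bonds among 2 GSLs -> 1.5 bonds per molecule on Sia3
        coords, topo, mmap, _ = make_membrane_fixture(
            n_gsl=2, species="GM1",
            planted_bonds=[("Sia3", "Sia3", 3), ("Gal2", "GalNAc4", 2)],
            box=16.0, seed=1,
        )
        table = moiety_hbond_table(coords, np.full(3, 16.0), topo, mmap)
        row = table.mean.loc["GM1"]
        assert row["Sia3"] == pytest.approx(1.5)
        assert row["Gal2"] == pytest.approx(0.5)     # 2 bonds x 0.5 / 2 molecules
        assert row["GalNAc4"] == pytest.approx(0.5)
        assert table.total["GM1"] == pytest.approx(2.5)  # 5 bonds / 2 molecules
        assert table.total["GM1"] == pytest.approx(row.sum())

    def test_ground_truth_energies_match_analysis(self):
        coords, topo, mmap, truth = make_membrane_fixture(
            n_gsl=3, species="GD1a", planted_bonds=[("Sia6", "Gal2", 3)],
            n_water=5, box=16.0, seed=7,
        )
        box = np.full(3, 16.0)
        mol = topo.atoms["mol_id"].to_numpy()
        for key, e_true in truth["pair_energies"].items():
            i, j = map(int, key.split("|"))
            e = pair_interaction_energy(
                coords, box, topo,
                np.flatnonzero(mol == i), np.flatnonzero(mol == j),
            )
            assert e == pytest.approx(e_true, rel=1e-10)

    def test_headgroup_water_counts_and_fraction(self):
        coords, topo, mmap, _ = make_membrane_fixture(
            n_gsl=2, species="GM1",
            planted_bonds=[("Sia3", "water", 4), ("Gal5", "water", 6)],
            box=18.0, seed=3,
        )
        table = headgroup_water_hbonds(coords, np.full(3, 18.0), topo, mmap)
        hg = table[table["moiety"] == "headgroup"].iloc[0]
        sia = table[table["moiety"] == "Sia3"].iloc[0]
        assert hg["bonds_per_gsl"] == pytest.approx(5.0)   # 10 bonds / 2 GSLs
        assert sia["bonds_per_gsl"] == pytest.approx(2.0)
        assert sia["sia_fraction_pct"] == pytest.approx(40.0)

    def test_isolated_mode_restricts_to_one_molecule(self):
        coords, topo, mmap, _ = make_membrane_fixture(
            n_gsl=2, species="GM1", planted_bonds=[("Sia3", "water", 4)],
            box=18.0, seed=3,
        )
        box = np.full(3, 18.0)
        # fixture alternates donor molecules 0,1,0,1 -> molecule 0 carries 2
        iso = headgroup_water_hbonds(
            coords, box, topo, mmap, mode="isolated", isolated_mol_id=0
        )
        assert iso[iso["moiety"] == "headgroup"].iloc[0]["bonds_per_gsl"] == 2.0
        with pytest.raises(ValueError, match="designated"):
            headgroup_water_hbonds(coords, box, topo, mmap, mode="isolated")

    def test_no_water_reports_missing_fraction(self):
        coords, topo, mmap, _ = make_membrane_fixture(
            n_gsl=2, species="GM1", planted_bonds=[("Sia3", "Sia3", 2)],
            n_water=0, box=14.0, seed=4,
        )
        table = headgroup_water_hbonds(coords, np.full(3, 14.0), topo, mmap)
        assert (table["bonds_per_gsl"] == 0).all()
        assert table["sia_fraction_pct"].isna().all()


class TestEnergySummary:
    def test_per_class_totals_and_normalisation(self):
        pair = pd.DataFrame(
            {
                "gsl_mol": [0, 0, 0, 1, 1],
                "partner_mol": [1, 2, 3, 0, 3],
                "gsl_species": ["GM1"] * 5,
                "partner_species": ["GM1", "DOPC", "DOPC", "GM1", "DOPC"],
                "contact_fraction": [1.0, 1.0, 0.2, 1.0, 0.6],
                "mean_energy_kj_mol": [-56.0, -40.0, -5.0, -56.0, -30.0],
            }
        )
        table = energy_summary(pair, partner_min_fraction=0.5).table
        # per GSL (2 molecules): GSL/GSL total (-56-56)/2, DOPC (-40-30)/2
        assert table.loc["GSL/GSL", "total_kj_mol"] == pytest.approx(-56.0)
        assert table.loc["GSL/DOPC", "total_kj_mol"] == pytest.approx(-35.0)
        assert table.loc["GSL/GSL", "normalized_kj_mol"] == pytest.approx(-56.0)
        assert table.loc["GSL/DOPC", "normalized_kj_mol"] == pytest.approx(-35.0)
        np.testing.assert_allclose(
            table["normalized_kj_mol"],
            table["total_kj_mol"] / table["n_partners"],
        )

    def test_fixture_class_bookkeeping(self):
        coords, topo, mmap, truth = make_membrane_fixture(
            n_gsl=2, species="GM1", planted_bonds=[("Sia3", "Sia3", 3)],
            n_water=6, box=16.0, seed=9,
        )
        pair = molecular_pair_energies(coords, np.full(3, 16.0), topo)
        table = energy_summary(pair, partner_min_fraction=0.5).table
        # hand computation from the generator's analytic ground truth
        gsl_gsl = truth["pair_energies"].get("0|1", 0.0)
        assert table.loc["GSL/GSL", "total_kj_mol"] == pytest.approx(
            gsl_gsl, rel=1e-9
        )

    def test_normalized_missing_when_no_partner(self):
        pair = pd.DataFrame(
            {
                "gsl_mol": [0],
                "partner_mol": [1],
                "gsl_species": ["GM1"],
                "partner_species": ["DOPC"],
                "contact_fraction": [0.1],
                "mean_energy_kj_mol": [-1.0],
            }
        )
        table = energy_summary(pair, partner_min_fraction=0.5).table
        assert np.isnan(table.loc["GSL/DOPC", "normalized_kj_mol"])


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref, new, expected",
        [(-35.0, -56.0, 60.0), (-35.0, -35.0, 0.0), (-35.0, -51.0, 45.714285714)],
    )
    def test_magnitude_change(self, ref, new, expected):
        assert percent_energy_change(ref, new) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_energy_change(0.0, -10.0)


class TestReferenceTableArithmetic:
    """The published tables must be internally consistent under our rules."""

    def test_hbond_row_totals(self):
        totals = reference.GSL_GSL_HBONDS.sum(axis=1, skipna=True)
        assert totals["GM1"] == pytest.approx(6.2)
        assert totals["GD1a"] == pytest.approx(10.0)
        assert totals["GM3"] == pytest.approx(4.7)
        assert totals["asialoGM1"] == pytest.approx(2.8)

    def test_sia_water_fractions(self):
        ref = reference.HEADGROUP_WATER_HBONDS.set_index(["species", "group"])
        gm1 = 100 * ref.loc[("GM1", "Sia1"), "nanodomain"] / ref.loc[
            ("GM1", "headgroup"), "nanodomain"
        ]
        gd1a = 100 * ref.loc[("GD1a", "Sia2"), "nanodomain"] / ref.loc[
            ("GD1a", "headgroup"), "nanodomain"
        ]
        assert round(gm1, 1) == 37.4
        assert round(gd1a, 1) == 29.0

    def test_sia_gain_in_interaction_energy(self):
        e = reference.GSL_INTERACTION_ENERGIES["GSL_GSL"]
        assert round(percent_energy_change(e["asialoGM1"], e["GM1"])) == 60
        assert percent_energy_change(e["asialoGM1"], e["GD1a"]) == pytest.approx(
            45.7, abs=0.05
        )


class TestDensityProfile:
    def test_uniform_is_flat(self, rng):
        coords = rng.uniform(0, 10, (1, 4000, 3))
        prof = density_profile(
            coords, BOX, np.arange(4000), n_bins=20, normalization="none"
        )
        expected = 4000 / 10.0
        se = np.sqrt(4000 / 20) / 0.5  # Poisson per bin / bin width
        assert np.all(np.abs(prof["density"] - expected) <= 3 * se)

    def test_integral_recovers_count(self, rng):
        coords = rng.uniform(0, 10, (3, 500, 3))
        prof = density_profile(
            coords, BOX, np.arange(500), n_bins=25, normalization="none"
        )
        width = 10.0 / 25
        assert prof["density"].sum() * width == pytest.approx(500.0)

    def test_planted_gaussian_mean_recovered(self, rng):
        n = 5000
        z = np.clip(rng.normal(6.0, 0.8, n), 0.01, 9.99)
        coords = np.c_[rng.uniform(0, 10, n), rng.uniform(0, 10, n), z][None]
        prof = density_profile(coords, BOX, np.arange(n), n_bins=50,
                               normalization="none")
        mu = np.average(prof["bin_center_nm"], weights=prof["density"])
        assert abs(mu - 6.0) <= 3 * 0.8 / np.sqrt(n) + 0.1  # binning offset slack

    def test_peak_normalisation_and_errors(self, rng):
        coords = rng.uniform(0, 10, (1, 100, 3))
        prof = density_profile(coords, BOX, np.arange(100), n_bins=10)
        assert prof["density"].max() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            density_profile(coords, BOX, np.array([]), n_bins=10)
        with pytest.raises(ValueError):
            density_profile(coords, BOX, np.arange(100), n_bins=5)


def test_block_se_decreases_with_more_frames(rng):
    series = rng.normal(size=(400, 1))
    se_short = _block_se(series[:100], 10)
    se_long = _block_se(series, 40)
    assert se_long[0] < se_short[0]
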