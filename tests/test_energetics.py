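import numpy as np
import pytest

from dockmd import energetics as en
from dockmd.synthetic import ToyComplexSpec, gen_toy_complex


def _cluster(rng, n, spread=6.0, min_sep=1.8):
    """Random cluster with a minimum separation (rejection sampling)."""
    pts = [rng.uniform(-spread, spread, 3)]
    while len(pts) < n:
        cand = rng.uniform(-spread, spread, 3)
        if min(np.linalg.norm(cand - p) for p in pts) >= min_sep:
            pts.append(cand)
    return np.array(pts)


class TestCoulomb:
    def test_unit_charge_pair_at_3A(self):
        coords = np.array([[0.0, 0, 0], [0, 0, 3.0]])
        e = en.coulomb_energy(coords, [1.0, -1.0])
        assert e == pytest.approx(-en.COULOMB_CONSTANT / 3.0)
        assert e == pytest.approx(-110.68, abs=0.005)

    def test_zero_charges(self, rng):
        coords = _cluster(rng, 5)
        assert en.coulomb_energy(coords, np.zeros(5)) == 0.0

    def test_doubling_distances_halves_energy(self, rng):
        coords = _cluster(rng, 6)
        q = rng.uniform(-1, 1, 6)
        assert en.coulomb_energy(2 * coords, q) == pytest.approx(
            0.5 * en.coulomb_energy(coords, q)
        )

    def test_matches_bruteforce_double_loop(self, rng):
        coords = _cluster(rng, 20)
        q = rng.uniform(-0.8, 0.8, 20)
        expected = 0.0
        for i in range(20):
            for j in range(i + 1, 20):
                expected += (
                    en.COULOMB_CONSTANT * q[i] * q[j]
                    / np.linalg.norm(coords[i] - coords[j])
                )
        assert en.coulomb_energy(coords, q) == pytest.approx(expected, abs=1e-10)

    def test_exclusions_and_14_scaling(self):
        # linear 4-atom chain: 1-2/1-3 excluded, 1-4 divided by 1.2
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [4.5, 0, 0]])
        q = np.array([0.5, -0.5, 0.5, -0.5])
        bonds = [(0, 1), (1, 2), (2, 3)]
        excl = en.exclusion_tables(4, bonds)
        e = en.coulomb_energy(coords, q, excl)
        expected = en.COULOMB_CONSTANT * q[0] * q[3] / 4.5 / 1.2
        assert e == pytest.approx(expected, abs=1e-12)


class TestLennardJones:
    def test_minimum_at_r_min(self):
        sigma = 3.4
        r_min = 2 ** (1 / 6) * sigma
        coords = np.array([[0.0, 0, 0], [r_min, 0, 0]])
        e = en.lj_energy(coords, [sigma, sigma], [0.25, 0.25])
        assert e == pytest.approx(-0.25, abs=1e-12)

    def test_vanishes_at_long_range(self):
        coords = np.array([[0.0, 0, 0], [500.0, 0, 0]])
        assert en.lj_energy(coords, [3.4, 3.4], [0.25, 0.25]) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_matches_bruteforce_double_loop(self, rng):
        n = 20
        coords = _cluster(rng, n, min_sep=2.5)
        sig = rng.uniform(2.5, 3.8, n)
        eps = rng.uniform(0.05, 0.3, n)
        expected = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                s = 0.5 * (sig[i] + sig[j])
                e_ij = np.sqrt(eps[i] * eps[j])
                r = np.linalg.norm(coords[i] - coords[j])
                expected += 4 * e_ij * ((s / r) ** 12 - (s / r) ** 6)
        assert en.lj_energy(coords, sig, eps) == pytest.approx(expected, abs=1e-10)


class TestBornRadii:
    def test_isolated_atom_offset_corrected(self):
        b = en.born_radii_hct(np.zeros((1, 3)), [1.7], [0.72])
        assert b[0] == pytest.approx(1.7 - 0.09)

    def test_neighbor_descreening_grows_radius(self, rng):
        # burial removes solvent: the effective radius can only grow, and the
        # self-solvation energy -1/B can only shrink in magnitude
        for _ in range(20):
            coords = _cluster(rng, 2, spread=4.0, min_sep=2.0)
            solo = en.born_radii_hct(coords[:1], [1.7], [0.72])[0]
            pair = en.born_radii_hct(coords, [1.7, 1.6], [0.72, 0.79])[0]
            assert pair >= solo - 1e-12

    def test_closer_neighbor_descreens_more(self):
        radii, screen = [1.7, 1.6], [0.72, 0.79]
        far = en.born_radii_hct(
            np.array([[0.0, 0, 0], [6.0, 0, 0]]), radii, screen
        )[0]
        near = en.born_radii_hct(
            np.array([[0.0, 0, 0], [2.5, 0, 0]]), radii, screen
        )[0]
        assert near > far

    def test_symmetric_dimer_equal_radii(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        b = en.born_radii_hct(coords, [1.5, 1.5], [0.8, 0.8])
        assert b[0] == pytest.approx(b[1])

    def test_missing_radius_names_atom(self):
        with pytest.raises(ValueError, match="atom 1"):
            en.born_radii_hct(np.zeros((2, 3)), [1.5, np.nan], [0.8, 0.8])

    def test_deeply_buried_atom_grows(self):
        # an atom surrounded by a shell has a larger effective radius
        shell = []
        for phi in np.linspace(0, np.pi, 5)[1:-1]:
            for theta in np.linspace(0, 2 * np.pi, 7)[:-1]:
                shell.append(
                    3.0 * np.array(
                        [np.sin(phi) * np.cos(theta),
                         np.sin(phi) * np.sin(theta), np.cos(phi)]
                    )
                )
        coords = np.vstack([[0.0, 0, 0], shell])
        n = len(coords)
        b = en.born_radii_hct(coords, [1.5] * n, [0.8] * n)
        assert b[0] > 1.5 - 0.09


class TestGBEnergy:
    def test_born_ion_closed_form_across_radii(self):
        # monoatomic solute: G = -(k/2)(1/eps_in - 1/eps_out) q^2 / R
        for radius in np.linspace(1.0, 5.0, 9):
            got = en.gb_energy(np.zeros((1, 3)), [1.0], [radius])
            expected = -0.5 * en.COULOMB_CONSTANT * (1 - 1 / 80.0) / radius
            assert abs(got - expected) / abs(expected) < 1e-8

    def test_printed_example_value(self):
        assert en.gb_energy(np.zeros((1, 3)), [1.0], [2.0]) == pytest.approx(
            -81.98, abs=0.005
        )

    def test_zero_charges(self, rng):
        coords = _cluster(rng, 4)
        assert en.gb_energy(coords, np.zeros(4), np.full(4, 1.5)) == 0.0

    def test_fgb_approaches_r_at_long_range(self):
        b = np.array([2.0, 3.0])
        r = 50 * b.max()
        f = np.sqrt(r**2 + b[0] * b[1] * np.exp(-(r**2) / (4 * b[0] * b[1])))
        assert abs(f - r) / r < 1e-6
        # and the pair energy matches the screened-Coulomb limit
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        got = en.gb_energy(coords, [1.0, -1.0], b)
        self_terms = en.gb_energy(np.zeros((1, 3)), [1.0], b[:1]) + en.gb_energy(
            np.zeros((1, 3)), [-1.0], b[1:]
        )
        pair = got - self_terms
        expected_pair = en.COULOMB_CONSTANT * (1 - 1 / 80.0) / r
        assert pair == pytest.approx(expected_pair, rel=1e-6)


class TestSasa:
    def test_lcpo_isolated_sphere(self):
        lcpo = np.array([[1.0, 0.0, 0.0, 0.0, 2.0]])
        per_atom, total = en.sasa_lcpo(np.zeros((1, 3)), lcpo)
        assert total == pytest.approx(4 * np.pi * 3.4**2)
        assert total == pytest.approx(145.27, abs=0.01)

    def test_far_separated_additivity(self):
        lcpo = np.array([[1.0, -1.0, 0.0, 0.0, 1.7]] * 2)
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        _, total = en.sasa_lcpo(coords, lcpo)
        _, single = en.sasa_lcpo(coords[:1], lcpo[:1])
        assert total == pytest.approx(2 * single)

    def test_numeric_sphere_within_1pct(self):
        got = en.sasa_numeric(np.zeros((1, 3)), np.array([2.0]))
        expected = 4 * np.pi * 3.4**2
        assert abs(got - expected) / expected < 0.01

    def test_numeric_buried_atom_zero(self):
        # small atom fully inside a big one
        coords = np.array([[0.0, 0, 0], [0.5, 0, 0]])
        got_total = en.sasa_numeric(coords, np.array([5.0, 0.5]))
        solo = en.sasa_numeric(np.zeros((1, 3)), np.array([5.0]))
        assert got_total == pytest.approx(solo, rel=1e-9)

    def test_numeric_point_count_convergence(self, rng):
        coords = _cluster(rng, 8, spread=4.0, min_sep=2.0)
        radii = rng.uniform(1.4, 2.0, 8)
        a = en.sasa_numeric(coords, radii, n_points=960)
        b = en.sasa_numeric(coords, radii, n_points=1920)
        assert abs(a - b) / b < 0.005

    def test_lcpo_within_15pct_of_numeric(self, rng):
        for n in (5, 9, 14, 20):
            radii = rng.uniform(1.4, 2.0, n)
            coords = _cluster(rng, n, spread=0.45 * n ** (1 / 1.5) + 3,
                              min_sep=2.4 * radii.mean())
            lcpo = np.column_stack(
                [np.ones(n), -np.ones(n), np.zeros(n), np.zeros(n), radii]
            )
            _, analytic = en.sasa_lcpo(coords, lcpo)
            numeric = en.sasa_numeric(coords, radii)
            assert abs(analytic - numeric) / numeric < 0.15


class TestGnp:
    def test_zero_sasa_gives_beta(self):
        assert en.gnp(0.0) == pytest.approx(0.92)

    def test_thousand_A2(self):
        assert en.gnp(1000.0) == pytest.approx(6.34)

    def test_linearity(self):
        assert en.gnp(500.0) - en.gnp(0.0) == pytest.approx(
            0.5 * (en.gnp(1000.0) - en.gnp(0.0))
        )


class TestMmgbsa:
    def _toy(self, q=0.4, sep=3.0):
        spec = ToyComplexSpec(
            host_atom_count=1, ligand_atom_count=1,
            charges=np.array([q, -q]), separation=sep,
        )
        return gen_toy_complex(spec)

    def test_empty_ligand_gives_exact_zero(self):
        s = self._toy()
        report = en.mmgbsa_binding(
            s.coords[None], s, receptor_mask=np.array([True, True]),
            ligand_mask=np.array([False, False]),
        )
        row = report.per_frame.iloc[0]
        for term in report.TERMS:
            assert row[term] == 0.0

    def test_delta_eele_equals_pair_coulomb(self):
        s = self._toy(q=1.0, sep=3.0)
        report = en.mmgbsa_binding(
            s.coords[None], s, receptor_mask=np.array([True, False]),
            ligand_mask=np.array([False, True]),
        )
        expected = en.COULOMB_CONSTANT * 1.0 * (-1.0) / 3.0
        assert report.per_frame.iloc[0]["dE_ele"] == pytest.approx(
            expected, abs=1e-10
        )

    def test_bookkeeping_identity_per_frame(self, rng):
        spec = ToyComplexSpec(
            host_atom_count=6, ligand_atom_count=2,
            charges=rng.uniform(-0.5, 0.5, 8), jitter=0.05, geometry_seed=3,
        )
        s = gen_toy_complex(spec)
        frames = s.coords[None] + rng.normal(scale=0.05, size=(4, 8, 3))
        report = en.mmgbsa_binding(
            frames, s, receptor_mask=~s.is_ligand(), ligand_mask=s.is_ligand()
        )
        pf = report.per_frame
        lhs = pf["dH"]
        rhs = pf["dE_vdw"] + pf["dE_ele"] + pf["dG_GB"] + pf["dG_NP"]
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)
        np.testing.assert_allclose(pf["dG_sol"], pf["dG_GB"] + pf["dG_NP"], atol=1e-12)

    def test_invariant_under_rigid_transform(self, rng):
        from scipy.spatial.transform import Rotation

        spec = ToyComplexSpec(
            host_atom_count=5, ligand_atom_count=1,
            charges=rng.uniform(-0.4, 0.4, 6), geometry_seed=1,
        )
        s = gen_toy_complex(spec)
        base = en.mmgbsa_binding(
            s.coords[None], s, ~s.is_ligand(), s.is_ligand()
        ).per_frame.iloc[0]
        rot = Rotation.from_rotvec([1.0, -0.3, 0.7])
        moved = rot.apply(s.coords) + np.array([10.0, -5.0, 2.0])
        other = en.mmgbsa_binding(
            moved[None], s, ~s.is_ligand(), s.is_ligand()
        ).per_frame.iloc[0]
        for term in ("dE_vdw", "dE_ele", "dG_GB", "dG_NP", "dG_binding"):
            assert other[term] == pytest.approx(base[term], abs=1e-8)

    def test_overlapping_masks_rejected(self):
        s = self._toy()
        with pytest.raises(ValueError, match="overlap"):
            en.mmgbsa_binding(
                s.coords[None], s, np.array([True, True]), np.array([False, True])
            )

    def test_report_flags_entropy_not_computed(self):
        s = self._toy()
        report = en.mmgbsa_binding(
            s.coords[None], s, ~s.is_ligand(), s.is_ligand()
        )
        assert report.entropy_computed is False
        summary = report.summary()
        de_int = summary[summary["term"] == "dE_int"].iloc[0]
        assert de_int["mean_kcal_mol"] == 0.0
        tds = summary[summary["term"] == "-T_dS"].iloc[0]
        assert np.isnan(tds["mean_kcal_mol"])

    def test_report_json_tsv_outputs(self, tmp_path):
        s = self._toy()
        report = en.mmgbsa_binding(
            s.coords[None], s, ~s.is_ligand(), s.is_ligand()
        )
        report.to_tsv(tmp_path / "r.tsv")
        report.to_json(tmp_path / "r.json")
        import json

        doc = json.loads((tmp_path / "r.json").read_text())
        assert doc["dE_int"] == 0.0
        assert len(doc["per_frame"]["dG_binding"]) == 1
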