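"""Scoring terms, presets, pair energies and energy sums."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vinakit.atomtypes import InteractionClass, TypedAtom, assign_interaction_classes
from vinakit.params import TermParameterSet, dump_params, load_params
from vinakit.pdbqt import LigandModel, ReceptorModel
from vinakit.scoring import (
    gauss_term,
    hbond_term,
    hydrophobic_term,
    intermolecular_energy,
    intramolecular_energy,
    lj_mn_term,
    pair_energy,
    predicted_affinity,
    repulsion_term,
    steric_profile,
    surface_distance,
    term_contributions,
)

from conftest import make_atom

HP = InteractionClass.HYDROPHOBIC


class TestPresets:
    def test_vina_table_values(self, vina):
        assert (vina.w1, vina.w2, vina.w3, vina.w4, vina.w5) == (
            -0.035579, -0.005156, 0.840245, -0.035069, -0.587439,
        )
        assert (vina.o1, vina.s1, vina.o2, vina.s2) == (0.0, 0.5, 3.0, 2.0)
        assert (vina.p1, vina.p2, vina.h1) == (0.5, 1.5, -0.7)
        assert vina.gauss2_enabled
        assert {t: vina.radii[t] for t in "C A N O".split()} == {
            "C": 1.9, "A": 1.9, "N": 1.8, "O": 1.7,
        }

    def test_vinardo_table_values(self, vinardo):
        assert (vinardo.w1, vinardo.w2, vinardo.w3, vinardo.w4, vinardo.w5) == (
            -0.045, 0.0, 0.8, -0.035, -0.6,
        )
        assert (vinardo.o1, vinardo.s1) == (0.0, 0.8)
        assert (vinardo.p1, vinardo.p2, vinardo.h1) == (0.0, 2.5, -0.6)
        assert not vinardo.gauss2_enabled
        assert {t: vinardo.radii[t] for t in "C A N O".split()} == {
            "C": 2.0, "A": 1.9, "N": 1.7, "O": 1.6,
        }

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="p1"):
            TermParameterSet(p1=2.0, p2=1.0)
        with pytest.raises(ValueError, match="h1"):
            TermParameterSet(h1=0.2)
        with pytest.raises(ValueError, match="s1"):
            TermParameterSet(s1=-1.0)

    def test_dump_load_round_trip(self, vinardo):
        back = load_params(dump_params(vinardo))
        assert back == vinardo


class TestElementaryTerms:
    @pytest.mark.parametrize(
        "r, ri, rj, expect",
        [(3.8, 1.9, 1.9, 0.0), (6.8, 1.9, 1.9, 3.0), (3.0, 2.0, 1.6, -0.6)],
    )
    def test_surface_distance(self, r, ri, rj, expect):
        assert surface_distance(r, ri, rj) == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize(
        "d, o, s, expect",
        [(0.0, 0.0, 0.8, 1.0), (0.8, 0.0, 0.8, np.exp(-1)), (0.0, 3.0, 2.0, np.exp(-2.25))],
    )
    def test_gauss(self, d, o, s, expect):
        assert gauss_term(d, o, s) == pytest.approx(expect, rel=1e-9)

    @pytest.mark.parametrize("d, expect", [(-0.5, 0.25), (0.0, 0.0), (1.0, 0.0)])
    def test_repulsion(self, d, expect):
        assert repulsion_term(d) == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize(
        "d, p1, p2, expect",
        [(1.0, 0.5, 1.5, 0.5), (1.25, 0.0, 2.5, 0.5), (2.5, 0.0, 2.5, 0.0)],
    )
    def test_hydrophobic(self, d, p1, p2, expect):
        assert hydrophobic_term(d, p1, p2) == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize(
        "d, h1, expect", [(-0.6, -0.6, 1.0), (-0.3, -0.6, 0.5), (0.2, -0.6, 0.0)]
    )
    def test_hbond(self, d, h1, expect):
        assert hbond_term(d, h1) == pytest.approx(expect, abs=1e-12)

    def test_lj_minimum_asymptote_and_closed_form(self):
        assert lj_mn_term(2.5, 4, 8, well_depth=1.3, r_min=2.5) == pytest.approx(-1.3)
        assert lj_mn_term(1e6, 4, 8, well_depth=1.3, r_min=2.5) == pytest.approx(0.0, abs=1e-12)
        # 4-8 form at r = r_min * 2^(1/4): q^8 = 1/4, q^4 = 1/2
        expect = 1.0 / 4.0 * (4 * 0.25 - 8 * 0.5)
        assert lj_mn_term(2.0 ** 0.25, 4, 8) == pytest.approx(expect, rel=1e-12)
        with pytest.raises(ValueError):
            lj_mn_term(1.0, 8, 4)

    @given(st.floats(-1.5, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_term_ranges(self, d):
        assert 0.0 < gauss_term(d, 0.0, 0.8) <= 1.0
        assert repulsion_term(d) >= 0.0
        assert 0.0 <= hydrophobic_term(d, 0.0, 2.5) <= 1.0
        assert 0.0 <= hbond_term(d, -0.6) <= 1.0

    def test_piecewise_terms_continuous(self):
        # dense scan across all joints; max step bounded by slope * h
        d = np.linspace(-2.0, 3.5, 110001)
        h = d[1] - d[0]
        for vals, slope in [
            (repulsion_term(d), 4.5),
            (hydrophobic_term(d, 0.5, 1.5), 1.1),
            (hydrophobic_term(d, 0.0, 2.5), 0.5),
            (hbond_term(d, -0.6), 1.8),
            (hbond_term(d, -0.7), 1.6),
        ]:
            assert np.max(np.abs(np.diff(vals))) <= slope * h + 1e-12


class TestPairEnergy:
    def test_vina_aromatic_carbon_vs_nitrogen(self, vina):
        a = make_atom("A", HP)
        b = make_atom("N", InteractionClass.POLAR_NONHB)
        # d = 0: steric terms only, no hydrophobic (b polar), no hbond
        expect = -0.035579 - 0.005156 * np.exp(-2.25)
        assert pair_energy(a, b, 3.7, vina) == pytest.approx(expect, abs=1e-6)
        assert expect == pytest.approx(-0.036122, abs=1e-6)

    def test_vinardo_hydrophobic_contact(self, vinardo):
        a = make_atom("A", HP)
        b = make_atom("A", HP, serial=2)
        assert pair_energy(a, b, 3.8, vinardo) == pytest.approx(-0.080, abs=1e-9)

    def test_vinardo_donor_acceptor(self, vinardo):
        donor = make_atom("N", InteractionClass.DONOR)
        acceptor = make_atom("OA", InteractionClass.ACCEPTOR, serial=2)
        # r = 1.7 + 1.6 - 0.6 -> d = -0.6
        expect = 0.8 * 0.36 - 0.045 * np.exp(-0.5625) - 0.600 * 1.0
        got = pair_energy(donor, acceptor, 2.7, vinardo)
        assert got == pytest.approx(expect, abs=1e-9)
        assert got == pytest.approx(-0.33764, abs=1e-5)

    def test_pair_energy_symmetric(self, vina, vinardo):
        rng = np.random.default_rng(7)
        pairs = [
            (make_atom("A", HP), make_atom("C", HP, serial=2)),
            (make_atom("N", InteractionClass.DONOR), make_atom("OA", InteractionClass.ACCEPTOR, serial=2)),
            (make_atom("OA", InteractionClass.DONOR_ACCEPTOR), make_atom("OA", InteractionClass.DONOR_ACCEPTOR, serial=2)),
        ]
        for params in (vina, vinardo):
            for a, b in pairs:
                for r in rng.uniform(1.5, 9.0, size=5):
                    assert pair_energy(a, b, r, params) == pytest.approx(
                        pair_energy(b, a, r, params), abs=1e-12
                    )

    def test_metal_scores_as_donor(self, vinardo):
        metal = make_atom("Zn", InteractionClass.METAL, element="Zn")
        acceptor = make_atom("OA", InteractionClass.ACCEPTOR, serial=2)
        carbon = make_atom("C", HP, serial=3)
        r = vinardo.radii["metal"] + vinardo.radii["O"] - 0.3  # d = -0.3
        with_hb = pair_energy(metal, acceptor, r, vinardo)
        base = (
            vinardo.w1 * gauss_term(-0.3, 0, 0.8)
            + vinardo.w3 * repulsion_term(-0.3)
        )
        assert with_hb == pytest.approx(base + vinardo.w5 * 0.5, abs=1e-12)
        # metal vs plain carbon: steric only
        r2 = vinardo.radii["metal"] + vinardo.radii["C"] - 0.3
        assert pair_energy(metal, carbon, r2, vinardo) == pytest.approx(base, abs=1e-12)


class TestStericShape:
    def test_vinardo_single_minimum_at_contact(self, vinardo):
        for ri, rj in [(1.9, 1.9), (2.0, 2.0), (2.0, 1.6), (1.7, 1.6)]:
            r = np.arange(max(0.05, ri + rj - 3.0), 12.0, 0.001)
            e = steric_profile(r, ri, rj, vinardo)
            interior = (e[1:-1] < e[:-2]) & (e[1:-1] < e[2:])
            minima = r[1:-1][interior]
            assert len(minima) == 1
            assert minima[0] == pytest.approx(ri + rj, abs=0.002)

    def test_vina_two_minima_outer_at_6p8(self, vina):
        r = np.arange(3.0, 12.0, 0.001)
        e = steric_profile(r, 1.9, 1.9, vina)
        interior = (e[1:-1] < e[:-2]) & (e[1:-1] < e[2:])
        minima = r[1:-1][interior]
        assert len(minima) == 2
        assert minima[-1] == pytest.approx(6.8, abs=0.05)
        # equivalently: 3 A beyond the sum of the radii
        assert minima[-1] - 3.8 == pytest.approx(3.0, abs=0.05)


def _random_complex(rng, n_lig=4, n_rec=15):
    def atoms(n, prefix):
        ad_types = ["C", "A", "OA", "N"]
        out = [
            TypedAtom(
                serial=i + 1,
                name=f"{prefix}{i}",
                element={"C": "C", "A": "C", "OA": "O", "N": "N"}[ad_types[i % 4]],
                coords=rng.uniform(-6, 6, size=3),
                partial_charge=0.0,
                ad_type=ad_types[i % 4],
            )
            for i in range(n)
        ]
        return assign_interaction_classes(out)

    lig = LigandModel(atoms(n_lig, "L"), [tuple(range(n_lig))], [], 0)
    rec = ReceptorModel(atoms(n_rec, "R"))
    return lig, rec


class TestEnergySums:
    def test_single_pair_equals_pair_energy(self, single_pair_pocket, vinardo):
        rec, lig, _ = single_pair_pocket
        bd = intermolecular_energy(lig, rec, vinardo)
        r = float(np.linalg.norm(lig.atoms[0].coords - rec.atoms[0].coords))
        assert bd.total == pytest.approx(
            pair_energy(lig.atoms[0], rec.atoms[0], r, vinardo), abs=1e-12
        )
        assert bd.n_pairs_evaluated == 1

    def test_beyond_cutoff_contributes_zero(self, vinardo):
        a = make_atom("A", HP)
        b = TypedAtom(2, "R", "C", np.array([9.0 + 3.8, 0, 0]), 0.0, "A", HP)
        lig = LigandModel([a], [(0,)], [], 0)
        rec = ReceptorModel([b])
        bd = intermolecular_energy(lig, rec, vinardo)
        assert bd.total == 0.0
        assert bd.n_pairs_evaluated == 0

    def test_matches_brute_force_double_loop(self, vina, vinardo):
        for trial in range(50):
            rng = np.random.default_rng(1000 + trial)
            lig, rec = _random_complex(rng)
            params = vina if trial % 2 else vinardo
            bd = intermolecular_energy(lig, rec, params)
            brute = 0.0
            for a in lig.atoms:
                for b in rec.atoms:
                    r = float(np.linalg.norm(a.coords - b.coords))
                    ri = params.radius_of(a.ad_type, a.element)
                    rj = params.radius_of(b.ad_type, b.element)
                    if r - ri - rj < params.cutoff:
                        brute += pair_energy(a, b, r, params)
            assert bd.total == pytest.approx(brute, abs=1e-9)

    def test_breakdown_total_is_sum_of_weighted(self, cage_pocket, vinardo):
        rec, lig, _ = cage_pocket
        bd = intermolecular_energy(lig, rec, vinardo)
        assert bd.total == pytest.approx(sum(bd.per_term_weighted.values()), abs=1e-9)
        assert sum(bd.per_term_percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_rigid_ligand_zero_intramolecular(self, vinardo, cage_pocket):
        _, lig, _ = cage_pocket
        assert intramolecular_energy(lig, vinardo).total == 0.0

    def test_intramolecular_matches_bond_graph_oracle(self, chain_ligand, vinardo):
        import networkx as nx

        from vinakit.atomtypes import perceive_bonds

        bd = intramolecular_energy(chain_ligand, vinardo)
        adj = perceive_bonds(chain_ligand.atoms)
        g = nx.Graph()
        g.add_nodes_from(range(6))
        for i, neigh in enumerate(adj):
            g.add_edges_from((i, j) for j in neigh)
        frag = chain_ligand.fragment_of()
        brute = 0.0
        n_pairs = 0
        for i in range(6):
            for j in range(i + 1, 6):
                if frag[i] == frag[j]:
                    continue
                if nx.shortest_path_length(g, i, j) < 4:
                    continue
                r = float(
                    np.linalg.norm(chain_ligand.atoms[i].coords - chain_ligand.atoms[j].coords)
                )
                brute += pair_energy(chain_ligand.atoms[i], chain_ligand.atoms[j], r, vinardo)
                n_pairs += 1
        assert n_pairs > 0
        assert bd.total == pytest.approx(brute, abs=1e-9)


class TestAffinityAndContributions:
    def test_predicted_affinity(self, vinardo):
        assert predicted_affinity(-8.0, 0, vinardo) == pytest.approx(-8.0)
        flat = vinardo.with_overrides(torsion_coeff=0.0)
        assert predicted_affinity(-8.0, 7, flat) == pytest.approx(-8.0)
        assert predicted_affinity(-8.0, 4, vinardo) == pytest.approx(-8.0 / 1.23384, abs=1e-4)
        with pytest.raises(ValueError):
            predicted_affinity(-8.0, -1, vinardo)

    def test_single_contact_contributions(self, single_pair_pocket, vinardo):
        rec, lig, _ = single_pair_pocket
        bd = intermolecular_energy(lig, rec, vinardo)
        pct = term_contributions([bd])
        steric = pct["gauss1"] + pct["gauss2"] + pct["repulsion"]
        assert steric == pytest.approx(56.25, abs=0.05)
        assert pct["hydrophobic"] == pytest.approx(43.75, abs=0.05)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_hbond_only_breakdown_is_all_hbond(self, vinardo):
        donor = make_atom("N", InteractionClass.DONOR)
        acceptor = TypedAtom(
            2, "O", "O", np.array([2.7, 0.0, 0.0]), 0.0, "OA", InteractionClass.ACCEPTOR
        )
        lig = LigandModel([donor], [(0,)], [], 0)
        rec = ReceptorModel([acceptor])
        bd = intermolecular_energy(lig, rec, vinardo)
        assert bd.per_term_weighted["hbond"] < 0
        assert bd.per_term_weighted["hydrophobic"] == 0.0
        # a breakdown whose only nonzero term is hbond contributes 100%
        from vinakit.scoring import ScoreBreakdown

        hb = bd.per_term_weighted["hbond"]
        pure = ScoreBreakdown(
            total=hb,
            per_term_raw={t: 0.0 for t in bd.per_term_raw} | {"hbond": bd.per_term_raw["hbond"]},
            per_term_weighted={t: 0.0 for t in bd.per_term_weighted} | {"hbond": hb},
            n_pairs_evaluated=1,
        )
        pct = term_contributions([pure])
        assert pct["hbond"] == pytest.approx(100.0, abs=1e-9)

    def test_term_contributions_errors(self):
        with pytest.raises(ValueError):
            term_contributions([])
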