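"""Structure container, SASA, cleavage mapping, restraints, stoichiometry."""

import math
import re

import numpy as np
import pytest

from relaxkit import (
    RestraintRecord,
    classify_restraints,
    exposed_cleavage_sites,
    generate_toy_structure,
    pepsin_sites,
    shrake_rupley_sasa,
    stoichiometry_ratio,
)
from relaxkit.structure import Atom, Structure
from relaxkit.synthetic import SYNTHETIC_SEQUENCE_114

try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


class TestStructureContainer:
    def test_pdb_round_trip(self, toy_helix_30, tmp_path):
        path = tmp_path / "helix.pdb"
        toy_helix_30.write_pdb(str(path))
        back = Structure.read_pdb(str(path))
        assert back.sequence() == toy_helix_30.sequence()
        np.testing.assert_allclose(
            back.select(atom_names=["CA"]).coords(),
            toy_helix_30.select(atom_names=["CA"]).coords(),
            atol=1e-3,  # PDB coordinate precision
        )

    def test_duplicate_atom_keys_rejected(self):
        a = Atom(1, "A", 1, "ALA", "CA", "C", 0, 0, 0)
        with pytest.raises(ValueError):
            Structure([a, a])

    def test_sequence_derivation(self):
        st_ = generate_toy_structure("ACDY", "extended")
        assert st_.sequence() == "ACDY"

    def test_transform_is_rigid(self, toy_helix_30):
        theta = 1.1
        R = np.array(
            [[1, 0, 0],
             [0, np.cos(theta), -np.sin(theta)],
             [0, np.sin(theta), np.cos(theta)]]
        )
        moved = toy_helix_30.transformed(R, np.array([3.0, 4.0, 5.0]))
        d0 = np.linalg.norm(
            toy_helix_30.atom(1, "CA").position - toy_helix_30.atom(30, "CA").position
        )
        d1 = np.linalg.norm(moved.atom(1, "CA").position - moved.atom(30, "CA").position)
        assert d1 == pytest.approx(d0, rel=1e-12)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        iso = Structure([Atom(1, "A", 1, "ALA", "C", "C", 0, 0, 0)])
        res = shrake_rupley_sasa(iso, probe=1.4, n_points=960)
        assert res.total == pytest.approx(4 * math.pi * 3.1**2, rel=0.02)

    def test_fully_enclosed_atom_has_zero_area(self):
        # central atom caged by a dense shell of neighbours
        atoms = [Atom(1, "A", 1, "ALA", "C", "C", 0, 0, 0)]
        k = 2
        golden = (1 + 5**0.5) / 2
        for i in range(40):
            z = 1 - (2 * i + 1) / 40
            r = (1 - z * z) ** 0.5
            phi = 2 * math.pi * i / golden
            atoms.append(
                Atom(1, "A", k, "ALA", "C", "C",
                     2.2 * r * math.cos(phi), 2.2 * r * math.sin(phi), 2.2 * z)
            )
            k += 1
        res = shrake_rupley_sasa(Structure(atoms), probe=1.4, n_points=480)
        assert res.atom_area(1, "C") == 0.0

    def test_two_sphere_cap_formula(self):
        d = 3.0
        st_ = Structure(
            [
                Atom(1, "A", 1, "ALA", "C", "C", 0, 0, 0),
                Atom(1, "A", 2, "ALA", "C", "C", d, 0, 0),
            ]
        )
        res = shrake_rupley_sasa(st_, probe=1.4, n_points=960)
        R = 1.7 + 1.4
        expected_per_atom = 4 * math.pi * R**2 - 2 * math.pi * R * (R - d / 2)
        assert res.atom_area(1, "C") == pytest.approx(expected_per_atom, rel=0.02)
        assert res.atom_area(2, "C") == pytest.approx(expected_per_atom, rel=0.02)

    def test_total_area_decreases_on_contact(self):
        def pair_total(d):
            st_ = Structure(
                [
                    Atom(1, "A", 1, "ALA", "C", "C", 0, 0, 0),
                    Atom(1, "A", 2, "ALA", "C", "C", d, 0, 0),
                ]
            )
            return shrake_rupley_sasa(st_, n_points=480).total

        totals = [pair_total(d) for d in (10.0, 6.0, 4.0, 2.0)]
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_against_biotite_cross_check(self, toy_helix_30):
        biotite_struct = pytest.importorskip("biotite.structure")
        model = toy_helix_30.select(heavy_only=True)
        import biotite.structure as bst

        arr = bst.AtomArray(len(model))
        arr.coord = model.coords()
        arr.chain_id = np.array([a.chain for a in model.atoms])
        arr.res_id = np.array([a.residue_index for a in model.atoms])
        arr.res_name = np.array([a.residue_name for a in model.atoms])
        arr.atom_name = np.array([a.atom_name for a in model.atoms])
        arr.element = np.array([a.element for a in model.atoms])
        ref = bst.sasa(
            arr, probe_radius=1.4, point_number=960,
            vdw_radii=np.array([1.70 if a.element == "C" else
                                1.55 if a.element == "N" else 1.52
                                for a in model.atoms]),
        )
        mine = shrake_rupley_sasa(toy_helix_30, probe=1.4, n_points=960)
        order = [(a.residue_index, a.atom_name) for a in model.atoms]
        mine_arr = np.array([mine.areas[key] for key in order])
        assert float(np.sum(ref)) == pytest.approx(mine_arr.sum(), rel=0.03)
        np.testing.assert_allclose(mine_arr, ref, atol=3.0)

    def test_unknown_element_warns_and_uses_default(self):
        st_ = Structure([Atom(1, "A", 1, "UNK", "X1", "XX", 0, 0, 0)])
        with pytest.warns(UserWarning):
            res = shrake_rupley_sasa(st_, n_points=240)
        assert res.total == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2, rel=0.02)


class TestPepsinSites:
    def test_no_sites_without_hydrophobic_anchor(self):
        assert pepsin_sites("AAAA").sites == ()

    @pytest.mark.parametrize("rule_set,key", [
        ("pepsin_pH1.3", "pepsin ph1.3"),
        ("pepsin_pH>2", "pepsin ph2.0"),
    ])
    def test_matches_external_rule_oracle(self, rule_set, key):
        pyteomics_parser = pytest.importorskip("pyteomics.parser")
        rng = np.random.default_rng(7)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = ["".join(rng.choice(aas, size=rng.integers(4, 60)))
                for _ in range(200)]
        seqs += ["GGFG", "GGPFAA", "AAFPAA", "HAFLAA", "RAFLAA", SYNTHETIC_SEQUENCE_114]
        for seq in seqs:
            expected = sorted(
                m.start() + 1
                for m in re.finditer(pyteomics_parser.expasy_rules[key], seq)
            )
            assert list(pepsin_sites(seq, rule_set).sites) == expected, seq

    def test_ph2_rule_set_is_superset(self):
        seq = SYNTHETIC_SEQUENCE_114
        s13 = set(pepsin_sites(seq, "pepsin_pH1.3").sites)
        s20 = set(pepsin_sites(seq, "pepsin_pH>2").sites)
        assert s13 <= s20

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError):
            pepsin_sites("AABAA")


class TestExposedCleavageSites:
    def test_threshold_extremes(self):
        seq = "AAAFAAAAAALF"
        st_ = generate_toy_structure(seq, "helix")
        cmap = pepsin_sites(seq)
        assert cmap.sites  # fixture must actually contain sites
        assert exposed_cleavage_sites(st_, cmap, sasa_threshold=0.0) == cmap.sites
        assert exposed_cleavage_sites(st_, cmap, sasa_threshold=1e9) == ()

    def test_sequence_mismatch_rejected(self):
        st_ = generate_toy_structure("AAAA", "helix")
        cmap = pepsin_sites("AAAFAAAA")
        with pytest.raises(ValueError):
            exposed_cleavage_sites(st_, cmap, sasa_threshold=1.0)


class TestClassifyRestraints:
    def test_one_per_category(self):
        records = [RestraintRecord(5, 5), RestraintRecord(5, 6),
                   RestraintRecord(5, 8), RestraintRecord(5, 20)]
        assert classify_restraints(records) == {
            "intra": 1, "sequential": 1, "short": 1, "long": 1
        }

    def test_empty_list(self):
        assert classify_restraints([]) == {
            "intra": 0, "sequential": 0, "short": 0, "long": 0
        }

    def test_published_taxonomy_total(self):
        # category counts of the deposited restraint table sum to 1038
        counts = {"intra": 606, "sequential": 329, "short": 92, "long": 11}
        records = []
        resi = 1
        for sep, n in zip((0, 1, 3, 9), counts.values()):
            for _ in range(n):
                records.append(RestraintRecord(resi, resi + sep))
                resi += 1
        got = classify_restraints(records)
        assert got == counts
        assert sum(got.values()) == 1038

    if HAVE_HYPOTHESIS:

        @given(
            st.lists(
                st.tuples(st.integers(1, 200), st.integers(1, 200)), max_size=300
            )
        )
        @settings(max_examples=50, deadline=None)
        def test_partition_exhaustive_and_disjoint(self, pairs):
            records = [RestraintRecord(i, j) for i, j in pairs]
            counts = classify_restraints(records)
            assert sum(counts.values()) == len(records)
            assert all(v >= 0 for v in counts.values())


class TestStoichiometry:
    @pytest.mark.parametrize("protein,metal,ratio,integer", [
        (28.0, 21.0, 4 / 3, "4:3"),
        (116.0, 1.78, 65.17, "65:1"),
        (10.0, 10.0, 1.0, "1:1"),
        (30.0, 10.0, 3.0, "3:1"),
        (10.0, 30.0, 1 / 3, "1:3"),
    ])
    def test_published_and_simple_ratios(self, protein, metal, ratio, integer):
        got_ratio, got_int = stoichiometry_ratio(protein, metal)
        assert got_ratio == pytest.approx(ratio, rel=1e-3)
        assert got_int == integer

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            stoichiometry_ratio(0.0, 1.0)
        with pytest.raises(ValueError):
            stoichiometry_ratio(1.0, -2.0)
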