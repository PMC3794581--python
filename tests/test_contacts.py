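"""Structure parsing, center-of-geometry contacts and set rules."""

import numpy as np
import pytest

from rnapref.contacts import (
    ContactTable,
    StructureFormatError,
    aggregate_contacts,
    apply_set_rule,
    center_of_geometry,
    compute_contacts,
    cutoff_sweep,
    find_neighbors,
    parse_structure,
    sweep_cutoff_grid,
)
from rnapref.synthetic import gen_random_structure, gen_toy_structure

from conftest import brute_force_neighbors, brute_force_set_rule


def _atom(serial, name, resname, chain, resnum, x, y, z, element=None, altloc=" ", occ=1.0):
    padded = name if len(name) >= 4 else f" {name:<3s}"
    el = element or name[0]
    return (
        f"ATOM  {serial:5d} {padded}{altloc}{resname:>3s} {chain}{resnum:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {el:>2s}"
    )


class TestCenterOfGeometry:
    @pytest.mark.parametrize(
        "atoms,expected",
        [
            ([(0, 0, 0), (2, 0, 0)], (1, 0, 0)),
            ([(3.5, -1, 2)], (3.5, -1, 2)),
            ([(0, 0, 0), (1, 1, 1), (2, 2, 2)], (1, 1, 1)),
        ],
    )
    def test_unweighted_mean(self, atoms, expected):
        assert np.allclose(center_of_geometry(atoms), expected)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            center_of_geometry([])


class TestParseStructure:
    def test_toy_round_trip(self):
        toy = gen_toy_structure([5.0, 7.5, 9.0])
        model = parse_structure(toy.pdb_text, "toy")
        assert len(model.protein_residues) == 1
        assert len(model.rna_bases) == 3
        # side-chain center sits exactly where the generator placed it
        assert np.allclose(model.protein_residues[0].center, toy.residue_center)
        for base, (_, _, _, d) in zip(model.rna_bases, toy.bases):
            assert abs(np.linalg.norm(base.center) - d) < 1e-3

    def test_first_model_only(self):
        lines = ["MODEL     1", _atom(1, "CB", "ALA", "A", 1, 0, 0, 0), "ENDMDL",
                 "MODEL     2", _atom(2, "CB", "ALA", "A", 2, 9, 9, 9), "ENDMDL", "END"]
        model = parse_structure("\n".join(lines))
        assert len(model.protein_residues) == 1
        assert model.protein_residues[0].resnum == 1

    def test_dna_excluded(self):
        lines = [
            _atom(1, "CB", "ALA", "A", 1, 0, 0, 0),
            _atom(2, "N1", "DA", "B", 1, 3, 0, 0, element="N"),
            _atom(3, "N1", "DT", "B", 2, 4, 0, 0, element="N"),
            "END",
        ]
        model = parse_structure("\n".join(lines))
        assert model.rna_bases == []
        assert model.skipped["dna"] == 2

    def test_hydrogens_and_backbone_excluded(self):
        lines = [
            _atom(1, "N", "SER", "A", 1, 9, 9, 9, element="N"),
            _atom(2, "CA", "SER", "A", 1, 8, 8, 8),
            _atom(3, "CB", "SER", "A", 1, 1, 0, 0),
            _atom(4, "OG", "SER", "A", 1, 3, 0, 0, element="O"),
            _atom(5, "HB2", "SER", "A", 1, 50, 50, 50, element="H"),
            "END",
        ]
        model = parse_structure("\n".join(lines))
        assert np.allclose(model.protein_residues[0].center, (2, 0, 0))

    def test_glycine_ca_surrogate_and_exclude_mode(self):
        lines = [
            _atom(1, "N", "GLY", "A", 1, 0, 0, 0, element="N"),
            _atom(2, "CA", "GLY", "A", 1, 1.5, 0, 0),
            _atom(3, "C", "GLY", "A", 1, 3, 0, 0),
            "END",
        ]
        model = parse_structure("\n".join(lines))
        assert len(model.protein_residues) == 1
        assert np.allclose(model.protein_residues[0].center, (1.5, 0, 0))
        excl = parse_structure("\n".join(lines), glycine="exclude")
        assert excl.protein_residues == []

    def test_mse_maps_to_met_and_others_skipped(self):
        lines = [
            _atom(1, "SE", "MSE", "A", 1, 0, 0, 0, element="SE"),
            _atom(2, "CB", "PTR", "A", 2, 1, 1, 1),  # phosphotyrosine: skipped
            "END",
        ]
        model = parse_structure("\n".join(lines))
        assert [r.kind for r in model.protein_residues] == ["M"]
        assert model.skipped["noncanonical"] == 1

    def test_altloc_highest_occupancy_kept(self):
        lines = [
            _atom(1, "CB", "ALA", "A", 1, 0, 0, 0, altloc="A", occ=0.4),
            _atom(2, "CB", "ALA", "A", 1, 5, 0, 0, altloc="B", occ=0.6),
            "END",
        ]
        model = parse_structure("\n".join(lines))
        assert np.allclose(model.protein_residues[0].center, (5, 0, 0))

    def test_sugar_phosphate_stripped_from_base(self):
        lines = [
            _atom(1, "P", "G", "B", 1, 40, 0, 0, element="P"),
            _atom(2, "C1'", "G", "B", 1, 30, 0, 0),
            _atom(3, "N9", "G", "B", 1, 2, 0, 0, element="N"),
            _atom(4, "C8", "G", "B", 1, 4, 0, 0),
            "END",
        ]
        model = parse_structure("\n".join(lines))
        assert np.allclose(model.rna_bases[0].center, (3, 0, 0))

    def test_empty_input_rejected(self):
        with pytest.raises(StructureFormatError):
            parse_structure("END\n")


class TestNeighborsAndRules:
    def test_strict_cutoff_and_order(self):
        toy = gen_toy_structure([5.0, 7.5, 9.0])
        model = parse_structure(toy.pdb_text)
        nm = find_neighbors(model, 8.0)
        assert [round(d, 3) for _, d in nm.lists[0]] == [5.0, 7.5]

    def test_base_exactly_at_cutoff_excluded(self):
        toy = gen_toy_structure([8.0])
        model = parse_structure(toy.pdb_text)
        assert find_neighbors(model, 8.0).lists[0] == []

    def test_no_rna_means_empty_lists(self):
        toy = gen_toy_structure([])
        model = parse_structure(toy.pdb_text)
        assert find_neighbors(model, 8.0).lists == [[]]

    @pytest.mark.parametrize("rule,expected_n", [("1+", 3), ("2+", 3), ("2", 2)])
    def test_set_rules_on_three_neighbors(self, rule, expected_n):
        toy = gen_toy_structure([5.0, 7.5, 7.9])
        model = parse_structure(toy.pdb_text)
        cs = compute_contacts(model, 8.0, rule)
        assert len(cs.records) == expected_n
        if rule == "2":
            assert [round(r.distance, 3) for r in cs.records] == [5.0, 7.5]

    def test_single_neighbor_dropped_by_two_plus(self):
        toy = gen_toy_structure([5.0])
        model = parse_structure(toy.pdb_text)
        assert compute_contacts(model, 8.0, "2+").records == []
        assert compute_contacts(model, 8.0, "1+").records != []

    def test_unknown_rule_rejected(self):
        toy = gen_toy_structure([5.0])
        nm = find_neighbors(parse_structure(toy.pdb_text), 8.0)
        with pytest.raises(ValueError):
            apply_set_rule(nm, "3+")

    def test_neighbors_match_brute_force_oracle(self, rng):
        """KD-tree detection agrees exactly with all-pairs distances."""
        for _ in range(10):
            model = parse_structure(gen_random_structure(rng))
            for cutoff in (6.0, 8.0, 10.0):
                got = find_neighbors(model, cutoff).lists
                want = brute_force_neighbors(model, cutoff)
                assert [[(j, round(d, 9)) for j, d in lst] for lst in got] == [
                    [(j, round(d, 9)) for j, d in lst] for lst in want
                ]

    def test_set_nesting_and_pair_count(self, rng):
        """Records nest 2 within 2+ within 1+; |set 2| = 2 x multi-neighbor residues."""
        model = parse_structure(gen_random_structure(rng, n_residues=15, n_bases=20))
        nm = find_neighbors(model, 8.0)
        sets = {
            rule: {
                (r.chain, r.resnum, r.base_chain, r.base_resnum)
                for r in apply_set_rule(nm, rule).records
            }
            for rule in ("1+", "2+", "2")
        }
        assert sets["2"] <= sets["2+"] <= sets["1+"]
        n_multi = sum(1 for lst in nm.lists if len(lst) >= 2)
        assert len(sets["2"]) == 2 * n_multi

    def test_rigid_motion_invariance(self, rng):
        """A rotation + translation leaves every contact distance unchanged."""
        text = gen_random_structure(rng, n_residues=8, n_bases=10)
        model = parse_structure(text)
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        shift = np.array([11.0, -3.0, 5.0])
        for group in model.protein_residues + model.rna_bases:
            object.__setattr__(group, "coords", group.coords @ rot.T + shift)
        moved = find_neighbors(model, 8.0)
        orig = find_neighbors(parse_structure(text), 8.0)
        for a, b in zip(orig.lists, moved.lists):
            assert [j for j, _ in a] == [j for j, _ in b]
            assert np.allclose([d for _, d in a], [d for _, d in b], atol=1e-9)


class TestAggregation:
    def test_counting(self):
        toy = gen_toy_structure([5.0, 6.0, 7.0, 7.5], base=["G", "G", "G", "A"])
        model = parse_structure(toy.pdb_text)
        table = aggregate_contacts([compute_contacts(model, 8.0, "1+")])
        assert table.counts.at["A", "G"] == 3
        assert table.counts.at["A", "A"] == 1
        assert table.n_total == 4

    def test_empty_input_gives_zero_table(self):
        table = aggregate_contacts([])
        assert table.n_total == 0

    def test_additivity_over_structures(self, rng):
        models = [
            parse_structure(gen_random_structure(rng, n_residues=6, n_bases=8))
            for _ in range(2)
        ]
        singles = [aggregate_contacts([compute_contacts(m, 8.0, "1+")]) for m in models]
        merged = aggregate_contacts([compute_contacts(m, 8.0, "1+") for m in models])
        assert (merged.counts == singles[0].counts + singles[1].counts).all().all()

    def test_mixed_cutoffs_rejected(self, rng):
        model = parse_structure(gen_random_structure(rng, n_residues=4, n_bases=4))
        with pytest.raises(ValueError):
            aggregate_contacts(
                [compute_contacts(model, 6.0, "1+"), compute_contacts(model, 8.0, "1+")]
            )

    def test_records_match_rule_oracle(self, rng):
        model = parse_structure(gen_random_structure(rng, n_residues=10, n_bases=14))
        nm = find_neighbors(model, 8.0)
        oracle = brute_force_neighbors(model, 8.0)
        for rule in ("1+", "2+", "2"):
            got = len(apply_set_rule(nm, rule).records)
            assert got == len(brute_force_set_rule(oracle, rule))


class TestCutoffSweep:
    def test_sweep_matches_independent_runs(self, rng):
        model = parse_structure(gen_random_structure(rng, n_residues=10, n_bases=12))
        cutoffs = [6.0, 8.0, 10.0]
        swept = cutoff_sweep(model, cutoffs, "1+")
        for c in cutoffs:
            single = aggregate_contacts([compute_contacts(model, c, "1+")])
            assert (swept[c].counts == single.counts).all().all()

    @pytest.mark.parametrize("rule", ["1+", "2+"])
    def test_total_nondecreasing_in_cutoff(self, rng, rule):
        model = parse_structure(gen_random_structure(rng, n_residues=10, n_bases=12))
        totals = [t.n_total for t in cutoff_sweep(model, [6, 7, 8, 9, 10], rule).values()]
        assert totals == sorted(totals)

    def test_below_minimum_distance_all_zero(self):
        toy = gen_toy_structure([5.0, 7.5])
        model = parse_structure(toy.pdb_text)
        assert cutoff_sweep(model, [1.0], "1+")[1.0].n_total == 0

    def test_grid_helper_covers_paper_range(self):
        grid = sweep_cutoff_grid(6.0, 10.0, 0.25)
        assert grid[0] == 6.0 and grid[-1] == 10.0 and len(grid) == 17


class TestContactTableIO:
    def test_tsv_round_trip(self, tmp_path, toy_table):
        path = tmp_path / "table.tsv"
        toy_table.to_tsv(path)
        back = ContactTable.from_tsv(path)
        assert (back.counts == toy_table.counts).all().all()
        assert back.cutoff == toy_table.cutoff
        assert back.set_rule == toy_table.set_rule
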