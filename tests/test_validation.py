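"""Restraint satisfaction, photo-reach validation and cross-validation."""

import numpy as np
import pytest

from conftest import random_rigid
from xldock.footprints import FootprintResidue, FootprintSet
from xldock.restraints import DistanceRestraint, RestraintSet, build_restraints
from xldock.structures import AtomRecord, Residue, ResidueRef, Structure, get_anchor_atom
from xldock.synthetic import simulate_pairwise
from xldock.validation import cross_validate, measure_restraints, validate_photo


def _residue(chain, seq, atoms, res_name="ALA"):
    return Residue(
        ResidueRef(chain, seq, res_name=res_name),
        [
            AtomRecord(serial=i + 1, name=name, element=elem, xyz=np.asarray(xyz, float))
            for i, (name, elem, xyz) in enumerate(atoms)
        ],
    )


class TestMeasureRestraints:
    def test_planted_complex_fully_satisfied(self, planted):
        cx, truth = planted
        rs = build_restraints(simulate_pairwise(cx, truth))
        report = measure_restraints(cx, rs)
        assert report.n_satisfied == report.n_total == len(rs)
        assert report.max_violation == 0.0

    def test_margin_of_one_angstrom(self):
        st = Structure(
            [
                _residue("L", 1, [("CB", "C", (0, 0, 0))]),
                _residue("R", 2, [("CB", "C", (11.0, 0, 0))]),
            ]
        )
        rs = RestraintSet([DistanceRestraint("L", 1, "CB", "R", 2, "CB", d0=10.0)])
        report = measure_restraints(st, rs)
        row = report.rows[0]
        assert not row.satisfied
        assert row.margin == pytest.approx(1.0)

    def test_satisfied_at_threshold_exactly(self):
        st = Structure(
            [
                _residue("L", 1, [("CB", "C", (0, 0, 0))]),
                _residue("R", 2, [("CB", "C", (10.0, 0, 0))]),
            ]
        )
        rs = RestraintSet([DistanceRestraint("L", 1, "CB", "R", 2, "CB", d0=10.0)])
        assert measure_restraints(st, rs).rows[0].satisfied

    def test_distances_match_brute_force(self, planted, rng):
        cx, _ = planted
        lig = [r.ref.seq for r in cx if r.ref.chain == "L"]
        rec = [r.ref.seq for r in cx if r.ref.chain == "R"]
        rs = RestraintSet(
            [
                DistanceRestraint(
                    "L", int(rng.choice(lig)), "CB", "R", int(rng.choice(rec)), "CB",
                    d0=10.0,
                )
                for _ in range(20)
            ]
        )
        report = measure_restraints(cx, rs)
        for r, row in zip(rs, report.rows):
            a = get_anchor_atom(cx, ("L", r.seq_a), "CB").xyz
            b = get_anchor_atom(cx, ("R", r.seq_b), "CB").xyz
            expected = float(np.sqrt(np.sum((a - b) ** 2)))
            assert row.distance == pytest.approx(expected, abs=1e-9)

    def test_satisfied_count_monotone_in_d0(self, planted, rng):
        cx, _ = planted
        lig = [r.ref.seq for r in cx if r.ref.chain == "L"]
        rec = [r.ref.seq for r in cx if r.ref.chain == "R"]
        pairs = [(int(rng.choice(lig)), int(rng.choice(rec))) for _ in range(15)]
        counts = []
        for d0 in (5.0, 8.0, 11.0, 20.0, 50.0):
            rs = RestraintSet(
                [DistanceRestraint("L", a, "CB", "R", b, "CB", d0=d0) for a, b in pairs]
            )
            counts.append(measure_restraints(cx, rs).n_satisfied)
        assert counts == sorted(counts)

    def test_missing_anchor_is_an_error(self, planted):
        cx, _ = planted
        rs = RestraintSet([DistanceRestraint("L", 999, "CB", "R", 1, "CB", d0=10.0)])
        with pytest.raises(KeyError):
            measure_restraints(cx, rs)

    def test_report_invariant_under_rigid_motion(self, planted, rng):
        cx, truth = planted
        rs = build_restraints(simulate_pairwise(cx, truth))
        base = measure_restraints(cx, rs)
        Q, t = random_rigid(rng)
        moved = measure_restraints(cx.transformed(Q, t), rs)
        for a, b in zip(base.rows, moved.rows):
            assert b.distance == pytest.approx(a.distance, abs=1e-9)


class TestValidatePhoto:
    def _complex(self, hit_distance):
        ligand = _residue("L", 1, [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))])
        receptor = _residue("R", 10, [("CB", "C", (1.5 + hit_distance, 0, 0))])
        return Structure([receptor, ligand])

    def test_within_radius_satisfied(self):
        st = self._complex(8.0)
        fp = FootprintSet({"pep": {FootprintResidue("R", 10)}})
        report = validate_photo(st, fp, "pep")
        assert report.rows[0].satisfied
        assert report.rows[0].distance == pytest.approx(8.0)

    def test_beyond_radius_flagged(self):
        st = self._complex(9.5)
        fp = FootprintSet({"pep": {FootprintResidue("R", 10)}})
        report = validate_photo(st, fp, "pep")
        assert [v.seq for v in report.violators] == [10]

    def test_hydrogens_excluded_from_nearest_atom_search(self):
        ligand = _residue(
            "L", 1, [("CA", "C", (0, 0, 0)), ("H", "H", (7.0, 0, 0))]
        )
        receptor = _residue("R", 10, [("CB", "C", (8.0, 0, 0))])
        st = Structure([receptor, ligand])
        fp = FootprintSet({"pep": {FootprintResidue("R", 10)}})
        report = validate_photo(st, fp, "pep")
        # nearest *heavy* atom is CA at 8 Å, not the hydrogen at 1 Å
        assert report.rows[0].distance == pytest.approx(8.0)

    def test_min_distance_matches_brute_force(self, planted, rng):
        cx, truth = planted
        seqs = sorted(truth.photo_truth)[:10]
        fp = FootprintSet({"pep": {FootprintResidue(c, s) for c, s in seqs}})
        report = validate_photo(cx, fp, "pep")
        by_seq = {r.seq: r.distance for r in report.rows}
        lig = cx.coords(chain="L", heavy_only=True)
        for c, s in seqs:
            cb = get_anchor_atom(cx, (c, s), "CB").xyz
            oracle = min(float(np.linalg.norm(cb - x)) for x in lig)
            assert by_seq[s] == pytest.approx(oracle, abs=1e-9)

    def test_planted_truth_has_zero_violators(self, planted):
        cx, truth = planted
        fp = FootprintSet(
            {"pep": {FootprintResidue(c, s) for c, s in truth.photo_truth}}
        )
        report = validate_photo(cx, fp, "pep", radius=truth.photo_radius)
        assert report.violators == []
        assert report.n_total == len(truth.photo_truth)

    def test_empty_ligand_chain_is_an_error(self, bundle):
        fp = FootprintSet({"pep": {FootprintResidue("R", 1)}})
        with pytest.raises(ValueError, match="heavy atoms"):
            validate_photo(bundle, fp, "pep", ligand_chain="L")


class TestCrossValidate:
    def test_identity_map_on_satisfied_model(self, planted):
        cx, truth = planted
        rs = build_restraints(simulate_pairwise(cx, truth))
        report = cross_validate(cx, rs)
        assert report.n_satisfied == report.n_total == len(rs)

    def test_offset_map_equals_direct_measurement(self, planted):
        cx, truth = planted
        rs = build_restraints(simulate_pairwise(cx, truth))
        # foreign numbering: every ligand position shifted by +1
        shifted = RestraintSet(
            [
                DistanceRestraint(
                    r.chain_a, r.seq_a + 1, r.anchor_a,
                    r.chain_b, r.seq_b, r.anchor_b, d0=r.d0, k=r.k,
                )
                for r in rs
            ]
        )
        remap = {r.seq_a + 1: r.seq_a for r in rs}
        crossed = cross_validate(cx, shifted, remap)
        direct = measure_restraints(cx, rs)
        assert crossed.n_total == direct.n_total
        for a, b in zip(crossed.rows, direct.rows):
            assert a.distance == pytest.approx(b.distance, abs=1e-12)
            assert a.satisfied == b.satisfied

    def test_unmappable_rows_reported_untestable(self, planted):
        cx, truth = planted
        rs = build_restraints(simulate_pairwise(cx, truth))
        remap = {}  # non-empty foreign set, but force a map with one entry
        remap = {rs[0].seq_a: rs[0].seq_a}
        report = cross_validate(cx, rs, remap)
        assert report.n_untestable == sum(1 for r in rs if r.seq_a != rs[0].seq_a)
        assert len(report.rows) == len(rs)  # nothing silently dropped

    def test_slack_loosens_borderline_rows(self):
        st = Structure(
            [
                _residue("L", 1, [("CB", "C", (0, 0, 0))]),
                _residue("R", 2, [("CB", "C", (9.4, 0, 0))]),
            ]
        )
        rs = RestraintSet([DistanceRestraint("L", 1, "CB", "R", 2, "CB", d0=9.0)])
        strict = cross_validate(st, rs)
        loose = cross_validate(st, rs, slack=0.5)
        assert not strict.rows[0].satisfied
        assert loose.rows[0].satisfied

    def test_packaged_homolog_fixture_is_consistent(self):
        """The packaged companion-agonist restraints and remap load and
        reference only mapped ligand positions present in the remap table."""
        from xldock import datasets

        foreign = datasets.ucn1_restraints()
        remap = datasets.crf_to_ucn1_remap()
        assert len(foreign) == 9
        assert all(r.d0 == 9.0 for r in foreign)
        assert set(remap.keys()) == {13, 15, 17, 18, 31, 33}
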