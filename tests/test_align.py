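"""The comparison pipeline: prechecks, cost matrices, the four algorithms."""

import numpy as np
import pytest

from conftest import line_residue
from descalign.align import (
    Alignment,
    ComparisonParams,
    Rejection,
    algorithm1,
    algorithm4,
    build_cost_matrix,
    compare,
    finalize,
    precheck,
    superposed_structures,
)
from descalign.assignment import AssignmentSolution
from descalign.descriptors import Descriptor, Element, make_duplexes, _merge_segments
from descalign.fixtures import FixtureSpec, generate_descriptor, generate_pair
from descalign.geometry import M_SENTINEL


def toy_descriptor(spacing=3.8, n_others=2, name="toy"):
    """A hand-made descriptor: straight central run plus parallel runs."""
    central = Element(
        residues=tuple(
            line_residue(i + 10, [spacing * i, 0.0, 0.0]) for i in range(5)
        ),
        is_central=True,
    )
    others = []
    for k in range(n_others):
        y = 6.0 * (k + 1)
        others.append(
            Element(
                residues=tuple(
                    line_residue(i + 30 + 10 * k, [3.8 * i, y, 0.0])
                    for i in range(5)
                )
            )
        )
    return Descriptor(
        name=name,
        central_element=central,
        other_elements=tuple(others),
        segments=_merge_segments([central, *others]),
    )


_SATELLITES = [
    np.array([7.0, 0.0, 0.0]),
    np.array([0.0, 7.0, 0.0]),
    np.array([-7.0, 0.0, 0.0]),
    np.array([0.0, -7.0, 0.0]),
]


def _axis_element(start_seq, origin, is_central=False):
    o = np.asarray(origin, float)
    return Element(
        residues=tuple(
            line_residue(start_seq + i, o + [0, 0, 3.8 * i]) for i in range(5)
        ),
        is_central=is_central,
    )


def _axis_descriptor(name, satellite_offsets):
    """Straight central element along z plus parallel satellite elements."""
    central = _axis_element(10, [0, 0, 0], True)
    others = tuple(
        _axis_element(30 + 10 * k, off)
        for k, off in enumerate(satellite_offsets)
    )
    return Descriptor(
        name=name,
        central_element=central,
        other_elements=others,
        segments=_merge_segments([central, *others]),
        representative_atom_kinds=("CA",),
    )


@pytest.fixture(scope="module")
def params():
    return ComparisonParams()


class TestPrecheck:
    def test_balanced_identical_pair_passes(self, params):
        d = toy_descriptor()
        assert precheck(d, d, params) is None

    def test_cardinality_imbalance_rejected(self, params):
        a = toy_descriptor(n_others=3)  # |A| = 4
        b = toy_descriptor(n_others=5)  # |B| = 6; 4/5*6 = 4.8 > 4
        assert precheck(a, b, params) is Rejection.CARDINALITY

    def test_distorted_central_element_rejected(self, params):
        a = toy_descriptor(spacing=3.8)
        b = toy_descriptor(spacing=5.0)  # stretched centre, RMSD > 1.2
        assert precheck(a, b, params) is Rejection.CENTRAL

    def test_mismatched_element_size_is_contract_error(self, params):
        a = toy_descriptor()
        b_el = Element(
            residues=tuple(line_residue(i, [3.8 * i, 0, 0]) for i in range(3)),
            is_central=True,
        )
        b = Descriptor(
            name="small", central_element=b_el, other_elements=(),
            segments=_merge_segments([b_el]), element_size=3,
        )
        with pytest.raises(ValueError):
            precheck(a, b, params)
        with pytest.raises(ValueError):
            compare(a, b)


class TestCostMatrix:
    def test_self_comparison_zero_diagonal(self, params):
        d = generate_descriptor(FixtureSpec(seed=7))
        dup = make_duplexes(d)
        mat = build_cost_matrix(dup, dup, params)
        assert np.allclose(np.diag(mat.costs), 0.0)

    def test_unequal_residue_counts_get_sentinel(self, params):
        d = generate_descriptor(FixtureSpec(seed=7, geometry="helix"))
        dup = make_duplexes(d)
        sizes = [x.residue_count for x in dup]
        assert len(set(sizes)) > 1  # helix overlaps produce 8- and 9-residue duplexes
        mat = build_cost_matrix(dup, dup, params)
        for i, si in enumerate(sizes):
            for j, sj in enumerate(sizes):
                if si != sj:
                    assert mat.costs[i, j] == params.big

    def test_perturbed_copy_all_comparable(self, params):
        a, b = generate_pair(FixtureSpec(seed=4, geometry="helix"), 0.2)
        mat = build_cost_matrix(make_duplexes(a), make_duplexes(b), params)
        diag = np.diag(mat.costs)
        assert (diag <= 3.5).all() and (diag < params.big).all()


class TestFinalize:
    def test_full_self_alignment_accepted(self, params):
        d = generate_descriptor(FixtureSpec(seed=7))
        dup = make_duplexes(d)
        mat = build_cost_matrix(dup, dup, params)
        cand = AssignmentSolution(
            pairs=tuple((i, i) for i in range(d.n)), total_cost=0.0
        )
        out = finalize(cand, d, d, mat, params)
        assert isinstance(out, Alignment)
        assert out.global_rmsd == pytest.approx(0.0, abs=1e-9)
        assert out.aligned_residue_counts == (d.residue_count, d.residue_count)
        assert len(out.residue_map) == d.residue_count

    def test_element_ratio_rejection(self):
        # demand full element coverage, then drop one pair
        strict = ComparisonParams(element_ratio=1.0)
        d = generate_descriptor(FixtureSpec(seed=7))
        dup = make_duplexes(d)
        mat = build_cost_matrix(dup, dup, strict)
        cand = AssignmentSolution(
            pairs=tuple((i, i) for i in range(d.n - 1)), total_cost=0.0
        )
        assert finalize(cand, d, d, mat, strict) is Rejection.ELEMENT_RATIO

    def test_residue_ratio_rejection(self):
        strict = ComparisonParams(element_ratio=0.0, residue_ratio=0.999)
        d = generate_descriptor(FixtureSpec(seed=1, target_element_count=8))
        dup = make_duplexes(d)
        mat = build_cost_matrix(dup, dup, strict)
        cand = AssignmentSolution(pairs=((0, 0),), total_cost=0.0)
        assert finalize(cand, d, d, mat, strict) is Rejection.RESIDUE_RATIO

    def test_atom_count_rejection_on_asymmetric_overlap(self, params):
        # align a heavily overlapping duplex of A with a disjoint one of B:
        # the merged sides then cover different residue counts
        helix = generate_descriptor(FixtureSpec(seed=7, geometry="helix"))
        dup = make_duplexes(helix)
        sizes = [x.residue_count for x in dup]
        i = sizes.index(min(sizes))
        j = sizes.index(max(sizes))
        mat = build_cost_matrix(dup, dup, params)
        cand = AssignmentSolution(pairs=((i, j),), total_cost=0.0)
        out = finalize(cand, helix, helix, mat, params)
        assert out is Rejection.ATOM_COUNT


class TestAlgorithms:
    def test_identical_descriptors_all_algorithms_agree(self):
        a, b = generate_pair(FixtureSpec(seed=3, target_element_count=7), 0.0)
        results = [compare(a, b, alg) for alg in (1, 2, 3, 4)]
        for res in results:
            assert res.similar
            assert res.alignment.n_aligned == a.n + 1
            assert res.alignment.total_cost == pytest.approx(0.0, abs=1e-9)
            assert res.element_ratio_achieved == pytest.approx(1.0)
            assert res.residue_ratio_achieved == pytest.approx(1.0)

    def test_no_k_rejection_for_tiny_duplex_sets(self, params):
        a = toy_descriptor(n_others=0)
        res = algorithm1(a, a, params)
        assert not res.similar
        assert res.rejection_reason is Rejection.NO_K

    def test_small_descriptor_k_is_forced_to_n(self):
        # n = 2: the only admissible K aligns both duplex sets completely
        a, b = generate_pair(FixtureSpec(seed=6, target_element_count=3), 0.1)
        if a.n == 2:
            from descalign.assignment import k_range

            assert k_range(a.n, b.n) == [2]
        res = compare(a, b, 4)
        assert res.similar
        assert res.alignment.n_aligned == a.n + 1

    def test_dominance_and_symmetry_small_population(self):
        for seed in range(8):
            for pert in (0.0, 0.4, 0.9):
                a, b = generate_pair(
                    FixtureSpec(seed=seed, target_element_count=5 + seed % 4),
                    pert,
                )
                results = {alg: compare(a, b, alg) for alg in (1, 2, 3, 4)}
                sim = {alg: results[alg].similar for alg in results}
                assert sim[1] <= sim[2] <= sim[3] <= sim[4]
                counts = {
                    alg: len(results[alg].alignment.duplex_pairs)
                    for alg in results if results[alg].similar
                }
                if counts:
                    assert 4 in counts
                    assert counts[4] >= max(counts.values())
                rev = compare(b, a, 4)
                assert rev.similar == results[4].similar
                if rev.similar:
                    assert rev.alignment.n_aligned == results[4].alignment.n_aligned
                    assert rev.alignment.global_rmsd == pytest.approx(
                        results[4].alignment.global_rmsd, abs=1e-9
                    )

    def test_f_monotonicity(self):
        # anything accepted under the stringent limit stays accepted
        # when the limit is relaxed
        for seed in range(6):
            a, b = generate_pair(
                FixtureSpec(seed=seed, target_element_count=6), 0.6
            )
            for alg in (2, 3):
                strict = compare(a, b, alg, ComparisonParams(f=1.75))
                loose = compare(a, b, alg, ComparisonParams(f=2.33))
                if strict.similar:
                    assert loose.similar

    def test_first_feasible_k_can_miss_what_all_k_finds(self):
        """A minimum-cost full assignment can fail the global-RMSD bound
        while a smaller-K assignment passes; the first-feasible strategy
        stops after the failed candidate, the all-K strategy recovers.

        Construction: straight central element on the z axis (rotationally
        symmetric for CA-only representatives), four parallel satellite
        elements; in B the fourth satellite is swung 120 degrees around
        the axis, which leaves its duplex RMSD tiny but wrecks the merged
        superposition.
        """
        a = _axis_descriptor("A", _SATELLITES)
        theta = np.deg2rad(120.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = [*_SATELLITES[:3], rot @ _SATELLITES[3] + np.array([0, 0, 0.3])]
        b = _axis_descriptor("B", moved)
        r1 = compare(a, b, 1)
        assert not r1.similar
        assert r1.rejection_reason is Rejection.GLOBAL_RMSD
        for alg in (2, 3, 4):
            res = compare(a, b, alg)
            assert res.similar
            assert res.alignment.n_aligned == 4  # one duplex pair dropped

    def test_borderline_cost_accepted_only_at_relaxed_f(self):
        """Total cost between 1.75*K and 2.33*K: the stringent limit
        rejects the alignment that the default limit accepts."""
        a = _axis_descriptor("A", _SATELLITES)
        b = _axis_descriptor(
            "B", [o + np.array([0, 0, 4.5]) for o in _SATELLITES]
        )
        strict = compare(a, b, 1, ComparisonParams(f=1.75))
        assert not strict.similar
        assert strict.rejection_reason is Rejection.COST_LIMIT
        loose = compare(a, b, 1, ComparisonParams(f=2.33))
        assert loose.similar

    def test_partial_solution_repairs_unequal_residue_counts(self):
        """Full assignments that merge to unequal residue counts are
        unusable; dropping the offending pair from the cost-sorted list
        yields a valid partial solution that only the partial-solution
        strategy (and the exact search) can reach.

        Construction: element 2 of B shares two residues with element 1
        (a sequence-contiguous continuation), so any alignment using
        both pairs covers fewer B residues than A residues.
        """

        def elem(start_seq, pts, central=False):
            return Element(
                residues=tuple(
                    line_residue(start_seq + i, p) for i, p in enumerate(pts)
                ),
                is_central=central,
            )

        def line(x, y, z0):
            return [np.array([x, y, z0 + 3.8 * i]) for i in range(5)]

        def desc(name, others):
            central = elem(10, line(0, 0, 0), True)
            return Descriptor(
                name=name, central_element=central, other_elements=others,
                segments=_merge_segments([central, *others]),
                representative_atom_kinds=("CA",),
            )

        a = desc("A", (
            elem(30, line(7, 0, 0)), elem(40, line(0, 7, 0)),
            elem(50, line(0, 7, 11.4)), elem(60, line(-7, 0, 0)),
        ))
        b1 = elem(80, [p + [0.25, 0, 0] for p in line(0, 7, 0)])
        b2 = elem(83, [
            b1.residues[3].atom("CA").position,
            b1.residues[4].atom("CA").position,
            *[p + [0.25, 0, 0] for p in line(0, 7, 11.4)[2:]],
        ])
        b = desc("B", (
            elem(70, [p + [0, 0, 0.2] for p in line(7, 0, 0)]),
            b1,
            b2,
            elem(90, [p + [0, 0, 6.0] for p in line(-7, 0, 0)]),
        ))
        for alg in (1, 2):
            res = compare(a, b, alg)
            assert not res.similar
            assert res.rejection_reason is Rejection.ATOM_COUNT
        for alg in (3, 4):
            res = compare(a, b, alg)
            assert res.similar
            assert len(res.alignment.duplex_pairs) == 3

    def test_unknown_algorithm_id(self):
        a, b = generate_pair(FixtureSpec(seed=1), 0.0)
        with pytest.raises(ValueError):
            compare(a, b, 5)


def test_superposed_structures_overlay(tmp_path):
    a, b = generate_pair(FixtureSpec(seed=5, target_element_count=6), 0.2)
    res = compare(a, b, 4)
    assert res.similar
    st_a, st_b = superposed_structures(a, b, res.alignment)
    # after superposition the two CA sets coincide to within the noise level
    ca_a = np.array([r.atom("CA").position for r in st_a.residues()])
    ca_b = np.array([r.atom("CA").position for r in st_b.residues()])
    assert ca_a.shape == ca_b.shape
    assert float(np.sqrt(np.mean(np.sum((ca_a - ca_b) ** 2, axis=1)))) < 1.0
    from descalign.structure_io import parse_structure, write_substructure

    out = tmp_path / "aligned_b.pdb"
    write_substructure(st_b, [r.rid for r in st_b.residues()], out)
    assert len(parse_structure(out)) == len(ca_b)
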