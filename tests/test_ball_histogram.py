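"""Ball-histogram construction: counting, sampling, marginalization, I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ballhist import (
    DataError,
    DegenerateSamplingError,
    Template,
    bounding_sphere,
    build_histogram,
    count_in_ball,
    marginalize,
    master_count_vectors,
    read_histogram,
    write_histogram,
)
from ballhist.ball_histogram import BallHistogram

from conftest import make_structure


class TestBoundingSphere:
    def test_single_residue(self, single_arg):
        s = bounding_sphere(single_arg, R=4.0)
        assert s.center == (0.0, 0.0, 0.0)
        assert s.radius == 4.0

    def test_two_residues(self):
        s = make_structure("p", [("ARG", (0.0, 0.0, 0.0)), ("GLY", (10.0, 0.0, 0.0))])
        sphere = bounding_sphere(s, R=12.0)
        assert sphere.center == (5.0, 0.0, 0.0)
        assert sphere.radius == pytest.approx(17.0)

    def test_radius_at_least_sampling_radius(self, arg_gly_far):
        assert bounding_sphere(arg_gly_far, R=3.0).radius >= 3.0

    def test_nonpositive_radius_rejected(self, single_arg):
        with pytest.raises(DataError):
            bounding_sphere(single_arg, R=0.0)


class TestCountInBall:
    def test_two_arg_one_leu(self, table):
        s = make_structure(
            "p",
            [
                ("ARG", (0.0, 0.0, 0.0)),
                ("ARG", (1.0, 0.0, 0.0)),
                ("LEU", (0.0, 1.0, 0.0)),
            ],
        )
        assert count_in_ball(s, Template(("Arg", "Lys")), (0, 0, 0), 4.0, table) == (2, 0)

    def test_his_and_asp_count_as_zero_zero(self, table):
        s = make_structure("p", [("HIS", (0.0, 0.0, 0.0)), ("ASP", (1.0, 0.0, 0.0))])
        assert count_in_ball(s, Template(("Arg", "Lys")), (0, 0, 0), 4.0, table) == (0, 0)

    def test_empty_ball_is_distinct_from_all_zero(self, table):
        s = make_structure("p", [("HIS", (0.0, 0.0, 0.0))])
        far = count_in_ball(s, Template(("Arg", "Lys")), (100, 0, 0), 4.0, table)
        near = count_in_ball(s, Template(("Arg", "Lys")), (0, 0, 0), 4.0, table)
        assert far is None
        assert near == (0, 0)

    def test_overlapping_properties_count_the_same_residue(self, single_arg, table):
        assert count_in_ball(
            single_arg, Template(("Arg", "Positive")), (0, 0, 0), 4.0, table
        ) == (1, 1)

    def test_boundary_is_inclusive(self, table):
        s = make_structure("p", [("ARG", (4.0, 0.0, 0.0))])
        assert count_in_ball(s, Template(("Arg",)), (0, 0, 0), 4.0, table) == (1,)


class TestBuildHistogram:
    def test_single_residue_every_ball_contains_it(self, single_arg, table):
        h = build_histogram(single_arg, Template(("Arg",)), R=4.0, n_samples=500, seed=3)
        assert h.bins == {(1,): 1.0}

    @pytest.mark.parametrize("seed", [0, 7])
    @pytest.mark.parametrize("radius", [4.0, 12.0])
    def test_weights_sum_to_one(self, arg_gly_far, radius, seed):
        h = build_histogram(arg_gly_far, Template(("Arg", "Lys")), R=radius,
                            n_samples=2000, seed=seed)
        assert h.total() == pytest.approx(1.0, abs=1e-9)

    def test_two_disjoint_equal_balls_split_mass_evenly(self, arg_gly_far):
        # Non-empty region = two disjoint R=4 balls of equal volume, one
        # around Arg (count 1), one around Gly (count 0).
        h = build_histogram(arg_gly_far, Template(("Arg",)), R=4.0,
                            n_samples=200_000, seed=1)
        assert h.bins[(1,)] == pytest.approx(0.5, abs=0.01)
        assert h.bins[(0,)] == pytest.approx(0.5, abs=0.01)

    def test_seeded_determinism(self, arg_gly_far):
        kwargs = dict(R=6.0, n_samples=3000, seed=42)
        h1 = build_histogram(arg_gly_far, Template(("Arg", "Gly")), **kwargs)
        h2 = build_histogram(arg_gly_far, Template(("Arg", "Gly")), **kwargs)
        assert h1 == h2 and h1.counts == h2.counts

    def test_all_empty_draws_is_degenerate(self):
        # Huge extra bounding radius makes hitting the single residue
        # astronomically unlikely within a handful of draws.
        s = make_structure("p", [("ARG", (0.0, 0.0, 0.0))])
        with pytest.raises(DegenerateSamplingError):
            build_histogram(s, Template(("Arg",)), R=0.5, n_samples=5, seed=0,
                            extra_bounding_radius=10_000.0)


class TestMasterAndMarginalize:
    def test_single_arg_master(self, single_arg, table):
        m = master_count_vectors(single_arg, ("Arg", "Lys"), R=4.0, n_samples=200, seed=1)
        assert m.bins == {(1, 0): 1.0}

    def test_master_vectors_span_whole_pool(self, arg_gly_far, table):
        pool = tuple(table.property_names)
        m = master_count_vectors(arg_gly_far, pool, R=5.0, n_samples=500, seed=2)
        assert all(len(vec) == len(pool) for vec in m.bins)

    def test_marginal_consistency_with_direct_histogram(self, arg_gly_far):
        pool = ("Arg", "Lys", "Gly", "Positive")
        kwargs = dict(R=6.0, n_samples=4000, seed=9)
        m = master_count_vectors(arg_gly_far, pool, **kwargs)
        for props in [("Arg",), ("Arg", "Positive"), ("Gly", "Lys")]:
            direct = build_histogram(arg_gly_far, Template(props), **kwargs)
            assert marginalize(m, Template(props)) == direct

    def test_printed_margins_of_perfectly_correlated_joint(self):
        joint = BallHistogram(Template(("Arg", "Lys")), 8.0, {(1, 1): 0.5, (0, 0): 0.5})
        assert marginalize(joint, Template(("Arg",))).bins == {(1,): 0.5, (0,): 0.5}

    def test_printed_margins_of_mixed_joint(self):
        joint = BallHistogram(
            Template(("Arg", "Gly")), 8.0,
            {(1, 1): 0.4, (1, 0): 0.1, (0, 1): 0.2, (0, 0): 0.3},
        )
        marg = marginalize(joint, Template(("Gly",)))
        assert marg.bins[(1,)] == pytest.approx(0.6)
        assert marg.bins[(0,)] == pytest.approx(0.4)

    def test_marginalizing_to_own_template_is_identity(self, arg_gly_far):
        h = build_histogram(arg_gly_far, Template(("Arg", "Gly")), R=5.0,
                            n_samples=1000, seed=4)
        assert marginalize(h, h.template) == h

    def test_non_subset_rejected(self):
        h = BallHistogram(Template(("Arg",)), 8.0, {(1,): 1.0})
        with pytest.raises(DataError):
            marginalize(h, Template(("Lys",)))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_marginal_mass_is_preserved(self, seed):
        s = make_structure(
            "p",
            [("ARG", (0.0, 0.0, 0.0)), ("LYS", (4.0, 0.0, 0.0)), ("GLY", (0.0, 4.0, 0.0))],
        )
        m = master_count_vectors(s, ("Arg", "Lys", "Gly"), R=5.0, n_samples=300, seed=seed)
        sub = marginalize(m, Template(("Lys",)))
        assert sub.total() == pytest.approx(1.0, abs=1e-9)


class TestInvariance:
    def test_rigid_transform_leaves_histogram_nearly_unchanged(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(scale=6.0, size=(25, 3))
        types = ["ARG", "LYS", "GLY", "ASP", "LEU"] * 5
        s = make_structure("orig", list(zip(types, map(tuple, pts))))
        # rotation about z by 60 degrees plus a translation
        theta = np.pi / 3
        Rz = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = make_structure(
            "moved", list(zip(types, map(tuple, pts @ Rz.T + np.array([5.0, -3.0, 8.0]))))
        )
        kwargs = dict(R=6.0, n_samples=200_000)
        h1 = build_histogram(s, Template(("Positive", "Negative")), seed=1, **kwargs)
        h2 = build_histogram(moved, Template(("Positive", "Negative")), seed=2, **kwargs)
        assert h1.l1_distance(h2) <= 0.05

    def test_inflating_bounding_sphere_changes_nothing_material(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(scale=6.0, size=(25, 3))
        types = ["ARG", "LYS", "GLY", "ASP", "LEU"] * 5
        s = make_structure("p", list(zip(types, map(tuple, pts))))
        kwargs = dict(R=6.0, n_samples=200_000)
        h1 = build_histogram(s, Template(("Positive",)), seed=5, **kwargs)
        h2 = build_histogram(s, Template(("Positive",)), seed=6,
                             extra_bounding_radius=20.0, **kwargs)
        assert h1.l1_distance(h2) <= 0.05


class TestSerialization:
    def test_round_trip_is_exact(self, arg_gly_far, tmp_path):
        h = build_histogram(arg_gly_far, Template(("Arg", "Gly")), R=5.0,
                            n_samples=2000, seed=11)
        path = str(tmp_path / "h.tsv")
        write_histogram(h, path)
        back = read_histogram(path)
        assert back == h
        assert back.counts == h.counts and back.n_used == h.n_used

    def test_analytic_histogram_round_trip(self, tmp_path):
        h = BallHistogram(Template(("Arg",)), 8.0, {(1,): 0.25, (0,): 0.75})
        path = str(tmp_path / "h.tsv")
        write_histogram(h, path)
        assert read_histogram(path) == h
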