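"""Angle extraction, uniform refinement, and the end-to-end estimator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sinosort as ss
from sinosort.angles import refine_uniform, wrap_signed
from sinosort.smds import CircleEmbedding


def _embedding_from_angles(angles):
    pts = np.column_stack([np.cos(angles), np.sin(angles)])
    return CircleEmbedding(points=pts, eigenvalues=(1.0, 1.0),
                           raw_eigvecs=pts)


class TestAnglesFromEmbedding:
    @pytest.mark.parametrize("point, expected", [
        ((1, 0), 0.0), ((0, 1), np.pi / 2),
        ((-1, 0), np.pi), ((0, -1), 3 * np.pi / 2),
    ])
    def test_axis_points(self, point, expected):
        emb = _embedding_from_angles(np.array([0.0]))
        emb.points = np.array([point], dtype=float)
        assert abs(ss.angles_from_embedding(emb)[0] - expected) < 1e-12

    def test_inverse_identity(self):
        emb = _embedding_from_angles(np.array([1.23]))
        assert abs(ss.angles_from_embedding(emb)[0] - 1.23) < 1e-12


class TestRefineUniform:
    def test_already_uniform_is_unchanged(self):
        raw = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assignment = refine_uniform(raw)
        np.testing.assert_allclose(assignment.refined_angles, raw)
        np.testing.assert_array_equal(assignment.order, np.arange(4))

    def test_rank_assignment_by_hand(self):
        raw = np.array([5.0, 0.1, 2.0, 3.9])
        refined = refine_uniform(raw).refined_angles
        np.testing.assert_allclose(
            refined, [3 * np.pi / 2, 0.0, np.pi / 2, np.pi])

    def test_duplicate_raw_angles_tie_break_by_index(self):
        refined = refine_uniform(np.array([1.0, 0.5, 0.5, 2.0])).refined_angles
        assert refined[1] < refined[2]  # earlier index gets smaller angle

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 2 * np.pi - 1e-9), min_size=2, max_size=40))
    def test_refinement_preserves_ranks(self, raw_list):
        raw = np.array(raw_list)
        assignment = refine_uniform(raw)
        raw_ranks = np.argsort(np.argsort(raw, kind="stable"), kind="stable")
        refined_ranks = np.argsort(
            np.argsort(assignment.refined_angles, kind="stable"), kind="stable")
        np.testing.assert_array_equal(raw_ranks, refined_ranks)

    def test_refinement_equivariant_under_rotation(self):
        # rotating all embedded points shifts raw angles but leaves the
        # refined assignment unchanged (same circular order, angles 2*pi*k/N)
        raw = np.random.default_rng(0).uniform(0.3, 5.8, size=17)
        shifted = np.mod(raw + 0.25, 2 * np.pi)
        a0, a1 = refine_uniform(raw), refine_uniform(shifted)
        # cyclic sequences of projection indices agree up to rotation
        doubled = np.tile(a1.order, 2)
        seq = a0.order
        assert any(np.array_equal(doubled[s:s + len(seq)], seq)
                   for s in range(len(seq)))


class TestEstimateViewAngles:
    def test_recovers_perfect_circular_order(self, sino256):
        assignment = ss.estimate_view_angles(sino256, ss.PipelineConfig())
        err, agreement = ss.angle_metrics(assignment, sino256.hidden_angles)
        assert agreement == 1.0
        assert err <= 2 * (2 * np.pi / 256)

    def test_duplicate_projection_gets_adjacent_angle(self, sino256):
        rows = np.vstack([sino256.rows, sino256.rows[10]])
        dup = dataclasses.replace(sino256, rows=rows, hidden_angles=None)
        assignment = ss.estimate_view_angles(dup, ss.PipelineConfig())
        n = assignment.n
        rank = np.empty(n, dtype=int)
        rank[assignment.order] = np.arange(n)
        assert abs(rank[256] - rank[10]) == 1

    def test_too_few_projections_rejected(self, phantom):
        sino = ss.radon_project(phantom, np.linspace(0, 3, 5), 65)
        with pytest.raises(ValueError, match="at least 8"):
            ss.estimate_view_angles(sino, ss.PipelineConfig())

    def test_magnitude_mode_uses_half_turn(self, sino256):
        cfg = ss.PipelineConfig(feature_mode="magnitude", band_fraction=0.5)
        assignment = ss.estimate_view_angles(sino256, cfg)
        assert assignment.period == pytest.approx(np.pi)
        assert assignment.refined_angles.max() < np.pi
        err, agreement = ss.angle_metrics(assignment, sino256.hidden_angles)
        assert agreement > 0.9 and err < 0.05

    def test_never_reads_hidden_angles(self, sino256):
        blind = dataclasses.replace(sino256, hidden_angles=None)
        a_blind = ss.estimate_view_angles(blind, ss.PipelineConfig())
        a_seen = ss.estimate_view_angles(sino256, ss.PipelineConfig())
        np.testing.assert_array_equal(a_blind.refined_angles,
                                      a_seen.refined_angles)


class TestWrapHelpers:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(-100, 100), st.sampled_from([np.pi, 2 * np.pi]))
    def test_wrap_signed_range(self, x, period):
        w = float(wrap_signed(x, period))
        assert -period / 2 <= w < period / 2
        assert abs((x - w) / period - round((x - w) / period)) < 1e-6
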