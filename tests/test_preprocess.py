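"""QC, interpolation and normalization tests, incl. similarity invariance."""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))
from _oracles import random_similarity_transform

from ethokit import (
    PoseSequence,
    interpolate_gaps,
    normalize_pose,
    qc_filter,
    read_pose_table,
    write_pose_table,
)
from ethokit.simulate import corrupt_session


def _clean_seq(rendered_session):
    seq, _ = rendered_session
    return seq.copy()


class TestPoseTableIO:
    def test_round_trip_identical(self, tmp_path, skeleton, rendered_session):
        seq, _ = rendered_session
        p = tmp_path / "s.csv"
        write_pose_table(seq, p)
        back = read_pose_table(p, skeleton)
        np.testing.assert_allclose(back.coords, seq.coords, rtol=0, atol=1e-7)
        np.testing.assert_array_equal(back.valid_mask, seq.valid_mask)
        assert back.fps == seq.fps
        assert back.subject_id == seq.subject_id

    def test_blank_cells_invalidate_frame(self, tmp_path, skeleton, rendered_session):
        seq, _ = rendered_session
        seq = corrupt_session(seq, dropout_runs=[(2, 1)])
        p = tmp_path / "s.csv"
        write_pose_table(seq, p)
        back = read_pose_table(p, skeleton)
        assert not back.valid_mask[2]
        assert back.valid_mask[[0, 1, 3]].all()

    def test_non_monotone_frame_index_rejected(self, tmp_path, skeleton, rendered_session):
        seq, _ = rendered_session
        p = tmp_path / "s.csv"
        write_pose_table(seq, p)
        lines = p.read_text().splitlines()
        lines[2], lines[3] = lines[3], lines[2]
        p.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="non-monotone"):
            read_pose_table(p, skeleton)

    def test_missing_landmark_columns_rejected(self, tmp_path, skeleton):
        p = tmp_path / "bad.csv"
        p.write_text("frame,time_s,nose_x\n0,0.0,1.0\n")
        with pytest.raises(ValueError, match="lacks landmark columns"):
            read_pose_table(p, skeleton)


class TestQCFilter:
    def test_out_of_cage_frame_invalidated(self, skeleton, rendered_session):
        seq = _clean_seq(rendered_session)
        seq.coords[10, 5, 2] = 3.0  # wrist above a 2.75 m cage
        out, report = qc_filter(seq, skeleton)
        assert not out.valid_mask[10]
        assert report.n_out_of_bounds == 1

    def test_collapsed_frame_invalidated(self, skeleton, rendered_session):
        seq = _clean_seq(rendered_session)
        seq.coords[4] = seq.coords[4].mean(axis=0)  # mean limb length 0 < 10 cm
        out, report = qc_filter(seq, skeleton)
        assert not out.valid_mask[4]
        assert report.n_collapsed == 1

    def test_clean_session_untouched(self, skeleton, rendered_session):
        seq, _ = rendered_session
        out, report = qc_filter(seq, skeleton)
        assert report.n_invalidated == 0
        assert out.valid_mask.all()

    def test_qc_monotone_in_threshold(self, skeleton, rendered_session):
        """Raising min limb length or shrinking the cage never un-rejects."""
        seq = _clean_seq(rendered_session)
        rng = np.random.default_rng(0)
        seq.coords[rng.integers(0, seq.n_frames, 20)] *= 0.2
        prev = -1
        for thresh in (0.02, 0.05, 0.10, 0.20):
            _, rep = qc_filter(seq, skeleton, min_mean_limb=thresh)
            assert rep.n_invalidated >= prev
            prev = rep.n_invalidated
        _, loose = qc_filter(seq, skeleton, cage_bounds=((0, 0, 0), (2.45, 2.45, 2.75)))
        _, tight = qc_filter(seq, skeleton, cage_bounds=((0.2, 0.2, 0.0), (2.0, 2.0, 2.0)))
        assert tight.n_invalidated >= loose.n_invalidated


class TestInterpolateGaps:
    def _with_gap(self, rendered_session, start, length):
        seq = _clean_seq(rendered_session)
        return corrupt_session(seq, dropout_runs=[(start, length)])

    def test_10_frame_gap_filled_11_not(self, rendered_session):
        s10 = interpolate_gaps(self._with_gap(rendered_session, 50, 10))
        assert s10.valid_mask[50:60].all()
        s11 = interpolate_gaps(self._with_gap(rendered_session, 50, 11))
        assert not s11.valid_mask[50:61].any()

    def test_no_gaps_identity(self, rendered_session):
        seq, _ = rendered_session
        out = interpolate_gaps(seq)
        np.testing.assert_array_equal(out.coords, seq.coords)

    def test_boundary_gap_never_filled(self, rendered_session):
        out = interpolate_gaps(self._with_gap(rendered_session, 0, 5))
        assert not out.valid_mask[:5].any()

    def test_linear_trajectory_reproduced(self, skeleton):
        """Shape-preserving cubic reproduces exactly linear data to 1e-9."""
        n = 40
        ramp = np.linspace(0.0, 1.0, n)
        coords = np.tile(ramp[:, None, None], (1, 15, 3)) + 0.5
        seq = PoseSequence(coords=coords, valid_mask=np.ones(n, bool))
        seq = corrupt_session(seq, dropout_runs=[(15, 8)])
        out = interpolate_gaps(seq)
        expect = np.tile(ramp[15:23, None, None], (1, 15, 3)) + 0.5
        np.testing.assert_allclose(out.coords[15:23], expect, atol=1e-9)

    def test_locality_outside_gap(self, rendered_session):
        seq = self._with_gap(rendered_session, 100, 6)
        out = interpolate_gaps(seq)
        before = np.r_[0:100, 106 : seq.n_frames]
        assert np.array_equal(out.coords[before], seq.coords[before], equal_nan=True)


class TestNormalizePose:
    def test_neck_at_origin_spine_unit(self, skeleton, rendered_session):
        seq, _ = rendered_session
        norm = normalize_pose(seq, skeleton)
        neck, hip = skeleton.spine_pair
        valid = norm.valid_mask
        np.testing.assert_allclose(norm.coords[valid, neck], 0, atol=1e-12)
        spine = np.linalg.norm(norm.coords[valid, hip] - norm.coords[valid, neck], axis=1)
        np.testing.assert_allclose(spine, 1.0, atol=1e-9)

    def test_canonical_orientation(self, skeleton, rendered_session):
        seq, _ = rendered_session
        norm = normalize_pose(seq, skeleton)
        neck, hip = skeleton.spine_pair
        lsh, rsh = skeleton.shoulder_pair
        t = np.flatnonzero(norm.valid_mask)[0]
        np.testing.assert_allclose(norm.coords[t, hip], [0, 0, -1], atol=1e-9)
        shoulder = norm.coords[t, rsh] - norm.coords[t, lsh]
        assert shoulder[0] > 0          # spine-orthogonal part along +X
        assert abs(shoulder[1]) < 1e-9  # no Y component after rotation

    def test_similarity_invariance_100_transforms(self, skeleton, rendered_session):
        """normalize(g . x) == normalize(x) for random similarity g."""
        seq, _ = rendered_session
        base = seq.coords[:1].copy()
        ref = normalize_pose(
            PoseSequence(coords=base, valid_mask=np.ones(1, bool)), skeleton
        ).coords[0]
        rng = np.random.default_rng(42)
        for _ in range(100):
            R, t, s = random_similarity_transform(rng)
            moved = (base[0] @ R.T) * s + t
            got = normalize_pose(
                PoseSequence(coords=moved[None], valid_mask=np.ones(1, bool)), skeleton
            ).coords[0]
            np.testing.assert_allclose(got, ref, atol=1e-6)

    def test_degenerate_frame_invalidated(self, skeleton, rendered_session):
        seq = _clean_seq(rendered_session)
        neck, hip = skeleton.spine_pair
        seq.coords[3, hip] = seq.coords[3, neck]  # zero spine
        norm = normalize_pose(seq, skeleton)
        assert not norm.valid_mask[3]
        assert "spine" in norm.invalid_reasons[3]
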