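"""I/O round trips, gap handling, and the C3D path."""

import numpy as np
import pytest

from prehension import _c3d, mocap_io
from prehension.mocap_io import (
    FormatError,
    MarkerMappingError,
    UnusableTrajectoryError,
    fill_gaps,
    read_trial_c3d,
    read_trial_tsv,
    write_trial_tsv,
)

from conftest import make_trajectory, make_trial


def random_trial(rng, n=5):
    fingers = []
    for _ in range(3):
        fingers.append(make_trajectory(rng.normal(size=(n, 3)) * 100))
    return make_trial(*fingers)


class TestTsvRoundTrip:
    def test_three_marker_file_round_trips_exactly(self, rng, tmp_path):
        trial = random_trial(rng)
        path = tmp_path / "t.tsv"
        write_trial_tsv(trial, path)
        back = read_trial_tsv(path)
        assert len(back.trajectories) == 3
        for name in ("thumb", "index", "middle"):
            a, b = trial.trajectories[name], back.trajectories[name]
            assert len(b) == 5
            np.testing.assert_array_equal(a.positions, b.positions)
            np.testing.assert_array_equal(a.valid_mask, b.valid_mask)
            np.testing.assert_allclose(a.times, b.times)

    def test_write_read_write_is_byte_identical(self, rng, tmp_path):
        trial = random_trial(rng, n=7)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_trial_tsv(trial, p1)
        write_trial_tsv(read_trial_tsv(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_triplet_masks_that_sample_only(self, rng, tmp_path):
        trial = random_trial(rng)
        trial.trajectories["index"].valid_mask[2] = False
        trial.trajectories["index"].positions[2] = np.nan
        path = tmp_path / "gap.tsv"
        write_trial_tsv(trial, path)
        back = read_trial_tsv(path)
        mask = back.trajectories["index"].valid_mask
        assert not mask[2]
        assert mask.sum() == 4
        assert back.trajectories["thumb"].valid_mask.all()

    def test_nonuniform_sampling_is_a_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        lines = ["frame\ttime\tthumb_X\tthumb_Y\tthumb_Z\tindex_X\tindex_Y\tindex_Z"
                 "\tmiddle_X\tmiddle_Y\tmiddle_Z"]
        for i, t in enumerate([0.0, 10.0, 25.0]):
            lines.append(f"{i}\t{t}" + "\t1.0" * 9)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError):
            read_trial_tsv(path)

    def test_missing_fingertip_marker_is_a_mapping_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        lines = ["frame\ttime\thand_X\thand_Y\thand_Z"]
        for i in range(4):
            lines.append(f"{i}\t{i * 10.0}\t1.0\t2.0\t3.0")
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(MarkerMappingError):
            read_trial_tsv(path)


class TestC3d:
    def test_single_marker_header_and_rate(self, tmp_path):
        pos = np.arange(300, dtype=float).reshape(1, 100, 3)
        res = np.zeros((1, 100))
        path = tmp_path / "one.c3d"
        _c3d.write_c3d(path, ["M1"], pos, res, rate=100.0)
        data = _c3d.read_c3d(path)
        assert data.points.shape == (1, 100, 3)
        assert data.rate == 100.0
        assert data.labels == ["M1"]
        np.testing.assert_allclose(data.points, pos, atol=1e-3)

    def test_negative_residual_marks_sample_invalid(self, rng, tmp_path):
        pos = rng.normal(size=(3, 20, 3)) * 50
        res = np.zeros((3, 20))
        res[1, 7] = -1.0
        path = tmp_path / "res.c3d"
        _c3d.write_c3d(path, ["thumb", "index", "middle"], pos, res, rate=100.0)
        trial = read_trial_c3d(path)
        assert not trial.trajectories["index"].valid_mask[7]
        assert trial.trajectories["index"].valid_mask.sum() == 19
        assert trial.trajectories["thumb"].valid_mask.all()

    def test_missing_mapped_marker_is_a_mapping_error(self, rng, tmp_path):
        pos = rng.normal(size=(1, 10, 3))
        path = tmp_path / "m.c3d"
        _c3d.write_c3d(path, ["hand"], pos, np.zeros((1, 10)), rate=100.0)
        with pytest.raises(MarkerMappingError):
            read_trial_c3d(path, marker_map={"thumb": "nope"})

    def test_tsv_and_c3d_encodings_agree(self, rng, tmp_path):
        """Cross-format oracle: the same trial through both codecs."""
        trial = random_trial(rng, n=50)
        tsv = tmp_path / "t.tsv"
        c3d = tmp_path / "t.c3d"
        write_trial_tsv(trial, tsv)
        names = ["thumb", "index", "middle"]
        pos = np.stack([trial.trajectories[m].positions for m in names])
        _c3d.write_c3d(c3d, names, pos, np.zeros(pos.shape[:2]), rate=100.0)
        a = read_trial_tsv(tsv)
        b = read_trial_c3d(c3d)
        for m in names:
            np.testing.assert_allclose(
                a.trajectories[m].positions, b.trajectories[m].positions, atol=1e-3
            )
            np.testing.assert_array_equal(
                a.trajectories[m].valid_mask, b.trajectories[m].valid_mask
            )


class TestFillGaps:
    def test_linear_interpolation_of_short_gap(self):
        valid = np.array([1, 0, 0, 0, 1, 1], dtype=bool)
        pos = np.array([[0, 0, 0], [np.nan] * 3, [np.nan] * 3, [np.nan] * 3,
                        [4, 0, 0], [5, 0, 0]], dtype=float)
        out = fill_gaps(make_trajectory(pos, valid=valid), max_gap=5)
        np.testing.assert_allclose(out.positions[1:4, 0], [1.0, 2.0, 3.0])
        assert out.valid_mask.all()

    def test_long_gap_left_untouched(self):
        pos = np.zeros((9, 3))
        valid = np.ones(9, dtype=bool)
        valid[1:7] = False  # 6-sample gap
        pos[1:7] = np.nan
        out = fill_gaps(make_trajectory(pos, valid=valid), max_gap=5)
        np.testing.assert_array_equal(out.valid_mask, valid)

    def test_never_modifies_valid_samples_and_matches_per_axis_interp(self, rng):
        """Oracle: brute-force per-coordinate interpolation of fillable runs."""
        for _ in range(25):
            n = 40
            pos = rng.normal(size=(n, 3)).cumsum(axis=0)
            valid = rng.random(n) > 0.25
            valid[0] = valid[-1] = True
            masked = pos.copy()
            masked[~valid] = np.nan
            traj = make_trajectory(masked.copy(), valid=valid.copy())
            out = fill_gaps(traj, max_gap=4)
            np.testing.assert_array_equal(out.positions[valid], pos[valid])
            # brute-force expectation
            expect = masked.copy()
            i = 0
            while i < n:
                if not valid[i]:
                    j = i
                    while j < n and not valid[j]:
                        j += 1
                    if j - i <= 4 and i > 0 and j < n:
                        for ax in range(3):
                            expect[i:j, ax] = np.interp(
                                np.arange(i, j), [i - 1, j], [pos[i - 1, ax], pos[j, ax]]
                            )
                    i = j
                else:
                    i += 1
            filled = out.valid_mask
            np.testing.assert_allclose(
                out.positions[filled], expect[filled], atol=1e-12
            )

    def test_all_invalid_is_unusable(self):
        pos = np.full((5, 3), np.nan)
        with pytest.raises(UnusableTrajectoryError):
            fill_gaps(make_trajectory(pos, valid=np.zeros(5, bool)), max_gap=5)


def test_manifest_round_trip(tmp_path):
    rows = [
        {"trial_id": "t1", "file": "t1.tsv", "participant_id": "P01",
         "block": 1, "surface": "matte", "content": "empty", "feedback": "visible"},
    ]
    path = tmp_path / "manifest.csv"
    mocap_io.write_manifest(rows, path)
    df = mocap_io.read_manifest(path)
    assert df.iloc[0]["trial_id"] == "t1"
    assert df.iloc[0]["block"] == 1
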