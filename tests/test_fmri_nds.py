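"""Design matrices, per-voxel OLS, the negative-minus-positive contrast,
and ROI NDS extraction."""

import numpy as np
import pytest

from lapref import fmri_nds as fn
from lapref import task_design as td


def _single_block_timeline(label="angry", onset=20.0, duration=20.0, total=100.0):
    cond = td.Condition(label)
    fix = td.Condition("fixation")
    events = [
        td.TimelineEvent(0.0, onset, fix, "fixation"),
        td.TimelineEvent(onset, duration, cond, label),
        td.TimelineEvent(onset + duration, total - onset - duration, fix, "fixation"),
    ]
    return td.StimulusTimeline(events=events, total_duration=total)


@pytest.fixture(scope="module")
def full_timeline():
    seq = td.generate_counterbalanced_sequence(td.default_conditions(), 10, seed=8)
    return td.build_timeline(seq, seed=8)


class TestDesignMatrix:
    def test_causality_and_peak_latency(self):
        tl = _single_block_timeline(onset=20.0)
        design = fn.build_design_matrix(tl, tr=2.5)
        col = design.matrix[:, design.column_index("angry")]
        times = (np.arange(len(col)) + 0.5) * 2.5
        assert np.allclose(col[times < 20.0], 0.0, atol=1e-6)
        # sustained 20-s block: regressor maximal 5-25 s after onset
        assert 25.0 <= times[np.argmax(col)] <= 45.0

    def test_fixation_is_implicit_baseline(self, full_timeline):
        design = fn.build_design_matrix(full_timeline)
        assert "fixation" not in design.columns
        assert design.columns[-2:] == ["intercept", "drift"]

    def test_convolution_linearity_across_blocks(self):
        one = _single_block_timeline(onset=20.0, total=200.0)
        other = _single_block_timeline(onset=120.0, total=200.0)
        both_events = [e for e in one.events if e.condition.label == "angry"] + [
            e for e in other.events if e.condition.label == "angry"
        ]
        both = td.StimulusTimeline(events=both_events, total_duration=200.0)
        col = lambda tl: fn.build_design_matrix(tl, tr=2.5).matrix[:, 0]
        assert np.allclose(col(both), col(one) + col(other), atol=1e-9)

    def test_empty_or_short_timelines_rejected(self):
        with pytest.raises(ValueError):
            fn.build_design_matrix(td.StimulusTimeline(events=[], total_duration=0.0))
        with pytest.raises(ValueError):
            fn.build_design_matrix(_single_block_timeline(total=100.0), tr=60.0)


class TestFitGLM:
    def test_noiseless_beta_recovery(self, full_timeline):
        design = fn.build_design_matrix(full_timeline)
        p = design.matrix.shape[1]
        rng = np.random.default_rng(0)
        betas_true = rng.uniform(-2, 2, size=(5, p))
        series = betas_true @ design.matrix.T
        vox = fn.VoxelTable(
            voxel_ids=[f"v{i}" for i in range(5)],
            roi_labels=["VS_NAc_left"] * 5,
            series=series,
            tr=design.tr,
        )
        fit = fn.fit_glm(vox, design)
        assert np.allclose(fit.betas, betas_true, rtol=1e-8, atol=1e-8)

    def test_pure_noise_z_is_standard_normal(self, full_timeline):
        design = fn.build_design_matrix(full_timeline)
        rng = np.random.default_rng(1)
        n_vox = 400
        series = rng.standard_normal((n_vox, design.matrix.shape[0]))
        vox = fn.VoxelTable(
            voxel_ids=[f"v{i}" for i in range(n_vox)],
            roi_labels=["none"] * n_vox,
            series=series,
            tr=design.tr,
        )
        z = np.array([c.z for c in fn.contrast_neg_minus_pos(fn.fit_glm(vox, design), vox)])
        assert abs(z.mean()) < 0.15
        assert z.std() == pytest.approx(1.0, abs=0.15)

    def test_duplicate_column_rejected(self, full_timeline):
        design = fn.build_design_matrix(full_timeline)
        X = design.matrix.copy()
        X[:, 1] = X[:, 0]
        dup = fn.DesignMatrix(matrix=X, columns=design.columns, tr=design.tr)
        vox = fn.VoxelTable(["v0"], ["none"], X[:, :1].T * 0, tr=design.tr)
        with pytest.raises(fn.RankDeficientDesignError):
            fn.fit_glm(vox, dup)


class TestContrast:
    @pytest.mark.parametrize(
        "amps,expected",
        [
            ({"angry": 1, "fearful": 1, "sad": 1, "happy": 1}, 0.0),
            ({"angry": 2, "fearful": 2, "sad": 2, "happy": 1}, 1.0),
            ({"angry": 1, "fearful": 2, "sad": 3, "happy": 2}, 0.0),
        ],
    )
    def test_contrast_is_mean_negative_minus_happy(self, full_timeline, amps, expected):
        design = fn.build_design_matrix(full_timeline)
        beta = np.zeros(design.matrix.shape[1])
        for lbl, a in amps.items():
            beta[design.column_index(lbl)] = a
        vox = fn.VoxelTable(["v0"], ["VS_NAc_left"], (design.matrix @ beta)[None, :], design.tr)
        (c,) = fn.contrast_neg_minus_pos(fn.fit_glm(vox, design), vox)
        assert c.contrast == pytest.approx(expected, abs=1e-10)
        assert c.contrast == pytest.approx(c.beta_neg - c.beta_pos, abs=1e-12)

    def test_contrast_invariant_to_common_offset(self, full_timeline):
        design = fn.build_design_matrix(full_timeline)
        face = ["angry", "fearful", "sad", "happy"]

        def contrast(offset):
            beta = np.zeros(design.matrix.shape[1])
            for lbl, a in zip(face, (1.5, 1.0, 0.5, 0.8)):
                beta[design.column_index(lbl)] = a + offset
            vox = fn.VoxelTable(["v0"], ["none"], (design.matrix @ beta)[None, :], design.tr)
            (c,) = fn.contrast_neg_minus_pos(fn.fit_glm(vox, design), vox)
            return c.contrast

        assert contrast(3.0) == pytest.approx(contrast(0.0), abs=1e-9)

    def test_missing_condition_rejected(self):
        tl = _single_block_timeline("angry")
        design = fn.build_design_matrix(tl)
        vox = fn.VoxelTable(["v0"], ["none"], np.zeros((1, design.matrix.shape[0])), design.tr)
        with pytest.raises(ValueError, match="missing"):
            fn.contrast_neg_minus_pos(fn.fit_glm(vox, design), vox)


def _contrast(vid, roi, value, z):
    return fn.ContrastResult(
        voxel_id=vid, beta_neg=value, beta_pos=0.0, contrast=value, z=z, roi_label=roi
    )


class TestExtractNDS:
    def test_mean_over_supra_threshold_roi_voxels(self):
        cons = [
            _contrast("a", "VS_NAc_left", 0.5, 3.0),
            _contrast("b", "VS_NAc_left", 0.7, 2.5),
            _contrast("c", "VS_NAc_left", 0.9, 4.0),
            _contrast("d", "VS_NAc_right", 5.0, 9.0),  # other hemisphere
            _contrast("e", "VS_NAc_left", -2.0, 0.5),  # sub-threshold
        ]
        res = fn.extract_nds(cons, roi="left")
        assert res.nds == pytest.approx(0.7)
        assert res.n_voxels_used == 3
        assert res.valid

    def test_all_sub_threshold_is_invalid(self):
        cons = [_contrast("a", "VS_NAc_left", 0.5, 1.0)]
        res = fn.extract_nds(cons, roi="left")
        assert not res.valid and res.n_voxels_used == 0

    def test_bilateral_pools_hemispheres(self):
        cons = [
            _contrast("a", "VS_NAc_left", 0.4, 3.0),
            _contrast("b", "VS_NAc_right", 0.8, 3.0),
        ]
        res = fn.extract_nds(cons, roi="bilateral")
        assert res.nds == pytest.approx(0.6)

    def test_unknown_roi_rejected(self):
        with pytest.raises(ValueError):
            fn.extract_nds([_contrast("a", "VS_NAc_left", 0.5, 3.0)], roi="amygdala")

    def test_no_voxels_in_roi_rejected(self):
        with pytest.raises(ValueError):
            fn.extract_nds([_contrast("a", "none", 0.5, 3.0)], roi="left")


class TestIO:
    def test_voxel_tsv_round_trip(self, tmp_path):
        vox = fn.VoxelTable(
            ["v0", "v1"],
            ["VS_NAc_left", "none"],
            np.arange(10, dtype=float).reshape(2, 5),
            tr=2.5,
        )
        path = tmp_path / "vox.tsv"
        fn.write_voxel_tsv(vox, path)
        back = fn.read_voxel_tsv(path)
        assert back.voxel_ids == vox.voxel_ids
        assert back.roi_labels == vox.roi_labels
        assert np.allclose(back.series, vox.series)

    def test_nifti_reader_matches_table(self, tmp_path):
        nib = pytest.importorskip("nibabel")
        rng = np.random.default_rng(3)
        img = rng.standard_normal((2, 2, 2, 6))
        mask = np.zeros((2, 2, 2), dtype=np.int16)
        mask[0, 0, 0] = 1
        mask[1, 1, 1] = 2
        nib.save(nib.Nifti1Image(img, np.eye(4)), tmp_path / "bold.nii")
        nib.save(nib.Nifti1Image(mask, np.eye(4)), tmp_path / "mask.nii")
        vox = fn.read_nifti_voxels(tmp_path / "bold.nii", tmp_path / "mask.nii")
        assert vox.n_voxels == 2
        assert set(vox.roi_labels) == {"VS_NAc_left", "VS_NAc_right"}
        assert np.allclose(vox.series[0], img[0, 0, 0])
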