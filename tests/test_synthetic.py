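"""Synthetic-data generator: templates, static trials, ADL streams, kinematic chain."""

import numpy as np
import pytest
from itertools import combinations

from graspquant.kinematics import AngleStream, angles_from_markers
from graspquant.segmentation import segment_adl
from graspquant.synthetic import (
    ChainGeometry,
    DegenerateGeometryError,
    GraspTemplate,
    SyntheticADLSpec,
    default_geometry,
    default_templates,
    forward_kinematics_markers,
    sample_adl_stream,
    sample_static_trial,
    templates_for,
)
from graspquant.taxonomy import FINGERS, GRASPS, finger_grasps


class TestDefaultTemplates:
    @pytest.mark.parametrize(
        "finger,expected", [("index", 13), ("middle", 12), ("ring", 8), ("little", 8)]
    )
    def test_per_finger_template_counts(self, templates, finger, expected):
        assert sum(t.finger == finger for t in templates) == expected

    def test_every_template_is_a_taxonomy_grasp(self, templates):
        assert {t.grasp for t in templates} == set(GRASPS)

    def test_same_grasp_differs_across_fingers(self, templates):
        for grasp in finger_grasps("ring"):
            means = [t.mean_angles for t in templates if t.grasp == grasp]
            for a, b in combinations(means, 2):
                assert np.any(a != b)

    def test_pairwise_separation_brute_force(self, templates):
        # exhaustive pairwise check within each finger, both metrics
        for finger in FINGERS:
            means = [t.mean_angles for t in templates if t.finger == finger]
            for a, b in combinations(means, 2):
                assert np.linalg.norm(a - b) >= 15.0 - 1e-9
                assert np.max(np.abs(a - b)) >= 15.0 - 1e-9

    def test_template_outside_finger_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            GraspTemplate(
                finger="ring", grasp="tripod", mean_angles=np.array([10.0, 10, 10, 0])
            )

    def test_anatomical_range_enforced(self):
        with pytest.raises(ValueError, match="flexion"):
            GraspTemplate(
                finger="index",
                grasp="tripod",
                mean_angles=np.array([150.0, 10, 10, 0]),
            )


class TestStaticTrials:
    def test_one_second_at_125_hz_gives_125_frames(self, templates):
        t = templates_for("index", templates)["tripod"]
        stream = sample_static_trial(t, duration_s=1.0, fs=125.0, seed=0)
        assert stream.n_frames == 125

    def test_zero_noise_reproduces_template_exactly(self, templates):
        t = templates_for("middle", templates)["lateral"]
        stream = sample_static_trial(t, noise_sd=0.0, seed=3)
        assert np.array_equal(stream.frames, np.tile(t.mean_angles, (125, 1)))

    def test_sample_sd_matches_generating_sd(self, templates):
        # Monte-Carlo: per-joint sample SD within 5% of 2 degrees
        t = templates_for("index", templates)["power_sphere"]
        stream = sample_static_trial(t, duration_s=80.0, fs=125.0, noise_sd=2.0, seed=7)
        sd = stream.frames.std(axis=0, ddof=1)
        assert np.all(np.abs(sd - 2.0) < 0.1)

    def test_negative_noise_rejected(self, templates):
        t = templates_for("index", templates)["tripod"]
        with pytest.raises(ValueError):
            sample_static_trial(t, noise_sd=-1.0)

    def test_identical_seeds_bit_identical(self, templates):
        t = templates_for("little", templates)["lateral"]
        a = sample_static_trial(t, seed=11)
        b = sample_static_trial(t, seed=11)
        assert np.array_equal(a.frames, b.frames)


class TestAdlStreams:
    def test_single_segment_spans_whole_stream(self, templates):
        spec = SyntheticADLSpec(
            "ring", ("lateral",), (2.0,), noise_sd=0.0, seed=0
        )
        stream, truth = sample_adl_stream(spec, templates)
        assert truth == [("lateral", 0, 250)]
        assert stream.n_frames == 250

    def test_noiseless_plateaus_meet_segmentation_criterion(self, templates):
        spec = SyntheticADLSpec(
            "index",
            ("tripod", "lateral", "medium_wrap"),
            (1.0, 1.0, 1.0),
            noise_sd=0.0,
            seed=0,
        )
        stream, truth = sample_adl_stream(spec, templates)
        for _label, a, b in truth:
            assert np.abs(np.diff(stream.frames[a:b], axis=0)).max() < 1.0

    def test_noiseless_zero_transition_recovered_exactly(self, templates):
        spec = SyntheticADLSpec(
            "middle",
            ("lateral", "tripod", "power_sphere"),
            (1.0, 1.0, 1.0),
            transition_duration=0.0,
            noise_sd=0.0,
        )
        stream, truth = sample_adl_stream(spec, templates)
        postures = segment_adl(stream)
        assert [p.source_interval for p in postures] == [(a, b) for _, a, b in truth]

    def test_label_outside_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            SyntheticADLSpec("ring", ("tripod",), (1.0,))

    def test_reproducible_under_seed(self, templates):
        spec = SyntheticADLSpec("index", ("tripod", "lateral"), (1.0, 1.0), seed=5)
        a, _ = sample_adl_stream(spec, templates)
        b, _ = sample_adl_stream(spec, templates)
        assert np.array_equal(a.frames, b.frames)


class TestForwardKinematics:
    def test_flat_hand_markers_collinear_along_metacarpal(self):
        geo = default_geometry()
        stream = AngleStream("index", 125.0, np.zeros((1, 4)))
        markers = forward_kinematics_markers(stream, geo)
        # first marker of each segment sits on the +Y bone axis
        origins = np.array([markers[s][0][0] for s in markers])
        assert np.allclose(origins[:, [0, 2]], 0.0)
        assert np.all(np.diff(origins[:, 1]) > 0)

    def test_right_angle_pip_flexion(self):
        geo = default_geometry()
        stream = AngleStream("index", 125.0, np.array([[0.0, 90.0, 0.0, 0.0]]))
        markers = forward_kinematics_markers(stream, geo)
        prox_axis = markers["proximal"][0][2] - markers["proximal"][0][0]
        mid_axis = markers["middle"][0][2] - markers["middle"][0][0]
        cos = prox_axis @ mid_axis / (
            np.linalg.norm(prox_axis) * np.linalg.norm(mid_axis)
        )
        assert abs(cos) < 1e-12

    def test_collinear_marker_geometry_rejected(self):
        bad = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            ChainGeometry(
                segment_lengths=(65.0, 40.0, 25.0, 18.0),
                marker_offsets={
                    s: bad for s in ("metacarpal", "proximal", "middle", "distal")
                },
            )

    def test_round_trip_recovers_angles(self, rng):
        # forward kinematics -> segment frames -> Cardan XYZ, noiseless
        geo = default_geometry()
        n = 100
        frames = np.column_stack(
            [
                rng.uniform(-10, 110, n),
                rng.uniform(-10, 110, n),
                rng.uniform(-10, 110, n),
                rng.uniform(-30, 30, n),
            ]
        )
        stream = AngleStream("index", 125.0, frames)
        markers = forward_kinematics_markers(stream, geo)
        recovered = angles_from_markers(markers, 125.0, "index")
        assert np.abs(recovered.frames - frames).max() < 0.1
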