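"""Synthetic-data generators: determinism, degenerate cases, calibration."""
import dataclasses

import numpy as np
import pytest

import flexlens as fl
from flexlens.errors import ParameterError
from flexlens.longevity import longevity_profile

from conftest import brute_force_runs


def flat_flex(phi_value, length, seed=0):
    return fl.FlexibilityProfile(
        phi=np.full(length, float(phi_value)),
        planted_regions=fl.RegionSet([]),
        seed=seed,
    )


class TestGenerateReference:
    def test_deterministic_for_fixed_seed(self):
        a = fl.generate_reference(length=200, seed=5)
        b = fl.generate_reference(length=200, seed=5)
        assert a[0].sequence == b[0].sequence
        assert a[0].labels_q8 == b[0].labels_q8
        assert np.array_equal(a[1].phi, b[1].phi)
        c = fl.generate_reference(length=200, seed=6)
        assert c[0].labels_q8 != a[0].labels_q8

    def test_pure_helix_mixture(self):
        ref, _ = fl.generate_reference(length=100, mix=(1.0, 0.0),
                                       coil_run_mean=1.0, seed=3)
        assert set(ref.labels_q8) <= {"H", "C"}
        # coil spacers are minimal: every coil run has length 1
        coil_runs = [n for lab, n in brute_force_runs(ref.labels_q8) if lab == "C"]
        assert coil_runs and max(coil_runs) == 1

    def test_geometric_run_length_calibration(self):
        ref, _ = fl.generate_reference(length=10000, helix_run_mean=6.0,
                                       mix=(1.0, 0.0), coil_run_mean=1.0, seed=11)
        helix_runs = [n for lab, n in brute_force_runs(ref.labels_q8) if lab == "H"]
        mean = np.mean(helix_runs)
        assert abs(mean - 6.0) / 6.0 < 0.05

    def test_phi_levels_follow_labels(self):
        ref, flex = fl.generate_reference(length=500, seed=2)
        lab = np.array(list(ref.labels_q8))
        assert flex.phi[lab == "C"].min() > 0.8
        assert flex.phi[lab != "C"].max() < 0.2

    def test_planted_blocks_recorded_and_flexible(self):
        ref, flex = fl.generate_reference(length=200, seed=4, planted_blocks=3,
                                          planted_block_len=15)
        assert len(flex.planted_regions) == 3
        for r in flex.planted_regions:
            assert len(r) == 15
            assert set(ref.labels_q8[r.start - 1 : r.end]) == {"C"}
            assert flex.phi[r.start - 1 : r.end].min() > 0.8

    @pytest.mark.parametrize("kwargs", [
        {"length": 5}, {"helix_run_mean": 0.5}, {"mix": (0.7, 0.7)},
        {"planted_blocks": 20, "planted_block_len": 15, "length": 100},
    ])
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            fl.generate_reference(**{"length": 100, **kwargs})


class TestGenerateTrajectory:
    def test_frozen_dynamics_reproduce_reference(self):
        ref, flex = fl.generate_reference(length=50, seed=1)
        traj = fl.generate_trajectory(ref, flex, n_frames=20, f_min=0, f_max=0, seed=1)
        assert all("".join(row) == ref.labels_q8 for row in traj.labels)
        assert np.all(longevity_profile(traj).longevity == 1.0)

    def test_maximal_flipping_gives_minimal_longevity(self):
        # flip guaranteed and the new label always differs -> every run is
        # one frame long, so mean-mode longevity is exactly 1/n_frames
        ref, flex = fl.generate_reference(length=50, seed=1)
        traj = fl.generate_trajectory(ref, flex, n_frames=40, f_min=1, f_max=1, seed=1)
        prof = longevity_profile(traj)
        assert np.all(prof.n_runs == 40)
        assert np.all(prof.longevity == 1.0 / 40)

    def test_frame_zero_and_times(self):
        ref, flex = fl.generate_reference(length=30, seed=2)
        traj = fl.generate_trajectory(ref, flex, n_frames=10, seed=2)
        assert "".join(traj.labels[0]) == ref.labels_q8
        assert np.array_equal(traj.frame_times, 200.0 * np.arange(10))

    def test_longevity_decreases_with_flexibility(self):
        ref, _ = fl.generate_reference(length=400, seed=3)
        phi = np.where(np.arange(400) < 200, 0.1, 0.9)
        flex = fl.FlexibilityProfile(phi=phi, planted_regions=fl.RegionSet([]), seed=3)
        traj = fl.generate_trajectory(ref, flex, n_frames=1500, seed=3)
        lon = longevity_profile(traj).longevity
        assert lon[200:].mean() < 0.5 * lon[:200].mean()

    def test_deterministic(self):
        ref, flex = fl.generate_reference(length=40, seed=7)
        t1 = fl.generate_trajectory(ref, flex, n_frames=50, seed=7)
        t2 = fl.generate_trajectory(ref, flex, n_frames=50, seed=7)
        assert np.array_equal(t1.labels, t2.labels)

    @pytest.mark.parametrize("kwargs", [
        {"f_min": 0.5, "f_max": 0.1}, {"f_max": 1.5}, {"n_frames": 1},
    ])
    def test_bad_parameters_rejected(self, kwargs):
        ref, flex = fl.generate_reference(length=20, seed=0)
        with pytest.raises(ParameterError):
            fl.generate_trajectory(ref, flex, **kwargs)


class TestGeneratePredictions:
    def test_perfect_accuracy_reproduces_reference(self):
        ref, flex = fl.generate_reference(length=60, seed=4)
        pred = fl.generate_predictions(ref, flex, a_max=1.0, a_min=1.0, seed=4)
        assert "".join(pred.predicted_labels) == fl.q8_to_q3(ref.labels_q8)

    @pytest.mark.parametrize("phi,expected", [(0.0, 0.9), (1.0, 0.5)])
    def test_accuracy_calibration_at_10k(self, phi, expected):
        ref, _ = fl.generate_reference(length=10000, seed=5)
        pred = fl.generate_predictions(ref, flat_flex(phi, 10000),
                                       a_max=0.9, a_min=0.5, seed=int(5 + phi))
        acc = fl.protein_accuracy(pred, ref.labels_q8)
        assert abs(acc - expected) < 0.02

    def test_emitted_label_carries_argmax_mass(self):
        ref, flex = fl.generate_reference(length=80, seed=6)
        for scheme in ("Q3", "Q8"):
            pred = fl.generate_predictions(ref, flex, scheme=scheme, seed=6)
            codes = np.array(pred.class_order)
            assert np.array_equal(codes[pred.probs.argmax(1)], pred.predicted_labels)
            assert np.allclose(pred.probs.sum(1), 1.0)

    def test_confidence_gain_out_of_range_rejected(self):
        ref, flex = fl.generate_reference(length=20, seed=0)
        with pytest.raises(ParameterError):
            # q = 0.5 - 0.9*0.1 < 1/3 at a = 0.4 for Q3
            fl.generate_predictions(ref, flat_flex(1.0, 20), a_max=0.4, a_min=0.4,
                                    conf_gain=2.0)


class TestGenerateDisorder:
    def test_logistic_step_limit(self):
        flex = fl.FlexibilityProfile(
            phi=np.repeat([0.0, 1.0], 20), planted_regions=fl.RegionSet([]), seed=0
        )
        (prof,) = fl.generate_disorder(flex, n_predictors=1, slope=50.0,
                                       noise_sd=0.0, seed=0)
        assert np.all(prof.scores[:20] < 0.01)
        assert np.all(prof.scores[20:] > 0.99)

    def test_blind_region_suppresses_signal(self):
        phi = np.full(60, 0.9)
        flex = fl.FlexibilityProfile(phi=phi, planted_regions=fl.RegionSet([]), seed=0)
        blind = fl.RegionSet([fl.Region("p", 21, 40, "blind")])
        (prof,) = fl.generate_disorder(flex, n_predictors=1, blind_regions=blind, seed=1)
        assert np.all(prof.scores[20:40] < 0.3)
        assert np.all(prof.scores[:20] > 0.7)

    def test_predictors_get_distinct_noise(self):
        flex = flat_flex(0.5, 50)
        d1, d2 = fl.generate_disorder(flex, n_predictors=2, seed=9)
        assert not np.array_equal(d1.scores, d2.scores)
        # same seed reproduces both streams
        e1, e2 = fl.generate_disorder(flex, n_predictors=2, seed=9)
        assert np.array_equal(d1.scores, e1.scores)
        assert np.array_equal(d2.scores, e2.scores)

    def test_monotone_in_phi(self):
        rng = np.random.default_rng(0)
        phi = rng.random(10000)
        flex = fl.FlexibilityProfile(phi=phi, planted_regions=fl.RegionSet([]), seed=0)
        (prof,) = fl.generate_disorder(flex, n_predictors=1, seed=2)
        assert fl.spearman(phi, prof.scores) > 0.9


class TestGenerateCoordinates:
    def test_zero_noise_static(self):
        traj = fl.generate_coordinates(np.zeros(20), sigma_min=0.0, sigma_max=0.0,
                                       n_frames=5, seed=0)
        assert np.all(traj.coords == traj.coords[0])
        assert np.allclose(fl.rmsf_profile(traj, align=False).rmsf, 0.0)

    def test_noise_stream_independent_of_rigid_flag(self):
        phi = np.full(15, 0.5)
        a = fl.generate_coordinates(phi, n_frames=10, rigid_motion=False, seed=3)
        b = fl.generate_coordinates(phi, n_frames=10, rigid_motion=True, seed=3)
        # frame k of b is a rigid transform of frame k of a
        for k in range(10):
            _, rmsd = fl.kabsch_superpose(b.coords[k], a.coords[k])
            assert rmsd < 1e-9

    def test_deterministic(self):
        phi = np.linspace(0, 1, 10)
        a = fl.generate_coordinates(phi, n_frames=6, seed=8)
        b = fl.generate_coordinates(phi, n_frames=6, seed=8)
        assert np.array_equal(a.coords, b.coords)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ParameterError):
            fl.generate_coordinates(np.zeros(10), sigma_min=2.0, sigma_max=1.0)
        with pytest.raises(ParameterError):
            fl.generate_coordinates(np.zeros(10), n_frames=1)


class TestScenarios:
    def test_ordered_population_spans_order_spectrum(self):
        pop = fl.ordered_population(30, seed=1)
        coil = [fl.order_score(r.labels_q8).coil_fraction for r, _ in pop]
        assert coil[0] < 0.3 and coil[-1] > 0.6
        lengths = [len(r) for r, _ in pop]
        assert min(lengths) >= 180 and max(lengths) <= 220

    def test_recovery_scenario_reproducible(self):
        a = fl.region_recovery_scenario(seed=2)
        b = fl.region_recovery_scenario(seed=2)
        assert np.array_equal(a.traj.labels, b.traj.labels)
        assert np.array_equal(a.disorder[0].scores, b.disorder[0].scores)
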