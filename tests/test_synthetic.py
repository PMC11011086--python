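import numpy as np
import pytest

from dogsleep.detection import GroundTruthDetector
from dogsleep.pipeline import analyze_stream
from dogsleep.comparison import frame_agreement
from dogsleep.sleep_state import State, extract_bouts, summarize
from dogsleep.synthetic import (
    DogSpec,
    NuisanceSpec,
    Scenario,
    observer_error_model,
    render_scenario,
    scenario_from_yaml,
    scenario_to_yaml,
    simulate,
)
from dogsleep.video_io import FrameMode, open_frame_source

from conftest import seq


def one_dog_scenario(schedule, seed=3, duration=None, fps=5.0, **dog_kwargs):
    duration = duration if duration is not None else sum(d for _, d in schedule)
    return Scenario(
        duration_s=duration, fps=fps, width=160, height=120, seed=seed,
        dogs=[DogSpec(start_position=(50.0, 60.0), schedule=schedule, **dog_kwargs)],
    )


class MemStream:
    def __init__(self, frames, fps):
        self.frames, self.fps, self.count = frames, fps, len(frames)

    def __iter__(self):
        return iter(self.frames)

    def __len__(self):
        return self.count


class TestScenarioValidation:
    def test_at_most_two_dogs(self):
        dog = DogSpec(schedule=[("asleep", 10.0)])
        with pytest.raises(ValueError, match="0-2 dogs"):
            Scenario(duration_s=10, dogs=[dog, dog, dog])

    def test_schedule_must_sum_to_duration(self):
        with pytest.raises(ValueError, match="schedule"):
            one_dog_scenario([("asleep", 5.0)], duration=10.0)

    def test_zero_duration_schedule_entries_rejected(self):
        with pytest.raises(ValueError, match="schedule"):
            DogSpec(schedule=[("asleep", 0.0)])


class TestSimulate:
    def test_all_asleep_no_twitch_is_pixel_static_inside_box(self):
        sc = one_dog_scenario([("asleep", 10.0)], twitch_prob=0.0)
        frames, truth = simulate(sc)
        for t in range(1, len(frames)):
            box = truth.boxes_by_frame[t][0]
            np.testing.assert_array_equal(
                box.crop(frames[t - 1].pixels), box.crop(frames[t].pixels))

    def test_same_seed_renders_bit_identical_frames(self):
        sc = one_dog_scenario([("awake", 5.0), ("asleep", 5.0)], seed=11)
        frames_a, _ = simulate(sc)
        frames_b, _ = simulate(sc)
        for a, b in zip(frames_a, frames_b):
            np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_truth_sequence_matches_schedule(self):
        sc = one_dog_scenario([("awake", 10.0), ("asleep", 20.0), ("awake", 10.0)])
        _, truth = simulate(sc)
        bouts = extract_bouts(truth.sequences[0])
        assert len(bouts) == 1
        assert bouts[0].duration == pytest.approx(20.0)
        assert truth.summaries[0].total_sleep_s == pytest.approx(20.0)

    def test_truth_summary_consistent_with_truth_sequence(self):
        sc = one_dog_scenario([("asleep", 6.0), ("awake", 4.0)])
        _, truth = simulate(sc)
        assert truth.summaries[0] == summarize(truth.sequences[0])

    def test_day_mode_renders_colour(self):
        sc = one_dog_scenario([("asleep", 2.0)])
        sc.mode = FrameMode.DAY_COLOUR
        frames, _ = simulate(sc)
        assert frames[0].pixels.ndim == 3

    def test_nuisance_streams_do_not_change_dog_trajectories(self):
        schedule = [("awake", 10.0)]
        quiet = one_dog_scenario(schedule, seed=5)
        noisy = one_dog_scenario(schedule, seed=5)
        noisy.nuisance = NuisanceSpec(sensor_noise_sd=4.0, flicker_amplitude=10.0)
        _, truth_q = simulate(quiet)
        _, truth_n = simulate(noisy)
        for t in truth_q.boxes_by_frame:
            assert truth_q.boxes_by_frame[t] == truth_n.boxes_by_frame[t]

    def test_two_dogs_tracked_distinctly(self):
        sc = Scenario(
            duration_s=10.0, fps=5.0, width=160, height=120, seed=9,
            dogs=[
                DogSpec(start_position=(40.0, 40.0), schedule=[("asleep", 10.0)]),
                DogSpec(start_position=(115.0, 80.0), schedule=[("awake", 10.0)]),
            ],
        )
        frames, truth = simulate(sc)
        result = analyze_stream(MemStream(frames, sc.fps),
                                GroundTruthDetector(truth.boxes_by_frame))
        assert sorted(result.summaries) == [0, 1]
        # identities preserved: dog 0 sleeps, dog 1 stays awake
        assert result.summaries[0].total_sleep_s > result.summaries[1].total_sleep_s


class TestEndToEndRecovery:
    def test_noiseless_scenario_recovers_schedule(self):
        sc = one_dog_scenario(
            [("awake", 45.0), ("asleep", 210.0), ("awake", 45.0)], seed=21)
        frames, truth = simulate(sc)
        result = analyze_stream(MemStream(frames, sc.fps),
                                GroundTruthDetector(truth.boxes_by_frame))
        (summary,) = result.summaries.values()
        assert summary.bout_count == 1
        # recovery within one decision window (3 s) per sleep onset
        assert abs(summary.total_sleep_s - 210.0) <= 3.0
        agreement = frame_agreement(result.sequences[0], truth.sequences[0])
        assert agreement >= 99.0

    def test_false_awake_rate_rises_monotonically_with_shake(self):
        """Camera shake inflates apparent wakefulness (windy-night effect)."""
        rates = []
        for shake in (0.0, 2.0, 6.0):
            sc = one_dog_scenario([("asleep", 60.0)], seed=13)
            sc.nuisance = NuisanceSpec(shake_sd=shake)
            frames, truth = simulate(sc)
            result = analyze_stream(MemStream(frames, sc.fps),
                                    GroundTruthDetector(truth.boxes_by_frame))
            states = result.sequences[0].states
            known = [s for s in states if s is not State.UNKNOWN]
            rates.append(sum(s is State.AWAKE for s in known) / len(known))
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]


class TestObserverErrorModel:
    def test_identity_with_no_lapse_and_no_jitter(self):
        truth = seq("WWSSSSWWSSW", fps=1)
        out = observer_error_model(truth, lapse_prob=0.0, boundary_jitter_sd=0.0, seed=1)
        assert out.states == truth.states

    def test_full_lapse_erases_all_sleep(self):
        truth = seq("WSSWSSSW", fps=1)
        out = observer_error_model(truth, lapse_prob=1.0, boundary_jitter_sd=0.0, seed=1)
        assert all(s is State.AWAKE for s in out.states)

    def test_jitter_is_deterministic_and_bout_preserving(self):
        truth = seq("W" * 20 + "S" * 30 + "W" * 20 + "S" * 25 + "W" * 20
                    + "S" * 40 + "W" * 20, fps=1)
        a = observer_error_model(truth, 0.0, 1.0, seed=42)
        b = observer_error_model(truth, 0.0, 1.0, seed=42)
        assert a.states == b.states
        # jitter of 1 s cannot merge bouts separated by 20 s of wake
        assert len(extract_bouts(a)) == len(extract_bouts(truth))
        assert summarize(a).total_sleep_s != summarize(truth).total_sleep_s


class TestRendering:
    def test_rendered_bundle_round_trips_through_frame_reader(self, tmp_path):
        sc = one_dog_scenario([("asleep", 4.0)], seed=2)
        frames_dir, truth = render_scenario(sc, tmp_path / "bundle")
        stream = open_frame_source(frames_dir, fps_override=sc.fps)
        reread = [f.pixels for f in stream]
        rendered, _ = simulate(sc)
        assert len(reread) == len(rendered)
        for a, b in zip(reread, rendered):
            np.testing.assert_array_equal(a, b.pixels)
        assert (tmp_path / "bundle" / "detections.csv").exists()
        assert (tmp_path / "bundle" / "observations_dog0.csv").exists()
        assert (tmp_path / "bundle" / "truth.json").exists()

    def test_scenario_yaml_round_trip(self, tmp_path):
        sc = one_dog_scenario([("awake", 3.0), ("asleep", 7.0)], seed=17,
                              twitch_prob=0.1)
        path = tmp_path / "s.yaml"
        scenario_to_yaml(sc, path)
        back = scenario_from_yaml(path)
        assert back == sc
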