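# Example synthetic kennel scenario: one dog, five minutes at 5 fps,
# night-vision grayscale, one long sleep bout flanked by activity.
duration_s: 300.0
fps: 5.0
width: 160
height: 120
seed: 42
mode: night_gray
dogs:
  - body_size: 24
    start_position: [50.0, 60.0]
    schedule:
      - [awake, 45.0]
      - [asleep, 210.0]
      - [awake, 45.0]
    awake_motion_sd: 2.0
    twitch_prob: 0.0
    twitch_amplitude: 2.0
nuisance:
  shake_sd: 0.0
  flicker_amplitude: 0.0
  flicker_period_s: 10.0
  sensor_noise_sd: 0.0
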