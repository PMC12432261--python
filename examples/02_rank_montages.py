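"""Rank candidate electrode montages on simulated smooth-pursuit data.

Simulates two participants tracking sinusoidal 1-D pursuit targets
(0.33/0.5/1 Hz, opening angles 2.5-15 degrees) with realistic sensor and
camera noise, then correlates each candidate differential pair with the
gold-standard horizontal EOG (maximum lag 12 samples) and with the camera
gaze trace (maximum lag 64 samples, covering device latency).  Per-trial
Pearson r values are averaged via the Fisher z-transformation.

The printed mean |r| ranks the montages: cross-ear pairs at eye level
(L8-R8, L1-R1) come out on top, pairs far from eye level (L3-L2, R2-R3)
at the bottom — closeness to the eyes wins.
"""

from eareog.montage import HORIZONTAL_CANDIDATES, rank_montages
from eareog.pipeline import PipelineConfig, collect_pursuit_trials, simulate_participant
from eareog.preprocess import bandpass_recording

config = PipelineConfig(seed=5, participants=2, cycles=1)
trials = []
for pid in range(config.participants):
    pdata = simulate_participant(config, pid, tasks=("pursuit",))
    schedule, recording, _truth, camera = pdata.pursuit
    filtered = bandpass_recording(recording)
    trials += collect_pursuit_trials(filtered, camera, schedule, "horizontal", pid)

print(f"{len(trials)} horizontal pursuit trials from {config.participants} participants\n")
for reference in ("gold_eog", "camera"):
    print(f"reference = {reference}")
    for res in rank_montages(trials, HORIZONTAL_CANDIDATES, reference):
        print(f"  {res.pair.label:>6}:  mean |r| = {abs(res.mean_r):.3f}   "
              f"mean lag = {res.mean_lag_samples:+5.1f} samples")
    print()

print("Correlations with the camera are lower and lag estimates larger: the "
      "camera path includes device latency and 60->125 Hz resampling.")
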