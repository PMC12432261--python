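"""Predict horizontal gaze-angle changes from saccade deflections.

Fits ordinary-least-squares models mapping voltage deflection (uV) to the
signed change in horizontal gaze angle (degrees), once per feature set:
the best pair (L8-R8), all candidate pairs, and the gold-standard hEOG.
Evaluation is leave-one-participant-out; the printed MAE is the mean
absolute angular error over held-out saccades, and the Bland-Altman limits
of agreement quantify how the ear-based and gold-standard predictions
agree saccade by saccade.
"""

from eareog.montage import HORIZONTAL_CANDIDATES, MontagePair
from eareog.pipeline import PipelineConfig, simulate_participant
from eareog.prediction import bland_altman, evaluate_mae
from eareog.preprocess import bandpass_recording
from eareog.saccades import deflection_table, extract_epochs, label_epochs

config = PipelineConfig(seed=9, participants=6, cycles=1)
epochs = []
for pid in range(config.participants):
    pdata = simulate_participant(config, pid, tasks=("saccade",))
    schedule, recording, _truth, _camera = pdata.saccade
    eps, _ = extract_epochs(bandpass_recording(recording), schedule, participant_id=pid)
    label_epochs(eps)
    epochs += eps

table = deflection_table(epochs, list(HORIZONTAL_CANDIDATES))
horizontal = table[(table["axis"] == "horizontal") & table["valid"]].dropna(
    subset=[p.label for p in HORIZONTAL_CANDIDATES] + ["hEOG"]
)
print(f"{len(horizontal)} valid horizontal saccades from {config.participants} participants\n")

feature_sets = {
    "best pair (L8-R8)": ["L8-R8"],
    "all pairs": [p.label for p in HORIZONTAL_CANDIDATES],
    "gold standard": ["hEOG"],
}
predictions = {}
for name, features in feature_sets.items():
    report, per = evaluate_mae(horizontal, features, cv="loo")
    overall = report[report["direction"] == "all"].iloc[0]
    predictions[name] = per["predicted_deg"].to_numpy()
    print(f"{name:>18}:  MAE = {overall['mae_deg']:.2f} deg "
          f"(SD {overall['sd_deg']:.2f}, n = {overall['n']})")

stats = bland_altman(predictions["best pair (L8-R8)"], predictions["gold standard"])
print(f"\nBland-Altman, ear vs gold predictions: mean diff "
      f"{stats.mean_diff:+.3f} deg, LoA [{stats.loa_low:+.2f}, {stats.loa_high:+.2f}] deg")
print("A mean difference near zero means no systematic bias between the "
      "ear-based and periorbital models; the LoA width is the saccade-level "
      "disagreement.")
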