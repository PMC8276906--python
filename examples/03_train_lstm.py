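"""Train the two-layer LSTM on one synthetic session (four classes).

Uses the 70:30 split and desk-scale training (30 epochs here; pass more
for the study-scale schedule). Prints the training curve tail, holdout
accuracy (chance = 0.25 on a balanced basis), the confusion matrix and
class-wise sensitivity/specificity.
"""

import numpy as np

import stressbci as sb
from stressbci.architectures import (TrainingConfig, build_lstm_rnn, predict,
                                     train_model)
from stressbci.metrics import classwise_report, confusion

profile = sb.session.sample_profile("L1", group="ASD", seed=42)
rec = sb.generate_recording(profile, sb.make_schedule(30.0))
windows = sb.extract_windows(sb.bandpass(rec), length_s=1.0)
train, test = sb.split_train_test(windows, sb.SplitSpec(0.7, seed=3))

model = train_model(build_lstm_rnn(2), TrainingConfig(epochs=30, seed=0), train)
print("final training loss/accuracy:",
      f"{model.history['loss'][-1]:.3f} / {model.history['accuracy'][-1]:.3f}")

scores, pred = predict(model, test)
cm = confusion(test.labels, pred)
print(f"holdout accuracy: {cm.accuracy:.3f} on {cm.total} windows")
print("confusion matrix (rows = true, cols = predicted):")
print(cm.counts)
rep = classwise_report(cm)
for name in sb.CONDITIONS:
    print(f"{name:9s} sensitivity {rep.sensitivity[name]:.3f}  "
          f"specificity {rep.specificity[name]:.3f}")
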