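"""Condition raw epochs for the classifier.

Zero-phase 0.3-50 Hz band-pass, -200..0 ms baseline correction, cropping
to the 0..1000 ms model window (251 samples at 250 Hz), 100 uV amplitude
rejection, and mastoid removal (63 -> 61 data channels).
"""

import eegdecode as eg

epochs = eg.simulate_cohort("task", n_subjects=2, seed=1, trials_per_task=70,
                            artifact_rate=0.05, epoch_window=(-0.3, 1.1))
print(f"raw: {epochs.n_trials} trials x {epochs.n_channels} ch x {epochs.n_samples} samples")

conditioned, report = eg.standard_pipeline(epochs)
print(f"conditioned: {conditioned.n_trials} trials x {conditioned.n_channels} ch "
      f"x {conditioned.n_samples} samples")
print(f"rejected {len(report['rejected_indices'])} trials above 100 uV "
      f"(5% of epochs carry a planted 150 uV artifact excursion)")
print(f"dropped channels: {report['channels_dropped']}")

# normalization is fit per subject on a training partition and applied to
# held-out data, so test trials never influence the statistics
train, holdout = eg.pooled_split(conditioned, "task", 0.8, seed=0)
train_norm, stats = eg.normalize_subject(train)
holdout_norm, _ = eg.normalize_subject(holdout, stats=stats)
print(f"train/holdout: {train_norm.n_trials}/{holdout_norm.n_trials} trials; "
      f"z-scoring statistics fit on the training partition only")
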