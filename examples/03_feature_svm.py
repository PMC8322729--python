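"""Train the 40-feature window SVM with a leakage-free subject-wise split.

Each 50-frame (0.5 s) window yields 40 features (statistics and spectral
descriptors of the acceleration/gyro magnitudes and the three Euler angles);
windows are z-scored with training statistics and classified fall vs ADL.
"""

import preimpact as pi

spec = pi.SimulationSpec(n_subjects=6,
                         tasks=["D01", "D06", "D08", "D13", "F03", "F09", "F13"],
                         trials_per_task=2, seed=3)
dataset = pi.generate_dataset(spec)

subjects = sorted({rec.subject_id for rec, _ in dataset})
train_ids, test_ids = pi.subject_split(subjects, test_fraction=0.25, seed=0)
train = [(r, l) for r, l in dataset if r.subject_id in train_ids]
test = [(r, l) for r, l in dataset if r.subject_id in test_ids]

w_tr, y_tr = pi.windows_and_labels(train)
w_te, y_te = pi.windows_and_labels(test)
norm = pi.fit_normalizer(pi.feature_matrix(w_tr))
model = pi.train_svm(norm.transform(pi.feature_matrix(w_tr)), y_tr)

acc = (pi.predict_windows(model, norm.transform(pi.feature_matrix(w_te))) == y_te).mean()
print(f"subjects: {train_ids} train / {test_ids} test (no subject overlap)")
print(f"windows:  {len(y_tr)} train ({int(y_tr.sum())} fall), "
      f"{len(y_te)} held out")
print(f"held-out window accuracy: {100 * acc:.2f} %")
print("windows are labeled fall iff they end inside the onset-to-impact "
      "phase; post-impact windows are excluded (pre-impact task).")
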