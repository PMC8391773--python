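"""How early can the onset be predicted? The backward-window protocol.

Trains on 5-minute segments immediately before onset (high ectopy) versus
controls, then tests on windows ending 0, 2.5, 5, 7.5 and 10 minutes before
the onset of longer records whose ectopy ramps up toward the onset.
Accuracy degrades (sensitivity first) as the window moves away from onset —
the farther windows look more and more like controls.
"""

import afpredict as af

train_recs = af.generate_cohort(10, seed=11)
train_vecs = [
    af.assemble_features(r.rr, subset="selected14",
                         segment_id=f"tr{i}", label=r.label)
    for i, r in enumerate(train_recs)
]
model = af.train(train_vecs, kind="rf", seed=11)

# evaluation records: 20 minutes long; pre-AF ectopy ramps toward the onset
eval_records = []
for i in range(8):
    ctl = af.generate_nsr_rr(af.SynthConfig(
        duration_s=1220, pac_rate_per_min=0.5, seed=500 + i))
    eval_records.append(af.EvalRecord(ctl.rr, onset_s=1210,
                                      label="control", record_id=f"c{i}"))
    pre = af.generate_nsr_rr(af.SynthConfig(
        duration_s=1220, pac_rate_per_min=4.0, pac_ramp=8.0, seed=600 + i))
    eval_records.append(af.EvalRecord(pre.rr, onset_s=1210,
                                      label="pre-AF", record_id=f"p{i}"))

print("offset_s  SEN     SPE     ACC")
for res in af.backward_evaluate(eval_records, model):
    m = res.report
    print(f"{res.offset_s:7.0f}  {m.sen:6.2f}  {m.spe:6.2f}  {m.acc:6.2f}")

print("\nOffset 600 s tests the window from 15 to 10 minutes before onset; "
      "specificity stays high while sensitivity decays with distance.")
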