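"""Extract the 14 selected HRV features from one synthetic pre-AF segment.

Generates a 5-minute tachogram with 6 premature atrial beats per minute,
runs the full preprocessing + feature pipeline and prints the selected
feature vector.  High AR residual power, VFCDM envelope variance and TQWT
band energies relative to a clean segment are the signature of frequent
premature beats.
"""

import afpredict as af

preaf = af.generate_nsr_rr(af.SynthConfig(seed=42, pac_rate_per_min=6.0))
control = af.generate_nsr_rr(af.SynthConfig(seed=42, pac_rate_per_min=0.0))

for name, rec in [("control", control), ("pre-AF", preaf)]:
    vec = af.assemble_features(rec.rr, subset="selected14", segment_id=name)
    print(f"\n{name} segment ({rec.rr.n_intervals} intervals, "
          f"{len(rec.pac_truth)} injected PACs):")
    for k, v in vec.values.items():
        print(f"  {k:16s} {v:12.4g}")

print("\nThe dispersion and energy features (rmssd_norm, sd1, ar_resid, "
      "vfcdm_var, tqwt_energy_*) all exceed their control values in the "
      "pre-AF segment; the spectral-shape features (lfn, band entropies) "
      "can move either way.")
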