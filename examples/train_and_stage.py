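"""Train the two-stage random-forest stager on a small synthetic cohort and
stage a held-out subject in both modes.

Fusion mode uses the snore-event context rule and the sound-based wake
detection; single-sensor mode is the radar-only baseline.  The per-stage
accuracies are recall against the ground-truth hypnogram, in percent.
"""

import sleepfusion as sf

print("simulating 4 subjects x 240 epochs (2 h each)...")
cohort = sf.simulate_cohort(4, 240, seed=2)

print("training wake/sleep and NREM/REM forests on subjects 0-2...")
stager = sf.train_from_cohort(cohort[:3], seed=2)
print(f"  wake/sleep model uses {len(stager.ws_features)} features, "
      f"NREM/REM model {len(stager.rnr_features)}")

held_out = cohort[3]
for mode in ("fusion", "single-sensor"):
    result = sf.run_pipeline(
        held_out.recording, held_out.sound, stager,
        mode=mode, reference=held_out.hypnogram,
    )
    rep = result.report
    print(f"\n{mode} mode ({len(result.rule_log)} post-processing corrections):")
    for key, val in rep.items():
        shown = f"{val:.1f}%" if val == val else "n/a (stage absent)"
        print(f"  {key}: {shown}")
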