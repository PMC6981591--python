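"""Desirability profiling with the published coefficient vector (skip-fit).

Reproduces the published per-factor profile grid — five levels
(mean ± 2, 1, 0 SD) per factor, predicted LQrv and partial desirability —
and the cut-off levels at which each positive factor alone drives the
prediction to the cohort mean.
"""

from mcsqol import DesirabilitySpec, ProfileContext, factor_profile, find_cutoffs, global_desirability

ctx = ProfileContext.from_study()   # published coefficients + factor stats
spec = DesirabilitySpec()           # band: LQrv 22 (d=0) .. 40 (d=1)
center = ctx.center_prediction
print(f"center prediction (all factors at their means): {center:.5f}  -> d = 0.5")

prof = factor_profile(ctx, "phase1_score", spec)
print("\nphase I class score profile (level, predicted LQrv, desirability):")
for lev, pred, d in zip(prof.levels, prof.predicted, prof.partial_d):
    print(f"  {lev:+9.5f}  {pred:9.5f}  {d:.6f}")
print("Desirability 0.5 marks the cohort-mean impairment; values toward 1 "
      "mark factor settings pushing LQrv toward the high-impairment limit 40.")

center_ds = [factor_profile(ctx, j, spec).partial_d[2] for j in range(9)]
print(f"\nglobal desirability at the center (geometric mean of 9 d's): "
      f"{global_desirability(center_ds):.6f}")

cuts = find_cutoffs(ctx, target=center, spec=spec)
print("\ncut-off levels reaching the cohort-mean LQrv (= factor means):")
print(cuts.round(4).to_string(index=False))
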