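"""Simulate a full stability study and refit its ground truth.

Generates a year-long, three-batch study (15 vials per time point,
measurement SD 96.6 U/L) whose per-temperature deactivation constants are
known, then runs the estimation pipeline: stop rule on the relative
activity trace, per-isotherm kd fits, Arrhenius regression and the
thermodynamic table.
"""

import enzstab as ez
from enzstab.synthetic import INITIAL_ACTIVITY, TABLE_KD

spec = ez.StudySpec(vials_per_batch=5, seed=11)  # 3 batches x 5 vials
study = ez.generate_study(spec)
print(f"simulated {len(study)} activity measurements")

result = ez.fit_stability_study(study, INITIAL_ACTIVITY)
print(f"\n{'T (K)':>8} {'true kd':>8} {'fitted kd':>10} {'R^2':>6} {'months':>7}")
for iso in result.isotherms:
    kept = iso.n_points // 15
    print(f"{iso.temperature:8.2f} {TABLE_KD[iso.temperature]:8.3f} "
          f"{iso.k_d:10.4f} {iso.r_squared:6.3f} {kept:7d}")

arr = result.arrhenius
print(f"\nE_d = {arr.E_d / 1000:.2f} kJ/mol, ln A = {arr.ln_A:.2f} "
      f"(R^2 = {arr.r_squared:.3f})")
print(f"predicted t1/2 at 25 degC: {ez.predict_half_life(298.15, arr):.1f} months")
# Fitted kd track the truth within a few percent; the hottest isotherm is
# truncated by the stop rule (sampling stops once ~75% activity is lost,
# keeping a minimum of five time points while activity stays measurable).
# The Arrhenius prediction smooths over the scatter of the underlying kd
# set (R^2 ~ 0.9), so it is more conservative than the 297.53 K isotherm's
# own t1/2 of ~12.6 months — the global fit, not a fitting defect.
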