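"""Adapt SRK/T to a patient group with support vector regression.

Simulates a cohort whose outcomes carry a systematic corneal-diameter bias
of 0.15 D per mm of white-to-white (the kind of population-specific error
constant optimization cannot remove), trains the SVR refinement layer on the
training split, and compares held-out errors against plain optimized SRK/T.
"""

import numpy as np

import iolcalc as m
from iolcalc.formulas import srkt_refraction_array
from iolcalc.simulate import CohortSpec, generate_cohort

cohort = generate_cohort(
    CohortSpec(n_patients=1160, bias_spec={"wtw": 0.15}, seed=42)
)
train, valid = m.split_train_validation(cohort, n_validation_patients=400, seed=7)

a_const = m.optimize_a_constant(train).constants
model = m.train_adapted_calculator(train, a_const, seed=11)
print(f"optimized A = {a_const.a_constant:.3f}; "
      f"grid search chose C={model.chosen_c}, gamma={model.chosen_gamma}")

mrse = valid.column("postop_mrse")
pe_srkt = mrse - srkt_refraction_array(
    valid.column("axial_length"), valid.column("mean_keratometry"),
    a_const.a_constant, valid.column("iol_power"),
)
pe_adapted = mrse - np.array(
    [m.adapted_predict_refraction(model, r, r.iol_power) for r in valid]
)

for name, pe in (("SRK/T", pe_srkt), ("adapted", pe_adapted)):
    s = m.summarize_errors(pe)
    r = m.regress_error_on_covariate(pe, valid.column("wtw"))
    print(f"{name:8s} held-out MedAE {s.medae:.3f} D, within +/-0.50 D "
          f"{s.pct_within_050:.1f}%, error-vs-WTW R^2 {r.r_squared:.4f}")
# The adapted calculator absorbs the WTW-dependent bias: its error-vs-WTW
# R^2 collapses toward zero. The overall MedAE moves little because the bias
# (SD ~0.06 D) is small next to the outcome noise (~0.4 D).
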