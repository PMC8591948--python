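"""Predict postoperative refraction for one eye with SRK/T and Haigis.

Builds an average cataract-surgery eye, predicts the spectacle-plane
refraction a 20 D implant would leave, finds the emmetropia power, and picks
the grid power for a -0.20 D target.
"""

import iolcalc as m

eye = m.EyeRecord(
    patient_id="demo", eye_side="right", age=72.8,
    axial_length=23.92, mean_keratometry=44.35, acd=3.15,
    lens_thickness=4.63, cct=518.4, wtw=11.7,
)

srkt = m.SRKTConstants(a_constant=119.18)
haigis = m.HaigisConstants(a0=-2.1245, a1=0.2032, a2=0.2866)

ref_srkt = m.srkt_predict_refraction(eye, srkt, iol_power=20.0)
ref_haigis = m.haigis_predict_refraction(eye, haigis, iol_power=20.0)
pemme = m.srkt_emmetropia_power(eye, srkt)
p_target = m.power_for_target_refraction("srkt", eye, srkt, target=-0.20)

print(f"SRK/T predicted refraction at 20.0 D:  {ref_srkt:+.3f} D")
print(f"Haigis predicted refraction at 20.0 D: {ref_haigis:+.3f} D")
print(f"SRK/T emmetropia power:                {pemme:.3f} D")
print(f"Grid power for a -0.20 D target:       {p_target:.1f} D")
# Negative refraction = residual myopia. A 20 D implant slightly overshoots
# this eye (about -0.5 D), so the surgeon targeting -0.20 D picks 19.5 D.
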