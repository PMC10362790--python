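"""Grade a set of paired predictions against the AAMI and BHS standards.

Uses a simulated error distribution to show the full compliance report:
MAE/RMSE/ME/SD/r-squared, cumulative error percentages, the BHS letter
grade, and the AAMI verdict.
"""

import numpy as np

from ppgvitals.evaluation import PairedPredictions, bland_altman, compliance_report

rng = np.random.default_rng(0)
n_subjects, per_subject = 120, 10
y, y_hat, subjects = [], [], []
for s in range(n_subjects):
    truth = rng.normal(125.0, 18.0)
    for _ in range(per_subject):
        y.append(truth + rng.normal(0, 2.0))
        y_hat.append(truth + rng.normal(0.1, 2.8))  # small bias, modest spread
        subjects.append(f"s{s}")

p = PairedPredictions(y=np.array(y), y_hat=np.array(y_hat), subject_id=subjects, target="ASBP")
rep = compliance_report(p)
print(f"n = {rep.n_pairs} pairs from {rep.n_subjects} subjects")
print(f"MAE {rep.mae:.2f}  RMSE {rep.rmse:.2f}  ME {rep.me:.3f}  SD {rep.sd:.2f}  r2 {rep.r2:.3f}")
print(f"BHS cumulative within 5/10/15 mmHg: {rep.bhs_cum[0]:.1f}% / "
      f"{rep.bhs_cum[1]:.1f}% / {rep.bhs_cum[2]:.1f}%  -> grade {rep.bhs_grade}")
print(f"AAMI (>85 subjects, |ME|<5, SD<8): {'pass' if rep.aami_pass else 'fail'}")
ba = bland_altman(p)
print(f"Bland-Altman bias {ba['bias']:.2f} mmHg, limits of agreement "
      f"[{ba['loa_low']:.2f}, {ba['loa_high']:.2f}]")
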