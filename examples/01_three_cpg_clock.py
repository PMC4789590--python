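"""Evaluate the shipped 3-CpG epigenetic-age model on a few samples.

The model predicts age in years from beta-values (fraction methylated,
0..1) at three CpGs near the genes ASPA, ITGA2B and PDE4C:

    age = 111.83 - 64.57 b(cg02228185) - 42.57 b(cg25809905)
                 + 75.15 b(cg17861230)
"""

import pandas as pd

from methclock import MethylationMatrix, compute_delta_age, predict_age, three_cpg_clock

clock = three_cpg_clock()
print(f"clock {clock.name!r}: intercept {clock.intercept} years")
for cpg, coef in clock.coefficients.items():
    print(f"  {cpg}: {coef:+.2f} years per unit beta")

# three synthetic donors: young-looking, intermediate, old-looking methylation
matrix = MethylationMatrix(
    pd.DataFrame(
        {
            "donor_young": [0.95, 0.70, 0.20],
            "donor_mid": [0.85, 0.60, 0.30],
            "donor_old": [0.75, 0.50, 0.40],
        },
        index=clock.cpg_ids,
    )
)
chronological = [35.0, 52.0, 70.0]
pred = predict_age(clock, matrix)
delta = compute_delta_age(pred, chronological)
print()
print(delta.to_string(index=False, float_format=lambda v: f"{v:7.2f}"))
print()
print("delta_age = predicted - chronological age; positive values mean the")
print("donor's methylation looks older than their calendar age.")
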