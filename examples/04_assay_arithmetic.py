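"""Enzyme-activity, standard-curve and substrate-ratio calculations.

The β-glucosidase assay tracks p-nitrophenol release photometrically; one
unit (U/mL) is 1 nmol p-nitrophenol per minute per mL enzyme.  Pigment
quantification uses a linear OD-vs-concentration standard curve.
"""

import numpy as np

import gbopt

# activity of a hypothetical undiluted sample: ΔA = 0.005 over the assay
assay = gbopt.ActivityAssay(
    dilution=1.0,
    delta_a_sample=0.005,
    delta_a_blank=0.0,
    total_volume_ml=1.0,
    molar_absorption=1.0,  # kit-specific; must be supplied
    enzyme_volume_ml=1.0,
)
print(f"enzyme activity: {gbopt.enzyme_activity(assay):.2f} U/mL")

# standard curve from a 1..6 μg/mL dilution series
conc = np.arange(1.0, 7.0)
od = 0.1 * conc + 0.02
curve = gbopt.fit_standard_curve(conc, od)
print(
    f"standard curve: OD = {curve.slope:.3f}·c + {curve.intercept:.3f} "
    f"(r² = {curve.r2:.4f})"
)
print(f"an OD reading of 0.32 corresponds to {gbopt.invert_curve(curve, 0.32):.2f} μg/mL")

# substrate stoichiometry: 8.8 mg geniposide vs 1.4 mg glycine per mL system
geni_umol = gbopt.micromoles(8.8, gbopt.GENIPOSIDE_MW)
glyc_umol = gbopt.micromoles(1.4, gbopt.GLYCINE_MW)
ratio = gbopt.molar_ratio(8.8, gbopt.GENIPOSIDE_MW, 1.4, gbopt.GLYCINE_MW)
print(
    f"\ngeniposide {geni_umol:.2f} μmol vs glycine {glyc_umol:.2f} μmol "
    f"-> molar ratio {ratio:.2f}:1"
)
print(
    "A ratio slightly above 1 means geniposide (the genipin source) is in "
    "mild molar excess over the amine donor."
)
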