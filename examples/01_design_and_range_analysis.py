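"""Build the 49-run orthogonal design and screen factor importance.

Constructs the strength-2 OA(49, 7^4) over GF(7), loads the packaged
measured yields, and runs Taguchi-style range analysis: K[l, f] is the mean
yield at level l of factor f, and R[f] = max K − min K measures how much
the factor moves the yield across its levels.
"""

import gbopt

design = gbopt.build_mixed_oa(gbopt.REFERENCE_FACTORS)
ok, _ = gbopt.verify_strength2(design)
print(f"design: {design.n_runs} runs, strength-2 orthogonal: {ok}")

_, yields = gbopt.load_reference_dataset()
result = gbopt.range_analysis(design, yields)

print("\nK/R table (μg/mL):")
print(result.to_frame().round(4).to_string())
print("\nfactor importance:", " > ".join(result.ranked_names))
print(
    "\nReaction time has the largest range (R ≈ "
    f"{result.R.max():.2f} μg/mL), so it influences pigment yield most; "
    "geniposide dose influences it least over the tested window."
)
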