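"""Subject-specific band edges from the two anchor frequencies.

The five individual bands hang off TF (theta/alpha transition) and IAF
(individual alpha peak).  With the cohort-mean anchors TF=6.9 and
IAF=10.9 Hz the scheme reproduces the canonical MCI cohort ranges.
"""

from alphaband import AnchorFrequencies, define_bands

scheme = define_bands(AnchorFrequencies(tf=6.9, iaf=10.9))
for name, (lo, hi) in scheme:
    print(f"{name:<7s} {lo:5.1f} - {hi:5.1f} Hz")

# delta..alpha3 are contiguous and subject-specific; beta1/beta2/gamma
# are fixed configuration defaults.  The alpha1/alpha2 boundary (8.9 Hz)
# is the midpoint of the TF-IAF range.
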