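"""Reciprocity null model: how much bidirectionality is expected by chance?

For a directed graph with n nodes and m links placed uniformly at random,
the expected fraction of links whose reverse also exists is
(m - 1) / (n(n-1) - 1).  The Monte Carlo sampler also provides a 95% band
for judging an observed network.
"""

from coopnet.metrics import reciprocity_null

n, m = 30, 500  # a dense late-round network
result = reciprocity_null(n, m, reps=10_000, seed=0)
lo, hi = result.percentile_band()
print(f"n={n}, m={m}")
print(f"closed form expectation : {result.expected:.4f}")
print(f"Monte Carlo mean (sd)   : {result.mean:.4f} ({result.sd:.4f})")
print(f"95% band                : [{lo:.4f}, {hi:.4f}]")
# An observed bidirectional fraction above the band means direct
# reciprocation beyond what link density alone produces.
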