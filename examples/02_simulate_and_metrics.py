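"""Simulate one session per treatment and compute its network metrics.

Prints the stationary network density (mean normalized generosity over the
last five rounds), the bidirectional-link fraction against the matched
random null, the mean behavioural type L, and the recipients-providers
Kendall tau.
"""

import json

from coopnet import SessionConfig, simulate_session
from coopnet.metrics import session_summary
from coopnet.simulate import PRESETS

for preset, treatment in [("recipient_only_default", "recipient_only"),
                          ("reciprocal_default", "reciprocal")]:
    config = SessionConfig(n_participants=30, n_rounds=60, treatment=treatment)
    session = simulate_session(config, PRESETS[preset], seed=42)
    summary = session_summary(session, seed=0)
    print(f"--- {treatment}")
    for key in ("stationary_generosity", "stationary_bidirectional",
                "null_expected_bidirectional", "mean_L_stationary", "mean_tau"):
        print(f"  {key}: {summary[key]:.3f}")
    print(f"  final type counts: {json.dumps(summary['type_counts'])}")
# A stationary density near the treatment's calibrated level, mean L near 0
# (fair players dominate) and a strongly positive tau (giving and receiving
# move together).  Note the bidirectional fraction of these synthetic agents
# sits close to (slightly below) the matched random-null expectation: the
# sign-balanced default policy does not secure reciprocal links the way
# human participants do.  Compare the null band in 04_reciprocity_null.py.
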