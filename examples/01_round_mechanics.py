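"""Round mechanics and token accounting of the donation game.

Builds the canonical first-round scenario by hand: a focal participant adds
two links while four others add links to the focal, with benefit b = 2 and
cost c = 1 per link per round.
"""

from coopnet import SessionConfig, accumulate_tokens
from coopnet.core import LinkUpdate, RoundState, validate_and_apply_round

config = SessionConfig(n_participants=7, n_rounds=1)
state = RoundState.initial(config)

updates = {0: [LinkUpdate(0, 1, "add"), LinkUpdate(0, 2, "add")]}
for provider in (3, 4, 5, 6):
    updates[provider] = [LinkUpdate(provider, 0, "add")]

nxt = validate_and_apply_round(state, updates, config, strict=True).state

print(f"focal: g={nxt.g[0]} recipients, l={nxt.l[0]} providers")
print(f"round payoff = l*b - g*c = {nxt.l[0]}*2 - {nxt.g[0]}*1 = {nxt.round_payoff[0]}")
print(f"tokens at start of round 2: {accumulate_tokens(1000, [nxt.round_payoff[0]])}")
# The focal pays 2 tokens for its two donations, receives 8 from its four
# providers, and so climbs from the 1000-token endowment to 1006.
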