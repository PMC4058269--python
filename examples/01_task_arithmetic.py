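"""Task arithmetic: odds, indifferent points and the species presets.

The probabilistic-delivery task pits a small certain reward (SS, 1-2 pellets)
against a large probabilistic one (LLL, 5-6 pellets). The odds against
delivery at set probability p are 1/p - 1; the indifferent point is the p at
which the two options pay off equally in expectation.
"""

from pdtask import (
    RewardSpec,
    default_protocol,
    indifference_zone,
    indifferent_point,
    set_odds,
)

for species in ("rat", "marmoset"):
    proto = default_protocol(species)
    print(
        f"{species}: {proto.session_minutes:g}-min sessions, "
        f"{proto.timeout_seconds:g}-s timeout, "
        f"{proto.schedule.n_sessions} testing sessions over levels "
        f"{[f'{100 * p:g}%' for p in proto.schedule.p_levels]}"
    )

print()
for p in default_protocol("rat").schedule.p_levels:
    print(f"p = {100 * p:>5.1f}%  ->  odds = {set_odds(p):.3f}")

print()
print(f"indifferent point, 5-fold reward ratio: p = {100 * indifferent_point(5):g}%")
print(f"indifferent point, 3-fold reward ratio: p = {100 * indifferent_point(3):.1f}%")
low, high = indifference_zone(RewardSpec())
print(f"indifference zone for the 1-2 vs 5-6 pellet task: "
      f"p = {100 * low:g}% to {100 * high:.1f}%")
print("below the zone, repeatedly choosing SS is the economically optimal strategy")
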