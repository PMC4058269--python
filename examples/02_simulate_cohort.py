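"""Simulate a synthetic rat cohort and write its trial-level event log.

The demo cohort mixes two temperaments: gambler-like agents whose %LLL
preference barely declines as delivery is rarefied (shallow slope), and
non-gambler-like agents that shift steeply to the small certain reward.
"""

from pdtask import default_protocol, demo_cohort, simulate_cohort, write_event_log

protocol = default_protocol("rat")
agents = demo_cohort("rat", n_gambler=6, n_non_gambler=6)
log = simulate_cohort(agents, protocol, seed=7)

write_event_log(log, "demo_event_log.csv")
print(f"{len(agents)} subjects x {protocol.schedule.n_sessions} sessions "
      f"-> {len(log)} completed trials (demo_event_log.csv)")

one = log[0]
print(f"first trial: subject={one.subject_id} session={one.session_index} "
      f"p_set={one.p_set:g} choice={one.choice} delivered={one.delivered} "
      f"pellets={one.pellets}")

omissions = sum(1 for r in log if r.choice == "LLL" and not r.delivered)
print(f"{omissions} omission trials — LLL chosen but nothing delivered; these "
      "are where inadequate (timeout-window) pokes concentrate")
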