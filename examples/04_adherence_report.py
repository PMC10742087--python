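"""Duration-weighted adherence metrics from a week of session log entries.

Builds a synthetic week in which the at-home sessions (days 2-7) are only
partly completed, then aggregates completed over scheduled seconds.
"""

from tremorkit import ProtocolConfig, SessionLogEntry, completion_metrics

cfg = ProtocolConfig()
completed = {1: 3600.0, 2: 1800.0, 3: 1800.0, 4: 900.0, 5: 508.0, 6: 500.0, 7: 0.0}
entries = [
    SessionLogEntry(
        day=d,
        started_at=f"2024-03-{10 + d:02d}T18:00:00+00:00",
        completed_duration=c,
        scheduled_duration=3600.0 if d == 1 else 1800.0,
        baseline_frequency=5.2,
        baseline_significant=True,
        ended_early=c < (3600.0 if d == 1 else 1800.0),
    )
    for d, c in completed.items()
]

m = completion_metrics(entries, cfg)
for day, frac in m.per_day.items():
    print(f"day {day}: {100 * frac:5.1f} % completed")
print(f"\nat-home (days 2-7): {100 * m.at_home_fraction:.0f} %")
print(f"overall           : {100 * m.overall_fraction:.1f} %")
# Fractions are seconds-completed over seconds-scheduled, so a skipped day
# (day 7 here) counts its full scheduled duration against adherence.
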