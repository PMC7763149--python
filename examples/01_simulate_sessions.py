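"""Simulate labelled shark accelerometer sessions and inspect them.

Generates two 10-minute sessions at 10 Hz with the default behaviour
regimes (rest, two swim classes, vertical swim, chew) and prints the
event schedule summary and per-behaviour time budget.
"""

from collections import Counter

from finbeat import GeneratorConfig, simulate_session

config = GeneratorConfig(seed=1, session_length=600.0)
stream, events = simulate_session(config)

print(f"stream: {len(stream)} samples at {config.sampling_rate:g} Hz "
      f"({len(stream) / config.sampling_rate:.0f} s)")
print(f"events: {len(events)}")

counts = Counter(ev.label for ev in events)
budget = Counter()
for ev in events:
    budget[ev.label] += ev.duration
print(f"{'behaviour':<15}{'events':>8}{'seconds':>10}")
for label in sorted(counts):
    print(f"{label:<15}{counts[label]:>8}{budget[label]:>10.1f}")

# The time budget mirrors a captive benthic shark: resting dominates,
# swimming is common, vertical swimming and chewing are brief and rare.
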