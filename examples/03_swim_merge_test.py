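"""Should 'swim in the water column' and 'swim on the floor' be one class?

Welch two-sample t-tests on four dynamic-body-acceleration epoch
features decide: if none differs significantly the two labels merge
into a single 'swim' class.  The generator gives both labels identical
signal parameters, so this is a true null and the expected decision is
'merge' (each test has its nominal ~5% false-positive chance).
"""

from finbeat import (GeneratorConfig, apply_ethogram, build_feature_table,
                     compare_swim_classes, simulate_session)
from finbeat.simulate import session_seeds

sessions = [(f"s{i}", *simulate_session(GeneratorConfig(seed=s, session_length=600.0)))
            for i, s in enumerate(session_seeds(1, 4))]
table = build_feature_table(sessions, epoch_seconds=2)

report = compare_swim_classes(table, alpha=0.05)
print(report.to_frame().round(4).to_string(index=False))
print(f"\ndecision: {report.decision}")

modelling = apply_ethogram(table, report)
print("modelling classes:", sorted(modelling["label"].unique()))
# p-values well above 0.05 on all four features -> the classes merge,
# leaving the four-class ethogram: chew, rest, swim, vertical_swim.
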