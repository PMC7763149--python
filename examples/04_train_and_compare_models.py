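"""Train and compare classifiers on synthetic sessions.

Event-level 80/20 split, fold-wise minority up-sampling, 10-fold
cross-validated grid search, then out-of-sample scoring.  Uses the
reduced tuning profile and three models to keep the demo quick; pass
all eight names (or use default_specs) for the full comparison.
"""

from finbeat import (GeneratorConfig, SplitConfig, apply_ethogram,
                     build_feature_table, run_experiment, simulate_session)
from finbeat.models import fast_specs
from finbeat.simulate import session_seeds

sessions = [(f"s{i}", *simulate_session(GeneratorConfig(seed=s, session_length=600.0)))
            for i, s in enumerate(session_seeds(1, 4))]
tables = {e: apply_ethogram(build_feature_table(sessions, e), "merge")
          for e in (1, 2)}

result = run_experiment(tables, fast_specs(("CART", "RF", "SVM")),
                        SplitConfig(seed=3), seed=7)
print(result.comparison.round(2).to_string(index=False))

cm = result.results[("SVM", 2)].confusion
print("\nSVM 2 s test confusion matrix (rows = predicted):")
print(cm.to_frame().to_string())
# The synthetic regimes are separable by construction, so test
# accuracies near 100% are expected; on real shark data the published
# comparison peaked at 89% (SVM, 2 s epochs).
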