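"""The full iterative loop: lasso -> ridge -> knee -> theme exclusion.

Each round excludes the dominant theme (the one holding the top-ranked
selected variable) and refits on what remains, until the model AUC drops
below 75%, three rounds pass without a new theme, or no new variables
surface.  Here the theme codes come from the generator's ground truth,
standing in for the two human coders.
"""

from themewise import (EngineConfig, SplitSpec, VariableDictionary, prepare,
                       run_iterative_analysis)
from themewise.engine import ground_truth_provider
from themewise.synthetic import default_recovery_config, generate_population

cfg = default_recovery_config(seed=3, n_respondents=6_000)
table, dct, truth = generate_population(cfg)
enc = prepare(table, VariableDictionary.from_mapping(dct))

engine_cfg = EngineConfig(split=SplitSpec(seed=3), cv_seed=3)
report = run_iterative_analysis(enc, ground_truth_provider(truth), engine_cfg)

print(f"{'round':>5} {'test AUC':>9} {'test BER':>9} {'knee':>5} "
      f"{'#selected':>9}  dominant theme")
for r in report["rounds"]:
    m = r["test_metrics"]
    print(f"{r['round']:>5} {m['auc']:>9.3f} {m['ber']:>9.3f} "
          f"{str(r.get('knee_rank', '-')):>5} "
          f"{len(r['selected_variables']):>9}  {r.get('dominant_theme')}")
print(f"\nstop reason: {report['stop_reason']}")
print(f"exclusion order: {report['excluded_themes']}")
print("planted dominance order:",
      [t for t, _ in sorted(truth.theme_strengths().items(),
                            key=lambda kv: -kv[1])])
# The strongest planted theme is excluded first and the loop stops once the
# remaining features no longer discriminate (AUC < 0.75).  At this modest
# sample size the two weaker themes are close enough that their exclusion
# order can swap between seeds; the recovery experiments in the test suite
# run at n=20 000 where the planted order is resolved reliably.
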