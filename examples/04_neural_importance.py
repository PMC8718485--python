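"""The neural-network variant: lasso prefilter, four hidden layers,
first-layer weight importance, knee-point selection.

Variable importance is the sum of absolute first-hidden-layer weights per
input; the selected set is the prefix of the importance ranking above the
curvature knee.
"""

from themewise import NNConfig, VariableDictionary, nn_pipeline, prepare
from themewise.synthetic import default_recovery_config, generate_population

cfg = default_recovery_config(seed=1, n_respondents=5_000)
table, dct, truth = generate_population(cfg)
enc = prepare(table, VariableDictionary.from_mapping(dct))

report = nn_pipeline(enc, NNConfig(epochs=30, seed=1), cv_seed=1,
                     lasso_kwargs={"tol": 1e-2, "solver": "liblinear"})

m = report["test_metrics"]
print(f"lasso support: {len(report['lasso_support'])} features")
print(f"NN test AUC {m['auc']:.3f}, BER {m['ber']:.3f}")
print(f"knee at rank {report['knee_rank']}; "
      f"{len(report['selected_features'])} features selected")

planted = truth.planted_variables(0.0)
sel_vars = {enc.provenance[f][0] for f in report["selected_features"]}
overlap = sel_vars & planted
print(f"planted variables among the selection: {len(overlap)}/{len(sel_vars)}")
# First-layer importance concentrates on the planted signal variables; the
# selection is always a rank prefix of the importance curve.
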