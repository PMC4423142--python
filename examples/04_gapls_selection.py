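"""Select descriptors by genetic algorithm with PLS fitness.

A 30-descriptor pool hides a 3-descriptor truth; the GA evolves binary
inclusion chromosomes whose fitness is the cross-validated Q² of a PLS model
on the encoded subset, minus a small penalty per descriptor. The printed
trace shows the monotone best-ever fitness elitism guarantees.
"""

from tyroqsar import GAConfig, ga_select, make_regression_dataset

bundle = make_regression_dataset(n=30, p=30, k_true=3, n_collinear_blocks=0,
                                 snr=10.0, seed=3)
config = GAConfig(population_size=20, generations=12, leave_n=10,
                  max_components=3, seed=3, enforce_population_band=False)
chromosome, model, trace = ga_select(bundle.X, bundle.y, config)

print(trace.table.iloc[::3].to_string(index=False))
print(f"\nselected subset ({model.k} descriptors, {model.n_components} latent "
      f"components): {', '.join(model.names)}")
print(f"generating truth: {', '.join(sorted(bundle.support))}")
print(f"truth covered: {set(bundle.support) <= set(model.names)}")
print(f"best fitness (penalized Q2): {chromosome.fitness:.3f}")
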