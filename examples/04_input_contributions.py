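"""PaD sensitivity: which sigma-profile regions drive the viscosity.

Computes exact gradients of the trained network and the squared-gradient
relative contribution of each molecular descriptor S1..S8.
"""

import warnings

import desvisc as dv

warnings.simplefilter("ignore")

config = dv.GeneratorConfig(seed=3, n_pure_systems=8, n_cosolvent_systems=10)
dataset, _ = dv.gen_viscosity_dataset(config)
dv.split_dataset(dataset, seed=3)
model = dv.train(dataset, (9, 8, 1), dv.TrainingConfig(seed=0, max_iterations=200))

report = dv.relative_contributions(model, dataset)
for name, value in report.as_dict().items():
    bar = "#" * int(round(value / 2))
    print(f"{name:>3} {value:6.2f}%  {bar}")
print(
    "\nContributions are squared partial derivatives of log10(eta), summed "
    "over the\ntraining records and normalized to 100% over the eight "
    "region areas."
)
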