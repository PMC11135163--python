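"""Williams-plot applicability domain of a trained model.

Flags every record by its leverage (h vs h* = 3(d*+1)/p) and its
standardized residual (|SDR| vs 3) and prints the domain coverage.
"""

import collections
import warnings

import desvisc as dv

warnings.simplefilter("ignore")

config = dv.GeneratorConfig(seed=3, n_pure_systems=8, n_cosolvent_systems=10)
dataset, _ = dv.gen_viscosity_dataset(config)
dv.split_dataset(dataset, seed=3)
model = dv.train(dataset, (9, 8, 1), dv.TrainingConfig(seed=0, max_iterations=200))

report = dv.williams_report(model, dataset)
print(f"critical leverage h* = {report.h_star:.4f}")
print(f"coverage: {report.coverage_percent:.2f}% of {len(dataset)} records")
print("flags:", dict(collections.Counter(report.flags)))
print(
    "\nPoints inside (h < h*, |SDR| < 3) are reliable predictions; "
    "leverage outliers\nare structurally unlike the training compositions, "
    "response outliers are\npoorly fitted despite familiar structure."
)
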