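"""Discretize sigma-profiles into S1..S8 descriptors and mix them.

Builds three synthetic sigma-profiles (a choline-chloride-like salt, a
glycol-like donor and water), integrates each into the eight region
areas, and combines them into the descriptors of a 1:2 eutectic diluted
with 30 mol% water.
"""

import numpy as np

import desvisc as dv

profiles = dv.gen_sigma_profiles(dv.GeneratorConfig(seed=0, n_hbd=1))
pure = {cid: dv.discretize_profile(p) for cid, p in profiles.items()}

print("S1..S8 region areas (donor side -> acceptor side):")
print(dv.descriptor_table(pure).round(2).to_string())

mixture = dv.ratio_to_fractions(
    1, 2, 0.3, hba_id="hba", hbd_id="hbd01", cosolvent_id="cos01"
)
mixed = dv.mix_descriptors(pure, mixture)
print("\nmole fractions:", {k: round(v, 4) for k, v in mixture.fractions().items()})
print("mixture descriptors:", np.round(mixed.s, 2))
print(
    "\nEach S_i is the area under the sigma-profile in one charge-density "
    "region;\nthe mixture row is the mole-fraction weighted average of its "
    "constituents."
)
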