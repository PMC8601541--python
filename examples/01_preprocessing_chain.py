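"""The compositional preprocessing chain on a small simulated count table.

Counts are closed to relative abundances, rare OTUs are filtered
(>0.005% in at least one sample and present in >=50% of the samples of
at least one design cell), zeros are replaced multiplicatively (CZM) and
the result is clr-transformed.  The printed numbers show how many OTUs
survive the filter and that the chain preserves closure / zero-sum rows.
"""

import numpy as np

import microbench as mb

template = mb.make_default_template(n_otus=120, n_per_cell=4, seed=7)
sim = mb.sample_counts(template, seed=8)
counts = sim.dataset.counts
print(f"simulated counts: {counts.n_samples} samples x {counts.n_otus} OTUs, "
      f"median depth {int(counts.library_sizes.median())}")

rel = mb.to_relative(counts)
groups = sim.dataset.metadata.astype(str).agg(".".join, axis=1)
rel_f = mb.filter_otus(rel, groups, min_rel=5e-5, prevalence=0.5)
print(f"filter keeps {rel_f.shape[1]} of {counts.n_otus} OTUs")

rel_z = mb.replace_zeros_czm(mb.to_relative(rel_f),
                             library_sizes=counts.library_sizes.to_numpy())
print(f"after CZM zero replacement: min entry {rel_z.to_numpy().min():.2e}, "
      f"row sums {rel_z.sum(axis=1).iloc[0]:.6f} (closure preserved)")

X = mb.clr(rel_z)
print(f"clr matrix rows sum to {np.abs(X.sum(axis=1)).max():.2e} (zero-sum rows); "
      f"these values feed every downstream multivariate method")
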