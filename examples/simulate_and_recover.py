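"""Simulate a synthetic coding genome and recover its f_HRi.

Draws 2,250 genes whose adaptive nonsynonymous rate follows an imposed
curvilinear law Ka+(rr) = a + b exp(-c rr) in the local recombination rate,
then runs the recombination-bin analysis (here with the generating
DFE-averaged fixation rate supplied, so no per-bin likelihood fits are
needed) and compares the estimated fraction of adaptive substitutions lost
to interference with the generator's ground truth.
"""

import numpy as np

import hriquant as hq

params = hq.SimParams(n_genes=2250, n_pop_grid=128)
genes, truth = hq.simulate_gene_counts(params, seed=5)
print(f"simulated {len(genes)} genes; true f_HRi = {truth.f_hri:.3f} "
      f"(curve asymptote a = {params.adaptive_curve[0]})")

rng = np.random.default_rng(0)
res, bins = hq.fhri_from_genes(genes, rng, n_bins=15,
                               fixation=truth.fixation_factor)
print(f"estimated f_HRi = {res.f_hri:.3f}  "
      f"(Ka+ without interference = {res.ka_no_hri:.5f})")
print("\nper-bin estimates (Ka+ rises with recombination and plateaus):")
print(bins[["mean_rr", "alpha", "ka_plus", "loess_pred"]].round(4).to_string())
print("\nBins below ~2 cM/Mb fall short of the plateau - that shortfall,")
print("weighted by each bin's nonsynonymous sites, is the adaptation lost")
print("to Hill-Robertson interference.")
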