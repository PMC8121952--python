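"""Network enrichment on a simulated GWAS.

Builds a small synthetic study (genes, SNPs, a TF->TG network), draws a
trait whose associations are enriched in the network, computes single-SNP
summary statistics, and tests the network for enrichment against the
near-gene control threshold.
"""

import numpy as np

from rssnet import benchmark, vb
from rssnet.datatypes import SimScenario
from rssnet.enrich import adaptive_threshold, enrichment_result

study = benchmark.make_study(p=1500, n_genes=300, n_tf=12, n_tg=48,
                             n_edges=360, seed=7)
scenario = SimScenario("M13", theta0=-2.5, theta=2.0, rho=0.9, h2=0.3,
                       n=1500, p=1500, seed=11)
ds = benchmark.simulate_study_dataset(study, scenario)
print(f"simulated {np.count_nonzero(ds.beta)} trait-associated SNPs "
      f"out of {len(ds.beta)} (heritability {scenario.h2})")

const = vb.likelihood_normalizer(ds.gwas, ds.ld)
fits = vb.fit_grid(ds.gwas, ds.ld, study.ann, study.grid, seed=1,
                   const=const)
res = enrichment_result(fits, study.grid, network=study.network.name)
ctrl_bf, _ = adaptive_threshold(ds.gwas, ds.ld, study.snps, study.genes,
                                study.grid, seed=1, const=const)

print(f"log10 BF (enrichment vs baseline): {res.log10_bf:.2f}")
print(f"  restricted patterns: proximity-only {res.log10_bf_m11:.2f}, "
      f"edges-only {res.log10_bf_m12:.2f}, both {res.log10_bf_m13:.2f}")
print(f"  best-supported pattern: {res.best_pattern}")
print(f"near-gene control threshold: {ctrl_bf:.2f}")
print(f"network passes the adaptive control: {res.log10_bf > ctrl_bf}")
# A BF well above the control means the trait's genetic signal clusters
# in this network beyond generic near-gene enrichment.
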