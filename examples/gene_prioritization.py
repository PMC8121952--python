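"""Gene prioritization with enrichment-aware posteriors.

Fits the model under the baseline, the near-gene control, and the target
network, then reports per-gene P1 — the posterior probability that a
gene's locus (transcribed region +/- 100 kb) holds at least one
trait-associated SNP — and flags genes whose evidence is driven by the
network.
"""

import numpy as np

from rssnet import benchmark, vb
from rssnet.annotation import annotate, near_gene_control
from rssnet.datatypes import SimScenario
from rssnet.enrich import enrichment_result, gene_report

study = benchmark.make_study(p=1500, n_genes=300, n_tf=12, n_tg=48,
                             n_edges=360, seed=7)
ds = benchmark.simulate_study_dataset(
    study, SimScenario("M13", theta0=-2.5, theta=2.0, rho=0.9, h2=0.3,
                       n=1500, p=1500, seed=11))

const = vb.likelihood_normalizer(ds.gwas, ds.ld)
net_fits = vb.fit_grid(ds.gwas, ds.ld, study.ann, study.grid, seed=1,
                       const=const)
ctrl_ann = annotate(study.snps, study.genes,
                    near_gene_control(study.genes))
ctrl_fits = vb.fit_grid(ds.gwas, ds.ld, ctrl_ann, study.grid, seed=1,
                        const=const)
res = enrichment_result(net_fits, study.grid, network="target")
ctrl_res = enrichment_result(ctrl_fits, study.grid, network="control")
res.control_log10_bf = ctrl_res.log10_bf
res.passes_control = res.log10_bf > ctrl_res.log10_bf

m0 = [net_fits[h] for h in study.grid.subgrid_index("M0")]
near = [ctrl_fits[h] for h in study.grid.subgrid_index("M1")]
net = [net_fits[h] for h in study.grid.subgrid_index("M1")]
report = gene_report(study.snps, study.genes, m0, near,
                     {"target": net}, enrichments={"target": res})
report["truth"] = ds.gene_labels

top = report.sort_values("p1_bma", ascending=False).head(8)
print(top[["gene_id", "p1_base", "p1_near", "p1_bma", "significant",
           "network_driven", "truth"]].to_string(index=False))
called = report[report["significant"]]
fdr = 1 - called["truth"].mean() if len(called) else float("nan")
print(f"\n{len(called)} genes at P1 >= 0.9; "
      f"empirical FDR vs simulation truth: {fdr:.3f}")
# p1_bma > p1_near marks genes whose prioritization is driven by the
# network's topology rather than generic near-gene enrichment.
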