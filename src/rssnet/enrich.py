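"""Network enrichment Bayes factors and gene prioritization.

Enrichment: evidence for each model pattern is approximated by
marginalizing per-grid-point ELBOs under independent uniform grid priors
(log-mean-exp over the subgrid), and the Bayes factor compares the
enrichment model M1 (theta > 0 or sigma^2 > 0, i.e. the union of the
M11/M12/M13 subgrids) to the baseline M0 (theta = 0 and sigma^2 = 0).
Because BF thresholds are not transferable across traits, the Bayes
factor of a near-gene control network (all genes as nodes, no edges) on
the same GWAS serves as an adaptive enrichment threshold: a network
"passes" iff its BF strictly exceeds the control's.

Prioritization: for a gene locus (transcribed region +/- 100 kb), P1 is
the posterior probability that at least one locus SNP has a nonzero
effect, averaged over the subgrid with ELBO-proportional weights.
P1 variants: base (M0 subgrid), near (M1 of the control network), net
(M1 of a given network) and bma (Bayesian model averaging of P1_net over
the passing networks, weighted by their BFs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .annotation import PROXIMITY_WINDOW, annotate, near_gene_control
from .datatypes import (EnrichmentResult, GeneCatalog, GwasSummary,
                        HyperGrid, LDMatrix, SnpTable, ValidationError,
                        VariationalFit)
from . import vb

LN10 = np.log(10.0)


def log_evidence(fits: list[VariationalFit]) -> float:
    """Log-mean-exp of per-point ELBOs: uniform hyper-prior marginal."""
    if not fits:
        raise ValidationError("empty subgrid")
    elbos = np.array([f.elbo for f in fits])
    return logsumexp(elbos) - np.log(len(elbos))


def bayes_factor(fits_m1: list[VariationalFit],
                 fits_m0: list[VariationalFit]) -> float:
    """log10 BF of the (possibly restricted) enrichment model vs M0."""
    return (log_evidence(fits_m1) - log_evidence(fits_m0)) / LN10


def enrichment_result(fits: list[VariationalFit], grid: HyperGrid,
                      network: str = "network") -> EnrichmentResult:
    """Full and restricted Bayes factors from one grid of fits."""
    sub = {lab: [fits[h] for h in grid.subgrid_index(lab)]
           for lab in ("M0", "M11", "M12", "M13", "M1")}
    lev = {lab: log_evidence(f) for lab, f in sub.items() if f}
    lbf = {lab: (lev[lab] - lev["M0"]) / LN10
           for lab in ("M1", "M11", "M12", "M13") if lab in lev}
    return EnrichmentResult(
        network=network, log10_bf=lbf["M1"],
        log10_bf_m11=lbf.get("M11", -np.inf),
        log10_bf_m12=lbf.get("M12", -np.inf),
        log10_bf_m13=lbf.get("M13", -np.inf),
        log_evidence=lev)


def subgrid_weights(fits: list[VariationalFit]) -> np.ndarray:
    """Normalized exp(ELBO) weights: the hyper-parameter posterior over
    the subgrid under its uniform prior."""
    elbos = np.array([f.elbo for f in fits])
    return np.exp(elbos - logsumexp(elbos))


def locus_p1(fits: list[VariationalFit], locus_snps: np.ndarray,
             weights: np.ndarray = None) -> float:
    """P1 = 1 - sum_h w_h prod_{j in locus} (1 - alpha_j^(h)).

    Weights default to the ELBO posterior over the subgrid.  An empty
    locus has P1 = 0.
    """
    locus_snps = np.asarray(locus_snps, dtype=np.int64)
    if locus_snps.size == 0:
        return 0.0
    if weights is None:
        weights = subgrid_weights(fits)
    none_prob = np.array([np.prod(1.0 - f.alpha[locus_snps]) for f in fits])
    return float(1.0 - weights @ none_prob)


def bma_p1(p1_net: np.ndarray, log10_bf: np.ndarray) -> float:
    """BF-weighted model average of P1 across passing networks.

    Computed in log space so BFs of magnitude 1e140 are handled exactly.
    """
    p1_net = np.asarray(p1_net, dtype=float)
    lbf = np.asarray(log10_bf, dtype=float) * LN10
    if len(p1_net) == 0:
        raise ValidationError("BMA requires at least one passing network")
    w = np.exp(lbf - logsumexp(lbf))
    return float(w @ p1_net)


def gene_loci(snps: SnpTable, genes: GeneCatalog,
              window: int = PROXIMITY_WINDOW) -> list[np.ndarray]:
    """Per-gene locus SNP index sets (transcribed region +/- window)."""
    out = []
    chrom = snps.chrom
    pos = snps.pos
    for _, g in genes.table.iterrows():
        sel = np.flatnonzero((chrom == g["chrom"])
                             & (pos >= g["tx_start"] - window)
                             & (pos <= g["tx_end"] + window))
        out.append(sel)
    return out


def adaptive_threshold(gwas: GwasSummary, ld: LDMatrix, snps: SnpTable,
                       genes: GeneCatalog, grid: HyperGrid, seed: int = 0,
                       const: float = None, **fit_kwargs):
    """Near-gene control run: returns (control log10 BF, control fits).

    The control's BF is the GWAS-specific enrichment threshold; it is
    adaptive to trait differences and sample size and absorbs generic
    near-gene enrichment.
    """
    control = near_gene_control(genes)
    ann = annotate(snps, genes, control)
    fits = vb.fit_grid(gwas, ld, ann, grid, seed=seed, const=const,
                       **fit_kwargs)
    res = enrichment_result(fits, grid, network=control.name)
    return res.log10_bf, fits


def gene_report(snps: SnpTable, genes: GeneCatalog,
                fits_m0: list[VariationalFit],
                fits_control: list[VariationalFit],
                network_fits: dict, grid_m1: HyperGrid = None,
                enrichments: dict = None,
                cutoff: float = 0.9,
                window: int = PROXIMITY_WINDOW) -> pd.DataFrame:
    """Per-gene P1 table across networks.

    ``network_fits``: {name: M1-subgrid fits}; ``enrichments``:
    {name: EnrichmentResult} used for the BMA weights and pass flags
    (all supplied networks are averaged when absent).  Significance is
    flagged at P1_bma >= cutoff (inclusive); genes with
    P1_net > P1_near for some passing network are flagged as
    network-driven.
    """
    loci = gene_loci(snps, genes, window)
    w_m0 = subgrid_weights(fits_m0)
    w_near = subgrid_weights(fits_control)
    net_w = {k: subgrid_weights(f) for k, f in network_fits.items()}
    if enrichments is not None:
        passing = [k for k in network_fits if enrichments[k].passes_control]
    else:
        passing = list(network_fits)
    rows = []
    for gi, locus in enumerate(loci):
        gene_id = genes.gene_ids[gi]
        p1_base = locus_p1(fits_m0, locus, w_m0)
        p1_near = locus_p1(fits_control, locus, w_near)
        p1_net = {k: locus_p1(network_fits[k], locus, net_w[k])
                  for k in network_fits}
        if passing:
            p1_bma = bma_p1([p1_net[k] for k in passing],
                            [enrichments[k].log10_bf if enrichments else 0.0
                             for k in passing])
        else:
            p1_bma = p1_near
        row = {"gene_id": gene_id, "n_snps": len(locus),
               "p1_base": p1_base, "p1_near": p1_near, "p1_bma": p1_bma,
               "significant": p1_bma >= cutoff,
               "network_driven": any(p1_net[k] > p1_near for k in passing)}
        for k, v in p1_net.items():
            row[f"p1_net_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
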