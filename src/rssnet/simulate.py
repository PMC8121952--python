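"""Synthetic GWAS generator.

Emulates the full data path the method consumes: a synthetic gene
catalog and TF->TG network, genotypes with block LD, SNP effects drawn
from the correctly specified model or from mis-specified alternatives,
phenotypes at a fixed heritability, and single-SNP summary statistics
with a banded LD matrix — so no external download is needed anywhere.

Genotypes: haplotypes come from a latent Gaussian with AR(1) correlation
inside consecutive SNP blocks (independent across blocks), thresholded
so each SNP's minor-allele frequency matches a uniform draw from
``maf_range``; a genotype is the sum of two independent haplotypes.
Block boundaries give an LD matrix that is exactly block diagonal, hence
banded with bandwidth block_size - 1 and positive definite after mild
shrinkage toward the identity.

Effect models ("positive" = the network-enrichment model itself,
"negative" = alternatives that must not be mistaken for it):

* M0 — baseline: uniform association probability 10^theta0 odds.
* M11/M12/M13 — enrichment through the proximity flag (theta > 0),
  through edge-weighted variance (rho > 0), or both.
* near_gene_random — elevated association near a random gene subset of
  the same size as the network's membership.
* near_re_random — elevated association near random RE intervals.
* maf_ld_dependent — per-SNP effect variance additive over 10 MAF bins
  and 6 LD-score quantile annotations.
* edge_altered — the M1 model applied to a rewired copy of the target
  network with identical node set and edge count.
* noisy_network — data from the intact target network; edge removal
  (:func:`remove_edges`) degrades the *analysis* network instead.

Effect-scale convention: slab variances use sigma0^2 = 1 - rho and
sigma^2 = rho / mean(s2sum | s2sum > 0), so rho is the expected share of
slab variance transmitted through network edges; the absolute scale is
irrelevant because the phenotype step fixes the realized PVE to h2
exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import _kernels
from .annotation import annotate, build_proximity_flag
from .datatypes import (GeneCatalog, GwasSummary, LDMatrix,
                        RegulatoryNetwork, SimDataset, SimScenario, SnpTable,
                        ValidationError)
from .enrich import gene_loci

logger = logging.getLogger("rssnet")


# ---------------------------------------------------------------------------
# synthetic catalog / network / SNP map

def make_gene_catalog(n_genes: int = 1000, n_chrom: int = 5,
                      gene_length: int = 10_000, spacing: int = 200_000,
                      first_start: int = 50_001) -> GeneCatalog:
    """Genes tiled along synthetic chromosomes (deterministic layout).

    Default: 1,000 genes over 5 chromosomes, one gene every 200 kb, so
    both the 100 kb proximity window and the 1 Mb cis window are
    exercised without covering the whole genome.
    """
    per = n_genes // n_chrom
    rows = []
    g = 0
    for c in range(n_chrom):
        for i in range(per + (1 if c < n_genes % n_chrom else 0)):
            start = first_start + i * spacing
            rows.append((f"G{g:05d}", f"chr{c + 1}", start,
                         start + gene_length - 1, False))
            g += 1
    return GeneCatalog(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tx_start", "tx_end", "is_tf"]))


def make_snp_table(p: int, genes: GeneCatalog, seed: int) -> SnpTable:
    """SNP positions uniform over each chromosome's gene-bearing span."""
    rng = np.random.default_rng(seed)
    gt = genes.table
    chroms = list(dict.fromkeys(gt["chrom"]))
    per = [p // len(chroms)] * len(chroms)
    for i in range(p % len(chroms)):
        per[i] += 1
    rows = []
    j = 0
    for c, k in zip(chroms, per):
        span = int(gt.loc[gt["chrom"] == c, "tx_end"].max()) + 50_000
        pos = np.sort(rng.choice(span, size=k, replace=False)) + 1
        for x in pos:
            rows.append((f"rs{j:06d}", c, int(x), "A", "G"))
            j += 1
    return SnpTable(pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "a1", "a2"]))


def make_network(genes: GeneCatalog, n_tf: int = 20, n_tg: int = 180,
                 n_edges: int = 600, seed: int = 0,
                 name: str = "target") -> tuple[RegulatoryNetwork, GeneCatalog]:
    """Random TF/TG membership from the catalog with Uniform(0.2, 1)
    edge weights.  Returns the network and the catalog with is_tf set.

    TF out-degrees follow a Zipf-like profile (a few hub TFs regulate
    many targets), mirroring the heavy-tailed degree distributions of
    inferred regulatory networks.
    """
    rng = np.random.default_rng(seed)
    ids = genes.gene_ids
    members = rng.choice(len(ids), size=n_tf + n_tg, replace=False)
    tfs, tgs = ids[members[:n_tf]], ids[members[n_tf:]]
    tf_prob = 1.0 / np.arange(1, n_tf + 1) ** 1.1
    tf_prob /= tf_prob.sum()
    pairs = set()
    while len(pairs) < n_edges:
        g = tfs[rng.choice(n_tf, p=tf_prob)]
        t = tgs[rng.integers(n_tg)]
        pairs.add((g, t))
    edges = pd.DataFrame(sorted(pairs), columns=["tf", "tg"])
    edges["weight"] = rng.uniform(0.2, 1.0, size=len(edges))
    cat = GeneCatalog(genes.table.assign(is_tf=genes.table["gene_id"].isin(tfs)))
    net = RegulatoryNetwork(edges, tf_nodes=frozenset(tfs),
                            tg_nodes=frozenset(tgs), name=name)
    return net, cat


def rewire_network(network: RegulatoryNetwork, seed: int) -> RegulatoryNetwork:
    """Edge-altered copy: same node set and edge count, different edges.

    New TF->TG pairs are sampled uniformly among pairs absent from the
    original edge set; the weight multiset is carried over.  Only the
    node sets and edge count are preserved — in particular hub TFs lose
    their concentration of targets, which is exactly the topology signal
    the edge-altered scenario is meant to remove.
    """
    rng = np.random.default_rng(seed)
    tfs = sorted(network.tf_nodes)
    tgs = sorted(network.tg_nodes)
    orig = set(zip(network.edges["tf"], network.edges["tg"]))
    new_pairs = set()
    rows = []
    for w in network.edges["weight"]:
        for _ in range(10_000):
            g = tfs[rng.integers(len(tfs))]
            t = tgs[rng.integers(len(tgs))]
            if (g, t) not in orig and (g, t) not in new_pairs:
                new_pairs.add((g, t))
                rows.append((g, t, w))
                break
        else:
            raise ValidationError("rewiring failed: graph too dense")
    edges = pd.DataFrame(rows, columns=["tf", "tg", "weight"])
    edges = edges.sort_values(["tf", "tg"], kind="mergesort").reset_index(drop=True)
    return RegulatoryNetwork(edges, tf_nodes=network.tf_nodes,
                             tg_nodes=network.tg_nodes,
                             name=f"{network.name}-rewired")


def remove_edges(network: RegulatoryNetwork, fraction: float,
                 seed: int) -> RegulatoryNetwork:
    """Noisy copy: remove a uniformly random fraction of edges."""
    if not 0 <= fraction <= 1:
        raise ValidationError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    m = len(network.edges)
    keep = np.sort(rng.choice(m, size=m - int(round(fraction * m)),
                              replace=False))
    return RegulatoryNetwork(network.edges.iloc[keep].reset_index(drop=True),
                             tf_nodes=network.tf_nodes,
                             tg_nodes=network.tg_nodes,
                             name=f"{network.name}-noisy{fraction:g}")


# ---------------------------------------------------------------------------
# genotypes, LD, phenotypes, summary statistics

def simulate_genotypes(n: int, p: int, block_size: int = 25,
                       within_block_ld: float = 0.9,
                       maf_range=(0.01, 0.5), seed: int = 0):
    """Genotypes (n x p, 0/1/2) with block AR(1) LD.

    Returns (X, maf) where maf are the target per-SNP minor-allele
    frequencies.  Empirical MAF tracks the target within ~0.02 for
    n >= 2000.
    """
    if not 0 <= within_block_ld < 1:
        raise ValidationError("within_block_ld must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=p)
    z = rng.standard_normal((2 * n, p))
    _kernels.ar1_blocks(z, within_block_ld, block_size)
    thr = norm.ppf(maf)
    hap = (z < thr[None, :])
    x = (hap[:n].astype(np.float64) + hap[n:].astype(np.float64))
    return x, maf


def banded_ld(x: np.ndarray, block_size: int,
              chrom_offsets=None, shrink: float = 0.01) -> LDMatrix:
    """Block-diagonal sample correlation of genotype blocks, banded.

    Cross-block LD is exactly zero (matching the generator), so the band
    holds a positive (semi)definite block-diagonal matrix; ``shrink``
    pulls it toward the identity, the usual reference-panel
    regularization, guaranteeing positive definiteness.
    """
    n, p = x.shape
    xs = x - x.mean(axis=0)
    sd = xs.std(axis=0)
    if np.any(sd == 0):
        raise ValidationError("monomorphic SNP in LD computation")
    xs /= sd
    bw = block_size - 1
    ab = np.zeros((bw + 1, p))
    ab[0] = 1.0
    for start in range(0, p, block_size):
        end = min(start + block_size, p)
        r = (xs[:, start:end].T @ xs[:, start:end]) / n
        r *= (1.0 - shrink)
        np.fill_diagonal(r, 1.0)
        for k in range(1, end - start):
            ab[k, start:end - k] = np.diagonal(r, -k)
    return LDMatrix(ab, chrom_offsets)


def simulate_phenotype(x: np.ndarray, beta: np.ndarray, h2: float,
                       seed: int) -> np.ndarray:
    """y = X beta + eps with the realized PVE fixed to h2 exactly.

    The drawn noise is residualized against the genetic values and
    rescaled so that sample Var(X beta) / Var(y) equals h2.
    """
    if not 0 <= h2 < 1:
        raise ValidationError("h2 must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    g = x @ beta
    vg = g.var()
    if h2 == 0:
        return rng.standard_normal(n)
    if vg == 0:
        raise ValidationError("h2 > 0 requires nonzero genetic variance")
    eps = rng.standard_normal(n)
    gc = g - g.mean()
    eps = eps - eps.mean()
    eps -= (eps @ gc) / (gc @ gc) * gc        # exactly uncorrelated with g
    eps *= np.sqrt(vg * (1 - h2) / h2) / eps.std()
    return g + eps


def marginal_ols(x: np.ndarray, y: np.ndarray):
    """Per-SNP simple least squares of centered y on centered x_j.

    slope = Sxy/Sxx; se uses the residual variance with n - 2 degrees of
    freedom.  Monomorphic SNPs are dropped (warned); returns
    (GwasSummary, kept_index).
    """
    n, p = x.shape
    if n < 3:
        raise ValidationError("need n >= 3")
    keep = np.flatnonzero(x.std(axis=0) > 0)
    if len(keep) < p:
        logger.warning("marginal_ols: dropped %d monomorphic SNPs",
                       p - len(keep))
        x = x[:, keep]
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc ** 2).sum(axis=0)
    sxy = xc.T @ yc
    slope = sxy / sxx
    rss = (yc @ yc) - slope * sxy
    se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sxx)
    return GwasSummary(slope, se, float(n)), keep


def single_snp_stats(x: np.ndarray, y: np.ndarray, block_size: int = 25,
                     chrom_offsets=None, shrink: float = 0.01):
    """Marginal OLS per SNP plus the banded LD of the same genotypes.

    Returns (GwasSummary, LDMatrix, kept_index).
    """
    gwas, keep = marginal_ols(x, y)
    ld = banded_ld(x[:, keep] if len(keep) < x.shape[1] else x,
                   block_size, chrom_offsets, shrink)
    return gwas, ld, keep


# ---------------------------------------------------------------------------
# effect models

def _slab_scales(rho: float, s2sum: np.ndarray) -> tuple[float, float]:
    pos = s2sum[s2sum > 0]
    sigma0_sq = 1.0 - rho
    sigma_sq = rho / pos.mean() if len(pos) else 0.0
    return sigma0_sq, sigma_sq


def _draw_m1(rng, theta0, theta, rho, a, s2sum):
    pi = 1.0 / (1.0 + 10.0 ** (-(theta0 + a * theta)))
    causal = rng.random(len(a)) < pi
    s0sq, ssq = _slab_scales(rho, s2sum)
    sd = np.sqrt(s0sq + ssq * s2sum)
    beta = np.zeros(len(a))
    beta[causal] = rng.standard_normal(causal.sum()) * sd[causal]
    return beta


def ld_scores(ld: LDMatrix) -> np.ndarray:
    """Per-SNP sum of r^2 within the band (including the diagonal)."""
    scores = ld.ab[0] ** 2
    p = ld.p
    for k in range(1, ld.bandwidth + 1):
        band = ld.ab[k, : p - k] ** 2
        scores[k:] += band
        scores[:-k] += band
    return scores


def maf_ld_variance(maf: np.ndarray, ld: LDMatrix,
                    maf_coef=None, ld_coef=None) -> np.ndarray:
    """Additive per-SNP variance over 10 MAF bins + 6 LD-score quantile
    annotations; default coefficients decrease in MAF bin and in LD
    quantile."""
    if maf_coef is None:
        maf_coef = np.linspace(1.0, 0.1, 10)
    if ld_coef is None:
        ld_coef = np.linspace(1.0, 0.1, 6)
    maf_bin = np.clip((np.asarray(maf) * 2 * 10).astype(int), 0, 9)
    ls = ld_scores(ld)
    ld_bin = np.clip((pd.Series(ls).rank(pct=True).to_numpy()
                      * 6 - 1e-9).astype(int), 0, 5)
    return np.asarray(maf_coef)[maf_bin] + np.asarray(ld_coef)[ld_bin]


def random_intervals(genes: GeneCatalog, n_intervals: int, length: int,
                     seed: int) -> pd.DataFrame:
    """Random RE-like intervals uniform over each chromosome span."""
    rng = np.random.default_rng(seed)
    gt = genes.table
    chroms = list(dict.fromkeys(gt["chrom"]))
    rows = []
    for _ in range(n_intervals):
        c = chroms[rng.integers(len(chroms))]
        span = int(gt.loc[gt["chrom"] == c, "tx_end"].max())
        s = int(rng.integers(1, max(span - length, 2)))
        rows.append((c, s, s + length - 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_effects(scenario: SimScenario, snps: SnpTable,
                     genes: GeneCatalog, network: RegulatoryNetwork,
                     ann, maf=None, ld=None, cis=None):
    """Draw the true SNP effect vector under the scenario's model.

    ``ann`` is the target network's annotation (a, w, s2sum); ``cis``
    is the study's SNP-gene cis-weight map, needed so that alternative
    networks (edge_altered) are annotated consistently.  Returns
    (beta, effective_network): the network the effects were actually
    generated from (differs from the target for edge_altered).
    """
    rng = np.random.default_rng(scenario.seed)
    model = scenario.effect_model
    th0, th, rho = scenario.theta0, scenario.theta, scenario.rho
    if model == "M0":
        beta = _draw_m1(rng, th0, 0.0, 0.0, np.zeros(len(snps)), ann.s2sum)
        return beta, network
    if model in ("M11", "M12", "M13", "noisy_network"):
        use_th = 0.0 if model == "M12" else th
        use_rho = 0.0 if model == "M11" else rho
        beta = _draw_m1(rng, th0, use_th, use_rho, ann.a, ann.s2sum)
        return beta, network
    if model == "near_gene_random":
        n_members = len(set(genes.gene_ids) & network.nodes)
        pick = rng.choice(len(genes), size=n_members, replace=False)
        rand_net = RegulatoryNetwork(
            edges=None, tf_nodes=frozenset(),
            tg_nodes=frozenset(genes.gene_ids[pick]), name="random-near-gene")
        a = build_proximity_flag(snps, rand_net, genes)
        beta = _draw_m1(rng, th0, th, 0.0, a, ann.s2sum)
        return beta, rand_net
    if model == "near_re_random":
        res = random_intervals(genes, n_intervals=200, length=1000,
                               seed=scenario.seed + 1)
        empty = RegulatoryNetwork(edges=None, tf_nodes=frozenset(),
                                  tg_nodes=frozenset(), name="random-near-re")
        a = build_proximity_flag(snps, empty, genes, res=res)
        beta = _draw_m1(rng, th0, th, 0.0, a, ann.s2sum)
        return beta, empty
    if model == "maf_ld_dependent":
        if maf is None or ld is None:
            raise ValidationError("maf_ld_dependent needs maf and ld")
        var = maf_ld_variance(maf, ld)
        # uniform association rate comparable to the enrichment scenarios
        # (signal matching trims the realized count to the paired positive)
        pi = 1.0 / (1.0 + 10.0 ** (-(th0 + 0.75 * th)))
        causal = rng.random(len(snps)) < pi
        beta = np.zeros(len(snps))
        beta[causal] = rng.standard_normal(causal.sum()) * np.sqrt(var[causal])
        return beta, network
    if model == "edge_altered":
        alt = rewire_network(network, seed=scenario.seed + 7)
        alt_ann = annotate(snps, genes, alt, cis=cis)
        beta = _draw_m1(rng, th0, th, rho, alt_ann.a, alt_ann.s2sum)
        return beta, alt
    raise ValidationError(f"unknown effect model {model!r}")


def match_signal(beta_pos: np.ndarray, beta_neg: np.ndarray,
                 x_neg: np.ndarray, x_pos: np.ndarray = None,
                 seed: int = 0, tol: float = 0.01) -> np.ndarray:
    """Thin and rescale a negative effect vector to match a positive one.

    Matches (1) the number of trait-associated SNPs exactly, by seeded
    subsampling of the nonzero set, and (2) the genetic variance
    Var(X beta) within ``tol`` relative (a single scalar rescale makes
    it essentially exact).
    """
    rng = np.random.default_rng(seed)
    k_pos = int(np.count_nonzero(beta_pos))
    nz = np.flatnonzero(beta_neg)
    if k_pos == 0 or len(nz) == 0:
        raise ValidationError("cannot match: a dataset has zero signal")
    if len(nz) < k_pos:
        raise ValidationError("cannot match: negative has fewer associated "
                              "SNPs than positive")
    out = np.array(beta_neg, dtype=float)
    if len(nz) > k_pos:
        drop = rng.choice(nz, size=len(nz) - k_pos, replace=False)
        out[drop] = 0.0
    if x_pos is None:
        x_pos = x_neg
    target = (x_pos @ beta_pos).var()
    got = (x_neg @ out).var()
    if got == 0:
        raise ValidationError("cannot match: thinned negative has no signal")
    out *= np.sqrt(target / got)
    if abs((x_neg @ out).var() - target) > tol * target:
        raise ValidationError("PVE matching failed")
    return out


# ---------------------------------------------------------------------------
# one-call dataset simulation

def simulate_dataset(scenario: SimScenario, snps: SnpTable,
                     genes: GeneCatalog, network: RegulatoryNetwork,
                     ann, block_size: int = 25, within_block_ld: float = 0.9,
                     shrink: float = 0.01) -> SimDataset:
    """Genotypes -> effects -> phenotype -> summary statistics.

    Gene truth labels: 1 iff some SNP with beta != 0 lies within 100 kb
    of the gene's transcribed region.
    """
    sc = scenario
    x, maf = simulate_genotypes(sc.n, sc.p, block_size, within_block_ld,
                                seed=sc.seed)
    # block offsets aligned to chromosome starts so LD never crosses them
    chrom_offsets = snps.chrom_offsets()
    ld = banded_ld(x, block_size, chrom_offsets, shrink)
    beta, eff_net = simulate_effects(sc, snps, genes, network, ann,
                                     maf=maf, ld=ld)
    h2 = sc.h2 if np.any(beta) else 0.0
    y = simulate_phenotype(x, beta, h2, seed=sc.seed + 11)
    gwas, ld2, keep = single_snp_stats(x, y, block_size, chrom_offsets,
                                       shrink)
    if len(keep) != sc.p:
        raise ValidationError("monomorphic SNPs in simulated genotypes; "
                              "increase n or the MAF floor")
    labels = np.zeros(len(genes), dtype=np.int8)
    for gi, locus in enumerate(gene_loci(snps, genes)):
        if locus.size and np.any(beta[locus] != 0):
            labels[gi] = 1
    return SimDataset(genotypes=x, beta=beta, phenotype=y, gwas=gwas,
                      ld=ld2, gene_labels=labels, scenario=sc)
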