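"""SNP-level network annotation.

Turns a TF->TG network plus a gene catalog and SNP-gene cis weights into
the quantities the network-induced prior consumes:

* ``a_j`` — 1 iff SNP j lies within 100 kb of any member gene's
  transcribed region (or any RE interval) of the network;
* ``G_j`` — the cis gene set: all genes whose transcribed region overlaps
  a 1 Mb window around SNP j;
* ``w_jg`` — combined SNP-gene weight,
  ``w_jt = c_jt * [t in G_j] + sum_{g in G_j, g TF} c_jg * v_gt``,
  so a SNP's total effect fans out through cis genes and, via TF edges,
  to distal target genes;
* ``s2sum_j = sum_g w_jg^2`` — the quadratic weight total entering the
  slab variance.

Windows are measured from transcribed-region boundaries, inclusive at
both ends.  When no cis-weight table is supplied, ``c_jg = 1`` for every
cis gene (a flat default, overridable by file).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import (CisWeightMap, GeneCatalog, NetworkAnnotation,
                        RegulatoryNetwork, SnpTable)

logger = logging.getLogger("rssnet")

CIS_WINDOW = 1_000_000
PROXIMITY_WINDOW = 100_000


def build_cis_window(snps: SnpTable, genes: GeneCatalog,
                     window: int = CIS_WINDOW) -> list[np.ndarray]:
    """Per-SNP cis gene sets G_j as arrays of catalog row indices.

    Gene g is in G_j iff its transcribed region overlaps
    ``[pos_j - window, pos_j + window]`` on the same chromosome.  SNPs on
    chromosomes absent from the catalog get an empty set (warned once).
    """
    gt = genes.table
    by_chrom = {c: idx.to_numpy() for c, idx in gt.groupby("chrom").groups.items()}
    starts = gt["tx_start"].to_numpy()
    ends = gt["tx_end"].to_numpy()
    out: list[np.ndarray] = []
    unknown = 0
    for chrom, pos in zip(snps.chrom, snps.pos):
        gidx = by_chrom.get(chrom)
        if gidx is None:
            unknown += 1
            out.append(np.empty(0, dtype=np.int64))
            continue
        hit = (starts[gidx] <= pos + window) & (ends[gidx] >= pos - window)
        out.append(gidx[hit])
    if unknown:
        logger.warning("build_cis_window: %d SNPs on chromosomes missing "
                       "from the catalog", unknown)
    return out


def _member_gene_rows(network: RegulatoryNetwork, genes: GeneCatalog):
    """Catalog rows of network member genes; logs dropped identifiers."""
    members = network.nodes
    gt = genes.table
    present = gt["gene_id"].isin(members)
    n_missing = len(members) - int(present.sum())
    if n_missing > 0:
        logger.warning("%d network genes absent from the catalog; dropped",
                       n_missing)
    return gt[present]


def build_proximity_flag(snps: SnpTable, network: RegulatoryNetwork,
                         genes: GeneCatalog, res: pd.DataFrame = None,
                         window: int = PROXIMITY_WINDOW) -> np.ndarray:
    """Binary a_j: SNP within ``window`` of any member gene or RE."""
    intervals: list[tuple[str, int, int]] = []
    mg = _member_gene_rows(network, genes)
    for chrom, s, e in zip(mg["chrom"], mg["tx_start"], mg["tx_end"]):
        intervals.append((chrom, s - window, e + window))
    if res is not None:
        for chrom, s, e in zip(res["chrom"], res["start"], res["end"]):
            intervals.append((chrom, s - window, e + window))
    a = np.zeros(len(snps), dtype=np.int8)
    if not intervals:
        return a
    iv = pd.DataFrame(intervals, columns=["chrom", "lo", "hi"])
    for chrom, grp in iv.groupby("chrom"):
        snp_sel = np.flatnonzero(snps.chrom == chrom)
        if snp_sel.size == 0:
            continue
        pos = snps.pos[snp_sel]
        lo = grp["lo"].to_numpy()[:, None]
        hi = grp["hi"].to_numpy()[:, None]
        a[snp_sel[np.any((pos >= lo) & (pos <= hi), axis=0)]] = 1
    return a


def build_annotation(network: RegulatoryNetwork,
                     cis_sets: list[np.ndarray],
                     genes: GeneCatalog,
                     snps: SnpTable,
                     cis: CisWeightMap = None,
                     a: np.ndarray = None) -> NetworkAnnotation:
    """Assemble w_jg, O_j and s2sum_j from the network and cis sets.

    ``cis_sets`` are the G_j index arrays from :func:`build_cis_window`.
    Missing cis entries default to ``c_jg = 1``.  The proximity flag
    ``a`` may be passed in; otherwise it is computed with the default
    100 kb window and no REs.
    """
    p = len(snps)
    gene_ids = genes.gene_ids
    gene_col = {g: i for i, g in enumerate(gene_ids)}
    cis_lookup = cis.lookup() if cis is not None else None
    snp_ids = snps.snp_ids

    # per-TF target columns and weights, restricted to catalog genes
    tf_targets: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tf, grp in network.edges.groupby("tf"):
        cols, ws = [], []
        for tg, v in zip(grp["tg"], grp["weight"]):
            ci = gene_col.get(tg)
            if ci is not None and v > 0:
                cols.append(ci)
                ws.append(v)
        tf_targets[tf] = (np.asarray(cols, dtype=np.int64),
                          np.asarray(ws, dtype=float))
    is_tf_gene = np.array([g in network.tf_nodes for g in gene_ids])

    rows, cols, vals = [], [], []
    for j in range(p):
        acc: dict[int, float] = {}
        gj = cis_sets[j]
        for gi in gj:
            gid = gene_ids[gi]
            if cis_lookup is None:
                c = 1.0
            else:
                c = float(cis_lookup.get((snp_ids[j], gid), 1.0))
            if c == 0.0:
                continue
            acc[gi] = acc.get(gi, 0.0) + c
            if is_tf_gene[gi]:
                tcols, tws = tf_targets.get(gid, (None, None))
                if tcols is not None:
                    for ci, v in zip(tcols, tws):
                        acc[ci] = acc.get(ci, 0.0) + c * v
        for ci, w in acc.items():
            if w > 0:
                rows.append(j)
                cols.append(ci)
                vals.append(w)
    w = sp.csr_matrix((vals, (rows, cols)), shape=(p, len(gene_ids)))
    if a is None:
        a = build_proximity_flag(snps, network, genes)
    return NetworkAnnotation(a=a, w=w, gene_ids=gene_ids)


def distance_decay_cis(snps: SnpTable, genes: GeneCatalog,
                       cis_sets: list[np.ndarray] = None,
                       scale: float = 150_000.0) -> CisWeightMap:
    """Exponential distance-decay cis weights, an eQTL-like default.

    ``c_jg = exp(-d/scale)`` with d the distance from the SNP to the
    gene's transcribed region (0 inside the gene).  Mirrors the rapid
    decay of cis-eQTL effects with distance, concentrating each SNP's
    cis weight on its nearest genes instead of spreading it flat over
    the whole 1 Mb window.
    """
    if cis_sets is None:
        cis_sets = build_cis_window(snps, genes)
    gt = genes.table
    starts = gt["tx_start"].to_numpy()
    ends = gt["tx_end"].to_numpy()
    gene_ids = genes.gene_ids
    snp_ids = snps.snp_ids
    pos = snps.pos
    rows = []
    for j, gidx in enumerate(cis_sets):
        for gi in gidx:
            if starts[gi] <= pos[j] <= ends[gi]:
                d = 0
            else:
                d = min(abs(pos[j] - starts[gi]), abs(pos[j] - ends[gi]))
            rows.append((snp_ids[j], gene_ids[gi], np.exp(-d / scale)))
    return CisWeightMap(pd.DataFrame(rows,
                                     columns=["snp_id", "gene_id", "c"]))


def near_gene_control(genes: GeneCatalog) -> RegulatoryNetwork:
    """Control network: every catalog gene a node, no edges.

    Its Bayes factor serves as the adaptive enrichment threshold for a
    given GWAS — it captures generic near-gene enrichment without any
    topology.
    """
    return RegulatoryNetwork(edges=None, tf_nodes=frozenset(),
                             tg_nodes=frozenset(genes.gene_ids),
                             name="near-gene-control")


def annotate(snps: SnpTable, genes: GeneCatalog, network: RegulatoryNetwork,
             cis: CisWeightMap = None, res: pd.DataFrame = None,
             cis_window: int = CIS_WINDOW,
             proximity_window: int = PROXIMITY_WINDOW) -> NetworkAnnotation:
    """One-call annotation: cis windows + proximity flag + weights."""
    cis_sets = build_cis_window(snps, genes, cis_window)
    a = build_proximity_flag(snps, network, genes, res, proximity_window)
    return build_annotation(network, cis_sets, genes, snps, cis=cis, a=a)
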