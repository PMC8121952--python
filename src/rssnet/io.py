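"""Readers and writers for all external file formats.

Formats (all plain text except LD and fits, which use HDF5):

* GWAS summary statistics: TSV with header
  ``snp_id chr pos a1 a2 betahat se n``.
* Gene catalog: BED (0-based half-open; converted to 1-based inclusive on
  load) plus an optional auxiliary TSV flagging TFs.
* Network: TSV edge list ``tf_id tg_id weight``.
* Cis weights: TSV ``snp_id gene_id c``.  RE intervals: BED.
* LD: HDF5, one banded dataset per chromosome, attribute ``bandwidth``.
* Annotation export: TSV ``snp_id a s2sum`` plus sparse TSV
  ``snp_id gene_id w``.

Every reader/writer pair is a lossless round trip at declared precision,
and loading is order-independent (inputs are sorted internally).
"""

from __future__ import annotations

import logging

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import (CisWeightMap, FormatError, GeneCatalog, GwasSummary,
                        LDMatrix, NetworkAnnotation, RegulatoryNetwork,
                        SnpTable, ValidationError, VariationalFit)

logger = logging.getLogger("rssnet")

GWAS_COLUMNS = ["snp_id", "chr", "pos", "a1", "a2", "betahat", "se", "n"]


def read_gwas_summary(path):
    """Load GWAS summary statistics.

    Rows with missing fields or se <= 0 are dropped (count logged and
    returned).  Returns ``(GwasSummary, SnpTable, n_dropped)``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chr": str},
                     float_precision="round_trip")
    missing = set(GWAS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"GWAS file missing columns: {sorted(missing)}")
    n_in = len(df)
    df = df.dropna(subset=GWAS_COLUMNS)
    df = df[pd.to_numeric(df["se"], errors="coerce") > 0]
    n_dropped = n_in - len(df)
    if n_dropped:
        logger.warning("read_gwas_summary: dropped %d invalid rows", n_dropped)
    if df["snp_id"].duplicated().any():
        raise ValidationError("duplicate snp_id in GWAS file")
    df = df.sort_values(["chr", "pos"], kind="mergesort").reset_index(drop=True)
    snps = SnpTable(df.rename(columns={"chr": "chrom"})[
        ["snp_id", "chrom", "pos", "a1", "a2"]].copy())
    gwas = GwasSummary(df["betahat"].to_numpy(float),
                       df["se"].to_numpy(float),
                       df["n"].to_numpy(float))
    return gwas, snps, n_dropped


def write_gwas_summary(path, gwas: GwasSummary, snps: SnpTable) -> None:
    t = snps.table
    out = pd.DataFrame({
        "snp_id": t["snp_id"], "chr": t["chrom"], "pos": t["pos"],
        "a1": t["a1"], "a2": t["a2"],
        "betahat": gwas.betahat, "se": gwas.se, "n": gwas.n,
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_catalog(bed_path, tf_flag_path=None) -> GeneCatalog:
    """Load a gene catalog from BED; optional TSV listing TF gene ids.

    BED chromStart/chromEnd (0-based half-open) become 1-based inclusive
    tx_start/tx_end.
    """
    bed = pd.read_csv(bed_path, sep="\t", header=None, comment="#",
                      dtype={0: str})
    if bed.shape[1] < 4:
        raise FormatError("gene catalog BED needs >= 4 columns (incl. name)")
    tf_ids = set()
    if tf_flag_path is not None:
        aux = pd.read_csv(tf_flag_path, sep="\t")
        if "gene_id" not in aux.columns:
            raise FormatError("TF flag file needs a gene_id column")
        if "is_tf" in aux.columns:
            tf_ids = set(aux.loc[aux["is_tf"].astype(bool), "gene_id"])
        else:
            tf_ids = set(aux["gene_id"])
    table = pd.DataFrame({
        "gene_id": bed[3].astype(str),
        "chrom": bed[0],
        "tx_start": bed[1].astype(np.int64) + 1,
        "tx_end": bed[2].astype(np.int64),
        "is_tf": bed[3].astype(str).isin(tf_ids),
    })
    return GeneCatalog(table)


def write_gene_catalog(bed_path, catalog: GeneCatalog, tf_flag_path=None):
    t = catalog.table
    bed = pd.DataFrame({
        0: t["chrom"], 1: t["tx_start"] - 1, 2: t["tx_end"],
        3: t["gene_id"], 4: 0, 5: "+",
    })
    bed.to_csv(bed_path, sep="\t", index=False, header=False)
    if tf_flag_path is not None:
        t[["gene_id", "is_tf"]].to_csv(tf_flag_path, sep="\t", index=False)


def read_network(path, name=None) -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"tf_id": str, "tg_id": str})
    missing = {"tf_id", "tg_id", "weight"} - set(df.columns)
    if missing:
        raise FormatError(f"network file missing columns: {sorted(missing)}")
    edges = df.rename(columns={"tf_id": "tf", "tg_id": "tg"})
    edges = edges.sort_values(["tf", "tg"], kind="mergesort").reset_index(drop=True)
    return RegulatoryNetwork(edges[["tf", "tg", "weight"]],
                             name=name or str(path))


def write_network(path, network: RegulatoryNetwork) -> None:
    out = network.edges.rename(columns={"tf": "tf_id", "tg": "tg_id"})
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_cis_weights(path) -> CisWeightMap:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene_id": str})
    missing = {"snp_id", "gene_id", "c"} - set(df.columns)
    if missing:
        raise FormatError(f"cis weight file missing columns: {sorted(missing)}")
    return CisWeightMap(df)


def read_intervals_bed(path) -> pd.DataFrame:
    """RE intervals from BED -> DataFrame(chrom, start, end), 1-based."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    return pd.DataFrame({"chrom": bed[0],
                         "start": bed[1].astype(np.int64) + 1,
                         "end": bed[2].astype(np.int64)})


def read_ld(path) -> LDMatrix:
    """Load banded LD from HDF5 (datasets chr_<i>, attr ``bandwidth``).

    Chromosome datasets are concatenated in lexicographic label order;
    entries outside the band are exactly zero.  Diagonal entries must be
    1 within 1e-6.
    """
    with h5py.File(path, "r") as f:
        if "bandwidth" not in f.attrs:
            raise FormatError("LD container missing 'bandwidth' attribute")
        bw = int(f.attrs["bandwidth"])
        names = sorted(f.keys())
        if not names:
            raise FormatError("LD container has no chromosome datasets")
        blocks, offsets = [], [0]
        for name in names:
            ab = np.asarray(f[name])
            if ab.shape[0] != bw + 1:
                raise FormatError(
                    f"dataset {name}: expected {bw + 1} band rows")
            blocks.append(ab)
            offsets.append(offsets[-1] + ab.shape[1])
    return LDMatrix(np.concatenate(blocks, axis=1), np.asarray(offsets))


def write_ld(path, ld: LDMatrix, chrom_labels=None) -> None:
    offs = ld.chrom_offsets
    n_chr = len(offs) - 1
    if chrom_labels is None:
        chrom_labels = [f"chr_{i:03d}" for i in range(n_chr)]
    with h5py.File(path, "w") as f:
        f.attrs["bandwidth"] = ld.bandwidth
        for i in range(n_chr):
            f.create_dataset(str(chrom_labels[i]),
                             data=ld.ab[:, offs[i]:offs[i + 1]])


def write_annotation(prefix, snps: SnpTable, ann: NetworkAnnotation) -> None:
    """Write ``<prefix>.snp.tsv`` (snp_id, a, s2sum) and ``<prefix>.w.tsv``."""
    pd.DataFrame({"snp_id": snps.snp_ids, "a": ann.a, "s2sum": ann.s2sum}
                 ).to_csv(f"{prefix}.snp.tsv", sep="\t", index=False,
                          float_format="%.17g")
    coo = ann.w.tocoo()
    pd.DataFrame({"snp_id": snps.snp_ids[coo.row],
                  "gene_id": ann.gene_ids[coo.col],
                  "w": coo.data}
                 ).to_csv(f"{prefix}.w.tsv", sep="\t", index=False,
                          float_format="%.17g")


def write_fits(path, fits: list[VariationalFit]) -> None:
    """Export grid fits to HDF5 (per-point alpha/nu/tau plus metadata)."""
    with h5py.File(path, "w") as f:
        for name in ("theta0", "theta", "eta", "rho", "elbo"):
            f.create_dataset(name,
                             data=[getattr(fit, name) for fit in fits])
        f.create_dataset("n_iter", data=[fit.n_iter for fit in fits])
        f.create_dataset("converged",
                         data=[fit.converged for fit in fits])
        for arr in ("alpha", "nu", "tau"):
            f.create_dataset(arr,
                             data=np.stack([getattr(fit, arr) for fit in fits]))


def read_fits(path) -> list[VariationalFit]:
    with h5py.File(path, "r") as f:
        n = len(f["elbo"])
        return [VariationalFit(
            alpha=np.asarray(f["alpha"][h]), nu=np.asarray(f["nu"][h]),
            tau=np.asarray(f["tau"][h]), elbo=float(f["elbo"][h]),
            n_iter=int(f["n_iter"][h]), converged=bool(f["converged"][h]),
            theta0=float(f["theta0"][h]), theta=float(f["theta"][h]),
            eta=float(f["eta"][h]), rho=float(f["rho"][h]),
        ) for h in range(n)]


def network_summary_stats(paths) -> dict:
    """Descriptive statistics over a collection of network edge-list files.

    Returns mean TF count, mean TG count and mean edge count across the
    supplied files (e.g. a directory of released context-specific
    networks).
    """
    paths = list(paths)
    if not paths:
        raise ValidationError("no network files supplied")
    n_tf, n_tg, n_edge = [], [], []
    for p in paths:
        net = read_network(p)
        n_tf.append(len(net.tf_nodes))
        n_tg.append(len(net.tg_nodes))
        n_edge.append(net.n_edges)
    return {"n_networks": len(paths),
            "mean_tf_count": float(np.mean(n_tf)),
            "mean_tg_count": float(np.mean(n_tg)),
            "mean_edge_count": float(np.mean(n_edge))}
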