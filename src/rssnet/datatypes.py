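"""Shared domain types.

Coordinate convention: all genomic coordinates are 1-based inclusive
internally.  BED input (0-based half-open) is converted on load.  Window
arithmetic everywhere (cis windows, proximity flags, gene loci) uses the
transcribed-region boundaries, inclusive at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class FormatError(ValueError):
    """Malformed input file (missing columns, bad container layout)."""


class ValidationError(ValueError):
    """Well-formed input with invalid content (duplicates, out-of-range)."""


@dataclass
class GeneCatalog:
    """Protein-coding gene catalog: one row per gene.

    ``table`` columns: gene_id (unique), chrom, tx_start, tx_end
    (1-based inclusive), is_tf (bool).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "tx_start", "tx_end", "is_tf"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"gene catalog missing columns: {sorted(missing)}")
        t = self.table
        if t["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id in catalog")
        if ((t["tx_start"] >= t["tx_end"]) | (t["tx_start"] < 0)).any():
            raise ValidationError("require 0 <= tx_start < tx_end")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.table["gene_id"].to_numpy()

    def subset(self, gene_ids) -> "GeneCatalog":
        keep = self.table["gene_id"].isin(set(gene_ids))
        return GeneCatalog(self.table[keep].reset_index(drop=True))


@dataclass
class SnpTable:
    """SNP positions, sorted by (chrom, pos) on load.

    ``table`` columns: snp_id (unique), chrom, pos (1-based), a1, a2.
    Alleles are carried for provenance but never used in computation;
    summary statistics are assumed pre-harmonized to the LD panel.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos", "a1", "a2"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"SNP table missing columns: {sorted(missing)}")
        if self.table["snp_id"].duplicated().any():
            raise ValidationError("duplicate snp_id")
        t = self.table.sort_values(["chrom", "pos"], kind="mergesort")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    def chrom_offsets(self) -> np.ndarray:
        """Start index of each chromosome run, plus terminal len(self)."""
        c = self.table["chrom"].to_numpy()
        starts = np.flatnonzero(np.r_[True, c[1:] != c[:-1]])
        return np.r_[starts, len(c)]


@dataclass
class GwasSummary:
    """Single-SNP association statistics aligned with a SnpTable.

    betahat: marginal effect estimates (trait units per allele);
    se: standard errors, strictly positive; n: per-SNP sample size.
    """

    betahat: np.ndarray
    se: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.betahat = np.asarray(self.betahat, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n = np.atleast_1d(np.asarray(self.n, dtype=float))
        if self.n.size == 1:
            self.n = np.full_like(self.betahat, float(self.n[0]))
        if not (len(self.betahat) == len(self.se) == len(self.n)):
            raise ValidationError("betahat, se, n length mismatch")
        if np.any(self.se <= 0) or not np.all(np.isfinite(self.se)):
            raise ValidationError("standard errors must be finite and > 0")

    def __len__(self) -> int:
        return len(self.betahat)


@dataclass
class LDMatrix:
    """Banded symmetric LD correlation matrix, unit diagonal.

    ``ab`` is scipy's diagonal-ordered lower-banded storage:
    ``ab[k, j] = R[j + k, j]`` for k = 0..bandwidth.  Cross-chromosome
    entries are exactly zero; ``chrom_offsets`` marks chromosome starts
    (with a terminal p) so construction can enforce that.
    """

    ab: np.ndarray
    chrom_offsets: np.ndarray = None

    def __post_init__(self) -> None:
        self.ab = np.asarray(self.ab, dtype=float)
        if self.ab.ndim != 2:
            raise FormatError("banded storage must be 2-D")
        p = self.ab.shape[1]
        if self.chrom_offsets is None:
            self.chrom_offsets = np.array([0, p])
        self.chrom_offsets = np.asarray(self.chrom_offsets, dtype=np.int64)
        if np.any(np.abs(self.ab[0] - 1.0) > 1e-6):
            raise ValidationError("LD diagonal must equal 1")
        self.ab[0] = 1.0
        if np.any(np.abs(self.ab) > 1.0 + 1e-12):
            raise ValidationError("LD entries must lie in [-1, 1]")
        # zero out entries that would fall outside the matrix or cross a
        # chromosome boundary
        for k in range(1, self.bandwidth + 1):
            if k <= p:
                self.ab[k, p - k:] = 0.0
            for b in self.chrom_offsets[1:-1]:
                lo = max(b - k, 0)
                self.ab[k, lo:b] = 0.0

    @property
    def bandwidth(self) -> int:
        return self.ab.shape[0] - 1

    @property
    def p(self) -> int:
        return self.ab.shape[1]

    def to_dense(self) -> np.ndarray:
        p = self.p
        r = np.zeros((p, p))
        for k in range(self.bandwidth + 1):
            for j in range(p - k):
                r[j + k, j] = self.ab[k, j]
                r[j, j + k] = self.ab[k, j]
        return r

    @classmethod
    def from_dense(cls, r: np.ndarray, bandwidth: int,
                   chrom_offsets=None) -> "LDMatrix":
        r = np.asarray(r, dtype=float)
        p = r.shape[0]
        ab = np.zeros((bandwidth + 1, p))
        for k in range(bandwidth + 1):
            ab[k, : p - k] = np.diagonal(r, -k)
        return cls(ab, chrom_offsets)

    @classmethod
    def identity(cls, p: int) -> "LDMatrix":
        return cls(np.ones((1, p)))

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """R @ x via the band."""
        y = self.ab[0] * x
        for k in range(1, self.bandwidth + 1):
            band = self.ab[k, : self.p - k]
            y[k:] += band * x[:-k]
            y[:-k] += band * x[k:]
        return y


@dataclass
class RegulatoryNetwork:
    """Weighted directed bipartite TF -> TG graph.

    ``edges`` columns: tf, tg, weight in (0, 1].  ``tf_nodes`` /
    ``tg_nodes`` may include isolated nodes (e.g. the near-gene control
    network, which has all genes as nodes and no edges).
    """

    edges: pd.DataFrame
    tf_nodes: frozenset = None
    tg_nodes: frozenset = None
    name: str = "network"

    def __post_init__(self) -> None:
        required = {"tf", "tg", "weight"}
        if self.edges is None or len(self.edges) == 0:
            self.edges = pd.DataFrame(columns=["tf", "tg", "weight"])
        missing = required - set(self.edges.columns)
        if missing:
            raise FormatError(f"edge list missing columns: {sorted(missing)}")
        w = self.edges["weight"].to_numpy(dtype=float)
        if len(w) and (np.any(w < 0) or np.any(w > 1)):
            raise ValidationError("edge weights must lie in [0, 1]")
        if self.tf_nodes is None:
            self.tf_nodes = frozenset(self.edges["tf"])
        else:
            self.tf_nodes = frozenset(self.tf_nodes)
        if self.tg_nodes is None:
            self.tg_nodes = frozenset(self.edges["tg"])
        else:
            self.tg_nodes = frozenset(self.tg_nodes)
        if not set(self.edges["tf"]) <= self.tf_nodes:
            raise ValidationError("edge TF not in TF node set")
        if not set(self.edges["tg"]) <= self.tg_nodes:
            raise ValidationError("edge TG not in TG node set")

    @property
    def nodes(self) -> frozenset:
        return self.tf_nodes | self.tg_nodes

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets_of(self, tf: str) -> dict:
        """T_g with weights: {tg: v_gt}. Empty for a non-TF gene."""
        sub = self.edges[self.edges["tf"] == tf]
        return dict(zip(sub["tg"], sub["weight"]))


@dataclass
class CisWeightMap:
    """Sparse (snp_id, gene_id) -> c_jg >= 0, restricted to cis pairs."""

    table: pd.DataFrame  # columns snp_id, gene_id, c

    def __post_init__(self) -> None:
        required = {"snp_id", "gene_id", "c"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"cis weight table missing: {sorted(missing)}")
        if (self.table["c"].to_numpy(dtype=float) < 0).any():
            raise ValidationError("cis weights must be non-negative")

    def lookup(self) -> dict:
        return {(r.snp_id, r.gene_id): r.c for r in self.table.itertuples()}


@dataclass
class NetworkAnnotation:
    """Per-SNP network annotation consumed by the prior.

    a: binary proximity flags (SNP within 100 kb of a member gene/RE);
    w: sparse (p x n_genes) matrix of combined SNP-gene weights w_jg;
    gene_ids: column labels of w; s2sum: row sums of w_jg^2.
    """

    a: np.ndarray
    w: sp.csr_matrix
    gene_ids: np.ndarray
    s2sum: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int8)
        if not np.all((self.a == 0) | (self.a == 1)):
            raise ValidationError("a_j must be binary")
        if self.w.min() < 0:
            raise ValidationError("w_jg must be non-negative")
        s2 = np.asarray(self.w.multiply(self.w).sum(axis=1)).ravel()
        if self.s2sum is None:
            self.s2sum = s2
        elif not np.allclose(self.s2sum, s2, atol=1e-12):
            raise ValidationError("s2sum inconsistent with w")

    @property
    def p(self) -> int:
        return len(self.a)

    def contributing_genes(self, j: int) -> set:
        """O_j: genes with w_jg > 0."""
        row = self.w.getrow(j)
        return {self.gene_ids[i] for i, v in zip(row.indices, row.data) if v > 0}


@dataclass
class HyperGrid:
    """Hyper-parameter grid with enrichment-pattern labels.

    ``points`` columns: theta0, theta, eta, rho, label where label is one
    of M0 (theta=0, rho=0), M11 (theta>0, rho=0), M12 (theta=0, rho>0),
    M13 (theta>0, rho>0); M1 is the union of M11/M12/M13.
    """

    points: pd.DataFrame

    LABELS = ("M0", "M11", "M12", "M13")

    def __post_init__(self) -> None:
        pts = self.points
        required = {"theta0", "theta", "eta", "rho"}
        missing = required - set(pts.columns)
        if missing:
            raise FormatError(f"grid missing columns: {sorted(missing)}")
        if np.any((pts["eta"] < 0) | (pts["eta"] > 1)):
            raise ValidationError("eta must lie in [0, 1]")
        if np.any((pts["rho"] < 0) | (pts["rho"] > 1)):
            raise ValidationError("rho must lie in [0, 1]")
        if np.any(pts["theta"] < 0):
            raise ValidationError("theta must be >= 0")
        lab = np.where(
            pts["theta"] > 0,
            np.where(pts["rho"] > 0, "M13", "M11"),
            np.where(pts["rho"] > 0, "M12", "M0"),
        )
        pts = pts.assign(label=lab).reset_index(drop=True)
        self.points = pts

    @classmethod
    def from_lists(cls, theta0, theta, eta, rho) -> "HyperGrid":
        grids = np.meshgrid(theta0, theta, eta, rho, indexing="ij")
        return cls(pd.DataFrame({
            "theta0": grids[0].ravel(), "theta": grids[1].ravel(),
            "eta": grids[2].ravel(), "rho": grids[3].ravel(),
        }))

    @classmethod
    def default(cls) -> "HyperGrid":
        """Spans 1-per-1e6 to 1-per-1e2 associated SNPs."""
        return cls.from_lists(
            theta0=np.arange(-6.0, -1.99, 0.5),
            theta=np.arange(0.0, 3.01, 0.3),
            eta=[0.05, 0.1, 0.2, 0.3, 0.5],
            rho=[0.0, 0.1, 0.3, 0.5, 0.7, 0.9],
        )

    @classmethod
    def compact(cls) -> "HyperGrid":
        """Coarse grid for desk-scale simulation studies."""
        return cls.from_lists(
            theta0=[-4.0, -3.0, -2.0],
            theta=[0.0, 1.5, 3.0],
            eta=[0.1, 0.3, 0.5],
            rho=[0.0, 0.5, 0.9],
        )

    def subgrid_index(self, label: str) -> np.ndarray:
        if label == "M1":
            return np.flatnonzero(self.points["label"] != "M0")
        if label not in self.LABELS:
            raise ValueError(f"unknown subgrid label {label!r}")
        return np.flatnonzero(self.points["label"] == label)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class VariationalFit:
    """Mean-field posterior at one hyper-grid point.

    q(beta) = prod_j [alpha_j N(nu_j, tau_j^2) + (1 - alpha_j) delta_0].
    """

    alpha: np.ndarray
    nu: np.ndarray
    tau: np.ndarray
    elbo: float
    n_iter: int
    converged: bool
    theta0: float = np.nan
    theta: float = np.nan
    eta: float = np.nan
    rho: float = np.nan
    elbo_trace: list = field(default_factory=list)


@dataclass
class EnrichmentResult:
    """Network-level Bayes factors against the baseline model M0."""

    network: str
    log10_bf: float                # M1 vs M0
    log10_bf_m11: float
    log10_bf_m12: float
    log10_bf_m13: float
    log_evidence: dict             # label -> natural-log evidence
    control_log10_bf: float = np.nan
    passes_control: bool = None

    def __post_init__(self) -> None:
        restricted = {"M11": self.log10_bf_m11, "M12": self.log10_bf_m12,
                      "M13": self.log10_bf_m13}
        self.best_pattern = max(restricted, key=restricted.get)
        if self.passes_control is None and np.isfinite(self.control_log10_bf):
            self.passes_control = bool(self.log10_bf > self.control_log10_bf)


@dataclass
class LocusResult:
    """Gene-level posterior association probabilities."""

    gene_id: str
    snp_index: np.ndarray
    p1_base: float = np.nan
    p1_near: float = np.nan
    p1_net: dict = field(default_factory=dict)
    p1_bma: float = np.nan


@dataclass
class SimScenario:
    """One simulation condition: effect model plus its knobs."""

    effect_model: str              # M0 | M11 | M12 | M13 | near_gene_random |
                                   # near_re_random | maf_ld_dependent |
                                   # edge_altered | noisy_network
    architecture: str = "sparse"   # sparse | polygenic
    theta0: float = None
    theta: float = 2.0
    rho: float = 0.5
    h2: float = 0.3
    n: int = 5000
    p: int = 5000
    edge_noise_fraction: float = 0.0
    seed: int = None

    MODELS = ("M0", "M11", "M12", "M13", "near_gene_random",
              "near_re_random", "maf_ld_dependent", "edge_altered",
              "noisy_network")

    def __post_init__(self) -> None:
        if self.effect_model not in self.MODELS:
            raise ValueError(f"unknown effect model {self.effect_model!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.theta0 is None:
            self.theta0 = -3.5 if self.architecture == "sparse" else -2.0


@dataclass
class SimDataset:
    """A simulated GWAS with its ground truth."""

    genotypes: np.ndarray          # n x p allele counts 0/1/2
    beta: np.ndarray               # true SNP effects
    phenotype: np.ndarray
    gwas: GwasSummary = None
    ld: LDMatrix = None
    gene_labels: np.ndarray = None  # 1 iff a causal SNP within 100 kb of gene
    scenario: SimScenario = None
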