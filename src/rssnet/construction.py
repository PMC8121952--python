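"""Context-specific network construction and comparison.

A context-specific TF->TG edge is scored by a trans-regulation score
combining four ingredients measured in one cell type or tissue:

    TRS_gt = 2^|R_gt| * sqrt(TF~_g * TG~_t) * sum_i (RE~_i * B_gi * I_it)

where R_gt is the cross-context expression correlation of TF g and TG t,
the tilde quantities are context-normalized levels (y~ = y^2 / y_med,
y_med the cross-context median), B_gi the motif binding strength of TF g
on regulatory element i, and I_it the regulating strength of RE i on
TG t (both supplied as inputs from upstream peak calling / motif scanning
/ omnibus regression, which are out of scope here).  A larger TRS means
stronger context-specific regulation, so TRS naturally ranks candidate
edges; (0, 1]-scale edge weights are set by
log2(1 + TRS) / max log2(1 + TRS).

External (CAGE-style) networks are harmonized by rescaling their weights
with min{1, x^(1/6)} and selecting top-ranked edges to match a target
edge count.  Networks are compared by Jaccard indices of node and edge
sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import RegulatoryNetwork, ValidationError


class UndefinedFeatureError(ValueError):
    """A feature's cross-context median is non-positive."""


@dataclass
class PecaContextData:
    """Inputs for TRS scoring in one context.

    corr: DataFrame (TF x TG) of cross-context expression correlations
    in [-1, 1]; *_level / *_median: Series of non-negative context levels
    and strictly positive cross-context medians; binding: DataFrame
    (TF x RE) of motif binding strengths B_gi; regulating: DataFrame
    (RE x TG) of RE-to-TG regulating strengths I_it.
    """

    corr: pd.DataFrame
    tf_level: pd.Series
    tf_median: pd.Series
    tg_level: pd.Series
    tg_median: pd.Series
    re_level: pd.Series
    re_median: pd.Series
    binding: pd.DataFrame
    regulating: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.corr.abs() > 1 + 1e-12).any().any():
            raise ValidationError("|R_gt| must be <= 1")
        for name in ("tf_level", "tg_level", "re_level"):
            if (getattr(self, name) < 0).any():
                raise ValidationError(f"{name} must be non-negative")
        if (self.binding < 0).any().any() or (self.regulating < 0).any().any():
            raise ValidationError("B_gi and I_it must be non-negative")


def normalize_context_level(y: float, y_med: float) -> float:
    """y~ = y^2 / y_med; amplifies levels above the cross-context median."""
    if y_med <= 0:
        raise UndefinedFeatureError("cross-context median must be > 0")
    return y * y / y_med


def trans_regulation_score(data: PecaContextData, g: str, t: str) -> float:
    """TRS for TF g and TG t in the given context (non-negative)."""
    r = abs(float(data.corr.loc[g, t]))
    ytf = normalize_context_level(float(data.tf_level[g]),
                                  float(data.tf_median[g]))
    ytg = normalize_context_level(float(data.tg_level[t]),
                                  float(data.tg_median[t]))
    res = data.binding.columns.intersection(data.regulating.index)
    total = 0.0
    for i in res:
        b = float(data.binding.loc[g, i])
        s = float(data.regulating.loc[i, t])
        if b > 0 and s > 0:
            yre = normalize_context_level(float(data.re_level[i]),
                                          float(data.re_median[i]))
            total += yre * b * s
    return (2.0 ** r) * np.sqrt(ytf * ytg) * total


def score_to_weight(trs: pd.Series) -> pd.Series:
    """Map TRS values to (0, 1] edge weights; zero-TRS candidates drop.

    weight = log2(1 + TRS) / max log2(1 + TRS); monotone in TRS and
    invariant in rank to any common positive rescaling of TRS.
    """
    trs = trs.astype(float)
    if (trs < 0).any():
        raise ValidationError("TRS values must be non-negative")
    pos = trs[trs > 0]
    if len(pos) == 0:
        raise ValidationError("all TRS values are zero: empty network")
    lw = np.log2(1.0 + pos)
    return lw / lw.max()


def rescale_external_weight(x):
    """Harmonize an external edge weight: min{1, x^(1/6)}."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValidationError("edge weights must be non-negative")
    return np.minimum(1.0, x ** (1.0 / 6.0))


def build_context_network(data: PecaContextData, candidates=None,
                          name: str = "context") -> RegulatoryNetwork:
    """Score candidate (TF, TG) pairs by TRS and weight the positives.

    ``candidates``: iterable of (tf, tg) pairs; defaults to all TF x TG
    pairs in ``data``.
    """
    if candidates is None:
        candidates = [(g, t) for g in data.corr.index for t in data.corr.columns]
    idx = pd.MultiIndex.from_tuples(candidates, names=["tf", "tg"])
    trs = pd.Series([trans_regulation_score(data, g, t) for g, t in candidates],
                    index=idx)
    w = score_to_weight(trs)
    edges = w.rename("weight").reset_index()
    edges = edges.sort_values(["tf", "tg"], kind="mergesort").reset_index(drop=True)
    return RegulatoryNetwork(edges, name=name)


def select_top_edges(candidates: pd.DataFrame, k: int,
                     name: str = "top-k") -> RegulatoryNetwork:
    """Keep the K largest-weight edges; cutoff ties break by (tf, tg).

    ``candidates`` columns: tf, tg, weight.
    """
    if k > len(candidates):
        raise ValidationError(f"K={k} exceeds {len(candidates)} candidates")
    ranked = candidates.sort_values(["weight", "tf", "tg"],
                                    ascending=[False, True, True],
                                    kind="mergesort")
    kept = ranked.head(k).sort_values(["tf", "tg"], kind="mergesort")
    return RegulatoryNetwork(kept.reset_index(drop=True), name=name)


def network_similarity(a: RegulatoryNetwork,
                       b: RegulatoryNetwork) -> tuple[float, float]:
    """(node Jaccard, edge Jaccard) between two networks.

    Node sets are TF union TG; edge sets compare unweighted (tf, tg)
    pairs.  An empty union on both axes is undefined.
    """
    na, nb = a.nodes, b.nodes
    ea = set(zip(a.edges["tf"], a.edges["tg"]))
    eb = set(zip(b.edges["tf"], b.edges["tg"]))
    if not (na | nb):
        raise ValidationError("similarity undefined for two empty networks")
    node_j = len(na & nb) / len(na | nb)
    edge_j = len(ea & eb) / len(ea | eb) if (ea | eb) else 0.0
    return node_j, edge_j
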