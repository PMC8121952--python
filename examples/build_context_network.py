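"""Build a context-specific TF->TG network from TRS scores.

Scores every candidate TF-TG pair by combining cross-context expression
correlation, context-normalized expression/accessibility levels, motif
binding strengths, and RE-to-gene regulating strengths; converts scores
to (0, 1] edge weights; and compares the result to a harmonized
external network.
"""

import numpy as np
import pandas as pd

from rssnet.construction import (PecaContextData, build_context_network,
                                 network_similarity,
                                 rescale_external_weight, select_top_edges)

rng = np.random.default_rng(3)
tfs = [f"TF{i}" for i in range(4)]
tgs = [f"TG{i}" for i in range(6)]
res = [f"RE{i}" for i in range(8)]

data = PecaContextData(
    corr=pd.DataFrame(rng.uniform(-1, 1, (4, 6)), index=tfs, columns=tgs),
    tf_level=pd.Series(rng.uniform(0.5, 4, 4), index=tfs),
    tf_median=pd.Series(rng.uniform(0.5, 2, 4), index=tfs),
    tg_level=pd.Series(rng.uniform(0.5, 4, 6), index=tgs),
    tg_median=pd.Series(rng.uniform(0.5, 2, 6), index=tgs),
    re_level=pd.Series(rng.uniform(0, 3, 8), index=res),
    re_median=pd.Series(rng.uniform(0.5, 2, 8), index=res),
    binding=pd.DataFrame(rng.uniform(0, 2, (4, 8)) *
                         (rng.random((4, 8)) > 0.4), index=tfs, columns=res),
    regulating=pd.DataFrame(rng.uniform(0, 1, (8, 6)) *
                            (rng.random((8, 6)) > 0.4),
                            index=res, columns=tgs),
)

net = build_context_network(data, name="context-A")
print(f"context network: {len(net.tf_nodes)} TFs, {len(net.tg_nodes)} TGs, "
      f"{net.n_edges} weighted edges")
print(net.edges.head(5).to_string(index=False))

# harmonize an external network: rescale weights, match edge count
external = pd.DataFrame({
    "tf": rng.choice(tfs, 20), "tg": rng.choice(tgs, 20),
    "weight": rescale_external_weight(rng.uniform(0, 2, 20) ** 6),
}).drop_duplicates(["tf", "tg"]).reset_index(drop=True)
matched = select_top_edges(external, k=min(net.n_edges, len(external)),
                           name="external-matched")

node_j, edge_j = network_similarity(net, matched)
print(f"\nsimilarity to harmonized external network: "
      f"node Jaccard {node_j:.2f}, edge Jaccard {edge_j:.2f}")
# High node overlap with lower edge overlap is typical: the same genes
# participate, but context-specific wiring differs between resources.
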