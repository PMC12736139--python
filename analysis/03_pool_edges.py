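"""Pool each edge across regions within each group (random-effects).

Fisher-Z DerSimonian-Laird pooling of the per-region latent correlations,
BH FDR over all pairs within a group, and the group-level network
summaries reported for such cohorts: edge count at FDR < 0.05, positive
fraction, and per-genus degree.  Exports the significant networks as
GraphML.
"""

from pathlib import Path

import pandas as pd

from metsnet import edge_meta, io_formats

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    edges = pd.read_csv(BASE / "region_edges.tsv", sep="\t")
    for group in ("nonMetS", "MetS"):
        pooled = edge_meta.pool_group_edges(edges[edges["group"] == group], group)
        edge_meta.pooled_to_frame(pooled).to_csv(
            BASE / f"pooled_{group}.tsv", sep="\t", index=False)
        net = edge_meta.significant_network(pooled, cut=0.05)
        io_formats.export_network(pooled, 0.05, BASE / f"network_{group}.graphml")
        top = sorted(net.degree.items(), key=lambda kv: -kv[1])[:3]
        pos = (f"{100 * net.positive_fraction:.1f}%"
               if net.positive_fraction is not None else "n/a")
        print(f"{group:8s}: {net.n_edges}/{len(pooled)} edges at FDR<0.05, "
              f"positive fraction {pos}, top degrees {top}")


if __name__ == "__main__":
    main()
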