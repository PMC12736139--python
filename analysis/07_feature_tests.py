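"""Group differences in genus abundances and functional features.

Inverse-rank transforms each feature, residualizes on all covariates by
OLS, and compares MetS vs non-MetS with the Wilcoxon rank-sum test, BH
FDR within each feature family (genera involved in differential edges;
functional features).
"""

from pathlib import Path

import pandas as pd

from metsnet import abundance_diff, io_formats

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    abundance = io_formats.read_abundance(BASE / "cohort" / "abundance.tsv",
                                          min_prevalence=0.10)
    metadata = io_formats.read_metadata(BASE / "cohort" / "metadata.tsv")
    functions = io_formats.read_functions(BASE / "cohort" / "functions.tsv")
    edges = io_formats.read_edge_table(BASE / "differential_edges.tsv")
    genera = sorted({t for p in edges.loc[edges["is_differential"], "pair"]
                     for t in p.split("-", 1)})
    meta = metadata.loc[abundance.sample_ids]

    frames = []
    if genera:
        res = abundance_diff.test_features(abundance.to_frame()[genera], meta,
                                           feature_kind="genus")
        frames.append(abundance_diff.results_to_frame(res))
    res = abundance_diff.test_features(functions.to_frame().loc[abundance.sample_ids],
                                       meta, feature_kind="EC")
    frames.append(abundance_diff.results_to_frame(res))
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(BASE / "feature_tests.tsv", sep="\t", index=False)
    hits = table[table["fdr"] < 0.05]
    print(f"tested {len(table)} features "
          f"({len(genera)} genera + {functions.values.shape[1]} functions); "
          f"{len(hits)} at FDR<0.05")
    for _, r in table.iterrows():
        mark = "*" if r["fdr"] < 0.05 else " "
        print(f" {mark} {r['feature_kind']:6s} {r['feature_id']:20s} "
              f"p={r['p']:.3g} fdr={r['fdr']:.3g} direction={r['direction']:+d}")


if __name__ == "__main__":
    main()
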