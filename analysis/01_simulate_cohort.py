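"""Generate the synthetic study cohort.

Emulates a three-region cross-sectional cohort at the target scale — 221
MetS and 382 non-MetS participants split over three regions — with 30
genera, five planted differential co-abundances (one of which flips sign
between groups, the direction-change phenomenon), and two functional
features driven by planted genus pairs, one through a pure interaction
term.  Writes abundance/metadata/function TSVs plus the ground truth.
"""

from pathlib import Path

from metsnet import io_formats, synthetic_data
from metsnet.synthetic_data import FunctionEffect, SimulationConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"

N_PER_STRATUM = {
    ("nonMetS", "region1"): 128, ("nonMetS", "region2"): 127,
    ("nonMetS", "region3"): 127,
    ("MetS", "region1"): 74, ("MetS", "region2"): 74, ("MetS", "region3"): 73,
}

DIFFERENTIAL_PAIRS = [
    ("g000", "g001", 0.60, 0.15),   # weakened in MetS
    ("g002", "g003", 0.55, 0.10),
    ("g004", "g005", 0.50, 0.05),
    ("g006", "g007", -0.50, -0.05),
    ("g008", "g009", -0.35, 0.25),  # direction change
]

FUNCTION_EFFECTS = [
    FunctionEffect("EC:sim.additive", "g000", "g001",
                   beta1=0.5, beta2=0.4, beta12=0.0, noise_sd=1.0),
    FunctionEffect("EC:sim.interaction", "g002", "g003",
                   beta1=0.3, beta2=0.2, beta12=0.4, noise_sd=1.0),
]


def main() -> None:
    config = SimulationConfig(
        p=30, n_per_stratum=N_PER_STRATUM, depth=10_000,
        base_edge_density=0.05, differential_pairs=DIFFERENTIAL_PAIRS,
        covariate_effects=[("age", "g010", 0.4), ("sex", "g011", 0.4)],
        group_shifts=[("g004", 0.6), ("g008", -0.6)],  # abundance-level group gap
        function_effects=FUNCTION_EFFECTS, mean_log_sd=2.0, seed=20230901)
    ds = synthetic_data.generate_dataset(config)
    OUT.mkdir(parents=True, exist_ok=True)
    io_formats.write_abundance(ds.abundance, OUT / "abundance.tsv")
    io_formats.write_metadata(ds.metadata, OUT / "metadata.tsv")
    io_formats.write_functions(ds.functions, OUT / "functions.tsv")
    synthetic_data.write_truth(ds.truth, OUT / "truth.json")
    prev = ds.abundance.prevalence()
    print(f"cohort: {ds.abundance.n_samples} samples x {ds.abundance.n_taxa} taxa "
          f"-> {OUT}")
    print(f"taxa at >=10% prevalence: {(prev >= 0.10).sum()}; "
          f"in the 25-75% window: {((prev >= 0.25) & (prev <= 0.75)).sum()}")
    print(f"planted differential pairs: {len(DIFFERENTIAL_PAIRS)} "
          f"(one with a sign flip); functions: {[e.function_id for e in FUNCTION_EFFECTS]}")


if __name__ == "__main__":
    main()
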