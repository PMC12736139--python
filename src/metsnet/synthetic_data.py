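"""Synthetic microbiome cohorts with known co-abundance ground truth.

The generator emulates a three-region cross-sectional cohort with a binary
disease label (MetS vs non-MetS): genus-level compositions, sample
covariates (age, sex, lifestyle, diet) and predicted functional profiles.
The latent model is logistic-normal — latent log-abundances are multivariate
normal with a specified correlation matrix per (group, region), exponentiated
and closed to a composition — matching the latent log-basis assumption under
which the correlation inference operates.  Zeros arise only through finite
multinomial sampling depth, the same mechanism that makes prevalence
filtering meaningful on real count data.

Differential edges are planted by giving a taxon pair different latent
correlations in the two groups; keystone structure is planted by shifting
the latent means of target taxa in samples where a candidate taxon is
present.  Every quantity needed to score recovery downstream is recorded in
:class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
import yaml

from .io_formats import AbundanceTable, FunctionTable, close_rows

GROUPS = ("nonMetS", "MetS")
REGIONS = ("region1", "region2", "region3")

# Cohort-scale defaults: 603 participants (221 MetS / 382 non-MetS) across
# three regions, 93 genera at the >=10% prevalence cut.
DEFAULT_N = {
    ("nonMetS", "region1"): 128, ("nonMetS", "region2"): 127, ("nonMetS", "region3"): 127,
    ("MetS", "region1"): 74, ("MetS", "region2"): 74, ("MetS", "region3"): 73,
}

# Table-1-like covariate frequencies (never / former / seldom / everyday etc.)
SMOKING_P = (0.67, 0.11, 0.02, 0.20)
ALCOHOL_P = (0.59, 0.34, 0.03, 0.04)
ACTIVITY_P = (0.20, 0.32, 0.48)
DIET_MEANS = {"grains": 365.0, "vegetables": 470.0, "fruits": 135.0,
              "dairy": 113.0, "animal_products": 194.0, "beans_nuts": 42.0}


@dataclass
class FunctionEffect:
    """Generative model of one functional feature from two genera.

    Y = beta1 * z_a + beta2 * z_b + beta12 * z_a * z_b + Normal(0, noise_sd),
    computed on standardized latent (pre-closure) log-abundances and then
    shifted/scaled to a non-negative abundance-like column.
    """

    function_id: str
    taxon_a: str
    taxon_b: str
    beta1: float = 0.0
    beta2: float = 0.0
    beta12: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.taxon_a == self.taxon_b:
            raise ValueError("function effect needs two distinct taxa")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything planted into a synthetic dataset, for downstream scoring."""

    latent_corr_by_group_region: dict
    differential_pairs: list
    function_effects: list
    keystone_taxa: list = field(default_factory=list)


@dataclass
class SyntheticDataset:
    abundance: AbundanceTable
    metadata: pd.DataFrame
    functions: FunctionTable | None
    truth: GroundTruth
    seed: int
    latent_log: pd.DataFrame | None = None  # hidden basis, for oracles
    config: "SimulationConfig | None" = None

    def stratum(self, group: str, region: str) -> AbundanceTable:
        keep = ((self.metadata["group"] == group)
                & (self.metadata["region"] == region)).to_numpy()
        return self.abundance.select_samples(keep)


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort."""

    p: int = 93
    n_per_stratum: dict = field(default_factory=lambda: dict(DEFAULT_N))
    depth: int = 10_000
    depth_cv: float = 0.3  # per-sample depth ~ lognormal(mean=depth, cv)
    base_edge_density: float = 0.05
    base_rho_range: tuple[float, float] = (0.4, 0.7)
    # (taxon_i, taxon_j, rho_nonMetS, rho_MetS)
    differential_pairs: list = field(default_factory=list)
    # (covariate, taxon, beta) added to latent log-mean per SD of covariate
    covariate_effects: list = field(default_factory=list)
    # (taxon, delta) added to the latent log-mean in MetS samples only
    group_shifts: list = field(default_factory=list)
    function_effects: list = field(default_factory=list)
    mean_log_sd: float = 3.0    # spread of taxon base log-means (rank-abundance)
    latent_sd: float = 1.0      # SD of latent log-abundance around its mean
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "n_per_stratum" in raw:
            raw["n_per_stratum"] = {tuple(k.split("/")): v
                                    for k, v in raw["n_per_stratum"].items()}
        if "function_effects" in raw:
            raw["function_effects"] = [FunctionEffect(**e) for e in raw["function_effects"]]
        if "differential_pairs" in raw:
            raw["differential_pairs"] = [tuple(x) for x in raw["differential_pairs"]]
        if "base_rho_range" in raw:
            raw["base_rho_range"] = tuple(raw["base_rho_range"])
        return cls(**raw)


def taxon_names(p: int) -> list[str]:
    return [f"g{i:03d}" for i in range(p)]


def check_correlation_matrix(corr: np.ndarray, tol: float = 1e-8) -> None:
    """Reject anything that is not a valid correlation matrix."""
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation matrix is not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ValueError("correlation matrix diagonal is not 1")
    if np.any(np.abs(corr) > 1 + 1e-12):
        raise ValueError("correlation entries must satisfy |rho| <= 1")
    w = np.linalg.eigvalsh(corr)
    if w.min() < -tol:
        raise ValueError(
            f"requested correlation matrix is not PSD: smallest eigenvalue {w.min():.3e}")


def build_group_correlations(config: SimulationConfig, rng: np.random.Generator
                             ) -> dict[str, np.ndarray]:
    """Per-group latent correlation matrices with planted differential pairs.

    Background edges are shared between groups.  Positive definiteness is
    guaranteed by budgeting each row's off-diagonal absolute sum below 1
    (strict diagonal dominance); should a user-extended matrix still fail,
    a small diagonal jitter is applied and the matrix re-normalized.
    """
    p = config.p
    names = taxon_names(p)
    idx = {t: i for i, t in enumerate(names)}
    budget = np.full(p, 0.9)
    corr = {g: np.eye(p) for g in GROUPS}

    for ti, tj, rho_non, rho_mets in config.differential_pairs:
        i, j = idx[str(ti)], idx[str(tj)]
        for rho in (rho_non, rho_mets):
            if abs(rho) >= 1:
                raise ValueError(f"planted |rho| must be < 1; got {rho} for ({ti},{tj})")
        used = max(abs(rho_non), abs(rho_mets))
        budget[i] -= used
        budget[j] -= used
        corr["nonMetS"][i, j] = corr["nonMetS"][j, i] = rho_non
        corr["MetS"][i, j] = corr["MetS"][j, i] = rho_mets
    if np.any(budget < 0):
        raise ValueError("planted differential pairs exceed the per-taxon "
                         "correlation budget; reduce |rho| or overlap")

    lo, hi = config.base_rho_range
    n_background = int(round(config.base_edge_density * p * (p - 1) / 2))
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)
             if corr["nonMetS"][i, j] == 0 and corr["MetS"][i, j] == 0]
    rng.shuffle(pairs)
    placed = 0
    for i, j in pairs:
        if placed >= n_background:
            break
        rho = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        if abs(rho) > min(budget[i], budget[j]):
            continue
        for g in GROUPS:
            corr[g][i, j] = corr[g][j, i] = rho
        budget[i] -= abs(rho)
        budget[j] -= abs(rho)
        placed += 1

    for g in GROUPS:
        w = np.linalg.eigvalsh(corr[g])
        if w.min() < 1e-8:  # jitter fallback; dominance should prevent this
            corr[g] = corr[g] + (abs(w.min()) + 1e-6) * np.eye(p)
            d = np.sqrt(np.diag(corr[g]))
            corr[g] = corr[g] / np.outer(d, d)
        check_correlation_matrix(corr[g])
    return corr


def _sample_depths(mean_depth: int, cv: float, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-sample sequencing depths, lognormal around the target mean."""
    if cv <= 0:
        return np.full(n, int(mean_depth))
    sigma2 = np.log1p(cv**2)
    draws = rng.lognormal(np.log(mean_depth) - sigma2 / 2.0, np.sqrt(sigma2), n)
    return np.maximum(np.round(draws).astype(int), 1)


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    cov = pd.DataFrame(index=range(n))
    cov["age"] = rng.normal(53.0, 12.5, n).round(1)
    cov["sex"] = rng.binomial(1, 0.45, n)
    cov["smoking"] = rng.choice(len(SMOKING_P), n, p=SMOKING_P)
    cov["alcohol"] = rng.choice(len(ALCOHOL_P), n, p=ALCOHOL_P)
    cov["physical_activity"] = rng.choice(len(ACTIVITY_P), n, p=ACTIVITY_P)
    for name, mean in DIET_MEANS.items():
        # gamma with shape 2 gives the right skew for grams/day intakes
        cov[name] = rng.gamma(2.0, mean / 2.0, n).round(1)
    return cov


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a full synthetic cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    p = config.p
    names = taxon_names(p)
    idx = {t: i for i, t in enumerate(names)}
    corr_by_group = build_group_correlations(config, rng)

    base_mu = rng.normal(0.0, config.mean_log_sd, p)

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    latent_blocks: list[np.ndarray] = []
    rel_blocks: list[np.ndarray] = []
    truth_corr: dict = {}

    for group in GROUPS:
        chol = np.linalg.cholesky(
            corr_by_group[group] + 1e-10 * np.eye(p))
        for region in REGIONS:
            n = int(config.n_per_stratum.get((group, region), 0))
            if n == 0:
                continue
            truth_corr[(group, region)] = corr_by_group[group]
            cov = _draw_covariates(n, rng)
            z = rng.standard_normal((n, p)) @ chol.T * config.latent_sd
            latent = base_mu + z
            for covariate, taxon, beta in config.covariate_effects:
                col = cov[covariate].to_numpy(dtype=float)
                sd = col.std() or 1.0
                latent[:, idx[str(taxon)]] += beta * (col - col.mean()) / sd
            if group == "MetS":
                for taxon, delta in config.group_shifts:
                    latent[:, idx[str(taxon)]] += delta
            basis = np.exp(latent)
            comp = close_rows(basis)
            depths = _sample_depths(config.depth, config.depth_cv, n, rng)
            counts = np.vstack([rng.multinomial(depths[i], comp[i])
                                for i in range(n)])
            rel = close_rows(counts)
            start = len(sample_ids)
            ids = [f"S{start + i:04d}" for i in range(n)]
            sample_ids.extend(ids)
            for i, sid in enumerate(ids):
                row = {"sample_id": sid, "group": group, "region": region}
                row.update(cov.iloc[i].to_dict())
                meta_rows.append(row)
            latent_blocks.append(latent)
            rel_blocks.append(rel)

    abundance = AbundanceTable(sample_ids, names, np.vstack(rel_blocks), relative=True)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    latent_log = pd.DataFrame(np.vstack(latent_blocks), index=sample_ids, columns=names)

    truth = GroundTruth(
        latent_corr_by_group_region=truth_corr,
        differential_pairs=[tuple(x) for x in config.differential_pairs],
        function_effects=list(config.function_effects),
        keystone_taxa=[],
    )
    dataset = SyntheticDataset(abundance=abundance, metadata=metadata,
                               functions=None, truth=truth, seed=config.seed,
                               latent_log=latent_log, config=config)
    if config.function_effects:
        cols, ids = [], []
        for k, eff in enumerate(config.function_effects):
            y = generate_function_profile(dataset, eff,
                                          rng=np.random.default_rng(
                                              np.random.SeedSequence([config.seed, 7, k])))
            cols.append(y)
            ids.append(eff.function_id)
        dataset.functions = FunctionTable(sample_ids, ids, np.column_stack(cols))
    return dataset


def generate_function_profile(dataset: SyntheticDataset, effect: FunctionEffect,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """One functional-feature column generated from two genera's latents."""
    rng = rng or np.random.default_rng(dataset.seed + 104729)
    for t in (effect.taxon_a, effect.taxon_b):
        if t not in dataset.latent_log.columns:
            raise ValueError(f"unknown taxon id {t!r}")
    za = dataset.latent_log[effect.taxon_a].to_numpy()
    zb = dataset.latent_log[effect.taxon_b].to_numpy()
    za = (za - za.mean()) / (za.std() or 1.0)
    zb = (zb - zb.mean()) / (zb.std() or 1.0)
    y = (effect.beta1 * za + effect.beta2 * zb + effect.beta12 * za * zb
         + rng.normal(0.0, effect.noise_sd, za.shape[0]))
    span = y.max() - y.min()
    return (y - y.min()) / (span if span > 0 else 1.0)


def plant_keystone(dataset: SyntheticDataset, taxon: str, shift_vector: dict[str, float],
                   prevalence_window: tuple[float, float] | None = None) -> SyntheticDataset:
    """Shift target taxa's latent means where ``taxon`` is present; resample.

    The candidate's own observed presence pattern defines the split.  The
    shift must target other taxa — a keystone acts on the rest of the
    community, not on itself.
    """
    if taxon in shift_vector:
        raise ValueError("shift_vector must not include the candidate taxon itself")
    names = dataset.abundance.taxon_ids
    for t in shift_vector:
        if t not in names:
            raise ValueError(f"unknown taxon id {t!r}")
    if taxon not in names:
        raise ValueError(f"unknown taxon id {taxon!r}")
    present = dataset.abundance.to_frame()[taxon].to_numpy() > 0
    prevalence = float(present.mean())
    if prevalence_window is not None:
        lo, hi = prevalence_window
        if not (lo <= prevalence <= hi):
            raise ValueError(
                f"{taxon} prevalence {prevalence:.3f} outside window [{lo}, {hi}]")
    latent = dataset.latent_log.copy()
    for t, delta in shift_vector.items():
        latent.loc[present, t] += delta
    rng = np.random.default_rng(np.random.SeedSequence([dataset.seed, 13]))
    # keep the candidate column exactly as observed (its presence pattern is
    # the split under study); resample the others from the shifted latents
    # into the remaining mass of each sample
    cand = names.index(taxon)
    others = [j for j in range(len(names)) if j != cand]
    comp_others = close_rows(np.exp(latent.to_numpy()[:, others]))
    depth = dataset.config.depth if dataset.config is not None else 20_000
    depth_cv = dataset.config.depth_cv if dataset.config is not None else 0.3
    depths = _sample_depths(depth, depth_cv, comp_others.shape[0], rng)
    counts = np.vstack([rng.multinomial(depths[i], comp_others[i])
                        for i in range(comp_others.shape[0])])
    rel_others = close_rows(counts)
    rel = np.empty((comp_others.shape[0], len(names)))
    cand_rel = dataset.abundance.values[:, cand]
    rel[:, cand] = cand_rel
    rel[:, others] = rel_others * (1.0 - cand_rel)[:, None]
    abundance = AbundanceTable(list(dataset.abundance.sample_ids), list(names),
                               rel, relative=True)
    truth = GroundTruth(
        latent_corr_by_group_region=dataset.truth.latent_corr_by_group_region,
        differential_pairs=dataset.truth.differential_pairs,
        function_effects=dataset.truth.function_effects,
        keystone_taxa=dataset.truth.keystone_taxa + [taxon],
    )
    return SyntheticDataset(abundance=abundance, metadata=dataset.metadata,
                            functions=dataset.functions, truth=truth,
                            seed=dataset.seed, latent_log=latent,
                            config=dataset.config)


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "latent_corr_by_group_region": {
            f"{g}/{r}": m.tolist() for (g, r), m in
            truth.latent_corr_by_group_region.items()},
        "differential_pairs": [list(x) for x in truth.differential_pairs],
        "function_effects": [asdict(e) for e in truth.function_effects],
        "keystone_taxa": list(truth.keystone_taxa),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
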