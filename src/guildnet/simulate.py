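"""Synthetic compositional cohorts with planted structure.

The generator emulates the post-profiling stage of a three-generation
longevity-family cohort: a taxa-by-sample count table over three age groups
(G1 centenarian, G2 elderly, G3 young) with

* planted co-abundance guilds - blocks of taxa sharing a latent per-sample
  factor, so their log-abundances covary;
* planted aging trajectories - per-class group shifts of the latent
  log-abundance (monotone up/down, rejuvenation, centenarian-specific,
  stable);
* family structure - each family contributes at most one sample per group,
  and taxa designated stable carry a heritable per-(taxon, family) effect;
* continuous host covariates linked to the latent abundance of chosen taxa.

Generative model per sample k and taxon i:

    y_ik = mu_i + lambda_i f_{g(i),k} + beta_i(group_k) * delta
           + gamma_{i, fam(k)} + eps_ik
    p_k  = softmax_i(y_ik),  counts_k ~ Multinomial(N_k, p_k),
    N_k  ~ round(LogNormal(depth_log_mean, depth_log_sd))

with f ~ N(0, tau^2), eps ~ N(0, sigma^2), gamma ~ N(0, family_effect_sd^2)
for heritable taxa, and beta patterns over (G3, G2, G1): monotone_up
(0, 1/2, 1), monotone_down (1, 1/2, 0), rejuvenation (0, 1, 0), centenarian
(0, 0, 1), stable (0, 0, 0).  A single seed drives every draw; identical
(config, seed) reproduce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountTable, SampleMetadata, SymmetricMatrix
from .errors import ConfigurationError

__all__ = ["SIGNATURE_CLASSES", "BETA_PATTERNS", "SimulationConfig",
           "SimulationTruth", "default_cohort_config", "simulate"]

SIGNATURE_CLASSES = ("monotone_up", "monotone_down", "rejuvenation",
                     "centenarian", "stable")
# beta over (G3, G2, G1), i.e. young -> elderly -> centenarian
BETA_PATTERNS = {
    "monotone_up": {"G3": 0.0, "G2": 0.5, "G1": 1.0},
    "monotone_down": {"G3": 1.0, "G2": 0.5, "G1": 0.0},
    "rejuvenation": {"G3": 0.0, "G2": 1.0, "G1": 0.0},
    "centenarian": {"G3": 0.0, "G2": 0.0, "G1": 1.0},
    "stable": {"G3": 0.0, "G2": 0.0, "G1": 0.0},
}


@dataclass
class SimulationConfig:
    n_taxa: int = 150
    guild_sizes: list[int] = field(default_factory=list)
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"G1": 32, "G2": 30, "G3": 11})
    n_families: int = 26
    depth_log_mean: float = float(np.log(20000.0))
    depth_log_sd: float = 0.3
    guild_factor_sd: float = 1.0          # tau
    loading_range: tuple[float, float] = (0.8, 1.2)
    signature_assignment: dict[str, str] = field(default_factory=dict)
    effect_size: float = 1.5              # delta, in latent log-abundance SD
    family_effect_sd: float = 0.5         # gamma SD for heritable taxa
    noise_sd: float = 0.5                 # sigma
    base_abundance_sd: float = 1.0        # spread of per-taxon means mu_i
    # log-scale baseline offset of taxa with an active trajectory class:
    # planting them in the low-abundance tail keeps the group shifts from
    # perturbing the closure (so taxa planted flat stay flat in relative
    # abundance), matching how differential genera sit in real communities
    trajectory_abundance_offset: float = -2.0
    overdispersion: float = 0.0           # >0: Dirichlet(p*overdispersion)
    host_var_spec: list[tuple[str, list[str], float]] = field(default_factory=list)
    seed: int = 0

    def taxon_ids(self) -> list[str]:
        return [f"taxon_{i:04d}" for i in range(self.n_taxa)]

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ConfigurationError("n_taxa must be >= 2")
        if any(s < 2 for s in self.guild_sizes):
            raise ConfigurationError("every guild needs at least 2 taxa")
        if sum(self.guild_sizes) > self.n_taxa:
            raise ConfigurationError("guild sizes exceed n_taxa")
        if set(self.group_sizes) != {"G1", "G2", "G3"}:
            raise ConfigurationError("group_sizes must cover G1, G2, G3")
        if any(n < 3 for n in self.group_sizes.values()):
            raise ConfigurationError("every group needs at least 3 samples")
        if self.effect_size < 0 or self.guild_factor_sd < 0:
            raise ConfigurationError("delta and tau must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.family_effect_sd < 0 or self.depth_log_sd < 0:
            raise ConfigurationError("spread parameters must be >= 0")
        lo, hi = self.loading_range
        if not 0 < lo <= hi:
            raise ConfigurationError("loading_range must satisfy 0 < lo <= hi")
        second_largest = sorted(self.group_sizes.values())[-2]
        if self.n_families < 2 or self.n_families > second_largest:
            raise ConfigurationError(
                "n_families must lie in [2, second-largest group size] so "
                "every family spans at least two groups")
        ids = set(self.taxon_ids())
        for taxon, cls in self.signature_assignment.items():
            if taxon not in ids:
                raise ConfigurationError(f"unknown taxon {taxon!r} in "
                                         "signature_assignment")
            if cls not in SIGNATURE_CLASSES:
                raise ConfigurationError(f"unknown signature class {cls!r}")
        for name, taxa, _ in self.host_var_spec:
            missing = [t for t in taxa if t not in ids]
            if missing:
                raise ConfigurationError(
                    f"host variable {name!r} links unknown taxa {missing[:3]}")


@dataclass
class SimulationTruth:
    guild_of: dict[str, int | None]
    signature_of: dict[str, str]
    heritable_taxa: list[str]
    latent_log_abundance: pd.DataFrame
    depths: pd.Series
    true_basis_correlation: SymmetricMatrix
    host_var_links: list[tuple[str, list[str], float]]
    config: SimulationConfig

    def to_json(self, path) -> None:
        payload = {
            "guild_of": self.guild_of,
            "signature_of": self.signature_of,
            "heritable_taxa": self.heritable_taxa,
            "host_var_links": [[n, t, c] for n, t, c in self.host_var_links],
            "seed": self.config.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def default_cohort_config(seed: int = 0) -> SimulationConfig:
    """The documented default cohort: 73 samples (11/30/32), 150 taxa.

    Eight guilds of 5-15 taxa occupy the first 80 taxa; of the remaining
    free taxa, 10 each get the four active trajectory classes and 20 are
    stable-heritable; 26 families link the generations.
    """
    guild_sizes = [5, 7, 9, 10, 11, 12, 13, 13]
    cfg = SimulationConfig(guild_sizes=guild_sizes, seed=seed)
    ids = cfg.taxon_ids()
    free_start = sum(guild_sizes)
    assignment: dict[str, str] = {}
    cursor = free_start
    for cls, n in (("monotone_up", 10), ("monotone_down", 10),
                   ("rejuvenation", 10), ("centenarian", 10), ("stable", 20)):
        for taxon in ids[cursor:cursor + n]:
            assignment[taxon] = cls
        cursor += n
    cfg.signature_assignment = assignment
    # host covariates track guild factors: the shared latent signal is strong
    # (sd ~ tau) so the planted association has a well-defined truth
    guild1 = ids[:3]
    guild2 = ids[guild_sizes[0]:guild_sizes[0] + 3]
    cfg.host_var_spec = [("cytokine_a", guild1, 1.0), ("neuro_b", guild2, -1.0)]
    cfg.validate()
    return cfg


def _assign_samples(config: SimulationConfig):
    """Sample ids, groups, family ids and generations, deterministically.

    Family f receives the f-th sample of every group that has one; samples
    beyond n_families carry no family id, so each family contributes at
    most one sample per group and every family spans >= 2 groups.
    """
    sample_ids, groups, families, generations = [], [], [], []
    counter = 0
    for group in ("G1", "G2", "G3"):
        for j in range(config.group_sizes[group]):
            counter += 1
            sample_ids.append(f"S{counter:03d}")
            groups.append(group)
            families.append(f"F{j + 1:02d}" if j < config.n_families else None)
            generations.append(int(group[1]))
    return sample_ids, groups, families, generations


def simulate(config: SimulationConfig
             ) -> tuple[CountTable, SampleMetadata, SimulationTruth]:
    """Draw one cohort from the generative model (single-seed, bit-stable)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    taxa = config.taxon_ids()
    n_taxa = config.n_taxa
    sample_ids, groups, families, generations = _assign_samples(config)
    n_samples = len(sample_ids)

    guild_of: dict[str, int | None] = {t: None for t in taxa}
    cursor = 0
    for gid, size in enumerate(config.guild_sizes, start=1):
        for t in taxa[cursor:cursor + size]:
            guild_of[t] = gid
        cursor += size
    guild_index = np.array([guild_of[t] or 0 for t in taxa])

    signature_of = {t: config.signature_assignment.get(t, "stable")
                    for t in taxa}
    heritable = [t for t in taxa
                 if config.signature_assignment.get(t) == "stable"]
    heritable_set = set(heritable)

    # fixed draw order: mu, loadings, guild factors, family effects, noise
    mu = rng.normal(0.0, config.base_abundance_sd, n_taxa)
    for i, t in enumerate(taxa):
        if config.signature_assignment.get(t, "stable") != "stable":
            mu[i] += config.trajectory_abundance_offset
    lo, hi = config.loading_range
    loadings = rng.uniform(lo, hi, n_taxa)
    loadings[guild_index == 0] = 0.0
    n_guilds = len(config.guild_sizes)
    factors = rng.normal(0.0, config.guild_factor_sd, (n_guilds, n_samples))
    gamma = rng.normal(0.0, config.family_effect_sd,
                       (len(heritable), config.n_families))
    eps = rng.normal(0.0, config.noise_sd, (n_taxa, n_samples))

    beta = np.zeros((n_taxa, n_samples))
    for i, t in enumerate(taxa):
        pattern = BETA_PATTERNS[signature_of[t]]
        if t not in config.signature_assignment:
            continue  # unmapped taxa are flat baseline
        beta[i] = [pattern[g] for g in groups]
    family_pos = {f"F{j + 1:02d}": j for j in range(config.n_families)}
    gamma_term = np.zeros((n_taxa, n_samples))
    heritable_rows = {t: r for r, t in enumerate(heritable)}
    for k, fam in enumerate(families):
        if fam is None:
            continue
        for t in heritable_set:
            gamma_term[taxa.index(t), k] = gamma[heritable_rows[t],
                                                 family_pos[fam]]

    guild_part = np.zeros((n_taxa, n_samples))
    mask = guild_index > 0
    guild_part[mask] = loadings[mask, None] * factors[guild_index[mask] - 1]
    y = mu[:, None] + guild_part + beta * config.effect_size \
        + gamma_term + eps

    logits = y - y.max(axis=0, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=0, keepdims=True)
    depths = np.maximum(
        1, np.round(rng.lognormal(config.depth_log_mean,
                                  config.depth_log_sd, n_samples))
    ).astype(np.int64)
    counts = np.empty((n_taxa, n_samples), dtype=np.int64)
    for k in range(n_samples):
        pk = p[:, k]
        if config.overdispersion > 0:
            pk = rng.dirichlet(pk * config.overdispersion)
        counts[:, k] = rng.multinomial(depths[k], pk)

    meta = pd.DataFrame({"group": groups, "family_id": families,
                         "generation": generations},
                        index=pd.Index(sample_ids, name="sample_id"))
    for name, linked, coef in config.host_var_spec:
        rows = [taxa.index(t) for t in linked]
        meta[name] = coef * y[rows].mean(axis=0) \
            + rng.standard_normal(n_samples)

    ct = CountTable(pd.DataFrame(counts, index=taxa, columns=sample_ids))
    md = SampleMetadata(meta)
    truth = SimulationTruth(
        guild_of=guild_of,
        signature_of=signature_of,
        heritable_taxa=heritable,
        latent_log_abundance=pd.DataFrame(y, index=taxa, columns=sample_ids),
        depths=pd.Series(depths, index=sample_ids, name="depth"),
        true_basis_correlation=_model_correlation(
            config, guild_index, loadings, beta, heritable_set, taxa),
        host_var_links=list(config.host_var_spec),
        config=config,
    )
    return ct, md, truth


def _model_correlation(config: SimulationConfig, guild_index: np.ndarray,
                       loadings: np.ndarray, beta: np.ndarray,
                       heritable: set, taxa: list[str]) -> SymmetricMatrix:
    """Model-implied latent correlation given the realised design.

    Covariance components: shared guild factor lambda_i lambda_j tau^2, the
    design covariance of the scaled group shifts, independent noise sigma^2
    and, on the diagonal of heritable taxa, the family-effect variance.
    """
    tau2 = config.guild_factor_sd ** 2
    same_guild = (guild_index[:, None] == guild_index[None, :]) \
        & (guild_index[:, None] > 0)
    cov = np.where(same_guild, np.outer(loadings, loadings) * tau2, 0.0)
    shifts = beta * config.effect_size
    centred = shifts - shifts.mean(axis=1, keepdims=True)
    cov = cov + (centred @ centred.T) / shifts.shape[1]
    diag_extra = np.full(len(taxa), config.noise_sd ** 2)
    for i, t in enumerate(taxa):
        if t in heritable:
            diag_extra[i] += config.family_effect_sd ** 2
    cov[np.diag_indices_from(cov)] = np.diag(cov) + diag_extra
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return SymmetricMatrix(taxa, corr, "correlation")
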