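"""Synthetic survey generator with known ground truth.

Emulates the shape of a fragmented-island (kipuka) plant survey: a regional
pool of species related by a birth–death phylogeny, one continuous trait (log
maximum vegetative height) evolved under BM or OU, a set of local communities
assembled from the pool under a known process (neutral, filtering, or
competition), and per-island geography covariates — area and isolation drawn
log-uniformly over the observed spans (700–114,100 m²; 17.65–2,137 m),
elevation uniformly over 1,358–1,678 m.  Optional ``geography_effects``
plant a linear dependence of assembly strength on a covariate so downstream
regressions have a recoverable signal.

The defaults reproduce the study conditions: 641 regional species, OU traits
with σ² = 0.92, α = 0.2, and 19 communities of 9–20 species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .assembly import AssemblyParams, assemble_local, simulate_birth_death_tree, simulate_traits
from .phylogeny import Phylogeny, write_newick

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_regional_pool",
    "generate_kipuka_survey",
    "generate_dataset",
    "synthesize_support_table",
    "write_dataset",
]

AREA_RANGE = (700.0, 114_100.0)  # m^2, log-uniform
ISOLATION_RANGE = (17.65, 2_137.0)  # m, log-uniform
ELEVATION_RANGE = (1_358.0, 1_678.0)  # m, uniform


@dataclass
class SyntheticConfig:
    """Ground-truth configuration of a synthetic survey."""

    n_regional: int = 641
    lam: float = 0.5  # speciation rate, events / lineage / time
    mu: float = 0.0  # extinction rate
    trait_model: str = "OU"
    sigma2: float = 0.92  # trait diffusion, (log trait)^2 / time
    alpha: float = 0.2  # OU pull, / time
    theta: float = 4.8  # OU optimum, log(cm)
    assembly_model: str = "neutral"
    tau: float = 30.0  # assembly strength; smaller = stronger effect
    n_communities: int = 19
    richness_range: tuple[int, int] = (9, 20)
    geography_effects: dict | None = None  # covariate -> linear coefficient on tau
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_regional < 2:
            raise ValidationError("n_regional must be >= 2")
        if not (self.lam > self.mu >= 0):
            raise ValidationError("require lambda > mu >= 0")
        if self.sigma2 <= 0:
            raise ValidationError("sigma2 must be positive")
        if self.alpha < 0:
            raise ValidationError("alpha must be nonnegative")
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        if self.trait_model not in ("BM", "OU"):
            raise ValidationError("trait_model must be BM or OU")
        if self.assembly_model not in ("neutral", "filtering", "competition"):
            raise ValidationError("unknown assembly model")
        lo, hi = self.richness_range
        if not (2 <= lo <= hi):
            raise ValidationError("richness_range min must be >= 2 and <= max")
        if hi > self.n_regional:
            raise ValidationError("richness_range max exceeds pool size")
        if self.n_communities < 1:
            raise ValidationError("n_communities must be >= 1")


@dataclass
class SyntheticDataset:
    """A generated survey plus the configuration that produced it."""

    regional_tree: Phylogeny
    traits: pd.Series  # log trait per species
    communities: dict[str, list[str]]
    geography: pd.DataFrame
    truth: SyntheticConfig
    community_tau: pd.Series = field(default=None)

    def communities_frame(self) -> pd.DataFrame:
        rows = [(cid, sp) for cid, members in self.communities.items() for sp in members]
        return pd.DataFrame(rows, columns=["community_id", "species"])

    def traits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.traits.index,
                "height_cm": np.exp(self.traits.to_numpy()),
                "log_height": self.traits.to_numpy(),
            }
        )


def generate_regional_pool(config: SyntheticConfig) -> tuple[Phylogeny, pd.Series]:
    """Simulate the regional phylogeny and one trait value per species.

    The birth–death simulation conditions on ``n_regional`` extant tips
    (extinct lineages pruned); the returned tree is ultrametric by
    construction.  Tips are renamed ``sp0000…``.
    """
    rng = np.random.default_rng(config.seed)
    return _generate_pool_rng(config, rng)


def _generate_pool_rng(config: SyntheticConfig, rng) -> tuple[Phylogeny, pd.Series]:
    tree = simulate_birth_death_tree(config.n_regional, config.lam, config.mu, rng)
    labels = [f"sp{i:04d}" for i in range(tree.n_tips)]
    tree.tip_labels = labels
    tree.tip_index = {lab: i for i, lab in enumerate(labels)}
    x = simulate_traits(
        tree,
        rng,
        model=config.trait_model,
        sigma2=config.sigma2,
        alpha=config.alpha,
        theta=config.theta,
    )
    return tree, pd.Series(x, index=labels, name="log_height")


def generate_kipuka_survey(
    pool: tuple[Phylogeny, pd.Series], config: SyntheticConfig
) -> SyntheticDataset:
    """Assemble the local communities and draw their geography covariates.

    Community richness is uniform over ``richness_range``.  When
    ``geography_effects`` maps a covariate name (``area``, ``isolation``,
    ``elevation`` or ``richness``) to a coefficient, each community's
    assembly strength becomes ``tau + coef * z`` where ``z`` is the
    standardized covariate (clipped below at 0.1).
    """
    tree, traits = pool
    if list(traits.index) != list(tree.tip_labels):
        raise ValidationError("pool traits misaligned with tree tips")
    lo, hi = config.richness_range
    if hi > tree.n_tips:
        raise ValidationError("requested richness exceeds pool size")
    rng = np.random.default_rng(
        None if config.seed is None else config.seed + 1_000_003
    )
    m = config.n_communities
    richness = rng.integers(lo, hi + 1, size=m)
    area = np.exp(rng.uniform(np.log(AREA_RANGE[0]), np.log(AREA_RANGE[1]), size=m))
    isolation = np.exp(
        rng.uniform(np.log(ISOLATION_RANGE[0]), np.log(ISOLATION_RANGE[1]), size=m)
    )
    elevation = rng.uniform(*ELEVATION_RANGE, size=m)
    ids = [f"K{i+1:02d}" for i in range(m)]
    geography = pd.DataFrame(
        {
            "community_id": ids,
            "area_m2": area,
            "isolation_m": isolation,
            "elevation_m": elevation,
            "richness": richness,
        }
    )

    covs = {
        "area": np.log(area),
        "isolation": np.log(isolation),
        "elevation": elevation,
        "richness": richness.astype(float),
    }
    tau_c = np.full(m, config.tau)
    if config.geography_effects:
        for name, coef in config.geography_effects.items():
            if name not in covs:
                raise ValidationError(f"unknown geography covariate {name!r}")
            v = covs[name]
            sd = v.std()
            z = (v - v.mean()) / sd if sd > 0 else np.zeros(m)
            tau_c = tau_c + float(coef) * z
    tau_c = np.clip(tau_c, 0.1, None)

    x = traits.to_numpy()
    communities: dict[str, list[str]] = {}
    for i, cid in enumerate(ids):
        params = AssemblyParams(
            model=config.assembly_model,
            tau=float(tau_c[i]),
            lam=config.lam,
            mu=config.mu,
            sigma2=config.sigma2,
            alpha=config.alpha,
            theta=config.theta,
            n_regional=tree.n_tips,
            n_local=int(richness[i]),
        )
        comm = assemble_local((tree, x), params, rng)
        communities[cid] = comm.members

    return SyntheticDataset(
        regional_tree=tree,
        traits=traits,
        communities=communities,
        geography=geography,
        truth=config,
        community_tau=pd.Series(tau_c, index=ids, name="tau"),
    )


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Pool + survey in one call."""
    return generate_kipuka_survey(generate_regional_pool(config), config)


def synthesize_support_table(
    geography: pd.DataFrame,
    effects: dict[tuple[str, str], float] | None = None,
    noise_sd: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-community model-support probabilities with optional planted effects.

    ``effects`` maps ``(response, covariate)`` — e.g.
    ``("p_competition", "richness")`` — to a coefficient on the standardized
    covariate added to that model's logit.  Supports are a softmax of the
    logits plus ``N(0, noise_sd²)`` noise, so rows sum to 1.  Used to
    calibrate and power-test the geography regressions without running the
    full inference chain.
    """
    rng = np.random.default_rng(seed)
    m = len(geography)
    covs = {
        "area": np.log(geography["area_m2"].to_numpy(dtype=float)),
        "isolation": np.log(geography["isolation_m"].to_numpy(dtype=float)),
        "elevation": geography["elevation_m"].to_numpy(dtype=float),
        "richness": geography["richness"].to_numpy(dtype=float),
    }
    responses = ["p_neutral", "p_filtering", "p_competition"]
    eta = rng.normal(0.0, noise_sd, size=(m, 3))
    if effects:
        for (resp, cov), coef in effects.items():
            if resp not in responses:
                raise ValidationError(f"unknown response {resp!r}")
            if cov not in covs:
                raise ValidationError(f"unknown covariate {cov!r}")
            v = covs[cov]
            sd = v.std()
            z = (v - v.mean()) / sd if sd > 0 else np.zeros(m)
            eta[:, responses.index(resp)] += float(coef) * z
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    out = pd.DataFrame(p, columns=responses)
    out.insert(0, "community_id", geography["community_id"].to_numpy())
    if "richness" in geography.columns:
        out["richness"] = geography["richness"].to_numpy()
    return out


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write tree (Newick), traits, communities and geography as plain text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "regional_tree.nwk",
        "traits": outdir / "traits.csv",
        "communities": outdir / "communities.csv",
        "geography": outdir / "geography.csv",
    }
    write_newick(dataset.regional_tree, paths["tree"])
    dataset.traits_frame().to_csv(paths["traits"], index=False)
    dataset.communities_frame().to_csv(paths["communities"], index=False)
    dataset.geography.to_csv(paths["geography"], index=False)
    return paths
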