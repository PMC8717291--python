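"""End-to-end orchestration: data → dispersion → trait fit → simulate → infer → regress.

One :class:`PipelineConfig` and one seed drive the whole analysis; per-stage
seeds are derived from the pipeline seed by fixed offsets and recorded in the
run manifest.  In synthetic mode the input survey is generated with known
ground truth; in real-data mode it is read from files (megaphylogeny Newick,
checklist/trait/community/geography tables) and the community phylogeny is
built by congener resolution and pruning.

The reference table — the expensive stage — is cached on disk keyed by a
content hash of everything that determines it (conditions, priors, sizes,
seed), so re-running inference reuses it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import KipukaError, ValidationError
from .assembly import DEFAULT_PRIORS, simulate_reference_table
from .dispersion import dispersion_report
from .geography import fit_support_regressions
from .inference import abc_reject, predict_model, train_rf
from .phylogeny import read_newick, resolve_names, prune_to_taxa
from .summary_stats import STAT_NAMES, compute_stats
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset
from .trait_models import fit_model

__all__ = ["PipelineConfig", "PipelineResult", "run"]

# fixed per-stage seed offsets
_SEED_DISPERSION = 11
_SEED_REFERENCE = 23
_SEED_FOREST = 37
_SEED_STATS = 53
_SEED_ABC = 71


@dataclass
class PipelineConfig:
    """Inputs and sizes for one full analysis run."""

    synthetic: SyntheticConfig | None = None
    # real-data mode paths
    megaphylogeny: str | None = None
    checklist: str | None = None
    traits: str | None = None
    communities: str | None = None
    geography: str | None = None
    # stage sizes
    n_reps: int = 1000  # dispersion null replicates
    n_per_model: int = 10_000  # reference-table rows per assembly model
    n_trees: int = 1000
    top_k: int = 10
    n_accept: int = 100
    priors: dict = field(default_factory=lambda: dict(DEFAULT_PRIORS))
    fit_trait_models: bool = True
    use_fitted_conditions: bool = False  # else simulate at the config's sigma2/alpha
    seed: int = 0
    outdir: str | None = None
    cache_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_reps", "n_per_model", "n_trees", "top_k", "n_accept"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.synthetic is None:
            needed = ["megaphylogeny", "checklist", "traits", "communities", "geography"]
            missing = [n for n in needed if getattr(self, n) is None]
            if missing:
                raise ValidationError(
                    f"real-data mode needs paths for {missing}; or set `synthetic`"
                )
            for n in needed:
                if not Path(getattr(self, n)).exists():
                    raise ValidationError(f"input file not found: {getattr(self, n)}")


@dataclass
class PipelineResult:
    """Bundle of every stage's output tables."""

    name_resolution: pd.DataFrame | None
    dispersion: pd.DataFrame
    trait_fits: pd.DataFrame | None
    reference: pd.DataFrame
    oob_report: pd.DataFrame
    importance: pd.Series
    support: pd.DataFrame
    regressions: pd.DataFrame
    manifest: dict


def _load_real(config: PipelineConfig):
    mega = read_newick(config.megaphylogeny)
    checklist = pd.read_csv(config.checklist)["species"].astype(str).tolist()
    res = resolve_names(checklist, mega.tip_labels)
    regional_tree = prune_to_taxa(mega, res.final_tips)
    traits_df = pd.read_csv(config.traits)
    traits = pd.Series(
        traits_df["log_height"].to_numpy(), index=traits_df["species"].astype(str)
    )
    comm_df = pd.read_csv(config.communities)
    communities = {
        cid: g["species"].astype(str).tolist() for cid, g in comm_df.groupby("community_id")
    }
    # keep only resolvable members
    tips = set(regional_tree.tip_labels)
    communities = {c: [s for s in m if s in tips] for c, m in communities.items()}
    geography = pd.read_csv(config.geography)
    return res.to_frame(), regional_tree, traits, communities, geography


def _reference_cache_key(conditions: dict, config: PipelineConfig) -> str:
    payload = json.dumps(
        {
            "conditions": conditions,
            "priors": {k: list(v) for k, v in config.priors.items()},
            "n_per_model": config.n_per_model,
            "seed": config.seed + _SEED_REFERENCE,
            "stats": STAT_NAMES,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; any stage error aborts with the stage named."""
    t0 = time.time()
    timings: dict[str, float] = {}
    manifest: dict = {"seed": config.seed, "stages": timings}
    stage = "load"
    try:
        if config.synthetic is not None:
            syn = SyntheticConfig(**{**asdict(config.synthetic), "seed": config.seed})
            dataset: SyntheticDataset = generate_dataset(syn)
            name_resolution = None
            regional_tree = dataset.regional_tree
            traits = dataset.traits
            communities = dataset.communities
            geography = dataset.geography
            manifest["mode"] = "synthetic"
            manifest["truth_model"] = syn.assembly_model
        else:
            name_resolution, regional_tree, traits, communities, geography = _load_real(config)
            manifest["mode"] = "real"
        timings[stage] = time.time() - t0

        stage = "dispersion"
        t = time.time()
        disp = dispersion_report(
            regional_tree,
            communities,
            traits=traits,
            n_reps=config.n_reps,
            seed=config.seed + _SEED_DISPERSION,
        )
        timings[stage] = time.time() - t

        stage = "trait_fit"
        t = time.time()
        trait_fits = None
        if config.fit_trait_models:
            fits = [
                fit_model(regional_tree, traits, "BM"),
                fit_model(regional_tree, traits, "OU", alpha_bound=1.0, seed=config.seed),
            ]
            trait_fits = pd.DataFrame(
                [
                    {
                        "model": f.model,
                        "sigma2": f.sigma2,
                        "alpha": f.alpha,
                        "theta": f.theta,
                        "z0": f.z0,
                        "loglik": f.loglik,
                        "aic": f.aic,
                        "alpha_bound": f.alpha_bound,
                    }
                    for f in fits
                ]
            )
        timings[stage] = time.time() - t

        stage = "reference_table"
        t = time.time()
        if config.use_fitted_conditions and trait_fits is not None:
            ou = trait_fits.loc[trait_fits["model"] == "OU"].iloc[0]
            sim_sigma2, sim_alpha, sim_theta = (
                float(ou["sigma2"]),
                float(ou["alpha"]),
                float(ou["theta"]),
            )
        elif config.synthetic is not None:
            sim_sigma2, sim_alpha, sim_theta = syn.sigma2, syn.alpha, syn.theta
        else:
            sim_sigma2, sim_alpha, sim_theta = 0.92, 0.2, float(np.mean(traits))
        conditions = {
            "n_regional": regional_tree.n_tips,
            "n_local_values": sorted({len(m) for m in communities.values()}),
            "sigma2": sim_sigma2,
            "alpha": sim_alpha,
            "theta": sim_theta,
        }
        manifest["conditions"] = conditions
        reference = None
        cache_path = None
        if config.cache_dir is not None:
            key = _reference_cache_key(conditions, config)
            cache_path = Path(config.cache_dir) / f"reference_{key}.csv"
            if cache_path.exists():
                reference = pd.read_csv(cache_path)
                manifest["reference_cached"] = True
        if reference is None:
            reference = simulate_reference_table(
                config.n_per_model,
                data_conditions=conditions,
                priors=config.priors,
                seed=config.seed + _SEED_REFERENCE,
            )
            manifest["reference_cached"] = False
            if cache_path is not None:
                cache_path.parent.mkdir(parents=True, exist_ok=True)
                reference.to_csv(cache_path, index=False)
        timings[stage] = time.time() - t

        stage = "random_forest"
        t = time.time()
        classifier = train_rf(
            reference, n_trees=config.n_trees, seed=config.seed + _SEED_FOREST
        )
        oob_report = pd.DataFrame(
            [{"label": "overall", "oob_error": classifier.result.oob_overall}]
            + [
                {"label": m, "oob_error": e}
                for m, e in classifier.result.oob_by_model.items()
            ]
        )
        timings[stage] = time.time() - t

        stage = "community_inference"
        t = time.time()
        obs_rows = {}
        for j, (cid, members) in enumerate(sorted(communities.items())):
            obs_rows[cid] = compute_stats(
                regional_tree, traits, members, seed=config.seed + _SEED_STATS + j
            )
        observed = pd.DataFrame(obs_rows).T
        probs = predict_model(classifier, observed)
        filtering_rows = reference.loc[reference["model"] == "filtering"]
        support_rows = []
        for j, cid in enumerate(observed.index):
            abc = abc_reject(
                filtering_rows,
                observed.loc[cid],
                classifier.result.importance,
                top_k=config.top_k,
                n_accept=min(config.n_accept, len(filtering_rows)),
                seed=config.seed + _SEED_ABC + j,
            )
            support_rows.append(
                {
                    "community_id": cid,
                    "p_neutral": probs.loc[cid, "neutral"],
                    "p_filtering": probs.loc[cid, "filtering"],
                    "p_competition": probs.loc[cid, "competition"],
                    "median_t": abc.median_t,
                    "hdi90_lo": abc.hdi90[0],
                    "hdi90_hi": abc.hdi90[1],
                    "hdi95_lo": abc.hdi95[0],
                    "hdi95_hi": abc.hdi95[1],
                }
            )
        support = pd.DataFrame(support_rows)
        timings[stage] = time.time() - t

        stage = "geography"
        t = time.time()
        _, regressions = fit_support_regressions(support, geography, skip_infeasible=True)
        timings[stage] = time.time() - t
    except KipukaError as exc:
        raise KipukaError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["n_communities"] = len(communities)
    manifest["n_reference_rows"] = len(reference)
    manifest["total_seconds"] = time.time() - t0

    result = PipelineResult(
        name_resolution=name_resolution,
        dispersion=disp,
        trait_fits=trait_fits,
        reference=reference,
        oob_report=oob_report,
        importance=classifier.result.importance,
        support=support,
        regressions=regressions,
        manifest=manifest,
    )
    if config.outdir is not None:
        _write_outputs(result, Path(config.outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if result.name_resolution is not None:
        result.name_resolution.to_csv(outdir / "name_resolution.csv", index=False)
    result.dispersion.to_csv(outdir / "dispersion.csv", index=False)
    if result.trait_fits is not None:
        result.trait_fits.to_csv(outdir / "trait_fits.csv", index=False)
    result.reference.to_csv(outdir / "reference_table.csv", index=False)
    result.oob_report.to_csv(outdir / "oob_report.csv", index=False)
    result.importance.rename("importance").to_csv(outdir / "importance.csv")
    result.support.to_csv(outdir / "support_table.csv", index=False)
    result.regressions.to_csv(outdir / "regressions.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
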