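"""The fixed 30-statistic summary of a (regional tree, traits, community) triple.

One vector feeds both the random-forest model selection and rejection ABC, so
the registry is frozen: 30 named statistics in fixed order, spanning local and
regional trait moments, phylogenetic dispersion of the community on the
regional tree (with small internal randomisation nulls), phylogenetic signal,
tree shape, distance–trait coupling, and trait-spacing extremes.  The list is
isolated here so it can be swapped without touching the inference machinery.

Degenerate inputs (zero-variance traits, zero-spread nulls) produce documented
sentinel values of 0 rather than NaN.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ._errors import ValidationError
from .phylogeny import Phylogeny, bm_pruning

__all__ = ["STAT_NAMES", "STAT_GROUPS", "compute_stats", "compute_stats_fast", "scale_by_sd", "registry_manifest"]

#: Fixed registry: (name, group) in vector order.
STAT_GROUPS: list[tuple[str, str]] = [
    ("local_trait_mean", "local trait moments"),
    ("local_trait_var", "local trait moments"),
    ("local_trait_skew", "local trait moments"),
    ("local_trait_kurt", "local trait moments"),
    ("local_trait_range", "local trait moments"),
    ("local_trait_median", "local trait moments"),
    ("regional_trait_mean", "regional trait moments"),
    ("regional_trait_var", "regional trait moments"),
    ("trait_mean_ratio", "local/regional ratios"),
    ("trait_var_ratio", "local/regional ratios"),
    ("mpd_local", "phylogenetic dispersion"),
    ("mntd_local", "phylogenetic dispersion"),
    ("ses_mpd", "phylogenetic dispersion"),
    ("ses_mntd", "phylogenetic dispersion"),
    ("faith_pd", "phylogenetic dispersion"),
    ("pd_per_species", "phylogenetic dispersion"),
    ("mean_branch_length", "phylogenetic dispersion"),
    ("tree_height", "phylogenetic dispersion"),
    ("blomberg_k_local", "phylogenetic signal"),
    ("blomberg_k_regional", "phylogenetic signal"),
    ("colless", "tree shape"),
    ("gamma", "tree shape"),
    ("richness_ratio", "tree shape"),
    ("local_richness", "tree shape"),
    ("dist_trait_cor_local", "distance-trait coupling"),
    ("dist_trait_cor_regional", "distance-trait coupling"),
    ("min_nn_trait_dist", "trait spacing extremes"),
    ("max_nn_trait_dist", "trait spacing extremes"),
    ("local_trait_gini", "trait spacing extremes"),
    ("mpd_ratio", "trait spacing extremes"),
]
STAT_NAMES: list[str] = [n for n, _ in STAT_GROUPS]
N_SES_REPS = 64  # internal null size; SES enters only as a classifier feature


def registry_manifest() -> pd.DataFrame:
    """Machine-readable statistic registry (name, group, position)."""
    return pd.DataFrame(
        [(i, n, g) for i, (n, g) in enumerate(STAT_GROUPS)],
        columns=["position", "name", "group"],
    )


def _moments(x: np.ndarray) -> tuple[float, float, float, float, float, float]:
    v = float(np.var(x, ddof=1)) if x.size > 1 else 0.0
    if v > 1e-300:
        skew = float(sstats.skew(x))
        kurt = float(sstats.kurtosis(x))
    else:
        skew, kurt = 0.0, 0.0
    return (
        float(np.mean(x)),
        v,
        skew,
        kurt,
        float(np.max(x) - np.min(x)),
        float(np.median(x)),
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) < 1e-300 or np.std(b) < 1e-300:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _gini(values: np.ndarray) -> float:
    """Gini coefficient of positive values (heights on the cm scale)."""
    v = np.sort(values)
    n = v.size
    total = v.sum()
    if total <= 0:
        return 0.0
    cum = np.cumsum(v)
    return float((n + 1 - 2 * (cum / total).sum()) / n)


def _blomberg_k_from_tree(tree: Phylogeny, x: np.ndarray) -> float:
    """Blomberg's K; 0 sentinel when trait variance vanishes."""
    n = tree.n_tips
    if np.var(x) < 1e-300 or n < 3:
        return 0.0
    root_val, root_var, ss, _ = bm_pruning(tree, x)
    mse0 = float(np.sum((x - root_val) ** 2)) / (n - 1)
    mse = ss / (n - 1)
    expected = (float(tree.tip_depths().sum()) - n * root_var) / (n - 1)
    if mse <= 0 or expected <= 0:
        return 0.0
    return (mse0 / mse) / expected


def compute_stats_fast(
    regional_tree: Phylogeny,
    regional_traits: np.ndarray,
    member_idx: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Array fast path: community given as tip positions on the regional tree."""
    x_reg = np.asarray(regional_traits, dtype=np.float64)
    idx = np.asarray(member_idx, dtype=np.int64)
    k = idx.size
    if k < 2:
        raise ValidationError("community must have at least two members")
    n = regional_tree.n_tips
    x_loc = x_reg[idx]

    D = regional_tree.patristic_matrix()
    iu_loc = np.triu_indices(k, 1)
    Dloc = D[np.ix_(idx, idx)]
    mpd_loc = float(Dloc[iu_loc].mean())
    np.fill_diagonal(Dloc, np.inf)
    mntd_loc = float(Dloc.min(axis=1).mean())
    np.fill_diagonal(Dloc, 0.0)

    # regional MPD in O(n) from MRCA depths: sum over pairs of 2(T_i+T_j)/2 - 2 s
    iu_reg_mean_d = _mean_pairwise(D)

    # internal nulls for SES (uniform richness-preserving resamples of the pool)
    null_mpd = np.empty(N_SES_REPS)
    null_mntd = np.empty(N_SES_REPS)
    for r in range(N_SES_REPS):
        sub = rng.choice(n, size=k, replace=False)
        Ds = D[np.ix_(sub, sub)]
        null_mpd[r] = Ds[iu_loc].mean()
        np.fill_diagonal(Ds, np.inf)
        null_mntd[r] = Ds.min(axis=1).mean()
    ses_mpd = _ses(mpd_loc, null_mpd)
    ses_mntd = _ses(mntd_loc, null_mntd)

    # Faith PD of the community (minimal spanning subtree incl. root)
    ind = np.zeros(n)
    ind[idx] = 1.0
    csum = np.concatenate([[0.0], np.cumsum(ind)])
    counts = csum[regional_tree.tip_hi] - csum[regional_tree.tip_lo]
    pd_val = float(regional_tree.blen[counts > 0].sum())

    # local community subtree for local phylogenetic signal
    members = [regional_tree.tip_labels[i] for i in idx]
    local_tree = regional_tree.prune(members)
    x_loc_tree = x_reg[[regional_tree.tip_index[t] for t in local_tree.tip_labels]]

    m_loc = _moments(x_loc)
    mean_reg = float(np.mean(x_reg))
    var_reg = float(np.var(x_reg, ddof=1))

    t_abs_loc = np.abs(x_loc[:, None] - x_loc[None, :])
    nn_trait = np.where(np.eye(k, dtype=bool), np.inf, t_abs_loc).min(axis=1)
    t_abs_reg_flat = np.abs(x_reg[:, None] - x_reg[None, :])[np.triu_indices(n, 1)]

    vals = [
        *m_loc,
        mean_reg,
        var_reg,
        m_loc[0] / mean_reg if abs(mean_reg) > 1e-300 else 0.0,
        m_loc[1] / var_reg if var_reg > 1e-300 else 0.0,
        mpd_loc,
        mntd_loc,
        ses_mpd,
        ses_mntd,
        pd_val,
        pd_val / k,
        float(regional_tree.blen[1:].mean()),
        regional_tree.height,
        _blomberg_k_from_tree(local_tree, x_loc_tree),
        _blomberg_k_from_tree(regional_tree, x_reg),
        regional_tree.colless_index(),
        regional_tree.gamma_statistic(),
        k / n,
        float(k),
        _safe_corr(Dloc[iu_loc], t_abs_loc[iu_loc]),
        _safe_corr(D[np.triu_indices(n, 1)], t_abs_reg_flat),
        float(nn_trait.min()),
        float(nn_trait.max()),
        _gini(np.exp(x_loc)),
        mpd_loc / iu_reg_mean_d if iu_reg_mean_d > 0 else 0.0,
    ]
    return np.array(vals)


def _mean_pairwise(D: np.ndarray) -> float:
    n = D.shape[0]
    return float((D.sum() / 2.0) / (n * (n - 1) / 2.0))


def _ses(obs: float, null: np.ndarray) -> float:
    sd = float(null.std(ddof=1))
    if sd < 1e-300:
        return 0.0
    return (obs - float(null.mean())) / sd


def compute_stats(
    regional_tree: Phylogeny,
    regional_traits: pd.Series | dict,
    community: Sequence[str],
    seed: int | None = None,
) -> pd.Series:
    """Summary-statistic vector for a named community on the regional tree.

    ``regional_traits`` maps species to log-trait values and must cover all
    tips; ``community`` is a subset of the tip labels.  The internal SES nulls
    are seeded by ``seed``.
    """
    traits = pd.Series(regional_traits)
    missing = [t for t in regional_tree.tip_labels if t not in traits.index]
    if missing:
        raise ValidationError(f"traits missing for tips: {missing[:5]}")
    comm = list(dict.fromkeys(community))
    bad = [c for c in comm if c not in regional_tree.tip_index]
    if bad:
        raise ValidationError(f"community members not in tree: {bad}")
    if len(comm) < 2:
        raise ValidationError("community must have at least two members")
    x_reg = traits.reindex(regional_tree.tip_labels).to_numpy(dtype=float)
    idx = np.array(sorted(regional_tree.tip_index[c] for c in comm))
    rng = np.random.default_rng(seed)
    vals = compute_stats_fast(regional_tree, x_reg, idx, rng)
    return pd.Series(vals, index=STAT_NAMES)


def scale_by_sd(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Divide each column by its standard deviation across rows.

    Returns ``(scaled, factors, flagged)``; columns with zero spread are left
    unscaled (factor 1) and listed in ``flagged``.  Applying the returned
    ``factors`` to held-out rows reproduces the training transform.
    """
    if len(table) < 2:
        raise ValidationError("scaling needs at least two rows")
    sd = table.std(ddof=1)
    flagged = sorted(sd.index[(sd == 0) | ~np.isfinite(sd)])
    factors = sd.mask((sd == 0) | ~np.isfinite(sd), 1.0)
    return table / factors, factors, flagged
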