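"""Community dispersion metrics and richness-preserving null-model tests.

Mean pairwise distance (MPD) and mean nearest-taxon distance (MNTD) are
computed on either patristic (phylogenetic) or absolute log-trait
(phenotypic) distances.  Each observed community is tested against a null in
which the same number of species is resampled uniformly without replacement
from the regional pool; the standardized effect size (SES), the rank of the
observed value within the null replicates, and a rank-based p-value classify
the community as *clustered* (habitat filtering signal), *neutral*, or
*overdispersed* (competitive exclusion signal).

Conventions: ``p = rank / n_reps`` with ``rank = #{null <= observed}`` (ties
count toward the rank); clustered when ``p < .025``, overdispersed when
``p > .975`` (two-tailed 5%).

Blomberg's K measures phylogenetic signal in a continuous trait: the ratio of
observed to Brownian-expected ``MSE0/MSE``, equal to 1 in expectation under
Brownian motion and falling toward 0 as signal is destroyed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import DataError, ValidationError
from .phylogeny import Phylogeny, bm_pruning

__all__ = [
    "DistanceMatrix",
    "DispersionResult",
    "patristic_matrix",
    "trait_distance_matrix",
    "mpd",
    "mntd",
    "ses_null_test",
    "blomberg_k",
    "dispersion_report",
]


class DistanceMatrix:
    """Square symmetric nonnegative distance matrix indexed by species labels."""

    def __init__(self, values: np.ndarray, labels: Sequence[str]) -> None:
        values = np.asarray(values, dtype=np.float64)
        labels = list(labels)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValidationError("distance matrix must be square")
        if values.shape[0] != len(labels):
            raise ValidationError("labels must match matrix dimension")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(values) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(values < 0):
            raise ValidationError("distances must be nonnegative")
        self.values = values
        self.labels = labels
        self.index = {lab: i for i, lab in enumerate(labels)}

    def positions(self, species: Sequence[str]) -> np.ndarray:
        missing = [s for s in species if s not in self.index]
        if missing:
            raise ValidationError(f"species not in distance matrix: {missing}")
        return np.array([self.index[s] for s in species], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def patristic_matrix(tree: Phylogeny) -> DistanceMatrix:
    """Pairwise sum of branch lengths along tip-to-tip paths."""
    if tree.n_tips < 2:
        raise ValidationError("tree must have at least two tips")
    return DistanceMatrix(tree.patristic_matrix(), tree.tip_labels)


def trait_distance_matrix(traits: Mapping[str, float] | pd.Series) -> DistanceMatrix:
    """Absolute pairwise differences of log-trait values."""
    s = pd.Series(traits, dtype=float)
    bad = s.index[~np.isfinite(s.to_numpy())].tolist()
    if bad:
        raise DataError(f"missing or non-finite trait value for: {bad}")
    x = s.to_numpy()
    return DistanceMatrix(np.abs(x[:, None] - x[None, :]), list(s.index))


def _mpd_from_values(D: np.ndarray, idx: np.ndarray) -> float:
    k = idx.size
    sub = D[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


def _mntd_from_values(D: np.ndarray, idx: np.ndarray) -> float:
    sub = D[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def mpd(community: Sequence[str], dist: DistanceMatrix) -> float:
    """Mean distance over all unordered within-community pairs."""
    comm = list(dict.fromkeys(community))
    if len(comm) < 2:
        raise ValidationError("MPD needs a community of at least two species")
    return _mpd_from_values(dist.values, dist.positions(comm))


def mntd(community: Sequence[str], dist: DistanceMatrix) -> float:
    """Mean distance from each member to its nearest other member."""
    comm = list(dict.fromkeys(community))
    if len(comm) < 2:
        raise ValidationError("MNTD needs a community of at least two species")
    return _mntd_from_values(dist.values, dist.positions(comm))


@dataclass
class DispersionResult:
    """One community's dispersion test against the richness-preserving null."""

    metric: str
    basis: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when the null has zero spread
    rank: int  # count of null replicates <= observed
    p: float  # rank / n_reps
    n_reps: int
    verdict: str  # clustered | neutral | overdispersed


def ses_null_test(
    community: Sequence[str],
    regional_pool: Sequence[str],
    dist: DistanceMatrix,
    metric: str = "MPD",
    basis: str = "phylogenetic",
    n_reps: int = 1000,
    seed: int | None = None,
) -> DispersionResult:
    """Test a community's MPD or MNTD against uniform resampling from the pool.

    Null replicate ``r`` draws ``|community|`` species uniformly without
    replacement from ``regional_pool`` and recomputes the metric.  The verdict
    is *clustered* when ``p < .025``, *overdispersed* when ``p > .975``, else
    *neutral*.  A zero-spread null (e.g. community == pool) yields an
    undefined SES with a warning and a verdict taken from the observed value's
    position relative to the degenerate null.
    """
    if metric not in ("MPD", "MNTD"):
        raise ValidationError(f"metric must be MPD or MNTD, got {metric!r}")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    comm = list(dict.fromkeys(community))
    pool = list(dict.fromkeys(regional_pool))
    if not set(comm) <= set(pool):
        raise ValidationError("community must be a subset of the regional pool")
    if len(comm) > len(pool):
        raise ValidationError("community larger than regional pool")
    k = len(comm)
    if k < 2:
        raise ValidationError("community must have at least two species")

    fn = _mpd_from_values if metric == "MPD" else _mntd_from_values
    D = dist.values
    observed = fn(D, dist.positions(comm))
    pool_idx = dist.positions(pool)
    rng = np.random.default_rng(seed)
    # uniform k-subsets of the pool, all replicates at once
    subs = pool_idx[np.argpartition(rng.random((n_reps, pool_idx.size)), k - 1, axis=1)[:, :k]]
    S = D[subs[:, :, None], subs[:, None, :]]
    if metric == "MPD":
        null = S.sum(axis=(1, 2)) / (k * (k - 1))
    else:
        S[:, np.arange(k), np.arange(k)] = np.inf
        null = S.min(axis=2).mean(axis=1)

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_reps > 1 else 0.0
    rank = int(np.count_nonzero(null <= observed))
    p = rank / n_reps
    if null_sd > 0:
        ses = (observed - null_mean) / null_sd
        verdict = "clustered" if p < 0.025 else ("overdispersed" if p > 0.975 else "neutral")
    else:
        warnings.warn("null distribution has zero spread; SES undefined", stacklevel=2)
        ses = float("nan")
        scale = max(abs(null_mean), 1.0)
        if abs(observed - null_mean) <= 1e-9 * scale:
            verdict = "neutral"
        else:
            verdict = "clustered" if observed < null_mean else "overdispersed"
    return DispersionResult(
        metric=metric,
        basis=basis,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        ses=ses,
        rank=rank,
        p=p,
        n_reps=n_reps,
        verdict=verdict,
    )


def blomberg_k(tree: Phylogeny, traits: Mapping[str, float] | pd.Series | np.ndarray) -> float:
    """Blomberg's K for a continuous trait on a tree (K = 1 expected under BM).

    ``K = (MSE0/MSE) / E[MSE0/MSE]`` with ``MSE0`` the trait mean squared
    deviation from the phylogenetic (GLS) mean, ``MSE`` the Brownian GLS mean
    square, and the expectation ``(tr(V) − n/(1'V⁻¹1))/(n−1)`` taken under
    Brownian motion on the same tree.
    """
    if isinstance(traits, (pd.Series, Mapping)):
        s = pd.Series(traits, dtype=float)
        missing = [t for t in tree.tip_labels if t not in s.index]
        if missing:
            raise DataError(f"traits missing for tips: {missing[:5]}")
        x = s.reindex(tree.tip_labels).to_numpy()
    else:
        x = np.asarray(traits, dtype=float)
        if x.shape[0] != tree.n_tips:
            raise ValidationError("trait vector length must equal tip count")
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite trait values")
    n = tree.n_tips
    if n < 3:
        raise ValidationError("Blomberg's K needs at least three tips")
    if np.var(x) < 1e-300:
        raise DataError("trait variance is zero; K undefined")
    root_val, root_var, ss, _ = bm_pruning(tree, x)
    mse0 = float(np.sum((x - root_val) ** 2)) / (n - 1)
    mse = ss / (n - 1)
    expected = (float(tree.tip_depths().sum()) - n * root_var) / (n - 1)
    return (mse0 / mse) / expected


def dispersion_report(
    tree: Phylogeny,
    communities: Mapping[str, Sequence[str]],
    traits: Mapping[str, float] | pd.Series | None = None,
    regional_pool: Sequence[str] | None = None,
    n_reps: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-community MPD/MNTD null tests on phylogenetic (and optionally trait) distances.

    Returns a tidy frame with one row per (community, metric, basis):
    columns ``community_id, metric, basis, observed, ses, rank, p, verdict``.
    """
    pool = list(regional_pool) if regional_pool is not None else list(tree.tip_labels)
    bases: list[tuple[str, DistanceMatrix]] = [("phylogenetic", patristic_matrix(tree))]
    if traits is not None:
        t = pd.Series(traits, dtype=float).reindex(pool)
        bases.append(("phenotypic", trait_distance_matrix(t)))
    rng = np.random.default_rng(seed)
    rows = []
    for cid, members in communities.items():
        for basis, dist in bases:
            for metric in ("MPD", "MNTD"):
                res = ses_null_test(
                    members,
                    pool,
                    dist,
                    metric=metric,
                    basis=basis,
                    n_reps=n_reps,
                    seed=int(rng.integers(2**31)),
                )
                rows.append(
                    {
                        "community_id": cid,
                        "metric": metric,
                        "basis": basis,
                        "observed": res.observed,
                        "ses": res.ses,
                        "rank": res.rank,
                        "p": res.p,
                        "verdict": res.verdict,
                    }
                )
    return pd.DataFrame(rows)
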