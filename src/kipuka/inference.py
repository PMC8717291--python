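"""Random-forest model selection and rejection-ABC estimation of assembly strength.

A 1000-tree classification forest is trained on the reference table's 30
summary statistics to distinguish neutral, habitat-filtering, and
competitive-exclusion assembly.  Accuracy is reported as the out-of-bag (OOB)
misclassification rate, overall and per model, and the forest's vote
fractions give per-community model probabilities for observed data.

Statistic informativeness is measured by permutation importance evaluated on
each tree's out-of-bag rows.  The top-ranked statistics then drive rejection
ABC for the filtering-strength parameter t: reference rows simulated under
the best model are ranked by Euclidean distance on SD-scaled statistics and
the closest ``n_accept`` rows' t values form the posterior sample, summarised
by its median and highest-density intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._errors import ContractError, ValidationError
from .summary_stats import STAT_NAMES

__all__ = [
    "MODEL_ORDER",
    "AssemblyClassifier",
    "ModelSelectionResult",
    "ABCResult",
    "train_rf",
    "predict_model",
    "abc_reject",
    "hdi",
]

MODEL_ORDER = ("neutral", "filtering", "competition")


@dataclass
class ModelSelectionResult:
    """OOB accuracy and statistic importance of a trained classification forest."""

    oob_overall: float
    oob_by_model: dict[str, float]
    importance: pd.Series  # descending
    per_community_probs: pd.DataFrame | None = None


@dataclass
class AssemblyClassifier:
    """A fitted forest bound to the statistic registry it was trained on."""

    forest: RandomForestClassifier
    stat_names: list[str]
    result: ModelSelectionResult


def _oob_indices_per_tree(forest: RandomForestClassifier, n_samples: int):
    """Out-of-bag row indices for every tree (mirrors the forest's bootstrap)."""
    from sklearn.ensemble._forest import (  # same helpers the forest uses internally
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    import inspect

    if "sample_weight" in inspect.signature(_get_n_samples_bootstrap).parameters:
        n_boot = _get_n_samples_bootstrap(n_samples, forest.max_samples, None)
        return [
            _generate_unsampled_indices(est.random_state, n_samples, n_boot, None)
            for est in forest.estimators_
        ]
    n_boot = _get_n_samples_bootstrap(n_samples, forest.max_samples)
    return [
        _generate_unsampled_indices(est.random_state, n_samples, n_boot)
        for est in forest.estimators_
    ]


def _oob_permutation_importance(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y_codes: np.ndarray,
    seed: int,
    n_trees_used: int = 200,
) -> np.ndarray:
    """Mean OOB accuracy drop per feature when that feature is permuted.

    Evaluated on a fixed subset of trees for throughput; deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    oob_idx = _oob_indices_per_tree(forest, n)
    use = range(min(n_trees_used, len(forest.estimators_)))
    drops = np.zeros(p)
    counts = 0
    for ti in use:
        est = forest.estimators_[ti]
        idx = oob_idx[ti]
        if idx.size == 0:
            continue
        Xo = X[idx]
        yo = y_codes[idx]
        base = float(np.mean(est.predict(Xo) == yo))
        perm = rng.permutation(idx.size)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            drops[j] += base - float(np.mean(est.predict(Xp) == yo))
        counts += 1
    if counts == 0:
        raise ValidationError("no out-of-bag rows available for importance")
    return drops / counts


def train_rf(
    reference: pd.DataFrame,
    n_trees: int = 1000,
    seed: int = 0,
    compute_importance: bool = True,
    n_trees_importance: int = 200,
) -> AssemblyClassifier:
    """Train the classification forest on a reference table.

    ``reference`` must carry a ``model`` label column and the 30 statistic
    columns.  Requires at least two labels with >= 10 rows each.  OOB errors
    come from the forest's out-of-bag votes.
    """
    missing = [c for c in STAT_NAMES if c not in reference.columns]
    if missing:
        raise ContractError(f"reference table missing statistics: {missing[:5]}")
    counts = reference["model"].value_counts()
    if len(counts) < 2:
        raise ValidationError("reference table has a single model label")
    if (counts < 10).any():
        raise ValidationError("each model label needs at least 10 rows")

    X = reference[STAT_NAMES].to_numpy(dtype=np.float64)
    labels = reference["model"].to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, labels)

    oob_prob = forest.oob_decision_function_
    valid = ~np.isnan(oob_prob).any(axis=1)
    pred = forest.classes_[np.argmax(oob_prob[valid], axis=1)]
    truth = labels[valid]
    oob_overall = float(np.mean(pred != truth))
    oob_by_model = {
        m: float(np.mean(pred[truth == m] != m)) for m in counts.index if (truth == m).any()
    }

    if compute_importance:
        class_codes = {c: i for i, c in enumerate(forest.classes_)}
        y_codes = np.array([class_codes[m] for m in labels])
        imp = _oob_permutation_importance(
            forest, X, y_codes, seed=seed + 1, n_trees_used=n_trees_importance
        )
        importance = pd.Series(imp, index=STAT_NAMES).sort_values(ascending=False)
    else:
        importance = pd.Series(dtype=float)

    result = ModelSelectionResult(oob_overall, oob_by_model, importance)
    return AssemblyClassifier(forest, list(STAT_NAMES), result)


def predict_model(classifier: AssemblyClassifier, observed) -> pd.DataFrame:
    """Vote-fraction model probabilities for observed statistic vectors.

    ``observed`` is a Series (one community) or DataFrame (one row per
    community) indexed/columned by the statistic registry.  Output columns are
    fixed to (neutral, filtering, competition) and rows sum to 1.
    """
    if isinstance(observed, pd.Series):
        obs = observed.to_frame().T
    else:
        obs = pd.DataFrame(observed)
    missing = [c for c in classifier.stat_names if c not in obs.columns]
    if missing:
        raise ContractError(f"observed vector missing statistics: {missing[:5]}")
    X = obs[classifier.stat_names].to_numpy(dtype=np.float64)
    probs = classifier.forest.predict_proba(X)
    out = pd.DataFrame(probs, columns=classifier.forest.classes_, index=obs.index)
    present = [m for m in MODEL_ORDER if m in out.columns]
    out = out[present]
    for m in MODEL_ORDER:
        if m not in out.columns:
            out[m] = 0.0
    return out[list(MODEL_ORDER)]


@dataclass
class ABCResult:
    """Rejection-ABC posterior sample for the assembly-strength parameter t."""

    accepted: np.ndarray
    median_t: float
    hdi90: tuple[float, float]
    hdi95: tuple[float, float]
    n_accepted: int
    distance_quantile: float
    top_stats: list[str] = field(default_factory=list)


def abc_reject(
    reference_rows: pd.DataFrame,
    observed: pd.Series,
    importance: pd.Series,
    top_k: int = 10,
    n_accept: int = 100,
    seed: int = 0,
    param: str = "tau",
) -> ABCResult:
    """Accept the ``n_accept`` reference rows closest to the observed statistics.

    Distance is Euclidean on the ``top_k`` most important statistics, each
    scaled by its standard deviation across the reference rows.  Ties at the
    acceptance cutoff are broken by row order after a seeded shuffle.
    """
    if len(reference_rows) < n_accept:
        raise ValidationError(
            f"need at least n_accept={n_accept} reference rows, have {len(reference_rows)}"
        )
    if importance.empty:
        raise ValidationError("importance ranking required to choose top statistics")
    top = [s for s in importance.index if s in reference_rows.columns][:top_k]
    if not top:
        raise ContractError("no importance-ranked statistics present in reference rows")
    ref = reference_rows[top].to_numpy(dtype=np.float64)
    sd = ref.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    obs = observed.reindex(top).to_numpy(dtype=np.float64)
    if np.any(~np.isfinite(obs)):
        raise ValidationError("observed vector missing one of the top statistics")
    d = np.sqrt((((ref - obs) / sd) ** 2).sum(axis=1))

    rng = np.random.default_rng(seed)
    shuffle = rng.permutation(d.size)
    order = shuffle[np.argsort(d[shuffle], kind="stable")]
    take = order[:n_accept]
    accepted = reference_rows[param].to_numpy()[take]
    return ABCResult(
        accepted=accepted,
        median_t=float(np.median(accepted)),
        hdi90=hdi(accepted, 0.90),
        hdi95=hdi(accepted, 0.95),
        n_accepted=n_accept,
        distance_quantile=float(n_accept / d.size),
        top_stats=top,
    )


def hdi(sample, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sample points."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2:
        raise ValidationError("HDI needs at least two sample points")
    if not (0 < mass < 1):
        raise ValidationError("mass must be in (0, 1)")
    m = int(np.ceil(mass * n))
    m = min(max(m, 2), n)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])
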