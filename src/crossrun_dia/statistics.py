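"""Target-decoy statistical validation with multi-run features.

A semi-supervised discriminant (random forest or gradient-boosted
trees) separates target from decoy peak groups using the four
single-run scores, the four multi-run scores and simple auxiliary
features (delta RT, peptide length, charge). Training follows the
iterative scheme familiar from semi-supervised reranking: start from
the main single-run score, repeatedly train on decoys versus the
currently best-scoring targets, and score every row out-of-fold so no
row is scored by a model that saw it.

The discriminant scores feed a decoy-based q-value estimate, and for
two-species entrapment designs the module provides the lower/upper
empirical FDR bounds based on entrapment identifications in runs known
to lack the entrapment species, with ``r`` the effective entrapment
fraction of the library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GroupKFold, KFold

__all__ = [
    "SINGLE_RUN_FEATURES",
    "MULTI_RUN_FEATURES",
    "AUX_FEATURES",
    "EntrapmentCounts",
    "DiscriminantResult",
    "feature_matrix",
    "learn_discriminant",
    "estimate_qvalues",
    "two_species_fdr",
    "feature_importance",
    "ablate_multirun",
    "score_and_qvalues",
]

SINGLE_RUN_FEATURES = ["sr_main", "sr_spectral_cosine", "sr_ms1_area", "sr_ms2_area"]
MULTI_RUN_FEATURES = ["mr_main", "mr_spectral_cosine", "mr_ms1_area", "mr_ms2_area"]
AUX_FEATURES = ["delta_rt", "peptide_length", "charge"]
ALL_FEATURES = SINGLE_RUN_FEATURES + MULTI_RUN_FEATURES + AUX_FEATURES


@dataclass(frozen=True)
class EntrapmentCounts:
    """Identification counts in the entrapment-free runs.

    ``n_entrapment`` — entrapment-species peptides identified where they
    are truly absent; ``n_native`` — native peptides identified in the
    same runs; ``r`` — effective entrapment fraction of the library.
    """

    n_entrapment: int
    n_native: int
    r: float


@dataclass
class DiscriminantResult:
    scores: np.ndarray
    model: object
    feature_names: list[str]


def feature_matrix(table: pd.DataFrame, feature_names: list[str] | None = None) -> np.ndarray:
    """Extract the feature matrix with per-column median imputation."""
    names = feature_names or [c for c in ALL_FEATURES if c in table.columns]
    X = table[names].to_numpy(dtype=float)
    for j in range(X.shape[1]):
        col = X[:, j]
        bad = ~np.isfinite(col)
        if bad.any():
            med = np.nanmedian(np.where(np.isfinite(col), col, np.nan))
            X[bad, j] = med if np.isfinite(med) else 0.0
    return X


def _make_model(model: str, seed: int):
    if model == "forest":
        return RandomForestClassifier(
            n_estimators=60, min_samples_leaf=5, random_state=seed, n_jobs=1
        )
    if model == "boosted_trees":
        return GradientBoostingClassifier(n_estimators=60, max_depth=3, random_state=seed)
    raise ValueError(f"unknown model {model!r}")


def learn_discriminant(
    table: pd.DataFrame,
    n_folds: int = 3,
    n_iterations: int = 10,
    model: str = "forest",
    seed: int = 0,
) -> DiscriminantResult:
    """Semi-supervised target-decoy discriminant with out-of-fold scoring.

    The initial ranking is the main single-run score (the designed
    primary discriminator). In each iteration the classifier is trained
    on decoys versus the top-scoring half of the targets, then rescores
    the training rows; held-out rows are scored only by the final model
    of folds that never saw them. Deterministic for a fixed seed.
    """
    if "is_decoy" not in table.columns:
        raise ValueError("feature table needs an is_decoy column")
    y = table["is_decoy"].to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise ValueError("feature table must contain both targets and decoys")
    names = [c for c in ALL_FEATURES if c in table.columns]
    X = feature_matrix(table, names)
    n = len(table)
    out_scores = np.full(n, np.nan)

    # fold by precursor when possible: rows of one peptide share sequence-level
    # features, and splitting them across folds would leak peptide identity
    if "precursor_id" in table.columns:
        groups = table["precursor_id"].to_numpy()
        splits = GroupKFold(n_splits=n_folds).split(X, groups=groups)
    else:
        splits = KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(X)
    final_model = None
    for fold, (train_idx, test_idx) in enumerate(splits):
        Xtr, ytr = X[train_idx], y[train_idx]
        current = Xtr[:, names.index("sr_main")].astype(float)
        clf = None
        for it in range(n_iterations):
            targets = ~ytr
            if targets.sum() < 2 or ytr.sum() < 2:
                break
            thresh = np.median(current[targets])
            pos = targets & (current >= thresh)
            if pos.sum() < 2:
                pos = targets
            train_rows = pos | ytr
            clf = _make_model(model, seed + 1000 * fold + it)
            clf.fit(Xtr[train_rows], (~ytr[train_rows]).astype(int))
            current = clf.predict_proba(Xtr)[:, 1]
        if clf is None:
            raise ValueError("degenerate table: could not train the discriminant")
        out_scores[test_idx] = clf.predict_proba(X[test_idx])[:, 1]
        final_model = clf

    # refit once on everything for importance reporting
    full = _make_model(model, seed)
    full.fit(X, (~y).astype(int))
    return DiscriminantResult(out_scores, full, names)


def estimate_qvalues(target_scores: np.ndarray, decoy_scores: np.ndarray) -> np.ndarray:
    """Decoy-based q-values for target rows.

    FDR(t) = pi0 * (#decoys >= t) / (#targets >= t), with the decoy
    count rescaled by the target/decoy size ratio so unequal decoy
    libraries stay calibrated; pi0 is estimated as twice the fraction
    of targets scoring at or below the decoy median (a null target
    falls below the decoy median half the time), capped at 1. Q-values
    are the running minimum of FDR from the lowest score up, hence
    monotone non-increasing in score.
    """
    t = np.asarray(target_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    if d.size == 0:
        raise ValueError("cannot estimate q-values without decoys")
    if d.size < 50:
        warnings.warn(f"only {d.size} decoys; q-value estimates will be unstable")

    pi0 = min(1.0, 2.0 * float(np.mean(t <= np.median(d))))
    ratio = t.size / d.size

    order = np.argsort(-t, kind="stable")
    sorted_t = t[order]
    d_sorted = np.sort(-d)
    n_decoys_ge = np.searchsorted(d_sorted, -sorted_t, side="right")
    n_targets_ge = np.arange(1, t.size + 1)
    fdr = pi0 * (n_decoys_ge * ratio) / n_targets_ge
    qvals_sorted = np.minimum.accumulate(np.clip(fdr, 0.0, 1.0)[::-1])[::-1]
    q = np.empty_like(qvals_sorted)
    q[order] = qvals_sorted
    return q


def two_species_fdr(counts: EntrapmentCounts) -> tuple[float, float]:
    """Lower/upper empirical FDR bounds from a two-species entrapment design.

    lower = N_e / (N_e + N_n); upper = N_e * (1 + 1/r) / (N_e + N_n),
    where N_e and N_n are entrapment and native identifications in the
    entrapment-free runs and r is the library's entrapment fraction.
    The upper bound is the conservative estimate; both are reported.
    """
    if counts.n_entrapment < 0 or counts.n_native < 0:
        raise ValueError("counts must be non-negative")
    total = counts.n_entrapment + counts.n_native
    if total == 0:
        raise ValueError("no identifications; two-species FDR undefined")
    if counts.r <= 0:
        raise ValueError("entrapment ratio r must be positive")
    lower = counts.n_entrapment / total
    upper = counts.n_entrapment * (1.0 + 1.0 / counts.r) / total
    return lower, upper


def feature_importance(result: DiscriminantResult) -> pd.Series:
    """Normalized impurity-gain importances, descending, summing to 1."""
    model = result.model
    if not hasattr(model, "feature_importances_"):
        raise ValueError("model is untrained or does not expose importances")
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=result.feature_names).sort_values(ascending=False)


def ablate_multirun(table: pd.DataFrame) -> pd.DataFrame:
    """Drop the four multi-run score columns (ablation control)."""
    return table.drop(columns=[c for c in MULTI_RUN_FEATURES if c in table.columns])


def score_and_qvalues(
    table: pd.DataFrame,
    n_folds: int = 3,
    n_iterations: int = 10,
    model: str = "forest",
    seed: int = 0,
) -> tuple[pd.DataFrame, DiscriminantResult]:
    """Learn the discriminant and attach q-values to rank-1 candidates.

    Lower-ranked candidates participate in learning only; q-values are
    estimated experiment-wide over all rank-1 (run, precursor) rows and
    reported for targets (decoy rows get NaN).
    """
    result = learn_discriminant(table, n_folds, n_iterations, model, seed)
    out = table.copy()
    out["discriminant_score"] = result.scores
    out["q_value"] = np.nan
    rank1 = out["rank"] == 1 if "rank" in out.columns else np.ones(len(out), dtype=bool)
    tmask = rank1 & ~out["is_decoy"]
    dmask = rank1 & out["is_decoy"]
    q = estimate_qvalues(
        out.loc[tmask, "discriminant_score"].to_numpy(),
        out.loc[dmask, "discriminant_score"].to_numpy(),
    )
    out.loc[tmask, "q_value"] = q
    return out, result
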