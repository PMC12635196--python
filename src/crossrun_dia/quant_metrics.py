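"""Quantification benchmark metrics for two-sample, two-species designs.

Works on peptide-by-run intensity matrices (rows: precursors with a
species tag; columns: runs assigned to Sample A or Sample B). Provides
the validity filters (minimum runs per sample, minimum intensity,
minimum run fraction), per-peptide log2 A/B ratios, and the benchmark
metrics: species-separation ability (SSA, the AUROC of the ratio as a
two-species classifier), median bias of the log ratios against the
known mixing ratio, dispersion (SD of log ratios), their normalized
geometric-mean summary (total quantification bias), matrix
completeness, and top-3 precursor protein rollup.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "filter_valid",
    "species_ratios",
    "ssa",
    "median_bias",
    "dispersion",
    "total_bias",
    "completeness",
    "top3_protein_quant",
]


def _split_runs(sample_groups: dict[str, str]) -> tuple[list[str], list[str]]:
    a = [r for r, g in sample_groups.items() if g == "A"]
    b = [r for r, g in sample_groups.items() if g == "B"]
    if not a or not b:
        raise ValueError("sample_groups must assign runs to both Sample A and Sample B")
    return a, b


def filter_valid(
    matrix: pd.DataFrame,
    sample_groups: dict[str, str],
    min_runs_per_sample: int = 3,
    min_intensity: float = 100.0,
    min_run_fraction: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Apply the benchmark validity rules to an intensity matrix.

    Intensities below ``min_intensity`` are set NaN first; rows must
    then be quantified in at least ``min_runs_per_sample`` runs of both
    samples and in at least ``min_run_fraction`` of all runs. The
    filter is idempotent.
    """
    a_runs, b_runs = _split_runs(sample_groups)
    m = matrix.copy()
    m[m < min_intensity] = np.nan
    n_a = m[a_runs].notna().sum(axis=1)
    n_b = m[b_runs].notna().sum(axis=1)
    n_all = m.notna().sum(axis=1)
    keep = (
        (n_a >= min_runs_per_sample)
        & (n_b >= min_runs_per_sample)
        & (n_all >= min_run_fraction * m.shape[1])
    )
    return m.loc[keep]


def species_ratios(
    matrix: pd.DataFrame, sample_groups: dict[str, str], species: pd.Series
) -> pd.DataFrame:
    """Per-peptide log2(Sample A / Sample B) ratios with species tags.

    Sides are aggregated by the arithmetic mean of available (non-NaN)
    intensities before taking the ratio; rows with a zero or missing B
    mean are skipped with a warning.
    """
    a_runs, b_runs = _split_runs(sample_groups)
    mean_a = matrix[a_runs].mean(axis=1)
    mean_b = matrix[b_runs].mean(axis=1)
    ok = mean_a.notna() & mean_b.notna() & (mean_b > 0) & (mean_a > 0)
    skipped = int((~ok).sum())
    if skipped:
        warnings.warn(f"{skipped} rows skipped in ratio computation (missing or zero side)")
    out = pd.DataFrame(
        {
            "log2_ratio": np.log2(mean_a[ok] / mean_b[ok]),
            "species": species.reindex(matrix.index)[ok],
        }
    )
    return out


def ssa(ratios: pd.DataFrame, species_pair: tuple[str, str]) -> float:
    """Species-separation ability: AUROC of the log ratio between two species.

    Computed from midranks (ties shared), folded to [0.5, 1] since
    separation direction is immaterial.
    """
    s1, s2 = species_pair
    x = ratios.loc[ratios["species"] == s1, "log2_ratio"].to_numpy()
    y = ratios.loc[ratios["species"] == s2, "log2_ratio"].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError(f"both species {s1!r} and {s2!r} must have quantified peptides")
    ranks = rankdata(np.concatenate([x, y]))
    u = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    auc = u / (x.size * y.size)
    return float(max(auc, 1.0 - auc))


def median_bias(ratios: pd.DataFrame | np.ndarray, ground_truth_ratio: float) -> float:
    """|median(log2 ratios) - log2(true A/B ratio)|."""
    r = _as_log_ratios(ratios)
    if r.size < 2:
        raise ValueError("median bias needs at least 2 ratios")
    return float(abs(np.median(r) - np.log2(ground_truth_ratio)))


def dispersion(ratios: pd.DataFrame | np.ndarray) -> float:
    """Standard deviation of the log2 ratios."""
    r = _as_log_ratios(ratios)
    if r.size < 2:
        raise ValueError("dispersion needs at least 2 ratios")
    return float(np.std(r, ddof=1))


def _as_log_ratios(ratios) -> np.ndarray:
    if isinstance(ratios, pd.DataFrame):
        return ratios["log2_ratio"].to_numpy(dtype=float)
    return np.asarray(ratios, dtype=float)


def total_bias(
    components: dict[str, float], baseline: dict[str, float], epsilon: float = 1e-6
) -> float:
    """Geometric mean of metric components normalized against a baseline.

    Components are typically {1 - SSA, MB, DISP} (three-metric mode) or
    a two-metric subset; each is divided by the named baseline
    configuration's value. Zero components are floored at ``epsilon``
    with a warning.
    """
    if not components:
        raise ValueError("no components given")
    vals = []
    for name, v in components.items():
        base = baseline[name]
        if base <= 0:
            warnings.warn(f"baseline component {name!r} is zero; flooring at epsilon")
            base = epsilon
        norm = v / base
        if norm <= 0:
            warnings.warn(f"component {name!r} is zero; flooring at epsilon")
            norm = epsilon
        vals.append(norm)
    return float(np.exp(np.mean(np.log(vals))))


def completeness(matrix: pd.DataFrame, min_runs: int = 3) -> float:
    """Validly quantified entries / total entries, over rows seen in >= min_runs runs."""
    if matrix.size == 0:
        raise ValueError("empty quantification matrix")
    keep = matrix.notna().sum(axis=1) >= min_runs
    sub = matrix.loc[keep]
    if sub.size == 0:
        raise ValueError("no rows identified in enough runs")
    return float(sub.notna().to_numpy().mean())


def top3_protein_quant(matrix: pd.DataFrame, protein_map: pd.Series) -> pd.DataFrame:
    """Protein-by-run intensities from the top-3 precursors per protein.

    The three precursors with the highest mean intensity across runs
    are selected once, globally, so the same precursors enter every
    run's sum and cross-run ratios stay valid; proteins with no mapped
    precursors are dropped.
    """
    proteins = protein_map.reindex(matrix.index)
    rows = []
    index = []
    for prot, grp in matrix.groupby(proteins):
        if len(grp) == 0:
            continue
        top = grp.mean(axis=1).sort_values(ascending=False).index[:3]
        rows.append(grp.loc[top].sum(axis=0, min_count=1))
        index.append(prot)
    return pd.DataFrame(rows, index=index)
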