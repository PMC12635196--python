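"""End-to-end orchestration of the cross-run analysis workflow.

Stages, in order: sliding-window scoring of every chromatogram; RT
normalization (anchor selection, best-RT location, per-run RT models,
inlier sets); global similarity matrix and minimum spanning tree;
per-peptide alignment and synchronization onto a root run; consensus
peak picking on the averaged profile; weight-decayed multi-run scoring;
semi-supervised target-decoy discriminant with q-values; and a
peptide-by-run quantification matrix of the accepted identifications.

Identical configuration and seed give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from crossrun_dia import alignment as al
from crossrun_dia import multirun_scoring as mrs
from crossrun_dia import rt_normalization as rtn
from crossrun_dia import statistics as stats
from crossrun_dia.data_model_io import Chromatogram, LibraryEntry
from crossrun_dia.peak_scoring import ScorerSpec, score_profile
from crossrun_dia.synthetic_data import SyntheticDataset

logger = logging.getLogger("crossrun_dia")

__all__ = ["RunConfig", "WorkflowResult", "run_workflow", "auto_select_k_for_dataset"]


@dataclass(frozen=True)
class RunConfig:
    """Workflow configuration; defaults follow the published method's defaults."""

    window_length: int = 17
    alignment_mode: str = "dialignr"  # none | global_linear | global_lowess | dialignr
    similarity_metric: str = "nc"
    k: float = 50.0  # weight-decay coefficient; 0 disables decay
    q_cutoff: float = 0.01
    top_n_candidates: int = 10
    n_anchors: int = 4000
    anchor_bins: int = 10
    oversample_edge: float = 0.20
    cosine_threshold: float = 0.95
    residual_threshold_s: float = 60.0
    band_width_s: float = 180.0  # 3x the inlier residual threshold
    gap_penalty: float = 0.05
    min_separation_s: float = 24.0
    stat_model: str = "forest"
    n_folds: int = 3
    n_iterations: int = 10
    seed: int = 0

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class WorkflowResult:
    """Bundle of workflow outputs.

    ``scored_table`` holds one row per (run, precursor, rank) with all
    features, discriminant score and q-value (rank-1 targets only);
    ``quant_matrix`` is the precursor-by-run intensity table of
    identifications accepted at the q-value cutoff.
    """

    scored_table: pd.DataFrame
    quant_matrix: pd.DataFrame
    similarity: rtn.SimilarityMatrix
    tree: al.RunTree
    root: str
    n_pairwise_alignments: int
    importance: pd.Series
    manifest: dict

    def n_identifications(self, q_cutoff: float = 0.01) -> int:
        t = self.scored_table
        mask = (t["rank"] == 1) & ~t["is_decoy"] & (t["q_value"] <= q_cutoff)
        return int(mask.sum())


def _score_all(
    chroms: dict[str, dict[str, Chromatogram]],
    library_by_id: dict[str, LibraryEntry],
    spec: ScorerSpec,
) -> dict[str, dict[str, "object"]]:
    profiles: dict[str, dict[str, object]] = {}
    for run_id, per_run in chroms.items():
        profiles[run_id] = {}
        for pid, chrom in per_run.items():
            profiles[run_id][pid] = score_profile(chrom, library_by_id[pid], spec)
    return profiles


def run_workflow(dataset: SyntheticDataset, config: RunConfig = RunConfig()) -> WorkflowResult:
    """Execute the full cross-run workflow on an in-memory dataset."""
    t0 = time.time()
    library = dataset.library
    library_by_id = {e.precursor_id: e for e in library}
    chroms = dataset.chromatograms
    runs = list(chroms.keys())
    spec = ScorerSpec(window_length=config.window_length)

    profiles = _score_all(chroms, library_by_id, spec)
    logger.info("scored %d runs (%.1f s)", len(runs), time.time() - t0)

    # --- RT normalization -------------------------------------------------
    anchor_ids = rtn.select_anchor_peptides(
        library,
        n_anchors=config.n_anchors,
        n_bins=config.anchor_bins,
        oversample_edge=config.oversample_edge,
        seed=config.seed,
    )
    model_kind = "lowess" if config.alignment_mode == "global_lowess" else "linear"
    anchors: dict[str, rtn.RunAnchors] = {}
    irt_models: dict[str, rtn.GlobalRTModel] = {}
    for run_id in runs:
        anchors[run_id], irt_models[run_id] = rtn.build_run_anchors(
            run_id,
            profiles[run_id],
            library_by_id,
            anchor_ids,
            kind="linear",
            cosine_threshold=config.cosine_threshold,
            residual_threshold_s=config.residual_threshold_s,
        )
    inlier_sets = {r: anchors[r].inlier_ids for r in runs}

    intensities = None
    if config.similarity_metric == "intensity":
        intensities = {
            r: {pid: float(c.ms2_traces.sum()) for pid, c in chroms[r].items()} for r in runs
        }
    similarity = rtn.build_similarity_matrix(
        runs,
        metric=config.similarity_metric,
        inlier_sets=inlier_sets,
        intensities=intensities,
        chromatograms=chroms,
    )

    tree = al.build_mst(similarity)
    root = al.choose_root(similarity)
    pair_models = (
        al.fit_pairwise_models(anchors, tree.edges, kind=model_kind)
        if config.alignment_mode != "none"
        else {}
    )
    logger.info("similarity + tree built; root=%s", root)

    # --- per-peptide alignment, picking, multi-run scoring ----------------
    target_pids = [e.precursor_id for e in library]
    rows: list[dict] = []
    n_alignments = 0
    for pid in target_pids:
        per_run_chroms = {r: chroms[r][pid] for r in runs if pid in chroms[r]}
        if root not in per_run_chroms:
            continue
        result = al.align_all(
            pid,
            per_run_chroms,
            tree,
            root,
            pair_models,
            mode=config.alignment_mode,
            band_width=config.band_width_s,
            gap_penalty=config.gap_penalty,
        )
        n_alignments += result.n_pairwise_alignments
        prof_dict = {
            r: profiles[r][pid].as_dict() for r in per_run_chroms if pid in profiles[r]
        }
        sync = al.synchronize(result, prof_dict, per_run_chroms, runs)
        try:
            cross = mrs.average_profiles(sync)
        except ValueError:
            continue
        candidates = mrs.pick_peaks(
            cross, top_n=config.top_n_candidates, min_separation=config.min_separation_s
        )
        if not candidates:
            continue
        entry = library_by_id[pid]
        stacks = sync.profiles
        for cand in candidates:
            g = cand.apex_idx
            for ti, run_id in enumerate(runs):
                if run_id not in per_run_chroms:
                    continue
                local_rt = sync.run_rt_at_grid[ti, g]
                if not np.isfinite(stacks["main_score"][ti, g]):
                    continue
                weights = similarity.row(run_id)
                row = {
                    "run_id": run_id,
                    "precursor_id": pid,
                    "rank": cand.rank,
                    "apex_rt": float(local_rt),
                    "left_rt": float(sync.run_rt_at_grid[ti, cand.left_idx]),
                    "right_rt": float(sync.run_rt_at_grid[ti, cand.right_idx]),
                    "is_decoy": entry.is_decoy,
                    "species": entry.species_tag,
                    "peptide_length": len(entry.peptide_sequence),
                    "charge": entry.charge,
                }
                for name, key in (
                    ("main", "main_score"),
                    ("spectral_cosine", "spectral_cosine"),
                    ("ms1_area", "ms1_area"),
                    ("ms2_area", "ms2_area"),
                ):
                    stack = stacks[key]
                    row[f"sr_{name}"] = float(stack[ti, g])
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        row[f"mr_{name}"] = mrs.multirun_score(
                            stack[:, g], weights, config.k, ti
                        )
                model = irt_models[run_id]
                row["delta_rt"] = float(
                    model.residuals_seconds(np.array([local_rt]), np.array([entry.irt]))[0]
                )
                rows.append(row)

    table = pd.DataFrame(rows)
    if table.empty:
        raise RuntimeError("stage multirun_scoring produced no candidates")
    logger.info("candidate table: %d rows (%.1f s)", len(table), time.time() - t0)

    # --- statistics -------------------------------------------------------
    scored, disc = stats.score_and_qvalues(
        table,
        n_folds=config.n_folds,
        n_iterations=config.n_iterations,
        model=config.stat_model,
        seed=config.seed,
    )
    importance = stats.feature_importance(disc)

    # --- quantification ---------------------------------------------------
    acc = scored[
        (scored["rank"] == 1) & ~scored["is_decoy"] & (scored["q_value"] <= config.q_cutoff)
    ]
    quant = acc.pivot_table(
        index="precursor_id", columns="run_id", values="sr_ms2_area", aggfunc="first"
    ).reindex(columns=runs)

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_runs": len(runs),
        "n_precursors": len(target_pids),
        "n_pairwise_alignments": n_alignments,
        "alignment_mode": config.alignment_mode,
        "q_value_scope": "global (experiment-wide over run-precursor rows)",
        "elapsed_s": round(time.time() - t0, 2),
    }
    logger.info("workflow finished in %.1f s", time.time() - t0)
    return WorkflowResult(
        scored, quant, similarity, tree, root, n_alignments, importance, manifest
    )


def auto_select_k_for_dataset(
    dataset: SyntheticDataset,
    config: RunConfig,
    k_grid=(0, 5, 10, 25, 50, 100, 200),
    library_downsample_fraction: float = 0.10,
    gaussian_sigma: float = 1.0,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Pick the weight-decay coefficient from the elbow of IDs vs k.

    The library is downsampled, the workflow runs once per grid point,
    and the first elbow of the Gaussian-smoothed identification-count
    curve is returned.
    """
    rng = np.random.default_rng(seed)
    pids = [e.precursor_id for e in dataset.library]
    n_keep = max(10, int(round(library_downsample_fraction * len(pids))))
    keep = set(rng.choice(pids, size=min(n_keep, len(pids)), replace=False))
    sub_library = [e for e in dataset.library if e.precursor_id in keep]
    sub_chroms = {
        r: {pid: c for pid, c in per_run.items() if pid in keep}
        for r, per_run in dataset.chromatograms.items()
    }
    sub = SyntheticDataset(
        dataset.config,
        sub_library,
        sub_chroms,
        dataset.ground_truth[dataset.ground_truth["precursor_id"].isin(keep)],
    )

    def id_count(k: float) -> int:
        res = run_workflow(sub, replace(config, k=k))
        return res.n_identifications(config.q_cutoff)

    return mrs.auto_select_k(id_count, k_grid, gaussian_sigma)
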