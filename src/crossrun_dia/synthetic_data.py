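"""Synthetic multi-run DIA datasets with known ground truth.

Generates a spectral library plus per-run extracted-ion chromatograms
(XICs) with the statistical structure the cross-run workflow assumes:
co-eluting Gaussian fragment peaks whose intensities follow the library
spectrum, run-to-run retention-time shifts (none / linear / smooth
nonlinear / peptide-specific), cofragmentation-style interference peaks,
additive detector noise, decoy precursors with noise-only traces, and
two-group entrapment designs in which a labelled peptide subset is truly
absent from one sample group while remaining in the library.

Every draw comes from a single seeded generator, so a fixed seed yields
byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from crossrun_dia.data_model_io import Chromatogram, Fragment, LibraryEntry, RunStore, write_library

__all__ = [
    "SyntheticConfig",
    "EntrapmentDesign",
    "SyntheticDataset",
    "generate_dataset",
    "make_entrapment_dataset",
]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class ConfigurationError(ValueError):
    """Invalid synthetic-dataset configuration."""


@dataclass(frozen=True)
class EntrapmentDesign:
    """Two-group design where a peptide subset is absent from one group.

    ``absent_run_indices`` lists the runs (0-based) from which the
    entrapment peptides are truly missing; the library keeps them (the
    trap). ``entrapment_fraction`` is the fraction of target peptides
    assigned to the entrapment subset.
    """

    absent_run_indices: tuple[int, ...]
    entrapment_fraction: float = 0.2
    entrapment_tag: str = "entrapment"
    native_tag: str = "native"


@dataclass(frozen=True)
class SyntheticConfig:
    n_runs: int = 6
    n_peptides: int = 50
    n_fragments_per_peptide: int = 6
    rt_grid: tuple[float, float, float] = (0.0, 600.0, 2.0)
    peak_width_sigma: float = 8.0
    rt_shift_model: str = "none"  # none | linear | lowess_like | peptide_specific
    shift_magnitude: float = 0.0
    interference_rate: float = 0.0
    noise_sd: float = 0.0
    decoy_fraction: float = 0.0
    entrapment_design: EntrapmentDesign | None = None
    # run heterogeneity: per-group whole-peptide dropout probability
    run_groups: tuple[int, ...] | None = None
    group_dropout: float = 0.0
    # per-species (tag) abundance multipliers per group, e.g. {"yeast": (2.0, 1.0)}
    species_ratio_design: dict[str, tuple[float, ...]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        start, end, step = self.rt_grid
        if step <= 0:
            raise ConfigurationError("rt grid step must be positive")
        if end <= start:
            raise ConfigurationError("rt grid end must exceed start")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ConfigurationError("decoy_fraction must lie in [0, 1]")
        if self.rt_shift_model not in {"none", "linear", "lowess_like", "peptide_specific"}:
            raise ConfigurationError(f"unknown rt_shift_model {self.rt_shift_model!r}")
        margin = 4.0 * self.peak_width_sigma + abs(self.shift_magnitude)
        if end - start <= 2.0 * margin:
            raise ConfigurationError(
                "rt grid too short to host a peak after shifts: need length > "
                f"{2.0 * margin:.1f} s, got {end - start:.1f} s"
            )
        if self.run_groups is not None and len(self.run_groups) != self.n_runs:
            raise ConfigurationError("run_groups must list one group index per run")


@dataclass
class SyntheticDataset:
    """A generated library, per-run chromatograms, and the ground truth.

    ``chromatograms[run_id][precursor_id]`` is a :class:`Chromatogram`;
    ``ground_truth`` has one row per (run, precursor) with the true apex,
    boundaries, presence flag, amplitude and species tag.
    """

    config: SyntheticConfig
    library: list[LibraryEntry]
    chromatograms: dict[str, dict[str, Chromatogram]]
    ground_truth: pd.DataFrame

    @property
    def run_ids(self) -> list[str]:
        return list(self.chromatograms.keys())

    def run_group(self, run_id: str) -> int:
        idx = self.run_ids.index(run_id)
        if self.config.run_groups is not None:
            return self.config.run_groups[idx]
        return 0

    def write(self, out_dir: str | Path) -> None:
        """Write library TSV, per-run SQLite XIC stores, and ground-truth TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_library(self.library, out / "library.tsv")
        self.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        for run_id, chroms in self.chromatograms.items():
            with RunStore(out / f"{run_id}.xic.sqlite") as store:
                for chrom in chroms.values():
                    store.store_xic(chrom)


def _gaussian(rt: np.ndarray, apex: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((rt - apex) / sigma) ** 2)


def _random_sequence(rng: np.random.Generator) -> str:
    length = int(rng.integers(7, 21))
    return "".join(rng.choice(_AMINO_ACIDS, size=length))


def _run_shift_parameters(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-run additive offsets and nonlinear warp amplitudes."""
    n = cfg.n_runs
    idx = np.arange(n)
    if cfg.rt_shift_model == "none" or cfg.shift_magnitude == 0:
        offsets = np.zeros(n)
        warp_amp = np.zeros(n)
    elif cfg.rt_shift_model in {"linear", "peptide_specific"}:
        centre = (n - 1) / 2.0 if n > 1 else 0.0
        offsets = cfg.shift_magnitude * (idx - centre) / max(centre, 1.0)
        warp_amp = np.zeros(n)
    else:  # lowess_like: smooth monotone warp, amplitude varies by run
        offsets = np.zeros(n)
        warp_amp = cfg.shift_magnitude * rng.uniform(-1.0, 1.0, size=n)
    return offsets, warp_amp


def _apply_shift(
    base_apex: float,
    run_idx: int,
    peptide_offset: float,
    offsets: np.ndarray,
    warp_amp: np.ndarray,
    cfg: SyntheticConfig,
) -> float:
    start, end, _ = cfg.rt_grid
    apex = base_apex + offsets[run_idx]
    if warp_amp[run_idx] != 0.0:
        # sinusoidal warp keeps elution order (derivative magnitude < 1)
        apex = apex + warp_amp[run_idx] * np.sin(
            2.0 * np.pi * (base_apex - start) / (end - start)
        )
    if cfg.rt_shift_model == "peptide_specific":
        apex = apex + peptide_offset
    lo = start + 3.0 * cfg.peak_width_sigma
    hi = end - 3.0 * cfg.peak_width_sigma
    return float(np.clip(apex, lo, hi))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a multi-run dataset with ground truth.

    Present peptides get a Gaussian co-eluting peak group across their
    fragments at the (shifted) apex. Interference comes from a simulated
    cofragmenting analyte with one reproducible RT per precursor (drawn
    >= 3 sigma from the true apex), hitting a fixed fragment subset and
    appearing per run with probability ``interference_rate``. Decoys are
    library entries with permuted fragment intensities and noise-only
    traces. Deterministic for a fixed seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    start, end, step = cfg.rt_grid
    rt = np.arange(start, end + step / 2, step)
    sigma = cfg.peak_width_sigma

    run_ids = [f"run_{i:02d}" for i in range(cfg.n_runs)]
    groups = (
        np.asarray(cfg.run_groups)
        if cfg.run_groups is not None
        else np.zeros(cfg.n_runs, dtype=int)
    )

    # --- library -----------------------------------------------------------
    irts = np.sort(rng.uniform(0.0, 100.0, size=cfg.n_peptides))
    margin = 4.0 * sigma + abs(cfg.shift_magnitude)
    base_apexes = start + margin + (irts / 100.0) * (end - start - 2.0 * margin)

    entrap_flags = np.zeros(cfg.n_peptides, dtype=bool)
    design = cfg.entrapment_design
    if design is not None:
        n_entrap = int(round(design.entrapment_fraction * cfg.n_peptides))
        if n_entrap == 0:
            raise ConfigurationError("entrapment design selects an empty peptide subset")
        entrap_idx = rng.choice(cfg.n_peptides, size=n_entrap, replace=False)
        entrap_flags[entrap_idx] = True
    absent_runs = set(design.absent_run_indices) if design is not None else set()

    library: list[LibraryEntry] = []
    lib_intensities = np.empty((cfg.n_peptides, cfg.n_fragments_per_peptide))
    for p in range(cfg.n_peptides):
        ints = np.sort(rng.uniform(0.1, 1.0, size=cfg.n_fragments_per_peptide))[::-1] * 1000.0
        lib_intensities[p] = ints
        tag = ""
        if design is not None:
            tag = design.entrapment_tag if entrap_flags[p] else design.native_tag
        seq = _random_sequence(rng)
        pid = f"PEP_{p:04d}"
        library.append(
            LibraryEntry(
                precursor_id=pid,
                peptide_sequence=seq,
                charge=int(rng.choice([2, 3])),
                precursor_mz=float(rng.uniform(400.0, 1200.0)),
                irt=float(irts[p]),
                fragments=[
                    Fragment(f"{pid}_f{k}", float(rng.uniform(200.0, 1500.0)), float(ints[k]))
                    for k in range(cfg.n_fragments_per_peptide)
                ],
                is_decoy=False,
                species_tag=tag,
                protein_id=f"PROT_{p // 3:04d}",
            )
        )

    n_decoys = int(round(cfg.decoy_fraction * cfg.n_peptides))
    for d in range(n_decoys):
        src = library[int(rng.integers(0, cfg.n_peptides))]
        perm = rng.permutation(cfg.n_fragments_per_peptide)
        pid = f"DECOY_{d:04d}"
        library.append(
            LibraryEntry(
                precursor_id=pid,
                peptide_sequence=_random_sequence(rng),
                charge=src.charge,
                precursor_mz=src.precursor_mz,
                irt=float(rng.uniform(0.0, 100.0)),
                fragments=[
                    Fragment(
                        f"{pid}_f{k}",
                        src.fragments[k].mz,
                        src.fragments[perm[k]].library_intensity,
                    )
                    for k in range(cfg.n_fragments_per_peptide)
                ],
                is_decoy=True,
                species_tag="decoy",
            )
        )

    # --- per-run structure --------------------------------------------------
    offsets, warp_amp = _run_shift_parameters(cfg, rng)
    peptide_offsets = (
        rng.normal(0.0, cfg.shift_magnitude / 2.0, size=(cfg.n_peptides, cfg.n_runs))
        if cfg.rt_shift_model == "peptide_specific"
        else np.zeros((cfg.n_peptides, cfg.n_runs))
    )

    # whole-group dropout (heterogeneity); a peptide is never dropped everywhere
    unique_groups = sorted(set(int(g) for g in groups))
    dropped = np.zeros((cfg.n_peptides, len(unique_groups)), dtype=bool)
    if cfg.group_dropout > 0 and len(unique_groups) > 0:
        dropped = rng.random((cfg.n_peptides, len(unique_groups))) < cfg.group_dropout
        all_dropped = dropped.all(axis=1)
        dropped[all_dropped, 0] = False

    base_amp = rng.uniform(500.0, 2000.0, size=cfg.n_peptides)
    run_amp_factor = np.exp(rng.normal(0.0, 0.15, size=(cfg.n_peptides, cfg.n_runs)))

    # interference: a cofragmenting analyte with its own reproducible RT.
    # One interferer per precursor (position >= 3 sigma from the true apex,
    # hitting a fixed fragment subset), present per run with probability
    # interference_rate and following the same run-level RT shifts.
    n_entries = len(library)
    interferer = [_draw_interferer(rng, base_apexes[p] if p < cfg.n_peptides else None, cfg)
                  for p in range(n_entries)]

    ratio_design = cfg.species_ratio_design or {}

    chromatograms: dict[str, dict[str, Chromatogram]] = {r: {} for r in run_ids}
    truth_rows: list[dict] = []

    for p, entry in enumerate(library[: cfg.n_peptides]):
        for j, run_id in enumerate(run_ids):
            g = unique_groups.index(int(groups[j]))
            present = not dropped[p, g]
            if entrap_flags[p] and j in absent_runs:
                present = False
            apex = _apply_shift(base_apexes[p], j, peptide_offsets[p, j], offsets, warp_amp, cfg)
            amp = base_amp[p] * run_amp_factor[p, j]
            if entry.species_tag in ratio_design:
                factors = ratio_design[entry.species_tag]
                amp *= factors[int(groups[j]) % len(factors)]

            traces = np.zeros((cfg.n_fragments_per_peptide, len(rt)))
            if present:
                shape = _gaussian(rt, apex, sigma)
                traces += (
                    amp * (lib_intensities[p] / lib_intensities[p].max())[:, None] * shape[None, :]
                )
            ms1 = amp * 1.5 * _gaussian(rt, apex, sigma) if present else np.zeros(len(rt))
            if rng.random() < cfg.interference_rate:
                tr_i, ms1_i = _interference_traces(
                    rng, rt, interferer[p], j, offsets, warp_amp, cfg
                )
                traces += tr_i
                ms1 += ms1_i
            if cfg.noise_sd > 0:
                traces = traces + rng.normal(0.0, cfg.noise_sd, size=traces.shape)
                traces = np.clip(traces, 0.0, None)
                ms1 = np.clip(ms1 + rng.normal(0.0, cfg.noise_sd, size=ms1.shape), 0.0, None)

            chromatograms[run_id][entry.precursor_id] = Chromatogram(
                run_id, entry.precursor_id, rt, traces, ms1
            )
            truth_rows.append(
                {
                    "run_id": run_id,
                    "precursor_id": entry.precursor_id,
                    "apex_rt": apex,
                    "left_boundary": max(start, apex - 2.5 * sigma),
                    "right_boundary": min(end, apex + 2.5 * sigma),
                    "present": present,
                    "amplitude": amp if present else 0.0,
                    "tag": entry.species_tag,
                }
            )

    # decoys: noise-only traces (plus interference)
    for d, entry in enumerate(library[cfg.n_peptides :]):
        for j, run_id in enumerate(run_ids):
            traces = np.zeros((cfg.n_fragments_per_peptide, len(rt)))
            ms1 = np.zeros(len(rt))
            if rng.random() < cfg.interference_rate:
                tr_i, ms1_i = _interference_traces(
                    rng, rt, interferer[cfg.n_peptides + d], j, offsets, warp_amp, cfg
                )
                traces += tr_i
                ms1 += ms1_i
            if cfg.noise_sd > 0:
                traces = np.clip(
                    traces + rng.normal(0.0, cfg.noise_sd, size=traces.shape), 0.0, None
                )
                ms1 = np.clip(ms1 + rng.normal(0.0, cfg.noise_sd, size=ms1.shape), 0.0, None)
            chromatograms[run_id][entry.precursor_id] = Chromatogram(
                run_id, entry.precursor_id, rt, traces, ms1
            )
            truth_rows.append(
                {
                    "run_id": run_id,
                    "precursor_id": entry.precursor_id,
                    "apex_rt": np.nan,
                    "left_boundary": np.nan,
                    "right_boundary": np.nan,
                    "present": False,
                    "amplitude": 0.0,
                    "tag": "decoy",
                }
            )

    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(cfg, library, chromatograms, truth)


def _draw_interferer(
    rng: np.random.Generator, base_apex: float | None, cfg: SyntheticConfig
) -> dict:
    """Peptide-level interferer: reproducible RT, fragment subset, abundance."""
    start, end, _ = cfg.rt_grid
    sigma = cfg.peak_width_sigma
    lo, hi = start + 3.0 * sigma, end - 3.0 * sigma
    pos = rng.uniform(lo, hi)
    for _ in range(50):
        if base_apex is None or abs(pos - base_apex) >= 3.0 * sigma:
            break
        pos = rng.uniform(lo, hi)
    n_frag = cfg.n_fragments_per_peptide
    n_hit = max(1, n_frag // 2)
    return {
        "pos": float(pos),
        "hit": rng.choice(n_frag, size=n_hit, replace=False),
        "frag_profile": rng.uniform(0.3, 1.0, size=n_hit),
        "amp": float(rng.uniform(500.0, 2000.0)),
    }


def _interference_traces(
    rng: np.random.Generator,
    rt: np.ndarray,
    spec: dict,
    run_idx: int,
    offsets: np.ndarray,
    warp_amp: np.ndarray,
    cfg: SyntheticConfig,
) -> np.ndarray:
    """The interferer's co-eluting peak in one run (shifted with the run, jittered)."""
    sigma = cfg.peak_width_sigma
    pos = _apply_shift(spec["pos"], run_idx, 0.0, offsets, warp_amp, cfg)
    pos += rng.normal(0.0, sigma / 4.0)
    amp = spec["amp"] * float(np.exp(rng.normal(0.0, 0.15)))
    shape = _gaussian(rt, pos, sigma)
    traces = np.zeros((cfg.n_fragments_per_peptide, len(rt)))
    traces[spec["hit"]] = amp * spec["frag_profile"][:, None] * shape[None, :]
    # the interferer's own precursor bleeds into the MS1 channel
    ms1 = 0.75 * amp * shape
    return traces, ms1


def make_entrapment_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a two-group entrapment dataset.

    Requires ``config.entrapment_design``; the entrapment peptide subset
    is flagged absent (ground truth ``present=False``) in the designated
    runs while the library retains the peptides.
    """
    if config.entrapment_design is None:
        raise ConfigurationError("entrapment_design must be set")
    if config.run_groups is None:
        absent = set(config.entrapment_design.absent_run_indices)
        groups = tuple(1 if i in absent else 0 for i in range(config.n_runs))
        config = replace(config, run_groups=groups)
    return generate_dataset(config)
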