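"""Core containers and readers/writers for libraries, XICs, profiles and results.

The on-disk formats are deliberately plain: the spectral library is a
tab-separated transition list (one row per fragment ion, OpenSWATH-style
columns), manual peak-boundary annotations are TSV, and per-run XICs and
scoring profiles live in one SQLite file per run so that stages can be
re-run from stored intermediates.

Conventions: retention times are absolute seconds, arrays are 0-based,
and boundary intervals are closed ``[left, right]``.
"""

from __future__ import annotations

import sqlite3
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Fragment",
    "LibraryEntry",
    "Chromatogram",
    "AnnotationRecord",
    "LibraryFormatError",
    "StoreIntegrityError",
    "read_library",
    "write_library",
    "read_annotations",
    "write_annotations",
    "RunStore",
]

LIBRARY_COLUMNS = [
    "transition_group_id",
    "peptide_sequence",
    "precursor_charge",
    "precursor_mz",
    "fragment_id",
    "product_mz",
    "library_intensity",
    "irt",
    "decoy",
    "species",
    "protein_id",
]


class LibraryFormatError(ValueError):
    """Raised when a transition list is missing required columns or rows are malformed."""


class StoreIntegrityError(RuntimeError):
    """Raised when stored arrays are inconsistent (e.g. profile grid != XIC grid)."""


@dataclass(frozen=True)
class Fragment:
    fragment_id: str
    mz: float
    library_intensity: float


@dataclass
class LibraryEntry:
    """One precursor of the spectral library with its fragment ions."""

    precursor_id: str
    peptide_sequence: str
    charge: int
    precursor_mz: float
    irt: float
    fragments: list[Fragment]
    is_decoy: bool = False
    species_tag: str = ""
    protein_id: str = ""

    @property
    def library_intensities(self) -> np.ndarray:
        return np.array([f.library_intensity for f in self.fragments], dtype=float)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


@dataclass
class Chromatogram:
    """One peptide's RT grid and fragment intensity traces in one run.

    ``ms2_traces`` has one row per library fragment (after top-k
    filtering), aligned to ``rt``; ``ms1_trace`` is optional.
    """

    run_id: str
    precursor_id: str
    rt: np.ndarray
    ms2_traces: np.ndarray
    ms1_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.ms2_traces = np.atleast_2d(np.asarray(self.ms2_traces, dtype=float))
        if self.rt.ndim != 1 or len(self.rt) < 2:
            raise ValueError("rt grid must be a 1-D vector with >= 2 points")
        if np.any(np.diff(self.rt) <= 0):
            raise ValueError("rt grid must be strictly increasing")
        if self.ms2_traces.shape[1] != len(self.rt):
            raise ValueError("ms2 trace length does not match rt grid")
        if self.ms1_trace is not None:
            self.ms1_trace = np.asarray(self.ms1_trace, dtype=float)
            if self.ms1_trace.shape != self.rt.shape:
                raise ValueError("ms1 trace length does not match rt grid")

    @property
    def n_points(self) -> int:
        return len(self.rt)


@dataclass(frozen=True)
class AnnotationRecord:
    """A manually annotated peak boundary for one (run, precursor)."""

    run_id: str
    precursor_id: str
    left_boundary: float
    right_boundary: float


# ---------------------------------------------------------------------------
# Spectral library


def read_library(path: str | Path, top_k_fragments: int = 6) -> list[LibraryEntry]:
    """Read a TSV transition list, keeping each precursor's top-k fragments.

    Fragments are ranked by library intensity (descending); ties at the
    cut are broken by lexicographic ``fragment_id`` so the result is
    deterministic. Entries left with zero fragments are dropped with a
    warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"fragment_id": str})
    required = set(LIBRARY_COLUMNS) - {"species", "protein_id"}
    missing = required - set(df.columns)
    if missing:
        raise LibraryFormatError(
            f"transition list is missing required column(s): {', '.join(sorted(missing))}"
        )
    if "species" not in df.columns:
        df["species"] = ""
    if "protein_id" not in df.columns:
        df["protein_id"] = ""

    entries: list[LibraryEntry] = []
    for pid, grp in df.groupby("transition_group_id", sort=True):
        grp = grp.sort_values(
            ["library_intensity", "fragment_id"], ascending=[False, True]
        ).head(top_k_fragments)
        frags = [
            Fragment(str(r.fragment_id), float(r.product_mz), float(r.library_intensity))
            for r in grp.itertuples()
            if r.library_intensity > 0
        ]
        if not frags:
            warnings.warn(f"precursor {pid!r} has no fragments after filtering; dropped")
            continue
        first = grp.iloc[0]
        entries.append(
            LibraryEntry(
                precursor_id=str(pid),
                peptide_sequence=str(first["peptide_sequence"]),
                charge=int(first["precursor_charge"]),
                precursor_mz=float(first["precursor_mz"]),
                irt=float(first["irt"]),
                fragments=frags,
                is_decoy=bool(first["decoy"]),
                species_tag=str(first["species"]) if pd.notna(first["species"]) else "",
                protein_id=str(first["protein_id"]) if pd.notna(first["protein_id"]) else "",
            )
        )
    return entries


def write_library(entries: list[LibraryEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        for f in e.fragments:
            rows.append(
                {
                    "transition_group_id": e.precursor_id,
                    "peptide_sequence": e.peptide_sequence,
                    "precursor_charge": e.charge,
                    "precursor_mz": e.precursor_mz,
                    "fragment_id": f.fragment_id,
                    "product_mz": f.mz,
                    "library_intensity": f.library_intensity,
                    "irt": e.irt,
                    "decoy": int(e.is_decoy),
                    "species": e.species_tag,
                    "protein_id": e.protein_id,
                }
            )
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotations


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read a peak-boundary annotation TSV.

    Rows with ``left >= right`` are rejected (ambiguous annotations);
    duplicate (run, precursor) rows keep the first occurrence with a
    warning. Unparseable rows raise with their line number.
    """
    records: list[AnnotationRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("run_id", "precursor_id", "left_boundary", "right_boundary"):
            if col not in idx:
                raise LibraryFormatError(f"annotation file missing column {col!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                rec = AnnotationRecord(
                    run_id=parts[idx["run_id"]],
                    precursor_id=parts[idx["precursor_id"]],
                    left_boundary=float(parts[idx["left_boundary"]]),
                    right_boundary=float(parts[idx["right_boundary"]]),
                )
            except (IndexError, ValueError) as exc:
                raise LibraryFormatError(f"unparseable annotation row at line {lineno}") from exc
            if rec.left_boundary >= rec.right_boundary:
                continue
            key = (rec.run_id, rec.precursor_id)
            if key in seen:
                warnings.warn(f"duplicate annotation for {key}; keeping the first")
                continue
            seen.add(key)
            records.append(rec)
    return records


def write_annotations(records: list[AnnotationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "run_id": r.run_id,
                "precursor_id": r.precursor_id,
                "left_boundary": r.left_boundary,
                "right_boundary": r.right_boundary,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-run SQLite store

_SCHEMA = """
CREATE TABLE IF NOT EXISTS RUNS (run_id TEXT PRIMARY KEY);
CREATE TABLE IF NOT EXISTS PRECURSORS (precursor_id TEXT PRIMARY KEY);
CREATE TABLE IF NOT EXISTS XIC (
    run_id TEXT, precursor_id TEXT,
    rt BLOB, traces BLOB, ms1 BLOB,
    n_fragments INTEGER, n_points INTEGER,
    PRIMARY KEY (run_id, precursor_id)
);
CREATE TABLE IF NOT EXISTS PROFILES (
    run_id TEXT, precursor_id TEXT, score_type TEXT,
    "values" BLOB, n_points INTEGER,
    PRIMARY KEY (run_id, precursor_id, score_type)
);
"""


class RunStore:
    """SQLite-backed store for one run's XICs and scoring profiles.

    Arrays are stored as little-endian float64 blobs; round trips are
    bit-exact. One file per run keeps concurrent reads of different runs
    fully independent.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "RunStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @staticmethod
    def _blob(a: np.ndarray) -> bytes:
        return np.ascontiguousarray(a, dtype="<f8").tobytes()

    @staticmethod
    def _unblob(b: bytes) -> np.ndarray:
        return np.frombuffer(b, dtype="<f8").copy()

    def store_xic(self, chrom: Chromatogram) -> None:
        self._conn.execute("INSERT OR IGNORE INTO RUNS VALUES (?)", (chrom.run_id,))
        self._conn.execute("INSERT OR IGNORE INTO PRECURSORS VALUES (?)", (chrom.precursor_id,))
        ms1 = self._blob(chrom.ms1_trace) if chrom.ms1_trace is not None else None
        self._conn.execute(
            "INSERT OR REPLACE INTO XIC VALUES (?,?,?,?,?,?,?)",
            (
                chrom.run_id,
                chrom.precursor_id,
                self._blob(chrom.rt),
                self._blob(chrom.ms2_traces),
                ms1,
                chrom.ms2_traces.shape[0],
                chrom.n_points,
            ),
        )
        self._conn.commit()

    def load_xic(self, run_id: str, precursor_id: str) -> Chromatogram:
        row = self._conn.execute(
            "SELECT rt, traces, ms1, n_fragments, n_points FROM XIC "
            "WHERE run_id=? AND precursor_id=?",
            (run_id, precursor_id),
        ).fetchone()
        if row is None:
            raise KeyError(f"no XIC stored for run {run_id!r}, precursor {precursor_id!r}")
        rt_b, tr_b, ms1_b, n_frag, n_pts = row
        rt = self._unblob(rt_b)
        traces = self._unblob(tr_b).reshape(n_frag, n_pts)
        ms1 = self._unblob(ms1_b) if ms1_b is not None else None
        return Chromatogram(run_id, precursor_id, rt, traces, ms1)

    def store_profiles(
        self, run_id: str, precursor_id: str, profiles: dict[str, np.ndarray]
    ) -> None:
        """Store named score traces; each must match the stored XIC grid length."""
        row = self._conn.execute(
            "SELECT n_points FROM XIC WHERE run_id=? AND precursor_id=?",
            (run_id, precursor_id),
        ).fetchone()
        for score_type, values in profiles.items():
            values = np.asarray(values, dtype=float)
            if row is not None and len(values) != row[0]:
                raise StoreIntegrityError(
                    f"profile {score_type!r} length {len(values)} does not match "
                    f"XIC grid length {row[0]} for {run_id}/{precursor_id}"
                )
            self._conn.execute(
                'INSERT OR REPLACE INTO PROFILES VALUES (?,?,?,?,?)',
                (run_id, precursor_id, score_type, self._blob(values), len(values)),
            )
        self._conn.commit()

    def load_profiles(self, run_id: str, precursor_id: str) -> dict[str, np.ndarray]:
        rows = self._conn.execute(
            'SELECT score_type, "values" FROM PROFILES WHERE run_id=? AND precursor_id=?',
            (run_id, precursor_id),
        ).fetchall()
        if not rows:
            raise KeyError(f"no profiles stored for run {run_id!r}, precursor {precursor_id!r}")
        return {score_type: self._unblob(b) for score_type, b in rows}
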