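"""Session, reference-glucose and manifest file handling.

A *session* is one wearing period of a multi-sensor device: a channel matrix
sampled on a uniform time grid (default 20 s step) together with a sparse
series of reference blood glucose (RBG) fingerprick samples in mg/dL.  All
module interfaces use seconds from session start; minutes/hours appear only
at the CLI boundary.

On-disk dialects (all plain CSV):

* session file   — header ``time_s,ch001,...,chNNN``, one row per grid sample
* RBG file       — header ``time_s,glucose_mgdl``
* manifest file  — header ``session_id,subject_id,session_file,rbg_file,split``
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Session",
    "ManifestEntry",
    "DatasetManifest",
    "SessionFormatError",
    "read_session",
    "write_session",
    "read_manifest",
    "write_manifest",
    "split_dataset",
]

#: relative tolerance on grid-step uniformity
GRID_RTOL = 1e-6


class SessionFormatError(ValueError):
    """Raised when a session/RBG/manifest file violates the format contract."""


@dataclass(eq=False)
class Session:
    """One multi-sensor wearing period with paired reference glucose.

    Parameters
    ----------
    session_id, subject_id : str
        Identifiers; ``subject_id`` groups sessions of one person.
    t : ndarray, shape (T,)
        Time grid in seconds from session start, strictly increasing with a
        uniform step ``dt``.
    X : ndarray, shape (C, T)
        Channel matrix in arbitrary units, one row per channel.  Channel
        count ``C`` is a file property — nothing downstream hard-codes it.
    rbg_times, rbg_values : ndarray
        Sparse reference blood glucose samples: seconds and mg/dL.  Times
        must lie within the session span and be strictly increasing; values
        must be positive.
    """

    session_id: str
    subject_id: str
    t: np.ndarray
    X: np.ndarray
    rbg_times: np.ndarray
    rbg_values: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.rbg_times = np.asarray(self.rbg_times, dtype=float)
        self.rbg_values = np.asarray(self.rbg_values, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        t = self.t
        if t.ndim != 1 or t.size < 2:
            raise SessionFormatError("time grid needs at least 2 samples")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise SessionFormatError("time grid is not strictly increasing")
        dt = steps[0]
        if np.any(np.abs(steps - dt) > GRID_RTOL * max(abs(dt), 1.0)):
            raise SessionFormatError("time grid is not uniform")
        if self.X.shape[1] != t.size:
            raise SessionFormatError(
                f"channel matrix has {self.X.shape[1]} columns, grid has {t.size}"
            )
        if not np.all(np.isfinite(self.X)):
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise SessionFormatError(
                f"missing/non-finite sample at channel {bad[0]}, row {bad[1]}"
            )
        if self.rbg_times.shape != self.rbg_values.shape:
            raise SessionFormatError("RBG times/values length mismatch")
        if self.rbg_times.size:
            if np.any(np.diff(self.rbg_times) <= 0):
                raise SessionFormatError("RBG times not strictly increasing")
            if self.rbg_times[0] < t[0] or self.rbg_times[-1] > t[-1]:
                row = int(np.argmax((self.rbg_times < t[0]) | (self.rbg_times > t[-1])))
                raise SessionFormatError(f"RBG outside session span (row {row})")
            if np.any(self.rbg_values <= 0):
                row = int(np.argmax(self.rbg_values <= 0))
                raise SessionFormatError(f"non-positive glucose (row {row})")

    # -- convenience ------------------------------------------------------
    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n_channels(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.t.size

    def nearest_index(self, time_s: float | np.ndarray) -> np.ndarray | int:
        """Index of the grid sample nearest to ``time_s`` (vectorised)."""
        idx = np.rint((np.asarray(time_s) - self.t[0]) / self.dt).astype(int)
        return np.clip(idx, 0, self.n_samples - 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        return (
            self.session_id == other.session_id
            and self.subject_id == other.subject_id
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.X, other.X)
            and np.array_equal(self.rbg_times, other.rbg_times)
            and np.array_equal(self.rbg_values, other.rbg_values)
        )


@dataclass
class ManifestEntry:
    session_id: str
    subject_id: str
    session_file: str
    rbg_file: str
    split: str = ""  # "part1" / "part2" once assigned


@dataclass
class DatasetManifest:
    """Assignment of sessions to subjects and identification/test splits."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def validate(self, require_split: bool = False) -> None:
        ids = [e.session_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise SessionFormatError("duplicate session_id in manifest")
        labels = {e.split for e in self.entries if e.split}
        if require_split or labels:
            if labels != {"part1", "part2"}:
                raise SessionFormatError(
                    f"split labels must partition into part1/part2, got {sorted(labels)}"
                )

    def by_split(self, split: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == split]

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.subject_id, None)
        return list(seen)


# ---------------------------------------------------------------------------
# session / RBG files
# ---------------------------------------------------------------------------

def _channel_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"ch{i + 1:0{width}d}" for i in range(n)]


def read_session(
    session_path: str | Path,
    rbg_path: str | Path,
    session_id: str = "",
    subject_id: str = "",
) -> Session:
    """Load a session + RBG CSV pair into a validated :class:`Session`.

    The channel count is inferred from the session-file header.  Malformed
    headers, non-uniform grids, RBG samples outside the session span and
    non-positive glucose values raise :class:`SessionFormatError` naming the
    offending row.
    """
    df = pd.read_csv(session_path, float_precision="round_trip")
    if df.columns[0] != "time_s" or not all(c.startswith("ch") for c in df.columns[1:]):
        raise SessionFormatError(f"malformed session header in {session_path}")
    if df.shape[1] < 2:
        raise SessionFormatError(f"no channel columns in {session_path}")
    rbg = pd.read_csv(rbg_path, float_precision="round_trip")
    if list(rbg.columns) != ["time_s", "glucose_mgdl"]:
        raise SessionFormatError(f"malformed RBG header in {rbg_path}")
    sid = session_id or Path(session_path).stem
    return Session(
        session_id=sid,
        subject_id=subject_id or sid,
        t=df["time_s"].to_numpy(float),
        X=df.iloc[:, 1:].to_numpy(float).T,
        rbg_times=rbg["time_s"].to_numpy(float),
        rbg_values=rbg["glucose_mgdl"].to_numpy(float),
    )


def write_session(
    session: Session, session_path: str | Path, rbg_path: str | Path
) -> tuple[Path, Path]:
    """Write a session to the two-CSV dialect; round-trips exactly.

    Floats are written with pandas' default shortest round-trip repr, so
    ``read_session(*write_session(s, ...)) == s`` bit-for-bit.
    """
    session.validate()
    session_path, rbg_path = Path(session_path), Path(rbg_path)
    df = pd.DataFrame(session.X.T, columns=_channel_names(session.n_channels))
    df.insert(0, "time_s", session.t)
    df.to_csv(session_path, index=False)
    pd.DataFrame(
        {"time_s": session.rbg_times, "glucose_mgdl": session.rbg_values}
    ).to_csv(rbg_path, index=False)
    return session_path, rbg_path


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["session_id", "subject_id", "session_file", "rbg_file", "split"]


def read_manifest(path: str | Path) -> DatasetManifest:
    df = pd.read_csv(path, dtype=str).fillna("")
    if list(df.columns) != MANIFEST_COLUMNS:
        raise SessionFormatError(f"malformed manifest header in {path}")
    manifest = DatasetManifest(
        [ManifestEntry(*row) for row in df.itertuples(index=False)]
    )
    manifest.validate()
    return manifest


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    manifest.validate()
    df = pd.DataFrame(
        [
            (e.session_id, e.subject_id, e.session_file, e.rbg_file, e.split)
            for e in manifest.entries
        ],
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(path, index=False)
    return Path(path)


def load_sessions(
    manifest: DatasetManifest, root: str | Path = "."
) -> list[Session]:
    """Read every session listed in a manifest (paths relative to ``root``)."""
    root = Path(root)
    return [
        read_session(
            root / e.session_file, root / e.rbg_file, e.session_id, e.subject_id
        )
        for e in manifest.entries
    ]


# ---------------------------------------------------------------------------
# identification / test split
# ---------------------------------------------------------------------------

def split_dataset(
    manifest: DatasetManifest, seed: int
) -> tuple[list[ManifestEntry], list[ManifestEntry]]:
    """Randomly split sessions into two parts, balanced per subject.

    Sessions of each subject are shuffled and dealt alternately so the two
    parts differ by at most one session per subject; which part receives a
    subject's odd session is itself random.  The returned entries carry
    ``split`` labels ``part1``/``part2``.  Deterministic given ``seed``.
    """
    if len(manifest.entries) < 2:
        raise ValueError("need at least 2 sessions to split")
    rng = np.random.default_rng(seed)
    part1: list[ManifestEntry] = []
    part2: list[ManifestEntry] = []
    for subject in manifest.subjects():
        entries = [e for e in manifest.entries if e.subject_id == subject]
        order = rng.permutation(len(entries))
        first = int(rng.integers(2))  # which part gets the odd session
        for k, idx in enumerate(order):
            e = entries[idx]
            e.split = "part1" if (k % 2 == first) else "part2"
            (part1 if e.split == "part1" else part2).append(e)
    if not part1 or not part2:
        # corner case: every subject has one session and all landed together
        src, dst = (part1, part2) if part2 == [] else (part2, part1)
        moved = src.pop()
        moved.split = "part2" if moved.split == "part1" else "part1"
        dst.append(moved)
    return part1, part2
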