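"""Functional datasets: per-subject voxels x conditions matrices.

A :class:`FunctionalDataset` carries, for one study, the normalized
activation estimates of every subject (``(n_subjects, P, N)``), together with
a condition table assigning every column to a (session, run, condition)
triple. Sessions partition the condition axis — each session gets its own
emission mean directions and concentration. Runs are repeated measurements
of the same conditions within a session; they are averaged before model
fitting, and selecting subsets of runs is how "amount of individual data"
is manipulated.

Missing measurements are NaN; a voxel/session whose sub-vector contains any
NaN or is exactly zero is flagged invalid and excluded from likelihood sums
rather than treated as an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

COND_COLUMNS = ("session", "run", "condition")


@dataclass
class FunctionalDataset:
    dataset_id: str
    subjects: list[str]
    data: np.ndarray  # (S, P, N), NaN = missing
    cond_info: pd.DataFrame  # columns: session, run, condition

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_subjects, P, N)")
        if len(self.subjects) != self.data.shape[0]:
            raise ValueError("subject list length does not match data")
        for col in COND_COLUMNS:
            if col not in self.cond_info.columns:
                raise ValueError(f"cond_info missing column {col!r}")
        if len(self.cond_info) != self.data.shape[2]:
            raise ValueError("cond_info rows must match condition axis")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def sessions(self) -> list:
        return sorted(self.cond_info["session"].unique())

    def session_partition(self) -> list[np.ndarray]:
        """Column indices per session, in session order; covers every column once."""
        return [
            np.flatnonzero((self.cond_info["session"] == s).to_numpy())
            for s in self.sessions
        ]

    def runs(self, session=None) -> list:
        info = self.cond_info
        if session is not None:
            info = info[info["session"] == session]
        return sorted(info["run"].unique())

    def select_runs(self, runs) -> "FunctionalDataset":
        """Restrict to the given run labels (all sessions)."""
        mask = self.cond_info["run"].isin(list(runs)).to_numpy()
        if not mask.any():
            raise ValueError("no columns match the requested runs")
        return FunctionalDataset(
            dataset_id=self.dataset_id,
            subjects=list(self.subjects),
            data=self.data[:, :, mask],
            cond_info=self.cond_info.loc[mask].reset_index(drop=True),
        )

    def split_half_by_runs(self) -> tuple["FunctionalDataset", "FunctionalDataset"]:
        """Two half-datasets by a floor split of the run labels."""
        runs = self.runs()
        if len(runs) < 2:
            raise ValueError("need at least two runs to split in half")
        half = len(runs) // 2
        return self.select_runs(runs[:half]), self.select_runs(runs[half:])

    def average_runs(self) -> "FunctionalDataset":
        """Average across runs, one column per (session, condition).

        NaNs are ignored in the mean; a cell missing in every run stays NaN.
        Output run label is 0 throughout.
        """
        info = self.cond_info
        keys = list(zip(info["session"], info["condition"]))
        uniq = list(dict.fromkeys(keys))  # preserves first-appearance order
        S, P, _ = self.data.shape
        out = np.empty((S, P, len(uniq)))
        for j, key in enumerate(uniq):
            cols = [c for c, k in enumerate(keys) if k == key]
            block = self.data[:, :, cols]
            with np.errstate(invalid="ignore"):
                out[:, :, j] = np.nanmean(block, axis=2)
        new_info = pd.DataFrame(
            {
                "session": [k[0] for k in uniq],
                "run": 0,
                "condition": [k[1] for k in uniq],
            }
        )
        return FunctionalDataset(self.dataset_id, list(self.subjects), out, new_info)

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """Write to a directory: matrices as a compressed array container,
        condition table and subject list as TSV."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path / "data.npz", data=self.data)
        self.cond_info.to_csv(path / "cond_info.tsv", sep="\t", index=False)
        pd.DataFrame({"subject": self.subjects}).to_csv(
            path / "subjects.tsv", sep="\t", index=False
        )
        (path / "dataset_id.txt").write_text(self.dataset_id + "\n")

    @classmethod
    def load(cls, path) -> "FunctionalDataset":
        path = Path(path)
        data = np.load(path / "data.npz")["data"]
        cond_info = pd.read_csv(path / "cond_info.tsv", sep="\t")
        subjects = pd.read_csv(path / "subjects.tsv", sep="\t")["subject"].astype(str)
        dataset_id = (path / "dataset_id.txt").read_text().strip()
        return cls(dataset_id, list(subjects), data, cond_info)


def normalize_profiles(
    data: np.ndarray, session_partition: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale each voxel's per-session sub-vector to unit norm.

    Parameters
    ----------
    data : (P, N) matrix for one subject (NaN = missing)
    session_partition : list of column-index arrays, one per session

    Returns
    -------
    normalized : (P, N), unit rows per session block; invalid blocks zeroed
    lengths : (P, n_sessions) signal lengths (vector norms before scaling)
    valid : (P, n_sessions) bool, False where the block was all-missing,
        contained NaN, or had zero norm
    """
    data = np.asarray(data, dtype=float)
    P = data.shape[0]
    S = len(session_partition)
    normalized = np.zeros_like(data)
    lengths = np.zeros((P, S))
    valid = np.zeros((P, S), dtype=bool)
    for n, cols in enumerate(session_partition):
        block = data[:, cols]
        finite = np.isfinite(block).all(axis=1)
        norms = np.zeros(P)
        norms[finite] = np.linalg.norm(block[finite], axis=1)
        ok = finite & (norms > 0)
        normalized[np.ix_(ok, cols)] = block[ok] / norms[ok, None]
        lengths[:, n] = norms
        valid[:, n] = ok
    return normalized, lengths, valid
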