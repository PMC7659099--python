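"""Longitudinal outcome container and wide-format CSV I/O.

A dataset is a subjects x timepoints matrix of a continuous outcome measured
at shared occasions, with an optional record of the simulated class each
subject was generated from. Missing cells are allowed (empty cells in CSV);
the likelihood marginalizes over them, assuming missing at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class LongitudinalDataset:
    """Wide-format repeated measures for one continuous outcome.

    Parameters
    ----------
    outcomes : (N, T) array
        Outcome values; unobserved cells may hold NaN.
    time_scores : (T,) array
        Real time codes used to build growth-curve design matrices
        (strictly increasing, e.g. ``0, 1, 2, 3, 4``).
    observed_mask : (N, T) bool array, optional
        True where the outcome was observed. Defaults to ``~isnan(outcomes)``.
    true_labels : (N,) int array, optional
        Simulated class memberships, coded 1..K. Only present for
        synthetic data; used by the evaluation layer.
    """

    outcomes: np.ndarray
    time_scores: np.ndarray
    observed_mask: np.ndarray | None = None
    true_labels: np.ndarray | None = None
    ids: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        self.time_scores = np.asarray(self.time_scores, dtype=float)
        if self.outcomes.ndim != 2:
            raise ValueError("outcomes must be a 2-D subjects x timepoints array")
        n, t = self.outcomes.shape
        if t < 2:
            raise ValueError("need at least two timepoints")
        if self.time_scores.shape != (t,):
            raise ValueError("time_scores length must match the number of columns")
        if np.any(np.diff(self.time_scores) <= 0):
            raise ValueError("time_scores must be strictly increasing")
        if self.observed_mask is None:
            self.observed_mask = ~np.isnan(self.outcomes)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.observed_mask.shape != (n, t):
            raise ValueError("observed_mask shape must match outcomes")
        if not self.observed_mask.any(axis=1).all():
            raise ValueError("every subject needs at least one observed timepoint")
        if not np.isfinite(self.outcomes[self.observed_mask]).all():
            raise ValueError("observed outcome values must be finite")
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=int)
            if self.true_labels.shape != (n,):
                raise ValueError("true_labels length must match the number of subjects")
        if self.ids is None:
            self.ids = np.arange(1, n + 1)

    @property
    def n_subjects(self) -> int:
        return self.outcomes.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.outcomes.shape[1]

    @property
    def is_complete(self) -> bool:
        return bool(self.observed_mask.all())

    def to_csv(self, path: str | Path) -> None:
        """Write as wide CSV: ``id,t1..tT[,true_class]``; missing = empty."""
        t = self.n_timepoints
        cols = {"id": self.ids}
        for j in range(t):
            col = self.outcomes[:, j].copy()
            col[~self.observed_mask[:, j]] = np.nan
            cols[f"t{j + 1}"] = col
        if self.true_labels is not None:
            cols["true_class"] = self.true_labels
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, time_scores: np.ndarray | None = None
    ) -> "LongitudinalDataset":
        """Read a wide CSV with header ``id,t1..tT[,true_class]``.

        ``time_scores`` defaults to ``0..T-1`` when not supplied.
        """
        df = pd.read_csv(path)
        tcols = [c for c in df.columns if c.lower().startswith("t") and c[1:].isdigit()]
        tcols = sorted(tcols, key=lambda c: int(c[1:]))
        if len(tcols) < 2:
            raise ValueError(f"no outcome columns t1..tT found in {path}")
        outcomes = df[tcols].to_numpy(dtype=float)
        labels = None
        if "true_class" in df.columns:
            labels = df["true_class"].to_numpy(dtype=int)
        if time_scores is None:
            time_scores = np.arange(len(tcols), dtype=float)
        ids = df["id"].to_numpy() if "id" in df.columns else None
        return cls(outcomes, time_scores, true_labels=labels, ids=ids)
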