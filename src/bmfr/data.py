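"""Input containers: exposure panel, longitudinal outcomes, covariates.

All three containers are thin validated wrappers over numpy arrays, built
from (and exportable to) long-format pandas DataFrames / delimited text.

Column dictionary for the delimited-text interface:

* exposure table — one row per subject: ``subject_id`` plus one column per
  metabolite (natural- or log-scale concentration per the pipeline stage).
* LOD table — ``metabolite, lod`` (same scale as the exposure table).
* outcome table — one row per visit: ``subject_id, age`` plus one column per
  outcome; empty cells mark missing outcomes.
* covariate table — one row per visit, aligned with the outcome table:
  ``subject_id, age`` plus covariate columns (baseline covariates repeated
  across a subject's visits).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExposurePanel", "LongitudinalOutcomes", "CovariateTable"]


@dataclass
class ExposurePanel:
    """Subject-by-metabolite concentrations with detection-limit metadata.

    ``values`` holds log-scale concentrations after preprocessing; censored
    entries hold a working value (e.g. the log-LOD or a sampler imputation)
    that must never exceed the metabolite's log-LOD.
    """

    values: np.ndarray  # (n, p)
    lod: np.ndarray | None = None  # (p,) log-scale detection limits
    censored: np.ndarray | None = None  # (n, p) bool
    metabolite_names: list[str] | None = None
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("exposure values must be 2-d (subjects x metabolites)")
        n, p = self.values.shape
        if self.censored is None:
            self.censored = np.zeros((n, p), dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.censored.shape != (n, p):
            raise ValueError("censoring mask shape mismatch")
        if self.lod is not None:
            self.lod = np.asarray(self.lod, dtype=float)
            if self.lod.shape != (p,):
                raise ValueError("lod must have one entry per metabolite")
        elif self.censored.any():
            raise ValueError("censored entries present but no LODs given")
        if self.metabolite_names is None:
            self.metabolite_names = [f"x{j}" for j in range(p)]
        self.validate()

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.values[~self.censored])):
            raise ValueError("non-finite values in uncensored exposure entries")
        if self.lod is not None and self.censored.any():
            bound = np.broadcast_to(self.lod, self.values.shape)
            bad = self.values[self.censored] > bound[self.censored] + 1e-9
            if np.any(bad):
                raise ValueError("censored exposure entries exceed their log-LOD")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        lod: pd.Series | dict | None = None,
        subject_col: str = "subject_id",
    ) -> "ExposurePanel":
        cols = [c for c in frame.columns if c != subject_col]
        values = frame[cols].to_numpy(dtype=float)
        subject_ids = (
            frame[subject_col].to_numpy() if subject_col in frame.columns else None
        )
        lod_vec = None
        censored = None
        if lod is not None:
            lod = dict(lod)
            lod_vec = np.array([lod[c] for c in cols], dtype=float)
            censored = values <= lod_vec[None, :]
        return cls(values, lod_vec, censored, list(cols), subject_ids)

    @classmethod
    def from_csv(
        cls, path: str | Path, lod_path: str | Path | None = None
    ) -> "ExposurePanel":
        frame = pd.read_csv(path)
        lod = None
        if lod_path is not None:
            lod_frame = pd.read_csv(lod_path)
            lod = dict(zip(lod_frame["metabolite"], lod_frame["lod"]))
        return cls.from_frame(frame, lod)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.metabolite_names)
        if self.subject_ids is not None:
            frame.insert(0, "subject_id", self.subject_ids)
        return frame


@dataclass
class LongitudinalOutcomes:
    """Ragged per-subject outcome series on a shared discrete age grid.

    Records are stored long: record ``r`` belongs to subject
    ``subject_index[r]`` and sits at grid slot ``t_index[r]`` (0-based into
    ``grid``). ``T = len(grid)`` equals the number of distinct observed ages.
    """

    y: np.ndarray  # (N, q)
    subject_index: np.ndarray  # (N,) int, 0..n-1
    t_index: np.ndarray  # (N,) int, 0..T-1
    grid: np.ndarray  # (T,) strictly increasing ages
    missing: np.ndarray | None = None  # (N, q) bool
    ages: np.ndarray | None = None  # (N,) raw visit ages in years
    outcome_names: list[str] | None = None
    subject_ids: np.ndarray | None = None  # (n,) original labels

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.subject_index = np.asarray(self.subject_index, dtype=int)
        self.t_index = np.asarray(self.t_index, dtype=int)
        self.grid = np.asarray(self.grid, dtype=float)
        N, q = self.y.shape
        if self.missing is None:
            self.missing = ~np.isfinite(self.y)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != (N, q):
            raise ValueError("missing mask shape mismatch")
        if self.subject_index.shape != (N,) or self.t_index.shape != (N,):
            raise ValueError("index array shape mismatch")
        if self.grid.size > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid ages must be strictly increasing")
        if self.t_index.min(initial=0) < 0 or self.t_index.max(initial=0) >= len(self.grid):
            raise ValueError("t_index out of grid range")
        if self.missing.all(axis=1).any():
            raise ValueError("records with every outcome missing must be dropped at load")
        if self.outcome_names is None:
            self.outcome_names = [f"y{j}" for j in range(q)]
        if self.ages is None:
            self.ages = self.grid[self.t_index]
        if N and self.subject_index.min() < 0:
            raise ValueError("negative subject index")
        # subjects appearing here each contribute >= 1 record by construction;
        # the full roster may contain exposure-only subjects with no visits
        self.y = np.where(self.missing, np.nan_to_num(self.y), self.y)

    @property
    def N(self) -> int:
        return self.y.shape[0]

    @property
    def q(self) -> int:
        return self.y.shape[1]

    @property
    def T(self) -> int:
        return len(self.grid)

    @property
    def n_subjects(self) -> int:
        return int(self.subject_index.max()) + 1

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        outcome_cols: list[str] | None = None,
        subject_col: str = "subject_id",
        age_col: str = "age",
        subject_order: np.ndarray | None = None,
    ) -> "LongitudinalOutcomes":
        """Build from a long table; visit ages are rounded to integer years
        to form the discrete grid."""
        if outcome_cols is None:
            outcome_cols = [c for c in frame.columns if c not in (subject_col, age_col)]
        y = frame[outcome_cols].to_numpy(dtype=float)
        missing = ~np.isfinite(y)
        keep = ~missing.all(axis=1)
        frame = frame.loc[keep]
        y, missing = y[keep], missing[keep]
        if subject_order is None:
            subject_order = pd.unique(frame[subject_col])
        sid_to_idx = {s: i for i, s in enumerate(subject_order)}
        subject_index = frame[subject_col].map(sid_to_idx).to_numpy(dtype=int)
        ages = frame[age_col].to_numpy(dtype=float)
        grid_ages = np.round(ages).astype(int)
        grid = np.unique(grid_ages).astype(float)
        t_index = np.searchsorted(grid, grid_ages)
        return cls(
            y, subject_index, t_index, grid, missing, ages,
            list(outcome_cols), np.asarray(subject_order),
        )

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "LongitudinalOutcomes":
        return cls.from_frame(pd.read_csv(path), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.y, columns=self.outcome_names)
        frame[np.asarray(self.missing)] = np.nan
        ids = (
            self.subject_ids[self.subject_index]
            if self.subject_ids is not None
            else self.subject_index
        )
        frame.insert(0, "age", self.ages)
        frame.insert(0, "subject_id", ids)
        return frame

    def visits_per_subject(self) -> np.ndarray:
        return np.bincount(self.subject_index, minlength=self.n_subjects)


@dataclass
class CovariateTable:
    """Per-record covariate design aligned with the outcome records."""

    z: np.ndarray  # (N, L)
    labels: list[str] | None = None
    is_dummy: np.ndarray | None = None  # (L,) bool

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("covariates must be 2-d (records x covariates)")
        L = self.z.shape[1]
        if self.labels is None:
            self.labels = [f"z{l}" for l in range(L)]
        if self.is_dummy is None:
            self.is_dummy = np.array(
                [set(np.unique(self.z[:, l])) <= {0.0, 1.0} for l in range(L)]
            )
        self.is_dummy = np.asarray(self.is_dummy, dtype=bool)

    @property
    def L(self) -> int:
        return self.z.shape[1]

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        drop_cols: tuple[str, ...] = ("subject_id", "age"),
    ) -> "CovariateTable":
        cols = [c for c in frame.columns if c not in drop_cols]
        return cls(frame[cols].to_numpy(dtype=float), list(cols))

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "CovariateTable":
        return cls.from_frame(pd.read_csv(path), **kwargs)
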