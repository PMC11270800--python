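"""Study-level binary-outcome meta-analysis datasets.

A dataset holds one row per study with event counts and sample sizes for a
control arm (``x0``, ``n0``) and an experimental arm (``x1``, ``n1``).
Either arm may be absent (a *single-arm* study); a study with zero events
in both arms is a *double-zero* study.  Both kinds are first-class citizens
here: the binomial likelihood of the arm-based model handles them without
continuity corrections, which are only ever applied for descriptive
plotting of observed event probabilities.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import pearsonr

__all__ = [
    "StudyRecord",
    "MetaDataset",
    "ValidationReport",
    "parse_dataset",
    "read_dataset",
    "validate_dataset",
    "observed_logit_probs",
    "empirical_arm_correlation",
]

CSV_COLUMNS = ("study_id", "x0", "n0", "x1", "n1")


@dataclass(frozen=True)
class StudyRecord:
    """One study's arm-level counts.

    Parameters
    ----------
    study_id : str
        Unique label for the study.
    x0, n0 : int or None
        Events and sample size in the control arm, or ``None`` if the study
        did not include a control arm.  The pair is all-or-nothing.
    x1, n1 : int or None
        Events and sample size in the experimental arm, analogously.
    """

    study_id: str
    x0: int | None = None
    n0: int | None = None
    x1: int | None = None
    n1: int | None = None

    def __post_init__(self):
        for label, x, n in (("control", self.x0, self.n0),
                            ("experimental", self.x1, self.n1)):
            if (x is None) != (n is None):
                raise ValueError(
                    f"study {self.study_id!r}: {label} arm must provide both "
                    f"event count and sample size, or neither")
            if x is not None:
                if n < 1:
                    raise ValueError(
                        f"study {self.study_id!r}: {label} arm sample size must be >= 1")
                if x < 0 or x > n:
                    raise ValueError(
                        f"study {self.study_id!r}: {label} arm needs 0 <= x <= n, "
                        f"got x={x}, n={n}")
        if self.x0 is None and self.x1 is None:
            raise ValueError(f"study {self.study_id!r}: both arms missing")

    @property
    def has_control(self) -> bool:
        return self.x0 is not None

    @property
    def has_experimental(self) -> bool:
        return self.x1 is not None

    @property
    def is_single_arm(self) -> bool:
        return not (self.has_control and self.has_experimental)

    @property
    def is_double_zero(self) -> bool:
        return self.x0 == 0 and self.x1 == 0 and not self.is_single_arm


@dataclass(frozen=True)
class MetaDataset:
    """An ordered collection of :class:`StudyRecord` forming one meta-analysis."""

    studies: tuple[StudyRecord, ...]
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "studies", tuple(self.studies))
        if len(self.studies) == 0:
            raise ValueError("a meta-analysis needs at least one study")
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate study_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    # ---- tabular views -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Return a DataFrame with columns study_id, x0, n0, x1, n1.

        Missing arms appear as NaN (nullable Int64 columns).
        """
        rows = [(s.study_id, s.x0, s.n0, s.x1, s.n1) for s in self.studies]
        df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
        for c in CSV_COLUMNS[1:]:
            df[c] = df[c].astype("Int64")
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "") -> "MetaDataset":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        studies = []
        for idx, row in df.iterrows():
            vals = {}
            for c in CSV_COLUMNS[1:]:
                v = row[c]
                if pd.isna(v):
                    vals[c] = None
                else:
                    f = float(v)
                    if f != int(f):
                        raise ValueError(
                            f"row {idx} ({row['study_id']!r}): column {c} "
                            f"must be an integer, got {v!r}")
                    vals[c] = int(f)
            try:
                studies.append(StudyRecord(str(row["study_id"]), **vals))
            except ValueError as err:
                raise ValueError(f"row {idx}: {err}") from err
        return cls(tuple(studies), name=name)

    # ---- serialization -------------------------------------------------
    def to_csv(self, path_or_buf=None):
        """Serialize to CSV; missing arms become empty cells."""
        return self.to_frame().to_csv(path_or_buf, index=False)

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "studies": [
                {"study_id": s.study_id, "x0": s.x0, "n0": s.n0,
                 "x1": s.x1, "n1": s.n1}
                for s in self.studies
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MetaDataset":
        payload = json.loads(text)
        studies = tuple(StudyRecord(**rec) for rec in payload["studies"])
        return cls(studies, name=payload.get("name", ""))

    # ---- arrays for the sampler ----------------------------------------
    def arm_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (x, n, observed) arrays of shape (N, 2).

        Missing arms carry x = n = 0 and observed = False; the likelihood
        must skip them.
        """
        N = len(self.studies)
        x = np.zeros((N, 2))
        n = np.zeros((N, 2))
        obs = np.zeros((N, 2), dtype=bool)
        for i, s in enumerate(self.studies):
            for k, (xv, nv) in enumerate(((s.x0, s.n0), (s.x1, s.n1))):
                if xv is not None:
                    x[i, k] = xv
                    n[i, k] = nv
                    obs[i, k] = True
        return x, n, obs


@dataclass(frozen=True)
class ValidationReport:
    n_studies: int
    n_single_arm: int
    n_double_zero: int
    warnings: tuple[str, ...] = field(default_factory=tuple)


def parse_dataset(csv_text: str, name: str = "") -> MetaDataset:
    """Parse a CSV string into a :class:`MetaDataset`.

    The header must contain ``study_id,x0,n0,x1,n1``; empty cells denote a
    missing arm.  Malformed numbers, x > n, negative counts, or a row with
    both arms missing are rejected with the offending row named.
    """
    df = pd.read_csv(io.StringIO(csv_text), dtype={"study_id": str})
    return MetaDataset.from_frame(df, name=name)


def read_dataset(path, name: str | None = None) -> MetaDataset:
    """Read a dataset CSV from ``path``."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if name is None:
        name = str(path)
    return parse_dataset(text, name=name)


def validate_dataset(d: MetaDataset) -> ValidationReport:
    """Describe a dataset: study counts and structural warnings.

    Purely descriptive — hard violations are already rejected at parse time.
    """
    n_single = sum(s.is_single_arm for s in d)
    n_dz = sum(s.is_double_zero for s in d)
    warnings = []
    n_complete = sum(not s.is_single_arm for s in d)
    if n_complete == 0:
        warnings.append(
            "no study reports both arms: comparative effect measures are "
            "inestimable without information borrowing across arms")
    if len(d) < 2:
        warnings.append("fewer than 2 studies: between-study heterogeneity "
                        "and correlation are not identifiable from data")
    if n_dz:
        warnings.append(f"{n_dz} double-zero study(ies) present; they are "
                        "retained by the binomial likelihood")
    return ValidationReport(len(d), n_single, n_dz, tuple(warnings))


def observed_logit_probs(d: MetaDataset, correction: float = 0.5) -> np.ndarray:
    """Observed per-arm event probabilities on the logit scale.

    For each present arm returns ``logit((x + c) / (n + 2c))`` with
    continuity correction ``c >= 0``; absent arms are NaN.  A positive
    correction is required whenever any arm has x = 0 or x = n, otherwise
    the logit is infinite.

    Returns an array of shape (N, 2), column 0 = control, 1 = experimental.
    """
    if correction < 0:
        raise ValueError("correction must be nonnegative")
    x, n, obs = d.arm_arrays()
    if correction == 0:
        bad = obs & ((x == 0) | (x == n))
        if bad.any():
            i = int(np.argwhere(bad)[0, 0])
            raise ValueError(
                f"study {d.studies[i].study_id!r} has a boundary event count; "
                "a positive continuity correction is required")
    p = (x + correction) / (n + 2 * correction)
    out = np.full_like(p, np.nan)
    out[obs] = logit(p[obs])
    return out


def empirical_arm_correlation(d: MetaDataset, correction: float = 0.5) -> float:
    """Pearson correlation of the two arms' observed logit probabilities.

    Computed across studies reporting both arms.  Requires at least three
    complete studies and non-degenerate variance in each arm.
    """
    lg = observed_logit_probs(d, correction)
    complete = ~np.isnan(lg).any(axis=1)
    pairs = lg[complete]
    if pairs.shape[0] < 3:
        raise ValueError(
            f"need >= 3 studies with both arms present, got {pairs.shape[0]}")
    if np.ptp(pairs[:, 0]) == 0 or np.ptp(pairs[:, 1]) == 0:
        raise ValueError("zero variance in one arm's observed logits")
    r, _ = pearsonr(pairs[:, 0], pairs[:, 1])
    return float(r)
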