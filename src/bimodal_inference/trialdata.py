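"""Trial-level data model and preprocessing for binary perceptual decision tables.

Two stimulus dialects are supported:

``binary_category``
    The stimulus is one of two categories, coded 0/1 (human-style forced
    choice between two alternatives).
``signed_contrast``
    The stimulus is a signed contrast difference (right minus left) in
    [-1, 1] (mouse two-alternative visual task style); its sign defines
    the correct response and zero-contrast trials have no correct answer.

A :class:`TrialSeries` is one subject/session's ordered trials; a
:class:`CohortDataset` is an ordered collection of series sharing a dialect.
Cohorts round-trip through a plain CSV contract with mandatory columns
``subject_id, group_id, stimulus, choice`` and optional
``confidence, response_time, difficulty``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BINARY_CATEGORY = "binary_category"
SIGNED_CONTRAST = "signed_contrast"
DIALECTS = (BINARY_CATEGORY, SIGNED_CONTRAST)

MANDATORY_COLUMNS = ("subject_id", "group_id", "stimulus", "choice")
OPTIONAL_COLUMNS = ("confidence", "response_time", "difficulty")

#: consistency constant making MAD comparable to the SD under normality
MAD_SCALE = 1.4826


class SchemaError(ValueError):
    """A table does not satisfy the cohort CSV column contract."""


class ValidationError(ValueError):
    """A table satisfies the schema but carries invalid values."""


def _as_optional(values, n: int) -> np.ndarray:
    if values is None:
        return np.full(n, np.nan)
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise ValidationError(f"optional column has shape {arr.shape}, expected ({n},)")
    return arr


@dataclass
class TrialSeries:
    """Ordered trials of one subject within one group (study or session)."""

    subject_id: str
    group_id: str
    stimulus: np.ndarray
    choice: np.ndarray
    dialect: str
    confidence: np.ndarray | None = None
    response_time: np.ndarray | None = None
    difficulty: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stimulus = np.asarray(self.stimulus, dtype=float)
        self.choice = np.asarray(self.choice)
        n = self.stimulus.size
        if self.dialect not in DIALECTS:
            raise ValidationError(f"unknown dialect {self.dialect!r}")
        if self.choice.shape != (n,):
            raise ValidationError("stimulus and choice must have equal length")
        choice_f = np.asarray(self.choice, dtype=float)
        bad = ~np.isin(choice_f, (0.0, 1.0))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"subject {self.subject_id!r}: non-binary choice "
                f"{choice_f[row]!r} at trial {row + 1}"
            )
        self.choice = choice_f.astype(np.int64)
        if not np.isfinite(self.stimulus).all():
            raise ValidationError(f"subject {self.subject_id!r}: non-finite stimulus")
        if self.dialect == BINARY_CATEGORY:
            if not np.isin(self.stimulus, (0.0, 1.0)).all():
                raise ValidationError(
                    f"subject {self.subject_id!r}: binary_category stimulus must be 0/1"
                )
        else:
            if np.abs(self.stimulus).max(initial=0.0) > 1.0 + 1e-12:
                raise ValidationError(
                    f"subject {self.subject_id!r}: signed contrast must lie in [-1, 1]"
                )
        for name in OPTIONAL_COLUMNS:
            arr = _as_optional(getattr(self, name), n)
            if np.nanmin(arr, initial=np.inf) < 0:
                raise ValidationError(f"subject {self.subject_id!r}: negative {name}")
            setattr(self, name, arr)

    @property
    def n_trials(self) -> int:
        return int(self.stimulus.size)

    @property
    def trial_index(self) -> np.ndarray:
        """1-based consecutive trial index."""
        return np.arange(1, self.n_trials + 1)

    def stimulus_category(self) -> np.ndarray:
        """Binary category per trial (0/1); NaN where no correct answer exists.

        For the signed-contrast dialect the category is the sign of the
        contrast and zero-contrast trials are undefined.
        """
        if self.dialect == BINARY_CATEGORY:
            return self.stimulus.copy()
        cat = np.where(self.stimulus > 0, 1.0, 0.0)
        return np.where(self.stimulus == 0, np.nan, cat)

    def accuracy(self, mask: np.ndarray | None = None) -> float:
        """Fraction of choices matching the stimulus category (NaN categories skipped)."""
        cat = self.stimulus_category()
        keep = ~np.isnan(cat)
        if mask is not None:
            keep &= mask
        if not keep.any():
            return np.nan
        return float(np.mean(self.choice[keep] == cat[keep]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group_id": self.group_id,
                "trial_index": self.trial_index,
                "stimulus": self.stimulus,
                "choice": self.choice,
                "confidence": self.confidence,
                "response_time": self.response_time,
                "difficulty": self.difficulty,
            }
        )


@dataclass
class CohortDataset:
    """Ordered collection of :class:`TrialSeries` sharing one dialect."""

    series: list[TrialSeries]
    dialect: str
    provenance: dict = field(default_factory=dict)
    filter_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = set()
        for s in self.series:
            if s.dialect != self.dialect:
                raise ValidationError("all series must share the cohort dialect")
            key = (s.subject_id, s.group_id)
            if key in keys:
                raise ValidationError(f"duplicate subject/group pair {key}")
            keys.add(key)

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    @property
    def n_trials(self) -> int:
        return sum(s.n_trials for s in self.series)

    def group_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.series:
            seen.setdefault(s.group_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.series], ignore_index=True)


def cohort_from_frame(frame: pd.DataFrame, dialect: str) -> CohortDataset:
    """Build a validated cohort from a long-format trial table.

    Rows are grouped by (subject_id, group_id) in order of first appearance;
    within a pair the file's row order defines the trial order and the
    trial index is regenerated as 1..N.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    series = []
    for (sid, gid), sub in frame.groupby(["subject_id", "group_id"], sort=False):
        kwargs = {}
        for name in OPTIONAL_COLUMNS:
            if name in sub.columns:
                kwargs[name] = pd.to_numeric(sub[name], errors="coerce").to_numpy()
        series.append(
            TrialSeries(
                subject_id=str(sid),
                group_id=str(gid),
                stimulus=pd.to_numeric(sub["stimulus"]).to_numpy(),
                choice=sub["choice"].to_numpy(),
                dialect=dialect,
                **kwargs,
            )
        )
    return CohortDataset(series=series, dialect=dialect)


def read_cohort(path: str | Path, dialect: str) -> CohortDataset:
    """Read a cohort CSV (UTF-8, header row required) in the given dialect."""
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}")
    frame = pd.read_csv(path, encoding="utf-8")
    cohort = cohort_from_frame(frame, dialect)
    cohort.provenance["source"] = str(path)
    return cohort


def write_cohort(cohort: CohortDataset, path: str | Path, sidecar: bool = True) -> None:
    """Write a cohort CSV plus a JSON sidecar with provenance and filter log."""
    path = Path(path)
    cohort.to_frame().to_csv(path, index=False, encoding="utf-8")
    if sidecar:
        meta = {
            "dialect": cohort.dialect,
            "provenance": cohort.provenance,
            "filter_log": cohort.filter_log,
            "n_series": len(cohort),
            "n_trials": cohort.n_trials,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def filter_mouse_sessions(
    cohort: CohortDataset,
    contrast_floor: float = 0.5,
    accuracy_floor: float = 0.8,
) -> CohortDataset:
    """Drop sessions with poor accuracy on easy (high-contrast) trials.

    A series is retained when its accuracy on trials with
    ``|stimulus| >= contrast_floor`` is at least ``accuracy_floor``.
    Sessions with no easy trials at all are excluded (conservative) and
    logged.
    """
    if cohort.dialect != SIGNED_CONTRAST:
        raise ValidationError("filter_mouse_sessions requires the signed_contrast dialect")
    kept, log = [], list(cohort.filter_log)
    for s in cohort.series:
        easy = np.abs(s.stimulus) >= contrast_floor
        acc = s.accuracy(mask=easy)
        if np.isnan(acc):
            log.append(
                f"excluded {s.subject_id}/{s.group_id}: no trials at |contrast| >= {contrast_floor}"
            )
        elif acc < accuracy_floor:
            log.append(
                f"excluded {s.subject_id}/{s.group_id}: easy-trial accuracy {acc:.3f} < {accuracy_floor}"
            )
        else:
            kept.append(s)
    return CohortDataset(kept, cohort.dialect, dict(cohort.provenance), log)


def filter_experiments_by_accuracy(cohort: CohortDataset, floor: float = 0.5) -> CohortDataset:
    """Drop every series of a group whose pooled accuracy falls below ``floor``."""
    correct: dict[str, int] = {}
    total: dict[str, int] = {}
    for s in cohort.series:
        cat = s.stimulus_category()
        keep = ~np.isnan(cat)
        correct[s.group_id] = correct.get(s.group_id, 0) + int((s.choice[keep] == cat[keep]).sum())
        total[s.group_id] = total.get(s.group_id, 0) + int(keep.sum())
    log = list(cohort.filter_log)
    bad_groups = set()
    for gid in total:
        acc = correct[gid] / total[gid] if total[gid] else np.nan
        if not np.isfinite(acc) or acc < floor:
            bad_groups.add(gid)
            log.append(f"excluded group {gid}: pooled accuracy {acc:.3f} < {floor}")
    kept = [s for s in cohort.series if s.group_id not in bad_groups]
    return CohortDataset(kept, cohort.dialect, dict(cohort.provenance), log)


def normalize_within_group(values: Sequence[float], groups: Sequence) -> np.ndarray:
    """Z-score values within each group over their non-missing entries.

    Missing entries (NaN) stay missing. Groups with zero variance return
    all zeros with a warning; groups need at least 2 non-missing entries.
    The sample standard deviation (ddof=1) is used.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = np.full_like(values, np.nan)
    for g in pd.unique(groups):
        idx = groups == g
        v = values[idx]
        ok = ~np.isnan(v)
        if ok.sum() < 2:
            raise ValidationError(f"group {g!r}: need >= 2 non-missing values to normalize")
        sd = np.std(v[ok], ddof=1)
        if sd == 0:
            warnings.warn(f"group {g!r}: zero variance, normalized values set to 0")
            z = np.where(ok, 0.0, np.nan)
        else:
            z = (v - np.mean(v[ok])) / sd
        out[idx] = z
    return out


def exclude_outliers(values: Sequence[float], rule: str = "mad", k: float = 3.0) -> np.ndarray:
    """Boolean mask of retained entries under a robust or Gaussian rule.

    ``mad``: retain entries within ``k`` scaled MADs (constant 1.4826) of the
    median. ``sd``: retain entries within ``k`` standard deviations of the
    mean. Missing entries are never retained. With a degenerate spread of 0
    (e.g. more than half the entries identical under the MAD rule) only
    entries equal to the center are retained, so all-identical input is
    fully retained while gross outliers still drop.
    """
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    v = values[ok]
    mask = np.zeros(values.shape, dtype=bool)
    if v.size == 0:
        return mask
    if rule == "mad":
        center = np.median(v)
        spread = MAD_SCALE * np.median(np.abs(v - center))
    elif rule == "sd":
        center = np.mean(v)
        spread = np.std(v, ddof=1) if v.size > 1 else 0.0
    else:
        raise ValueError(f"unknown rule {rule!r}")
    mask[ok] = np.abs(v - center) <= k * spread
    return mask
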