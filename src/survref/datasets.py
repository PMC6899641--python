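"""Subject-level survival data container and delimited-text round-tripping.

The canonical in-memory object is a validated :class:`pandas.DataFrame` wrapped
by :class:`SurvivalData`. One row per subject with columns

    subject_id, time, event, arm, <covariate columns...>

``time`` is a positive study time, ``event`` is 1 if the event was observed at
``time`` and 0 if the subject was right-censored there, ``arm`` is the binary
treatment indicator (1 = active, 0 = reference). Any further numeric columns
are baseline covariates carried into the imputation model's linear predictor.

Stacked multiple-imputation files follow the common MI long-format convention:
an extra leading ``imputation`` column, index 0 reserved for the original
(incomplete) data and 1..K for the completed copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

REQUIRED_COLUMNS = ("subject_id", "time", "event", "arm")
IMPUTATION_COLUMN = "imputation"


def _bad_rows(mask: np.ndarray, limit: int = 10) -> str:
    rows = np.flatnonzero(mask)
    head = ", ".join(str(r) for r in rows[:limit])
    more = "" if rows.size <= limit else f" (+{rows.size - limit} more)"
    return head + more


@dataclass(frozen=True)
class SurvivalData:
    """Validated two-arm survival dataset.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``subject_id, time, event, arm`` plus covariates. A defensive
        copy is stored; downstream code never mutates it.
    covariate_names : tuple of str
        Ordered covariate column labels (may be empty).
    time_unit : str
        Free-text metadata (e.g. ``"years"``); informational only.
    """

    frame: pd.DataFrame
    covariate_names: tuple[str, ...] = ()
    time_unit: str = ""

    # ------------------------------------------------------------------ build
    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        covariate_names: Sequence[str] | None = None,
        time_unit: str = "",
    ) -> "SurvivalData":
        """Validate ``frame`` and wrap it.

        Covariates default to every column beyond the required four, in order.
        """
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        if covariate_names is None:
            covariate_names = [c for c in frame.columns if c not in REQUIRED_COLUMNS]
        else:
            absent = [c for c in covariate_names if c not in frame.columns]
            if absent:
                raise ValidationError(f"covariate columns not present: {absent}")
        cols = list(REQUIRED_COLUMNS) + list(covariate_names)
        df = frame[cols].copy().reset_index(drop=True)

        time = pd.to_numeric(df["time"], errors="coerce").to_numpy(float)
        bad = ~np.isfinite(time) | (time <= 0)
        if bad.any():
            raise ValidationError(f"nonpositive or non-numeric time in rows: {_bad_rows(bad)}")
        event = pd.to_numeric(df["event"], errors="coerce").to_numpy(float)
        bad = ~np.isin(event, (0.0, 1.0))
        if bad.any():
            raise ValidationError(f"event must be 0/1; offending rows: {_bad_rows(bad)}")
        arm = pd.to_numeric(df["arm"], errors="coerce").to_numpy(float)
        bad = ~np.isin(arm, (0.0, 1.0))
        if bad.any():
            raise ValidationError(f"arm must be 0/1; offending rows: {_bad_rows(bad)}")
        if df["subject_id"].duplicated().any():
            dup = df["subject_id"][df["subject_id"].duplicated()].unique()[:10]
            raise ValidationError(f"duplicate subject_ids: {list(dup)}")
        for c in covariate_names:
            x = pd.to_numeric(df[c], errors="coerce").to_numpy(float)
            if not np.isfinite(x).all():
                raise ValidationError(
                    f"covariate {c!r} non-numeric/non-finite in rows: "
                    f"{_bad_rows(~np.isfinite(x))}"
                )
            df[c] = x
        df["time"] = time
        df["event"] = event.astype(np.int64)
        df["arm"] = arm.astype(np.int64)
        return cls(df, tuple(covariate_names), time_unit)

    # -------------------------------------------------------------- accessors
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def times(self) -> np.ndarray:
        return self.frame["time"].to_numpy(float)

    @property
    def events(self) -> np.ndarray:
        return self.frame["event"].to_numpy(np.int64)

    @property
    def arms(self) -> np.ndarray:
        return self.frame["arm"].to_numpy(np.int64)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    def covariates(self) -> np.ndarray:
        """Covariate matrix of shape (n, p); p may be 0."""
        if not self.covariate_names:
            return np.empty((self.n, 0))
        return self.frame[list(self.covariate_names)].to_numpy(float)

    def design_matrix(self) -> np.ndarray:
        """Arm indicator followed by covariates: shape (n, 1 + p)."""
        return np.column_stack([self.arms.astype(float), self.covariates()])

    def n_events(self, arm: int | None = None) -> int:
        if arm is None:
            return int(self.events.sum())
        return int(self.events[self.arms == arm].sum())

    def with_rows(self, times: np.ndarray, events: np.ndarray) -> "SurvivalData":
        """Copy with replaced time/event columns (same subjects, same order)."""
        df = self.frame.copy()
        df["time"] = np.asarray(times, float)
        df["event"] = np.asarray(events, np.int64)
        return SurvivalData(df, self.covariate_names, self.time_unit)

    def __eq__(self, other: object) -> bool:  # value semantics for tests
        if not isinstance(other, SurvivalData):
            return NotImplemented
        return (
            self.covariate_names == other.covariate_names
            and self.frame.equals(other.frame)
        )

    # --------------------------------------------------------------------- io
    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, time_unit: str = "") -> "SurvivalData":
        try:
            frame = pd.read_csv(path)
        except FileNotFoundError:
            raise
        except Exception as exc:  # malformed delimited text
            raise ValidationError(f"could not parse {path}: {exc}") from exc
        return cls.from_frame(frame, time_unit=time_unit)


# ------------------------------------------------------------------ MI stack
def write_stacked(
    original: SurvivalData,
    completed: Iterable[SurvivalData],
    path: str | Path,
) -> None:
    """Write original data (index 0) and completed copies (1..K) long-format."""
    frames = [original.frame.assign(**{IMPUTATION_COLUMN: 0})]
    for k, ds in enumerate(completed, start=1):
        frames.append(ds.frame.assign(**{IMPUTATION_COLUMN: k}))
    out = pd.concat(frames, ignore_index=True)
    cols = [IMPUTATION_COLUMN] + [c for c in out.columns if c != IMPUTATION_COLUMN]
    out[cols].to_csv(path, index=False)


def read_stacked(path: str | Path) -> tuple[SurvivalData, list[SurvivalData]]:
    """Read a stacked MI file; returns (original, [K completed datasets]).

    K is detected from the imputation index; index 0 must be present.
    """
    frame = pd.read_csv(path, comment="#")
    if IMPUTATION_COLUMN not in frame.columns:
        raise ValidationError(f"stacked file lacks an {IMPUTATION_COLUMN!r} column")
    idx = frame[IMPUTATION_COLUMN].to_numpy()
    levels = sorted(set(int(i) for i in idx))
    if levels[0] != 0:
        raise ValidationError("stacked file must contain the original data at imputation=0")
    def _sub(k: int) -> SurvivalData:
        sub = frame[frame[IMPUTATION_COLUMN] == k].drop(columns=[IMPUTATION_COLUMN])
        return SurvivalData.from_frame(sub)
    original = _sub(0)
    completed = [_sub(k) for k in levels[1:]]
    return original, completed
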