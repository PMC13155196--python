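"""Long-format recurrent-event data container.

One row per gap time: subject id, recurrence index, gap time, event
indicator, latency covariates Z and incidence covariates V (with a leading
intercept column).  Records are stored sorted by (subject, recurrence
index) so that each subject's rows are contiguous, which the estimation
code relies on for fast per-subject reductions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DataValidationError(ValueError):
    """Raised when a long-format table violates the data contract.

    Carries the offending (0-based) row indices of the source table.
    """

    def __init__(self, message: str, rows=None):
        self.rows = [] if rows is None else list(rows)
        if self.rows:
            message = f"{message} (rows: {self.rows})"
        super().__init__(message)


@dataclass(frozen=True)
class RecurrentData:
    """Immutable array-of-records view of a recurrent-event gap-time table.

    Attributes
    ----------
    subject_labels : original subject identifiers, one per record.
    subject : integer subject codes 0..N-1, one per record, nondecreasing.
    recurrence : 1-based recurrence index within subject.
    gap : positive gap times.
    delta : event indicators (1 = recurrence observed, 0 = censored).
    Z : (n_records, p) latency covariate matrix.
    V : (n_records, q) incidence covariate matrix, first column all ones.
    unit : time-unit metadata ("years" for simulated data, "days" for the
        hospital-readmission layout); carried through, never converted.
    """

    subject_labels: np.ndarray
    subject: np.ndarray
    recurrence: np.ndarray
    gap: np.ndarray
    delta: np.ndarray
    Z: np.ndarray
    V: np.ndarray
    z_names: tuple = ()
    v_names: tuple = ()
    unit: str = "years"

    def __post_init__(self):
        if self.gap.shape[0] != self.delta.shape[0]:
            raise DataValidationError("gap and delta lengths differ")

    # -- shapes ------------------------------------------------------------
    @property
    def n_records(self) -> int:
        return self.gap.shape[0]

    @property
    def n_subjects(self) -> int:
        return 0 if self.n_records == 0 else int(self.subject.max()) + 1

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    @property
    def q(self) -> int:
        return self.V.shape[1]

    @property
    def is_event(self) -> np.ndarray:
        return self.delta == 1

    @property
    def subject_starts(self) -> np.ndarray:
        """Start index of each subject's contiguous block (for reduceat)."""
        if self.n_records == 0:
            return np.zeros(0, dtype=np.int64)
        change = np.flatnonzero(np.diff(self.subject)) + 1
        return np.concatenate(([0], change))

    def subject_counts(self) -> np.ndarray:
        return np.bincount(self.subject, minlength=self.n_subjects)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        z_cols,
        v_cols,
        id_col: str = "subject_id",
        gap_col: str = "gap_time",
        event_col: str = "event",
        index_col: str = "recurrence_index",
        add_intercept: bool = True,
        unit: str = "years",
        validate: bool = True,
    ) -> "RecurrentData":
        z_cols = list(z_cols)
        v_cols = list(v_cols)
        missing = [c for c in [id_col, gap_col, event_col] + z_cols + v_cols
                   if c not in df.columns]
        if missing:
            raise DataValidationError(f"missing columns: {missing}")

        df = df.reset_index(drop=True)
        if validate:
            gaps = pd.to_numeric(df[gap_col], errors="coerce")
            bad_gap = df.index[~(gaps > 0)].tolist()
            if bad_gap:
                raise DataValidationError("non-positive or non-numeric gap_time",
                                          rows=bad_gap)
            ev = pd.to_numeric(df[event_col], errors="coerce")
            bad_ev = df.index[~ev.isin([0, 1])].tolist()
            if bad_ev:
                raise DataValidationError("event indicator must be 0 or 1",
                                          rows=bad_ev)

        if index_col in df.columns:
            order_key = df[index_col]
        else:
            order_key = df.groupby(id_col, sort=False).cumcount() + 1
            df = df.assign(**{index_col: order_key})
        df = df.sort_values([id_col, index_col], kind="stable").reset_index(drop=True)

        labels = df[id_col].to_numpy()
        codes, _ = pd.factorize(df[id_col], sort=False)
        gap = df[gap_col].to_numpy(dtype=float)
        delta = df[event_col].to_numpy(dtype=np.int8)
        recurrence = df[index_col].to_numpy(dtype=np.int64)

        if validate and len(df):
            # within a subject only the last record should be censored in
            # model-generated data; observed data may violate this -> warn.
            cens = delta == 0
            last = np.zeros(len(df), dtype=bool)
            starts = np.concatenate(
                ([0], np.flatnonzero(np.diff(codes)) + 1, [len(codes)]))
            last[starts[1:] - 1] = True
            odd = np.flatnonzero(cens & ~last)
            if odd.size:
                warnings.warn(
                    f"{odd.size} censored record(s) are not the last record of "
                    "their subject; the model treats gaps as exchangeable given "
                    "the frailty, so this is allowed but unusual.",
                    UserWarning,
                )

        Z = df[z_cols].to_numpy(dtype=float) if z_cols else np.zeros((len(df), 0))
        Vraw = df[v_cols].to_numpy(dtype=float) if v_cols else np.zeros((len(df), 0))
        if add_intercept:
            V = np.column_stack([np.ones(len(df)), Vraw])
            v_names = ("intercept",) + tuple(v_cols)
        else:
            V = Vraw
            v_names = tuple(v_cols)
        return cls(
            subject_labels=labels,
            subject=codes.astype(np.int64),
            recurrence=recurrence,
            gap=gap,
            delta=delta,
            Z=Z,
            V=V,
            z_names=tuple(z_cols),
            v_names=v_names,
            unit=unit,
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "subject_id": self.subject_labels,
                "recurrence_index": self.recurrence,
                "gap_time": self.gap,
                "event": self.delta.astype(int),
            }
        )
        for j, name in enumerate(self.z_names):
            out[name] = self.Z[:, j]
        for j, name in enumerate(self.v_names):
            if name == "intercept":
                continue
            out[name] = self.V[:, j]
        return out
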