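"""Balanced panel time-series container and I/O.

A *panel* here is the canonical repeated-measures layout of physiological
time-course studies: N subjects observed at the same T ordinal time points
for V variables, optionally under a named experimental condition.  All
downstream statistics (panel unit-root testing, pooled within-estimator
Granger tests) assume the panel is balanced and complete, so the loader
rejects — never imputes — anything unbalanced, duplicated, or missing.

Time is ordinal: t = 0..T-1 in within-subject sort order of the declared
time column.  Real clock times (which may be unevenly spaced) can be kept
as metadata via ``time_labels`` but never enter any computation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "PanelError",
    "read_panel",
    "read_conditions",
    "write_panel",
    "correct_calcium",
    "difference",
]

#: default column names for the long layout
LONG_COLUMNS = ("subject", "condition", "time", "variable", "value")


class PanelError(ValueError):
    """Raised for structurally invalid panels (unbalanced, duplicated, ...)."""


@dataclass(frozen=True)
class PanelDataset:
    """Balanced N x T x V panel of real-valued measurements.

    Parameters
    ----------
    subjects
        Ordered unique subject identifiers (length N).
    variables
        Ordered unique variable names (length V).
    values
        Array of shape (N, T, V); no NaN/Inf allowed.
    condition
        Optional experimental-condition label for the whole block (panels
        from different conditions are analyzed separately, never pooled).
    units
        Optional free-text unit per variable.
    time_labels
        Optional metadata labels (e.g. clock times) for the T ordinal points.
    transform_log
        Human-readable record of transformations applied (differencing etc.).
    """

    subjects: tuple[str, ...]
    variables: tuple[str, ...]
    values: np.ndarray
    condition: str | None = None
    units: dict[str, str] = field(default_factory=dict)
    time_labels: tuple | None = None
    transform_log: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "subjects", tuple(str(s) for s in self.subjects))
        object.__setattr__(self, "variables", tuple(str(v) for v in self.variables))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if len(set(self.subjects)) != len(self.subjects):
            raise PanelError("subject identifiers must be unique")
        if len(set(self.variables)) != len(self.variables):
            raise PanelError("variable names must be unique")
        if not self.variables:
            raise PanelError("panel needs at least one variable")
        if vals.ndim != 3:
            raise PanelError(f"values must be 3-d (N, T, V), got shape {vals.shape}")
        n, t, v = vals.shape
        if n != len(self.subjects) or v != len(self.variables):
            raise PanelError(
                f"values shape {vals.shape} inconsistent with "
                f"{len(self.subjects)} subjects / {len(self.variables)} variables"
            )
        if n < 2:
            raise PanelError(f"panel requires N >= 2 subjects, got N={n}")
        if t < 4:
            raise PanelError(f"panel requires T >= 4 time points, got T={t}")
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise PanelError(
                "non-finite value at subject "
                f"{self.subjects[bad[0]]!r}, time {bad[1]}, "
                f"variable {self.variables[bad[2]]!r}"
            )

    # -- convenience ------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_variables(self) -> int:
        return self.values.shape[2]

    def series(self, variable: str) -> np.ndarray:
        """Return the (N, T) array of one variable's series."""
        return self.values[:, :, self._var_index(variable)]

    def _var_index(self, variable: str) -> int:
        try:
            return self.variables.index(variable)
        except ValueError:
            raise KeyError(f"unknown variable {variable!r}; have {self.variables}") from None

    def with_values(self, values: np.ndarray, log_entry: str | None = None,
                    time_labels: tuple | None = None) -> "PanelDataset":
        log = self.transform_log + ((log_entry,) if log_entry else ())
        return replace(self, values=values, transform_log=log, time_labels=time_labels)

    def to_frame(self, layout: str = "long") -> pd.DataFrame:
        """Render as a DataFrame in ``long`` or ``wide`` layout."""
        n, t, v = self.values.shape
        if layout == "long":
            rows = {
                "subject": np.repeat(self.subjects, t * v),
                "time": np.tile(np.repeat(np.arange(t), v), n),
                "variable": np.tile(self.variables, n * t),
                "value": self.values.reshape(-1),
            }
            df = pd.DataFrame(rows)
            if self.condition is not None:
                df.insert(1, "condition", self.condition)
            return df
        if layout == "wide":
            df = pd.DataFrame(
                self.values.reshape(n * t, v), columns=list(self.variables)
            )
            df.insert(0, "time", np.tile(np.arange(t), n))
            df.insert(0, "subject", np.repeat(self.subjects, t))
            if self.condition is not None:
                df.insert(1, "condition", self.condition)
            return df
        raise ValueError(f"unknown layout {layout!r}; use 'long' or 'wide'")


# -- I/O ------------------------------------------------------------------

def _delimiter(path: str) -> str:
    return "," if os.path.splitext(path)[1].lower() == ".csv" else "\t"


def _apply_schema(df: pd.DataFrame, schema: dict[str, str] | None) -> pd.DataFrame:
    if schema:
        rename = {src: dst for dst, src in schema.items() if src in df.columns}
        df = df.rename(columns=rename)
    return df


def _from_long(df: pd.DataFrame, condition: str | None) -> PanelDataset:
    for col in ("subject", "time", "variable", "value"):
        if col not in df.columns:
            raise PanelError(f"long layout requires a {col!r} column")
    has_cond = "condition" in df.columns
    if has_cond:
        conds = sorted(df["condition"].astype(str).unique())
        if condition is not None:
            df = df[df["condition"].astype(str) == condition]
            if df.empty:
                raise PanelError(f"no rows with condition {condition!r} (have {conds})")
        elif len(conds) > 1:
            raise PanelError(
                f"file contains multiple conditions {conds}; pass a condition "
                "filter or use read_conditions()"
            )
        else:
            condition = conds[0]

    vals = pd.to_numeric(df["value"], errors="coerce")
    if vals.isna().any():
        row = int(df.index[vals.isna()][0])
        raise PanelError(f"non-numeric value at input row {row}")

    dup = df.duplicated(subset=["subject", "time", "variable"])
    if dup.any():
        rec = df.loc[dup.idxmax()]
        raise PanelError(
            f"duplicate (subject, time, variable) record: "
            f"({rec['subject']!r}, {rec['time']!r}, {rec['variable']!r})"
        )

    subjects = sorted(df["subject"].astype(str).unique())
    variables = list(pd.unique(df["variable"].astype(str)))
    times = sorted(df["time"].unique())
    t_count = len(times)

    # balance: every subject must carry every (time, variable) cell
    expected = t_count * len(variables)
    counts = df.groupby(df["subject"].astype(str)).size()
    bad = counts[counts != expected]
    if len(bad):
        detail = ", ".join(f"{s} ({c}/{expected} cells)" for s, c in bad.items())
        raise PanelError(f"unbalanced panel; offending subjects: {detail}")

    cube = np.full((len(subjects), t_count, len(variables)), np.nan)
    s_idx = {s: i for i, s in enumerate(subjects)}
    t_idx = {t: i for i, t in enumerate(times)}
    v_idx = {v: i for i, v in enumerate(variables)}
    cube[
        [s_idx[s] for s in df["subject"].astype(str)],
        [t_idx[t] for t in df["time"]],
        [v_idx[v] for v in df["variable"].astype(str)],
    ] = vals.to_numpy(dtype=float)
    if np.isnan(cube).any():
        i, t, v = np.argwhere(np.isnan(cube))[0]
        raise PanelError(
            f"missing cell: subject {subjects[i]!r}, time {times[t]!r}, "
            f"variable {variables[v]!r}"
        )
    return PanelDataset(subjects, variables, cube, condition=condition,
                        time_labels=tuple(times))


def _from_wide(df: pd.DataFrame, condition: str | None) -> PanelDataset:
    for col in ("subject", "time"):
        if col not in df.columns:
            raise PanelError(f"wide layout requires a {col!r} column")
    id_cols = ["subject", "time"] + (["condition"] if "condition" in df.columns else [])
    variables = [c for c in df.columns if c not in id_cols]
    if not variables:
        raise PanelError("wide layout has no variable columns")
    long = df.melt(id_vars=id_cols, value_vars=variables,
                   var_name="variable", value_name="value")
    return _from_long(long, condition)


def read_panel(path: str, layout: str = "long",
               schema: dict[str, str] | None = None,
               condition: str | None = None) -> PanelDataset:
    """Load a balanced panel from a delimited text file.

    Parameters
    ----------
    path
        CSV (comma) or TSV/other (tab) file; delimiter inferred from the
        extension.
    layout
        ``"long"`` — columns subject, [condition,] time, variable, value;
        ``"wide"`` — one row per (subject, [condition,] time), one column
        per variable.
    schema
        Optional mapping from canonical column names (``subject`` ...) to
        the names actually used in the file.
    condition
        Optional filter when the file holds several conditions.

    Raises
    ------
    PanelError
        On unbalanced panels (naming the offending subjects), duplicate
        (subject, time, variable) records, missing cells, or non-numeric
        values (with the row number).
    """
    df = pd.read_csv(path, sep=_delimiter(path), float_precision="round_trip")
    df = _apply_schema(df, schema)
    if layout == "long":
        return _from_long(df, condition)
    if layout == "wide":
        return _from_wide(df, condition)
    raise ValueError(f"unknown layout {layout!r}; use 'long' or 'wide'")


def read_conditions(path: str, layout: str = "long",
                    schema: dict[str, str] | None = None) -> dict[str, PanelDataset]:
    """Load a multi-condition file as one balanced panel per condition."""
    df = pd.read_csv(path, sep=_delimiter(path), float_precision="round_trip")
    df = _apply_schema(df, schema)
    if "condition" not in df.columns:
        raise PanelError("file has no condition column")
    parser = _from_long if layout == "long" else _from_wide
    return {
        str(c): parser(df, str(c))
        for c in pd.unique(df["condition"].astype(str))
    }


def write_panel(panel: PanelDataset, path: str, layout: str = "long") -> None:
    """Serialize a panel so that :func:`read_panel` round-trips it exactly.

    Values are written at full precision (``repr`` float formatting);
    any rounding is a presentation concern, never a storage one.
    """
    df = panel.to_frame(layout)
    df.to_csv(path, sep=_delimiter(path), index=False,
              float_format=None)  # full precision


# -- small numeric utilities ---------------------------------------------

def correct_calcium(total_calcium, albumin):
    """Albumin-corrected serum calcium (mmol/L).

    corrected = total + 0.02 x (40 - albumin), with total calcium in mmol/L
    and albumin in g/L; 40 g/L is the reference albumin at which no
    correction applies.  Accepts scalars or arrays.
    """
    ca = np.asarray(total_calcium, dtype=float)
    alb = np.asarray(albumin, dtype=float)
    if not (np.all(np.isfinite(ca)) and np.all(np.isfinite(alb))):
        raise ValueError("non-finite input to correct_calcium")
    if np.any(alb <= 0):
        raise ValueError("albumin must be positive (g/L)")
    out = ca + 0.02 * (40.0 - alb)
    return float(out) if out.ndim == 0 else out


def difference(panel: PanelDataset, variable: str, order: int = 1) -> PanelDataset:
    """Within-subject differencing of one variable.

    The named variable's series is replaced by its order-``order``
    differences; every other variable is truncated by dropping the first
    ``order`` time points so the panel stays balanced (T shrinks by
    ``order``).  The transformation is recorded in ``transform_log``.
    """
    return _difference_many(panel, [variable], order)


def _difference_many(panel: PanelDataset, variables: list[str], order: int = 1) -> PanelDataset:
    if order < 1:
        raise ValueError(f"difference order must be >= 1, got {order}")
    if order >= panel.n_times:
        raise ValueError(
            f"difference order {order} >= T={panel.n_times}; nothing would remain"
        )
    idx = [panel._var_index(v) for v in variables]
    new = panel.values[:, order:, :].copy()
    for j in idx:
        new[:, :, j] = np.diff(panel.values[:, :, j], n=order, axis=1)
    labels = panel.time_labels[order:] if panel.time_labels else None
    entry = f"difference(order={order}) on {', '.join(variables)}; T {panel.n_times}->{panel.n_times - order}"
    return panel.with_values(new, log_entry=entry, time_labels=labels)
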