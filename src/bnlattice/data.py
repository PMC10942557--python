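"""Sample-by-variable data container with per-column type metadata.

A :class:`DataMatrix` wraps a :class:`pandas.DataFrame` of N samples by p
variables, records whether each column is continuous or categorical, and
optionally designates one variable as the *outcome* (phenotype).  The
outcome may be a continuous column, a binary column, or a survival pair
(time column plus 0/1 event indicator); a survival outcome is exposed to
the rest of the package as a single virtual network node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: Integer-valued columns with at most this many distinct values are treated
#: as categorical by default (overridable per column).
CATEGORICAL_CARDINALITY = 5


@dataclass(frozen=True)
class Outcome:
    """Designated outcome variable.

    ``kind`` is one of ``continuous``, ``binary`` or ``survival``.  For a
    survival outcome ``time_column``/``event_column`` name the backing data
    columns and ``name`` is the virtual node label; otherwise ``name`` is
    the data column itself.
    """

    kind: str
    name: str
    time_column: str | None = None
    event_column: str | None = None

    @property
    def is_survival(self) -> bool:
        return self.kind == "survival"


class DataMatrix:
    """N x p data matrix with column types and an optional outcome."""

    def __init__(
        self,
        frame: pd.DataFrame,
        kinds: dict[str, str] | None = None,
        outcome: Outcome | None = None,
    ):
        if frame.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if frame.columns.duplicated().any():
            dupes = frame.columns[frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicate column names: {dupes}")
        if frame.isna().any().any():
            col = frame.columns[frame.isna().any()][0]
            row = int(frame[col].isna().idxmax())
            raise ValueError(f"missing value at row {row}, column {col!r}")
        self.frame = frame
        self.kinds = dict(kinds) if kinds is not None else infer_kinds(frame)
        for c in frame.columns:
            if c not in self.kinds:
                raise ValueError(f"no type for column {c!r}")
        self.outcome = outcome
        if outcome is not None and outcome.is_survival:
            t = frame[outcome.time_column].to_numpy(dtype=float)
            e = frame[outcome.event_column].to_numpy()
            if not np.all(t > 0):
                raise ValueError(
                    f"survival time column {outcome.time_column!r} must be > 0"
                )
            if not np.isin(e, [0, 1]).all():
                bad = sorted(set(e) - {0, 1})
                raise ValueError(
                    f"event column {outcome.event_column!r} must be 0/1, "
                    f"found {bad}"
                )
        self._validate_categorical()

    def _validate_categorical(self) -> None:
        for c, k in self.kinds.items():
            if k == CATEGORICAL and c in self.frame.columns:
                if self.frame[c].nunique() < 2:
                    raise ValueError(
                        f"categorical column {c!r} has < 2 observed levels"
                    )

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.frame.shape[0]

    @property
    def variables(self) -> list[str]:
        """Network node names, in original column order.

        For a survival outcome the (time, event) columns are replaced by the
        single virtual outcome node, appended last.
        """
        cols = list(self.frame.columns)
        out = self.outcome
        if out is not None and out.is_survival:
            cols = [c for c in cols if c not in (out.time_column, out.event_column)]
            cols.append(out.name)
        return cols

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def outcome_name(self) -> str | None:
        return self.outcome.name if self.outcome is not None else None

    def kind_of(self, name: str) -> str:
        out = self.outcome
        if out is not None and name == out.name:
            if out.kind == "survival":
                return "survival"
            if out.kind == "binary":
                return CATEGORICAL
            return CONTINUOUS
        return self.kinds[name]

    def column(self, name: str) -> np.ndarray:
        """Numeric values of a (non-survival) variable."""
        out = self.outcome
        if out is not None and out.is_survival and name == out.name:
            raise KeyError("survival outcome has no single value column")
        return self.frame[name].to_numpy()

    def survival_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        out = self.outcome
        if out is None or not out.is_survival:
            raise ValueError("no survival outcome designated")
        return (
            self.frame[out.time_column].to_numpy(dtype=float),
            self.frame[out.event_column].to_numpy(dtype=int),
        )

    def standardized(self) -> "DataMatrix":
        """Copy with continuous columns z-scored (population sd).

        Structure scores based on residual variances are not scale
        invariant; scoring standardized columns makes the discovered
        structure independent of measurement units.  Categorical columns
        and survival time/event columns are untouched; constant columns are
        left as-is (they are screened out upstream).
        """
        frame = self.frame.copy()
        skip = set()
        if self.outcome is not None and self.outcome.is_survival:
            skip = {self.outcome.time_column, self.outcome.event_column}
        for c in frame.columns:
            if c in skip or self.kinds.get(c) != CONTINUOUS:
                continue
            sd = float(frame[c].std(ddof=0))
            if sd > 0:
                frame[c] = (frame[c] - frame[c].mean()) / sd
        return DataMatrix(frame, kinds=self.kinds, outcome=self.outcome)

    def restrict(self, names: list[str]) -> "DataMatrix":
        """Sub-matrix keeping the given variables, in original order."""
        order = [v for v in self.variables if v in set(names)]
        out = self.outcome
        cols: list[str] = []
        for v in order:
            if out is not None and out.is_survival and v == out.name:
                cols.extend([out.time_column, out.event_column])
            else:
                cols.append(v)
        kinds = {c: self.kinds[c] for c in cols if c in self.kinds}
        return DataMatrix(self.frame[cols].copy(), kinds=kinds, outcome=out)


def infer_kinds(frame: pd.DataFrame) -> dict[str, str]:
    """Default column typing: numeric columns are continuous unless they are
    integer-valued with <= CATEGORICAL_CARDINALITY distinct values; anything
    non-numeric is categorical."""
    kinds: dict[str, str] = {}
    for c in frame.columns:
        s = frame[c]
        if pd.api.types.is_numeric_dtype(s):
            vals = s.to_numpy()
            if (
                np.all(np.asarray(vals, dtype=float) == np.floor(vals.astype(float)))
                and s.nunique() <= CATEGORICAL_CARDINALITY
            ):
                kinds[c] = CATEGORICAL
            else:
                kinds[c] = CONTINUOUS
        else:
            kinds[c] = CATEGORICAL
    return kinds


def from_array(
    values: np.ndarray,
    names: list[str] | None = None,
    kinds: dict[str, str] | None = None,
    outcome: Outcome | None = None,
) -> DataMatrix:
    """Convenience constructor from a dense array of continuous values."""
    values = np.asarray(values)
    if names is None:
        names = [f"v{i + 1}" for i in range(values.shape[1])]
    frame = pd.DataFrame(values, columns=names)
    if kinds is None:
        kinds = {c: CONTINUOUS for c in names}
    return DataMatrix(frame, kinds=kinds, outcome=outcome)
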