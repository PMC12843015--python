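"""The 3x2 contingency table for a (1:1:1) shared-referent trial.

Rows are the three arms — row 1 is ALWAYS the shared referent-control arm
``T0``, rows 2 and 3 the treatment arms ``T1`` and ``T2``.  Columns are the
outcome: column 1 is the unfavorable event, column 2 the favorable one.  Both
relative risks are oriented referent-over-treatment, so this row/column
convention is semantic, not cosmetic; file readers never reorder rows.

The module provides the validated table type, CSV/TSV/JSON input and output,
and a binomial fixture generator for synthetic trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from numbers import Integral
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import TableValidationError

__all__ = [
    "ThreeByTwoTable",
    "make_table",
    "read_table",
    "write_table",
    "generate_table",
]

DEFAULT_ARM_LABELS = ("T0", "T1", "T2")
DEFAULT_OUTCOME_LABELS = ("unfavorable", "favorable")

_CSV_COLUMNS = ["arm", "unfavorable", "favorable"]


@dataclass(frozen=True)
class ThreeByTwoTable:
    """Validated integer counts for the three-arm, binary-outcome design.

    Parameters
    ----------
    counts
        3x2 array of non-negative integer cell frequencies ``a_ij``.  Row
        order is (referent T0, treatment T1, treatment T2); column order is
        (unfavorable, favorable).
    arm_labels, outcome_labels
        Display labels; the first arm label names the referent arm.

    Notes
    -----
    Invariants enforced at construction: all six counts are non-negative
    integers and every row total ``a_i+`` is positive.
    """

    counts: np.ndarray
    arm_labels: tuple[str, str, str] = DEFAULT_ARM_LABELS
    outcome_labels: tuple[str, str] = DEFAULT_OUTCOME_LABELS

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 2):
            raise TableValidationError(
                f"expected a 3x2 table of counts, got shape {arr.shape}"
            )
        for value in arr.ravel():
            if isinstance(value, (bool, np.bool_)) or not isinstance(
                value, (Integral, np.integer)
            ):
                raise TableValidationError(
                    f"cell counts must be integers, got {value!r}"
                )
        arr = arr.astype(np.int64)
        if (arr < 0).any():
            raise TableValidationError(
                f"cell counts must be non-negative, got {int(arr.min())}"
            )
        row_totals = arr.sum(axis=1)
        for i, total in enumerate(row_totals):
            if total <= 0:
                raise TableValidationError(
                    f"row total for arm {self.arm_labels[i]!r} (row {i + 1}) is zero"
                )
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)
        object.__setattr__(self, "arm_labels", tuple(str(a) for a in self.arm_labels))
        object.__setattr__(
            self, "outcome_labels", tuple(str(o) for o in self.outcome_labels)
        )
        if len(self.arm_labels) != 3 or len(self.outcome_labels) != 2:
            raise TableValidationError("need exactly 3 arm labels and 2 outcome labels")

    # dataclass __eq__ would compare arrays ambiguously; define it explicitly
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ThreeByTwoTable):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.arm_labels == other.arm_labels
            and self.outcome_labels == other.outcome_labels
        )

    def __hash__(self) -> int:
        return hash((self.counts.tobytes(), self.arm_labels, self.outcome_labels))

    @property
    def row_totals(self) -> np.ndarray:
        """Per-arm sample sizes ``(a_1+, a_2+, a_3+)``."""
        return self.counts.sum(axis=1)

    @property
    def n(self) -> int:
        """Total number of patients across all six cells."""
        return int(self.counts.sum())

    @property
    def event_counts(self) -> np.ndarray:
        """Unfavorable-event counts ``(a_11, a_21, a_31)``."""
        return self.counts[:, 0]

    @property
    def risks(self) -> np.ndarray:
        """Observed per-arm unfavorable-event risks ``a_i1 / a_i+``."""
        return self.counts[:, 0] / self.row_totals

    def to_dict(self) -> dict:
        return {
            "arms": list(self.arm_labels),
            "outcomes": list(self.outcome_labels),
            "counts": self.counts.tolist(),
        }


def make_table(
    counts: Sequence[int],
    arm_labels: Sequence[str] = DEFAULT_ARM_LABELS,
    outcome_labels: Sequence[str] = DEFAULT_OUTCOME_LABELS,
) -> ThreeByTwoTable:
    """Build a validated table from six counts in row-major order.

    ``counts`` is ``(a11, a12, a21, a22, a31, a32)``: referent arm first,
    unfavorable column first.

    >>> t = make_table([54, 6, 48, 12, 36, 24])
    >>> t.n, tuple(t.row_totals)
    (180, (60, 60, 60))
    """
    counts = list(counts)
    if len(counts) != 6:
        raise TableValidationError(f"expected six counts, got {len(counts)}")
    grid = np.array(counts, dtype=object).reshape(3, 2)
    return ThreeByTwoTable(grid, tuple(arm_labels), tuple(outcome_labels))


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = {".csv": "csv", ".tsv": "tsv", ".json": "json"}.get(path.suffix.lower(), "")
    if fmt not in {"csv", "tsv", "json"}:
        raise TableValidationError(
            f"unsupported table format {format or path.suffix!r}; use csv, tsv or json"
        )
    return fmt


def read_table(path: str | Path, format: str | None = None) -> ThreeByTwoTable:
    """Read a 3x2 table from CSV, TSV or JSON.

    CSV/TSV files need the header ``arm,unfavorable,favorable`` and exactly
    three data rows, referent arm first.  JSON mirrors
    ``{"arms": [...], "outcomes": [...], "counts": [[...], ...]}``.
    Row order in the file is preserved: the first data row is the referent.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        try:
            counts = payload["counts"]
            arms = payload.get("arms", list(DEFAULT_ARM_LABELS))
            outcomes = payload.get("outcomes", list(DEFAULT_OUTCOME_LABELS))
        except (TypeError, KeyError) as exc:
            raise TableValidationError(f"{path}: malformed JSON table: {exc}") from exc
        grid = np.array(counts, dtype=object)
        if grid.shape != (3, 2):
            raise TableValidationError(
                f"{path}: 'counts' must be 3 rows of 2 cells, got shape {grid.shape}"
            )
        return ThreeByTwoTable(grid, tuple(arms), tuple(outcomes))

    sep = "," if fmt == "csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, dtype={"arm": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TableValidationError(f"{path}: could not parse {fmt.upper()}: {exc}") from exc
    if list(frame.columns) != _CSV_COLUMNS:
        raise TableValidationError(
            f"{path}: expected columns {_CSV_COLUMNS}, got {list(frame.columns)}"
        )
    if len(frame) != 3:
        raise TableValidationError(
            f"{path}: expected exactly three data rows (referent first), got {len(frame)}"
        )
    cells = []
    for i, row in frame.iterrows():
        for col in ("unfavorable", "favorable"):
            value = row[col]
            if pd.isna(value) or float(value) != int(value):
                raise TableValidationError(
                    f"{path}: row {i + 1} column {col!r}: non-integer cell {value!r}"
                )
            cells.append(int(value))
    return ThreeByTwoTable(
        np.array(cells, dtype=object).reshape(3, 2),
        tuple(frame["arm"].tolist()),
        DEFAULT_OUTCOME_LABELS,
    )


def write_table(table: ThreeByTwoTable, path: str | Path, format: str | None = None) -> None:
    """Write ``table`` so that :func:`read_table` reproduces it exactly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "json":
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(table.to_dict(), fh, indent=1)
                fh.write("\n")
        else:
            sep = "," if fmt == "csv" else "\t"
            frame = pd.DataFrame(
                {
                    "arm": list(table.arm_labels),
                    "unfavorable": table.counts[:, 0],
                    "favorable": table.counts[:, 1],
                }
            )
            frame.to_csv(path, sep=sep, index=False)
    except OSError as exc:
        raise OSError(f"could not write table to {path}: {exc}") from exc


def generate_table(
    n_per_arm: Iterable[int],
    risks: Iterable[float],
    seed: int,
    arm_labels: Sequence[str] = DEFAULT_ARM_LABELS,
) -> ThreeByTwoTable:
    """Draw a synthetic trial table with binomial per-arm event counts.

    Each arm's unfavorable count is ``a_i1 ~ Binomial(n_i, pi_i)`` with
    ``a_i2 = n_i - a_i1``; this matches the sampling model in which the three
    event counts are independent binomial variables given fixed arm sizes.
    Deterministic for a fixed ``seed``.

    Parameters
    ----------
    n_per_arm
        Three positive arm sizes ``(n_0, n_1, n_2)``, referent first.
    risks
        Three true unfavorable-event probabilities strictly inside (0, 1),
        in the same arm order.
    seed
        Seed for the random generator (numpy PCG64).
    """
    sizes = [int(n) for n in n_per_arm]
    probs = [float(p) for p in risks]
    if len(sizes) != 3 or len(probs) != 3:
        raise TableValidationError("need exactly three arm sizes and three risks")
    if any(n <= 0 for n in sizes):
        raise TableValidationError(f"arm sizes must be positive, got {sizes}")
    for p in probs:
        if not 0.0 < p < 1.0:
            raise TableValidationError(f"risks must lie strictly in (0, 1), got {p}")
    rng = np.random.default_rng(seed)
    events = rng.binomial(sizes, probs)
    grid = np.column_stack([events, np.array(sizes) - events])
    return ThreeByTwoTable(grid.astype(object), tuple(arm_labels))
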