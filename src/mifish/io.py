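"""Reading, writing and validating per-nucleus signal tables.

A signal table is a TSV with one header row of probe names and one row
per nucleus of non-negative integer signal counts.  Nuclei with missing
or malformed cells are rejected at read time: the enumeration contract
is that only nuclei with clearly scorable signals for every probe enter
the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import ProbePanel

#: Recommended minimum number of enumerated nuclei per sample.
MIN_NUCLEI = 250


@dataclass(frozen=True)
class NucleusRecord:
    """Signal counts for one nucleus, in panel probe order."""

    nucleus_id: str
    counts: tuple[int, ...]

    def __post_init__(self):
        if any(c < 0 for c in self.counts):
            raise ValueError(f"nucleus {self.nucleus_id}: negative count")


@dataclass(frozen=True)
class SignalPattern:
    """A distinct signal-count vector with the number of nuclei sharing it."""

    counts: tuple[int, ...]
    multiplicity: int

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass
class ValidationReport:
    """Outcome of sample-level input validation (warning, not rejection)."""

    n_nuclei: int
    min_nuclei: int
    level: str  # "pass" | "warning" | "error"
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.level == "pass"


def read_signal_table(path: str | Path, panel: ProbePanel) -> list[NucleusRecord]:
    """Read a per-nucleus signal TSV into records in panel probe order.

    The header must contain every panel probe name; columns may appear
    in any order and are re-mapped by name.  An optional ``nucleus_id``
    column supplies ids; otherwise row numbers are used.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [n for n in panel.names if n not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing probe column(s): {', '.join(missing)}")
    ids = (
        df["nucleus_id"].astype(str).tolist()
        if "nucleus_id" in df.columns
        else [str(i + 1) for i in range(len(df))]
    )
    records = []
    for row_i, (_, row) in enumerate(df.iterrows()):
        counts = []
        for name in panel.names:
            cell = row[name]
            if pd.isna(cell):
                raise ValueError(
                    f"{path}: row {row_i + 1}, column {name}: missing value"
                )
            try:
                value = int(str(cell).strip())
            except ValueError:
                raise ValueError(
                    f"{path}: row {row_i + 1}, column {name}: "
                    f"non-integer cell {cell!r}"
                ) from None
            if value < 0:
                raise ValueError(
                    f"{path}: row {row_i + 1}, column {name}: negative count {value}"
                )
            counts.append(value)
        records.append(NucleusRecord(ids[row_i], tuple(counts)))
    return records


def write_signal_table(
    records: list[NucleusRecord], path: str | Path, panel: ProbePanel
) -> None:
    """Write records as a TSV (header = ``nucleus_id`` + probe names)."""
    df = pd.DataFrame(
        [(r.nucleus_id, *r.counts) for r in records],
        columns=["nucleus_id"] + panel.names,
    )
    df.to_csv(path, sep="\t", index=False)


def aggregate_patterns(records: list[NucleusRecord]) -> list[SignalPattern]:
    """Group identical count vectors into signal patterns.

    Returns patterns sorted by multiplicity descending, ties broken by
    lexicographically smaller vector; the first pattern is the major
    clone.  The multiplicities always sum to ``len(records)``.
    """
    if not records:
        raise ValueError("aggregate_patterns: empty input")
    counter: dict[tuple[int, ...], int] = {}
    for r in records:
        counter[r.counts] = counter.get(r.counts, 0) + 1
    return [
        SignalPattern(vec, mult)
        for vec, mult in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def validate_sample(
    records: list[NucleusRecord], min_nuclei: int = MIN_NUCLEI
) -> ValidationReport:
    """Check a sample against the minimum-nuclei recommendation.

    Falling short of the minimum is a warning (the sample is still
    analysable); an empty sample is an error-level flag.
    """
    n = len(records)
    if n == 0:
        return ValidationReport(0, min_nuclei, "error", ["no nuclei in sample"])
    if n < min_nuclei:
        return ValidationReport(
            n,
            min_nuclei,
            "warning",
            [f"only {n} nuclei enumerated (recommended minimum {min_nuclei})"],
        )
    return ValidationReport(n, min_nuclei, "pass")


def records_to_matrix(records: list[NucleusRecord]) -> np.ndarray:
    """Stack records into an (n_nuclei, n_probes) integer array."""
    return np.array([r.counts for r in records], dtype=np.int64)
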