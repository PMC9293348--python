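"""Count data for randomized paired screen-positive trials.

In a randomized paired screen-positive design, subjects are randomized to
receive one of two screening tests first (new test A or standard test B).
Only subjects positive on their first test receive the other test and the
gold-standard disease verification.  The observable data per arm therefore
reduce to five cells: the four (disease x second-test) categories among
first-test positives, and the number of first-test negatives.

This module defines the cell-count containers, their structural validation,
CSV/JSON (de)serialization, and the built-in counts of the IMPROVE cervical
cancer screening trial used as the worked example throughout the package.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

__all__ = [
    "ArmFirstA",
    "ArmFirstB",
    "TrialCounts",
    "ValidationError",
    "validate",
    "read_counts",
    "write_counts",
    "improve_fixture",
]


class ValidationError(ValueError):
    """A structural invariant of the trial count layout is violated."""


@dataclass(frozen=True)
class ArmFirstA:
    """Observed cells for the arm screened with the new test A first.

    Attributes
    ----------
    n_dab : int
        Diseased, positive on A and on B (``N_DAB^A``).
    n_dab_not : int
        Diseased, positive on A, negative on B (``N_DAB̄^A``).
    n_ndab : int
        Nondiseased, positive on A and on B (``N_D̄AB^A``).
    n_ndab_not : int
        Nondiseased, positive on A, negative on B (``N_D̄AB̄^A``).
    n_aneg : int
        Negative on the first test A (``N_Ā^A``); second test and
        verification are not performed for these subjects.
    n_screened : int
        Subjects with complete follow-up in this arm (``N_A``).
    """

    n_dab: int
    n_dab_not: int
    n_ndab: int
    n_ndab_not: int
    n_aneg: int
    n_screened: int

    @property
    def n_daa(self) -> int:
        """Diseased subjects positive on the first test A (``N_DA^A``)."""
        return self.n_dab + self.n_dab_not

    @property
    def n_ndaa(self) -> int:
        """Nondiseased subjects positive on the first test A (``N_D̄A^A``)."""
        return self.n_ndab + self.n_ndab_not

    @property
    def n_ab(self) -> int:
        """Subjects positive on both tests in this arm (``N_AB^A``)."""
        return self.n_dab + self.n_ndab


@dataclass(frozen=True)
class ArmFirstB:
    """Observed cells for the arm screened with the standard test B first.

    Field meanings mirror :class:`ArmFirstA` with the roles of the tests
    swapped: all subjects in these cells were positive on B first, and the
    second test is A (``n_da_not_b`` is diseased, B+, A−; ``n_bneg`` counts
    first-test negatives).
    """

    n_dab: int
    n_da_not_b: int
    n_ndab: int
    n_nda_not_b: int
    n_bneg: int
    n_screened: int

    @property
    def n_dbb(self) -> int:
        """Diseased subjects positive on the first test B (``N_DB^B``)."""
        return self.n_dab + self.n_da_not_b

    @property
    def n_ndbb(self) -> int:
        """Nondiseased subjects positive on the first test B (``N_D̄B^B``)."""
        return self.n_ndab + self.n_nda_not_b

    @property
    def n_ab(self) -> int:
        """Subjects positive on both tests in this arm (``N_AB^B``)."""
        return self.n_dab + self.n_ndab


@dataclass(frozen=True)
class TrialCounts:
    """All observed counts of one randomized paired screen-positive trial.

    ``m_a`` and ``m_b`` are the numbers randomized to each arm; the arm
    containers hold the screened subjects with complete follow-up.  Subjects
    positive on the first test whose second test or verification is missing
    must be excluded by the caller before construction (missing at random
    is assumed for post-positive missingness).
    """

    arm_a: ArmFirstA
    arm_b: ArmFirstB
    m_a: int
    m_b: int

    @property
    def n_total(self) -> int:
        """Total screened with complete follow-up, ``N = N_A + N_B``."""
        return self.arm_a.n_screened + self.arm_b.n_screened

    @property
    def n_ab_total(self) -> int:
        """Subjects positive on both tests over both arms (``N_AB``)."""
        return self.arm_a.n_ab + self.arm_b.n_ab


def _check_cells(name: str, cells: dict[str, int]) -> None:
    for field, value in cells.items():
        if isinstance(value, bool) or not isinstance(value, int):
            raise ValidationError(f"{name}.{field} must be an integer, got {value!r}")
        if value < 0:
            raise ValidationError(f"{name}.{field} must be >= 0, got {value}")


def validate(counts: TrialCounts) -> TrialCounts:
    """Check all structural invariants; return ``counts`` unchanged.

    Raises
    ------
    ValidationError
        Naming the first violated invariant: negative or non-integer
        cells, an arm total that is not the sum of its five cells, or
        fewer randomized than screened.
    """
    _check_cells("arm_a", asdict(counts.arm_a))
    _check_cells("arm_b", asdict(counts.arm_b))
    _check_cells("trial", {"m_a": counts.m_a, "m_b": counts.m_b})
    a, b = counts.arm_a, counts.arm_b
    sum_a = a.n_dab + a.n_dab_not + a.n_ndab + a.n_ndab_not + a.n_aneg
    if a.n_screened != sum_a:
        raise ValidationError(
            f"arm_a.n_screened ({a.n_screened}) != sum of its five cells ({sum_a})"
        )
    sum_b = b.n_dab + b.n_da_not_b + b.n_ndab + b.n_nda_not_b + b.n_bneg
    if b.n_screened != sum_b:
        raise ValidationError(
            f"arm_b.n_screened ({b.n_screened}) != sum of its five cells ({sum_b})"
        )
    if counts.m_a < a.n_screened:
        raise ValidationError(f"m_a ({counts.m_a}) < arm_a.n_screened ({a.n_screened})")
    if counts.m_b < b.n_screened:
        raise ValidationError(f"m_b ({counts.m_b}) < arm_b.n_screened ({b.n_screened})")
    return counts


_ARM_A_FIELDS = ("n_dab", "n_dab_not", "n_ndab", "n_ndab_not", "n_aneg", "n_screened")
_ARM_B_FIELDS = ("n_dab", "n_da_not_b", "n_ndab", "n_nda_not_b", "n_bneg", "n_screened")
_CSV_COLUMNS = (
    ["m_a", "m_b"]
    + [f"arm_a.{f}" for f in _ARM_A_FIELDS]
    + [f"arm_b.{f}" for f in _ARM_B_FIELDS]
)


def _as_int(name: str, value: object) -> int:
    if isinstance(value, bool):
        raise ValidationError(f"field {name} must be an integer, got {value!r}")
    if isinstance(value, int):
        return value
    if isinstance(value, str):
        try:
            return int(value)
        except ValueError:
            pass
    if isinstance(value, float) and value.is_integer():
        return int(value)
    raise ValidationError(f"field {name} must be an integer, got {value!r}")


def _from_mapping(record: dict) -> TrialCounts:
    try:
        arm_a = ArmFirstA(**{f: _as_int(f"arm_a.{f}", record["arm_a"][f]) for f in _ARM_A_FIELDS})
        arm_b = ArmFirstB(**{f: _as_int(f"arm_b.{f}", record["arm_b"][f]) for f in _ARM_B_FIELDS})
        counts = TrialCounts(
            arm_a=arm_a,
            arm_b=arm_b,
            m_a=_as_int("m_a", record["m_a"]),
            m_b=_as_int("m_b", record["m_b"]),
        )
    except KeyError as exc:  # missing field
        raise ValidationError(f"missing field {exc.args[0]!r}") from exc
    return validate(counts)


def to_mapping(counts: TrialCounts) -> dict:
    """Nested-dict form matching the documented JSON schema."""
    return {
        "m_a": counts.m_a,
        "m_b": counts.m_b,
        "arm_a": asdict(counts.arm_a),
        "arm_b": asdict(counts.arm_b),
    }


def read_counts(path: str | Path, format: Literal["csv", "json"] | None = None) -> TrialCounts:
    """Read and validate trial counts from a CSV or JSON file.

    ``format`` defaults to the file extension.  The JSON schema is the
    nested ``{m_a, m_b, arm_a{...}, arm_b{...}}`` record; the CSV twin is a
    single data row under a header of the 12 dotted column names.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()  # type: ignore[assignment]
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            record = json.load(fh)
        if not isinstance(record, dict):
            raise ValidationError("JSON counts file must contain an object")
        return _from_mapping(record)
    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        if len(rows) != 1:
            raise ValidationError(f"CSV counts file must have exactly one data row, got {len(rows)}")
        row = rows[0]
        record: dict = {"arm_a": {}, "arm_b": {}}
        for col in _CSV_COLUMNS:
            if col not in row or row[col] is None:
                raise ValidationError(f"missing field {col!r}")
            head, _, tail = col.partition(".")
            if tail:
                record[head][tail] = row[col]
            else:
                record[head] = row[col]
        return _from_mapping(record)
    raise ValidationError(f"unknown counts format {format!r}")


def write_counts(
    counts: TrialCounts, path: str | Path, format: Literal["csv", "json"] | None = None
) -> None:
    """Write validated counts so that :func:`read_counts` round-trips exactly."""
    validate(counts)
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()  # type: ignore[assignment]
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(to_mapping(counts), fh, indent=2)
            fh.write("\n")
        return
    if format == "csv":
        record = to_mapping(counts)
        flat = {}
        for col in _CSV_COLUMNS:
            head, _, tail = col.partition(".")
            flat[col] = record[head][tail] if tail else record[head]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            writer.writerow(flat)
        return
    raise ValidationError(f"unknown counts format {format!r}")


def improve_fixture() -> TrialCounts:
    """Counts of the IMPROVE cervical cancer screening trial.

    IMPROVE randomized 16410 women 1:1 to HPV testing on a self-collected
    sample first (arm A, 8212 women) or on a provider-collected sample
    first (arm B, 8198 women); CIN3+ is the gold-standard endpoint.  Among
    the 7643 women screened in the self-sampling arm, 569 tested positive;
    548 of these had paired test results, of whom 72 were verified CIN3+
    (69 also positive on the provider test) and 476 were not (327 positive
    on the provider test).  Among the 6282 screened in the provider arm,
    451 tested positive; 416 had paired results, of whom 41 were CIN3+
    (39 positive on the self test) and 375 were not (278 positive on the
    self test).

    Provenance note: the 569-548=21 and 451-416=35 first-test positives
    without paired results are excluded here, under the assumption that
    missingness of the second test / verification after a positive first
    test is missing at random.  The per-arm screened totals count complete
    follow-up only: 7643-21=7622 and 6282-35=6247.
    """
    arm_a = ArmFirstA(
        n_dab=69,
        n_dab_not=3,
        n_ndab=327,
        n_ndab_not=149,
        n_aneg=7074,
        n_screened=7622,
    )
    arm_b = ArmFirstB(
        n_dab=39,
        n_da_not_b=2,
        n_ndab=278,
        n_nda_not_b=97,
        n_bneg=5831,
        n_screened=6247,
    )
    return validate(TrialCounts(arm_a=arm_a, arm_b=arm_b, m_a=8212, m_b=8198))
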