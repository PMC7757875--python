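"""Subject-table reading, validation, and conversion to analysis frames.

The canonical input is a CSV with one row per subject:

    id, sex, uninformed, c0..c20,
    maoa_a1, maoa_a2 (empty for men), oxtr_a1, oxtr_a2, rs3_a1_bp, rs3_a2_bp

Behavioral columns are validated strictly (malformed headers, non-integer
or out-of-range schedule entries are errors).  Genotype fields may be
missing, in which case the affected variant is coded ``excluded`` for that
subject while the behavioral data are retained; rows violating structural
genotype invariants (a man with two MAOA alleles) are rejected with
line-numbered diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .classifier import StrategyCall
from .genetics import (
    EXCLUDED,
    CodedGenotypes,
    RawGenotype,
    code_maoa,
    code_oxtr,
    code_rs3,
)
from .pgg import ContingentSchedule, Decision, SCHEDULE_LEN
from .association import scenario_means
from .synthetic import CSV_COLUMNS

__all__ = [
    "SubjectRecord",
    "RowRejected",
    "read_subjects",
    "write_subjects",
    "analysis_frame",
]


class RowRejected(ValueError):
    """A row violating a structural genotype invariant; dropped, not fatal."""


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's behavioral and (possibly partial) genetic data."""

    id: str
    sex: str
    decision: Decision
    maoa_repeats: Optional[tuple[float, ...]]
    oxtr_alleles: Optional[tuple[str, str]]
    rs3_lengths_bp: Optional[tuple[int, int]]

    @property
    def schedule(self) -> ContingentSchedule:
        return self.decision.schedule

    @property
    def uninformed(self) -> int:
        return self.decision.uninformed

    def coded(self) -> CodedGenotypes:
        """Analysis categories; any missing variant codes ``excluded``."""
        if self.maoa_repeats is None:
            maoa = EXCLUDED
        else:
            maoa = code_maoa(
                RawGenotype(
                    sex=self.sex,
                    maoa_repeats=self.maoa_repeats,
                    oxtr_alleles=("A", "A"),
                    rs3_lengths_bp=(330, 330),
                )
            )
        oxtr = EXCLUDED if self.oxtr_alleles is None else code_oxtr(self.oxtr_alleles)
        rs3 = (
            EXCLUDED
            if self.rs3_lengths_bp is None
            else code_rs3(self.rs3_lengths_bp)
        )
        return CodedGenotypes(maoa=maoa, oxtr=oxtr, avpr1a=rs3)


def _parse_row(line_no: int, row: pd.Series) -> SubjectRecord:
    sex = str(row["sex"]).strip().lower()
    if sex not in ("female", "male"):
        raise ValueError(f"line {line_no}: sex must be female/male, got {row['sex']!r}")

    entries = []
    for j in range(SCHEDULE_LEN):
        v = row[f"c{j}"]
        fv = float(v)
        if not fv.is_integer():
            raise ValueError(f"line {line_no}: schedule entry c{j}={v!r} is not an integer")
        entries.append(int(fv))
    uninformed = float(row["uninformed"])
    if not uninformed.is_integer():
        raise ValueError(f"line {line_no}: uninformed={row['uninformed']!r} is not an integer")
    decision = Decision(uninformed=int(uninformed), schedule=ContingentSchedule(tuple(entries)))

    def blank(v) -> bool:
        return pd.isna(v) or (isinstance(v, str) and not v.strip())

    a1, a2 = row["maoa_a1"], row["maoa_a2"]
    if blank(a1) and blank(a2):
        maoa = None
    else:
        alleles = tuple(float(a) for a in (a1, a2) if not blank(a))
        expected = 2 if sex == "female" else 1
        if len(alleles) != expected:
            raise RowRejected(
                f"line {line_no}: {sex} subject must carry exactly {expected} "
                f"MAOA allele(s), found {len(alleles)}"
            )
        maoa = alleles

    o1, o2 = row["oxtr_a1"], row["oxtr_a2"]
    if blank(o1) or blank(o2):
        oxtr = None
    else:
        oxtr = (str(o1).strip(), str(o2).strip())

    r1, r2 = row["rs3_a1_bp"], row["rs3_a2_bp"]
    if blank(r1) or blank(r2):
        rs3 = None
    else:
        rs3 = (int(float(r1)), int(float(r2)))

    return SubjectRecord(
        id=str(row["id"]),
        sex=sex,
        decision=decision,
        maoa_repeats=maoa,
        oxtr_alleles=oxtr,
        rs3_lengths_bp=rs3,
    )


def read_subjects(path) -> tuple[list[SubjectRecord], list[str]]:
    """Read and validate a subject CSV.

    Returns (records, diagnostics): rows that violate structural genotype
    invariants are dropped and described in ``diagnostics``; behavioral
    validation failures and a malformed header raise immediately.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty subject file") from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no subject rows")

    records: list[SubjectRecord] = []
    diagnostics: list[str] = []
    for i, (_, row) in enumerate(df.iterrows()):
        line_no = i + 2  # header is line 1
        try:
            records.append(_parse_row(line_no, row))
        except RowRejected as exc:
            diagnostics.append(str(exc))
        except ValueError as exc:
            if str(exc).startswith(f"line {line_no}"):
                raise
            raise ValueError(f"line {line_no}: {exc}") from None
    if not records:
        raise ValueError(f"{path}: no valid subject rows remain")
    return records, diagnostics


def write_subjects(df: pd.DataFrame, path) -> None:
    """Write a subject table (e.g. from generate_cohort) as CSV."""
    df.to_csv(path, index=False)


def analysis_frame(
    records: list[SubjectRecord], calls: list[StrategyCall]
) -> pd.DataFrame:
    """Assemble the per-subject frame the association battery consumes."""
    if len(records) != len(calls):
        raise ValueError("records and calls must align")
    rows = []
    for rec, call in zip(records, calls):
        coded = rec.coded()
        sm = scenario_means(rec.schedule)
        rows.append(
            {
                "id": rec.id,
                "sex": rec.sex,
                "strategy": call.label,
                "maoa": coded.maoa,
                "oxtr": coded.oxtr,
                "avpr1a": coded.avpr1a,
                "uninformed": rec.uninformed,
                "scenario_low": sm.low,
                "scenario_mid": sm.mid,
                "scenario_high": sm.high,
            }
        )
    return pd.DataFrame(rows)
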