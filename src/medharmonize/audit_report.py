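"""Stage accounting, QA sampling, and the append-only audit log.

Every record that moves through the pipeline leaves a trail: per-stage
counts of correct / flagged / unmatched entries (the stage-accounting
report), and one JSON-lines audit record per state transition.  The
accounting obeys a conservation law — at every stage, correct + flagged +
unmatched equals the stage's input count — and percentages are always the
stage's correct count over the *phase* total, rounded half-up to one
decimal.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import MedHarmonizeError, ValidationError

__all__ = [
    "StageCounts",
    "AuditRecord",
    "AuditLog",
    "percentage",
    "build_report",
    "qa_sample",
    "verify_audit_chain",
]


class IntegrityError(MedHarmonizeError):
    """Stage counts violate the conservation law."""


def percentage(correct: int, phase_total: int) -> float:
    """correct / phase_total as a percentage, rounded half-up to one decimal."""
    if phase_total <= 0:
        return 0.0
    pct = Decimal(correct) * 100 / Decimal(phase_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StageCounts:
    """Accounting for one pipeline process (one report row).

    ``total`` is the number of entries *entering* this process;
    ``phase_total`` is the denominator of the reported percentage (the
    phase's overall entry count).  ``ambiguous`` includes entries held as
    borderline at a fuzzy stage.
    """

    phase: str
    process_label: str
    correct: int
    ambiguous: int
    unmatched: int
    total: int
    phase_total: int

    def __post_init__(self) -> None:
        if self.correct + self.ambiguous + self.unmatched != self.total:
            raise IntegrityError(
                f"stage {self.process_label!r}: correct ({self.correct}) + "
                f"ambiguous ({self.ambiguous}) + unmatched ({self.unmatched}) "
                f"!= process total ({self.total})"
            )

    @property
    def percentage(self) -> float:
        return percentage(self.correct, self.phase_total)


def build_report(counts: Sequence[StageCounts]) -> pd.DataFrame:
    """Assemble the stage-accounting table (one row per process + phase totals).

    Raises :class:`IntegrityError` (at ``StageCounts`` construction) if any
    row violates conservation.
    """
    rows = [
        {
            "phase": c.phase,
            "process": c.process_label,
            "correct": c.correct,
            "ambiguous": c.ambiguous,
            "unmatched": c.unmatched,
            "total": c.total,
            "percentage": c.percentage,
        }
        for c in counts
    ]
    report = pd.DataFrame(
        rows,
        columns=[
            "phase", "process", "correct", "ambiguous", "unmatched",
            "total", "percentage",
        ],
    )
    totals = []
    for phase in report["phase"].unique():
        sub = report[report["phase"] == phase]
        phase_total = next(
            c.phase_total for c in counts if c.phase == phase
        )
        correct = int(sub["correct"].sum())
        totals.append(
            {
                "phase": phase,
                "process": "TOTAL",
                "correct": correct,
                "ambiguous": int(sub["ambiguous"].sum()),
                "unmatched": int(sub["unmatched"].iloc[-1]),
                "total": phase_total,
                "percentage": percentage(correct, phase_total),
            }
        )
    return pd.concat([report, pd.DataFrame(totals)], ignore_index=True)


# ---------------------------------------------------------------------------
# Audit log
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AuditRecord:
    """One state transition in the curation trail (append-only)."""

    timestamp: str
    record_id: str
    phase: str
    stage: int
    action: str
    before: str
    after: str
    score_pct: float | None = None
    actor: str = "automated"


class AuditLog:
    """Append-only JSONL stream of :class:`AuditRecord` transitions."""

    def __init__(self, records: Iterable[AuditRecord] | None = None):
        self.records: list[AuditRecord] = list(records or [])

    def append(
        self,
        record_id: str,
        phase: str,
        stage: int,
        action: str,
        before: str,
        after: str,
        score_pct: float | None = None,
        actor: str = "automated",
        timestamp: str | None = None,
    ) -> AuditRecord:
        if actor != "automated" and not actor:
            raise ValidationError("non-automated audit actions must name an actor")
        rec = AuditRecord(
            timestamp=timestamp
            or _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
            record_id=str(record_id),
            phase=phase,
            stage=stage,
            action=action,
            before=before,
            after=after,
            score_pct=score_pct,
            actor=actor,
        )
        self.records.append(rec)
        return rec

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(asdict(rec), sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "AuditLog":
        records = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    records.append(AuditRecord(**json.loads(line)))
        return cls(records)

    def for_record(self, record_id: str) -> list[AuditRecord]:
        return [r for r in self.records if r.record_id == str(record_id)]


def verify_audit_chain(
    audit: AuditLog, final_states: dict[str, str]
) -> tuple[bool, list[str]]:
    """Check that every terminal result state is reachable from its audit trail.

    ``final_states`` maps record_id → terminal status.  A record whose
    trail is missing, broken (a transition's ``before`` disagrees with the
    previous ``after``), or ends in a different state than the result table
    is reported as a discrepancy.  Failures are findings, not errors.
    """
    discrepancies: list[str] = []
    for record_id, status in final_states.items():
        trail = audit.for_record(record_id)
        if not trail:
            discrepancies.append(f"{record_id}: no audit trail for terminal "
                                 f"state {status!r}")
            continue
        for prev, curr in zip(trail, trail[1:]):
            if curr.before != prev.after:
                discrepancies.append(
                    f"{record_id}: broken chain at stage {curr.stage} "
                    f"({curr.before!r} does not follow {prev.after!r})"
                )
        if trail[-1].after != status:
            discrepancies.append(
                f"{record_id}: audit trail ends in {trail[-1].after!r} but "
                f"result table says {status!r}"
            )
    return (not discrepancies, discrepancies)


def qa_sample(
    population: pd.DataFrame,
    n: int | None = None,
    fraction: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded uniform QA sample (without replacement) for independent review.

    Rows resolved by a fuzzy or expert method are flagged for dual
    verification.  Exactly one of ``n`` / ``fraction`` must be given.
    """
    if (n is None) == (fraction is None):
        raise ValidationError("specify exactly one of n or fraction")
    if fraction is not None:
        n = int(round(fraction * len(population)))
    assert n is not None
    if n > len(population):
        raise ValidationError(
            f"requested sample of {n} exceeds population of {len(population)}"
        )
    sample = population.sample(n=n, random_state=seed).copy()
    if "method" in sample.columns:
        sample["dual_verification"] = sample["method"].isin(
            ["fuzzy_ngram", "dict_fuzzy", "fuzzy_scdf", "expert"]
        )
    else:
        sample["dual_verification"] = False
    return sample.reset_index(drop=True)
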