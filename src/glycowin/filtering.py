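"""Post-search filtering of glycopeptide assignments by retention window.

Given a table of candidate glycopeptide identifications (peptide, glycoform,
measured RT) and an RRT window model, each peptide's anchor glycoform is
located, absolute windows are predicted from its RT, and every other record
receives a verdict:

    anchor     the record is the peptide's anchor glycoform itself
    within     measured RT inside the predicted window (inclusive)
    outside    measured RT outside the predicted window
    no_window  glycoform not covered by the model (no claim is made)

Isomer peaks of one (peptide, glycoform) assignment are judged individually,
but the assignment as a whole passes if any of its peaks is within the
window — isobaric isomers share one window, and rejecting an assignment
because a second isomer peak strays would inflate false negatives.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

from glycowin.glycoforms import GlycoformError, parse_glycoform_code
from glycowin.rrt_model import (
    AnchorTieBreak,
    PredictionWindow,
    RRTWindowModel,
    RTObservation,
    is_within,
    predict_window,
)

__all__ = [
    "AssignmentRecord",
    "ValidationSummary",
    "resolve_anchor",
    "validate_assignments",
    "format_summary",
]

VERDICTS = ("anchor", "within", "outside", "no_window")


@dataclass(frozen=True)
class AssignmentRecord:
    """A candidate glycopeptide identification with its window verdict.

    ``predicted`` is populated only for verdicts ``within``/``outside``;
    anchors and unmodeled glycoforms carry no window.
    """

    peptide_id: str
    glycoform: str
    rt_min: float
    peak_index: int = 1
    intensity: Optional[float] = None
    predicted: Optional[PredictionWindow] = None
    verdict: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.rt_min > 0:
            raise ValueError(f"rt_min must be positive, got {self.rt_min}")
        if self.peak_index < 1:
            raise ValueError(f"peak_index must be >= 1, got {self.peak_index}")
        if self.verdict is not None and self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


@dataclass
class ValidationSummary:
    """Per-verdict record counts plus assignment-level (any-peak) verdicts."""

    counts: Counter = field(default_factory=Counter)
    malformed: List[Tuple[str, str, str]] = field(default_factory=list)
    #: (peptide_id, glycoform) -> verdict with the any-peak-within rule.
    assignments: Dict[Tuple[str, str], str] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


def resolve_anchor(
    records: Iterable[AssignmentRecord],
    model: RRTWindowModel,
    tie_break: Optional[AnchorTieBreak] = None,
) -> float:
    """Anchor RT for one peptide's records.

    Exactly one anchor-glycoform record is expected; several anchor peaks
    require an explicit tie-break (``first_eluting`` or ``most_intense``),
    and none at all is an error — the model cannot run without a
    high-fidelity anchor.
    """
    records = list(records)
    if not records:
        raise ValueError("no records given")
    pid = records[0].peptide_id
    anchors = [r for r in records if r.glycoform == model.anchor_glycoform]
    if not anchors:
        raise ValueError(
            f"peptide {pid!r} has no {model.anchor_glycoform} anchor record; "
            "windows cannot be predicted"
        )
    if len(anchors) == 1:
        return anchors[0].rt_min
    if tie_break is None:
        raise ValueError(
            f"peptide {pid!r} has {len(anchors)} anchor records and no tie-break configured"
        )
    if tie_break == "first_eluting":
        return min(a.rt_min for a in anchors)
    if tie_break == "most_intense":
        if any(a.intensity is None for a in anchors):
            raise ValueError(
                f"tie-break 'most_intense' needs intensities on all anchor records of {pid!r}"
            )
        return max(anchors, key=lambda a: a.intensity).rt_min
    raise ValueError(f"unknown anchor tie-break {tie_break!r}")


def validate_assignments(
    records: Iterable[AssignmentRecord],
    model: RRTWindowModel,
    tie_break: Optional[AnchorTieBreak] = None,
) -> Tuple[List[AssignmentRecord], ValidationSummary]:
    """Annotate every record with its predicted window and verdict.

    Records are grouped by peptide; each group's anchor RT scales the
    model's RRT limits into absolute windows.  Malformed glycoform codes are
    collected in the summary (verdict ``no_window`` — such a code cannot be
    in the model) rather than silently dropped.  Output order matches input
    order, and identical inputs give identical outputs.
    """
    records = list(records)
    by_peptide: Dict[str, List[AssignmentRecord]] = {}
    for r in records:
        by_peptide.setdefault(r.peptide_id, []).append(r)

    anchor_rt = {
        pid: resolve_anchor(group, model, tie_break) for pid, group in by_peptide.items()
    }

    summary = ValidationSummary()
    annotated: List[AssignmentRecord] = []
    for r in records:
        if r.glycoform == model.anchor_glycoform:
            out = replace(r, predicted=None, verdict="anchor")
        else:
            try:
                parse_glycoform_code(r.glycoform)
            except GlycoformError as exc:
                summary.malformed.append((r.peptide_id, r.glycoform, str(exc)))
                out = replace(r, predicted=None, verdict="no_window")
            else:
                if r.glycoform not in model.entries:
                    out = replace(r, predicted=None, verdict="no_window")
                else:
                    window = predict_window(model, r.glycoform, anchor_rt[r.peptide_id])
                    verdict = "within" if is_within(r.rt_min, window) else "outside"
                    out = replace(r, predicted=window, verdict=verdict)
        summary.counts[out.verdict] += 1
        annotated.append(out)

    # Assignment-level verdicts: one (peptide, glycoform) passes if any of
    # its isomer peaks is within the window.
    for out in annotated:
        key = (out.peptide_id, out.glycoform)
        prev = summary.assignments.get(key)
        if out.verdict == "within" or prev == "within":
            summary.assignments[key] = "within"
        elif prev is None or prev == out.verdict:
            summary.assignments[key] = out.verdict
        elif "outside" in (prev, out.verdict):
            summary.assignments[key] = "outside"
        else:
            summary.assignments[key] = out.verdict
    return annotated, summary


def format_summary(summary: ValidationSummary) -> str:
    """Plain-text block suitable for logging."""
    lines = [f"records: {summary.n_total}"]
    for verdict in VERDICTS:
        lines.append(f"  {verdict:>9}: {summary.counts.get(verdict, 0)}")
    if summary.malformed:
        lines.append(f"malformed glycoform codes: {len(summary.malformed)}")
        for pid, code, msg in summary.malformed:
            lines.append(f"  {pid} {code!r}: {msg}")
    n_pass = sum(1 for v in summary.assignments.values() if v == "within")
    n_assign = sum(1 for v in summary.assignments.values() if v in ("within", "outside"))
    lines.append(f"assignments within window (any isomer peak): {n_pass}/{n_assign}")
    return "\n".join(lines)
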