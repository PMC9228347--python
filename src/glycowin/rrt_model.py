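"""The relative retention time (RRT) window model.

A glycoform's RRT is its retention time divided by the retention time of the
anchor glycoform (A2G2) on the same peptide in the same run.  Because the
peptide backbone contributes a multiplicative factor that cancels in the
ratio, RRTs pool across peptides.  The model stores, per glycoform, the
median and standard deviation of the pooled RRTs and the window limits
median +/- k*sigma (k = 3 covers 99.7% of a Gaussian).  Given one
confidently identified anchor glycopeptide, the absolute elution window of
any modeled glycoform is anchor RT times the stored limits.

Isobaric glycan isomers (e.g. alpha-2,3 vs alpha-2,6 sialylation) may give
several chromatographic peaks for one glycoform; each peak enters the fit as
its own observation, so a single window spans all isomeric species.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "RTObservation",
    "RRTWindowEntry",
    "RRTWindowModel",
    "PredictionWindow",
    "AnchorTieBreak",
    "compute_rrt",
    "fit_windows",
    "predict_window",
    "is_within",
    "round_minutes",
]

DEFAULT_ANCHOR = "A2G2"

AnchorTieBreak = Literal["first_eluting", "most_intense"]


def round_minutes(x: float, decimals: int = 1) -> float:
    """Round half-up to the reporting precision (0.1 min by default).

    Used only for display; window membership is always decided on the
    unrounded endpoints.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RTObservation:
    """One chromatographic peak of one glycopeptide in one run.

    ``peak_index`` orders multiple isomer peaks of the same glycoform;
    ``replicate`` distinguishes repeated injections, each of which carries
    its own anchor measurement.
    """

    peptide_id: str
    glycoform: str
    rt_min: float
    peak_index: int = 1
    intensity: Optional[float] = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if not self.peptide_id:
            raise ValueError("peptide_id must be non-empty")
        if not self.rt_min > 0:
            raise ValueError(f"rt_min must be positive, got {self.rt_min}")
        if self.peak_index < 1:
            raise ValueError(f"peak_index must be >= 1, got {self.peak_index}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError(f"intensity must be nonnegative, got {self.intensity}")


class RRTWindowEntry(BaseModel):
    """Fitted window of one glycoform: median, sigma, and the limits
    median -/+ k*sigma on the dimensionless RRT scale.

    ``n_obs`` is None for parameter sets transcribed from a report that does
    not state observation counts.  ``degenerate`` flags windows fitted from
    a single observation (sigma = 0, zero width).
    """

    model_config = ConfigDict(extra="forbid")

    median: float = Field(gt=0)
    sigma: float = Field(ge=0)
    lower: float = Field(gt=0)
    upper: float = Field(gt=0)
    n_obs: Optional[int] = Field(default=None, ge=1)
    degenerate: bool = False

    @model_validator(mode="after")
    def _check_ordering(self) -> "RRTWindowEntry":
        if not self.lower <= self.median <= self.upper:
            raise ValueError(
                f"window limits must satisfy lower <= median <= upper, "
                f"got {self.lower} / {self.median} / {self.upper}"
            )
        return self


class RRTWindowModel(BaseModel):
    """Per-glycoform RRT windows relative to one anchor glycoform.

    The anchor's RRT is identically 1, so it never appears among the
    entries.  ``k`` records the limit multiplier the entries were built
    with; prediction uses the stored limits directly, so models transcribed
    from rounded published limits reproduce those limits exactly.
    """

    model_config = ConfigDict(extra="forbid")

    anchor_glycoform: str = DEFAULT_ANCHOR
    k: float = Field(default=3.0, gt=0)
    entries: Dict[str, RRTWindowEntry] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_anchor(self) -> "RRTWindowModel":
        if self.anchor_glycoform in self.entries:
            raise ValueError(
                f"anchor glycoform {self.anchor_glycoform!r} must not appear among entries"
            )
        return self

    @property
    def glycoforms(self) -> list[str]:
        return list(self.entries)

    def entry(self, glycoform: str) -> RRTWindowEntry:
        try:
            return self.entries[glycoform]
        except KeyError:
            known = ", ".join(sorted(self.entries))
            raise KeyError(f"glycoform {glycoform!r} not in model; entries: {known}") from None


class PredictionWindow(BaseModel):
    """Absolute elution window (minutes) of one glycoform for one anchor RT.

    Endpoints are carried at full precision; :meth:`rounded` applies the
    0.1-min half-up reporting convention.
    """

    model_config = ConfigDict(extra="forbid")

    glycoform: str
    lower_min: float = Field(gt=0)
    upper_min: float = Field(gt=0)

    @model_validator(mode="after")
    def _check_order(self) -> "PredictionWindow":
        if self.lower_min > self.upper_min:
            raise ValueError(f"lower_min {self.lower_min} exceeds upper_min {self.upper_min}")
        return self

    def rounded(self, decimals: int = 1) -> Tuple[float, float]:
        return round_minutes(self.lower_min, decimals), round_minutes(self.upper_min, decimals)


def compute_rrt(tr_x: float, tr_anchor: float) -> float:
    """RRT of a glycoform: its retention time over the anchor's, same run."""
    if not tr_anchor > 0:
        raise ValueError(f"anchor retention time must be positive, got {tr_anchor}")
    if not tr_x > 0:
        raise ValueError(f"retention time must be positive, got {tr_x}")
    return tr_x / tr_anchor


def _resolve_group_anchor(
    anchors: list[RTObservation],
    peptide_id: str,
    tie_break: Optional[AnchorTieBreak],
) -> float:
    if not anchors:
        raise ValueError(f"peptide {peptide_id!r} has no anchor-glycoform observation")
    if len(anchors) == 1:
        return anchors[0].rt_min
    if tie_break is None:
        raise ValueError(
            f"peptide {peptide_id!r} has {len(anchors)} anchor peaks and no tie-break is "
            "configured (options: 'first_eluting', 'most_intense')"
        )
    if tie_break == "first_eluting":
        return min(a.rt_min for a in anchors)
    if tie_break == "most_intense":
        if any(a.intensity is None for a in anchors):
            raise ValueError(
                f"tie-break 'most_intense' requires intensities on every anchor peak "
                f"of peptide {peptide_id!r}"
            )
        return max(anchors, key=lambda a: a.intensity).rt_min
    raise ValueError(f"unknown anchor tie-break {tie_break!r}")


def fit_windows(
    observations: Iterable[RTObservation],
    k: float = 3.0,
    anchor: str = DEFAULT_ANCHOR,
    ddof: int = 1,
    anchor_tie_break: Optional[AnchorTieBreak] = None,
) -> RRTWindowModel:
    """Fit per-glycoform RRT windows from observed retention times.

    RRTs are computed within each (peptide, replicate) group against that
    group's anchor observation, then pooled across peptides, replicates and
    isomer peaks.  Each glycoform gets median, sample standard deviation
    (``ddof=1`` by default, small training groups) and limits
    median +/- k*sigma.  A glycoform seen only once gets a zero-width window
    flagged ``degenerate``.

    A group with several anchor peaks is resolved by ``anchor_tie_break``;
    without one it is an error, because a mischosen anchor corrupts every
    window derived from it.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("no observations to fit")
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")

    groups: Dict[Tuple[str, int], list[RTObservation]] = {}
    for o in obs:
        groups.setdefault((o.peptide_id, o.replicate), []).append(o)

    pooled: Dict[str, list[float]] = {}
    for (pid, _rep), group in groups.items():
        anchors = [o for o in group if o.glycoform == anchor]
        anchor_rt = _resolve_group_anchor(anchors, pid, anchor_tie_break)
        for o in group:
            if o.glycoform == anchor:
                continue
            pooled.setdefault(o.glycoform, []).append(compute_rrt(o.rt_min, anchor_rt))

    if not pooled:
        raise ValueError("no non-anchor observations; nothing to fit")

    entries: Dict[str, RRTWindowEntry] = {}
    for glycoform, rrts in pooled.items():
        arr = np.asarray(rrts, dtype=float)
        median = float(np.median(arr))
        if arr.size > ddof:
            sigma = float(np.std(arr, ddof=ddof))
        else:
            sigma = 0.0
        degenerate = arr.size == 1
        lower = median - k * sigma
        upper = median + k * sigma
        if lower <= 0:
            raise ValueError(
                f"glycoform {glycoform!r}: lower limit {lower:.4f} is not positive; "
                "RRT scatter is too large for a meaningful window at this k"
            )
        entries[glycoform] = RRTWindowEntry(
            median=median,
            sigma=sigma,
            lower=lower,
            upper=upper,
            n_obs=arr.size,
            degenerate=degenerate,
        )
    return RRTWindowModel(anchor_glycoform=anchor, k=k, entries=entries)


def predict_window(model: RRTWindowModel, glycoform: str, anchor_rt: float) -> PredictionWindow:
    """Absolute elution window of ``glycoform`` given the anchor's RT.

    Scales the model's stored RRT limits by ``anchor_rt``; linear in the
    anchor RT by construction.
    """
    if not anchor_rt > 0:
        raise ValueError(f"anchor retention time must be positive, got {anchor_rt}")
    entry = model.entry(glycoform)
    return PredictionWindow(
        glycoform=glycoform,
        lower_min=anchor_rt * entry.lower,
        upper_min=anchor_rt * entry.upper,
    )


def is_within(rt: float, window: PredictionWindow) -> bool:
    """Window membership, boundaries inclusive, on unrounded endpoints.

    A measurement exactly at median +/- k*sigma validates, consistent with
    the 99.7% Gaussian coverage intent of k = 3.
    """
    return window.lower_min <= rt <= window.upper_min
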