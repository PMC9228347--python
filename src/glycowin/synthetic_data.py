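"""Synthetic retention-time tables with the structure the RRT model assumes.

The generator emulates the data-generating process behind the window model:
each peptide backbone has its own anchor retention time (drawn uniformly
over a plausible HILIC elution range); each glycoform's true RRT on that
backbone is drawn from a Gaussian around its glycoform-specific median
(backbone invariance, optionally perturbed); every replicate injection
measures each species with multiplicative noise of a configurable relative
standard deviation (0.6% by default, typical instrument reproducibility).
Isobaric isomers can be added as deterministic RRT offsets, producing extra
peaks that the fit pools into one window.

The ground truth used for every draw is returned alongside the
observations, so parameter-recovery and coverage tests close the loop
without any real LC-MS data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from glycowin.rrt_model import DEFAULT_ANCHOR, RTObservation

__all__ = ["GlycoformTruth", "SimulationConfig", "SimulationResult", "simulate_dataset"]


class GlycoformTruth(BaseModel):
    """True RRT distribution of one glycoform: Normal(median, sigma)."""

    model_config = ConfigDict(extra="forbid")

    median: float = Field(gt=0)
    sigma: float = Field(ge=0)


def _default_glycoforms() -> Dict[str, GlycoformTruth]:
    from glycowin.fixtures import reference_window_model

    model = reference_window_model()
    return {
        g: GlycoformTruth(median=e.median, sigma=e.sigma) for g, e in model.entries.items()
    }


class SimulationConfig(BaseModel):
    """Study design of a simulated retention-time experiment.

    Defaults mirror the reference study: the ten modeled glycoforms with
    their fitted medians/sigmas as truth, anchor RTs in the 25-40 min range
    the training backbones span, 0.6% replicate RSD, four injections.
    """

    model_config = ConfigDict(extra="forbid")

    n_peptides: int = Field(default=6, ge=1)
    glycoforms: Dict[str, GlycoformTruth] = Field(default_factory=_default_glycoforms)
    anchor_glycoform: str = DEFAULT_ANCHOR
    anchor_rt_range: Tuple[float, float] = (25.0, 40.0)
    measurement_rsd: float = Field(default=0.006, ge=0)
    n_replicates: int = Field(default=4, ge=1)
    #: glycoform -> additional isomer peaks as RRT offsets from the main peak
    isomer_spec: Dict[str, List[float]] = Field(default_factory=dict)
    #: sigma of an optional per-backbone RRT perturbation (0 = strict
    #: backbone invariance); lets tests probe violations of the model.
    per_peptide_sd: float = Field(default=0.0, ge=0)
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        lo, hi = self.anchor_rt_range
        if not (0 < lo < hi):
            raise ValueError(f"anchor_rt_range must satisfy 0 < min < max, got {self.anchor_rt_range}")
        if self.anchor_glycoform in self.glycoforms:
            raise ValueError("anchor glycoform must not appear among simulated glycoforms")
        for g, offsets in self.isomer_spec.items():
            if g not in self.glycoforms:
                raise ValueError(f"isomer_spec references unknown glycoform {g!r}")
            if any(self.glycoforms[g].median + o <= 0 for o in offsets):
                raise ValueError(f"isomer offset for {g!r} yields nonpositive RRT")
        return self


@dataclass
class SimulationResult:
    """Observations plus the exact ground truth they were drawn from."""

    observations: List[RTObservation]
    #: peptide_id -> true anchor RT (min), before measurement noise
    anchor_rt: Dict[str, float]
    #: peptide_id -> glycoform -> true RRT of the main peak
    rrt: Dict[str, Dict[str, float]]
    config: SimulationConfig

    def truth_dict(self) -> dict:
        """JSON-serializable ground-truth record."""
        return {
            "anchor_rt": self.anchor_rt,
            "rrt": self.rrt,
            "config": self.config.model_dump(mode="json"),
        }


def simulate_dataset(config: SimulationConfig, seed: Optional[int] = None) -> SimulationResult:
    """Draw a complete observation table from the configured process.

    ``seed`` overrides ``config.seed``; the same seed and config give
    byte-identical tables.  Anchor observations are emitted for every
    peptide and replicate, so fits on simulated data always have an anchor.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.anchor_rt_range

    observations: List[RTObservation] = []
    anchor_truth: Dict[str, float] = {}
    rrt_truth: Dict[str, Dict[str, float]] = {}

    width = len(str(config.n_peptides))
    for p in range(config.n_peptides):
        pid = f"pep{p + 1:0{width}d}"
        anchor_rt = float(rng.uniform(lo, hi))
        anchor_truth[pid] = anchor_rt
        rrt_truth[pid] = {}

        species: List[Tuple[str, float, int]] = [(config.anchor_glycoform, 1.0, 1)]
        for g, truth in config.glycoforms.items():
            rrt = float(rng.normal(truth.median, truth.sigma))
            if config.per_peptide_sd > 0:
                rrt += float(rng.normal(0.0, config.per_peptide_sd))
            if rrt <= 0:
                raise ValueError(
                    f"drew nonpositive RRT for {g!r}; sigma too large for this median"
                )
            rrt_truth[pid][g] = rrt
            species.append((g, rrt, 1))
            for j, offset in enumerate(config.isomer_spec.get(g, []), start=2):
                species.append((g, rrt + offset, j))

        for rep in range(1, config.n_replicates + 1):
            for g, rrt, peak in species:
                noise = 1.0 + float(rng.normal(0.0, config.measurement_rsd)) if config.measurement_rsd else 1.0
                observations.append(
                    RTObservation(
                        peptide_id=pid,
                        glycoform=g,
                        rt_min=anchor_rt * rrt * noise,
                        peak_index=peak,
                        replicate=rep,
                    )
                )
    return SimulationResult(
        observations=observations, anchor_rt=anchor_truth, rrt=rrt_truth, config=config
    )
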