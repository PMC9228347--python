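"""Packaged reference data.

Three small datasets ship with the package:

* the training-protein glycopeptide inventory — which glycoforms were
  observed on the tryptic peptides of haptoglobin, hemopexin and sex
  hormone-binding globulin (the backbones behind the reference model);
* the reference RRT window model (per-glycoform median and +/-3-sigma
  limits relative to A2G2) fitted on those glycopeptides;
* the fetuin validation table: measured retention times of fetuin
  glycopeptides together with the elution windows published for them.

Two example anchor retention times (A2G2 on two different backbones eluting
at 35.2 and 28.9 min) illustrate how strongly the peptide moiety shifts
absolute retention while leaving RRTs unchanged.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Dict, List, Tuple

from glycowin.filtering import AssignmentRecord
from glycowin.rrt_model import RRTWindowModel

__all__ = [
    "EXAMPLE_ANCHOR_RTS",
    "glycopeptide_inventory",
    "reference_window_model",
    "fetuin_assignments",
    "fetuin_published_windows",
]

#: A2G2 anchor retention times (min) of two training backbones, showing the
#: backbone-dependent absolute retention that the RRT normalization removes.
EXAMPLE_ANCHOR_RTS: Dict[str, float] = {
    "LDVDQALNR": 35.2,
    "SWPAVGNCSSALR": 28.9,
}

_DATA = resources.files("glycowin") / "data"


def glycopeptide_inventory() -> List[dict]:
    """Training glycopeptides: protein, peptide sequence, observed glycoforms."""
    with (_DATA / "glycopeptide_inventory.json").open(encoding="utf-8") as fh:
        return json.load(fh)


def reference_window_model() -> RRTWindowModel:
    """The packaged RRT window model (10 glycoforms, anchor A2G2, k = 3).

    Limits are stored as published; sigma is back-computed as
    (upper - median)/3, so it inherits the rounding of the printed limits.
    """
    with (_DATA / "reference_window_model.json").open(encoding="utf-8") as fh:
        return RRTWindowModel.model_validate(json.load(fh))


def fetuin_assignments() -> List[AssignmentRecord]:
    """Measured fetuin glycopeptide retention times (3 peptides, 14 records)."""
    from glycowin.io import read_assignments  # local import avoids a cycle

    with resources.as_file(_DATA / "fetuin_assignments.csv") as path:
        return read_assignments(path)


def fetuin_published_windows() -> Dict[str, Dict[str, Tuple[float, float]]]:
    """Published elution windows (min) for the fetuin glycopeptides.

    Most cells equal anchor RT times the reference-model limits; a few do
    not (see the methods note on window-table inconsistencies), which is why
    these values are kept separate from the model itself.
    """
    with (_DATA / "fetuin_published_windows.json").open(encoding="utf-8") as fh:
        raw = json.load(fh)
    return {pid: {g: tuple(w) for g, w in d.items()} for pid, d in raw.items()}
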