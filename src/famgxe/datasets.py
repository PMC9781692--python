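"""Design template and published summary numbers of the PFHxA study.

The package models a family-based developmental-exposure design in a
genetically heterogeneous (Tropical 5D) zebrafish population: twelve
full-sibling families (pair spawns P1..P12), four families per exposure,
exposed 6-120 hpf to vehicle control (0.33% DMSO), 16.4 uM PFHxA
(medium) or 74.8 uM PFHxA (high).  The per-family larva counts retained
after morphology/mortality QC and the reported behavioral LMM variance
summary are kept here as reference inputs for worked examples and
arithmetic checks; they are data, not estimates this package produces.
"""

from __future__ import annotations

import pandas as pd

#: retained larvae per family after QC, with each family's exposure
FAMILY_DESIGN: tuple[tuple[str, str, int], ...] = (
    ("P1", "control", 45),
    ("P2", "control", 42),
    ("P3", "control", 45),
    ("P4", "control", 48),
    ("P5", "medium", 44),
    ("P6", "medium", 35),
    ("P7", "medium", 48),
    ("P8", "medium", 47),
    ("P9", "high", 42),
    ("P10", "high", 48),
    ("P11", "high", 46),
    ("P12", "high", 48),
)

#: variance components of the published behavioral interaction LMM
BEHAVIOR_LMM_VARIANCES: dict[str, float] = {
    "family": 4221.0,
    "family_x_exposure": 19547.0,
    "residual": 77515.0,
}

#: fixed-effect estimates (estimate, SE) of the same fit
BEHAVIOR_LMM_FIXED: dict[str, tuple[float, float]] = {
    "intercept": (376.54, 63.50),
    "exposure": (-0.74, 1.43),
}

#: samples per family individually sequenced for the expression arm
EXPRESSION_SAMPLES_PER_FAMILY = 6

#: genes quantified per sample before low-expression filtering
GENES_SEQUENCED = 32171


def study_design() -> pd.DataFrame:
    """The 12-family nested design as a frame (family_id, exposure, n)."""
    return pd.DataFrame(FAMILY_DESIGN, columns=["family_id", "exposure", "n"])


def study_metadata() -> pd.DataFrame:
    """Per-individual sample metadata expanded from the design counts.

    One row per retained larva (``excluded`` all False, since the design
    counts are post-QC)."""
    rows = []
    for fam, exp, n in FAMILY_DESIGN:
        for i in range(n):
            rows.append({
                "individual_id": f"{fam}_{i:03d}",
                "family_id": fam,
                "exposure": exp,
                "excluded": False,
            })
    return pd.DataFrame(rows)
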