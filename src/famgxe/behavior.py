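"""Larval photomotor response (LPR) endpoint extraction.

At 120 hpf zebrafish larvae are tracked through alternating light/dark
periods (default: 4 cycles of 3 min light then 3 min dark, distances
integrated over 6-s bins, 240 bins in 24 min).  The analysis endpoint is
the total distance moved during dark phases, with the entire first
light/dark cycle discarded as acclimation, and dead or
morphology-flagged individuals removed before endpoint computation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import FamGxeError, FormatError, validate_metadata

logger = logging.getLogger(__name__)

LIGHT = "light"
DARK = "dark"


@dataclass(frozen=True)
class AssaySchedule:
    """Light/dark schedule of the photomotor assay.

    Bins are half-open ``[t, t + bin_seconds)`` intervals; a bin belongs
    to the phase containing its start time.  Within each cycle the first
    phase runs ``phase_seconds`` and the second the same, in
    ``phase_order`` (light first by default).
    """

    n_cycles: int = 4
    phase_seconds: int = 180
    bin_seconds: int = 6
    phase_order: tuple[str, str] = (LIGHT, DARK)

    def __post_init__(self) -> None:
        if self.n_cycles < 2:
            raise FamGxeError("n_cycles must be >= 2 (the first cycle is dropped)")
        if self.phase_seconds % self.bin_seconds != 0:
            raise FamGxeError("phase_seconds must be divisible by bin_seconds")
        if sorted(self.phase_order) != [DARK, LIGHT]:
            raise FamGxeError("phase_order must contain 'light' and 'dark'")

    @property
    def bins_per_phase(self) -> int:
        return self.phase_seconds // self.bin_seconds

    @property
    def n_bins(self) -> int:
        return self.n_cycles * 2 * self.bins_per_phase


def classify_bins(schedule: AssaySchedule) -> pd.DataFrame:
    """Label every bin of the schedule with its cycle and phase.

    Returns a frame with columns ``bin_index, cycle, phase``; cycles are
    1-based, bins contiguous from 0.
    """
    bpp = schedule.bins_per_phase
    bins = np.arange(schedule.n_bins)
    cycle = bins // (2 * bpp) + 1
    within = (bins % (2 * bpp)) // bpp
    phase = np.asarray(schedule.phase_order, dtype=object)[within]
    return pd.DataFrame({"bin_index": bins, "cycle": cycle, "phase": phase})


def _check_bins(bins: np.ndarray, schedule: AssaySchedule, who: str) -> None:
    expected = set(range(schedule.n_bins))
    got = set(int(b) for b in bins)
    if len(bins) != len(got):
        raise FormatError(f"duplicate bins for {who}")
    missing = sorted(expected - got)
    extra = sorted(got - expected)
    if missing:
        raise FormatError(f"missing bins for {who}: {missing[:10]}"
                          + ("..." if len(missing) > 10 else ""))
    if extra:
        raise FormatError(f"bins beyond the schedule for {who}: {extra[:10]}")


def total_dark_distance(trace: pd.DataFrame, schedule: AssaySchedule,
                        drop_first_cycle: bool = True,
                        phase: str = DARK) -> float:
    """Endpoint for one individual: summed distance over the dark bins of
    cycles 2..n (the first cycle is acclimation and is ignored).

    ``trace`` must cover the schedule exactly (fail-fast on gaps or extra
    bins — hardware dropouts are an upstream QC problem, not imputed).
    """
    bins = trace["bin_index"].to_numpy(dtype=int)
    who = str(trace["individual_id"].iloc[0]) if "individual_id" in trace else "trace"
    _check_bins(bins, schedule, who)
    dist = trace["distance"].to_numpy(dtype=float)
    if (dist < 0).any():
        raise FormatError(f"negative distance for {who}")
    labels = classify_bins(schedule)
    lab = labels.set_index("bin_index").loc[bins]
    keep = (lab["phase"].to_numpy() == phase)
    if drop_first_cycle:
        keep &= lab["cycle"].to_numpy() >= 2
    return float(dist[keep].sum())


def phase_totals(trace: pd.DataFrame, schedule: AssaySchedule,
                 drop_first_cycle: bool = True) -> dict[str, float]:
    """Summed distance per phase (light and dark) after first-cycle drop.

    The dark total is the analysis endpoint; the light total is computed
    for completeness but unused downstream.
    """
    return {ph: total_dark_distance(trace, schedule,
                                    drop_first_cycle=drop_first_cycle,
                                    phase=ph)
            for ph in (LIGHT, DARK)}


def build_phenotype_table(traces: pd.DataFrame, meta: pd.DataFrame,
                          schedule: AssaySchedule | None = None) -> pd.DataFrame:
    """Compute the endpoint for every retained individual.

    Excluded (dead / abnormal-morphology) individuals are dropped before
    endpoint computation; per-family retained counts are logged.  A trace
    without metadata is an error.
    """
    schedule = schedule or AssaySchedule()
    meta = validate_metadata(meta)
    trace_ids = pd.unique(traces["individual_id"])
    known = set(meta["individual_id"])
    orphans = [t for t in trace_ids if t not in known]
    if orphans:
        raise FormatError(f"traces without metadata: {orphans[:5]}")
    retained = meta.loc[~meta["excluded"]]
    rows = []
    for ind, sub in traces.groupby("individual_id", sort=True):
        if ind not in set(retained["individual_id"]):
            continue
        m = retained.loc[retained["individual_id"] == ind].iloc[0]
        rows.append({
            "individual_id": ind,
            "family_id": m["family_id"],
            "exposure": m["exposure"],
            "value": total_dark_distance(sub, schedule),
        })
    table = pd.DataFrame(rows, columns=["individual_id", "family_id",
                                        "exposure", "value"])
    if table.empty:
        warnings.warn("all individuals excluded; empty phenotype table",
                      UserWarning, stacklevel=2)
        return table
    counts = table.groupby("family_id").size().sort_index()
    for fam, n in counts.items():
        logger.info("family %s: %d larvae retained", fam, n)
    logger.info("%d individuals retained across %d families",
                len(table), len(counts))
    return table
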