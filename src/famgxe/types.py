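"""Shared domain containers and validation.

The pipeline passes around a small set of tabular objects:

* sample metadata — one row per individual with family, exposure and a
  morphology/mortality exclusion flag;
* phenotype tables — one endpoint value per retained individual;
* count matrices — genes x samples non-negative integers with per-sample
  metadata.

Tables are plain :class:`pandas.DataFrame` objects with fixed column
contracts (validated here) rather than bespoke classes, so they compose with
the ordinary pandas/numpy toolchain; the count matrix gets a light dataclass
because it couples an array with two ID axes and metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical exposure labels of the developmental PFHxA design and their
#: nominal water concentrations in micromolar.
EXPOSURE_CONCENTRATIONS: dict[str, float] = {
    "control": 0.0,
    "medium": 16.4,
    "high": 74.8,
}

#: Ordinal codes for the same exposures (0 = control, 1 = medium, 2 = high).
EXPOSURE_ORDINALS: dict[str, float] = {"control": 0.0, "medium": 1.0, "high": 2.0}

METADATA_COLUMNS = ("individual_id", "family_id", "exposure", "excluded")
PHENOTYPE_COLUMNS = ("individual_id", "family_id", "exposure", "value")


class FamGxeError(Exception):
    """Base class for errors raised by this package."""


class FormatError(FamGxeError):
    """Malformed input file or table."""


class DegenerateDataError(FamGxeError):
    """Data carry no information about the requested variance components."""


class CrossedDesignWarning(UserWarning):
    """A family appears under more than one exposure (crossed design)."""


def exposure_codes(labels, coding: str = "concentration") -> np.ndarray:
    """Map exposure labels to numeric codes.

    coding = "concentration" uses micromolar values (0 / 16.4 / 74.8);
    "ordinal" uses 0/1/2.  "cell" has no per-label code (the interaction is
    an effect per family-exposure cell) and falls back to ordinal codes for
    the fixed-effect column.
    """
    if coding in ("concentration",):
        table = EXPOSURE_CONCENTRATIONS
    elif coding in ("ordinal", "cell"):
        table = EXPOSURE_ORDINALS
    else:
        raise ValueError(f"unknown exposure coding {coding!r}")
    labels = pd.Series(labels, dtype=object)
    unknown = sorted(set(labels) - set(table))
    if unknown:
        raise FormatError(
            f"unknown exposure label(s) {unknown}; allowed: {sorted(table)}"
        )
    return labels.map(table).to_numpy(dtype=float)


def validate_metadata(meta: pd.DataFrame, allowed_exposures=None) -> pd.DataFrame:
    """Validate a sample-metadata table and check the nested design.

    Requires columns ``individual_id, family_id, exposure, excluded``.
    Every individual must appear once.  If a family appears under more than
    one exposure the design is *crossed*; that is permitted but flagged with
    :class:`CrossedDesignWarning` and recorded in ``meta.attrs['crossed']``,
    because the nested-design analyses downstream interpret the family
    variance differently.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing column(s) {missing}")
    meta = meta.copy()
    if meta["individual_id"].duplicated().any():
        dupes = meta.loc[meta["individual_id"].duplicated(), "individual_id"]
        raise FormatError(f"duplicate individual_id(s): {sorted(set(dupes))[:5]}")
    if meta["exposure"].isna().any() or (meta["exposure"].astype(str) == "").any():
        raise FormatError("empty exposure label in metadata")
    allowed = set(allowed_exposures) if allowed_exposures is not None else set(
        EXPOSURE_CONCENTRATIONS
    )
    unknown = sorted(set(meta["exposure"]) - allowed)
    if unknown:
        raise FormatError(
            f"unknown exposure label(s) {unknown}; allowed: {sorted(allowed)}"
        )
    meta["excluded"] = coerce_bool(meta["excluded"])
    n_exp = meta.groupby("family_id")["exposure"].nunique()
    crossed = bool((n_exp > 1).any())
    if crossed:
        bad = sorted(n_exp.index[n_exp > 1])
        warnings.warn(
            f"family(ies) {bad} appear under more than one exposure; "
            "treating the design as crossed",
            CrossedDesignWarning,
            stacklevel=2,
        )
    meta.attrs["crossed"] = crossed
    return meta


def coerce_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    out = []
    for v in series:
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
        elif isinstance(v, (int, np.integer)) and v in (0, 1):
            out.append(bool(v))
        else:
            key = str(v).strip().lower()
            if key not in mapping:
                raise FormatError(f"cannot interpret excluded flag {v!r}")
            out.append(mapping[key])
    return pd.Series(out, index=series.index, dtype=bool)


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"phenotype table missing column(s) {missing}")
    if table["individual_id"].duplicated().any():
        raise FormatError("phenotype table has duplicate individuals")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise FormatError("phenotype table contains non-finite values")
    return table


@dataclass
class CountMatrix:
    """Genes x samples integer count matrix with sample metadata.

    ``counts[i, j]`` is the count of ``gene_ids[i]`` in ``sample_ids[j]``.
    ``meta`` has one row per sample, aligned to ``sample_ids`` by its
    ``individual_id`` column.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen, dupes = set(), []
            for g in self.gene_ids:
                if g in seen:
                    dupes.append(g)
                seen.add(g)
            raise FormatError(f"duplicate gene ID(s): {dupes[:5]}")
        if self.counts.size:
            if not np.issubdtype(self.counts.dtype, np.integer):
                rounded = np.rint(self.counts)
                if not np.allclose(self.counts, rounded, atol=0, rtol=0):
                    i, j = np.argwhere(self.counts != rounded)[0]
                    raise FormatError(
                        f"non-integer count at gene {self.gene_ids[i]!r}, "
                        f"sample {self.sample_ids[j]!r}"
                    )
                self.counts = rounded.astype(np.int64)
            if (self.counts < 0).any():
                i, j = np.argwhere(self.counts < 0)[0]
                raise FormatError(
                    f"negative count at gene {self.gene_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}"
                )
        if len(self.meta):
            order = {s: k for k, s in enumerate(self.sample_ids)}
            missing = [s for s in self.sample_ids
                       if s not in set(self.meta["individual_id"])]
            if missing:
                raise FormatError(f"samples without metadata: {missing[:5]}")
            self.meta = (
                self.meta.set_index("individual_id")
                .loc[self.sample_ids]
                .reset_index()
            )
            del order

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized (float) expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    scheme: str = "log-cpm"

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
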