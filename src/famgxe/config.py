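"""Run configuration and deterministic seed derivation."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .types import FamGxeError

VALID_ENDPOINTS = ("dark_total",)
VALID_CODINGS = ("concentration", "ordinal", "cell")
VALID_NORMALIZATIONS = ("log-cpm", "cpm", "median-of-ratios")


def child_seed(master: int, stage: str) -> int:
    """Derive a per-stage (or per-gene) seed from the master seed.

    Stable across processes and platforms: SHA-256 of ``"{master}:{stage}"``
    reduced to 31 bits, so each stage is reproducible independently of the
    order in which stages run.
    """
    digest = hashlib.sha256(f"{int(master)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**31)


@dataclass
class RunConfig:
    """Settings shared across pipeline stages.

    Attributes
    ----------
    endpoint : behavioral endpoint; only ``dark_total`` (summed dark-phase
        distance, first cycle dropped) is defined.
    coding : numeric coding of exposure in the interaction LMM —
        ``concentration`` (0 / 16.4 / 74.8 uM), ``ordinal`` (0/1/2) or
        ``cell`` (an interaction effect per family-exposure cell).
    n_boot : parametric-bootstrap replicates (study default 1000).
    ci_level : bootstrap confidence level for the interaction variance.
    min_count, min_frac : low-expression filter — a gene must reach
        ``min_count`` in at least ``min_frac`` of some treatment group's
        samples.
    strict_filter : require the threshold in *every* treatment group
        instead of at least one.
    normalization : count normalization scheme.
    seed : master seed; stages draw child seeds via :func:`child_seed`.
    """

    endpoint: str = "dark_total"
    coding: str = "concentration"
    n_boot: int = 1000
    ci_level: float = 0.95
    min_count: int = 20
    min_frac: float = 0.25
    strict_filter: bool = False
    normalization: str = "log-cpm"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.endpoint not in VALID_ENDPOINTS:
            raise FamGxeError(f"endpoint must be one of {VALID_ENDPOINTS}")
        if self.coding not in VALID_CODINGS:
            raise FamGxeError(f"coding must be one of {VALID_CODINGS}")
        if not (isinstance(self.n_boot, int) and self.n_boot >= 1):
            raise FamGxeError("n_boot must be a positive integer")
        if not (0.0 < self.ci_level < 1.0):
            raise FamGxeError("ci_level must lie in (0, 1)")
        if self.min_count < 0:
            raise FamGxeError("min_count must be >= 0")
        if not (0.0 < self.min_frac <= 1.0):
            raise FamGxeError("min_frac must lie in (0, 1]")
        if self.normalization not in VALID_NORMALIZATIONS:
            raise FamGxeError(
                f"normalization must be one of {VALID_NORMALIZATIONS}"
            )
        self.seed = int(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = dict(kwargs.pop("extra", {}) or {})
        extra.update({k: v for k, v in data.items() if k not in known})
        return cls(extra=extra, **kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FamGxeError(f"config file {path} is not a mapping")
        return cls.from_dict(data)
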