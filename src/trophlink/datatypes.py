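"""Core containers shared across the pipeline.

All isotope values are in per-mil (‰): carbon relative to PDB, nitrogen
relative to atmospheric N2. Arrays indexed by isotope are always ordered
``(d13c, d15n)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: canonical isotope ordering used by every (n, 2) array in the package
ISOTOPES = ("d13c", "d15n")


def _as_iso_pair(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (2,):
        raise ValueError(f"{name} must have shape (2,) = (d13c, d15n), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr}")
    return arr


@dataclass
class SourceSummary:
    """Per-source isotope distribution plus its trophic enrichment factor.

    ``mu``/``sd`` describe the source tissue itself; ``tef_mu``/``tef_sd`` the
    diet-to-consumer enrichment applied when this source is eaten, so the
    consumer sees the source at ``mu + tef_mu`` with pooled variance
    ``sd**2 + tef_sd**2``.
    """

    label: str
    mu: np.ndarray
    sd: np.ndarray
    tef_mu: np.ndarray
    tef_sd: np.ndarray

    def __post_init__(self) -> None:
        self.mu = _as_iso_pair(self.mu, "mu")
        self.sd = _as_iso_pair(self.sd, "sd")
        self.tef_mu = _as_iso_pair(self.tef_mu, "tef_mu")
        self.tef_sd = _as_iso_pair(self.tef_sd, "tef_sd")
        if np.any(self.sd < 0) or np.any(self.tef_sd < 0):
            raise ValueError(f"source '{self.label}': standard deviations must be >= 0")

    @property
    def shifted_mu(self) -> np.ndarray:
        """TEF-corrected mean seen by the consumer."""
        return self.mu + self.tef_mu

    @property
    def pooled_var(self) -> np.ndarray:
        """Source variance plus TEF variance, per isotope."""
        return self.sd**2 + self.tef_sd**2


@dataclass
class IsotopeSample:
    """One individual's isotope measurement with station/taxon metadata."""

    sample_id: str
    station_id: str
    species: str
    functional_group: str
    d13c: float
    d15n: float
    c_to_n: float | None = None
    total_length: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d13c) and math.isfinite(self.d15n)):
            raise ValueError(f"sample {self.sample_id}: isotope values must be finite")
        if self.c_to_n is not None and self.c_to_n < 0:
            raise ValueError(f"sample {self.sample_id}: C:N must be >= 0")


@dataclass
class TefModel:
    """Trophic enrichment factors.

    Carbon enrichment is a constant 1.0 ± 0.4 ‰ per trophic step. Nitrogen
    enrichment is either the classical constant 3.4 ‰ or, by default, scales
    down linearly with the consumer's own δ15N (more enriched consumers sit
    higher in the web and fractionate less): Δ15N = 5.92 − 0.27 · δ15N.
    """

    carbon_mean: float = 1.0
    carbon_sd: float = 0.4
    mode: str = "proportional"  # "proportional" or "constant"
    constant_mean: float = 3.4
    constant_sd: float = 1.0
    intercept: float = 5.92
    slope: float = 0.27

    def __post_init__(self) -> None:
        if self.mode not in ("proportional", "constant"):
            raise ValueError(f"unknown TEF mode {self.mode!r}")
        if self.carbon_sd < 0 or self.constant_sd < 0:
            raise ValueError("TEF standard deviations must be >= 0")

    def nitrogen_mean(self, d15n_consumer: float) -> float:
        if self.mode == "constant":
            return self.constant_mean
        return self.intercept - self.slope * d15n_consumer

    def nitrogen_sd(self, d15n_consumer_sd: float) -> float:
        """SD of the group TEF induced by spread in member δ15N values."""
        if self.mode == "constant":
            return self.constant_sd
        return self.slope * d15n_consumer_sd

    def for_consumer(self, d15n_mean: float, d15n_sd: float) -> tuple[np.ndarray, np.ndarray]:
        """(tef_mu, tef_sd) pair for a consumer group, both isotopes."""
        return (
            np.array([self.carbon_mean, self.nitrogen_mean(d15n_mean)]),
            np.array([self.carbon_sd, self.nitrogen_sd(d15n_sd)]),
        )


@dataclass
class GroupSummary:
    """Functional-group roll-up of individual isotope samples."""

    group: str
    n: int
    d13c_mean: float
    d13c_sd: float
    d15n_mean: float
    d15n_sd: float
    tl_mean: float
    tl_sd: float
    tef_d15n_mean: float
    tef_d15n_sd: float
    single_member: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group '{self.group}': n must be >= 1")
        for name in ("d13c_sd", "d15n_sd", "tl_sd", "tef_d15n_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"group '{self.group}': {name} must be >= 0")

    def as_source(self, consumer_tef: tuple[np.ndarray, np.ndarray]) -> SourceSummary:
        """View this group as a diet source for some consumer's TEF."""
        tef_mu, tef_sd = consumer_tef
        return SourceSummary(
            label=self.group,
            mu=np.array([self.d13c_mean, self.d15n_mean]),
            sd=np.array([self.d13c_sd, self.d15n_sd]),
            tef_mu=tef_mu,
            tef_sd=tef_sd,
        )


@dataclass
class TrophicLevelEstimate:
    """Trophic position from δ15N enrichment above a baseline consumer."""

    label: str
    tl: float
    sd: float
    d15n_base: float
    lambda_base: float = 2.0
    enrichment: float = 3.4

    def __post_init__(self) -> None:
        if self.enrichment <= 0:
            raise ValueError("enrichment (Δ15N per trophic step) must be > 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
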