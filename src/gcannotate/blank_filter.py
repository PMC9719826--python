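"""Blank feature filtering (BFF).

A feature is retained only when its sample statistic (mean by default, or a
percentile) strictly exceeds ``c * (blank mean + 3 * blank SD)``. Filtering
is a precondition for every confidence level: background artifacts must not
be annotated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .spectra_io import FeatureRecord

__all__ = ["BFFConfig", "BlankStats", "BlankFilterResult",
           "bff_threshold", "passes_blank_filter"]


@dataclass(frozen=True)
class BFFConfig:
    """Blank-filter settings.

    ``c`` is the abundance multiplier (field practice ranges roughly 2-10;
    default 3). ``min_blanks`` reflects the recommendation to acquire at
    least four blanks; fewer blanks trigger a warning, not an error.
    """

    c: float = 3.0
    sample_statistic: str = "mean"  # or "percentile"
    percentile: float | None = None  # fraction in (0, 1], used for "percentile"
    min_blanks: int = 4

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ContractError("c must be positive")
        if self.sample_statistic not in ("mean", "percentile"):
            raise ContractError(
                f"unknown sample statistic {self.sample_statistic!r}"
            )
        if self.sample_statistic == "percentile":
            if self.percentile is None or not (0 < self.percentile <= 1):
                raise ContractError("percentile must lie in (0, 1]")


@dataclass(frozen=True)
class BlankStats:
    mean: float
    sd: float
    n_blanks: int

    def __post_init__(self) -> None:
        if self.sd < 0 or self.n_blanks < 1:
            raise ContractError("invalid blank statistics")


@dataclass(frozen=True)
class BlankFilterResult:
    passed: bool
    threshold: float
    sample_statistic_value: float
    n_blanks: int


def bff_threshold(stats: BlankStats, config: BFFConfig) -> float:
    """``threshold = c * (mean + 3 * sd)``; zero blank signal gives zero."""
    return config.c * (stats.mean + 3.0 * stats.sd)


def blank_stats(abundances: np.ndarray | list[float]) -> BlankStats:
    """Blank mean and sample SD (ddof=1; 0 for a single blank)."""
    arr = np.asarray(abundances, dtype=float)
    if arr.size == 0:
        return BlankStats(0.0, 0.0, 1)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return BlankStats(float(arr.mean()), sd, int(arr.size))


def passes_blank_filter(
    feature: FeatureRecord, config: BFFConfig | None = None
) -> BlankFilterResult:
    """Gate one feature against its blank abundances.

    Missing blank measurements count as 0. The feature passes iff its sample
    statistic is strictly greater than the threshold. Fewer than
    ``min_blanks`` blanks emit a warning but the feature is still evaluated.
    """
    config = config or BFFConfig()
    if not feature.sample_abundances:
        raise ContractError(
            f"feature {feature.feature_id}: no sample abundances"
        )
    blanks = np.asarray(list(feature.blank_abundances.values()), dtype=float)
    stats = blank_stats(blanks)
    if stats.n_blanks < config.min_blanks:
        warnings.warn(
            f"feature {feature.feature_id}: only {stats.n_blanks} blank(s); "
            f"at least {config.min_blanks} recommended",
            stacklevel=2,
        )
    threshold = bff_threshold(stats, config)
    samples = np.asarray(list(feature.sample_abundances.values()), dtype=float)
    if config.sample_statistic == "mean":
        value = float(samples.mean())
    else:
        value = float(np.quantile(samples, config.percentile))
    return BlankFilterResult(value > threshold, threshold, value, stats.n_blanks)
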