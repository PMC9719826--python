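"""Validation metrics for annotation pipelines.

Given a truth sheet of spiked standards, computes per-level false-positive
and false-negative rates (a false positive is a feature whose top-ranked
candidate at the level is not the true compound; a false negative is a
detected truth compound that receives no assignment at the level). Close
isomers can be pooled via equivalence groups so that a hit within the truth
compound's group does not count as a false positive.

Also reproduces filter-retention arithmetic for published candidate-count
tables: per-compound percent-of-candidates-removed with mean +/- SD
summaries, false-negative rates from correct-candidate-retained flags, and
single-surviving-candidate counts. A 19-standard validation table from
indoor/outdoor air monitoring is bundled for reference
(:func:`load_air_validation_counts`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError

__all__ = [
    "TruthRecord",
    "FilterCountRow",
    "TopHit",
    "LevelMetrics",
    "evaluate",
    "percent_filtered",
    "false_negative_rate_from_flags",
    "single_candidate_count",
    "total_spectral_ion_abundance",
    "load_filter_counts",
    "load_air_validation_counts",
    "tophits_from_assignments",
    "tophits_from_results",
    "truth_from_spike_sheet",
]


@dataclass(frozen=True)
class TruthRecord:
    """One spiked standard: the feature it produced and its identity."""

    feature_id: str
    name: str
    identifier: str
    equivalence_group: str = ""


@dataclass
class FilterCountRow:
    """Candidate counts for one compound under a set of filters."""

    compound: str
    total_detected: int
    retained: dict[str, int] = field(default_factory=dict)
    correct_retained: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, n in self.retained.items():
            if not (0 <= n <= self.total_detected):
                raise ContractError(
                    f"{self.compound}: retained[{name}]={n} outside "
                    f"[0, {self.total_detected}]"
                )


@dataclass(frozen=True)
class TopHit:
    """Minimal view of one feature's annotation for evaluation."""

    feature_id: str
    level: str | None
    identifier: str
    name: str = ""


@dataclass
class LevelMetrics:
    level: str
    n_assigned: int
    n_truth_assigned: int
    n_wrong: int
    fp_rate: float
    fn_rate: float
    n_truth_detected: int


def tophits_from_assignments(assignments: Sequence) -> list[TopHit]:
    """Adapt :class:`~gcannotate.scoring_engine.LevelAssignment` objects."""
    return [
        TopHit(
            feature_id=a.feature_id,
            level=a.level,
            identifier=a.best_identifier,
            name=a.best_candidate.name if a.best_candidate else "",
        )
        for a in assignments
    ]


def tophits_from_results(df: pd.DataFrame) -> list[TopHit]:
    """Adapt a results-CSV DataFrame (rank-1 rows) to :class:`TopHit`."""
    hits = []
    for fid, grp in df.groupby("feature_id", sort=False):
        ranked = grp[grp["rank"] == 1]
        row = ranked.iloc[0] if len(ranked) else grp.iloc[0]
        level = row["level"]
        level = None if (pd.isna(level) or level == "") else str(level)
        ident = row["candidate_identifier"]
        hits.append(
            TopHit(
                feature_id=str(fid),
                level=level,
                identifier="" if pd.isna(ident) else str(ident),
                name=str(row["candidate_name"]) if not pd.isna(row["candidate_name"]) else "",
            )
        )
    return hits


def truth_from_spike_sheet(df: pd.DataFrame) -> list[TruthRecord]:
    return [
        TruthRecord(
            feature_id=str(r["feature_id"]),
            name=str(r["name"]),
            identifier=str(r["identifier"]),
            equivalence_group=str(r.get("equivalence_group", "")),
        )
        for _, r in df.iterrows()
    ]


def evaluate(
    assignments: Sequence[TopHit] | Sequence,
    truth: Sequence[TruthRecord],
    isomer_mode: str = "exact",
) -> dict[str, LevelMetrics]:
    """Per-level FP and FN rates against a truth sheet.

    ``FP_L`` = (# features whose top candidate at level L is wrong) /
    (# features assigned L). Only features present in the truth sheet can be
    judged wrong; features absent from truth enter the denominator only.
    ``FN_L`` = (# truth compounds detected but not assigned L) /
    (# truth compounds detected). With ``isomer_mode="equivalence"`` a
    candidate inside the truth compound's equivalence group counts as
    correct. Rates are percentages.
    """
    if not truth:
        raise ContractError("truth sheet is empty")
    if isomer_mode not in ("exact", "equivalence"):
        raise ContractError(f"unknown isomer mode {isomer_mode!r}")
    ids = [t.identifier for t in truth]
    if len(set(ids)) != len(ids):
        raise ContractError("truth identifier collision")
    if assignments and not isinstance(assignments[0], TopHit):
        assignments = tophits_from_assignments(assignments)

    truth_by_feature = {t.feature_id: t for t in truth}
    group_of = {t.identifier: t.equivalence_group for t in truth if t.equivalence_group}
    detected = [t for t in truth if t.feature_id in {a.feature_id for a in assignments}]
    n_detected = len(detected)

    def correct(candidate_id: str, t: TruthRecord) -> bool:
        if candidate_id == t.identifier:
            return True
        if isomer_mode == "equivalence" and t.equivalence_group:
            return group_of.get(candidate_id, None) == t.equivalence_group
        return False

    levels = sorted({a.level for a in assignments if a.level is not None})
    out: dict[str, LevelMetrics] = {}
    for level in levels:
        at_level = [a for a in assignments if a.level == level]
        truth_at_level = [a for a in at_level if a.feature_id in truth_by_feature]
        wrong = sum(
            1
            for a in truth_at_level
            if not correct(a.identifier, truth_by_feature[a.feature_id])
        )
        fp = 100.0 * wrong / len(at_level) if at_level else 0.0
        assigned_features = {a.feature_id for a in at_level}
        missed = sum(1 for t in detected if t.feature_id not in assigned_features)
        fn = 100.0 * missed / n_detected if n_detected else 0.0
        out[level] = LevelMetrics(
            level=level,
            n_assigned=len(at_level),
            n_truth_assigned=len(truth_at_level),
            n_wrong=wrong,
            fp_rate=fp,
            fn_rate=fn,
            n_truth_detected=n_detected,
        )
    return out


def percent_filtered(
    rows: Sequence[FilterCountRow],
    aggregation: str = "per_compound",
) -> tuple[dict[str, tuple[float, float]], pd.DataFrame]:
    """Percent of candidates removed by each filter.

    ``per_compound`` (default): percent removed is computed per compound and
    summarized as the equal-weight mean and sample SD across compounds.
    ``pooled``: a single percentage over summed counts (SD 0). Rows with
    zero total candidates are excluded with a warning. Returns the summary
    map filter -> (mean, sd) and the per-compound percentage table.
    """
    valid = []
    for r in rows:
        if r.total_detected == 0:
            import warnings

            warnings.warn(
                f"{r.compound}: zero candidates detected; row excluded",
                stacklevel=2,
            )
            continue
        valid.append(r)
    if not valid:
        raise ContractError("no usable rows")
    filters = sorted({f for r in valid for f in r.retained})
    table = pd.DataFrame(
        {
            "compound": [r.compound for r in valid],
            **{
                f: [
                    100.0 * (1.0 - r.retained[f] / r.total_detected)
                    if f in r.retained
                    else np.nan
                    for r in valid
                ]
                for f in filters
            },
        }
    )
    summary: dict[str, tuple[float, float]] = {}
    for f in filters:
        if aggregation == "per_compound":
            vals = table[f].dropna().to_numpy()
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        elif aggregation == "pooled":
            tot = sum(r.total_detected for r in valid if f in r.retained)
            kept = sum(r.retained[f] for r in valid if f in r.retained)
            mean, sd = 100.0 * (1.0 - kept / tot), 0.0
        else:
            raise ContractError(f"unknown aggregation {aggregation!r}")
        summary[f] = (mean, sd)
    return summary, table


def false_negative_rate_from_flags(
    rows: Sequence[FilterCountRow], filter_name: str
) -> float:
    """Percent of compounds whose correct candidate the filter removed."""
    flags = []
    for r in rows:
        if filter_name not in r.correct_retained:
            raise ContractError(
                f"{r.compound}: no correct-retained flag for {filter_name!r}"
            )
        flags.append(r.correct_retained[filter_name])
    return 100.0 * sum(1 for f in flags if not f) / len(flags)


def single_candidate_count(
    rows: Sequence[FilterCountRow], filter_name: str
) -> int:
    """Number of compounds left with exactly one candidate by the filter."""
    return sum(1 for r in rows if r.retained.get(filter_name) == 1)


def total_spectral_ion_abundance(
    peak_area_or_height: float, avg_ratio: float
) -> float:
    """Estimate total spectral ion abundance from an integrated peak area
    (or height) and the run's average abundance-to-area ratio."""
    if peak_area_or_height <= 0:
        raise ContractError("peak area/height must be positive")
    if avg_ratio <= 0:
        raise ContractError("ratio must be positive")
    return peak_area_or_height * avg_ratio


_FLAG_COLUMNS = {
    "correct_level2_retained": "level2_all",
    "correct_molecular_ion_observed": "molecular_ion",
}


def load_filter_counts(source: str | Path | pd.DataFrame) -> list[FilterCountRow]:
    """Read a filter-count CSV (``compound``, ``total_detected``, one column
    per filter, optional ``correct_*`` yes/no flag columns) into rows."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, comment="#")
    rows = []
    flag_cols = [c for c in df.columns if c.startswith("correct_")]
    count_cols = [
        c for c in df.columns if c not in ("compound", "total_detected") + tuple(flag_cols)
    ]
    for _, r in df.iterrows():
        flags = {}
        for c in flag_cols:
            target = _FLAG_COLUMNS.get(c, c.removeprefix("correct_"))
            flags[target] = str(r[c]).strip().lower() in ("yes", "true", "1")
        rows.append(
            FilterCountRow(
                compound=str(r["compound"]),
                total_detected=int(r["total_detected"]),
                retained={c: int(r[c]) for c in count_cols},
                correct_retained=flags,
            )
        )
    return rows


def load_air_validation_counts() -> list[FilterCountRow]:
    """The bundled 19-standard air-monitoring validation table: candidate
    counts retained by each Level-2/3 filter, with correct-candidate flags
    for the combined Level-2 filter and the molecular-ion filter."""
    with resources.files("gcannotate.data").joinpath(
        "air_validation_counts.csv"
    ).open("r") as fh:
        return load_filter_counts(pd.read_csv(fh))
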