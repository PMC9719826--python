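"""Five-level annotation confidence scoring.

Levels, from strongest to weakest evidence:

* **1** — confirmed identification against an in-house standard: retention
  time within 1 % of the standard's, plus either 2+ reference ions at
  expected ratios (within 20 %) or an in-house spectral match > 600.
* **2** — probable structure or close isomer from external libraries:
  reverse dot product > 600 and forward dot product > 500 (or, for soft
  ionization, >= 5 library-matched fragments), an RI match (experimental:
  |dRI| < 50 and < 1.5 %; predicted: |dRI| < 100), and accurate-mass support
  (exact-mass library RSI > 600 or RHRMF > 75).
* **3** — tentative candidate: the spectral + accurate-mass conditions
  without an RI pass; alternatively |dRI| < 100 together with >= 3 rule-based
  accurate-mass ions or an accurate-mass molecular ion.
* **4A/4B/4C** — formula / homologous series / chemical class evidence,
  reported as flags alongside levels 2/3 (the sublevels are not ordered by
  confidence and never suppress a 2 or 3).
* **5** — reproducibly detected unknown feature that passes blank filtering
  but meets no higher criterion.

All printed thresholds are strict inequalities; boundary values fail.
Blank filtering is a precondition for every level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from . import evidence as ev_mod
from .blank_filter import BFFConfig, BlankFilterResult, passes_blank_filter
from .chem_core import (
    ELECTRON_MASS,
    Formula,
    decompose_mass,
    isotope_pattern,
    kendrick_mass_defect,
    monoisotopic_mass,
)
from .errors import ContractError, InsufficientStandardError
from .evidence import (
    MatchWeighting,
    RIMatchRule,
    compute_retention_index,
    count_matched_fragments,
    detect_molecular_ion,
    dot_product_score,
    match_peaks,
    reverse_dot_product_score,
    rhrmf,
)
from .spectra_io import AlkaneCalibration, FeatureRecord, LibraryEntry, Spectrum

logger = logging.getLogger(__name__)

CI_MODES = ("PCI", "ECNI", "APCI")

__all__ = [
    "TieBreakConfig",
    "ScoringConfig",
    "CandidateEvidence",
    "LevelAssignment",
    "Level1Standard",
    "SeriesMember",
    "SeriesGroup",
    "assign_level",
    "check_level1",
    "level4a_unequivocal_formula",
    "detect_homologous_series",
    "flag_class",
    "rank_candidates",
    "dedupe",
    "build_candidate_evidence",
    "annotate_feature",
    "annotate_run",
]


@dataclass(frozen=True)
class TieBreakConfig:
    """Dominance margins for declaring a single preferred top hit."""

    evidence_count_factor: float = 10.0
    delta_ri_margin: float = 30.0
    rsi_margin: float = 50.0
    rhrmf_margin: float = 10.0


@dataclass(frozen=True)
class ScoringConfig:
    """All level thresholds, defaulting to the published cutoffs."""

    rsi_min: float = 600.0
    si_min: float = 500.0
    rhrmf_min: float = 75.0
    exact_mass_rsi_min: float = 600.0
    inhouse_match_min: float = 600.0
    ci_min_fragments: int = 5
    ci_requires_exact_mass: bool = True
    level3_alt_ri_max: float = 100.0
    level3_alt_min_accurate_ions: int = 3
    level1_rt_max_rel_dev: float = 0.01
    level1_ratio_tol: float = 0.20
    require_molecular_ion: bool = False
    tie_break: TieBreakConfig = field(default_factory=TieBreakConfig)
    ri_rule: RIMatchRule = field(default_factory=RIMatchRule)


@dataclass
class CandidateEvidence:
    """All evidence layers computed for one feature-candidate pair."""

    feature_id: str
    candidate: LibraryEntry
    si: float
    rsi: float
    delta_ri: float | None = None
    ri_source: str = "absent"
    library_ri: float | None = None
    rhrmf: float | None = None
    exact_mass_library_rsi: float | None = None
    molecular_ion: bool = False
    matched_fragments: int = 0
    ionization: str = "EI"
    accurate_ion_matches: int = 0
    evidence_count: int | None = None


@dataclass
class LevelAssignment:
    """The outcome for one feature: level, ranked candidates, flags."""

    feature_id: str
    level: str | None
    blank_pass: bool
    multi_hit: bool = False
    rank: int = 0
    best_candidate: LibraryEntry | None = None
    rationale: list[str] = field(default_factory=list)
    candidates: list[CandidateEvidence] = field(default_factory=list)
    blank_threshold: float = 0.0
    sample_statistic_value: float = 0.0
    sample_abundance_mean: float = 0.0
    blank_abundance_mean: float = 0.0

    @property
    def best_identifier(self) -> str:
        return self.best_candidate.identifier if self.best_candidate else ""

    @property
    def best_rsi(self) -> float:
        return self.candidates[0].rsi if self.candidates else float("-inf")


def _ri_ok(ev: CandidateEvidence, rule: RIMatchRule) -> bool:
    if ev.delta_ri is None or ev.ri_source == "absent" or ev.library_ri is None:
        return False
    observed = ev.library_ri + ev.delta_ri
    return ev_mod.ri_match(observed, ev.library_ri, ev.ri_source, rule).passed


def assign_level(
    ev: CandidateEvidence, config: ScoringConfig | None = None
) -> tuple[str | None, list[str]]:
    """Assign Level 2, Level 3 or no level to one candidate's evidence.

    Blank filtering must already have been applied upstream. Missing
    optional evidence simply fails its criterion; all comparisons are
    strict.
    """
    config = config or ScoringConfig()
    notes: list[str] = []

    ei_ok = ev.rsi > config.rsi_min and ev.si > config.si_min
    ci_path = ev.ionization in CI_MODES
    ci_ok = ci_path and ev.matched_fragments >= config.ci_min_fragments
    spectral_ok = ei_ok or ci_ok
    notes.append(
        f"spectral {'pass' if spectral_ok else 'fail'} "
        f"(rsi={ev.rsi:.0f}, si={ev.si:.0f}"
        + (f", ci fragments={ev.matched_fragments}" if ci_path else "")
        + ")"
    )

    exact_ok = (
        ev.exact_mass_library_rsi is not None
        and ev.exact_mass_library_rsi > config.exact_mass_rsi_min
    ) or (ev.rhrmf is not None and ev.rhrmf > config.rhrmf_min)
    if ci_ok and not config.ci_requires_exact_mass:
        exact_ok = True
    notes.append(
        f"exact-mass {'pass' if exact_ok else 'fail'} "
        f"(rhrmf={'n/a' if ev.rhrmf is None else f'{ev.rhrmf:.0f}'})"
    )

    ri_ok = _ri_ok(ev, config.ri_rule)
    notes.append(
        "ri "
        + ("pass" if ri_ok else "fail")
        + (
            f" (delta={ev.delta_ri:+.1f}, {ev.ri_source})"
            if ev.delta_ri is not None
            else " (no RI)"
        )
    )

    mol_ok = ev.molecular_ion or not config.require_molecular_ion
    if config.require_molecular_ion:
        notes.append(f"molecular ion {'pass' if ev.molecular_ion else 'fail'}")

    if spectral_ok and exact_ok and ri_ok and mol_ok:
        return "2", notes
    if spectral_ok and exact_ok:
        return "3", notes
    alt = (
        ev.delta_ri is not None
        and abs(ev.delta_ri) < config.level3_alt_ri_max
        and (
            ev.accurate_ion_matches >= config.level3_alt_min_accurate_ions
            or ev.molecular_ion
        )
    )
    if alt:
        notes.append(
            "level-3 alternative path: RI within "
            f"{config.level3_alt_ri_max:.0f} with accurate-mass ion evidence"
        )
        return "3", notes
    return None, notes


@dataclass
class Level1Standard:
    """An in-house certified standard: expected RT plus either reference
    ions with expected relative intensities or a reference spectrum."""

    entry: LibraryEntry
    expected_rt: float
    reference_peaks: tuple[tuple[float, float], ...] = ()  # (mz, rel intensity)


def check_level1(
    feature: FeatureRecord,
    standard: Level1Standard,
    config: ScoringConfig | None = None,
    weighting: MatchWeighting | None = None,
    mz_tol_ppm: float = 10.0,
) -> tuple[bool, list[str]]:
    """Confirmed identification against an authentic standard.

    Requires RT within 1 % of the standard's, and either >= 2 reference ions
    observed at expected ratios (within 20 %, ratios taken relative to the
    most intense reference peak) or an in-house spectral match > 600.
    """
    config = config or ScoringConfig()
    if not standard.reference_peaks and standard.entry.spectrum is None:
        raise InsufficientStandardError(
            "standard provides neither reference peaks nor a spectrum"
        )
    notes = []
    rt_dev = abs(feature.retention_time - standard.expected_rt) / standard.expected_rt
    rt_ok = rt_dev <= config.level1_rt_max_rel_dev
    notes.append(f"rt deviation {100 * rt_dev:.2f}% {'pass' if rt_ok else 'fail'}")
    if not rt_ok:
        return False, notes

    ratio_ok = False
    if standard.reference_peaks:
        exp_base = max(r for _, r in standard.reference_peaks)
        observed: list[tuple[float, float]] = []  # (expected_rel, observed raw)
        for mz, rel in standard.reference_peaks:
            tol = mz * mz_tol_ppm * 1e-6
            diffs = np.abs(feature.spectrum.mz - mz)
            k = int(np.argmin(diffs))
            if diffs[k] <= tol:
                observed.append((rel / exp_base, float(feature.spectrum.intensity[k])))
        if observed:
            obs_base = max(i for _, i in observed)
            good = sum(
                1
                for exp_rel, raw in observed
                if abs(raw / obs_base - exp_rel) <= config.level1_ratio_tol * exp_rel
            )
            ratio_ok = good >= 2
        notes.append(
            f"reference ions at expected ratios: {'pass' if ratio_ok else 'fail'}"
        )
    spectral_ok = False
    if not ratio_ok and standard.entry.spectrum is not None:
        score = dot_product_score(
            feature.spectrum, standard.entry.spectrum, weighting or MatchWeighting()
        )
        spectral_ok = score > config.inhouse_match_min
        notes.append(
            f"in-house spectral match {score} {'pass' if spectral_ok else 'fail'}"
        )
    return ratio_ok or spectral_ok, notes


def level4a_unequivocal_formula(
    feature: FeatureRecord,
    bounds: Formula,
    tol_ppm: float = 5.0,
    precursor_mz: float | None = None,
    iso_abundance_tol: float = 0.10,
    iso_min_rel: float = 0.05,
    dominant_fraction: float = 0.10,
    h_transfer: int = 1,
) -> Formula | None:
    """Unequivocal molecular formula from precursor mass, isotope pattern and
    fragment explicability.

    Candidate formulas from mass decomposition are kept only when (a) every
    predicted isotopologue above ``iso_min_rel`` of the base is observed at a
    relative abundance within ``iso_abundance_tol`` (absolute, base-
    normalized), and (b) every dominant fragment (>= ``dominant_fraction`` of
    the base peak, below the precursor envelope) is explicable as a
    subformula cation. The formula is returned iff exactly one candidate
    survives.
    """
    precursor = precursor_mz if precursor_mz is not None else feature.reference_mz
    if precursor is None:
        raise ContractError("no precursor/molecular-ion peak designated")
    spec = feature.spectrum
    neutral = precursor + ELECTRON_MASS
    survivors = []
    diffs = np.abs(spec.mz - precursor)
    k0 = int(np.argmin(diffs))
    precursor_intensity = float(spec.intensity[k0])
    dominant = spec.mz[
        (spec.intensity >= dominant_fraction * spec.base_intensity)
        & (spec.mz < precursor - 0.5)
    ]
    for cand in decompose_mass(neutral, tol_ppm, bounds):
        pattern = isotope_pattern(cand, abundance_cutoff=iso_min_rel, normalize="base")
        mono = pattern.peaks[0][0]
        iso_ok = True
        for mass, rel in pattern.peaks:
            ion_mz = precursor + (mass - mono)
            tol = ion_mz * tol_ppm * 1e-6
            d = np.abs(spec.mz - ion_mz)
            j = int(np.argmin(d))
            if d[j] > tol:
                iso_ok = False
                break
            obs_rel = float(spec.intensity[j]) / precursor_intensity
            if abs(obs_rel - rel) > iso_abundance_tol:
                iso_ok = False
                break
        if not iso_ok:
            continue
        if dominant.size:
            masses = ev_mod._explainable_cation_masses(
                cand, float(dominant[-1]) * (1 + tol_ppm * 1e-6), h_transfer
            )
            if not ev_mod._fraction_explained(dominant, masses, tol_ppm).all():
                continue
        survivors.append(cand)
        if len(survivors) > 1:
            return None
    return survivors[0] if len(survivors) == 1 else None


@dataclass(frozen=True)
class SeriesMember:
    feature_id: str
    mass: float
    retention_index: float


@dataclass
class SeriesGroup:
    members: list[SeriesMember]
    repeat: Formula
    kmd: float
    r_squared: float


def detect_homologous_series(
    members: Sequence[SeriesMember],
    repeat: Formula,
    kmd_tol: float = 0.002,
    min_members: int = 3,
    r2_min: float = 0.99,
    mass_tol: float = 0.005,
) -> list[SeriesGroup]:
    """Group features into homologous series by shared Kendrick mass defect,
    integer repeat-unit spacing, and RI-vs-repeat-count linearity.

    Groups smaller than ``min_members`` or with RI-linearity R^2 below
    ``r2_min`` are discarded.
    """
    if min_members < 3:
        raise ContractError("min_members must be >= 3")
    repeat_mass = monoisotopic_mass(repeat)
    pts = sorted(
        (
            (kendrick_mass_defect(m.mass, repeat).kendrick_mass_defect, m)
            for m in members
        ),
        key=lambda t: (t[0], t[1].feature_id),
    )
    groups: list[SeriesGroup] = []
    cluster: list[tuple[float, SeriesMember]] = []

    def flush() -> None:
        if len(cluster) < min_members:
            return
        anchor = min(m.mass for _, m in cluster)
        keep: list[tuple[int, SeriesMember]] = []
        for _, m in cluster:
            n = round((m.mass - anchor) / repeat_mass)
            if abs(m.mass - anchor - n * repeat_mass) <= mass_tol:
                keep.append((n, m))
        if len(keep) < min_members:
            return
        ns = np.array([n for n, _ in keep], dtype=float)
        ris = np.array([m.retention_index for _, m in keep])
        if np.unique(ns).size < 2 or np.allclose(ris, ris[0]):
            return
        fit = _scipy_stats.linregress(ns, ris)
        r2 = float(fit.rvalue**2)
        if r2 >= r2_min:
            groups.append(
                SeriesGroup(
                    members=[
                        m for _, m in sorted(keep, key=lambda t: (t[0], t[1].feature_id))
                    ],
                    repeat=repeat,
                    kmd=float(np.mean([k for k, _ in cluster])),
                    r_squared=r2,
                )
            )

    for kmd, m in pts:
        if cluster and kmd - cluster[0][0] > kmd_tol:
            flush()
            cluster = []
        cluster.append((kmd, m))
    flush()
    return groups


def flag_class(
    feature: FeatureRecord,
    diagnostics: Sequence[tuple[str, Sequence[float]]],
    tol_ppm: float = 10.0,
    min_hits: int = 1,
) -> list[str]:
    """Label a feature with each chemical class whose diagnostic fragment
    m/z values are matched at least ``min_hits`` times. Classes are
    evaluated independently, so shared fragments can yield several labels.
    """
    if not diagnostics:
        raise ContractError("diagnostics list is empty")
    if min_hits < 1:
        raise ContractError("min_hits must be >= 1")
    labels = []
    for name, frags in diagnostics:
        hits = 0
        for mz in frags:
            tol = mz * tol_ppm * 1e-6
            if np.any(np.abs(feature.spectrum.mz - mz) <= tol):
                hits += 1
        if hits >= min_hits:
            labels.append(name)
    return labels


def _dominates(
    top: CandidateEvidence, runner: CandidateEvidence, tb: TieBreakConfig
) -> bool:
    if (
        top.evidence_count is not None
        and runner.evidence_count is not None
        and runner.evidence_count > 0
        and top.evidence_count >= tb.evidence_count_factor * runner.evidence_count
    ):
        return True
    if (
        top.delta_ri is not None
        and runner.delta_ri is not None
        and abs(runner.delta_ri) - abs(top.delta_ri) >= tb.delta_ri_margin
    ):
        return True
    if top.rsi - runner.rsi >= tb.rsi_margin:
        return True
    if (
        top.rhrmf is not None
        and runner.rhrmf is not None
        and top.rhrmf - runner.rhrmf >= tb.rhrmf_margin
    ):
        return True
    return False


def rank_candidates(
    cands: Sequence[CandidateEvidence],
    config: ScoringConfig | None = None,
    score_fn: Callable[[CandidateEvidence], float] | None = None,
) -> tuple[list[CandidateEvidence], bool]:
    """Order candidates (descending RSI by default, or by ``score_fn``) and
    decide whether the top hit is uniquely preferred.

    The top candidate is preferred iff any dominance margin over the
    runner-up holds: evidence count >= 10x, |dRI| smaller by >= 30, RSI
    larger by >= 50, or RHRMF larger by >= 10. Otherwise the feature is a
    multi-hit.
    """
    if not cands:
        raise ContractError("rank_candidates requires at least one candidate")
    config = config or ScoringConfig()
    key = score_fn or (lambda e: e.rsi)
    ordered = sorted(
        cands,
        key=lambda e: (-key(e), -e.si, e.candidate.name, e.candidate.identifier),
    )
    if len(ordered) == 1:
        return ordered, True
    return ordered, _dominates(ordered[0], ordered[1], config.tie_break)


def weighted_total_score(
    weights: dict[str, float] | None = None,
) -> Callable[[CandidateEvidence], float]:
    """A pluggable weighted-sum ranking metric over the evidence layers."""
    w = {"rsi": 1.0, "si": 0.0, "rhrmf": 0.0, "abs_delta_ri": 0.0}
    w.update(weights or {})

    def score(ev: CandidateEvidence) -> float:
        total = w["rsi"] * ev.rsi + w["si"] * ev.si
        if ev.rhrmf is not None:
            total += w["rhrmf"] * ev.rhrmf
        if ev.delta_ri is not None:
            total -= w["abs_delta_ri"] * abs(ev.delta_ri)
        return total

    return score


_LEVEL_ORDER = {"1": 0, "2": 1, "3": 2, "4A": 3, "4B": 4, "4C": 5, "5": 6, None: 7}


def _normalize_name(name: str) -> str:
    return " ".join(name.lower().split())


def dedupe(assignments: Sequence[LevelAssignment]) -> list[LevelAssignment]:
    """Retain one assignment per unique compound.

    Assignments sharing an identifier (or, lacking identifiers, a
    case/whitespace-normalized name) are collapsed to the best one (best
    level, then highest top RSI). Name collisions across *distinct*
    identifiers are kept but logged for review. Features without any
    candidate are never deduplicated. Removals are logged.
    """
    best: dict[str, LevelAssignment] = {}
    passthrough: list[LevelAssignment] = []

    def sort_key(a: LevelAssignment):
        return (_LEVEL_ORDER.get(a.level, 7), -a.best_rsi, a.feature_id)

    for a in assignments:
        if a.best_candidate is None:
            passthrough.append(a)
            continue
        key = a.best_identifier or f"name::{_normalize_name(a.best_candidate.name)}"
        if key not in best or sort_key(a) < sort_key(best[key]):
            if key in best:
                logger.info(
                    "dedupe: dropping %s (duplicate of %s, key %s)",
                    best[key].feature_id,
                    a.feature_id,
                    key,
                )
            best[key] = a
        else:
            logger.info(
                "dedupe: dropping %s (duplicate of %s, key %s)",
                a.feature_id,
                best[key].feature_id,
                key,
            )

    # review pass: identical normalized names under distinct identifiers
    by_name: dict[str, list[str]] = {}
    for a in best.values():
        by_name.setdefault(_normalize_name(a.best_candidate.name), []).append(
            a.best_identifier
        )
    for name, ids in by_name.items():
        if len(set(ids)) > 1:
            logger.warning(
                "dedupe: name %r shared by distinct identifiers %s; "
                "flagged for review",
                name,
                sorted(set(ids)),
            )
    kept_ids = {id(a) for a in best.values()}
    ordered = [a for a in assignments if id(a) in kept_ids or a.best_candidate is None]
    return ordered


def build_candidate_evidence(
    feature: FeatureRecord,
    entry: LibraryEntry,
    observed_ri: float | None,
    weighting: MatchWeighting,
    hrmf_tol_ppm: float = 10.0,
    h_transfer: int = 1,
    mol_ion_tol_ppm: float = 10.0,
) -> CandidateEvidence:
    """Compute every evidence layer for one feature-candidate pair."""
    spec, lib = feature.spectrum, entry.spectrum
    si = dot_product_score(spec, lib, weighting)
    rsi = reverse_dot_product_score(spec, lib, weighting)
    delta_ri = None
    if observed_ri is not None and entry.retention_index is not None:
        delta_ri = observed_ri - entry.retention_index
    r = None
    if (
        entry.formula is not None
        and spec.resolution_class == "accurate"
        and weighting.mode == "accurate"
    ):
        r = rhrmf(spec, lib, entry.formula, weighting, hrmf_tol_ppm, h_transfer)
    exact_rsi = None
    if (
        lib.resolution_class == "accurate"
        and spec.resolution_class == "accurate"
        and weighting.mode == "accurate"
    ):
        exact_rsi = rsi
    mol = False
    if entry.formula is not None and spec.resolution_class == "accurate":
        mol = detect_molecular_ion(spec, entry.formula, mol_ion_tol_ppm).present
    n_matched = count_matched_fragments(spec, lib, weighting)
    return CandidateEvidence(
        feature_id=feature.feature_id,
        candidate=entry,
        si=si,
        rsi=rsi,
        delta_ri=delta_ri,
        ri_source=entry.ri_source if delta_ri is not None else "absent",
        library_ri=entry.retention_index,
        rhrmf=r,
        exact_mass_library_rsi=exact_rsi,
        molecular_ion=mol,
        matched_fragments=n_matched,
        ionization=entry.ionization,
        accurate_ion_matches=n_matched if weighting.mode == "accurate" else 0,
        evidence_count=entry.evidence_count,
    )


def annotate_feature(
    feature: FeatureRecord,
    library: Sequence[LibraryEntry],
    cal: AlkaneCalibration | None = None,
    scoring: ScoringConfig | None = None,
    weighting: MatchWeighting | None = None,
    bff: BFFConfig | None = None,
    blank_result: BlankFilterResult | None = None,
    hrmf_tol_ppm: float = 10.0,
    h_transfer: int = 1,
    score_fn: Callable[[CandidateEvidence], float] | None = None,
) -> LevelAssignment:
    """Annotate one feature against a spectral library.

    Blank filtering is applied first (a failing feature gets no level and
    ``blank_pass=False``). Every library entry is scored, levels are
    assigned per candidate, candidates at the best achieved level are
    ranked, and multi-hits flagged. A feature matching nothing becomes
    Level 5.
    """
    scoring = scoring or ScoringConfig()
    weighting = weighting or MatchWeighting.accurate()
    samples = list(feature.sample_abundances.values())
    blanks = list(feature.blank_abundances.values())
    means = dict(
        sample_abundance_mean=float(np.mean(samples)) if samples else 0.0,
        blank_abundance_mean=float(np.mean(blanks)) if blanks else 0.0,
    )
    blank_result = blank_result or passes_blank_filter(feature, bff)
    if not blank_result.passed:
        return LevelAssignment(
            feature_id=feature.feature_id,
            level=None,
            blank_pass=False,
            rationale=["failed blank feature filter"],
            blank_threshold=blank_result.threshold,
            sample_statistic_value=blank_result.sample_statistic_value,
            **means,
        )
    if not library:
        warnings.warn("empty library: feature can only be Level 5", stacklevel=2)

    observed_ri: float | None = None
    if cal is not None:
        try:
            observed_ri = compute_retention_index(feature.retention_time, cal).value
        except Exception:
            observed_ri = None

    by_level: dict[str, list[CandidateEvidence]] = {"2": [], "3": []}
    rationales: dict[str, list[str]] = {}
    all_evidence: list[CandidateEvidence] = []
    for entry in library:
        if entry.spectrum is None:
            continue
        ev = build_candidate_evidence(
            feature, entry, observed_ri, weighting, hrmf_tol_ppm, h_transfer
        )
        all_evidence.append(ev)
        level, notes = assign_level(ev, scoring)
        if level is not None:
            by_level[level].append(ev)
            rationales[f"{level}:{entry.name}"] = notes

    for level in ("2", "3"):
        if by_level[level]:
            ordered, preferred = rank_candidates(by_level[level], scoring, score_fn)
            top = ordered[0]
            return LevelAssignment(
                feature_id=feature.feature_id,
                level=level,
                blank_pass=True,
                multi_hit=not preferred,
                rank=1,
                best_candidate=top.candidate,
                rationale=rationales[f"{level}:{top.candidate.name}"],
                candidates=ordered,
                blank_threshold=blank_result.threshold,
                sample_statistic_value=blank_result.sample_statistic_value,
                **means,
            )

    # Level 5: reproducibly detected unknown; keep the best spectral hit (if
    # any) for reference without asserting identity.
    top5 = (
        sorted(all_evidence, key=lambda e: (-e.rsi, e.candidate.name))[:1]
        if all_evidence
        else []
    )
    return LevelAssignment(
        feature_id=feature.feature_id,
        level="5",
        blank_pass=True,
        best_candidate=None,
        rationale=["no level 1-4 criterion met"],
        candidates=top5,
        blank_threshold=blank_result.threshold,
        sample_statistic_value=blank_result.sample_statistic_value,
        **means,
    )


def annotate_run(
    features: Sequence[FeatureRecord],
    library: Sequence[LibraryEntry],
    cal: AlkaneCalibration | None = None,
    scoring: ScoringConfig | None = None,
    weighting: MatchWeighting | None = None,
    bff: BFFConfig | None = None,
    deduplicate: bool = False,
    **kwargs,
) -> list[LevelAssignment]:
    """Blank-filter and annotate every feature; optionally deduplicate."""
    out = [
        annotate_feature(
            f, library, cal, scoring=scoring, weighting=weighting, bff=bff, **kwargs
        )
        for f in features
    ]
    if deduplicate:
        out = dedupe(out)
    return out
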