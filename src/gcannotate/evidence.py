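"""Per-candidate evidence layers for GC-HRMS annotation.

Implements the individual lines of evidence that the confidence levels are
built from:

* forward and reverse dot-product spectral similarity (SI / RSI) on the
  conventional 0-1000 scale, with ``mz^a * intensity^b`` peak weighting;
* Kovats-style retention indices by van den Dool & Kratz interpolation over
  an n-alkane calibration, and the RI match rule (experimental libraries:
  |dRI| < 50 and < 1.5 %; predicted libraries: |dRI| < 100);
* (reverse) high-resolution mass filtering — the percentage of (library-
  matched) fragment ions whose accurate masses are explicable as subformula
  cations of the candidate's molecular formula;
* molecular-ion detection and matched-fragment counting.

Similarity scores default to plain cosine with weights a=0, b=0.5
(square-root intensity), scaled to 0-1000; unit-resolution matching bins m/z
to the nearest integer, accurate-mass matching pairs peaks within a ppm
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .chem_core import ELECTRON_MASS, Formula, enumerate_subformulas, MONOISOTOPIC
from .errors import (
    MissingRIError,
    OutOfRangeError,
    ResolutionError,
    UndefinedScoreError,
)
from .spectra_io import AlkaneCalibration, Spectrum

__all__ = [
    "MatchWeighting",
    "RIMatchRule",
    "RIValue",
    "RIMatchResult",
    "MolecularIonResult",
    "match_peaks",
    "dot_product_score",
    "reverse_dot_product_score",
    "compute_retention_index",
    "ri_match",
    "hrmf",
    "rhrmf",
    "detect_molecular_ion",
    "count_matched_fragments",
]


@dataclass(frozen=True)
class MatchWeighting:
    """Peak weighting and matching mode for spectral comparison.

    Weighted intensity is ``mz ** mz_power * intensity ** intensity_power``.
    Exactly one of ``bin_width`` (unit-resolution: peaks match when their m/z
    round into the same integer bin) or ``tol_ppm`` (accurate mode: nearest
    peak within the ppm window) must be set.
    """

    mz_power: float = 0.0
    intensity_power: float = 0.5
    bin_width: float | None = 1.0
    tol_ppm: float | None = None

    def __post_init__(self) -> None:
        if self.mz_power < 0 or self.intensity_power < 0:
            raise ValueError("weight exponents must be >= 0")
        if (self.bin_width is None) == (self.tol_ppm is None):
            raise ValueError("set exactly one of bin_width or tol_ppm")
        if self.bin_width is not None and self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.tol_ppm is not None and self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")

    @property
    def mode(self) -> str:
        return "unit" if self.bin_width is not None else "accurate"

    @classmethod
    def unit(cls, mz_power: float = 0.0, intensity_power: float = 0.5,
             bin_width: float = 1.0) -> "MatchWeighting":
        return cls(mz_power, intensity_power, bin_width, None)

    @classmethod
    def accurate(cls, tol_ppm: float = 10.0, mz_power: float = 0.0,
                 intensity_power: float = 0.5) -> "MatchWeighting":
        return cls(mz_power, intensity_power, None, tol_ppm)


def match_peaks(
    query: Spectrum, library: Spectrum, weighting: MatchWeighting
) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest-m/z peak pairing.

    Candidate pairs within the bin/tolerance are accepted in order of
    increasing |dm/z|, ties broken toward the higher summed intensity, then
    the lower m/z — fully deterministic. Returns (query index, library index)
    pairs sorted by query index.
    """
    q_mz, l_mz = query.mz, library.mz
    if weighting.mode == "unit":
        w = weighting.bin_width
        allowed = lambda qm, lm: round(qm / w) == round(lm / w)  # noqa: E731
        window = w
    else:
        tol = weighting.tol_ppm * 1e-6
        allowed = lambda qm, lm: abs(qm - lm) <= lm * tol  # noqa: E731
        window = float(l_mz[-1]) * tol + 1e-12

    cands: list[tuple[float, float, float, float, int, int]] = []
    j_lo = 0
    for i, qm in enumerate(q_mz):
        while j_lo < l_mz.size and l_mz[j_lo] < qm - window:
            j_lo += 1
        j = j_lo
        while j < l_mz.size and l_mz[j] <= qm + window:
            if allowed(qm, l_mz[j]):
                cands.append(
                    (
                        abs(qm - l_mz[j]),
                        -(query.intensity[i] + library.intensity[j]),
                        qm,
                        l_mz[j],
                        i,
                        j,
                    )
                )
            j += 1
    cands.sort()
    used_q: set[int] = set()
    used_l: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, _, _, i, j in cands:
        if i in used_q or j in used_l:
            continue
        used_q.add(i)
        used_l.add(j)
        pairs.append((i, j))
    pairs.sort()
    return pairs


def _weights(spectrum: Spectrum, weighting: MatchWeighting) -> np.ndarray:
    return (spectrum.mz ** weighting.mz_power) * (
        spectrum.intensity ** weighting.intensity_power
    )


def dot_product_score(
    query: Spectrum, library: Spectrum, weighting: MatchWeighting | None = None
) -> int:
    """Forward spectral similarity: 1000 x cosine of the weighted intensity
    vectors over the union of matched positions, rounded to an integer.

    Unmatched peaks on either side contribute to the norms but not to the
    inner product, so extra peaks lower the score. Symmetric in its
    arguments. Raises :class:`UndefinedScoreError` when either weighted
    vector is all-zero.
    """
    weighting = weighting or MatchWeighting()
    pairs = match_peaks(query, library, weighting)
    wq, wl = _weights(query, weighting), _weights(library, weighting)
    nq, nl = float(np.linalg.norm(wq)), float(np.linalg.norm(wl))
    if nq == 0.0 or nl == 0.0:
        raise UndefinedScoreError("all-zero weighted intensity vector")
    num = sum(wq[i] * wl[j] for i, j in pairs)
    return round(1000.0 * num / (nq * nl))


def reverse_dot_product_score(
    query: Spectrum, library: Spectrum, weighting: MatchWeighting | None = None
) -> int:
    """Reverse similarity: the same cosine computed after discarding query
    peaks unmatched to any library peak.

    Deconvolution artifacts in the experimental spectrum therefore do not
    penalize the score; residual mismatch from unmatched *library* peaks
    still does. Always >= the forward score.
    """
    weighting = weighting or MatchWeighting()
    pairs = match_peaks(query, library, weighting)
    wq, wl = _weights(query, weighting), _weights(library, weighting)
    nl = float(np.linalg.norm(wl))
    if float(np.linalg.norm(wq)) == 0.0 or nl == 0.0:
        raise UndefinedScoreError("all-zero weighted intensity vector")
    if not pairs:
        return 0
    qi = [i for i, _ in pairs]
    nq = float(np.linalg.norm(wq[qi]))
    if nq == 0.0:
        return 0
    num = sum(wq[i] * wl[j] for i, j in pairs)
    return round(1000.0 * num / (nq * nl))


@dataclass(frozen=True)
class RIValue:
    value: float
    extrapolated: bool = False


def compute_retention_index(
    rt: float, cal: AlkaneCalibration, allow_extrapolation: bool = False
) -> RIValue:
    """Van den Dool & Kratz linear-temperature-programmed retention index.

    ``RI = 100 n + 100 (rt - t_n) / (t_{n+1} - t_n)`` for the bracketing
    alkane anchors. Outside the calibration span an
    :class:`OutOfRangeError` is raised unless ``allow_extrapolation`` is
    set, in which case the end segment is extended and the result flagged.
    """
    pts = cal.points
    lo, hi = cal.rt_span
    extrapolated = rt < lo or rt > hi
    if extrapolated and not allow_extrapolation:
        raise OutOfRangeError(
            f"rt {rt} outside calibration span [{lo}, {hi}]"
        )
    if rt <= lo:
        seg = 0
    elif rt >= hi:
        seg = len(pts) - 2
    else:
        seg = max(
            k for k in range(len(pts) - 1) if pts[k][1] <= rt
        )
    (c0, t0), (c1, t1) = pts[seg], pts[seg + 1]
    ri = 100.0 * c0 + 100.0 * (c1 - c0) * (rt - t0) / (t1 - t0)
    return RIValue(ri, extrapolated)


@dataclass(frozen=True)
class RIMatchRule:
    """Thresholds for retention-index agreement, by library RI provenance."""

    max_abs_delta_experimental: float = 50.0
    max_rel_delta_experimental: float = 0.015
    max_abs_delta_predicted: float = 100.0

    def __post_init__(self) -> None:
        if min(
            self.max_abs_delta_experimental,
            self.max_rel_delta_experimental,
            self.max_abs_delta_predicted,
        ) <= 0:
            raise ValueError("RI thresholds must be positive")


@dataclass(frozen=True)
class RIMatchResult:
    passed: bool
    delta: float


def ri_match(
    observed_ri: float,
    library_ri: float,
    source: str,
    rule: RIMatchRule | None = None,
) -> RIMatchResult:
    """Apply the RI match rule. Experimental library RIs must agree both
    absolutely (< 50 units) and relatively (< 1.5 %); predicted RIs within
    < 100 units. All comparisons strict.
    """
    rule = rule or RIMatchRule()
    if source == "absent":
        raise MissingRIError("library entry has no retention index")
    if source not in ("experimental", "predicted"):
        raise ValueError(f"unknown RI source {source!r}")
    delta = observed_ri - library_ri
    if source == "experimental":
        passed = (
            abs(delta) < rule.max_abs_delta_experimental
            and abs(delta) / library_ri < rule.max_rel_delta_experimental
        )
    else:
        passed = abs(delta) < rule.max_abs_delta_predicted
    return RIMatchResult(passed, delta)


@lru_cache(maxsize=512)
def _all_cation_masses(candidate: Formula, h_transfer: int) -> np.ndarray:
    """Sorted cation masses (subformula mass - electron mass) achievable from
    ``candidate``, with the fragment's hydrogen count adjustable by up to
    ``h_transfer`` while remaining within the parent's bounds.

    With exhaustive subformula enumeration the hydrogen adjustment is
    subsumed (any H-shifted vector still within the parent is itself a
    subformula); the expansion is kept so the contract holds if the
    enumeration is ever restricted. Cached per formula: the pipeline calls
    this once per feature-candidate pair.
    """
    parent_h = candidate["H"]
    h_mass = MONOISOTOPIC["H"]
    masses: set[float] = set()
    for sub in enumerate_subformulas(candidate):
        h = sub["H"]
        for dh in range(-h_transfer, h_transfer + 1):
            h_new = h + dh
            if h_new < 0 or h_new > parent_h:
                continue
            masses.add(sub.mass + dh * h_mass - ELECTRON_MASS)
    return np.array(sorted(masses))


def _explainable_cation_masses(
    candidate: Formula, max_mass: float, h_transfer: int
) -> np.ndarray:
    masses = _all_cation_masses(candidate, h_transfer)
    return masses[masses <= max_mass + 1.0]


def _fraction_explained(
    mz: np.ndarray, masses: np.ndarray, tol_ppm: float
) -> np.ndarray:
    """Boolean mask: each m/z explicable by some mass within tol_ppm."""
    if masses.size == 0:
        return np.zeros(mz.shape, dtype=bool)
    idx = np.searchsorted(masses, mz)
    out = np.zeros(mz.shape, dtype=bool)
    for k, (m, i) in enumerate(zip(mz, idx)):
        tol = m * tol_ppm * 1e-6
        for j in (i - 1, i):
            if 0 <= j < masses.size and abs(masses[j] - m) <= tol:
                out[k] = True
                break
    return out


def hrmf(
    spectrum: Spectrum,
    candidate: Formula,
    tol_ppm: float = 10.0,
    h_transfer: int = 1,
) -> float:
    """High-resolution mass filter score: the percentage of spectrum peaks
    whose accurate m/z matches a subformula cation mass of ``candidate``
    (hydrogen count adjustable by +/- ``h_transfer``) within ``tol_ppm``.
    """
    if spectrum.resolution_class != "accurate":
        raise ResolutionError("HRMF requires an accurate-mass spectrum")
    masses = _explainable_cation_masses(
        candidate, float(spectrum.mz[-1]) * (1 + tol_ppm * 1e-6), h_transfer
    )
    explained = _fraction_explained(spectrum.mz, masses, tol_ppm)
    return 100.0 * float(explained.sum()) / spectrum.n_peaks


def rhrmf(
    query: Spectrum,
    library: Spectrum,
    candidate: Formula,
    weighting: MatchWeighting | None = None,
    tol_ppm: float = 10.0,
    h_transfer: int = 1,
) -> float | None:
    """Reverse HRMF: the HRMF computed only over the query peaks matched to
    library peaks, so deconvolution artifacts absent from the library do not
    dilute the score.

    Returns ``None`` when no query peak matches the library (the criterion
    is unavailable rather than failed).
    """
    if query.resolution_class != "accurate":
        raise ResolutionError("RHRMF requires an accurate-mass query spectrum")
    weighting = weighting or MatchWeighting.accurate(tol_ppm)
    pairs = match_peaks(query, library, weighting)
    if not pairs:
        return None
    qi = sorted(i for i, _ in pairs)
    mz = query.mz[qi]
    masses = _explainable_cation_masses(
        candidate, float(mz[-1]) * (1 + tol_ppm * 1e-6), h_transfer
    )
    explained = _fraction_explained(mz, masses, tol_ppm)
    return 100.0 * float(explained.sum()) / len(qi)


@dataclass(frozen=True)
class MolecularIonResult:
    present: bool
    mass_error_ppm: float | None


def detect_molecular_ion(
    spectrum: Spectrum, candidate: Formula, tol_ppm: float = 10.0
) -> MolecularIonResult:
    """Look for the radical-cation molecular ion M+. — a peak within
    ``tol_ppm`` of the candidate's monoisotopic mass minus one electron."""
    target = candidate.mass - ELECTRON_MASS
    tol = target * tol_ppm * 1e-6
    diffs = np.abs(spectrum.mz - target)
    k = int(np.argmin(diffs))
    if diffs[k] <= tol:
        return MolecularIonResult(True, 1e6 * (spectrum.mz[k] - target) / target)
    return MolecularIonResult(False, None)


def count_matched_fragments(
    query: Spectrum, library: Spectrum, weighting: MatchWeighting | None = None
) -> int:
    """Number of query-library peak pairs under the greedy matching."""
    weighting = weighting or MatchWeighting()
    return len(match_peaks(query, library, weighting))
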