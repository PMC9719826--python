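"""Molecular-formula algebra for fragment-ion interpretation.

This module provides the low-level chemistry used throughout the package:
Hill-notation formula parsing, monoisotopic masses, exhaustive subformula
enumeration (the basis of high-resolution mass filtering), molecular-formula
decomposition from an accurate mass, isotope-pattern simulation by
convolution, and Kendrick mass-defect rescaling for homologous-series
detection.

Element masses and isotope abundances are embedded as static data (IUPAC/NIST
monoisotopic masses and representative terrestrial abundances) so that results
are bit-reproducible offline. The default element alphabet —
C, H, N, O, S, P, F, Cl, Br, I, Si — covers the analyte classes typical of
environmental GC-HRMS work (PAHs, PCBs, organophosphate esters, halogenated
flame retardants, siloxane background).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

from .errors import FormulaError

__all__ = [
    "ELECTRON_MASS",
    "DEFAULT_ALPHABET",
    "Formula",
    "IsotopePattern",
    "KendrickPoint",
    "parse_formula",
    "monoisotopic_mass",
    "enumerate_subformulas",
    "decompose_mass",
    "isotope_pattern",
    "kendrick_mass_defect",
]

#: Mass of the electron in Da; EI fragment ions are cations, so one electron
#: mass is subtracted from the neutral (sub)formula mass when matching peaks.
ELECTRON_MASS = 0.000548579909

#: Per-element isotope tables: symbol -> tuple of (exact mass, abundance),
#: sorted by mass, abundances summing to 1. The first entry is the lightest
#: isotope, whose mass defines the element's monoisotopic mass.
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.00782503207, 0.999885), (2.01410177785, 0.000115)),
    "C": ((12.0, 0.9893), (13.00335483507, 0.0107)),
    "N": ((14.0030740048, 0.99636), (15.0001088989, 0.00364)),
    "O": (
        (15.99491461956, 0.99757),
        (16.9991317012, 0.00038),
        (17.9991610040, 0.00205),
    ),
    "S": (
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ),
    "P": ((30.97376163, 1.0),),
    "F": ((18.99840322, 1.0),),
    "Cl": ((34.96885268, 0.7576), (36.96590259, 0.2424)),
    "Br": ((78.9183371, 0.5069), (80.9162906, 0.4931)),
    "I": ((126.904473, 1.0),),
    "Si": (
        (27.97692653, 0.92223),
        (28.97649470, 0.04685),
        (29.97377017, 0.03092),
    ),
}

DEFAULT_ALPHABET: tuple[str, ...] = (
    "C", "H", "N", "O", "S", "P", "F", "Cl", "Br", "I", "Si",
)

MONOISOTOPIC: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}


def _hill_sorted(elements: Iterable[str]) -> list[str]:
    """Hill convention: C first, then H, then all others alphabetically.

    Without carbon, all elements (including H) sort alphabetically.
    """
    els = set(elements)
    if "C" in els:
        rest = sorted(els - {"C", "H"})
        return ["C"] + (["H"] if "H" in els else []) + rest
    return sorted(els)


@dataclass(frozen=True)
class Formula:
    """An element->count map over a restricted element alphabet.

    Immutable and hashable; items are stored Hill-sorted so two formulas with
    the same composition compare and hash equal.
    """

    items: tuple[tuple[str, int], ...]

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "Formula":
        clean = {}
        for el, n in counts.items():
            if el not in ISOTOPES:
                raise FormulaError(f"unknown element symbol {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}")
            if n > 0:
                clean[el] = int(n)
        if not clean:
            raise FormulaError("empty formula")
        return cls(tuple((el, clean[el]) for el in _hill_sorted(clean)))

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.items)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __contains__(self, element: str) -> bool:
        return self[element] > 0

    @property
    def n_atoms(self) -> int:
        return sum(n for _, n in self.items)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill(self) -> str:
        """Serialize in Hill order, omitting unit multipliers."""
        return "".join(
            f"{el}{n}" if n > 1 else el for el, n in self.items
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    def __add__(self, other: "Formula") -> "Formula":
        merged = self.counts
        for el, n in other.items:
            merged[el] = merged.get(el, 0) + n
        return Formula.from_counts(merged)

    def contains(self, other: "Formula") -> bool:
        """True when ``other`` fits component-wise inside this formula."""
        mine = self.counts
        return all(mine.get(el, 0) >= n for el, n in other.items)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str, alphabet: Iterable[str] = DEFAULT_ALPHABET) -> Formula:
    """Parse a Hill-notation string like ``"C6H5Cl"`` into a :class:`Formula`.

    Multipliers default to 1. Raises :class:`FormulaError` for an empty
    string, an unknown element symbol, or leftover unparseable text.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    allowed = set(alphabet)
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula at {text[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        if el not in allowed or el not in ISOTOPES:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return Formula.from_counts(counts)


def monoisotopic_mass(f: Formula) -> float:
    """Sum of count x lightest-isotope exact mass over the formula."""
    if not f.items:
        raise FormulaError("empty formula")
    return sum(MONOISOTOPIC[el] * n for el, n in f.items)


def enumerate_subformulas(
    parent: Formula,
    min_mass: float = 0.0,
    max_mass: float = math.inf,
) -> Iterator[Formula]:
    """Yield every non-empty component-wise subformula of ``parent`` whose
    monoisotopic mass lies in ``[min_mass, max_mass]``.

    Order is deterministic: lexicographic over the parent's Hill-sorted
    element counts. A depth-first search prunes branches once the partial
    mass exceeds ``max_mass`` (element masses are positive, so no deeper
    vector can recover).
    """
    if min_mass < 0 or min_mass > max_mass:
        raise ValueError("require 0 <= min_mass <= max_mass")
    elements = [el for el, _ in parent.items]
    maxima = [n for _, n in parent.items]
    masses = [MONOISOTOPIC[el] for el in elements]
    # max mass attainable from elements i.. onward, for min_mass pruning
    suffix_max = [0.0] * (len(elements) + 1)
    for i in range(len(elements) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + masses[i] * maxima[i]

    counts = [0] * len(elements)

    def rec(i: int, acc_mass: float) -> Iterator[Formula]:
        if acc_mass > max_mass:
            return
        if i == len(elements):
            if acc_mass >= min_mass and any(counts):
                yield Formula.from_counts(
                    {el: c for el, c in zip(elements, counts) if c > 0}
                )
            return
        if acc_mass + suffix_max[i] < min_mass:
            return
        for c in range(maxima[i] + 1):
            m = acc_mass + c * masses[i]
            if m > max_mass:
                break
            counts[i] = c
            yield from rec(i + 1, m)
        counts[i] = 0

    yield from rec(0, 0.0)


def decompose_mass(
    target: float, tol_ppm: float, bounds: Formula
) -> list[Formula]:
    """All formulas within ``bounds`` whose monoisotopic mass lies within
    ``tol_ppm`` of ``target``, sorted by absolute mass error (ties broken by
    Hill string for determinism). An empty list is a valid result.
    """
    if target <= 0:
        raise ValueError("target mass must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    window = target * tol_ppm * 1e-6
    hits = list(enumerate_subformulas(bounds, target - window, target + window))
    hits.sort(key=lambda f: (abs(f.mass - target), f.hill()))
    return hits


@dataclass(frozen=True)
class IsotopePattern:
    """Simulated isotopologue envelope: (mass, relative abundance) pairs,
    masses strictly increasing."""

    peaks: tuple[tuple[float, float], ...]

    @property
    def masses(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.peaks)

    @property
    def abundances(self) -> tuple[float, ...]:
        return tuple(a for _, a in self.peaks)


def _convolve(
    a: list[tuple[float, float]],
    b: tuple[tuple[float, float], ...],
    prune: float,
) -> list[tuple[float, float]]:
    out: dict[float, float] = {}
    for ma, pa in a:
        for mb, pb in b:
            p = pa * pb
            if p < prune:
                continue
            m = ma + mb
            out[m] = out.get(m, 0.0) + p
    return sorted(out.items())


def _merge_window(
    peaks: list[tuple[float, float]], window: float
) -> list[tuple[float, float]]:
    """Aggregate peaks closer than ``window`` Da into abundance-weighted
    centroids."""
    merged: list[list[float]] = []
    for m, p in peaks:  # peaks sorted by mass
        if merged and m - merged[-1][0] <= window:
            m0, p0 = merged[-1]
            tot = p0 + p
            merged[-1] = [(m0 * p0 + m * p) / tot, tot]
        else:
            merged.append([m, p])
    return [(m, p) for m, p in merged]


def isotope_pattern(
    f: Formula,
    abundance_cutoff: float = 0.0,
    merge_window: float = 1e-4,
    normalize: str | None = None,
    _conv_prune: float = 1e-12,
) -> IsotopePattern:
    """Isotopologue pattern of ``f`` by iterative convolution of per-element
    isotope distributions.

    Peaks are aggregated within ``merge_window`` Da, then peaks below
    ``abundance_cutoff`` x base peak are pruned. ``normalize`` may be
    ``"base"`` (base peak scaled to 1) or ``None`` (probabilities; they sum
    to 1 before pruning).
    """
    if not f.items:
        raise FormulaError("empty formula")
    if not (0 <= abundance_cutoff < 1):
        raise ValueError("abundance_cutoff must lie in [0, 1)")
    dist: list[tuple[float, float]] = [(0.0, 1.0)]
    for el, n in f.items:
        for _ in range(n):
            dist = _convolve(dist, ISOTOPES[el], _conv_prune)
    dist = _merge_window(dist, merge_window)
    base = max(p for _, p in dist)
    dist = [(m, p) for m, p in dist if p >= abundance_cutoff * base]
    if normalize == "base":
        dist = [(m, p / base) for m, p in dist]
    elif normalize is not None:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    return IsotopePattern(tuple(dist))


@dataclass(frozen=True)
class KendrickPoint:
    """A mass rescaled to the Kendrick scale of a repeat unit.

    Members of a homologous series (masses spaced by exact multiples of the
    repeat unit) share a common Kendrick mass defect.
    """

    observed_mass: float
    kendrick_mass: float
    kendrick_mass_defect: float
    repeat_unit: Formula


def kendrick_mass_defect(
    mass: float, repeat: Formula, convention: str = "round"
) -> KendrickPoint:
    """Kendrick rescaling: ``KM = mass x nominal(repeat) / exact(repeat)``;
    ``KMD = nominal(KM) - KM`` where nominal is round-to-nearest by default
    (``convention="floor"`` selects the floor variant also used in the
    literature).
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    exact = monoisotopic_mass(repeat)
    nominal = round(exact)
    km = mass * nominal / exact
    if convention == "round":
        kmd = round(km) - km
    elif convention == "floor":
        kmd = math.floor(km) - km
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return KendrickPoint(mass, km, kmd, repeat)
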