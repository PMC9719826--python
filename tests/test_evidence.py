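"""Spectral similarity, retention index, HRMF/RHRMF and molecular-ion
evidence, including the score axioms and a brute-force subformula oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

from gcannotate.chem_core import ELECTRON_MASS, Formula, parse_formula
from gcannotate.errors import (
    MissingRIError,
    OutOfRangeError,
    ResolutionError,
    UndefinedScoreError,
)
from gcannotate.evidence import (
    MatchWeighting,
    compute_retention_index,
    count_matched_fragments,
    detect_molecular_ion,
    dot_product_score,
    hrmf,
    match_peaks,
    reverse_dot_product_score,
    rhrmf,
    ri_match,
)
from gcannotate.spectra_io import AlkaneCalibration, Spectrum

UNIT = MatchWeighting.unit()
ACC = MatchWeighting.accurate(10.0)


def spec(*pairs, resolution="accurate"):
    return Spectrum.from_pairs(pairs, resolution)


# -- peak matching ----------------------------------------------------------


def test_match_identical_spectra_pairs_everything():
    s = spec((50.0, 10.0), (60.0, 5.0), (70.0, 1.0))
    assert match_peaks(s, s, UNIT) == [(0, 0), (1, 1), (2, 2)]


def test_match_disjoint_is_empty():
    a, b = spec((50.0, 10.0)), spec((60.0, 10.0))
    assert match_peaks(a, b, UNIT) == []


def test_match_tie_breaks_toward_higher_intensity():
    # two query peaks equidistant from one library peak: higher intensity wins
    q = spec((99.998, 5.0), (100.002, 50.0))
    l = spec((100.0, 10.0))
    assert match_peaks(q, l, UNIT) == [(1, 0)]


# -- dot product ------------------------------------------------------------


def test_dot_product_hand_example():
    q = spec((100.0, 100.0), (200.0, 50.0))
    l = spec((100.0, 100.0), (200.0, 100.0))
    assert dot_product_score(q, l, UNIT) == 986


def test_dot_product_identity_and_disjoint():
    s = spec((50.0, 10.0), (60.0, 5.0))
    assert dot_product_score(s, s, UNIT) == 1000
    assert dot_product_score(s, spec((80.0, 2.0)), UNIT) == 0


def test_dot_product_symmetric():
    q = spec((50.0, 10.0), (60.0, 5.0), (75.0, 1.0))
    l = spec((50.0, 3.0), (75.0, 9.0))
    assert dot_product_score(q, l, UNIT) == dot_product_score(l, q, UNIT)


def test_zero_intensity_raises():
    z = spec((50.0, 0.0))
    with pytest.raises(UndefinedScoreError):
        dot_product_score(z, z, UNIT)


random_spectra = st.lists(
    st.tuples(
        st.integers(min_value=50, max_value=300),
        st.floats(min_value=1.0, max_value=1000.0),
    ),
    min_size=1,
    max_size=12,
    unique_by=lambda p: p[0],
).map(lambda pairs: Spectrum.from_pairs([(float(m), i) for m, i in pairs]))


@given(q=random_spectra, l=random_spectra, scale=st.floats(1e-3, 1e3))
@settings(max_examples=60, deadline=None)
def test_score_axioms(q, l, scale):
    """Scale invariance and reverse >= forward on arbitrary spectra."""
    fwd = dot_product_score(q, l, UNIT)
    rev = reverse_dot_product_score(q, l, UNIT)
    assert 0 <= fwd <= 1000 and 0 <= rev <= 1000
    assert rev >= fwd
    q_scaled = Spectrum(q.mz, q.intensity * scale)
    assert dot_product_score(q_scaled, l, UNIT) == fwd
    assert reverse_dot_product_score(q_scaled, l, UNIT) == rev


@given(q=random_spectra, l=random_spectra)
@settings(max_examples=40, deadline=None)
def test_cosine_agrees_with_matchms(q, l):
    """Independent cross-check against the reference greedy-cosine scorer."""
    matchms_similarity = pytest.importorskip("matchms.similarity")
    import matchms

    cosine = matchms_similarity.CosineGreedy(
        tolerance=0.4, mz_power=0.0, intensity_power=0.5
    )
    ref = cosine.pair(
        matchms.Spectrum(mz=q.mz, intensities=q.intensity, metadata={}),
        matchms.Spectrum(mz=l.mz, intensities=l.intensity, metadata={}),
    )
    ours = dot_product_score(q, l, UNIT)
    assert abs(ours - 1000.0 * float(ref["score"])) <= 1


def test_reverse_ignores_extra_query_peaks():
    lib = spec((50.0, 10.0), (60.0, 5.0))
    query = spec((50.0, 10.0), (60.0, 5.0), (200.0, 99.0))
    assert reverse_dot_product_score(query, lib, UNIT) == 1000
    assert dot_product_score(query, lib, UNIT) < 1000


def test_reverse_penalizes_unmatched_library_peaks():
    lib = spec((50.0, 10.0), (60.0, 5.0), (70.0, 5.0))
    query = spec((50.0, 10.0), (60.0, 5.0))
    assert reverse_dot_product_score(query, lib, UNIT) < 1000


# -- retention index --------------------------------------------------------


def test_ri_anchor_identity(calibration):
    for carbon, rt in calibration.points:
        assert compute_retention_index(rt, calibration).value == pytest.approx(
            100.0 * carbon
        )


def test_ri_midpoint():
    cal = AlkaneCalibration(((10, 10.0), (11, 12.0)))
    assert compute_retention_index(11.0, cal).value == pytest.approx(1050.0)


def test_ri_strictly_increasing(calibration):
    lo, hi = calibration.rt_span
    rts = np.linspace(lo, hi, 50)
    ris = [compute_retention_index(t, calibration).value for t in rts]
    assert all(b > a for a, b in zip(ris, ris[1:]))


def test_ri_out_of_range(calibration):
    with pytest.raises(OutOfRangeError):
        compute_retention_index(7.0, calibration)
    flagged = compute_retention_index(7.0, calibration, allow_extrapolation=True)
    assert flagged.extrapolated and flagged.value < 800.0


@pytest.mark.parametrize(
    "observed,library,source,expected",
    [
        (4049.0, 4000.0, "experimental", True),   # 49 < 50 and 1.23% < 1.5%
        (2040.0, 2000.0, "experimental", False),  # 2.0% >= 1.5%
        (1099.0, 1000.0, "predicted", True),      # 99 < 100
        (1100.0, 1000.0, "predicted", False),     # strict boundary
        (1050.0, 1000.0, "experimental", False),  # strict boundary
    ],
)
def test_ri_match_rule(observed, library, source, expected):
    assert ri_match(observed, library, source).passed is expected


def test_ri_match_absent_source():
    with pytest.raises(MissingRIError):
        ri_match(1000.0, 1000.0, "absent")


# -- HRMF / RHRMF -----------------------------------------------------------


def cation(text):
    return pyteomics_mass.calculate_mass(
        composition=parse_formula(text).counts
    ) - ELECTRON_MASS


def test_hrmf_all_peaks_explained():
    s = spec((cation("CH3"), 100.0), (cation("C2H5O"), 50.0))
    assert hrmf(s, parse_formula("C2H6O"), 5.0, 0) == 100.0


def test_hrmf_chlorine_peak_unexplained():
    s = spec((cation("CH3"), 100.0), (34.9689, 50.0))
    assert hrmf(s, parse_formula("C2H6O"), 5.0, 0) == 50.0


def test_hrmf_single_atom():
    s = spec((12.0 - ELECTRON_MASS, 5.0))
    assert hrmf(s, Formula.from_counts({"C": 1}), 5.0, 0) == 100.0


def test_hrmf_requires_accurate_spectrum():
    with pytest.raises(ResolutionError):
        hrmf(spec((50.0, 1.0), resolution="unit"), parse_formula("C2H6O"))


def brute_force_hrmf(spectrum, parent, tol_ppm, h_transfer):
    """Oracle: exhaustive subformula table via itertools + pyteomics."""
    items = parent.items
    masses = set()
    parent_h = dict(items).get("H", 0)
    h1 = pyteomics_mass.calculate_mass(composition={"H": 1})
    for counts in itertools.product(*(range(n + 1) for _, n in items)):
        if not any(counts):
            continue
        comp = {el: c for (el, _), c in zip(items, counts) if c > 0}
        m = pyteomics_mass.calculate_mass(composition=comp)
        h = comp.get("H", 0)
        for dh in range(-h_transfer, h_transfer + 1):
            if 0 <= h + dh <= parent_h:
                masses.add(m + dh * h1 - ELECTRON_MASS)
    n_hit = sum(
        1
        for mz in spectrum.mz
        if any(abs(mz - m) <= mz * tol_ppm * 1e-6 for m in masses)
    )
    return 100.0 * n_hit / spectrum.n_peaks


@pytest.mark.parametrize("text", ["C6H5Cl", "C4H8N2O2", "C7H14O"])
@pytest.mark.parametrize("h_transfer", [0, 1])
def test_hrmf_matches_brute_force_oracle(text, h_transfer):
    parent = parse_formula(text)
    assert parent.n_atoms <= 30
    rng = np.random.default_rng(11)
    mzs = np.sort(
        np.concatenate(
            [
                [cation("CH2"), cation("C2H3"), cation(text)],
                rng.uniform(20.0, parent.mass, 5),
            ]
        )
    )
    s = Spectrum(mzs, np.ones_like(mzs))
    ours = hrmf(s, parent, 10.0, h_transfer)
    assert ours == pytest.approx(brute_force_hrmf(s, parent, 10.0, h_transfer))


def test_hrmf_monotone_in_tolerance_and_h_transfer():
    parent = parse_formula("C6H5Cl")
    rng = np.random.default_rng(5)
    mzs = np.sort(rng.uniform(20.0, parent.mass, 10))
    s = Spectrum(mzs, np.ones_like(mzs))
    scores_tol = [hrmf(s, parent, t, 0) for t in (1.0, 10.0, 100.0, 1000.0)]
    assert scores_tol == sorted(scores_tol)
    assert hrmf(s, parent, 10.0, 1) >= hrmf(s, parent, 10.0, 0)


def test_rhrmf_restricted_to_library_matches():
    lib = spec((cation("CH3"), 100.0), (cation("C2H5O"), 50.0))
    # query has an inexplicable extra peak not present in the library
    query = spec((cation("CH3"), 90.0), (cation("C2H5O"), 60.0), (333.3333, 40.0))
    assert rhrmf(query, lib, parse_formula("C2H6O"), ACC, 5.0, 0) == 100.0
    # the same inexplicable peak *in* the library drags the score to 2/3
    lib2 = spec((cation("CH3"), 100.0), (cation("C2H5O"), 50.0), (333.3333, 40.0))
    assert rhrmf(query, lib2, parse_formula("C2H6O"), ACC, 5.0, 0) == pytest.approx(
        200.0 / 3.0
    )


def test_rhrmf_half_explained():
    lib = spec((cation("CH3"), 100.0), (34.9689, 50.0))
    query = spec((cation("CH3"), 90.0), (34.9689, 60.0))
    assert rhrmf(query, lib, parse_formula("C2H6O"), ACC, 5.0, 0) == 50.0


def test_rhrmf_no_matches_is_unavailable_not_zero():
    lib = spec((400.0, 10.0))
    query = spec((50.0, 10.0))
    assert rhrmf(query, lib, parse_formula("C2H6O"), ACC) is None


# -- molecular ion & fragment counting --------------------------------------


def test_molecular_ion_detection():
    benzene = parse_formula("C6H6")
    target = benzene.mass - ELECTRON_MASS
    hit = detect_molecular_ion(spec((target, 5.0), (51.02, 10.0)), benzene, 10.0)
    assert hit.present and abs(hit.mass_error_ppm) < 0.01
    miss = detect_molecular_ion(spec((50.0, 1.0)), benzene, 10.0)
    assert not miss.present and miss.mass_error_ppm is None
    # offset by twice the tolerance: not detected
    off = detect_molecular_ion(
        spec((target * (1 + 20e-6), 5.0)), benzene, 10.0
    )
    assert not off.present


def test_count_matched_fragments():
    s = spec(*[(50.0 + 10 * k, 5.0) for k in range(7)])
    assert count_matched_fragments(s, s, UNIT) == 7
    assert count_matched_fragments(s, spec((999.0, 1.0)), UNIT) == 0
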