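"""Level assignment, Level-1/4 checks, candidate ranking, deduplication and
the end-to-end per-feature annotation path."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcannotate.chem_core import ELECTRON_MASS, parse_formula
from gcannotate.errors import ContractError, InsufficientStandardError
from gcannotate.evidence import MatchWeighting
from gcannotate.scoring_engine import (
    CandidateEvidence,
    Level1Standard,
    ScoringConfig,
    SeriesMember,
    annotate_feature,
    assign_level,
    check_level1,
    dedupe,
    detect_homologous_series,
    flag_class,
    level4a_unequivocal_formula,
    rank_candidates,
)
from gcannotate.spectra_io import FeatureRecord, LibraryEntry, Spectrum


def entry(name="X", identifier="1-1-1", **kw):
    kw.setdefault("spectrum", Spectrum.from_pairs([(50.0, 1.0)]))
    return LibraryEntry(name=name, identifier=identifier, **kw)


def evidence(**kw):
    defaults = dict(feature_id="F1", candidate=entry(), si=0.0, rsi=0.0)
    defaults.update(kw)
    return CandidateEvidence(**defaults)


# -- assign_level -----------------------------------------------------------


def test_level2_full_evidence():
    ev = evidence(
        rsi=650, si=520, delta_ri=30.0, ri_source="experimental",
        library_ri=4000.0, rhrmf=80.0,
    )
    assert assign_level(ev)[0] == "2"


def test_level3_without_ri():
    ev = evidence(rsi=650, si=520, rhrmf=80.0, ri_source="absent")
    assert assign_level(ev)[0] == "3"


def test_boundary_values_fail_strictly():
    ev = evidence(
        rsi=600, si=520, delta_ri=10.0, ri_source="experimental",
        library_ri=2000.0, rhrmf=80.0,
    )
    assert assign_level(ev)[0] is None
    # exactly at the RHRMF cutoff also fails
    ev2 = dataclasses.replace(
        evidence(
            rsi=650, si=520, delta_ri=10.0, ri_source="experimental",
            library_ri=2000.0, rhrmf=75.0,
        )
    )
    assert assign_level(ev2)[0] is None


def test_level3_alternative_path_molecular_ion():
    ev = evidence(
        rsi=400, si=300, delta_ri=80.0, ri_source="predicted",
        library_ri=1500.0, molecular_ion=True,
    )
    assert assign_level(ev)[0] == "3"


def test_level3_alternative_path_accurate_ions():
    ev = evidence(
        rsi=400, si=300, delta_ri=-60.0, ri_source="experimental",
        library_ri=1500.0, accurate_ion_matches=3,
    )
    assert assign_level(ev)[0] == "3"


def test_ci_path_with_five_fragments():
    ev = evidence(
        rsi=100, si=100, ionization="PCI", matched_fragments=5,
        delta_ri=10.0, ri_source="experimental", library_ri=2000.0, rhrmf=90.0,
    )
    assert assign_level(ev)[0] == "2"
    assert assign_level(dataclasses.replace(ev, matched_fragments=4))[0] is None


def test_require_molecular_ion_switch():
    ev = evidence(
        rsi=650, si=520, delta_ri=10.0, ri_source="experimental",
        library_ri=2000.0, rhrmf=90.0, molecular_ion=False,
    )
    strict = ScoringConfig(require_molecular_ion=True)
    assert assign_level(ev, strict)[0] != "2"
    assert assign_level(ev)[0] == "2"


def test_level_nesting_level2_implies_level3_spectral_path():
    """Removing the RI evidence from any Level-2 candidate leaves the
    Level-3 main path satisfied."""
    ev = evidence(
        rsi=700, si=600, delta_ri=5.0, ri_source="experimental",
        library_ri=1800.0, rhrmf=95.0,
    )
    assert assign_level(ev)[0] == "2"
    no_ri = dataclasses.replace(ev, delta_ri=None, ri_source="absent", library_ri=None)
    assert assign_level(no_ri)[0] == "3"


level_values = {None: 3, "3": 2, "2": 1}


@given(
    rsi=st.floats(0, 1000),
    si=st.floats(0, 1000),
    rhrmf_=st.one_of(st.none(), st.floats(0, 100)),
    delta=st.one_of(st.none(), st.floats(-200, 200)),
    scale=st.floats(0.5, 1.0),
)
@settings(max_examples=80, deadline=None)
def test_threshold_monotonicity(rsi, si, rhrmf_, delta, scale):
    """Lowering every threshold never demotes a candidate."""
    ev = evidence(
        rsi=rsi, si=si, rhrmf=rhrmf_,
        delta_ri=delta,
        ri_source="experimental" if delta is not None else "absent",
        library_ri=2000.0 if delta is not None else None,
    )
    base = ScoringConfig()
    lowered = dataclasses.replace(
        base,
        rsi_min=base.rsi_min * scale,
        si_min=base.si_min * scale,
        rhrmf_min=base.rhrmf_min * scale,
        exact_mass_rsi_min=base.exact_mass_rsi_min * scale,
    )
    assert level_values[assign_level(ev, lowered)[0]] <= level_values[
        assign_level(ev, base)[0]
    ]


# -- Level 1 ----------------------------------------------------------------


def l1_feature(rt, peaks):
    return FeatureRecord(
        feature_id="F1",
        retention_time=rt,
        spectrum=Spectrum.from_pairs(peaks),
        sample_abundances={"sample_1": 100.0},
    )


def test_level1_reference_ion_route():
    std = Level1Standard(
        entry=entry(), expected_rt=10.0,
        reference_peaks=((100.0, 1.0), (150.0, 0.5)),
    )
    ok, _ = check_level1(l1_feature(10.05, [(100.0, 80.0), (150.0, 40.0)]), std)
    assert ok


def test_level1_rt_deviation_fails_regardless_of_spectrum():
    std = Level1Standard(
        entry=entry(), expected_rt=10.0,
        reference_peaks=((100.0, 1.0), (150.0, 0.5)),
    )
    ok, notes = check_level1(l1_feature(10.15, [(100.0, 80.0), (150.0, 40.0)]), std)
    assert not ok and any("fail" in n for n in notes)


def test_level1_spectral_route_rescues_bad_ratios():
    lib_spec = Spectrum.from_pairs([(100.0, 80.0), (150.0, 40.0)])
    std = Level1Standard(
        entry=entry(spectrum=lib_spec), expected_rt=10.0,
        reference_peaks=((100.0, 1.0), (150.0, 0.5)),
    )
    # ratios off by ~50% but the in-house match is high
    ok, _ = check_level1(l1_feature(10.02, [(100.0, 80.0), (150.0, 20.0)]), std)
    assert ok


def test_level1_insufficient_standard():
    std = Level1Standard(entry=entry(spectrum=None), expected_rt=10.0)
    with pytest.raises(InsufficientStandardError):
        check_level1(l1_feature(10.0, [(100.0, 1.0)]), std)


# -- Level 4A ---------------------------------------------------------------


def cation(text):
    return parse_formula(text).mass - ELECTRON_MASS


def l4_feature(peaks, reference_mz):
    return FeatureRecord(
        feature_id="F4",
        retention_time=5.0,
        spectrum=Spectrum.from_pairs(peaks),
        sample_abundances={"sample_1": 1.0},
        reference_mz=reference_mz,
    )


def test_level4a_water_unique():
    mz = cation("H2O")
    feat = l4_feature([(mz, 100.0), (cation("HO"), 20.0)], mz)
    got = level4a_unequivocal_formula(feat, parse_formula("C2H8N2O2S"), 5.0)
    assert got == parse_formula("H2O")


def test_level4a_ambiguous_returns_none():
    # 2000 ppm around 28 admits CO, N2 and CH2N; nothing disambiguates
    feat = l4_feature([(28.0, 100.0)], 28.0)
    assert (
        level4a_unequivocal_formula(feat, parse_formula("C2H6N2O"), 2000.0) is None
    )


def test_level4a_fragment_filter_selects_survivor():
    # C+ excludes N2; CH2+ excludes CO; only CH2N explains all dominant ions
    feat = l4_feature(
        [(cation("C"), 50.0), (cation("CH2"), 60.0), (28.018, 100.0)], 28.018
    )
    got = level4a_unequivocal_formula(feat, parse_formula("CH6N2O"), 2000.0)
    assert got == parse_formula("CH2N")


def test_level4a_requires_precursor():
    feat = FeatureRecord(
        feature_id="F",
        retention_time=1.0,
        spectrum=Spectrum.from_pairs([(50.0, 1.0)]),
        sample_abundances={"s": 1.0},
    )
    with pytest.raises(ContractError):
        level4a_unequivocal_formula(feat, parse_formula("CHNO"), 5.0)


# -- Level 4B / 4C ----------------------------------------------------------


def test_homologous_series_detected():
    ch2 = parse_formula("CH2")
    base = 178.0783
    members = [
        SeriesMember(f"F{k}", base + k * ch2.mass, 1800.0 + 100.0 * k)
        for k in range(3)
    ]
    (group,) = detect_homologous_series(members, ch2)
    assert [m.feature_id for m in group.members] == ["F0", "F1", "F2"]
    assert group.r_squared >= 0.99


def test_homologous_series_nonlinear_ri_rejected():
    ch2 = parse_formula("CH2")
    base = 178.0783
    members = [
        SeriesMember("F0", base, 1800.0),
        SeriesMember("F1", base + ch2.mass, 2600.0),
        SeriesMember("F2", base + 2 * ch2.mass, 1900.0),
    ]
    assert detect_homologous_series(members, ch2) == []


def test_homologous_series_size_gate():
    ch2 = parse_formula("CH2")
    members = [
        SeriesMember("F0", 178.0783, 1800.0),
        SeriesMember("F1", 178.0783 + ch2.mass, 1900.0),
    ]
    assert detect_homologous_series(members, ch2, min_members=3) == []


def test_flag_class():
    feat = l4_feature([(68.9952, 10.0), (99.9936, 5.0)], 99.9936)
    diagnostics = [
        ("PFAS (CF3+)", [68.9947]),
        ("PFAS (C2F4+)", [99.9930]),
        ("organochlorine", [34.9689]),
    ]
    labels = flag_class(feat, diagnostics, tol_ppm=100.0)
    assert labels == ["PFAS (CF3+)", "PFAS (C2F4+)"]
    assert flag_class(feat, [("organochlorine", [34.9689])], 10.0) == []


# -- ranking & dedupe -------------------------------------------------------


def test_rank_prefers_higher_rsi_margin():
    a = evidence(rsi=700, candidate=entry("A", "1"))
    b = evidence(rsi=640, candidate=entry("B", "2"))
    ordered, preferred = rank_candidates([b, a])
    assert ordered[0].candidate.name == "A" and preferred


def test_rank_prefers_more_accurate_ri():
    a = evidence(rsi=650, delta_ri=10.0, candidate=entry("A", "1"))
    b = evidence(rsi=650, delta_ri=45.0, candidate=entry("B", "2"))
    ordered, preferred = rank_candidates([a, b])
    assert ordered[0].candidate.name == "A" and preferred


def test_rank_multi_hit_when_no_dominance():
    a = evidence(rsi=650, candidate=entry("A", "1"))
    b = evidence(rsi=630, candidate=entry("B", "2"))
    _, preferred = rank_candidates([a, b])
    assert not preferred


def test_rank_evidence_count_factor():
    a = evidence(rsi=650, evidence_count=200, candidate=entry("A", "1"))
    b = evidence(rsi=640, evidence_count=10, candidate=entry("B", "2"))
    _, preferred = rank_candidates([a, b])
    assert preferred


def test_rank_empty_contract():
    with pytest.raises(ContractError):
        rank_candidates([])


def assignment(feature_id, level, name, identifier, rsi):
    from gcannotate.scoring_engine import LevelAssignment

    ev = evidence(rsi=rsi, candidate=entry(name, identifier))
    return LevelAssignment(
        feature_id=feature_id, level=level, blank_pass=True,
        best_candidate=ev.candidate, candidates=[ev],
    )


def test_dedupe_keeps_best_level():
    a = assignment("F1", "2", "Pyrene", "129-00-0", 900)
    b = assignment("F2", "3", "Pyrene", "129-00-0", 950)
    kept = dedupe([b, a])
    assert [x.feature_id for x in kept] == ["F1"]


def test_dedupe_normalizes_names_without_identifiers():
    a = assignment("F1", "3", "  Pyrene ", "", 900)
    b = assignment("F2", "3", "pyrene", "", 800)
    kept = dedupe([a, b])
    assert [x.feature_id for x in kept] == ["F1"]


def test_dedupe_distinct_identifiers_same_name_both_kept():
    a = assignment("F1", "2", "Pyrene", "129-00-0", 900)
    b = assignment("F2", "2", "Pyrene", "999-99-9", 880)
    assert len(dedupe([a, b])) == 2


# -- annotate_feature -------------------------------------------------------


def test_true_spike_is_level2_rank1(small_sim, small_annotations):
    _, run = small_sim
    truth_ids = set(run.truth["feature_id"])
    by_id = {a.feature_id: a for a in small_annotations}
    truth_map = dict(zip(run.truth["feature_id"], run.truth["identifier"]))
    for fid in truth_ids:
        a = by_id[fid]
        assert a.level == "2" and a.rank == 1
        assert a.best_identifier == truth_map[fid]


def test_blank_failing_feature_gets_no_level(small_sim, small_annotations):
    _, run = small_sim
    by_id = {a.feature_id: a for a in small_annotations}
    for fid in run.contaminant_feature_ids:
        a = by_id[fid]
        assert not a.blank_pass and a.level is None


def test_unmatched_feature_is_level5():
    rng = np.random.default_rng(3)
    feat = FeatureRecord(
        feature_id="F",
        retention_time=5.0,
        spectrum=Spectrum(np.sort(rng.uniform(60, 300, 6)), np.ones(6)),
        sample_abundances={"s": 1000.0},
        blank_abundances={f"b{i}": 0.0 for i in range(4)},
    )
    lib = [entry("A", "1", spectrum=Spectrum.from_pairs([(400.0, 1.0)]))]
    a = annotate_feature(feat, lib, weighting=MatchWeighting.accurate(10.0))
    assert a.level == "5" and a.blank_pass and a.best_candidate is None


def test_empty_library_warns_and_gives_level5():
    feat = FeatureRecord(
        feature_id="F",
        retention_time=5.0,
        spectrum=Spectrum.from_pairs([(50.0, 1.0)]),
        sample_abundances={"s": 1000.0},
        blank_abundances={f"b{i}": 0.0 for i in range(4)},
    )
    with pytest.warns(UserWarning, match="empty library"):
        a = annotate_feature(feat, [])
    assert a.level == "5"
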