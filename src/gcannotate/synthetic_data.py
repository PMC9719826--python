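"""Seeded generator of libraries, spiked runs, decoys and blanks.

Emulates a spike-recovery validation design: a spectral library of plausible
small molecules, a chromatographic run containing true spikes (features whose
spectra, retention and abundances are consistent with their library entries),
decoy features (perturbed library spectra at retention times inconsistent
with their source compound's retention index, mimicking the structurally
similar isomer failure mode), and background contamination present in blanks
and samples at comparable levels.

Every fragment m/z in a generated spectrum is a true subformula cation mass
of its compound, so a library entry self-matches with dot product 1000 and
HRMF 100. The retention-index model is a monotone affine map from
monoisotopic mass onto the alkane calibration span, giving every compound a
well-defined true RI and retention time.

Defaults describe a small but fully-controlled study: 120 library compounds,
50 true spikes, 50 decoys, 10 contamination features, 6 samples and 4 field
blanks, 1 % multiplicative intensity noise and 0.005 min RT jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_core import ELECTRON_MASS, Formula, enumerate_subformulas
from .errors import ContractError
from .spectra_io import (
    AlkaneCalibration,
    FeatureRecord,
    LibraryEntry,
    Spectrum,
    write_alkane_calibration,
    write_feature_table,
    write_msp,
    write_spike_sheet,
)

__all__ = ["SimConfig", "SyntheticRun", "generate_library", "generate_run",
           "write_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the generator."""

    seed: int = 0
    n_compounds: int = 120
    n_true_spikes: int = 50
    n_decoys: int = 50
    n_contaminants: int = 10
    elements: tuple[str, ...] = ("C", "H", "N", "O", "Cl")
    fragment_count_range: tuple[int, int] = (6, 12)
    intensity_noise_sd: float = 0.01  # multiplicative fraction
    rt_jitter_sd: float = 0.005  # minutes
    n_samples: int = 6
    n_blanks: int = 4
    ri_noise_sd: float = 0.0  # RI units added to library RIs
    molecular_ion_prob: float = 1.0
    decoy_dropout: float = 0.3
    decoy_ri_offset: float = 300.0
    spike_abundance: float = 1.0e6
    contamination_abundance: float = 1.0e5

    def __post_init__(self) -> None:
        if self.n_true_spikes + self.n_decoys > self.n_compounds:
            raise ContractError("spikes + decoys exceed library size")
        if min(self.intensity_noise_sd, self.rt_jitter_sd, self.ri_noise_sd) < 0:
            raise ContractError("noise SDs must be >= 0")


# calibration: n-alkanes C8..C32, RT = carbon number in minutes -> 100 RI
# units per minute across an 8-32 min run
_CAL_CARBONS = tuple(range(8, 33))


def default_calibration() -> AlkaneCalibration:
    return AlkaneCalibration(tuple((c, float(c)) for c in _CAL_CARBONS))


def _rt_for_ri(ri: float) -> float:
    return ri / 100.0


def _random_formula(rng: np.random.Generator, elements: Sequence[str]) -> Formula:
    n_c = int(rng.integers(6, 21))
    counts = {"C": n_c}
    # keep H plausible for a (poly)cyclic scaffold, leaving room for halogens
    counts["H"] = int(rng.integers(max(2, n_c // 2), 2 * n_c + 2))
    for el in elements:
        if el in ("C", "H"):
            continue
        if rng.random() < 0.5:
            n = int(rng.integers(1, 4))
            if el in ("Cl", "Br"):
                n = min(n, counts["H"])
                counts["H"] -= n  # halogens substitute hydrogens
            counts[el] = n
    return Formula.from_counts({k: v for k, v in counts.items() if v > 0})


def _random_spectrum(
    rng: np.random.Generator, formula: Formula, config: SimConfig
) -> Spectrum:
    """An EI-like spectrum whose fragment m/z are exact subformula cation
    masses (plus the molecular ion), guaranteeing HRMF = 100 self-match."""
    subs = [
        f
        for f in enumerate_subformulas(formula, 45.0, formula.mass - 10.0)
        if f["C"] >= 1
    ]
    lo, hi = config.fragment_count_range
    n_frag = int(rng.integers(lo, hi + 1))
    n_frag = min(n_frag, len(subs))
    idx = rng.choice(len(subs), size=n_frag, replace=False)
    mzs = [subs[i].mass - ELECTRON_MASS for i in idx]
    intens = rng.lognormal(mean=0.0, sigma=1.0, size=n_frag) * 100.0
    peaks = list(zip(mzs, intens))
    if rng.random() < config.molecular_ion_prob:
        peaks.append((formula.mass - ELECTRON_MASS, float(50.0 + rng.random() * 100)))
    return Spectrum.from_pairs(peaks, "accurate")


def generate_library(config: SimConfig) -> list[LibraryEntry]:
    """Deterministic (seeded) library of ``n_compounds`` entries with
    formulas, subformula-consistent spectra, evidence counts and RIs from
    the mass->RI model."""
    rng = np.random.default_rng(config.seed)
    cal = default_calibration()
    ri_lo, ri_hi = 100.0 * _CAL_CARBONS[0] + 60, 100.0 * _CAL_CARBONS[-1] - 60
    entries = []
    formulas = [_random_formula(rng, config.elements) for _ in range(config.n_compounds)]
    masses = np.array([f.mass for f in formulas])
    m_lo, m_hi = masses.min(), masses.max()
    span = m_hi - m_lo if m_hi > m_lo else 1.0
    for i, f in enumerate(formulas):
        true_ri = ri_lo + (f.mass - m_lo) / span * (ri_hi - ri_lo)
        lib_ri = true_ri + rng.normal(0.0, config.ri_noise_sd)
        entries.append(
            LibraryEntry(
                name=f"Compound {i:03d}",
                identifier=f"SYN-{i:04d}",
                formula=f,
                spectrum=_random_spectrum(rng, f, config),
                retention_index=float(lib_ri),
                ri_source="experimental",
                evidence_count=int(rng.integers(1, 200)),
                ionization="EI",
                metadata={"TRUE_RI": repr(float(true_ri))},
            )
        )
    return entries


@dataclass
class SyntheticRun:
    features: list[FeatureRecord]
    calibration: AlkaneCalibration
    truth: pd.DataFrame  # feature_id, name, identifier, equivalence_group
    library: list[LibraryEntry]
    decoy_feature_ids: list[str]
    contaminant_feature_ids: list[str]


def _noisy_spectrum(
    rng: np.random.Generator, spec: Spectrum, noise_sd: float
) -> Spectrum:
    factors = np.clip(1.0 + rng.normal(0.0, noise_sd, spec.n_peaks), 0.05, None)
    return Spectrum(spec.mz.copy(), spec.intensity * factors, spec.resolution_class)


def generate_run(library: Sequence[LibraryEntry], config: SimConfig) -> SyntheticRun:
    """Generate the feature table, calibration and truth sheet for one run.

    The first ``n_true_spikes`` library entries become true-spike features;
    the next ``n_decoys`` become decoy features (peak dropout + RI-shifted
    retention); ``n_contaminants`` background features carry comparable
    sample and blank abundances and must fail blank filtering.
    """
    if config.n_true_spikes > len(library):
        raise ContractError("n_true_spikes exceeds library size")
    rng = np.random.default_rng(config.seed + 1)
    cal = default_calibration()
    sample_ids = [f"sample_{i + 1:02d}" for i in range(config.n_samples)]
    blank_ids = [f"blank_{i + 1:02d}" for i in range(config.n_blanks)]
    features: list[FeatureRecord] = []
    truth_rows = []
    decoy_ids: list[str] = []
    contaminant_ids: list[str] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"F{counter:04d}"

    def true_ri(entry: LibraryEntry) -> float:
        return float(entry.metadata.get("TRUE_RI", entry.retention_index))

    for entry in library[: config.n_true_spikes]:
        fid = next_id()
        rt = _rt_for_ri(true_ri(entry)) + rng.normal(0.0, config.rt_jitter_sd)
        abundances = {
            s: float(config.spike_abundance * rng.lognormal(0.0, 0.2))
            for s in sample_ids
        }
        features.append(
            FeatureRecord(
                feature_id=fid,
                retention_time=float(rt),
                spectrum=_noisy_spectrum(rng, entry.spectrum, config.intensity_noise_sd),
                sample_abundances=abundances,
                blank_abundances={b: 0.0 for b in blank_ids},
                reference_mz=float(entry.formula.mass - ELECTRON_MASS),
            )
        )
        truth_rows.append(
            {
                "feature_id": fid,
                "name": entry.name,
                "identifier": entry.identifier,
                "equivalence_group": entry.identifier,
            }
        )

    for entry in library[config.n_true_spikes : config.n_true_spikes + config.n_decoys]:
        fid = next_id()
        decoy_ids.append(fid)
        spec = entry.spectrum
        keep = rng.random(spec.n_peaks) > config.decoy_dropout
        if keep.sum() < 3:
            keep[:3] = True
        decoy_spec = Spectrum(
            spec.mz[keep],
            spec.intensity[keep]
            * np.clip(1.0 + rng.normal(0.0, 0.05, int(keep.sum())), 0.05, None),
            spec.resolution_class,
        )
        ri = true_ri(entry)
        lo, hi = 100.0 * _CAL_CARBONS[0] + 10, 100.0 * _CAL_CARBONS[-1] - 10
        shifted = ri + config.decoy_ri_offset
        if shifted > hi:
            shifted = ri - config.decoy_ri_offset
        shifted = min(max(shifted, lo), hi)
        rt = _rt_for_ri(shifted) + rng.normal(0.0, config.rt_jitter_sd)
        features.append(
            FeatureRecord(
                feature_id=fid,
                retention_time=float(rt),
                spectrum=decoy_spec,
                sample_abundances={
                    s: float(config.spike_abundance * 0.3 * rng.lognormal(0.0, 0.2))
                    for s in sample_ids
                },
                blank_abundances={b: 0.0 for b in blank_ids},
            )
        )

    for _ in range(config.n_contaminants):
        fid = next_id()
        contaminant_ids.append(fid)
        n_pk = int(rng.integers(4, 9))
        mzs = np.sort(rng.uniform(60.0, 400.0, n_pk))
        intens = rng.lognormal(0.0, 1.0, n_pk) * 100.0
        rt = float(rng.uniform(_CAL_CARBONS[0] + 0.5, _CAL_CARBONS[-1] - 0.5))
        level = config.contamination_abundance
        features.append(
            FeatureRecord(
                feature_id=fid,
                retention_time=rt,
                spectrum=Spectrum(mzs, intens, "accurate"),
                # comparable levels in samples and blanks: the blank threshold
                # c*(mean + 3 sd) sits well above the sample mean
                sample_abundances={
                    s: float(level * rng.lognormal(0.0, 0.1)) for s in sample_ids
                },
                blank_abundances={
                    b: float(level * rng.lognormal(0.0, 0.1)) for b in blank_ids
                },
            )
        )

    truth = pd.DataFrame(
        truth_rows, columns=["feature_id", "name", "identifier", "equivalence_group"]
    )
    return SyntheticRun(
        features=features,
        calibration=cal,
        truth=truth,
        library=list(library),
        decoy_feature_ids=decoy_ids,
        contaminant_feature_ids=contaminant_ids,
    )


def write_dataset(run: SyntheticRun, out_dir: str | Path, config: SimConfig) -> dict:
    """Write library.msp, features.csv, calibration.csv and truth.csv with
    the seed recorded in every CSV header. Returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"generator_seed": config.seed}
    paths = {
        "library": out / "library.msp",
        "features": out / "features.csv",
        "calibration": out / "calibration.csv",
        "truth": out / "truth.csv",
    }
    write_msp(run.library, paths["library"])
    write_feature_table(run.features, paths["features"], provenance)
    write_alkane_calibration(run.calibration, paths["calibration"], provenance)
    write_spike_sheet(run.truth, paths["truth"], provenance)
    return paths
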