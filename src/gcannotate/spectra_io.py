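"""Readers and writers for the package's text formats.

Formats handled here:

* MSP (NIST text dialect) spectral libraries — ``Name``, ``CASNO``,
  ``Formula``, ``RI``, ``RI_SOURCE``, ``EVIDENCE_COUNT``, ``IONIZATION``
  headers, then ``Num Peaks: n`` and n ``mz intensity`` pairs.
* Feature tables — CSV, one deconvoluted feature per row, spectrum encoded as
  ``"mz:intensity;mz:intensity;..."``; sample/blank abundance columns selected
  by configurable name patterns (the dialect config stands in for vendor
  export schemas).
* Alkane calibrations — CSV with ``carbon_number, rt_min`` columns.
* Spike (truth) sheets — CSV with ``feature_id, name, identifier,
  equivalence_group`` columns.
* Annotation result tables — CSV, one row per feature-candidate.

All tables are UTF-8 CSV with "." decimals. Lines starting with ``#`` are
provenance comments (resolved configuration) and are skipped by the readers.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .chem_core import Formula, parse_formula
from .errors import ConfigError, FormatError

__all__ = [
    "Spectrum",
    "LibraryEntry",
    "FeatureRecord",
    "AlkaneCalibration",
    "FeatureTableDialect",
    "read_msp",
    "write_msp",
    "read_feature_table",
    "write_feature_table",
    "read_alkane_calibration",
    "write_alkane_calibration",
    "read_spike_sheet",
    "write_spike_sheet",
    "write_results",
    "read_results",
]

IONIZATION_MODES = ("EI", "PCI", "ECNI", "APCI")
RI_SOURCES = ("experimental", "predicted", "absent")


@dataclass
class Spectrum:
    """A peak list with strictly increasing m/z and non-negative intensities.

    ``resolution_class`` is ``"accurate"`` for high-resolution data or
    ``"unit"`` for nominal-mass (library) data. Construction canonicalizes:
    peaks are sorted by m/z and duplicate m/z values are merged by intensity
    summation (deconvolution occasionally emits split centroids).
    """

    mz: np.ndarray
    intensity: np.ndarray
    resolution_class: str = "accurate"

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or mz.shape != inten.shape:
            raise FormatError("mz and intensity must be equal-length 1-D arrays")
        if mz.size == 0:
            raise FormatError("a spectrum requires at least one peak")
        if np.any(inten < 0):
            raise FormatError("negative intensity")
        if self.resolution_class not in ("accurate", "unit"):
            raise FormatError(
                f"unknown resolution class {self.resolution_class!r}"
            )
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        uniq, inverse = np.unique(mz, return_inverse=True)
        if uniq.size != mz.size:
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, inten)
            mz, inten = uniq, summed
        self.mz = mz
        self.intensity = inten

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[float, float]], resolution_class: str = "accurate"
    ) -> "Spectrum":
        arr = np.asarray(list(pairs), dtype=float).reshape(-1, 2)
        return cls(arr[:, 0], arr[:, 1], resolution_class)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def base_intensity(self) -> float:
        return float(self.intensity.max())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.resolution_class == other.resolution_class
            and np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
        )


@dataclass
class LibraryEntry:
    """One library compound: identity, spectrum and annotation metadata."""

    name: str
    identifier: str = ""
    formula: Formula | None = None
    spectrum: Spectrum | None = None
    retention_index: float | None = None
    ri_source: str = "absent"
    evidence_count: int | None = None
    ionization: str = "EI"
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ri_source not in RI_SOURCES:
            raise FormatError(f"unknown RI source {self.ri_source!r}")
        if self.retention_index is not None and self.ri_source == "absent":
            raise FormatError("retention_index present requires an ri_source")
        if self.evidence_count is not None and self.evidence_count < 0:
            raise FormatError("evidence_count must be >= 0")
        if self.ionization not in IONIZATION_MODES:
            raise FormatError(f"unknown ionization mode {self.ionization!r}")


@dataclass
class FeatureRecord:
    """One deconvoluted feature: RT, spectrum and per-sample/blank abundances."""

    feature_id: str
    retention_time: float
    spectrum: Spectrum
    sample_abundances: dict[str, float]
    blank_abundances: dict[str, float] = field(default_factory=dict)
    reference_mz: float | None = None

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise FormatError(
                f"feature {self.feature_id}: retention_time must be > 0"
            )
        if not self.sample_abundances:
            raise FormatError(
                f"feature {self.feature_id}: at least one sample abundance required"
            )


@dataclass
class AlkaneCalibration:
    """n-Alkane anchors: strictly increasing carbon numbers and RTs."""

    points: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((int(c), float(t)) for c, t in self.points)
        if len(pts) < 2:
            raise FormatError("alkane calibration needs at least 2 points")
        carbons = [c for c, _ in pts]
        rts = [t for _, t in pts]
        if any(c < 1 for c in carbons):
            raise FormatError("carbon numbers must be >= 1")
        if any(b <= a for a, b in zip(carbons, carbons[1:])):
            raise FormatError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise FormatError("retention times must be strictly increasing")
        self.points = pts

    @property
    def rt_span(self) -> tuple[float, float]:
        return self.points[0][1], self.points[-1][1]


# ---------------------------------------------------------------------------
# MSP libraries
# ---------------------------------------------------------------------------

_MSP_KNOWN = {
    "name": "name",
    "casno": "identifier",
    "cas": "identifier",
    "formula": "formula",
    "ri": "retention_index",
    "ri_source": "ri_source",
    "evidence_count": "evidence_count",
    "ionization": "ionization",
}


def read_msp(path: str | Path) -> list[LibraryEntry]:
    """Parse an MSP library file into :class:`LibraryEntry` records.

    Unknown header keys are preserved in each entry's ``metadata`` map.
    Raises :class:`FormatError` (naming the record and line) on missing
    ``Name``, peak-count mismatches, or unreadable numerics.
    """
    path = Path(path)
    entries: list[LibraryEntry] = []
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.readlines()

    i, n = 0, len(lines)
    while i < n:
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        # start of a record
        fields: dict[str, str] = {}
        meta: dict[str, str] = {}
        num_peaks = None
        record_line = i + 1
        while i < n:
            line = lines[i].strip()
            if not line:
                break
            key, _, value = line.partition(":")
            key_norm = key.strip().lower().replace(" ", "_")
            value = value.strip()
            if key_norm == "num_peaks":
                try:
                    num_peaks = int(value)
                except ValueError:
                    raise FormatError(
                        f"{path.name}:{i + 1}: unreadable Num Peaks {value!r}"
                    )
                i += 1
                break
            if key_norm in _MSP_KNOWN:
                fields[_MSP_KNOWN[key_norm]] = value
            else:
                meta[key.strip()] = value
            i += 1
        name = fields.get("name")
        if not name:
            raise FormatError(
                f"{path.name}:{record_line}: record missing required field Name"
            )
        if num_peaks is None:
            raise FormatError(
                f"{path.name}:{record_line}: record {name!r} missing Num Peaks"
            )
        # collect num_peaks (mz, intensity) pairs; pairs may be split across
        # lines and separated by whitespace or semicolons
        values: list[float] = []
        while i < n and len(values) < 2 * num_peaks:
            line = lines[i].strip()
            if not line:
                break
            for tok in re.split(r"[;\s]+", line):
                if tok:
                    try:
                        values.append(float(tok))
                    except ValueError:
                        raise FormatError(
                            f"{path.name}:{i + 1}: record {name!r}: "
                            f"unreadable peak value {tok!r}"
                        )
            i += 1
        if len(values) != 2 * num_peaks:
            raise FormatError(
                f"{path.name}:{record_line}: record {name!r} declares "
                f"{num_peaks} peaks but {len(values) // 2} were found"
            )
        pairs = [(values[2 * k], values[2 * k + 1]) for k in range(num_peaks)]
        resolution = meta.pop("Resolution", "accurate")
        entry = LibraryEntry(
            name=name,
            identifier=fields.get("identifier", ""),
            formula=(
                parse_formula(fields["formula"]) if fields.get("formula") else None
            ),
            spectrum=Spectrum.from_pairs(pairs, resolution),
            retention_index=(
                float(fields["retention_index"])
                if fields.get("retention_index")
                else None
            ),
            ri_source=fields.get(
                "ri_source",
                "experimental" if fields.get("retention_index") else "absent",
            ),
            evidence_count=(
                int(fields["evidence_count"])
                if fields.get("evidence_count")
                else None
            ),
            ionization=fields.get("ionization", "EI"),
            metadata=meta,
        )
        entries.append(entry)
    return entries


def write_msp(entries: Sequence[LibraryEntry], path: str | Path) -> None:
    """Write entries in the MSP dialect that :func:`read_msp` parses."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(f"Name: {e.name}\n")
            if e.identifier:
                fh.write(f"CASNO: {e.identifier}\n")
            if e.formula is not None:
                fh.write(f"Formula: {e.formula.hill()}\n")
            if e.retention_index is not None:
                fh.write(f"RI: {float(e.retention_index)!r}\n")
                fh.write(f"RI_SOURCE: {e.ri_source}\n")
            if e.evidence_count is not None:
                fh.write(f"EVIDENCE_COUNT: {e.evidence_count}\n")
            fh.write(f"IONIZATION: {e.ionization}\n")
            if e.spectrum is not None and e.spectrum.resolution_class != "accurate":
                fh.write(f"Resolution: {e.spectrum.resolution_class}\n")
            for k, v in e.metadata.items():
                fh.write(f"{k}: {v}\n")
            spec = e.spectrum
            if spec is None:
                fh.write("Num Peaks: 0\n\n")
                continue
            fh.write(f"Num Peaks: {spec.n_peaks}\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                fh.write(f"{float(mz)!r} {float(inten)!r}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureTableDialect:
    """Column mapping for feature-table CSVs.

    The native schema uses ``feature_id``, ``rt_min``, ``spectrum`` and
    ``sample_*`` / ``blank_*`` abundance columns; vendor exports are adapted
    by overriding the column names and patterns.
    """

    feature_id: str = "feature_id"
    rt: str = "rt_min"
    spectrum: str = "spectrum"
    reference_mz: str = "reference_mz"
    sample_pattern: str = r"^sample"
    blank_pattern: str = r"^blank"
    resolution_class: str = "accurate"


def parse_spectrum_cell(
    cell: str, resolution_class: str = "accurate"
) -> Spectrum:
    """Decode a ``"mz:intensity;..."`` cell into a canonical Spectrum."""
    pairs = []
    for chunk in str(cell).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        mz_s, _, int_s = chunk.partition(":")
        pairs.append((float(mz_s), float(int_s)))
    if not pairs:
        raise FormatError("empty spectrum cell")
    return Spectrum.from_pairs(pairs, resolution_class)


def format_spectrum_cell(spectrum: Spectrum) -> str:
    return ";".join(
        f"{float(mz)!r}:{float(inten)!r}"
        for mz, inten in zip(spectrum.mz, spectrum.intensity)
    )


def read_feature_table(
    path: str | Path, dialect: FeatureTableDialect | None = None
) -> list[FeatureRecord]:
    """Read a feature-table CSV into :class:`FeatureRecord` rows.

    Empty abundance cells are treated as 0 with a warning. Raises
    :class:`ConfigError` when a mapped column is missing and
    :class:`FormatError` (naming the feature) for malformed spectrum cells.
    """
    dialect = dialect or FeatureTableDialect()
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    for col in (dialect.feature_id, dialect.rt, dialect.spectrum):
        if col not in df.columns:
            raise ConfigError(f"feature table missing mapped column {col!r}")
    sample_re = re.compile(dialect.sample_pattern, re.IGNORECASE)
    blank_re = re.compile(dialect.blank_pattern, re.IGNORECASE)
    sample_cols = [c for c in df.columns if sample_re.search(c)]
    blank_cols = [c for c in df.columns if blank_re.search(c)]
    if not sample_cols:
        raise ConfigError(
            f"no columns match sample pattern {dialect.sample_pattern!r}"
        )

    def abundance(row, col: str) -> float:
        raw = row[col].strip()
        if raw == "":
            warnings.warn(
                f"feature {row[dialect.feature_id]}: empty abundance in "
                f"{col!r} treated as 0",
                stacklevel=2,
            )
            return 0.0
        return float(raw)

    records = []
    for _, row in df.iterrows():
        fid = row[dialect.feature_id]
        try:
            spectrum = parse_spectrum_cell(
                row[dialect.spectrum], dialect.resolution_class
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(
                f"feature {fid!r}: malformed spectrum cell ({exc})"
            ) from exc
        ref_raw = (
            row[dialect.reference_mz].strip()
            if dialect.reference_mz in df.columns
            else ""
        )
        records.append(
            FeatureRecord(
                feature_id=fid,
                retention_time=float(row[dialect.rt]),
                spectrum=spectrum,
                sample_abundances={c: abundance(row, c) for c in sample_cols},
                blank_abundances={c: abundance(row, c) for c in blank_cols},
                reference_mz=float(ref_raw) if ref_raw else None,
            )
        )
    return records


def _write_provenance(fh: TextIO, config: Mapping[str, object] | None) -> None:
    if config:
        for key, value in config.items():
            fh.write(f"# {key} = {value}\n")


def write_feature_table(
    features: Sequence[FeatureRecord],
    path: str | Path,
    config: Mapping[str, object] | None = None,
) -> None:
    """Write features in the native CSV schema read by
    :func:`read_feature_table`."""
    sample_ids = sorted({k for f in features for k in f.sample_abundances})
    blank_ids = sorted({k for f in features for k in f.blank_abundances})
    rows = []
    for f in features:
        row: dict[str, object] = {
            "feature_id": f.feature_id,
            "rt_min": repr(float(f.retention_time)),
            "spectrum": format_spectrum_cell(f.spectrum),
            "reference_mz": (
                "" if f.reference_mz is None else repr(float(f.reference_mz))
            ),
        }
        for s in sample_ids:
            row[s] = repr(float(f.sample_abundances.get(s, 0.0)))
        for b in blank_ids:
            row[b] = repr(float(f.blank_abundances.get(b, 0.0)))
        rows.append(row)
    cols = ["feature_id", "rt_min", "spectrum", "reference_mz"]
    cols += sample_ids + blank_ids
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        _write_provenance(fh, config)
        pd.DataFrame(rows, columns=cols).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Calibrations, spike sheets, results
# ---------------------------------------------------------------------------


def read_alkane_calibration(path: str | Path) -> AlkaneCalibration:
    df = pd.read_csv(path, comment="#")
    for col in ("carbon_number", "rt_min"):
        if col not in df.columns:
            raise ConfigError(f"calibration file missing column {col!r}")
    return AlkaneCalibration(
        tuple(zip(df["carbon_number"].astype(int), df["rt_min"].astype(float)))
    )


def write_alkane_calibration(
    cal: AlkaneCalibration,
    path: str | Path,
    config: Mapping[str, object] | None = None,
) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        _write_provenance(fh, config)
        pd.DataFrame(cal.points, columns=["carbon_number", "rt_min"]).to_csv(
            fh, index=False
        )


def read_spike_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    for col in ("feature_id", "name", "identifier", "equivalence_group"):
        if col not in df.columns:
            raise ConfigError(f"spike sheet missing column {col!r}")
    return df


def write_spike_sheet(
    rows: pd.DataFrame | Sequence[Mapping[str, str]],
    path: str | Path,
    config: Mapping[str, object] | None = None,
) -> None:
    df = pd.DataFrame(rows)
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        _write_provenance(fh, config)
        df.to_csv(fh, index=False)


RESULT_COLUMNS = [
    "feature_id",
    "candidate_name",
    "candidate_identifier",
    "level",
    "si",
    "rsi",
    "delta_ri",
    "ri_source",
    "rhrmf",
    "molecular_ion",
    "matched_fragments",
    "rank",
    "multi_hit",
    "blank_pass",
    "blank_threshold",
    "sample_statistic",
    "evidence_count",
    "sample_abundance_mean",
    "blank_abundance_mean",
    "rationale",
]


def write_results(
    assignments: Sequence,
    path: str | Path,
    config: Mapping[str, object] | None = None,
) -> None:
    """Serialize level assignments to CSV, one row per feature-candidate.

    ``assignments`` is a sequence of :class:`~gcannotate.scoring_engine.
    LevelAssignment`. An empty sequence produces a header-only file.
    """
    rows = []
    for a in assignments:
        base = {
            "feature_id": a.feature_id,
            "level": a.level or "",
            "multi_hit": bool(a.multi_hit),
            "blank_pass": bool(a.blank_pass),
            "blank_threshold": a.blank_threshold,
            "sample_statistic": a.sample_statistic_value,
            "sample_abundance_mean": a.sample_abundance_mean,
            "blank_abundance_mean": a.blank_abundance_mean,
        }
        if a.candidates:
            for rank, ev in enumerate(a.candidates, start=1):
                rows.append(
                    {
                        **base,
                        "candidate_name": ev.candidate.name,
                        "candidate_identifier": ev.candidate.identifier,
                        "si": ev.si,
                        "rsi": ev.rsi,
                        "delta_ri": "" if ev.delta_ri is None else ev.delta_ri,
                        "ri_source": ev.ri_source,
                        "rhrmf": "" if ev.rhrmf is None else ev.rhrmf,
                        "molecular_ion": bool(ev.molecular_ion),
                        "matched_fragments": ev.matched_fragments,
                        "rank": rank,
                        "evidence_count": (
                            "" if ev.evidence_count is None else ev.evidence_count
                        ),
                        "rationale": " | ".join(a.rationale),
                    }
                )
        else:
            rows.append(
                {
                    **base,
                    "candidate_name": "",
                    "candidate_identifier": "",
                    "si": "",
                    "rsi": "",
                    "delta_ri": "",
                    "ri_source": "",
                    "rhrmf": "",
                    "molecular_ion": "",
                    "matched_fragments": "",
                    "rank": "",
                    "evidence_count": "",
                    "rationale": " | ".join(a.rationale),
                }
            )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        _write_provenance(fh, config)
        df.to_csv(fh, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV back into a DataFrame (provenance lines skipped)."""
    df = pd.read_csv(path, comment="#", dtype={"level": str})
    if list(df.columns) != RESULT_COLUMNS:
        missing = set(RESULT_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"results file missing columns {sorted(missing)}")
    return df
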