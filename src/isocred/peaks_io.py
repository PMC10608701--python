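"""Peak-table and reference-library I/O plus instrument-level filters.

Peak tables are plain CSV/TSV with columns ``mz, rt, intensity`` and an
optional ``snr`` column, one row per centroided LC-MS feature. Reference
libraries are TSV with ``name, formula`` and optional ``rt``; MS2 spectra
live in a companion MSP file keyed by compound name (read and written via
matchms). An optional mzML adapter pulls centroided peaks via pyteomics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .formula import hill_formula, monoisotopic_mass, parse_formula

log = logging.getLogger("isocred")

CONDITIONS = ("U", "C13", "N15", "C13N15")
POLARITIES = ("positive", "negative")
SOURCES = ("ESI", "APCI")

DEFAULT_MZ_RANGE = (70.0, 1000.0)
DEFAULT_MIN_SNR = 5.0


class PeakTableError(ValueError):
    """Malformed peak table (missing columns or unparseable rows)."""


class Peak(NamedTuple):
    """One centroided LC-MS feature."""

    mz: float
    rt: float
    intensity: float
    snr: float
    polarity: str
    source: str
    id: int = -1


@dataclass
class PeakSet:
    """Peaks of one condition x polarity x source, kept sorted by m/z.

    Column arrays (mz, rt, intensity, snr, ids) are aligned; ``ids`` are
    opaque provenance tags (row index on file read, planted-peak id from
    the simulator) used to trace peaks back to ground truth.
    """

    condition: str
    polarity: str
    source: str
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    rt: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    snr: np.ndarray = field(default_factory=lambda: np.empty(0))
    ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        arrs = [np.asarray(a, dtype=float) for a in (self.mz, self.rt, self.intensity, self.snr)]
        n = len(arrs[0])
        if any(len(a) != n for a in arrs):
            raise ValueError("column arrays have unequal lengths")
        ids = np.asarray(self.ids, dtype=np.int64)
        if len(ids) == 0 and n:
            ids = np.arange(n, dtype=np.int64)
        if len(ids) != n:
            raise ValueError("ids length mismatch")
        order = np.argsort(arrs[0], kind="stable")
        self.mz, self.rt, self.intensity, self.snr = (a[order] for a in arrs)
        self.ids = ids[order]

    def __len__(self) -> int:
        return len(self.mz)

    def __getitem__(self, i: int) -> Peak:
        return Peak(
            float(self.mz[i]), float(self.rt[i]), float(self.intensity[i]),
            float(self.snr[i]), self.polarity, self.source, int(self.ids[i]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mz": self.mz, "rt": self.rt, "intensity": self.intensity, "snr": self.snr}
        )


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_peak_table(path, condition: str, polarity: str, source: str) -> PeakSet:
    """Read a peak table (CSV/TSV) into a m/z-sorted :class:`PeakSet`.

    Required columns: mz, rt, intensity; snr is optional and defaults to
    +inf (peaks then always survive the S/N filter). Rows with
    non-numeric values are collected and reported together with their
    0-based row indices; they are never silently dropped.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = {"mz", "rt", "intensity"} - set(df.columns)
    if missing:
        raise PeakTableError(f"{path}: missing required column(s) {sorted(missing)}")
    if "snr" not in df.columns:
        df["snr"] = math.inf
    cols = df[["mz", "rt", "intensity", "snr"]].apply(pd.to_numeric, errors="coerce")
    bad = cols.isna().any(axis=1)
    if bad.any():
        rows = ", ".join(str(i) for i in df.index[bad].tolist())
        raise PeakTableError(f"{path}: non-numeric values in row(s) {rows}")
    if len(df) == 0:
        log.warning("%s: empty peak table (header only)", path)
    return PeakSet(
        condition, polarity, source,
        mz=cols["mz"].to_numpy(), rt=cols["rt"].to_numpy(),
        intensity=cols["intensity"].to_numpy(), snr=cols["snr"].to_numpy(),
        ids=df.index.to_numpy(dtype=np.int64),
    )


def write_peak_table(ps: PeakSet, path) -> None:
    ps.to_dataframe().to_csv(path, sep=_sep_for(path), index=False, float_format="%.6f")


def filter_peaks(
    ps: PeakSet,
    min_snr: float = DEFAULT_MIN_SNR,
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE,
) -> PeakSet:
    """Apply the instrument-level filters: S/N strictly greater than
    ``min_snr`` and m/z inside the scan range (inclusive bounds).

    Idempotent; returns a new PeakSet.
    """
    if min_snr < 0:
        raise ValueError("min_snr must be >= 0")
    lo, hi = mz_range
    if lo >= hi:
        raise ValueError(f"inverted mz_range ({lo}, {hi})")
    keep = (ps.snr > min_snr) & (ps.mz >= lo) & (ps.mz <= hi)
    return PeakSet(
        ps.condition, ps.polarity, ps.source,
        mz=ps.mz[keep], rt=ps.rt[keep], intensity=ps.intensity[keep],
        snr=ps.snr[keep], ids=ps.ids[keep],
    )


# ---------------------------------------------------------------------------
# Reference library


@dataclass(frozen=True)
class ReferenceEntry:
    """Library record standing in for an authenticated standard or a
    spectral-database compound."""

    name: str
    formula: dict[str, int]
    neutral_mass: float
    rt: float | None = None
    ms2: tuple[tuple[float, float], ...] | None = None  # (mz, rel intensity 0-100]

    @property
    def formula_str(self) -> str:
        return hill_formula(self.formula)


def read_msp(path) -> dict[str, list[tuple[float, float]]]:
    """Read an MSP spectral file into {compound name: [(mz, intensity)]}.

    Intensities are rescaled to relative (max = 100).
    """
    from matchms.importing import load_from_msp

    out: dict[str, list[tuple[float, float]]] = {}
    for spec in load_from_msp(str(path), metadata_harmonization=False):
        if spec is None:
            continue
        name = spec.metadata.get("compound_name") or spec.metadata.get("name")
        mz = spec.peaks.mz
        inten = spec.peaks.intensities
        if name is None or len(mz) == 0:
            continue
        rel = inten / inten.max() * 100.0
        out[str(name)] = list(zip(mz.tolist(), rel.tolist()))
    return out


def write_msp(spectra: dict[str, tuple[float, list[tuple[float, float]]]], path) -> None:
    """Write {name: (precursor_mz, [(mz, intensity)])} as MSP via matchms."""
    from matchms import Spectrum
    from matchms.exporting import save_as_msp

    specs = []
    for name, (prec, frags) in spectra.items():
        frags = sorted(frags)
        specs.append(
            Spectrum(
                mz=np.array([f[0] for f in frags], dtype=float),
                intensities=np.array([f[1] for f in frags], dtype=float),
                metadata={"compound_name": name, "precursor_mz": float(prec)},
                metadata_harmonization=False,
            )
        )
    save_as_msp(specs, str(path))


def read_library(path, msp_path=None) -> list[ReferenceEntry]:
    """Read a reference library TSV (columns: name, formula; optional rt,
    neutral_mass) plus an optional companion MSP file with MS2 spectra.

    Neutral masses are always recomputed from the parsed formula; a
    provided mass deviating by more than 1 mDa triggers a warning.
    Unparseable formulas raise with the entry name and offending token.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"name", "formula"} - set(df.columns)
    if missing:
        raise PeakTableError(f"{path}: missing required column(s) {sorted(missing)}")
    ms2 = read_msp(msp_path) if msp_path is not None else {}
    entries: list[ReferenceEntry] = []
    errors: list[str] = []
    for _, row in df.iterrows():
        try:
            counts = parse_formula(str(row["formula"]))
        except ValueError as e:
            errors.append(f"{row['name']}: {e}")
            continue
        mass = monoisotopic_mass(counts)
        if "neutral_mass" in df.columns and pd.notna(row.get("neutral_mass")):
            if abs(float(row["neutral_mass"]) - mass) > 1e-3:
                log.warning(
                    "%s: provided mass %.5f deviates from computed %.5f",
                    row["name"], float(row["neutral_mass"]), mass,
                )
        rt = None
        if "rt" in df.columns and pd.notna(row.get("rt")):
            rt = float(row["rt"])
        spec = ms2.get(str(row["name"]))
        entries.append(
            ReferenceEntry(
                name=str(row["name"]), formula=counts, neutral_mass=mass,
                rt=rt, ms2=tuple(map(tuple, spec)) if spec else None,
            )
        )
    if errors:
        raise PeakTableError(f"{path}: unparseable formula entries: " + "; ".join(errors))
    return entries


def write_library(entries: Sequence[ReferenceEntry], path, msp_path=None) -> None:
    rows = [
        {
            "name": e.name,
            "formula": e.formula_str,
            "neutral_mass": round(e.neutral_mass, 6),
            "rt": e.rt if e.rt is not None else "",
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if msp_path is not None:
        spectra = {
            e.name: (e.neutral_mass, list(e.ms2))
            for e in entries
            if e.ms2
        }
        write_msp(spectra, msp_path)


def read_mzml(path, condition: str, polarity: str, source: str,
              ms_level: int = 1) -> PeakSet:
    """Optional adapter: collect centroided MS1 peaks from an mzML file.

    Expects centroided spectra (profile data is out of scope); every
    (mz, intensity) pair of every matching scan becomes a Peak with the
    scan's retention time and snr = +inf (apply :func:`filter_peaks`
    afterwards as usual).
    """
    from pyteomics import mzml as _mzml

    mzs, rts, intens = [], [], []
    with _mzml.read(str(path)) as reader:
        for scan in reader:
            if scan.get("ms level") != ms_level:
                continue
            rt = float(scan["scanList"]["scan"][0]["scan start time"])
            m = np.asarray(scan["m/z array"], dtype=float)
            i = np.asarray(scan["intensity array"], dtype=float)
            mzs.append(m)
            intens.append(i)
            rts.append(np.full(len(m), rt))
    if not mzs:
        return PeakSet(condition, polarity, source)
    mz = np.concatenate(mzs)
    return PeakSet(
        condition, polarity, source,
        mz=mz, rt=np.concatenate(rts), intensity=np.concatenate(intens),
        snr=np.full(len(mz), math.inf),
    )
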