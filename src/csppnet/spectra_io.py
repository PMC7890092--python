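"""Reading, writing and linking of CID spectra and LC-MS feature tables.

The data model mirrors a four-way spectral database split by instrument
platform (FT = ion-trap Fourier-transform, QTOF = quadrupole time of
flight) and ionization polarity: FTMS_neg, FTMS_pos, QTOF_neg,
QTOF_pos.  Spectra are exchanged as MSP (NIST-style) or MGF; feature
tables as CSV with per-sample abundance columns named
``organ:genotype:replicate``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from matchms import Spectrum as _MatchmsSpectrum
from matchms.exporting import save_as_msp
from matchms.importing import load_from_msp
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Spectrum",
    "Feature",
    "SubDB",
    "SUBDB_LABELS",
    "read_spectra",
    "write_spectra",
    "read_feature_table",
    "write_feature_table",
    "link_spectra_to_features",
]

SUBDB_LABELS = ("FTMS_neg", "FTMS_pos", "QTOF_neg", "QTOF_pos")


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """One CID spectrum with provenance.

    MS/MS (QTOF) and MS2 (ion trap) spectra are both ``ms_level`` 2 and
    are treated as complementary same-compound evidence; MS3 spectra
    carry a ``parent_spectrum_id`` pointing at the MS2 scan whose product
    ion was fragmented.
    """

    spectrum_id: str
    precursor_mz: float
    rt: float  # minutes
    polarity: str  # "neg" | "pos"
    instrument: str  # "FT" | "QTOF"
    ms_level: int = 2
    parent_spectrum_id: Optional[str] = None
    peaks: List[Peak] = field(default_factory=list)
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ms_level == 3 and not self.parent_spectrum_id:
            raise ValueError(f"{self.spectrum_id}: MS3 spectrum requires parent_spectrum_id")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)


@dataclass
class Feature:
    """A chromatographic peak: m/z + retention time with per-sample abundances.

    ``sample_meta`` maps each sample id to its (organ, genotype) pair.
    """

    feature_id: str
    mz: float
    rt: float  # minutes
    polarity: str
    instrument: str
    abundances: Dict[str, float] = field(default_factory=dict)
    sample_meta: Dict[str, Tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError(f"{self.feature_id}: negative retention time")
        if not self.abundances:
            raise ValueError(f"{self.feature_id}: at least one abundance required")
        if not (100.0 <= self.mz <= 1000.0):
            logger.warning(
                "feature %s m/z %.4f outside the default 100-1000 scan range",
                self.feature_id,
                self.mz,
            )

    def organ_abundance(self, organ: str) -> float:
        return sum(
            v for s, v in self.abundances.items() if self.sample_meta.get(s, (None,))[0] == organ
        )


@dataclass
class SubDB:
    """One instrument x polarity partition of the spectral database."""

    label: str
    features: List[Feature] = field(default_factory=list)
    spectra: List[Spectrum] = field(default_factory=list)
    feature_spectra: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in SUBDB_LABELS:
            raise ValueError(f"unknown subDB label {self.label!r}")
        instrument, polarity = self.label.split("_")
        instrument = {"FTMS": "FT", "QTOF": "QTOF"}[instrument]
        for f in self.features:
            if (f.instrument, f.polarity) != (instrument, polarity):
                raise ValueError(
                    f"feature {f.feature_id} ({f.instrument}, {f.polarity}) "
                    f"does not belong in subDB {self.label}"
                )
        for s in self.spectra:
            if (s.instrument, s.polarity) != (instrument, polarity):
                raise ValueError(
                    f"spectrum {s.spectrum_id} ({s.instrument}, {s.polarity}) "
                    f"does not belong in subDB {self.label}"
                )

    @property
    def instrument(self) -> str:
        return {"FTMS": "FT", "QTOF": "QTOF"}[self.label.split("_")[0]]

    @property
    def polarity(self) -> str:
        return self.label.split("_")[1]

    def spectra_by_id(self) -> Dict[str, Spectrum]:
        return {s.spectrum_id: s for s in self.spectra}

    def spectra_for_feature(self, feature_id: str, ms_level: Optional[int] = None) -> List[Spectrum]:
        by_id = self.spectra_by_id()
        out = [by_id[sid] for sid in self.feature_spectra.get(feature_id, []) if sid in by_id]
        if ms_level is not None:
            out = [s for s in out if s.ms_level == ms_level]
        return out


# ---------------------------------------------------------------------------
# Spectra I/O (MSP via matchms, MGF via pyteomics)
# ---------------------------------------------------------------------------

def _polarity_from_text(text: str) -> str:
    t = str(text).strip().lower()
    if t in ("neg", "negative", "-", "1-"):
        return "neg"
    if t in ("pos", "positive", "+", "1+"):
        return "pos"
    raise ValueError(f"cannot interpret ion mode {text!r}")


def read_spectra(path, format: Optional[str] = None) -> List[Spectrum]:
    """Read spectra from an MSP or MGF file.

    Precursor m/z, retention time (seconds converted to minutes), ion
    mode, instrument, MS level and parentage are mapped onto
    :class:`Spectrum` fields.  Records without a precursor m/z are
    skipped with a logged warning; the total skip count is logged once.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").upper()
    format = format.upper()
    if format == "MSP":
        return _read_msp(path)
    if format == "MGF":
        return _read_mgf(path)
    raise ValueError(f"unsupported spectra format {format!r}")


def _read_msp(path: Path) -> List[Spectrum]:
    out: List[Spectrum] = []
    skipped = 0
    for i, ms in enumerate(load_from_msp(str(path), metadata_harmonization=False)):
        meta = {k.lower(): v for k, v in ms.metadata.items()}
        precursor = meta.get("precursor_mz") or meta.get("precursormz")
        if precursor is None:
            skipped += 1
            logger.warning("MSP record %d in %s lacks a precursor m/z; skipped", i, path)
            continue
        rt = float(meta.get("retention_time", meta.get("retentiontime", 0.0)) or 0.0)
        ms_level = int(meta.get("ms_level", meta.get("spectrum_type", "2").lstrip("MSms") or 2))
        out.append(
            Spectrum(
                spectrum_id=str(meta.get("compound_name", meta.get("name", f"spec{i}"))),
                precursor_mz=float(precursor),
                rt=rt,
                polarity=_polarity_from_text(meta.get("ionmode", meta.get("ion_mode", "neg"))),
                instrument=str(meta.get("instrument", "FT")),
                ms_level=ms_level,
                parent_spectrum_id=meta.get("parent_spectrum") or None,
                peaks=[Peak(float(m), float(h)) for m, h in zip(ms.peaks.mz, ms.peaks.intensities)],
                sample_id=meta.get("sample_id") or None,
            )
        )
    if skipped:
        logger.warning("%d MSP records skipped in %s (missing precursor m/z)", skipped, path)
    return out


def _read_mgf(path: Path) -> List[Spectrum]:
    out: List[Spectrum] = []
    skipped = 0
    with _mgf.MGF(str(path)) as reader:
        for i, rec in enumerate(reader):
            params = rec["params"]
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                skipped += 1
                logger.warning("MGF record %d in %s lacks PEPMASS; skipped", i, path)
                continue
            rt = params.get("rtinseconds")
            if rt is not None:
                rt = float(rt) / 60.0
            else:
                rt = float(params.get("retentiontime", 0.0))
            charge = params.get("charge")
            if charge:
                polarity = "neg" if int(charge[0]) < 0 else "pos"
            else:
                polarity = _polarity_from_text(params.get("ionmode", "neg"))
            out.append(
                Spectrum(
                    spectrum_id=str(params.get("title", f"spec{i}")),
                    precursor_mz=float(pepmass[0]),
                    rt=rt,
                    polarity=polarity,
                    instrument=str(params.get("instrument", "QTOF")),
                    ms_level=int(params.get("mslevel", 2)),
                    parent_spectrum_id=params.get("parent_spectrum") or None,
                    peaks=[
                        Peak(float(m), float(h))
                        for m, h in zip(rec["m/z array"], rec["intensity array"])
                    ],
                    sample_id=params.get("sample_id") or None,
                )
            )
    if skipped:
        logger.warning("%d MGF records skipped in %s (missing PEPMASS)", skipped, path)
    return out


def write_spectra(spectra: Sequence[Spectrum], path, format: Optional[str] = None) -> None:
    """Write spectra to MSP (via matchms) or MGF (via pyteomics)."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").upper()
    format = format.upper()
    if format == "MSP":
        ms_list = []
        for s in spectra:
            meta = {
                "compound_name": s.spectrum_id,
                "precursor_mz": s.precursor_mz,
                "retention_time": s.rt,
                "ionmode": "negative" if s.polarity == "neg" else "positive",
                "instrument": s.instrument,
                "ms_level": s.ms_level,
            }
            if s.parent_spectrum_id:
                meta["parent_spectrum"] = s.parent_spectrum_id
            if s.sample_id:
                meta["sample_id"] = s.sample_id
            ms_list.append(
                _MatchmsSpectrum(
                    mz=np.asarray([p.mz for p in s.peaks], dtype=float),
                    intensities=np.asarray([p.intensity for p in s.peaks], dtype=float),
                    metadata=meta,
                    metadata_harmonization=False,
                )
            )
        if path.exists():
            path.unlink()  # save_as_msp appends
        save_as_msp(ms_list, str(path))
    elif format == "MGF":
        recs = []
        for s in spectra:
            params = {
                "title": s.spectrum_id,
                "pepmass": (s.precursor_mz, None),
                "rtinseconds": s.rt * 60.0,
                "charge": "1-" if s.polarity == "neg" else "1+",
                "instrument": s.instrument,
                "mslevel": s.ms_level,
            }
            if s.parent_spectrum_id:
                params["parent_spectrum"] = s.parent_spectrum_id
            if s.sample_id:
                params["sample_id"] = s.sample_id
            recs.append(
                {
                    "m/z array": np.asarray([p.mz for p in s.peaks], dtype=float),
                    "intensity array": np.asarray([p.intensity for p in s.peaks], dtype=float),
                    "params": params,
                }
            )
        _mgf.write(recs, str(path), file_mode="w")
    else:
        raise ValueError(f"unsupported spectra format {format!r}")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

_META_COLUMNS = ["feature_id", "mz", "rt", "polarity", "instrument"]


def read_feature_table(path) -> List[Feature]:
    """Read a feature table CSV.

    Columns: ``feature_id, mz, rt, polarity, instrument`` followed by one
    column per sample named ``organ:genotype:replicate``.  Missing
    abundances read as 0; duplicate feature ids and non-numeric
    abundances are rejected.
    """
    df = pd.read_csv(path, dtype={"feature_id": str}, float_precision="round_trip")
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ValueError(f"duplicate feature_id: {dup!r}")
    sample_cols = [c for c in df.columns if c not in _META_COLUMNS]
    sample_meta: Dict[str, Tuple[str, str]] = {}
    for c in sample_cols:
        parts = c.split(":")
        if len(parts) < 2:
            raise ValueError(f"sample column {c!r} is not of the form organ:genotype[:replicate]")
        sample_meta[c] = (parts[0], parts[1])
    features: List[Feature] = []
    for ridx, row in df.iterrows():
        abundances = {}
        for c in sample_cols:
            v = row[c]
            if pd.isna(v):
                v = 0.0
            try:
                v = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric abundance at row {ridx}, column {c!r}: {row[c]!r}"
                ) from None
            abundances[c] = v
        features.append(
            Feature(
                feature_id=str(row["feature_id"]),
                mz=float(row["mz"]),
                rt=float(row["rt"]),
                polarity=str(row["polarity"]),
                instrument=str(row["instrument"]),
                abundances=abundances,
                sample_meta=dict(sample_meta),
            )
        )
    return features


def write_feature_table(features: Sequence[Feature], path) -> None:
    if not features:
        pd.DataFrame(columns=_META_COLUMNS).to_csv(path, index=False)
        return
    sample_cols = sorted({s for f in features for s in f.abundances})
    rows = []
    for f in features:
        row = {
            "feature_id": f.feature_id,
            "mz": f.mz,
            "rt": f.rt,
            "polarity": f.polarity,
            "instrument": f.instrument,
        }
        for c in sample_cols:
            row[c] = f.abundances.get(c, 0.0)
        rows.append(row)
    pd.DataFrame(rows, columns=_META_COLUMNS + sample_cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature <-> spectrum linkage
# ---------------------------------------------------------------------------

def link_spectra_to_features(
    subdb: SubDB, mz_tol: float = 0.01, rt_tol: float = 0.5
) -> Dict[str, List[str]]:
    """Associate each spectrum with its nearest feature in (m/z, RT).

    A spectrum links to the feature minimizing \\|dmz\\| subject to
    \\|dmz\\| <= mz_tol and \\|drt\\| <= rt_tol.  The resulting index is
    stored on the subDB and returned; unlinked spectra are counted and
    logged.
    """
    index: Dict[str, List[str]] = {}
    if subdb.features:
        order = np.argsort([f.mz for f in subdb.features])
        feats = [subdb.features[i] for i in order]
        mzs = np.array([f.mz for f in feats])
    else:
        feats, mzs = [], np.array([])
    unlinked = 0
    for s in subdb.spectra:
        lo = np.searchsorted(mzs, s.precursor_mz - mz_tol, side="left")
        hi = np.searchsorted(mzs, s.precursor_mz + mz_tol, side="right")
        best = None
        for f in feats[lo:hi]:
            if abs(f.rt - s.rt) > rt_tol:
                continue
            dmz = abs(f.mz - s.precursor_mz)
            if best is None or dmz < best[0]:
                best = (dmz, f.feature_id)
        if best is None:
            unlinked += 1
            continue
        index.setdefault(best[1], []).append(s.spectrum_id)
    if unlinked:
        logger.info("%d/%d spectra unlinked in %s", unlinked, len(subdb.spectra), subdb.label)
    subdb.feature_spectra = index
    return index
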