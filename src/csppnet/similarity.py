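"""CID spectral similarity scoring and spectral-library matching.

The score is a weighted cosine over greedily matched fragment peaks:
peaks of the two spectra are paired within an m/z tolerance, closest
|dmz| first, each peak used at most once, and the score is the dot
product of the weighted intensities of the paired peaks normalized by
the weighted norms of both full spectra (weight = intensity^p * mz^q,
default p = 0.5, q = 0: square-root intensity weighting).  Identical
spectra score 1; spectra without any peak pair within tolerance score
0.  A threshold of 0.6 is the conventional cut-off for calling a
library match positive.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .spectra_io import Spectrum

__all__ = ["SimilarityScore", "cosine_similarity", "library_match", "write_match_report"]


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    n_matched_peaks: int


def _weights(mz: np.ndarray, intensity: np.ndarray, p: float, q: float) -> np.ndarray:
    w = np.power(np.clip(intensity, 0.0, None), p)
    if q != 0.0:
        w = w * np.power(mz, q)
    return w


def cosine_similarity(
    a: Spectrum,
    b: Spectrum,
    mz_tol: float = 0.01,
    intensity_power: float = 0.5,
    mz_power: float = 0.0,
) -> SimilarityScore:
    """Greedy-matched weighted cosine similarity between two spectra.

    Candidate peak pairs within ``mz_tol`` are accepted in order of
    increasing |dmz| (ties broken symmetrically on the pair's m/z sum
    then gap), each peak participating at most once.  The score is
    symmetric in argument order and lies in [0, 1].
    """
    if not a.peaks or not b.peaks:
        raise ValueError("cosine_similarity requires non-empty spectra")
    mza, inta = a.mz_array, a.intensity_array
    mzb, intb = b.mz_array, b.intensity_array
    wa = _weights(mza, inta, intensity_power, mz_power)
    wb = _weights(mzb, intb, intensity_power, mz_power)
    norm = float(np.linalg.norm(wa) * np.linalg.norm(wb))
    if norm == 0.0:
        return SimilarityScore(0.0, 0)

    # enumerate candidate pairs within tolerance via two-pointer windows
    cands: List[Tuple[float, float, float, int, int]] = []
    lo = 0
    for i, m in enumerate(mza):
        while lo < len(mzb) and mzb[lo] < m - mz_tol:
            lo += 1
        j = lo
        while j < len(mzb) and mzb[j] <= m + mz_tol:
            d = abs(m - mzb[j])
            # sort key symmetric under argument swap
            cands.append((d, m + mzb[j], abs(m - mzb[j]), i, j))
            j += 1
    cands.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a = np.zeros(len(mza), dtype=bool)
    used_b = np.zeros(len(mzb), dtype=bool)
    dot = 0.0
    n_matched = 0
    for _, _, _, i, j in cands:
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = True
        used_b[j] = True
        dot += wa[i] * wb[j]
        n_matched += 1
    value = min(1.0, dot / norm)
    if n_matched == 0:
        value = 0.0
    return SimilarityScore(float(value), n_matched)


def library_match(
    query: Spectrum,
    library: Sequence[Spectrum],
    sim_threshold: float = 0.6,
    precursor_tol: float = 0.01,
    mz_tol: float = 0.01,
    intensity_power: float = 0.5,
    mz_power: float = 0.0,
) -> List[Tuple[Spectrum, SimilarityScore]]:
    """Match one query spectrum against a spectral library.

    Candidates are prefiltered on |precursor delta| <= ``precursor_tol``;
    hits are candidates scoring >= ``sim_threshold`` (inclusive), sorted
    by score descending then |precursor delta| ascending.
    """
    if not library:
        raise ValueError("library must be non-empty")
    hits: List[Tuple[Spectrum, SimilarityScore]] = []
    for entry in library:
        d = abs(entry.precursor_mz - query.precursor_mz)
        if d > precursor_tol:
            continue
        score = cosine_similarity(
            query, entry, mz_tol=mz_tol, intensity_power=intensity_power, mz_power=mz_power
        )
        if score.value >= sim_threshold:
            hits.append((entry, score))
    hits.sort(key=lambda t: (-t[1].value, abs(t[0].precursor_mz - query.precursor_mz), t[0].spectrum_id))
    return hits


def write_match_report(
    rows: Sequence[Tuple[str, str, SimilarityScore, float]], path
) -> None:
    """Write a delimited match report.

    ``rows`` are (query_id, library_id, score, precursor_delta) tuples.
    """
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["query_id", "library_id", "score", "n_matched_peaks", "precursor_delta"])
        for query_id, library_id, score, delta in rows:
            writer.writerow([query_id, library_id, f"{score.value:.6f}", score.n_matched_peaks, f"{delta:.6f}"])
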