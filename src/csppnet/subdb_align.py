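"""Cross-instrument and cross-polarity alignment of spectral sub-databases.

Features recorded on different platforms (FT vs QTOF) or polarities
(neg vs pos) are aligned by combining three pieces of evidence: the
ions must agree in neutral mass, the retention times must agree after a
robust monotone RT mapping between the two chromatographic systems, and
the CID spectra of the two features must be similar.  Only features
carrying at least one level-2 CID spectrum take part.  Retained pairs
are mutual best hits, so every feature appears in at most one pair.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .chem import PROTON_MASS
from .similarity import SimilarityScore, cosine_similarity
from .spectra_io import Feature, Spectrum, SubDB

logger = logging.getLogger(__name__)

__all__ = [
    "RtMap",
    "AlignmentPair",
    "AlignmentResult",
    "fit_rt_map",
    "align_subdbs",
    "alignment_proportion",
    "percentage",
]


@dataclass
class RtMap:
    """A robust monotone (Theil-Sen) linear map rt_A -> rt_B.

    ``residual_scale`` is 1.4826 x the median absolute residual of the
    anchors about the fit, i.e. a robust sigma estimate in minutes.
    """

    slope: float
    intercept: float
    residual_scale: float
    anchors: List[Tuple[float, float]] = field(default_factory=list)

    def predict(self, rt_a: float) -> float:
        return self.slope * rt_a + self.intercept


def fit_rt_map(anchor_pairs: Sequence[Tuple[float, float]]) -> RtMap:
    """Fit a robust monotone line through (rt_A, rt_B) anchor pairs.

    Theil-Sen (median of pairwise slopes) with the slope clipped to be
    non-negative; requires at least 3 anchors, otherwise the caller
    should fall back to an identity mapping.
    """
    if len(anchor_pairs) < 3:
        raise ValueError(
            f"fit_rt_map requires >= 3 anchor pairs, got {len(anchor_pairs)}; "
            "consider an identity mapping"
        )
    x = np.array([p[0] for p in anchor_pairs], dtype=float)
    y = np.array([p[1] for p in anchor_pairs], dtype=float)
    if np.ptp(x) == 0.0:
        slope, intercept = 0.0, float(np.median(y))
    else:
        slope, intercept, _, _ = stats.theilslopes(y, x)
        if slope < 0.0:
            slope = 0.0
            intercept = float(np.median(y))
    resid = y - (slope * x + intercept)
    scale = 1.4826 * float(np.median(np.abs(resid)))
    return RtMap(
        slope=float(slope),
        intercept=float(intercept),
        residual_scale=max(scale, 1e-6),
        anchors=list(anchor_pairs),
    )


def identity_rt_map() -> RtMap:
    return RtMap(slope=1.0, intercept=0.0, residual_scale=1e-6)


@dataclass(frozen=True)
class AlignmentPair:
    feature_a: str
    feature_b: str
    similarity: SimilarityScore
    rt_a: float
    rt_b: float
    rt_residual: float
    mass_delta: float


@dataclass
class AlignmentResult:
    label_a: str
    label_b: str
    pairs: List[AlignmentPair]
    rt_map: RtMap
    n_features_a: int
    n_features_b: int
    n_without_spectra_a: int
    n_without_spectra_b: int

    @property
    def proportion_a(self) -> float:
        return alignment_proportion(len(self.pairs), self.n_features_a)

    @property
    def proportion_b(self) -> float:
        return alignment_proportion(len(self.pairs), self.n_features_b)

    def summary(self) -> str:
        """Counts with parenthetical proportions, one line per side."""
        n = len(self.pairs)
        return (
            f"{self.label_a} vs {self.label_b}: {n} aligned features\n"
            f"  vs {self.label_a}: {n} ({self.proportion_a:.2f}) of {self.n_features_a}\n"
            f"  vs {self.label_b}: {n} ({self.proportion_b:.2f}) of {self.n_features_b}\n"
            f"  without level-2 spectra: {self.n_without_spectra_a} ({self.label_a}), "
            f"{self.n_without_spectra_b} ({self.label_b})"
        )


def alignment_proportion(n_aligned: int, n_total: int) -> float:
    """Aligned-feature proportion, rounded to the conventional 2 decimals."""
    if n_total <= 0:
        return 0.0
    return round(n_aligned / n_total, 2)


def percentage(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage of a count ratio at the stated precision."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


def _mass_match(mz_a: float, mz_b: float, pol_a: str, pol_b: str, mode: str, tol: float) -> Optional[float]:
    """Return the neutral-mass discrepancy if within tolerance, else None."""
    if mode == "same_polarity":
        d = mz_a - mz_b
    else:
        # [M+H]+ minus [M-H]- of the same compound differs by 2 protons
        mz_pos, mz_neg = (mz_a, mz_b) if pol_a == "pos" else (mz_b, mz_a)
        d = mz_pos - mz_neg - 2.0 * PROTON_MASS
    return d if abs(d) <= tol else None


def align_subdbs(
    a: SubDB,
    b: SubDB,
    sim_threshold: float = 0.6,
    rt_tol: Optional[float] = None,
    mass_mode: Optional[str] = None,
    mass_tol: float = 0.02,
    mz_tol: Optional[float] = None,
    seed_sim_threshold: float = 0.8,
) -> AlignmentResult:
    """Align the features of two sub-databases.

    Two-pass procedure: high-confidence candidate pairs (spectral
    similarity >= ``seed_sim_threshold`` and neutral-mass agreement)
    seed a robust RT map; the full pass then requires mass agreement
    within ``mass_tol``, RT agreement within ``rt_tol`` (default:
    3 x the RT map's residual scale, floored at 0.25 min) after RT
    correction, and spectral similarity >= ``sim_threshold`` between the
    level-2 spectra of the two features.  Retained pairs are mutual best
    hits ranked by similarity, ties broken by smaller |RT residual|.

    Features without any level-2 spectrum are non-alignable and only
    counted.  The result is symmetric: aligning (B, A) yields the same
    pair set as (A, B).
    """
    if a.label == b.label:
        raise ValueError("cannot align a subDB with itself (labels equal)")
    # canonical orientation for exact (A,B)/(B,A) symmetry
    if a.label > b.label:
        res = align_subdbs(
            b,
            a,
            sim_threshold=sim_threshold,
            rt_tol=rt_tol,
            mass_mode=mass_mode,
            mass_tol=mass_tol,
            mz_tol=mz_tol,
            seed_sim_threshold=seed_sim_threshold,
        )
        return AlignmentResult(
            label_a=a.label,
            label_b=b.label,
            pairs=[
                AlignmentPair(
                    feature_a=p.feature_b,
                    feature_b=p.feature_a,
                    similarity=p.similarity,
                    rt_a=p.rt_b,
                    rt_b=p.rt_a,
                    rt_residual=p.rt_residual,
                    mass_delta=-p.mass_delta,
                )
                for p in res.pairs
            ],
            rt_map=res.rt_map,
            n_features_a=res.n_features_b,
            n_features_b=res.n_features_a,
            n_without_spectra_a=res.n_without_spectra_b,
            n_without_spectra_b=res.n_without_spectra_a,
        )

    if mass_mode is None:
        mass_mode = "same_polarity" if a.polarity == b.polarity else "cross_polarity"
    if mass_mode == "same_polarity" and a.polarity != b.polarity:
        raise ValueError("same_polarity mode requires equal polarities")
    if mass_mode == "cross_polarity" and a.polarity == b.polarity:
        raise ValueError("cross_polarity mode requires different polarities")
    if mz_tol is None:
        # cross-instrument similarity uses the looser instrument tolerance
        mz_tol = 0.05 if "QTOF" in (a.instrument, b.instrument) else 0.01

    spectra_a = {f.feature_id: a.spectra_for_feature(f.feature_id, ms_level=2) for f in a.features}
    spectra_b = {f.feature_id: b.spectra_for_feature(f.feature_id, ms_level=2) for f in b.features}
    feats_a = [f for f in a.features if spectra_a[f.feature_id]]
    feats_b = [f for f in b.features if spectra_b[f.feature_id]]
    n_wo_a = len(a.features) - len(feats_a)
    n_wo_b = len(b.features) - len(feats_b)

    feats_b_sorted = sorted(feats_b, key=lambda f: f.mz)
    mzb = np.array([f.mz for f in feats_b_sorted])

    def mass_candidates(f: Feature) -> List[Tuple[Feature, float]]:
        if mass_mode == "same_polarity":
            target = f.mz
        elif f.polarity == "neg":  # b is positive
            target = f.mz + 2.0 * PROTON_MASS
        else:
            target = f.mz - 2.0 * PROTON_MASS
        lo = np.searchsorted(mzb, target - mass_tol, side="left")
        hi = np.searchsorted(mzb, target + mass_tol, side="right")
        out = []
        for g in feats_b_sorted[lo:hi]:
            d = _mass_match(f.mz, g.mz, f.polarity, g.polarity, mass_mode, mass_tol)
            if d is not None:
                out.append((g, d))
        return out

    def _to_neg_scale(spec: Spectrum) -> Spectrum:
        # opposite-polarity spectra are compared on a common ion scale:
        # [frag+H]+ peaks sit 2 x proton above the matching [frag-H]- peaks
        from .spectra_io import Peak

        return Spectrum(
            spectrum_id=spec.spectrum_id,
            precursor_mz=spec.precursor_mz - 2.0 * PROTON_MASS,
            rt=spec.rt,
            polarity="neg",
            instrument=spec.instrument,
            ms_level=spec.ms_level,
            parent_spectrum_id=spec.parent_spectrum_id,
            peaks=[Peak(p.mz - 2.0 * PROTON_MASS, p.intensity) for p in spec.peaks],
        )

    def best_similarity(fa: Feature, fb: Feature) -> SimilarityScore:
        best = SimilarityScore(0.0, 0)
        for sa in spectra_a[fa.feature_id]:
            if mass_mode == "cross_polarity" and sa.polarity == "pos":
                sa = _to_neg_scale(sa)
            for sb in spectra_b[fb.feature_id]:
                if mass_mode == "cross_polarity" and sb.polarity == "pos":
                    sb = _to_neg_scale(sb)
                s = cosine_similarity(sa, sb, mz_tol=mz_tol)
                if s.value > best.value:
                    best = s
        return best

    # pass 1: seed the RT map with high-confidence matches (no RT constraint)
    seeds: List[Tuple[float, float]] = []
    for f in feats_a:
        for g, _ in mass_candidates(f):
            s = best_similarity(f, g)
            if s.value >= seed_sim_threshold:
                seeds.append((f.rt, g.rt))
    if len(seeds) >= 3:
        rt_map = fit_rt_map(seeds)
    else:
        logger.warning(
            "only %d high-similarity seed pairs between %s and %s; using identity RT map",
            len(seeds),
            a.label,
            b.label,
        )
        rt_map = identity_rt_map()
    if rt_tol is None:
        rt_tol = max(0.25, 3.0 * rt_map.residual_scale)

    # pass 2: full candidate evaluation with the fitted RT correction
    best_of_a: Dict[str, Tuple[float, float, str, AlignmentPair]] = {}
    best_of_b: Dict[str, Tuple[float, float, str, AlignmentPair]] = {}
    for f in feats_a:
        for g, mass_d in mass_candidates(f):
            resid = g.rt - rt_map.predict(f.rt)
            if abs(resid) > rt_tol:
                continue
            s = best_similarity(f, g)
            if s.value < sim_threshold:
                continue
            pair = AlignmentPair(
                feature_a=f.feature_id,
                feature_b=g.feature_id,
                similarity=s,
                rt_a=f.rt,
                rt_b=g.rt,
                rt_residual=resid,
                mass_delta=mass_d,
            )
            key = (-s.value, abs(resid), g.feature_id)
            cur = best_of_a.get(f.feature_id)
            if cur is None or key < (cur[0], cur[1], cur[2]):
                best_of_a[f.feature_id] = (key[0], key[1], key[2], pair)
            key_b = (-s.value, abs(resid), f.feature_id)
            cur = best_of_b.get(g.feature_id)
            if cur is None or key_b < (cur[0], cur[1], cur[2]):
                best_of_b[g.feature_id] = (key_b[0], key_b[1], key_b[2], pair)

    pairs = []
    for fid, (_, _, _, pair) in sorted(best_of_a.items()):
        other = best_of_b.get(pair.feature_b)
        if other is not None and other[3] is pair:
            pairs.append(pair)

    return AlignmentResult(
        label_a=a.label,
        label_b=b.label,
        pairs=pairs,
        rt_map=rt_map,
        n_features_a=len(a.features),
        n_features_b=len(b.features),
        n_without_spectra_a=n_wo_a,
        n_without_spectra_b=n_wo_b,
    )


def write_alignment_report(result: AlignmentResult, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["feature_a", "feature_b", "similarity", "rt_a", "rt_b", "rt_residual", "mass_delta"]
        )
        for p in result.pairs:
            writer.writerow(
                [
                    p.feature_a,
                    p.feature_b,
                    f"{p.similarity.value:.6f}",
                    f"{p.rt_a:.4f}",
                    f"{p.rt_b:.4f}",
                    f"{p.rt_residual:.4f}",
                    f"{p.mass_delta:.6f}",
                ]
            )
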