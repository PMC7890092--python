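"""Mass-difference census over LC-MS feature tables.

For each (organ, genotype) group, all pairwise m/z differences between
features detected in that group are binned at 0.001 Da over [0, 250) Da,
yielding a Manhattan-style frequency profile.  Mass differences that
recur far more often than their local background are candidate
biotransformations: each bin is compared against a local frequency
threshold (median + k x MAD of the counts in a +/-0.25 Da window,
floored at a minimum count), and bins exceeding the threshold in at
least one (organ, genotype) are selected.  Selected bins are ranked by
their threshold-normalized frequency into order-of-importance (OOI)
numbers, partitioned across organs into Venn regions, and annotated
against a biotransformation catalog.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import Biotransformation
from .spectra_io import Feature

__all__ = [
    "MassDiffHistogram",
    "CandidateBiotransformation",
    "compute_histogram",
    "local_threshold",
    "select_candidates",
    "organ_venn",
    "annotate_candidates",
    "manhattan_table",
    "candidate_table",
    "plot_manhattan",
]

GroupKey = Tuple[str, str]  # (organ, genotype)


@dataclass
class MassDiffHistogram:
    """Binned pairwise mass-difference counts per (organ, genotype)."""

    bin_width: float
    max_delta: float
    counts: Dict[GroupKey, np.ndarray]
    n_features: Dict[GroupKey, int]

    @property
    def n_bins(self) -> int:
        return int(round(self.max_delta / self.bin_width))

    def bin_label(self, index: int) -> float:
        """Lower edge of a bin (the bin's reported mass-difference label)."""
        return round(index * self.bin_width, 6)

    @property
    def groups(self) -> List[GroupKey]:
        return sorted(self.counts)

    @property
    def organs(self) -> List[str]:
        return sorted({o for o, _ in self.counts})

    @property
    def genotypes(self) -> List[str]:
        return sorted({g for _, g in self.counts})


def compute_histogram(
    features: Sequence[Feature],
    bin_width: float = 0.001,
    max_delta: float = 250.0,
    abundance_floor: float = 0.0,
) -> MassDiffHistogram:
    """Census of pairwise |m/z| differences per (organ, genotype) group.

    A feature participates in a group's census only if its abundance in
    at least one of that group's samples exceeds ``abundance_floor``.
    Differences >= ``max_delta`` are dropped; bins use floor binning
    (labelled by their lower edge), so a physical delta straddling a bin
    edge may populate two adjacent bins.
    """
    polarities = {f.polarity for f in features}
    if len(polarities) > 1:
        raise ValueError(f"features must share polarity, got {sorted(polarities)}")
    n_bins = int(round(max_delta / bin_width))
    groups: Dict[GroupKey, List[float]] = {}
    all_groups = sorted(
        {meta for f in features for meta in f.sample_meta.values()}
    )
    for key in all_groups:
        groups[key] = []
    for f in features:
        present: set = set()
        for sample, ab in f.abundances.items():
            meta = f.sample_meta.get(sample)
            if meta is not None and ab > abundance_floor:
                present.add(meta)
        for key in present:
            groups.setdefault(key, []).append(f.mz)
    counts: Dict[GroupKey, np.ndarray] = {}
    n_features: Dict[GroupKey, int] = {}
    for key, mzs in groups.items():
        vec = np.zeros(n_bins, dtype=np.int64)
        arr = np.sort(np.asarray(mzs, dtype=float))
        n_features[key] = arr.size
        for i in range(arr.size):
            hi = np.searchsorted(arr, arr[i] + max_delta, side="left")
            if hi <= i + 1:
                continue
            diffs = arr[i + 1 : hi] - arr[i]
            # 1e-6 of a bin (~1e-9 Da) guards against float representation
            # pushing an exact-edge delta into the bin below
            idx = np.floor(diffs / bin_width + 1e-6).astype(np.int64)
            idx = idx[idx < n_bins]  # guard float-edge spillover
            np.add.at(vec, idx, 1)
        counts[key] = vec
    return MassDiffHistogram(
        bin_width=bin_width, max_delta=max_delta, counts=counts, n_features=n_features
    )


def _rolling_sum(x: np.ndarray, halfwidth: int) -> np.ndarray:
    """Sum over a centered window of +/-halfwidth bins, excluding the center."""
    pad = np.pad(x.astype(np.int64), halfwidth, mode="reflect")
    csum = np.concatenate([[0], np.cumsum(pad)])
    n = x.size
    idx = np.arange(n)
    total = csum[idx + 2 * halfwidth + 1] - csum[idx]
    return total - x


def _window_threshold_exact(
    counts: np.ndarray, indices: np.ndarray, halfwidth: int, k: float, min_count: float
) -> np.ndarray:
    """Exact median + k*MAD threshold at the given bin indices."""
    pad = np.pad(counts.astype(np.float64), halfwidth, mode="reflect")
    out = np.empty(indices.size, dtype=float)
    for out_i, b in enumerate(indices):
        window = pad[b : b + 2 * halfwidth + 1]
        window = np.delete(window, halfwidth)  # exclude the bin itself
        med = np.median(window)
        mad = np.median(np.abs(window - med))
        out[out_i] = max(min_count, med + k * mad)
    return out


def local_threshold(
    h: MassDiffHistogram,
    window_halfwidth: float = 0.25,
    k: float = 5.0,
    min_count: float = 5.0,
) -> Dict[GroupKey, np.ndarray]:
    """Local frequency threshold per bin and (organ, genotype) group.

    threshold(b) = max(min_count, median_W(b) + k * MAD_W(b)) where W is
    the window of bins within +/-``window_halfwidth`` Da of b, excluding
    b itself (reflected at the range edges).  Over the sparse regions
    that dominate a real census (more than half of the window empty) the
    median and MAD are exactly 0, so the threshold reduces to
    ``min_count``; that shortcut keeps the scan over 250,000 bins cheap
    without changing the result.
    """
    hw = int(round(window_halfwidth / h.bin_width))
    if hw < 10:
        raise ValueError("window_halfwidth must be at least 10 bins wide")
    out: Dict[GroupKey, np.ndarray] = {}
    for key, counts in h.counts.items():
        thresh = np.full(counts.size, float(min_count))
        nz = (counts > 0).astype(np.int64)
        n_nonzero = _rolling_sum(nz, hw)
        window_size = 2 * hw  # center excluded
        dense = np.nonzero(n_nonzero * 2 >= window_size)[0]
        if dense.size:
            thresh[dense] = _window_threshold_exact(counts, dense, hw, k, float(min_count))
        out[key] = thresh
    return out


@dataclass
class CandidateBiotransformation:
    """A selected mass-difference bin with its per-group statistics.

    ``bin_center`` is the bin's reported label (its lower edge, matching
    floor binning).  ``ooi`` holds per-(organ, genotype) dense ranks of
    the threshold-normalized frequency (rank 1 = most frequent);
    ``organ_ooi``/``organ_avooi`` are the minimum resp. mean across
    genotypes, and ``organ_exceeds`` flags organs where the bin exceeds
    its local threshold in at least one genotype.
    """

    bin_index: int
    bin_center: float
    count: Dict[GroupKey, int]
    threshold: Dict[GroupKey, float]
    normalized_frequency: Dict[GroupKey, float]
    exceeds: Dict[GroupKey, bool]
    ooi: Dict[GroupKey, int]
    organ_ooi: Dict[str, int] = field(default_factory=dict)
    organ_avooi: Dict[str, float] = field(default_factory=dict)
    organ_exceeds: Dict[str, bool] = field(default_factory=dict)
    annotations: List[Biotransformation] = field(default_factory=list)

    @property
    def selected(self) -> bool:
        return any(self.exceeds.values())

    @property
    def annotation_label(self) -> str:
        if not self.annotations:
            return "Unknown"
        return "; ".join(bt.short_code for bt in self.annotations)


def _dense_rank_desc(values: np.ndarray) -> np.ndarray:
    """Dense descending rank (1 = largest; ties share a rank)."""
    order = np.argsort(-values, kind="stable")
    ranks = np.empty(values.size, dtype=np.int64)
    rank = 0
    prev = None
    for pos in order:
        v = values[pos]
        if prev is None or v != prev:
            rank += 1
            prev = v
        ranks[pos] = rank
    return ranks


def select_candidates(
    h: MassDiffHistogram, thresholds: Mapping[GroupKey, np.ndarray]
) -> List[CandidateBiotransformation]:
    """Select bins exceeding their local threshold in >= 1 (organ, genotype).

    Exceedance is strict (count > threshold), so a flat background
    selects nothing.  OOI numbers are dense descending ranks of the
    normalized frequency (count / threshold) computed per (organ,
    genotype) over all occupied bins; the per-organ OOI is the minimum
    across genotypes and avOOI the mean.  Candidates are returned in
    ascending bin order.
    """
    groups = h.groups
    nf: Dict[GroupKey, np.ndarray] = {}
    exceeds: Dict[GroupKey, np.ndarray] = {}
    for key in groups:
        counts = h.counts[key].astype(float)
        thr = np.asarray(thresholds[key], dtype=float)
        nf[key] = counts / thr
        exceeds[key] = counts > thr
    selected_mask = np.zeros(h.n_bins, dtype=bool)
    for key in groups:
        selected_mask |= exceeds[key]
    selected_bins = np.nonzero(selected_mask)[0]

    # OOI ranks per group over occupied bins
    ooi_per_group: Dict[GroupKey, Dict[int, int]] = {}
    for key in groups:
        occupied = np.nonzero(h.counts[key] > 0)[0]
        ranks = _dense_rank_desc(nf[key][occupied])
        ooi_per_group[key] = dict(zip(occupied.tolist(), ranks.tolist()))

    organs = h.organs
    genotypes = h.genotypes
    out: List[CandidateBiotransformation] = []
    for b in selected_bins:
        cand = CandidateBiotransformation(
            bin_index=int(b),
            bin_center=h.bin_label(int(b)),
            count={k: int(h.counts[k][b]) for k in groups},
            threshold={k: float(thresholds[k][b]) for k in groups},
            normalized_frequency={k: float(nf[k][b]) for k in groups},
            exceeds={k: bool(exceeds[k][b]) for k in groups},
            ooi={k: ooi_per_group[k].get(int(b), 0) for k in groups},
        )
        for organ in organs:
            ranks = [
                cand.ooi[(organ, g)]
                for g in genotypes
                if (organ, g) in cand.ooi and cand.ooi[(organ, g)] > 0
            ]
            if ranks:
                cand.organ_ooi[organ] = min(ranks)
                cand.organ_avooi[organ] = float(np.mean(ranks))
            cand.organ_exceeds[organ] = any(
                cand.exceeds.get((organ, g), False) for g in genotypes
            )
        out.append(cand)
    return out


def organ_venn(
    candidates: Sequence[CandidateBiotransformation], organs: Optional[Sequence[str]] = None
) -> Dict[Tuple[str, ...], int]:
    """Partition selected candidates into Venn regions by organ occurrence.

    A candidate occurs in an organ if it exceeds the local threshold
    there in any genotype; each candidate is counted in exactly the
    region of its full organ set, so region counts sum to the number of
    selected candidates with at least one organ.
    """
    if organs is None:
        organs = sorted({o for c in candidates for o in c.organ_exceeds})
    regions: Dict[Tuple[str, ...], int] = {}
    for cand in candidates:
        members = tuple(o for o in organs if cand.organ_exceeds.get(o, False))
        if not members:
            continue
        regions[members] = regions.get(members, 0) + 1
    return regions


def annotate_candidates(
    candidates: Sequence[CandidateBiotransformation],
    catalog: Sequence[Biotransformation],
    match_tol: float = 0.0015,
    bin_width: float = 0.001,
) -> List[CandidateBiotransformation]:
    """Annotate candidate bins with catalog deltas within tolerance.

    A catalog delta matches a bin when it lies within ``match_tol`` of
    the bin midpoint (lower edge + half a bin width).  Candidates with
    no match keep an empty annotation list and report "Unknown".
    """
    for cand in candidates:
        mid = cand.bin_center + bin_width / 2.0
        cand.annotations = [
            bt for bt in catalog if abs(bt.delta_mass - mid) <= match_tol
        ]
    return list(candidates)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def manhattan_table(
    h: MassDiffHistogram,
    thresholds: Mapping[GroupKey, np.ndarray],
    only_occupied: bool = True,
) -> pd.DataFrame:
    """Long-format table: bin_center, organ, genotype, count, threshold, ..."""
    rows = []
    for key in h.groups:
        organ, genotype = key
        counts = h.counts[key]
        thr = np.asarray(thresholds[key], dtype=float)
        bins = np.nonzero(counts)[0] if only_occupied else np.arange(h.n_bins)
        for b in bins:
            c = int(counts[b])
            rows.append(
                {
                    "bin_center": h.bin_label(int(b)),
                    "organ": organ,
                    "genotype": genotype,
                    "count": c,
                    "threshold": float(thr[b]),
                    "normalized_frequency": c / float(thr[b]),
                    "exceeds": bool(c > thr[b]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "bin_center",
            "organ",
            "genotype",
            "count",
            "threshold",
            "normalized_frequency",
            "exceeds",
        ],
    )


def candidate_table(candidates: Sequence[CandidateBiotransformation]) -> pd.DataFrame:
    """Candidate summary with per-organ ``OOI (avOOI)`` columns."""
    organs = sorted({o for c in candidates for o in c.organ_exceeds})
    rows = []
    for cand in candidates:
        row = {
            "mz_delta": f"{cand.bin_center:.3f}",
            "formula": "; ".join(
                bt.formula.hill() for bt in cand.annotations if bt.formula is not None
            ),
            "putative_conversion": "; ".join(bt.name for bt in cand.annotations) or "Unknown",
            "short": cand.annotation_label,
            "class": "; ".join(bt.btclass for bt in cand.annotations),
        }
        for organ in organs:
            if organ in cand.organ_ooi:
                row[organ] = f"{cand.organ_ooi[organ]} ({cand.organ_avooi[organ]:.0f})"
            else:
                row[organ] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def plot_manhattan(
    h: MassDiffHistogram,
    thresholds: Mapping[GroupKey, np.ndarray],
    group: GroupKey,
    path,
    max_points: int = 200_000,
) -> None:
    """Manhattan plot (counts per bin with the local threshold line)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = h.counts[group]
    thr = np.asarray(thresholds[group], dtype=float)
    occupied = np.nonzero(counts)[0]
    if occupied.size > max_points:
        occupied = occupied[:: occupied.size // max_points + 1]
    x = occupied * h.bin_width
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.vlines(x, 0, counts[occupied], color="0.3", linewidth=0.5)
    ax.plot(np.arange(h.n_bins) * h.bin_width, thr, color="gold", linewidth=0.8, label="local threshold")
    ax.set_xlabel("mass difference (Da)")
    ax.set_ylabel("feature pairs")
    ax.set_title(f"organ={group[0]}, genotype={group[1]}")
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
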