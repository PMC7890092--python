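"""PCA on feature abundances and on mass-difference frequency profiles.

Samples (organ x genotype) are rows; variables are either LC-MS feature
abundances or threshold-normalized mass-difference frequencies (count /
local threshold per 0.001 Da bin, optionally restricted to the selected
candidate biotransformations).  Variables are centered and unit
variance-scaled before decomposition; zero-variance columns are dropped
and reported.  With one sample per organ x genotype cell the analysis
is descriptive: it shows how profiles cluster, with no significance
testing attached.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .massdiff import CandidateBiotransformation, GroupKey, MassDiffHistogram
from .spectra_io import Feature

__all__ = [
    "SampleMatrix",
    "PcaResult",
    "abundance_matrix",
    "normalized_frequency_matrix",
    "pca",
    "biplot",
]


@dataclass
class SampleMatrix:
    """Samples x variables matrix with preprocessing bookkeeping."""

    data: pd.DataFrame  # rows: sample labels; columns: variable labels
    centered: bool = False
    unit_variance: bool = False
    dropped_columns: List[str] = field(default_factory=list)

    def preprocess(self, center: bool = True, scale: bool = True) -> "SampleMatrix":
        """Drop zero-variance columns, then center and/or scale."""
        df = self.data.astype(float)
        # relative tolerance: a column constant up to float residue must be
        # treated as zero-variance, or scaling would blow it up
        stds = df.std(axis=0, ddof=0)
        scale_ref = df.abs().max(axis=0).clip(lower=1.0)
        keep = stds > 1e-9 * scale_ref
        dropped = [str(c) for c in df.columns[~keep]]
        df = df.loc[:, keep]
        if center:
            df = df - df.mean(axis=0)
        if scale:
            df = df / df.std(axis=0, ddof=0)
        return SampleMatrix(
            data=df,
            centered=center,
            unit_variance=scale,
            dropped_columns=self.dropped_columns + dropped,
        )


def abundance_matrix(features: Sequence[Feature]) -> SampleMatrix:
    """Per-sample feature abundances (samples x features)."""
    if not features:
        raise ValueError("no features")
    samples = sorted({s for f in features for s in f.abundances})
    data = {
        f.feature_id: [f.abundances.get(s, 0.0) for s in samples] for f in features
    }
    df = pd.DataFrame(data, index=samples)
    return SampleMatrix(data=df)


def normalized_frequency_matrix(
    h: MassDiffHistogram,
    thresholds: Mapping[GroupKey, np.ndarray],
    bins: Optional[Sequence[int]] = None,
    candidates: Optional[Sequence[CandidateBiotransformation]] = None,
) -> SampleMatrix:
    """Threshold-normalized mass-difference frequencies per sample.

    One row per (organ, genotype); one column per bin holding
    count / local threshold.  ``bins`` (bin indices) or ``candidates``
    restricts the columns, e.g. to the selected candidate
    biotransformations; by default only occupied bins are kept (empty
    bins are zero in every sample and would be dropped as zero-variance
    anyway).
    """
    if candidates is not None:
        bins = [c.bin_index for c in candidates]
    groups = h.groups
    if bins is None:
        occupied = np.zeros(h.n_bins, dtype=bool)
        for key in groups:
            occupied |= h.counts[key] > 0
        bins = np.nonzero(occupied)[0]
    bins = np.asarray(sorted(bins), dtype=int)
    rows = []
    labels = []
    for key in groups:
        counts = h.counts[key].astype(float)
        thr = np.asarray(thresholds[key], dtype=float)
        rows.append(counts[bins] / thr[bins])
        labels.append(f"{key[0]}:{key[1]}")
    df = pd.DataFrame(
        np.vstack(rows), index=labels, columns=[f"{b * h.bin_width:.3f}" for b in bins]
    )
    return SampleMatrix(data=df)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components
    variance_explained: np.ndarray  # fractions, sum to 1 over all components

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(m: SampleMatrix, n_components: Optional[int] = None) -> PcaResult:
    """Principal component analysis of a (preprocessed) sample matrix.

    The matrix is centered/scaled here if it has not been already.  The
    decomposition keeps all components (so the explained-variance
    fractions sum to 1) and reports the first ``n_components`` of them.
    Component signs are fixed by making each component's
    largest-magnitude loading positive, so results are reproducible
    across runs and libraries.
    """
    if m.data.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    work = m if (m.centered and m.unit_variance) else m.preprocess()
    if work.data.shape[1] < 2:
        raise ValueError("PCA requires at least 2 surviving variables")
    X = work.data.to_numpy(dtype=float)
    full = _SkPCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    scores = full.fit_transform(X)
    loadings = full.components_.T  # variables x components
    ratios = full.explained_variance_ratio_.copy()
    total = ratios.sum()
    if total > 0:
        ratios = ratios / total  # fractions over retained (full-rank) components
    # deterministic sign: largest-|loading| entry positive per component
    for c in range(loadings.shape[1]):
        col = loadings[:, c]
        top = int(np.argmax(np.abs(col)))
        if col[top] < 0:
            loadings[:, c] = -col
            scores[:, c] = -scores[:, c]
    if n_components is not None:
        scores = scores[:, :n_components]
        loadings = loadings[:, :n_components]
    comp_labels = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=work.data.index, columns=comp_labels),
        loadings=pd.DataFrame(loadings, index=work.data.columns, columns=comp_labels),
        variance_explained=ratios,
    )


def biplot(result: PcaResult, path, top_k: int = 10) -> None:
    """Score plot with the top-k loading vectors overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    xs = result.scores.iloc[:, 0]
    ys = result.scores.iloc[:, 1] if result.scores.shape[1] > 1 else 0 * xs
    ax.scatter(xs, ys, s=25, color="tab:blue")
    for label, x, y in zip(result.scores.index, xs, ys):
        ax.annotate(str(label), (x, y), fontsize=7, alpha=0.8)
    # rank variables by squared contribution to PC1/PC2
    lx = result.loadings.iloc[:, 0]
    ly = result.loadings.iloc[:, 1] if result.loadings.shape[1] > 1 else 0 * lx
    contrib = lx**2 + ly**2
    top = contrib.sort_values(ascending=False).head(top_k).index
    scale = 0.8 * max(float(np.abs(xs).max()), float(np.abs(ys).max()), 1e-9) / max(
        float(np.abs(lx[top]).max()), float(np.abs(ly[top]).max()), 1e-9
    )
    for var in top:
        ax.annotate(
            "",
            xy=(lx[var] * scale, ly[var] * scale),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="tab:red", lw=1),
        )
        ax.annotate(str(var), (lx[var] * scale, ly[var] * scale), fontsize=7, color="tab:red")
    ve = result.variance_explained
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.0f}%)")
    if len(ve) > 1:
        ax.set_ylabel(f"PC2 ({100 * ve[1]:.0f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
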