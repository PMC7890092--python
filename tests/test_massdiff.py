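"""Mass-difference census, local thresholds, candidate selection, OOI, Venn."""
from itertools import combinations

import numpy as np
import pytest

from csppnet import massdiff
from csppnet.chem import default_catalog
from csppnet.massdiff import (
    MassDiffHistogram,
    annotate_candidates,
    compute_histogram,
    local_threshold,
    organ_venn,
    select_candidates,
)
from csppnet.spectra_io import Feature


def feature(fid, mz, abundances=None):
    ab = abundances or {"stem:OH43:1": 1.0}
    return Feature(
        feature_id=fid, mz=mz, rt=10.0, polarity="neg", instrument="FT",
        abundances=ab, sample_meta={s: (s.split(":")[0], s.split(":")[1]) for s in ab},
    )


def hist_from_counts(counts, bin_width=0.001, max_delta=250.0):
    return MassDiffHistogram(
        bin_width=bin_width,
        max_delta=max_delta,
        counts={k: np.asarray(v, dtype=np.int64) for k, v in counts.items()},
        n_features={k: 0 for k in counts},
    )


class TestHistogram:
    def test_single_pair_lands_in_floor_bin(self):
        h = compute_histogram([feature("a", 100.000), feature("b", 118.011)])
        vec = h.counts[("stem", "OH43")]
        assert vec.sum() == 1
        assert vec[18011] == 1  # bin labelled 18.011

    def test_single_feature_gives_empty_histogram(self):
        h = compute_histogram([feature("a", 100.0)])
        assert h.counts[("stem", "OH43")].sum() == 0

    def test_mixed_polarity_rejected(self):
        f1 = feature("a", 100.0)
        f2 = Feature(feature_id="b", mz=200.0, rt=1.0, polarity="pos", instrument="FT",
                     abundances={"s:g:1": 1.0}, sample_meta={"s:g:1": ("s", "g")})
        with pytest.raises(ValueError, match="polarity"):
            compute_histogram([f1, f2])

    def test_abundance_floor_excludes_features(self):
        feats = [
            feature("a", 100.0, {"stem:OH43:1": 0.5}),
            feature("b", 150.0, {"stem:OH43:1": 10.0}),
            feature("c", 180.0, {"stem:OH43:1": 10.0}),
        ]
        h = compute_histogram(feats, abundance_floor=1.0)
        assert h.counts[("stem", "OH43")].sum() == 1  # only the b-c pair
        assert h.n_features[("stem", "OH43")] == 2

    def test_matches_brute_force_census(self, rng):
        mzs = rng.uniform(100.0, 1000.0, 200)
        feats = [feature(f"f{i}", mz) for i, mz in enumerate(mzs)]
        h = compute_histogram(feats)
        vec = h.counts[("stem", "OH43")]
        brute = np.zeros_like(vec)
        for a, b in combinations(mzs, 2):
            d = abs(a - b)
            if d < 250.0:
                idx = int(np.floor(d / 0.001 + 1e-6))
                if idx < brute.size:
                    brute[idx] += 1
        assert np.array_equal(vec, brute)
        assert vec.sum() <= 200 * 199 // 2

    def test_invariant_under_relabeling(self, rng):
        mzs = rng.uniform(100.0, 500.0, 40)
        feats = [feature(f"f{i}", mz) for i, mz in enumerate(mzs)]
        shuffled = [feature(f"g{i}", mz) for i, mz in enumerate(mzs[::-1])]
        h1 = compute_histogram(feats)
        h2 = compute_histogram(shuffled)
        assert np.array_equal(h1.counts[("stem", "OH43")], h2.counts[("stem", "OH43")])


class TestLocalThreshold:
    def test_constant_background_selects_nothing(self):
        h = hist_from_counts({("stem", "g"): np.full(2000, 7)}, max_delta=2.0)
        thr = local_threshold(h)
        cands = select_candidates(h, thr)
        assert cands == []

    def test_spike_over_poisson_background_is_detected(self):
        rng = np.random.default_rng(123)
        counts = rng.poisson(2.0, 20000)
        counts[10000] = 100
        h = hist_from_counts({("stem", "g"): counts}, max_delta=20.0)
        thr = local_threshold(h)
        cands = select_candidates(h, thr)
        selected_bins = {c.bin_index for c in cands}
        assert 10000 in selected_bins
        # false positives among the Poisson bins stay below 0.1%
        assert (len(selected_bins) - 1) / 20000 <= 0.001

    def test_threshold_monotone_in_k(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(3.0, 5000)
        h = hist_from_counts({("stem", "g"): counts}, max_delta=5.0)
        t1 = local_threshold(h, k=3.0)[("stem", "g")]
        t2 = local_threshold(h, k=6.0)[("stem", "g")]
        assert np.all(t2 >= t1)

    def test_sparse_fast_path_matches_exact_computation(self):
        """The sparse shortcut (median/MAD = 0 where over half the window is
        empty) must agree with the windowed median + k*MAD evaluated
        directly."""
        rng = np.random.default_rng(9)
        counts = np.zeros(3000, dtype=np.int64)
        occupied = rng.choice(3000, 500, replace=False)
        counts[occupied] = rng.poisson(4.0, 500) + 1
        h = hist_from_counts({("stem", "g"): counts}, max_delta=3.0)
        thr = local_threshold(h, window_halfwidth=0.25, k=5.0, min_count=5.0)[("stem", "g")]
        hw = 250
        pad = np.pad(counts.astype(float), hw, mode="reflect")
        for b in rng.choice(3000, 60, replace=False):
            window = np.delete(pad[b : b + 2 * hw + 1], hw)
            med = np.median(window)
            mad = np.median(np.abs(window - med))
            assert thr[b] == pytest.approx(max(5.0, med + 5.0 * mad))

    def test_narrow_window_rejected(self):
        h = hist_from_counts({("stem", "g"): np.zeros(100, dtype=int)}, max_delta=0.1)
        with pytest.raises(ValueError):
            local_threshold(h, window_halfwidth=0.005)


class TestSelection:
    def test_normalized_frequency_and_exceeds(self):
        counts = np.zeros(1000, dtype=np.int64)
        counts[500] = 10
        h = hist_from_counts({("stem", "g"): counts}, max_delta=1.0)
        thr = {("stem", "g"): np.full(1000, 5.0)}
        cands = select_candidates(h, thr)
        assert len(cands) == 1
        c = cands[0]
        assert c.normalized_frequency[("stem", "g")] == pytest.approx(2.0)
        assert c.exceeds[("stem", "g")]

    def test_ooi_is_dense_descending_rank(self):
        counts = np.zeros(1000, dtype=np.int64)
        counts[[100, 200, 300]] = [30, 15, 2]
        h = hist_from_counts({("stem", "g"): counts}, max_delta=1.0)
        thr = {("stem", "g"): np.full(1000, 10.0)}
        cands = select_candidates(h, thr)
        oois = {c.bin_index: c.ooi[("stem", "g")] for c in cands}
        assert oois == {100: 1, 200: 2}  # bin 300 does not exceed

    def test_ooi_min_and_mean_across_genotypes_match_brute_force(self, rng):
        genotypes = ["g1", "g2", "g3", "g4"]
        counts = {("stem", g): rng.poisson(1.0, 100) for g in genotypes}
        for g in genotypes:
            counts[("stem", g)][rng.integers(0, 100, 5)] += 20
        h = hist_from_counts(counts, max_delta=0.1)
        thr = {k: np.full(100, 5.0) for k in counts}
        cands = select_candidates(h, thr)
        for c in cands:
            expected = {}
            for g in genotypes:
                vec = counts[("stem", g)].astype(float) / 5.0
                occupied = np.nonzero(counts[("stem", g)])[0]
                vals = sorted({vec[b] for b in occupied}, reverse=True)
                if counts[("stem", g)][c.bin_index] > 0:
                    expected[g] = vals.index(vec[c.bin_index]) + 1
            ranks = [c.ooi[("stem", g)] for g in genotypes if expected.get(g)]
            assert ranks == [expected[g] for g in genotypes if expected.get(g)]
            assert c.organ_ooi["stem"] == min(ranks)
            assert c.organ_avooi["stem"] == pytest.approx(np.mean(ranks))

    def test_planted_grammar_deltas_all_selected(self, small_sim):
        h = compute_histogram(small_sim.subdbs["FTMS_neg"].features)
        thr = local_threshold(h)
        cands = select_candidates(h, thr)
        centers = np.array([c.bin_center for c in cands])
        for code, delta in small_sim.truth.grammar_deltas.items():
            assert np.any(np.abs(centers + 0.0005 - delta) <= 0.0015), code


class TestVenn:
    def _candidate(self, organ_flags, idx=0):
        from csppnet.massdiff import CandidateBiotransformation

        return CandidateBiotransformation(
            bin_index=idx, bin_center=idx * 0.001, count={}, threshold={},
            normalized_frequency={}, exceeds={("x", "g"): True}, ooi={},
            organ_exceeds=organ_flags,
        )

    def test_all_organ_candidate_counted_once(self):
        organs = ["ear", "late cob", "leaf", "stem", "tassel"]
        cand = self._candidate({o: True for o in organs})
        regions = organ_venn([cand], organs)
        assert regions == {tuple(organs): 1}

    def test_single_organ_region(self):
        organs = ["ear", "tassel"]
        cand = self._candidate({"ear": False, "tassel": True})
        assert organ_venn([cand], organs) == {("tassel",): 1}

    def test_counts_sum_and_match_brute_force(self, rng):
        organs = ["a", "b", "c", "d", "e"]
        flags = rng.random((50, 5)) < 0.5
        cands = [
            self._candidate({o: bool(flags[i, j]) for j, o in enumerate(organs)}, idx=i)
            for i in range(50)
        ]
        regions = organ_venn(cands, organs)
        n_nonempty = int((flags.any(axis=1)).sum())
        assert sum(regions.values()) == n_nonempty
        # brute-force enumeration
        brute = {}
        for i in range(50):
            members = tuple(o for j, o in enumerate(organs) if flags[i, j])
            if members:
                brute[members] = brute.get(members, 0) + 1
        assert regions == brute


class TestAnnotation:
    def _cand_at(self, delta):
        from csppnet.massdiff import CandidateBiotransformation

        idx = int(np.floor(delta / 0.001))
        return CandidateBiotransformation(
            bin_index=idx, bin_center=round(idx * 0.001, 6), count={}, threshold={},
            normalized_frequency={}, exceeds={}, ooi={},
        )

    def test_oxygenation_bin(self):
        cand = self._cand_at(15.9949)
        annotate_candidates([cand], default_catalog())
        assert "OXY" in [bt.short_code for bt in cand.annotations]

    def test_methoxylation_bin(self):
        cand = self._cand_at(30.0106)
        annotate_candidates([cand], default_catalog())
        assert "MOX" in [bt.short_code for bt in cand.annotations]

    def test_unknown_bin(self):
        cand = self._cand_at(0.015)
        annotate_candidates([cand], default_catalog())
        assert cand.annotations == []
        assert cand.annotation_label == "Unknown"


def test_manhattan_table_reports_occupied_bins(small_sim):
    feats = small_sim.subdbs["FTMS_neg"].features[:50]
    h = compute_histogram(feats)
    thr = local_threshold(h)
    df = massdiff.manhattan_table(h, thr)
    assert set(df.columns) == {
        "bin_center", "organ", "genotype", "count", "threshold",
        "normalized_frequency", "exceeds",
    }
    assert (df["count"] > 0).all()
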