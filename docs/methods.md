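# Methods

This note documents the models and procedures implemented in `csppnet`,
the parameters that matter, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## Masses and formulas

Monoisotopic masses are vendored as a single table (`chem.ISOTOPE_MASSES`,
≥ 9 decimals, ¹²C = 12 exactly; proton 1.007276467 Da). All mass deltas
are computed from this table, never from printed 3-decimal values: a
printed value such as 162.052 for hexosylation is a *floor-binned label*
(the true delta is 162.05282 Da), so rounding and flooring disagree at
the third decimal for some deltas and the package always carries full
precision internally. Ion ↔ neutral conversion supports singly
(de)protonated species only — [M−H]⁻ and [M+H]⁺ — which covers the
dominant ESI adducts in phenolic profiling; other adducts are an
extension point, not a supported mode.

## The biotransformation catalog

The default catalog holds 34 single-conversion deltas (reductions,
alkylations, oxygenations, acylations, glycosylations, organic-acid and
phenolic couplings), each with:

- a molecular formula (the delta is its monoisotopic mass);
- a class — *decoration* (true enzymatic additions on a core),
  *structural* (mass gap between two distinct cores), *core transfer*
  (coupling of a whole core unit), *multiple options* (ambiguous
  composites);
- an elution-order rule for reversed-phase chromatography:
  `product_earlier` for polarity-increasing additions (sugars,
  oxygenation, hydration, organic acids), `product_later` for
  hydrophobicity-increasing ones (alkylations, aromatic acylations and
  couplings), `any` where the net effect is ambiguous (e.g.
  methoxylation = oxygenation + methylation).

The exact membership of a "well-known biotransformations" list is a
curation decision; this catalog is the package's own reconstruction of
the conversions routinely annotated in plant phenolic metabolism, and
both the membership and every rt rule are data: a CSV catalog
(`short,name,formula,raw_delta,class,rt_rule`) replaces the default
wholesale. A separate `isotope_entry()` (¹³C−¹²C, 1.00336 Da) can be
added when the natural-isotope sub-network should be represented
explicitly.

## Mass-difference census and local thresholds

All pairwise |Δ m/z| within one polarity are binned at 0.001 Da over
[0, 250) Da, per (organ, genotype); a feature participates in a group
when its abundance there exceeds `abundance_floor` (default 0, i.e. any
detection). Floor binning labels each bin by its lower edge, which is
why a physical delta sitting near a bin edge (reduction at 2.0157 Da)
populates two adjacent bins — a phenomenon the package reproduces
rather than hides. A guard of 10⁻⁶ bin widths (~10⁻⁹ Da) is added
before flooring so that an exactly representable decimal delta cannot
fall into the bin below through float representation.

The local threshold is `max(c_min, median + k·MAD)` over the ±0.25 Da
window around each bin, excluding the bin itself and reflecting the
counts at the range edges; defaults k = 5, c_min = 5, all three
config keys. Exceedance is strict (`count > threshold`), so a constant
background selects nothing. Over the sparse regions that dominate a
real census (most of the window empty) the window median and MAD are
exactly zero; the implementation shortcuts those bins to `c_min`
directly and evaluates the windowed statistics only where at least half
the window is occupied. This is an exact optimization, verified
against the direct computation in the tests, and keeps a full
250,000-bin scan per 20 groups below a second.

OOI (order of importance) numbers are dense descending ranks of the
threshold-normalized frequency (count/threshold), computed per
(organ, genotype) **over all occupied bins** — not merely the selected
candidates. The reported per-organ OOI is the minimum across genotypes
and avOOI the mean; ranking over the full census is what produces OOI
values far larger than the number of selected candidates for bins that
barely exceed locally, matching how such tables are printed in
practice. Ties share a rank; candidate output order is by bin
ascending, so results are deterministic.

Venn partitioning assigns each selected candidate to exactly the region
of the organs where it exceeds in ≥ 1 genotype; region counts therefore
sum to the number of selected candidates.

## CSPP networks

Edges are stored in the addition direction only: the lighter feature is
the candidate substrate. For every catalog delta a sorted-m/z window
search finds pairs within `mass_tol` (default 0.002 Da for FT data,
0.01 Da suggested for QTOF), and the rt rule of the entry is enforced
strictly when it is not `any`. The windowed search is exactly
equivalent to the all-pairs scan (asserted in tests up to n = 300).
A MultiDiGraph keyed by the biotransformation code lets one feature
pair carry several catalog interpretations. With `require_spectra`
(default) only features carrying at least one CID spectrum become
nodes. Spectral similarity *colors* edges (max cosine over the
substrate × product level-2 spectra) but never gates their existence;
an optional `min_similarity` filter exists and is off by default.

Node organ labels are the organ of maximal summed abundance, ties
broken by a fixed organ order (ear, late cob, leaf, stem, tassel) and
flagged; all-zero nodes are `unassigned`.

Annotation propagation is breadth-first from seed nodes (formula +
name) up to `max_hops`: traversing an edge along its direction adds the
edge's formula, against it removes it; a candidate survives only when
the arithmetic succeeds *and* the resulting monoisotopic mass matches
the node's neutral mass within `mass_tol`. Formula-less (raw-delta)
edges block propagation — a numeric delta cannot update a formula.
Conflicting candidates on one node are all kept and logged.

## Spectral similarity

The score is a weighted cosine over greedily matched peaks: candidate
pairs within `mz_tol` are accepted closest-|Δmz| first, each peak used
once; the dot product of matched weighted intensities is normalized by
the weighted norms of both *full* spectra, so unmatched peaks dilute
the score and identical spectra score exactly 1. Defaults: weight =
intensity^0.5 (square-root stabilization of dominant peaks), no m/z
weighting, mz_tol 0.01 Da for FT and 0.05 Da for QTOF spectra — all
exposed. Greedy matching is deterministic and O(n log n); the tie-break
key is symmetric in the two spectra, making the score exactly
symmetric under argument order (a property the tests assert, alongside
agreement with an independent greedy-cosine implementation on spectra
whose matching is unambiguous). Library matching prefilters on
precursor tolerance and keeps hits scoring ≥ 0.6 (inclusive), sorted
by score then precursor gap.

## Sub-database alignment

Aligning two sub-databases (FT vs QTOF, or neg vs pos) uses three
criteria: (i) neutral-mass agreement — same polarity: |Δmz| ≤ mass_tol;
cross polarity: |mz₊ − mz₋ − 2·m_proton| ≤ mass_tol; (ii) RT agreement
after a robust RT map; (iii) CID spectral similarity ≥ 0.6. The RT map
is a Theil–Sen line (median of pairwise slopes, slope clipped to ≥ 0)
fitted in a first pass on high-confidence seeds (similarity ≥ 0.8,
mass-gated, no RT constraint), with residual scale 1.4826 × median
|residual|; the second pass applies it with rt_tol = 3 × residual scale
(floor 0.25 min). Retained pairs are mutual best hits by similarity,
ties by |RT residual|, so each feature aligns at most once. Features
without level-2 spectra are non-alignable and counted. The procedure is
canonically oriented internally, so align(A,B) and align(B,A) return
identical pair sets.

Opposite-polarity CID spectra share no ion m/z directly — fragments
appear as [frag−H]⁻ in negative and [frag+H]⁺ in positive mode — so
cross-polarity similarity is computed after shifting the positive-mode
spectrum down by 2 × proton mass onto the negative-ion scale. This is
the package's design choice for making spectral matching usable across
polarities; it assumes the dominant fragments ionize in both modes,
which holds for the synthetic data and approximately for real phenolics.

## PCA

Variables (feature abundances, or count/threshold normalized
mass-difference frequencies, optionally restricted to the selected
candidates) are centered and unit-variance scaled; columns whose
standard deviation is below 10⁻⁹ × their magnitude are dropped as
zero-variance (an exact-zero test would let float residue survive
scaling and explode). The decomposition retains full rank, so the
explained-variance fractions sum to 1; component signs are fixed by
making each component's largest-magnitude loading positive. With the
emulated design of one sample per organ × genotype there are no
replicates, so the analysis is purely descriptive.

## The synthetic benchmark

The generator emulates the study design the toolkit targets: 5 organs ×
4 genotypes (one sample each), m/z 100–1000, a 0–30 min gradient, four
sub-databases. Fifty random CHO scaffolds (mass 150–450 Da, base RT
uniform in 5–27 min) are decorated by an 8-transformation grammar
(HEX, PEN, RHA, MET, ACE, BEN, OXY, RED — three glycosylations, two
alkyl/acyl additions, an aromatic acylation, an oxygenation, a
reduction) to depth ≤ 3, each transformation applied with probability
0.3 per node; commutative duplicates collapse, so a lineage is the set
of generated transformation multisets. Each transformation draws one
RT shift (0.15 min + half-normal(σ = 0.6), signed by its rt rule) that
composes additively along the multiset, so every pair of compounds
differing by one transformation automatically satisfies that
transformation's elution rule — the planted truth is defined as exactly
those formula-difference pairs with compliant elution order.

Instruments re-observe the same compounds with m/z noise σ = 0.0002 Da
(FT-class accuracy) or 0.003 Da (QTOF-class), RT noise 0.02/0.05 min,
and a +0.4 min global RT offset on the QTOF platform. Abundances are
log-normal (σ = 0.3) around a per-compound base, ×10 in the lineage's
home organ; a compound is present outside its home organ with
probability 0.35 and drops out per genotype with probability 0.1.
Fragment spectra combine recursive random splits of the scaffold
formula (shared along the lineage) with neutral losses of the applied
transformations, so substrate–product and cross-platform spectra
overlap; intensities are Dirichlet-distributed per compound with
per-platform log-normal jitter. Everything is driven by one
`numpy.random.default_rng(seed)`, and two runs with the same seed are
byte-identical on disk.

What passing the recovery benchmarks shows: the census, threshold,
selection, network and alignment machinery are mutually consistent and
recover a known generative structure essentially perfectly under
realistic instrument noise. What it does not show: performance on real
chromatograms, where peak-picking artifacts, isotopologues, in-source
fragments, adduct heterogeneity and chimeric spectra produce both
missing and spurious features that this generator deliberately omits.
Absolute candidate counts from real data therefore cannot be compared
with the synthetic ones.

## Problem sizes and determinism

The default benchmark (50 scaffolds → ~1,100 compounds, ~2,500 planted
edges, 20 groups × 250,000 bins) runs the full census + selection +
network + alignment pipeline in roughly 10 s on one CPU; tests use a
10-scaffold variant where full size adds nothing. All tie-breaks
(greedy peak matching, mutual-best ranking, OOI ties, organ-label
ties, PCA signs) are specified deterministically, so identical inputs
and seeds give identical outputs.

## Known limitations

- Only ±H adducts and singly charged ions; no isotope-envelope
  modeling beyond the optional ¹³C catalog entry.
- The local-threshold construction (median + k·MAD window) is one
  principled realization of a "local frequency threshold" line; the
  constants are config keys and the function is replaceable.
- Alignment is strictly one-to-one (mutual best); genuinely split or
  merged peaks across platforms are not modeled.
- The candidate census does not restrict pairs by co-elution or
  intensity; `abundance_floor` is the only participation filter.
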