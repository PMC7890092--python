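"""Synthetic metabolome generator with planted biotransformation structure.

Emulates the study design every other module is tested against: five
organs x four genotypes profiled on two instrument platforms (FT and
QTOF) in both ionization polarities, features in m/z 100-1000 over a
0-30 min reversed-phase gradient.  Compounds are generated by applying
a small biotransformation grammar (a catalog subset) to random CHO
scaffolds up to a fixed depth; products respect the elution-order rule
of the transformation that formed them, organs preferentially
accumulate the lineages "homed" there, and each instrument re-observes
the same compounds with its own m/z and RT noise plus a global RT
offset.  Fragment spectra are built by recursive moiety splitting of
the scaffold formula plus neutral losses of the applied
transformations, so substrate-product pairs share fragments and
spectral edge scores are informative.

The generator returns, alongside the data, a complete ground truth
(compounds, planted edges, feature and spectrum maps, cross-instrument
correspondences) so recovery rates can be measured exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .chem import (
    Biotransformation,
    Formula,
    default_catalog,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
)
from .spectra_io import (
    Feature,
    Peak,
    Spectrum,
    SubDB,
    write_feature_table,
    write_spectra,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "simulate_metabolome",
    "write_dataset",
    "fixture_config",
]

DEFAULT_ORGANS = ("ear", "late cob", "leaf", "stem", "tassel")
DEFAULT_GENOTYPES = ("CML91", "H99", "W153R", "OH43")

#: Default 8-transformation grammar: three glycosylations, two alkyl/acyl
#: additions, an aromatic acylation, an oxygenation and a reduction --
#: the conversion types that dominate plant specialized metabolism.
DEFAULT_GRAMMAR = ("HEX", "PEN", "RHA", "MET", "ACE", "BEN", "OXY", "RED")


@dataclass
class SimConfig:
    """Study-design parameters of the simulated metabolome.

    Defaults mirror the emulated study: 5 organs x 4 genotypes without
    biological replicates, 50 scaffolds decorated by an 8-transformation
    grammar to depth 3, FT-class m/z noise of 0.0002 Da versus
    QTOF-class 0.003 Da, a +0.4 min RT offset between platforms, and a
    10-fold organ enrichment of each scaffold lineage in its home organ.
    """

    seed: int
    n_scaffolds: int = 50
    grammar: Sequence[str] = DEFAULT_GRAMMAR
    max_depth: int = 3
    apply_prob: float = 0.3
    organs: Sequence[str] = DEFAULT_ORGANS
    genotypes: Sequence[str] = DEFAULT_GENOTYPES
    enrichment_fold: float = 10.0
    presence_prob_other_organ: float = 0.35
    genotype_dropout: float = 0.1
    scaffold_mass_range: Tuple[float, float] = (150.0, 450.0)
    rt_range: Tuple[float, float] = (5.0, 27.0)
    rt_shift_min: float = 0.15
    rt_shift_sigma: float = 0.6
    ft_mz_sigma: float = 0.0002
    qtof_mz_sigma: float = 0.003
    ft_rt_sigma: float = 0.02
    qtof_rt_sigma: float = 0.05
    qtof_rt_offset: float = 0.4
    n_core_fragments: int = 4
    fragment_mz_jitter_qtof: float = 0.01
    fragment_mz_jitter_ft: float = 0.001
    intensity_jitter_sigma: float = 0.2
    abundance_log10_range: Tuple[float, float] = (5.0, 7.0)
    abundance_noise_sigma: float = 0.3
    max_compound_mass: float = 1000.0

    def catalog(self) -> List[Biotransformation]:
        by_code = {bt.short_code: bt for bt in default_catalog()}
        missing = [c for c in self.grammar if c not in by_code]
        if missing:
            raise ValueError(f"grammar codes not in default catalog: {missing}")
        return [by_code[c] for c in self.grammar]


def fixture_config(seed: int = 42) -> SimConfig:
    """The canonical test dataset configuration (all defaults, fixed seed).

    50 scaffolds decorated by the 8-transformation grammar to depth 3;
    used throughout the test suite so recovery rates are measured under
    one shared, reproducible study design.
    """
    return SimConfig(seed=seed)


@dataclass
class Compound:
    compound_id: str
    scaffold: int
    formula: Formula
    transformations: Tuple[str, ...]  # sorted multiset of grammar codes
    rt: float
    home_organ: str

    @property
    def neutral(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass
class GroundTruth:
    """Everything planted: compounds, edges, maps, correspondences."""

    compounds: List[Compound]
    # true edges per polarity-independent compound graph: (substrate_id,
    # product_id, code); includes every compound pair differing by exactly
    # one grammar transformation with a compliant elution order.
    edges: List[Tuple[str, str, str]]
    feature_to_compound: Dict[str, Dict[str, str]]  # subdb label -> feature_id -> compound_id
    spectrum_to_compound: Dict[str, Dict[str, str]]  # subdb label -> spectrum_id -> compound_id
    correspondences: Dict[Tuple[str, str], List[Tuple[str, str]]]
    organ_of_compound: Dict[str, str]
    grammar_deltas: Dict[str, float]

    def to_json(self) -> str:
        payload = {
            "compounds": [
                {
                    "compound_id": c.compound_id,
                    "scaffold": c.scaffold,
                    "formula": c.formula.hill(),
                    "transformations": list(c.transformations),
                    "rt": c.rt,
                    "home_organ": c.home_organ,
                }
                for c in self.compounds
            ],
            "edges": [list(e) for e in self.edges],
            "feature_to_compound": self.feature_to_compound,
            "spectrum_to_compound": self.spectrum_to_compound,
            "correspondences": {
                f"{a}|{b}": [list(p) for p in pairs]
                for (a, b), pairs in self.correspondences.items()
            },
            "organ_of_compound": self.organ_of_compound,
            "grammar_deltas": self.grammar_deltas,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SimResult:
    config: SimConfig
    subdbs: Dict[str, SubDB]
    truth: GroundTruth


def _random_scaffold(rng: np.random.Generator, cfg: SimConfig) -> Formula:
    lo, hi = cfg.scaffold_mass_range
    while True:
        c = int(rng.integers(7, 21))
        o = int(rng.integers(2, 10))
        h = int(rng.integers(c, 2 * c + 1))
        f = Formula({"C": c, "H": h, "O": o})
        if lo <= monoisotopic_mass(f) <= hi:
            return f


def _grow_lineage(
    rng: np.random.Generator, cfg: SimConfig, catalog: Sequence[Biotransformation]
) -> Dict[FrozenSet, Tuple[Formula, Tuple[str, ...]]]:
    """Generate the multiset-of-transformations lineage of one scaffold.

    Returns distinct compounds keyed by the transformation multiset
    (order of application does not change the formula, so commutative
    duplicates collapse).
    """
    base = _random_scaffold(rng, cfg)
    compounds: Dict[Tuple[str, ...], Formula] = {(): base}
    frontier: List[Tuple[str, ...]] = [()]
    for _ in range(cfg.max_depth):
        next_frontier: List[Tuple[str, ...]] = []
        for multiset in frontier:
            f = compounds[multiset]
            for bt in catalog:
                if rng.random() >= cfg.apply_prob:
                    continue
                nf = f + bt.formula
                if monoisotopic_mass(nf) > cfg.max_compound_mass:
                    continue
                key = tuple(sorted(multiset + (bt.short_code,)))
                if key in compounds:
                    continue
                compounds[key] = nf
                next_frontier.append(key)
        frontier = next_frontier
    return {k: (v, k) for k, v in compounds.items()}


def _assign_rts(
    rng: np.random.Generator,
    cfg: SimConfig,
    lineage: Mapping[Tuple[str, ...], Tuple[Formula, Tuple[str, ...]]],
    catalog_by_code: Mapping[str, Biotransformation],
) -> Dict[Tuple[str, ...], float]:
    """Retention times respecting each transformation's elution rule.

    The scaffold gets a uniform base RT; each added transformation
    shifts the product's RT by a positive half-normal amount in the
    direction its rt_rule dictates (either direction for 'any').
    Shifts compose along the multiset, so every pair differing by one
    transformation automatically satisfies that transformation's rule.
    """
    base_rt = float(rng.uniform(*cfg.rt_range))
    shift_of_code: Dict[str, float] = {}
    rts: Dict[Tuple[str, ...], float] = {}
    for key in sorted(lineage, key=lambda k: (len(k), k)):
        rt = base_rt
        for code in key:
            if code not in shift_of_code:
                mag = cfg.rt_shift_min + abs(rng.normal(0.0, cfg.rt_shift_sigma))
                rule = catalog_by_code[code].rt_rule
                if rule == "product_earlier":
                    shift_of_code[code] = -mag
                elif rule == "product_later":
                    shift_of_code[code] = mag
                else:
                    shift_of_code[code] = mag * (1.0 if rng.random() < 0.5 else -1.0)
            rt += shift_of_code[code]
        rts[key] = float(np.clip(rt, 0.1, 29.9))
    return rts


def _split_formula_masses(
    rng: np.random.Generator, f: Formula, depth: int
) -> List[float]:
    """Recursive moiety splitting: fragment neutral masses of a formula."""
    if depth == 0:
        return []
    counts = f.element_counts
    left = {}
    right = {}
    for sym, n in counts.items():
        nl = int(rng.integers(0, n + 1))
        if nl:
            left[sym] = nl
        if n - nl:
            right[sym] = n - nl
    out = []
    for part in (left, right):
        if not part:
            continue
        pf = Formula(part)
        m = monoisotopic_mass(pf)
        if m >= 40.0:
            out.append(m)
            out.extend(_split_formula_masses(rng, pf, depth - 1))
    return out


def _compound_fragments(
    compound: Compound,
    scaffold_frags: List[float],
    grammar_deltas: Mapping[str, float],
) -> List[float]:
    """Neutral fragment masses: shared scaffold core + neutral losses."""
    frags = list(scaffold_frags)
    m = compound.neutral
    seen = set()
    for code in compound.transformations:
        loss = m - grammar_deltas[code]
        if loss > 50.0 and code not in seen:
            frags.append(loss)
            seen.add(code)
    return frags


def simulate_metabolome(cfg: SimConfig) -> SimResult:
    """Generate the four sub-databases plus ground truth.

    Deterministic given ``cfg.seed``.  Compounds whose grammar growth
    would exceed the m/z scan range are dropped during growth (and thus
    never emitted).
    """
    rng = np.random.default_rng(cfg.seed)
    catalog = cfg.catalog()
    catalog_by_code = {bt.short_code: bt for bt in catalog}
    grammar_deltas = {bt.short_code: bt.delta_mass for bt in catalog}
    organs = list(cfg.organs)
    genotypes = list(cfg.genotypes)
    samples = [f"{o}:{g}:1" for o in organs for g in genotypes]
    sample_meta = {s: (s.split(":")[0], s.split(":")[1]) for s in samples}

    compounds: List[Compound] = []
    scaffold_frag_masses: Dict[int, List[float]] = {}
    for sc in range(cfg.n_scaffolds):
        lineage = _grow_lineage(rng, cfg, catalog)
        rts = _assign_rts(rng, cfg, lineage, catalog_by_code)
        home = organs[sc % len(organs)]
        base_formula = lineage[()][0]
        scaffold_frag_masses[sc] = sorted(
            set(
                round(m, 4)
                for m in _split_formula_masses(rng, base_formula, 2)[: cfg.n_core_fragments]
            )
        )
        for key in sorted(lineage, key=lambda k: (len(k), k)):
            formula, multiset = lineage[key]
            compounds.append(
                Compound(
                    compound_id=f"cpd{sc:03d}_" + ("+".join(multiset) if multiset else "base"),
                    scaffold=sc,
                    formula=formula,
                    transformations=multiset,
                    rt=rts[key],
                    home_organ=home,
                )
            )

    # planted truth edges: every compound pair differing by exactly one
    # grammar transformation, elution order compliant with its rt_rule
    edges: List[Tuple[str, str, str]] = []
    by_formula_mass: List[Tuple[float, Compound]] = sorted(
        ((c.neutral, c) for c in compounds), key=lambda t: (t[0], t[1].compound_id)
    )
    masses = np.array([t[0] for t in by_formula_mass])
    for code, bt in catalog_by_code.items():
        delta_formula = bt.formula
        for mi, (m, sub) in enumerate(by_formula_mass):
            target = m + bt.delta_mass
            lo = np.searchsorted(masses, target - 1e-6, side="left")
            hi = np.searchsorted(masses, target + 1e-6, side="right")
            for j in range(lo, hi):
                prod = by_formula_mass[j][1]
                if prod.compound_id == sub.compound_id:
                    continue
                try:
                    expected = sub.formula + delta_formula
                except ValueError:
                    continue
                if expected != prod.formula:
                    continue
                rule = bt.rt_rule
                if rule == "product_earlier" and not prod.rt < sub.rt:
                    continue
                if rule == "product_later" and not prod.rt > sub.rt:
                    continue
                edges.append((sub.compound_id, prod.compound_id, code))
    edges.sort()

    # per-compound presence / abundance pattern (shared across platforms;
    # both instruments profile the same extracts)
    abundance: Dict[str, Dict[str, float]] = {}
    for c in compounds:
        base = 10.0 ** rng.uniform(*cfg.abundance_log10_range)
        per_sample: Dict[str, float] = {}
        for o in organs:
            present_in_organ = (o == c.home_organ) or (
                rng.random() < cfg.presence_prob_other_organ
            )
            fold = cfg.enrichment_fold if o == c.home_organ else 1.0
            for g in genotypes:
                s = f"{o}:{g}:1"
                if not present_in_organ or rng.random() < cfg.genotype_dropout:
                    per_sample[s] = 0.0
                else:
                    per_sample[s] = base * fold * float(
                        rng.lognormal(0.0, cfg.abundance_noise_sigma)
                    )
        abundance[c.compound_id] = per_sample

    # compound-level fragment profile shared by both platforms (fragment
    # branching ratios are a property of the compound; platforms only
    # jitter them), so cross-platform spectra of one compound are similar
    frag_profile: Dict[str, Tuple[List[float], np.ndarray]] = {}
    for c in compounds:
        frag_neutrals = _compound_fragments(
            c, scaffold_frag_masses[c.scaffold], grammar_deltas
        )
        n_peaks = len(frag_neutrals) + 1  # + precursor
        intens = rng.dirichlet(np.ones(n_peaks)) * 1000.0 + 1.0
        frag_profile[c.compound_id] = (frag_neutrals, intens)

    subdbs: Dict[str, SubDB] = {}
    feature_to_compound: Dict[str, Dict[str, str]] = {}
    spectrum_to_compound: Dict[str, Dict[str, str]] = {}
    for label in ("FTMS_neg", "FTMS_pos", "QTOF_neg", "QTOF_pos"):
        instrument = "FT" if label.startswith("FTMS") else "QTOF"
        polarity = label.split("_")[1]
        mz_sigma = cfg.ft_mz_sigma if instrument == "FT" else cfg.qtof_mz_sigma
        rt_sigma = cfg.ft_rt_sigma if instrument == "FT" else cfg.qtof_rt_sigma
        rt_offset = 0.0 if instrument == "FT" else cfg.qtof_rt_offset
        frag_jitter = (
            cfg.fragment_mz_jitter_ft if instrument == "FT" else cfg.fragment_mz_jitter_qtof
        )
        features: List[Feature] = []
        spectra: List[Spectrum] = []
        f2c: Dict[str, str] = {}
        s2c: Dict[str, str] = {}
        index: Dict[str, List[str]] = {}
        for c in compounds:
            mz = ion_mz(c.neutral, polarity) + float(rng.normal(0.0, mz_sigma))
            rt = float(np.clip(c.rt + rt_offset + rng.normal(0.0, rt_sigma), 0.0, 35.0))
            fid = f"{label}_{c.compound_id}"
            features.append(
                Feature(
                    feature_id=fid,
                    mz=mz,
                    rt=rt,
                    polarity=polarity,
                    instrument=instrument,
                    abundances=dict(abundance[c.compound_id]),
                    sample_meta=dict(sample_meta),
                )
            )
            f2c[fid] = c.compound_id
            # one consensus CID spectrum per compound and platform
            frag_neutrals, intens = frag_profile[c.compound_id]
            peak_masses = [ion_mz(m, polarity) for m in frag_neutrals] + [mz]
            peaks = [
                Peak(
                    m + float(rng.normal(0.0, frag_jitter)),
                    float(h * rng.lognormal(0.0, cfg.intensity_jitter_sigma)),
                )
                for m, h in zip(peak_masses, intens)
            ]
            sid = f"{label}_spec_{c.compound_id}"
            spectra.append(
                Spectrum(
                    spectrum_id=sid,
                    precursor_mz=mz,
                    rt=rt,
                    polarity=polarity,
                    instrument=instrument,
                    ms_level=2,
                    peaks=peaks,
                )
            )
            s2c[sid] = c.compound_id
            index[fid] = [sid]
        subdbs[label] = SubDB(
            label=label, features=features, spectra=spectra, feature_spectra=index
        )
        feature_to_compound[label] = f2c
        spectrum_to_compound[label] = s2c

    correspondences: Dict[Tuple[str, str], List[Tuple[str, str]]] = {}
    for la, lb in combinations(sorted(subdbs), 2):
        pairs = []
        inv_b = {v: k for k, v in feature_to_compound[lb].items()}
        for fid_a, cid in feature_to_compound[la].items():
            if cid in inv_b:
                pairs.append((fid_a, inv_b[cid]))
        correspondences[(la, lb)] = sorted(pairs)

    truth = GroundTruth(
        compounds=compounds,
        edges=edges,
        feature_to_compound=feature_to_compound,
        spectrum_to_compound=spectrum_to_compound,
        correspondences=correspondences,
        organ_of_compound={c.compound_id: c.home_organ for c in compounds},
        grammar_deltas=grammar_deltas,
    )
    return SimResult(config=cfg, subdbs=subdbs, truth=truth)


def write_dataset(result: SimResult, out_dir) -> Dict[str, Path]:
    """Write feature tables (CSV), spectra (MSP for FT, MGF for QTOF) and
    the ground truth (JSON) into ``out_dir``; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for label, subdb in sorted(result.subdbs.items()):
        fpath = out_dir / f"features_{label}.csv"
        write_feature_table(subdb.features, fpath)
        paths[f"features_{label}"] = fpath
        ext = "msp" if subdb.instrument == "FT" else "mgf"
        spath = out_dir / f"spectra_{label}.{ext}"
        write_spectra(subdb.spectra, spath)
        paths[f"spectra_{label}"] = spath
    tpath = out_dir / "ground_truth.json"
    tpath.write_text(result.truth.to_json())
    paths["ground_truth"] = tpath
    return paths
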