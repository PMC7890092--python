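"""Candidate substrate-product pair (CSPP) network construction.

A CSPP links two LC-MS features whose m/z difference matches a
biotransformation delta and whose elution order agrees with the
expected change in molecular structure (on a reversed-phase column, a
more polar product elutes earlier than its substrate, a more
hydrophobic one later).  Edges run from the lighter feature (candidate
substrate) to the heavier one (candidate product); each edge carries
the biotransformation code, the mass error, and optionally the CID
spectral similarity between the substrate and product spectra.  Nodes
are labelled with the organ in which the feature is most abundant, and
molecular-formula annotations are propagated from seed nodes over the
edges by formula arithmetic.
"""
from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .chem import (
    Biotransformation,
    Formula,
    apply_formula_delta,
    monoisotopic_mass,
    neutral_mass,
    parse_formula,
)
from .similarity import cosine_similarity
from .spectra_io import Feature, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "build_network",
    "score_edges",
    "label_organ_of_max",
    "propagate_annotations",
    "export_network",
    "import_network",
    "Annotation",
    "ORGAN_ORDER",
]

#: Fixed tie-break order for the organ-of-maximal-abundance label.
ORGAN_ORDER = ("ear", "late cob", "leaf", "stem", "tassel")


def _rt_rule_ok(rule: str, rt_substrate: float, rt_product: float) -> bool:
    if rule == "product_earlier":
        return rt_product < rt_substrate
    if rule == "product_later":
        return rt_product > rt_substrate
    return True


def build_network(
    features: Sequence[Feature],
    catalog: Sequence[Biotransformation],
    mass_tol: float = 0.002,
    require_spectra: bool = True,
    feature_spectra: Optional[Mapping[str, Sequence[str]]] = None,
    min_similarity: Optional[float] = None,
) -> nx.MultiDiGraph:
    """Build a CSPP network over a set of same-polarity features.

    For every ordered pair (substrate, product) with
    mz(product) - mz(substrate) within ``mass_tol`` of a catalog delta
    and an elution order compatible with the catalog entry's rt_rule, a
    directed edge substrate -> product is created (a MultiDiGraph keyed
    by the biotransformation short code, so one pair can carry several
    biotransformations).  Candidate pairs are found by a sorted-m/z
    window per catalog delta rather than an all-pairs scan.

    With ``require_spectra`` (the default) only features appearing in
    ``feature_spectra`` with at least one spectrum become nodes,
    mirroring a network restricted to ions with recorded CID spectra.
    ``min_similarity`` is an optional post-hoc edge filter applied by
    :func:`score_edges`; edge existence itself is never gated on
    similarity here.
    """
    polarities = {f.polarity for f in features}
    if len(polarities) > 1:
        raise ValueError(f"features must share polarity, got {sorted(polarities)}")
    if not catalog:
        raise ValueError("catalog must be non-empty")
    if require_spectra:
        if feature_spectra is None:
            raise ValueError("require_spectra=True needs a feature->spectra index")
        nodes = [f for f in features if feature_spectra.get(f.feature_id)]
    else:
        nodes = list(features)

    net = nx.MultiDiGraph()
    net.graph["polarity"] = polarities.pop() if polarities else "neg"
    net.graph["mass_tol"] = mass_tol
    for f in nodes:
        net.add_node(f.feature_id, mz=f.mz, rt=f.rt, feature=f)

    order = sorted(range(len(nodes)), key=lambda i: (nodes[i].mz, nodes[i].feature_id))
    snodes = [nodes[i] for i in order]
    mzs = np.array([f.mz for f in snodes])
    formulas = {bt.short_code: bt for bt in catalog}
    for bt in catalog:
        delta = bt.delta_mass
        for i, sub in enumerate(snodes):
            lo = np.searchsorted(mzs, sub.mz + delta - mass_tol, side="left")
            hi = np.searchsorted(mzs, sub.mz + delta + mass_tol, side="right")
            for j in range(lo, hi):
                prod = snodes[j]
                if prod.feature_id == sub.feature_id:
                    continue
                if prod.mz <= sub.mz:
                    continue
                if not _rt_rule_ok(bt.rt_rule, sub.rt, prod.rt):
                    continue
                err = prod.mz - sub.mz - delta
                net.add_edge(
                    sub.feature_id,
                    prod.feature_id,
                    key=bt.short_code,
                    biotransformation=bt.short_code,
                    mass_error=float(err),
                )
    net.graph["catalog"] = {code: bt for code, bt in formulas.items()}
    return net


def score_edges(
    net: nx.MultiDiGraph,
    spectra: Mapping[str, Sequence[Spectrum]],
    mz_tol: float = 0.01,
    min_similarity: Optional[float] = None,
) -> nx.MultiDiGraph:
    """Attach the substrate-product CID spectral similarity to each edge.

    The edge similarity is the maximum cosine over all (substrate
    spectrum, product spectrum) level-2 pairs; edges lacking spectra on
    either side keep their similarity unset.  If ``min_similarity`` is
    given, scored edges below it are removed (unscored edges are kept).
    """
    to_drop = []
    for u, v, key, data in net.edges(keys=True, data=True):
        spec_u = [s for s in spectra.get(u, []) if s.ms_level == 2]
        spec_v = [s for s in spectra.get(v, []) if s.ms_level == 2]
        if not spec_u or not spec_v:
            continue
        best = 0.0
        matched = 0
        for su in spec_u:
            for sv in spec_v:
                s = cosine_similarity(su, sv, mz_tol=mz_tol)
                if s.value > best:
                    best, matched = s.value, s.n_matched_peaks
        data["similarity"] = best
        data["n_matched_peaks"] = matched
        if min_similarity is not None and best < min_similarity:
            to_drop.append((u, v, key))
    for u, v, key in to_drop:
        net.remove_edge(u, v, key=key)
    return net


def label_organ_of_max(
    net: nx.MultiDiGraph, organ_order: Sequence[str] = ORGAN_ORDER
) -> nx.MultiDiGraph:
    """Label each node with the organ of maximal summed abundance.

    Ties are broken by the fixed organ order and flagged; nodes with
    all-zero abundances are labelled ``"unassigned"``.
    """
    for node, data in net.nodes(data=True):
        f: Optional[Feature] = data.get("feature")
        if f is None:
            data["organ"] = "unassigned"
            continue
        organs = list(dict.fromkeys([o for o, _ in f.sample_meta.values()]))
        ordered = [o for o in organ_order if o in organs] + sorted(
            o for o in organs if o not in organ_order
        )
        totals = {o: f.organ_abundance(o) for o in ordered}
        if not totals or max(totals.values()) <= 0.0:
            data["organ"] = "unassigned"
            continue
        best = max(totals.values())
        winners = [o for o in ordered if totals[o] == best]
        data["organ"] = winners[0]
        data["organ_tie"] = len(winners) > 1
    return net


@dataclass(frozen=True)
class Annotation:
    """A propagated molecular-formula candidate for a network node."""

    formula: Formula
    seed: str
    hops: int
    path: Tuple[str, ...]  # edge biotransformation codes from the seed
    name: Optional[str] = None


def propagate_annotations(
    net: nx.MultiDiGraph,
    seeds: Mapping[str, Tuple[Formula, str]],
    max_hops: int = 3,
    mass_tol: float = 0.002,
) -> Dict[str, List[Annotation]]:
    """Propagate molecular formulas from seed nodes over network edges.

    Breadth-first from each seed up to ``max_hops``: traversing an edge
    in its direction adds the biotransformation formula, traversing
    against it removes it.  A candidate is kept only when the formula
    arithmetic succeeds and the resulting monoisotopic mass matches the
    node's neutral mass (from its m/z and the network polarity) within
    ``mass_tol``.  Raw-delta (formula-less) catalog entries stop
    propagation through their edges.  A node reachable from several
    seeds keeps all distinct candidates; contradictory formulas on one
    node are flagged in the log.
    """
    catalog: Mapping[str, Biotransformation] = net.graph.get("catalog", {})
    polarity = net.graph.get("polarity", "neg")
    results: Dict[str, List[Annotation]] = {}

    def node_neutral(node: str) -> float:
        return neutral_mass(net.nodes[node]["mz"], polarity)

    for seed_node, (formula, name) in seeds.items():
        if seed_node not in net:
            logger.warning("seed node %s not in network; skipped", seed_node)
            continue
        if abs(monoisotopic_mass(formula) - node_neutral(seed_node)) > mass_tol:
            raise ValueError(
                f"seed formula {formula.hill()} does not match node {seed_node} "
                f"neutral mass within {mass_tol} Da"
            )
        start = Annotation(formula=formula, seed=seed_node, hops=0, path=(), name=name)
        results.setdefault(seed_node, []).append(start)
        visited = {seed_node}
        queue = deque([(seed_node, formula, 0, ())])
        while queue:
            node, f, hops, path = queue.popleft()
            if hops >= max_hops:
                continue
            steps: List[Tuple[str, str, str]] = []  # (neighbor, code, direction)
            for _, v, key in net.out_edges(node, keys=True):
                steps.append((v, key, "add"))
            for u, _, key in net.in_edges(node, keys=True):
                steps.append((u, key, "remove"))
            for neighbor, code, direction in steps:
                if neighbor in visited:
                    continue
                bt = catalog.get(code)
                if bt is None or bt.formula is None:
                    continue  # raw-delta edges block formula propagation
                try:
                    nf = apply_formula_delta(f, bt.formula, direction)
                except ValueError:
                    continue
                if abs(monoisotopic_mass(nf) - node_neutral(neighbor)) > mass_tol:
                    continue
                visited.add(neighbor)
                ann = Annotation(
                    formula=nf, seed=seed_node, hops=hops + 1, path=path + (code,)
                )
                results.setdefault(neighbor, []).append(ann)
                queue.append((neighbor, nf, hops + 1, path + (code,)))

    for node, anns in results.items():
        if len({a.formula for a in anns}) > 1:
            logger.warning(
                "node %s received contradictory formula candidates: %s",
                node,
                sorted({a.formula.hill() for a in anns}),
            )
        net.nodes[node]["annotation"] = anns[0].formula.hill()
    return results


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_network(net: nx.MultiDiGraph, path, format: Optional[str] = None) -> None:
    """Write the network as GraphML or a tab-delimited edge table."""
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix == ".graphml" else "edge_table"
    if format == "graphml":
        out = nx.MultiDiGraph()
        for node, data in net.nodes(data=True):
            attrs = {"mz": float(data["mz"]), "rt": float(data["rt"])}
            if "organ" in data:
                attrs["organ"] = data["organ"]
            if "annotation" in data:
                attrs["annotation"] = data["annotation"]
            out.add_node(node, **attrs)
        for u, v, key, data in net.edges(keys=True, data=True):
            attrs = {
                "biotransformation": data["biotransformation"],
                "mass_error": float(data["mass_error"]),
            }
            if "similarity" in data:
                attrs["similarity"] = float(data["similarity"])
            out.add_edge(u, v, key=key, **attrs)
        nx.write_graphml(out, str(path))
    elif format == "edge_table":
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(
                ["substrate", "product", "biotransformation", "mass_error", "similarity"]
            )
            for u, v, key, data in sorted(net.edges(keys=True, data=True)):
                sim = data.get("similarity")
                writer.writerow(
                    [
                        u,
                        v,
                        data["biotransformation"],
                        f"{data['mass_error']:.6f}",
                        "" if sim is None else f"{sim:.6f}",
                    ]
                )
    else:
        raise ValueError(f"unknown network format {format!r}")


def import_network(path) -> nx.MultiDiGraph:
    """Re-import a GraphML file written by :func:`export_network`."""
    net = nx.read_graphml(str(path), force_multigraph=True)
    out = nx.MultiDiGraph()
    for node, data in net.nodes(data=True):
        out.add_node(str(node), **data)
    for u, v, key, data in net.edges(keys=True, data=True):
        out.add_edge(str(u), str(v), key=data.get("biotransformation", key), **data)
    return out
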