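"""Spectral similarity and repository-scale search.

Raw cosine matches fragment peaks directly within a tolerance; modified
cosine additionally allows peaks shifted by the precursor mass difference,
which links structural analogs (e.g. chain-length homologs) in molecular
networks. Peak pairing is an exact maximum-weight one-to-one assignment on
the tolerance-feasible bipartite graph, so toy cases agree with brute-force
enumeration to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectra import Spectrum, split_provenance

#: Monoisotopic deltas linking chain-length / saturation homologs (CH2, C2H4, H2).
HOMOLOG_DELTAS: Dict[str, float] = {
    "CH2": 14.01565,
    "C2H4": 28.03130,
    "H2": 2.01565,
}


def _weights(spectrum: Spectrum, weighting: str) -> np.ndarray:
    if weighting == "sqrt":
        return np.sqrt(spectrum.peaks_intensity)
    if weighting == "none":
        return spectrum.peaks_intensity.astype(float)
    raise ValueError(f"unknown intensity weighting {weighting!r}")


def match_peaks(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float,
    precursor_shift: float = 0.0,
    weighting: str = "sqrt",
) -> List[Tuple[int, int]]:
    """Optimal one-to-one peak pairing between two centroided MS2 spectra.

    Peak i of ``a`` may pair with peak j of ``b`` when their m/z agree within
    ``frag_tol`` directly, or (if ``precursor_shift`` is nonzero) after
    shifting peak j by the precursor difference. The returned pairing
    maximizes the summed weight products; each peak is used at most once.
    Ties are resolved deterministically (smaller |dm/z|, then lower index).
    """
    n_a, n_b = a.n_peaks, b.n_peaks
    if n_a == 0 or n_b == 0:
        return []
    diff = np.abs(a.peaks_mz[:, None] - b.peaks_mz[None, :])
    feasible = diff <= frag_tol
    if precursor_shift != 0.0:
        shifted = np.abs(a.peaks_mz[:, None] - (b.peaks_mz[None, :] + precursor_shift))
        feasible |= shifted <= frag_tol
        diff = np.minimum(diff, shifted)
    if not feasible.any():
        return []
    w_a = _weights(a, weighting)
    w_b = _weights(b, weighting)
    # ties between equal-total assignments cannot change the cosine value;
    # the assignment solver itself is deterministic, which is what matters
    score = np.where(feasible, w_a[:, None] * w_b[None, :], 0.0)
    rows, cols = linear_sum_assignment(score, maximize=True)
    pairs = [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if feasible[i, j]
    ]
    return sorted(pairs)


def _cosine(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float,
    precursor_shift: float,
    weighting: str,
) -> Tuple[float, int]:
    if a.n_peaks and a.total_intensity == 0:
        raise ValueError("degenerate spectrum: all intensities zero")
    if b.n_peaks and b.total_intensity == 0:
        raise ValueError("degenerate spectrum: all intensities zero")
    pairs = match_peaks(a, b, frag_tol, precursor_shift, weighting)
    if not pairs:
        return 0.0, 0
    w_a = _weights(a, weighting)
    w_b = _weights(b, weighting)
    num = float(sum(w_a[i] * w_b[j] for i, j in pairs))
    denom = float(np.linalg.norm(w_a) * np.linalg.norm(w_b))
    if denom == 0:
        return 0.0, 0
    return min(num / denom, 1.0), len(pairs)


def raw_cosine(
    a: Spectrum, b: Spectrum, frag_tol: float = 0.02, weighting: str = "sqrt"
) -> Tuple[float, int]:
    """Direct-match cosine similarity and matched-peak count.

    Symmetric, bounded in [0, 1], and 1 for a nonempty spectrum against
    itself. Intensities are square-root weighted by default (configurable).
    """
    return _cosine(a, b, frag_tol, 0.0, weighting)


def modified_cosine(
    a: Spectrum, b: Spectrum, frag_tol: float = 0.02, weighting: str = "sqrt"
) -> Tuple[float, int]:
    """Shift-tolerant cosine allowing matches offset by the precursor delta.

    Never smaller than the raw cosine on the same pair, since the feasible
    pairing set is a superset of the direct-match set.
    """
    if a.precursor_mz is None or b.precursor_mz is None:
        raise ValueError("modified cosine requires precursor m/z on both spectra")
    shift = a.precursor_mz - b.precursor_mz
    return _cosine(a, b, frag_tol, shift, weighting)


@dataclass(frozen=True)
class SpectralMatch:
    """One library-spectrum hit in a corpus file."""

    query_id: str
    corpus_file: str
    scan: int
    cosine: float
    n_matched: int
    precursor_delta: float


def fasst_search(
    library: Sequence,
    corpus: Sequence[Spectrum],
    prec_tol: float = 0.02,
    frag_tol: float = 0.02,
    min_cos: float = 0.7,
    min_matched: int = 3,
    weighting: str = "sqrt",
) -> List[SpectralMatch]:
    """Batch library-vs-corpus search (MASST/FASST style).

    ``library`` items are either :class:`Spectrum` objects or objects with a
    ``spectrum`` attribute and a ``query_id``/``provenance`` label. Corpus
    candidates are pruned by a sorted precursor index; pruning is complete
    (the probe window is widened by ``prec_tol``), so the result set equals
    an exhaustive all-pairs scan.
    """
    if not corpus:
        return []
    precursors = np.array(
        [s.precursor_mz if s.precursor_mz is not None else np.nan for s in corpus]
    )
    order = np.argsort(precursors, kind="stable")
    sorted_prec = precursors[order]

    matches: List[SpectralMatch] = []
    for entry in library:
        spectrum = getattr(entry, "spectrum", entry)
        query_id = getattr(entry, "query_id", None) or spectrum.provenance
        if spectrum.precursor_mz is None:
            continue
        lo = np.searchsorted(sorted_prec, spectrum.precursor_mz - prec_tol, side="left")
        hi = np.searchsorted(sorted_prec, spectrum.precursor_mz + prec_tol, side="right")
        for idx in order[lo:hi]:
            candidate = corpus[int(idx)]
            delta = spectrum.precursor_mz - candidate.precursor_mz
            if abs(delta) > prec_tol:
                continue
            cos, n_matched = raw_cosine(spectrum, candidate, frag_tol, weighting)
            if cos >= min_cos and n_matched >= min_matched:
                file_id, scan = split_provenance(candidate.provenance)
                matches.append(
                    SpectralMatch(
                        query_id=query_id,
                        corpus_file=file_id,
                        scan=scan,
                        cosine=cos,
                        n_matched=n_matched,
                        precursor_delta=delta,
                    )
                )
    matches.sort(key=lambda m: (m.query_id, m.corpus_file, m.scan))
    return matches


@dataclass(frozen=True)
class NetworkEdge:
    """Undirected molecular-network edge (canonical ordering a < b)."""

    feature_a: str
    feature_b: str
    cosine: float
    n_matched: int
    delta_mass: float  # precursor_a - precursor_b


def build_network(
    features: Sequence[Spectrum],
    min_cos: float = 0.7,
    min_matched: int = 2,
    frag_tol: float = 0.02,
    top_k: Optional[int] = None,
    weighting: str = "sqrt",
) -> List[NetworkEdge]:
    """Molecular network over MS2 features via modified cosine.

    An edge joins every feature pair with modified cosine >= ``min_cos`` and
    at least ``min_matched`` matched peaks; the low matched-peak default (2)
    accommodates sparse spectra such as short-chain or sodiated ions.
    ``top_k`` optionally keeps only each node's K best edges (off by default).
    """
    edges: List[NetworkEdge] = []
    for i in range(len(features)):
        for j in range(i + 1, len(features)):
            f_i, f_j = features[i], features[j]
            cos, n_matched = modified_cosine(f_i, f_j, frag_tol, weighting)
            if cos >= min_cos and n_matched >= min_matched:
                a, b = f_i, f_j
                if b.provenance < a.provenance:
                    a, b = b, a
                edges.append(
                    NetworkEdge(
                        feature_a=a.provenance,
                        feature_b=b.provenance,
                        cosine=cos,
                        n_matched=n_matched,
                        delta_mass=a.precursor_mz - b.precursor_mz,
                    )
                )
    if top_k is not None:
        kept: List[NetworkEdge] = []
        by_node: Dict[str, int] = {}
        for edge in sorted(edges, key=lambda e: -e.cosine):
            if by_node.get(edge.feature_a, 0) < top_k and by_node.get(edge.feature_b, 0) < top_k:
                kept.append(edge)
                by_node[edge.feature_a] = by_node.get(edge.feature_a, 0) + 1
                by_node[edge.feature_b] = by_node.get(edge.feature_b, 0) + 1
        edges = sorted(kept, key=lambda e: (e.feature_a, e.feature_b))
    return edges


@dataclass
class SeedAnnotation:
    """A confidently annotated network node used to seed propagation."""

    node: str
    head: str
    carbons: int
    unsaturations: int
    rt: Optional[float] = None


@dataclass
class PropagatedAnnotation:
    """Chain-length-analog annotation inferred through the network (MSI level 2)."""

    node: str
    name: str
    head: str
    carbons: int
    unsaturations: int
    via: str
    delta_label: str
    level: str = "putative"
    ambiguous: bool = False


def propagate_annotations(
    edges: Sequence[NetworkEdge],
    seeds: Sequence[SeedAnnotation],
    node_rt: Mapping[str, float],
    frag_tol: float = 0.02,
    rt_tol: float = 0.05,
    max_hops: int = 1,
    homolog_deltas: Mapping[str, float] = HOMOLOG_DELTAS,
) -> List[PropagatedAnnotation]:
    """Propagate chain-length analog annotations along homolog-delta edges.

    A neighbor of an annotated node inherits an analog annotation when the
    edge's mass delta matches a CH2/C2H4/H2 homolog difference within
    ``frag_tol`` and the retention-time rule holds: the heavier (longer or
    more saturated) homolog elutes no earlier than ``rt_tol`` minutes before
    the lighter one. Propagation is breadth-first up to ``max_hops`` hops;
    conflicting names on one node are all recorded and flagged ambiguous.
    """
    adjacency: Dict[str, List[NetworkEdge]] = {}
    for edge in edges:
        adjacency.setdefault(edge.feature_a, []).append(edge)
        adjacency.setdefault(edge.feature_b, []).append(edge)

    # node -> list of proposed annotations
    proposals: Dict[str, List[PropagatedAnnotation]] = {}
    frontier: List[SeedAnnotation] = [
        SeedAnnotation(s.node, s.head, s.carbons, s.unsaturations, s.rt if s.rt is not None else node_rt.get(s.node))
        for s in seeds
    ]
    seed_nodes = {s.node for s in seeds}
    visited = set(seed_nodes)

    for _hop in range(max_hops):
        next_frontier: List[SeedAnnotation] = []
        for current in frontier:
            for edge in adjacency.get(current.node, []):
                neighbor = edge.feature_b if edge.feature_a == current.node else edge.feature_a
                if neighbor in visited:
                    continue
                # mass delta of neighbor relative to the annotated node
                delta = -edge.delta_mass if edge.feature_a == current.node else edge.delta_mass
                analog = _homolog_analog(current, delta, homolog_deltas, frag_tol)
                if analog is None:
                    continue
                carbons, unsats, label = analog
                if not _rt_rule_holds(current, neighbor, delta, node_rt, rt_tol):
                    continue
                name = f"3OH-C{carbons}:{unsats} {current.head}"
                proposals.setdefault(neighbor, []).append(
                    PropagatedAnnotation(
                        node=neighbor,
                        name=name,
                        head=current.head,
                        carbons=carbons,
                        unsaturations=unsats,
                        via=current.node,
                        delta_label=label,
                    )
                )
                next_frontier.append(
                    SeedAnnotation(neighbor, current.head, carbons, unsats, node_rt.get(neighbor))
                )
        for ann_list in proposals.values():
            for ann in ann_list:
                visited.add(ann.node)
        frontier = next_frontier

    results: List[PropagatedAnnotation] = []
    for node in sorted(proposals):
        names = {ann.name for ann in proposals[node]}
        ambiguous = len(names) > 1
        for ann in proposals[node]:
            ann.ambiguous = ambiguous
            results.append(ann)
    return results


def _homolog_analog(
    seed: SeedAnnotation,
    delta: float,
    homolog_deltas: Mapping[str, float],
    tol: float,
) -> Optional[Tuple[int, int, str]]:
    """Map a signed mass delta to a (carbons, unsaturations, label) analog."""
    for sign in (1, -1):
        if abs(delta - sign * homolog_deltas["CH2"]) <= tol:
            return seed.carbons + sign, seed.unsaturations, f"{'+' if sign > 0 else '-'}CH2"
        if abs(delta - sign * homolog_deltas["C2H4"]) <= tol:
            return seed.carbons + 2 * sign, seed.unsaturations, f"{'+' if sign > 0 else '-'}C2H4"
        if abs(delta - sign * homolog_deltas["H2"]) <= tol:
            unsats = seed.unsaturations - sign  # +H2 = one fewer double bond
            if unsats < 0:
                return None
            return seed.carbons, unsats, f"{'+' if sign > 0 else '-'}H2"
    return None


def _rt_rule_holds(
    seed: SeedAnnotation,
    neighbor: str,
    delta: float,
    node_rt: Mapping[str, float],
    rt_tol: float,
) -> bool:
    rt_seed = seed.rt if seed.rt is not None else node_rt.get(seed.node)
    rt_neighbor = node_rt.get(neighbor)
    if rt_seed is None or rt_neighbor is None:
        return False
    if delta > 0:  # neighbor is the heavier homolog: must elute later
        return rt_neighbor - rt_seed > -rt_tol and rt_neighbor > rt_seed - rt_tol
    return rt_seed - rt_neighbor > -rt_tol


def matches_to_frame(matches: Sequence[SpectralMatch]):
    """Tabulate matches in the MASST-style result layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "query_id": m.query_id,
                "file": m.corpus_file,
                "scan": m.scan,
                "cosine": m.cosine,
                "n_matched": m.n_matched,
                "precursor_delta": m.precursor_delta,
            }
            for m in matches
        ],
        columns=["query_id", "file", "scan", "cosine", "n_matched", "precursor_delta"],
    )


def edges_to_graph(edges: Sequence[NetworkEdge]):
    """Build a networkx graph from a molecular-network edge list."""
    import networkx as nx

    graph = nx.Graph()
    for edge in edges:
        graph.add_edge(
            edge.feature_a,
            edge.feature_b,
            cosine=edge.cosine,
            n_matched=edge.n_matched,
            delta_mass=edge.delta_mass,
        )
    return graph
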