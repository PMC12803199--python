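"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive recursion and nested
loops — and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Tuple

import numpy as np

# Same physical constants, restated independently (NIST).
_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}
_PROTON = 1.007276


def brute_force_cosine(
    mz_a: Sequence[float],
    int_a: Sequence[float],
    mz_b: Sequence[float],
    int_b: Sequence[float],
    frag_tol: float,
    precursor_shift: float = 0.0,
) -> Tuple[float, int]:
    """Max-total-score one-to-one peak pairing by exhaustive recursion.

    Returns (cosine, n_matched) using square-root intensity weights, for
    spectra small enough (<= ~8 peaks) that full enumeration is instant.
    """
    w_a = [math.sqrt(x) for x in int_a]
    w_b = [math.sqrt(x) for x in int_b]
    feasible: List[List[int]] = []
    for i, mza in enumerate(mz_a):
        row = []
        for j, mzb in enumerate(mz_b):
            if abs(mza - mzb) <= frag_tol or (
                precursor_shift != 0.0 and abs(mza - (mzb + precursor_shift)) <= frag_tol
            ):
                row.append(j)
        feasible.append(row)

    best = {"score": 0.0, "n": 0}

    def recurse(i: int, used: set, score: float, n: int) -> None:
        if i == len(mz_a):
            if score > best["score"] + 1e-300 or (
                abs(score - best["score"]) < 1e-300 and n > best["n"]
            ):
                best["score"], best["n"] = score, n
            return
        recurse(i + 1, used, score, n)  # leave peak i unmatched
        for j in feasible[i]:
            if j not in used:
                recurse(i + 1, used | {j}, score + w_a[i] * w_b[j], n + 1)

    recurse(0, set(), 0.0, 0)
    denom = math.sqrt(sum(w * w for w in w_a)) * math.sqrt(sum(w * w for w in w_b))
    if denom == 0 or best["n"] == 0:
        return 0.0, 0
    return min(best["score"] / denom, 1.0), best["n"]


def brute_force_search(
    library: Sequence, corpus: Sequence, prec_tol: float, frag_tol: float,
    min_cos: float, min_matched: int,
) -> set:
    """All-pairs library-vs-corpus scan; returns {(query_id, file, scan)}."""
    from revmet.search import raw_cosine
    from revmet.spectra import split_provenance

    hits = set()
    for entry in library:
        spectrum = getattr(entry, "spectrum", entry)
        query_id = getattr(entry, "query_id", None) or spectrum.provenance
        for candidate in corpus:
            if candidate.precursor_mz is None or spectrum.precursor_mz is None:
                continue
            if abs(spectrum.precursor_mz - candidate.precursor_mz) > prec_tol:
                continue
            cos, n = raw_cosine(spectrum, candidate, frag_tol)
            if cos >= min_cos and n >= min_matched:
                hits.add((query_id, *split_provenance(candidate.provenance)))
    return hits


def subformula_peak_masses(parent: Dict[str, int], frag_tol: float) -> List[float]:
    """All protonated sub-formula masses of a small parent, by nested loops."""
    elements = sorted(parent)
    ranges = [range(parent[e] + 1) for e in elements]
    masses = []
    for counts in itertools.product(*ranges):
        masses.append(sum(_MASS[e] * c for e, c in zip(elements, counts)) + _PROTON)
    return sorted(masses)


def explained_fraction_oracle(
    mz: Sequence[float], intensity: Sequence[float], parent: Dict[str, int], frag_tol: float
) -> float:
    """Explained-intensity fraction by exhaustive sub-formula enumeration."""
    masses = subformula_peak_masses(parent, frag_tol)
    total = sum(intensity)
    if total == 0:
        return 0.0
    explained = 0.0
    for m, i in zip(mz, intensity):
        if any(abs(m - cand) <= frag_tol for cand in masses):
            explained += i
    return explained / total


def wilcoxon_exact_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum p-value by full enumeration of group assignments."""
    pooled = sorted(list(x) + list(y))
    n_x = len(x)
    ranks = {v: r + 1 for r, v in enumerate(pooled)}  # tie-free inputs only
    w_obs = sum(ranks[v] for v in x)
    n = len(pooled)
    all_w = [sum(combo) for combo in itertools.combinations(range(1, n + 1), n_x)]
    mean_w = n_x * (n + 1) / 2.0
    dev = abs(w_obs - mean_w)
    extreme = sum(1 for w in all_w if abs(w - mean_w) >= dev - 1e-12)
    return extreme / len(all_w)


def atom_counts_from_smiles_graph(smiles: str) -> Dict[str, int]:
    """Independent atom count over a SMILES string's heavy-atom graph.

    A minimal SMILES walk (sufficient for the simple test molecules used):
    counts ring-free heavy atoms and adds implicit hydrogens by standard
    valences, so it stays independent of RDKit.
    """
    import re

    valence = {"C": 4, "N": 3, "O": 2, "S": 2}
    tokens = re.findall(r"Cl|Br|[A-Z][a-z]?|[a-z]|\(|\)|=|#|\d", smiles)
    atoms: List[Dict] = []
    stack: List[int] = []
    prev: int | None = None
    bond_order = 1
    for tok in tokens:
        if tok == "(":
            stack.append(prev)
        elif tok == ")":
            prev = stack.pop()
        elif tok == "=":
            bond_order = 2
        elif tok == "#":
            bond_order = 3
        elif tok.isdigit():
            continue  # ring closures unused in test molecules
        elif tok[0].isalpha():
            symbol = tok.upper() if tok.islower() else tok
            atoms.append({"symbol": symbol, "bonds": 0})
            idx = len(atoms) - 1
            if prev is not None:
                atoms[prev]["bonds"] += bond_order
                atoms[idx]["bonds"] += bond_order
            prev = idx
            bond_order = 1
    counts: Dict[str, int] = {}
    h = 0
    for atom in atoms:
        counts[atom["symbol"]] = counts.get(atom["symbol"], 0) + 1
        h += max(valence.get(atom["symbol"], 0) - atom["bonds"], 0)
    if h:
        counts["H"] = counts.get("H", 0) + h
    return counts
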