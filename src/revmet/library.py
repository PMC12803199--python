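"""Targeted extraction and validation of reference MS2 spectra.

Given enumerated conjugate targets and LC-MS/MS runs of crude reaction
mixtures, this module finds candidate ions within a ppm window of each
adducted target mass, applies intensity floors, scores how much of each MS2
spectrum is explainable by sub-formulas of the parent, checks head-group
diagnostic fragments, enforces the adduct-inclusion rule, and writes the
surviving spectra as a shareable MGF library with a batch-style TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import (
    AdductSpec,
    PROTON_MASS,
    enumerate_subformulas,
    formula_to_string,
    get_adduct,
    ppm_window,
)
from .conjugates import AmineHead, ConjugateTarget
from .spectra import Spectrum, write_mgf


@dataclass
class LCMSRun:
    """A centroided LC-MS/MS run as parallel MS1 and MS2 scan lists."""

    name: str
    ms1_scans: List[Spectrum] = field(default_factory=list)
    ms2_scans: List[Spectrum] = field(default_factory=list)
    centroided: bool = True

    def ms1_rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.ms1_scans], dtype=float)


@dataclass
class GateConfig:
    """Thresholds for library curation.

    Defaults follow targeted reverse-metabolomics practice: 10 ppm precursor
    window, 5e4 MS1 intensity floor, 1e5 feature-height floor, 0.6 minimum
    explained-intensity fraction, and a 0.01 Da fragment tolerance for
    explanation/diagnostic checks (reference instruments are high-resolution;
    the looser 0.02 Da tolerance is for repository search).
    """

    ppm_tol: float = 10.0
    ms1_min: float = 5e4
    height_min: float = 1e5
    explanation_min: float = 0.6
    frag_tol: float = 0.01
    min_diag: Optional[int] = None  # None = all listed fragments required
    min_feature_width: float = 0.2  # minutes
    adducts: Tuple[str, ...] = ("[M+H]+", "[M+Na]+", "[M+K]+", "[M+NH4]+", "[M-H2O+H]+")

    def adduct_specs(self) -> List[AdductSpec]:
        return [get_adduct(name) for name in self.adducts]


#: Adducts that anchor the inclusion rule: other ion forms of a target enter
#: the library only if one of these was itself accepted for that target.
ANCHOR_ADDUCTS = ("[M+H]+", "[M+NH4]+")


@dataclass
class LibraryEntry:
    """A candidate (eventually validated) reference spectrum."""

    target: ConjugateTarget
    adduct: AdductSpec
    spectrum: Spectrum
    ms1_intensity: float
    feature_height: float
    explanation_score: float = float("nan")
    diagnostic_status: str = "untested"  # pass / fail / uncurated / untested
    accepted: bool = False
    rejected_by: Optional[str] = None

    @property
    def target_key(self) -> Tuple[str, str, int]:
        return (self.target.head.name, self.target.tail.name, self.target.isomer_index)

    @property
    def query_id(self) -> str:
        return f"{self.target.name}|{self.adduct.name}|{self.spectrum.provenance}"

    @property
    def diagnostic_pass(self) -> bool:
        return self.diagnostic_status in ("pass", "uncurated")


def ms2_explanation_score(
    spectrum: Spectrum, parent_formula: Mapping[str, int], frag_tol: float = 0.01
) -> float:
    """Fraction of MS2 intensity assignable to protonated parent sub-formulas.

    A peak is explained if some element-wise sub-composition ``f`` of the
    parent satisfies ``|mass(f) + proton - mz| <= frag_tol`` (water loss and
    the charge-carrying proton are themselves sub-formula arithmetic, so no
    special cases are needed). Enumeration is exact with mass pruning.
    """
    if not parent_formula:
        raise ValueError("parent formula must be non-empty")
    if spectrum.n_peaks == 0:
        warnings.warn("empty peak list: explanation score is 0", stacklevel=2)
        return 0.0
    total = spectrum.total_intensity
    if total == 0:
        return 0.0
    max_mz = float(spectrum.peaks_mz.max())
    masses, _comps = enumerate_subformulas(parent_formula, max_mass=max_mz)
    candidates = masses + PROTON_MASS
    idx = np.searchsorted(candidates, spectrum.peaks_mz)
    explained = np.zeros(spectrum.n_peaks, dtype=bool)
    for offset in (0, -1, 1):
        probe = np.clip(idx + offset, 0, candidates.size - 1)
        explained |= np.abs(candidates[probe] - spectrum.peaks_mz) <= frag_tol
    return float(spectrum.peaks_intensity[explained].sum() / total)


def diagnostic_status(
    spectrum: Spectrum,
    head: AmineHead,
    frag_tol: float = 0.01,
    min_diag: Optional[int] = None,
) -> str:
    """Diagnostic-fragment verdict: 'pass', 'fail', or 'uncurated'.

    A head with no curated diagnostic list passes vacuously but is flagged
    'uncurated'. By default every listed fragment must be present within
    ``frag_tol``; ``min_diag`` relaxes this to a minimum count.
    """
    frags = head.diagnostic_fragments
    if not frags:
        return "uncurated"
    required = len(frags) if min_diag is None else min(min_diag, len(frags))
    found = sum(
        1
        for frag in frags
        if spectrum.n_peaks and np.min(np.abs(spectrum.peaks_mz - frag)) <= frag_tol
    )
    return "pass" if found >= required else "fail"


def diagnostic_fragment_check(
    spectrum: Spectrum,
    head: AmineHead,
    frag_tol: float = 0.01,
    min_diag: Optional[int] = None,
) -> bool:
    """Boolean form of :func:`diagnostic_status` (uncurated counts as pass)."""
    return diagnostic_status(spectrum, head, frag_tol, min_diag) != "fail"


def _xic(run: LCMSRun, mz: float, ppm_tol: float) -> np.ndarray:
    """Extracted-ion intensity per MS1 scan within a ±ppm window."""
    half = ppm_window(mz, ppm_tol)
    trace = np.zeros(len(run.ms1_scans))
    for i, scan in enumerate(run.ms1_scans):
        lo = np.searchsorted(scan.peaks_mz, mz - half, side="left")
        hi = np.searchsorted(scan.peaks_mz, mz + half, side="right")
        if hi > lo:
            trace[i] = scan.peaks_intensity[lo:hi].sum()
    return trace


def _features_from_xic(
    trace: np.ndarray, rts: np.ndarray, min_width: float
) -> List[Tuple[float, float, float]]:
    """Contiguous nonzero XIC regions as (rt_start, rt_end, height) features."""
    features = []
    nonzero = trace > 0
    i = 0
    n = len(trace)
    while i < n:
        if not nonzero[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and nonzero[j + 1]:
            j += 1
        if rts[j] - rts[i] >= min_width:
            features.append((float(rts[i]), float(rts[j]), float(trace[i : j + 1].max())))
        i = j + 1
    return features


def extract_candidates(
    run: LCMSRun,
    targets: Sequence[ConjugateTarget],
    adducts: Sequence[AdductSpec],
    ppm_tol: float = 10.0,
    ms1_min: float = 5e4,
    height_min: float = 1e5,
    min_feature_width: float = 0.2,
    _audit: Optional[List[dict]] = None,
) -> List[LibraryEntry]:
    """Candidate library entries passing the ppm / MS1 / feature-height gates.

    One entry per (target, adduct, MS2 scan) whose observed precursor lies
    within ``ppm_tol`` of the theoretical adduct m/z, whose MS1 extracted-ion
    intensity at the MS2's retention time is at least ``ms1_min``, and whose
    enclosing XIC feature reaches ``height_min``. When ``_audit`` is given,
    gate-failing candidates are appended to it with the first failing gate.
    """
    if not run.centroided:
        raise ValueError(
            f"run {run.name!r} contains profile-mode spectra; centroid before extraction"
        )
    entries: List[LibraryEntry] = []
    if not run.ms2_scans:
        return entries
    rts = run.ms1_rts()
    for target in targets:
        for adduct in adducts:
            theo_mz = target.adduct_mz(adduct)
            half = ppm_window(theo_mz, ppm_tol)
            ms2_hits = [
                s
                for s in run.ms2_scans
                if s.precursor_mz is not None and abs(s.precursor_mz - theo_mz) <= half
            ]
            if not ms2_hits:
                continue
            trace = _xic(run, theo_mz, ppm_tol) if run.ms1_scans else np.empty(0)
            features = (
                _features_from_xic(trace, rts, min_feature_width) if trace.size else []
            )
            for ms2 in ms2_hits:
                ms1_intensity = 0.0
                if trace.size and ms2.rt is not None:
                    nearest = int(np.argmin(np.abs(rts - ms2.rt)))
                    ms1_intensity = float(trace[nearest])
                height = 0.0
                for rt_start, rt_end, feat_height in features:
                    if ms2.rt is not None and rt_start - 1e-9 <= ms2.rt <= rt_end + 1e-9:
                        height = feat_height
                        break
                entry = LibraryEntry(
                    target=target,
                    adduct=adduct,
                    spectrum=ms2,
                    ms1_intensity=ms1_intensity,
                    feature_height=height,
                )
                if ms1_intensity < ms1_min:
                    entry.rejected_by = "ms1_intensity"
                elif height < height_min:
                    entry.rejected_by = "feature_height"
                if entry.rejected_by is None:
                    entries.append(entry)
                elif _audit is not None:
                    _audit.append(_audit_row(run.name, entry))
    return entries


def apply_adduct_inclusion(entries: Sequence[LibraryEntry]) -> List[LibraryEntry]:
    """Keep non-anchor adduct entries only when the target has an anchor form.

    Anchor forms ([M+H]+ or [M+NH4]+) are never removed by this rule; sodium,
    potassium and water-loss entries require an accepted anchor entry for the
    same conjugate target. Dropped entries are labeled ``adduct_inclusion``.
    """
    anchored = {
        e.target_key
        for e in entries
        if e.adduct.name in ANCHOR_ADDUCTS and e.rejected_by is None
    }
    accepted: List[LibraryEntry] = []
    for entry in entries:
        if entry.rejected_by is not None:
            continue
        if entry.adduct.name in ANCHOR_ADDUCTS or entry.target_key in anchored:
            accepted.append(entry)
        else:
            entry.rejected_by = "adduct_inclusion"
    return accepted


@dataclass
class Library:
    """A validated spectral library plus its curation audit trail."""

    entries: List[LibraryEntry]
    audit: pd.DataFrame
    summary: Dict[str, int]

    @property
    def unique_compounds(self) -> int:
        """Distinct (head, tail) pairs across accepted entries."""
        return len({(e.target.head.name, e.target.tail.name) for e in self.entries})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound": e.target.name,
                "head": e.target.head.name,
                "tail": e.target.tail.name,
                "isomer_index": e.target.isomer_index,
                "adduct": e.adduct.name,
                "smiles": e.target.smiles,
                "exact_mass": round(e.target.mono_mass, 6),
                "provenance": e.spectrum.provenance,
                "explanation_score": round(e.explanation_score, 4),
                "diagnostic": e.diagnostic_status,
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows)


def _audit_row(run_name: str, entry: LibraryEntry) -> dict:
    return {
        "run": run_name,
        "compound": entry.target.name,
        "adduct": entry.adduct.name,
        "provenance": entry.spectrum.provenance,
        "ms1_intensity": entry.ms1_intensity,
        "feature_height": entry.feature_height,
        "explanation_score": entry.explanation_score,
        "diagnostic": entry.diagnostic_status,
        "accepted": entry.accepted,
        "rejected_by": entry.rejected_by or "",
        "external_tool_verdict": "",  # slot for out-of-repo validation (e.g. SIRIUS)
    }


def build_library(
    runs: Sequence[LCMSRun],
    targets: Sequence[ConjugateTarget],
    config: GateConfig = GateConfig(),
) -> Library:
    """Run the full curation cascade over reaction-mixture runs.

    Acceptance requires, in order: the extraction gates (ppm window, MS1
    floor, feature height), explained-intensity fraction >= the configured
    minimum, the diagnostic-fragment check, and the adduct-inclusion rule.
    Per-run failures are collected and re-raised only if every run fails.
    """
    adducts = config.adduct_specs()
    audit_rows: List[dict] = []
    candidates: List[LibraryEntry] = []
    run_errors: List[str] = []
    for run in runs:
        try:
            candidates.extend(
                extract_candidates(
                    run,
                    targets,
                    adducts,
                    ppm_tol=config.ppm_tol,
                    ms1_min=config.ms1_min,
                    height_min=config.height_min,
                    min_feature_width=config.min_feature_width,
                    _audit=audit_rows,
                )
            )
        except Exception as exc:  # noqa: BLE001 - per-run isolation is the contract
            run_errors.append(f"{run.name}: {exc}")
    if run_errors and len(run_errors) == len(runs):
        raise RuntimeError("all runs failed:\n" + "\n".join(run_errors))

    for entry in candidates:
        entry.explanation_score = ms2_explanation_score(
            entry.spectrum, entry.target.formula, config.frag_tol
        )
        entry.diagnostic_status = diagnostic_status(
            entry.spectrum, entry.target.head, config.frag_tol, config.min_diag
        )
        if entry.explanation_score < config.explanation_min:
            entry.rejected_by = "explanation_score"
        elif entry.diagnostic_status == "fail":
            entry.rejected_by = "diagnostic"

    accepted = apply_adduct_inclusion(candidates)
    for entry in accepted:
        entry.accepted = True

    run_name_of = {}
    for run in runs:
        for scan in run.ms2_scans:
            run_name_of[scan.provenance] = run.name
    for entry in candidates:
        audit_rows.append(_audit_row(run_name_of.get(entry.spectrum.provenance, ""), entry))
    audit = pd.DataFrame(
        audit_rows,
        columns=[
            "run",
            "compound",
            "adduct",
            "provenance",
            "ms1_intensity",
            "feature_height",
            "explanation_score",
            "diagnostic",
            "accepted",
            "rejected_by",
            "external_tool_verdict",
        ],
    )
    gates = ["ms1_intensity", "feature_height", "explanation_score", "diagnostic", "adduct_inclusion"]
    summary = {
        "candidates": len(audit),
        "accepted": len(accepted),
        **{f"rejected_{g}": int((audit["rejected_by"] == g).sum()) for g in gates},
    }
    if run_errors:
        summary["failed_runs"] = len(run_errors)
    return Library(entries=accepted, audit=audit, summary=summary)


def write_library(library: Library, mgf_path, tsv_path=None) -> None:
    """Write accepted entries as an MGF library and a batch-style TSV."""
    spectra = []
    for entry in library.entries:
        spectrum = entry.spectrum
        annotated = Spectrum(
            peaks_mz=spectrum.peaks_mz,
            peaks_intensity=spectrum.peaks_intensity,
            ms_level=2,
            precursor_mz=spectrum.precursor_mz,
            rt=spectrum.rt,
            drift=spectrum.drift,
            provenance=entry.query_id,
            metadata={
                "COMPOUND": entry.target.name,
                "ADDUCT": entry.adduct.name,
                "SMILES": entry.target.smiles,
                "FORMULA": formula_to_string(entry.target.formula),
                "EXPLANATION_SCORE": f"{entry.explanation_score:.4f}",
            },
        )
        spectra.append(annotated)
    write_mgf(spectra, mgf_path)
    if tsv_path is not None:
        frame = pd.DataFrame(
            [
                {
                    "filename": entry.spectrum.provenance.rsplit(":", 1)[0],
                    "compound_name": entry.target.name,
                    "adduct": entry.adduct.name,
                    "smiles": entry.target.smiles,
                    "exact_mass": round(entry.target.mono_mass, 6),
                    "scan": entry.spectrum.provenance.rsplit(":", 1)[-1],
                }
                for entry in library.entries
            ]
        )
        frame.to_csv(tsv_path, sep="\t", index=False)
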