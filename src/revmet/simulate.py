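"""Seeded generators for every input the pipeline consumes.

These stand in for the wet lab and the public repositories: amine/tail
definition tables, reaction-mixture LC-MS/MS runs with planted conjugate
spectra, a multi-file spectral corpus with planted library copies and
decoys, ReDU-style metadata over those files, and two-group feature tables
with planted effects. Every generator takes an integer seed and is fully
deterministic; each returns a ground-truth manifest that downstream tests
treat as the single source of truth.

The fragment model makes no attempt at physical realism: planted MS2 peaks
are protonated sub-formula masses (head fragments, water losses, the
precursor) plus uniform spurious peaks — exactly the structures the
explanation and diagnostic gates measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import (
    AdductSpec,
    PROTON_MASS,
    combine_formulas,
    get_adduct,
    monoisotopic_mass,
    subtract_formula,
)
from .conjugates import (
    AmineHead,
    ConjugateTarget,
    LipidTail,
    enumerate_conjugates,
)
from .library import LCMSRun, LibraryEntry
from .search import raw_cosine
from .spectra import Spectrum
from .stats import FeatureTable

# ---------------------------------------------------------------------------
# Curated real amine head groups: proteinogenic amino acids, polyamines,
# and amine metabolites/neurotransmitters; SMILES carry no stereochemistry.

CURATED_HEADS: List[Tuple[str, str]] = [
    ("glycine", "NCC(=O)O"),
    ("alanine", "CC(N)C(=O)O"),
    ("valine", "CC(C)C(N)C(=O)O"),
    ("leucine", "CC(C)CC(N)C(=O)O"),
    ("isoleucine", "CCC(C)C(N)C(=O)O"),
    ("serine", "OCC(N)C(=O)O"),
    ("threonine", "CC(O)C(N)C(=O)O"),
    ("cysteine", "SCC(N)C(=O)O"),
    ("methionine", "CSCCC(N)C(=O)O"),
    ("aspartic acid", "OC(=O)CC(N)C(=O)O"),
    ("glutamic acid", "OC(=O)CCC(N)C(=O)O"),
    ("asparagine", "NC(=O)CC(N)C(=O)O"),
    ("glutamine", "NC(=O)CCC(N)C(=O)O"),
    ("phenylalanine", "NC(Cc1ccccc1)C(=O)O"),
    ("tyrosine", "NC(Cc1ccc(O)cc1)C(=O)O"),
    ("tryptophan", "NC(Cc1c[nH]c2ccccc12)C(=O)O"),
    ("histidine", "NC(Cc1c[nH]cn1)C(=O)O"),
    ("lysine", "NCCCCC(N)C(=O)O"),
    ("ornithine", "NCCCC(N)C(=O)O"),
    ("arginine", "NC(CCCNC(=N)N)C(=O)O"),
    ("putrescine", "NCCCCN"),
    ("cadaverine", "NCCCCCN"),
    ("1,3-diaminopropane", "NCCCN"),
    ("agmatine", "NCCCCNC(=N)N"),
    ("spermidine", "NCCCCNCCCN"),
    ("dopamine", "NCCc1ccc(O)c(O)c1"),
    ("serotonin", "NCCc1c[nH]c2ccc(O)cc12"),
    ("histamine", "NCCc1c[nH]cn1"),
    ("tyramine", "NCCc1ccc(O)cc1"),
    ("phenethylamine", "NCCc1ccccc1"),
    ("tryptamine", "NCCc1c[nH]c2ccccc12"),
    ("GABA", "NCCCC(=O)O"),
    ("beta-alanine", "NCCC(=O)O"),
    ("5-aminovaleric acid", "NCCCCC(=O)O"),
    ("taurine", "NCCS(=O)(=O)O"),
    ("ethanolamine", "NCCO"),
    ("citrulline", "NC(CCCNC(N)=O)C(=O)O"),
    ("2-aminobutyric acid", "CCC(N)C(=O)O"),
    ("norvaline", "CCCC(N)C(=O)O"),
    ("norleucine", "CCCCC(N)C(=O)O"),
    ("benzylamine", "NCc1ccccc1"),
    ("octopamine", "NCC(O)c1ccc(O)cc1"),
]

_H2O = {"H": 2, "O": 1}
_FORMIC = {"C": 1, "H": 2, "O": 2}
_NH3 = {"N": 1, "H": 3}


@dataclass
class NoiseConfig:
    """Spectral noise: m/z jitter, lognormal intensity spread, spurious peaks.

    ``mz_sd`` defaults well under a third of the 0.01 Da curation fragment
    tolerance so planted peaks survive the gates by construction.
    """

    mz_sd: float = 0.002
    intensity_sigma: float = 0.3
    n_spurious: int = 5
    spurious_rel_intensity: float = 0.02


@dataclass
class CorpusConfig:
    """Shape of the simulated public corpus and its metadata world."""

    n_files: int = 40
    planted_fraction: float = 0.5
    copies_per_file: int = 2
    organs: Tuple[str, ...] = ("brain", "feces", "blood", "skin", "urine")
    taxa: Tuple[str, ...] = (
        "9606|Homo sapiens",
        "10090|Mus musculus",
        "2|Bacteria",
        "33090|Viridiplantae",
    )
    diseases: Tuple[str, ...] = ("no disease", "diabetes mellitus", "inflammatory bowel disease")
    decoy_peaks: int = 12


@dataclass
class EffectConfig:
    """Planted two-group effect structure for feature tables."""

    n_features: int = 200
    n_affected: int = 20
    effect_log10: float = 1.0
    n_group_a: int = 20
    n_group_b: int = 20
    n_blanks: int = 3
    n_contaminants: int = 10
    base_log10_mean: float = 5.0
    base_log10_sigma: float = 0.4


@dataclass
class GeneratorConfig:
    """Top-level configuration; same config + seed => byte-identical outputs."""

    seed: int
    n_heads: int = 42
    n_tails: int = 19
    curated_fraction: float = 1.0  # fraction of heads with diagnostic lists
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)


# ---------------------------------------------------------------------------
# Heads and tails


def head_diagnostic_fragments(smiles: str) -> List[float]:
    """Characteristic head fragments: protonated head minus small losses.

    Carboxylated heads lose water, formic acid, or both from the protonated
    molecule (for glutamic acid: 130.05, 102.06 and 84.04, the consensus
    diagnostic triplet); pure amines keep the protonated head and its
    ammonia loss instead.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    comp: Dict[str, int] = {}
    for atom in Chem.AddHs(mol).GetAtoms():
        comp[atom.GetSymbol()] = comp.get(atom.GetSymbol(), 0) + 1
    has_acid = bool(mol.GetSubstructMatches(Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")))
    loss_sets = (
        ([_H2O], [_FORMIC], [_H2O, _FORMIC]) if has_acid else ([], [_NH3])
    )
    fragments: List[float] = []
    for losses in loss_sets:
        try:
            reduced = comp
            for loss in losses:
                reduced = subtract_formula(reduced, loss)
        except ValueError:
            continue
        mz = monoisotopic_mass(reduced) + PROTON_MASS
        if mz > 40.0:
            fragments.append(round(mz, 4))
    # deduplicate, heaviest first for readability
    unique = sorted(set(fragments), reverse=True)[:3]
    return unique


def generate_heads(config: GeneratorConfig) -> List[AmineHead]:
    """Deterministic head list: curated real amines, extended if needed.

    The first ``curated_fraction`` of heads carry diagnostic-fragment lists
    derived from their own sub-formula masses; the rest are left uncurated.
    Requests beyond the curated catalogue append linear alkane diamines.
    """
    if config.n_heads < 1:
        raise ValueError("n_heads must be >= 1")
    catalogue = list(CURATED_HEADS)
    k = 6
    while len(catalogue) < config.n_heads:
        catalogue.append((f"1,{k}-diaminoalkane-C{k}", "N" + "C" * k + "N"))
        k += 1
    n_curated = int(round(config.curated_fraction * config.n_heads))
    heads = []
    for i, (name, smiles) in enumerate(catalogue[: config.n_heads]):
        frags = head_diagnostic_fragments(smiles) if i < n_curated else []
        heads.append(AmineHead.from_smiles(name, smiles, frags))
    return heads


def _tail_smiles(carbons: int, unsaturations: int) -> str:
    if carbons < 3 or carbons > 18:
        raise ValueError("tail carbons must be in [3, 18]")
    if carbons == 3:
        if unsaturations:
            raise ValueError("C3 tail cannot carry a double bond here")
        return "OCCC(=O)O"
    chain = carbons - 3  # carbons before the C3 hydroxyl carbon
    if unsaturations == 0:
        return "C" * chain + "C(O)CC(=O)O"
    if unsaturations == 1 and chain >= 3:
        after = 1
        before = chain - 2 - after
        return "C" * before + "C=C" + "C" * after + "C(O)CC(=O)O"
    raise ValueError(f"unsupported tail C{carbons}:{unsaturations}")


def generate_tails(config: GeneratorConfig) -> List[LipidTail]:
    """Deterministic tail list: saturated C3..C18, then mid-chain Cn:1 forms."""
    if config.n_tails < 1:
        raise ValueError("n_tails must be >= 1")
    specs: List[Tuple[int, int]] = [(n, 0) for n in range(3, 19)]
    specs += [(n, 1) for n in (10, 12, 14, 16, 18)]
    if config.n_tails > len(specs):
        raise ValueError(f"at most {len(specs)} tails available")
    tails = []
    for carbons, unsats in specs[: config.n_tails]:
        name = f"3OH-C{carbons}:{unsats}"
        tails.append(LipidTail.from_smiles(name, _tail_smiles(carbons, unsats)))
    return tails


def write_heads_tails(heads: Sequence[AmineHead], tails: Sequence[LipidTail], out_dir) -> None:
    """Emit heads.tsv / tails.tsv in the input-table dialect."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "name": [h.name for h in heads],
            "smiles": [h.smiles for h in heads],
            "diagnostic_fragments": [
                ";".join(f"{f:.4f}" for f in h.diagnostic_fragments) for h in heads
            ],
        }
    ).to_csv(out / "heads.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"name": [t.name for t in tails], "smiles": [t.smiles for t in tails]}
    ).to_csv(out / "tails.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Conjugate MS2 spectra


def simulate_conjugate_spectrum(
    target: ConjugateTarget,
    adduct: AdductSpec,
    noise: NoiseConfig,
    rng: np.random.Generator,
    rt: Optional[float] = None,
    provenance: str = "",
) -> Tuple[Spectrum, float]:
    """A planted conjugate MS2 spectrum and its planted explained fraction.

    Chemical peaks are head diagnostics, the protonated head and its water
    loss, the acylium-like tail fragment, the water-loss precursor and the
    protonated molecule — all protonated sub-formulas of the parent, hence
    explainable by construction. Spurious uniform peaks are added at low
    relative intensity; the returned fraction is chemical / total intensity.
    """
    head, tail = target.head, target.tail
    chemical_mz: List[float] = list(head.diagnostic_fragments)
    chemical_mz.append(head.mono_mass + PROTON_MASS)
    for losses in (_H2O,):
        try:
            chemical_mz.append(
                monoisotopic_mass(subtract_formula(head.formula, losses)) + PROTON_MASS
            )
        except ValueError:
            pass
    try:
        acyl = subtract_formula(tail.formula, _H2O)
        chemical_mz.append(monoisotopic_mass(acyl) + PROTON_MASS)
    except ValueError:
        pass
    precursor = target.adduct_mz(adduct)
    m_plus_h = target.mono_mass + PROTON_MASS
    chemical_mz.extend([m_plus_h - 18.010565, m_plus_h])
    chemical_mz = sorted(set(round(m, 6) for m in chemical_mz if m > 40.0))

    base = 1000.0
    intensities = base * np.exp(
        noise.intensity_sigma * rng.standard_normal(len(chemical_mz))
    )
    jittered = np.asarray(chemical_mz) + noise.mz_sd * rng.standard_normal(len(chemical_mz))

    n_spurious = noise.n_spurious
    spurious_mz = rng.uniform(50.0, max(precursor, 60.0), size=n_spurious)
    spurious_int = (
        base
        * noise.spurious_rel_intensity
        * np.exp(noise.intensity_sigma * rng.standard_normal(n_spurious))
    )

    mz = np.concatenate([jittered, spurious_mz])
    intensity = np.concatenate([intensities, spurious_int])
    explained_fraction = float(intensities.sum() / intensity.sum())
    spectrum = Spectrum(
        peaks_mz=mz,
        peaks_intensity=intensity,
        ms_level=2,
        precursor_mz=precursor,
        rt=rt,
        provenance=provenance,
    )
    return spectrum, explained_fraction


# ---------------------------------------------------------------------------
# Reaction-mixture runs


@dataclass
class PlantedEntry:
    """Ground truth for one planted (target, adduct) feature in a run."""

    compound: str
    head: str
    tail: str
    isomer_index: int
    adduct: str
    run: str
    scans: List[int]
    rt: float
    feature_height: float
    ms1_intensity: float
    explained_fraction: float
    expect_accept: bool


def simulate_reaction_run(
    targets: Sequence[ConjugateTarget],
    noise: NoiseConfig,
    seed: int,
    run_name: str = "run1",
    adducts: Sequence[str] = ("[M+H]+",),
    detection_prob: float = 1.0,
    height_plan: Optional[Mapping[Tuple[str, str], float]] = None,
    default_height: float = 1e6,
    rt_step: float = 0.05,
    rt_span: float = 10.0,
) -> Tuple[LCMSRun, List[PlantedEntry]]:
    """Simulate one reaction-mixture LC-MS/MS run with planted features.

    Each detected (target, adduct) gets a triangular XIC feature of width
    0.5 min centred on a deterministic retention time, with apex height from
    ``height_plan`` (keyed by (compound name, adduct name)) or
    ``default_height``, plus one MS2 scan at the apex. ``expect_accept`` in
    the truth records whether the feature was planted above both intensity
    floors with a passing explained fraction.
    """
    rng = np.random.default_rng(seed)
    adduct_specs = [get_adduct(a) for a in adducts]
    rts = np.arange(rt_step, rt_span, rt_step)
    ms1_peaks: List[List[Tuple[float, float]]] = [[] for _ in rts]
    ms2_scans: List[Spectrum] = []
    truth: List[PlantedEntry] = []
    scan_counter = 1

    for target in targets:
        for adduct in adduct_specs:
            if rng.uniform() > detection_prob:
                continue
            height = default_height
            if height_plan is not None:
                height = height_plan.get((target.name, adduct.name), default_height)
            rt_apex = float(rng.uniform(1.0, rt_span - 1.0))
            apex_idx = int(np.argmin(np.abs(rts - rt_apex)))
            rt_apex = float(rts[apex_idx])
            mz = target.adduct_mz(adduct)
            half_width = 0.25  # minutes; full width 0.5 >= the 0.2 min floor
            for i, rt in enumerate(rts):
                frac = 1.0 - abs(rt - rt_apex) / half_width
                if frac > 0:
                    ms1_peaks[i].append((mz, height * frac))
            spectrum, explained = simulate_conjugate_spectrum(
                target,
                adduct,
                noise,
                rng,
                rt=rt_apex,
                provenance=f"{run_name}:{scan_counter}",
            )
            ms2_scans.append(spectrum)
            truth.append(
                PlantedEntry(
                    compound=target.name,
                    head=target.head.name,
                    tail=target.tail.name,
                    isomer_index=target.isomer_index,
                    adduct=adduct.name,
                    run=run_name,
                    scans=[scan_counter],
                    rt=rt_apex,
                    feature_height=height,
                    ms1_intensity=height,
                    explained_fraction=explained,
                    expect_accept=(height >= 1e5 and height >= 5e4 and explained >= 0.6),
                )
            )
            scan_counter += 1

    ms1_scans = []
    for i, rt in enumerate(rts):
        pairs = sorted(ms1_peaks[i])
        if not pairs:
            continue
        arr = np.asarray(pairs)
        ms1_scans.append(
            Spectrum(
                peaks_mz=arr[:, 0],
                peaks_intensity=arr[:, 1],
                ms_level=1,
                rt=float(rt),
                provenance=f"{run_name}:ms1:{i}",
            )
        )
    return LCMSRun(name=run_name, ms1_scans=ms1_scans, ms2_scans=ms2_scans), truth


# ---------------------------------------------------------------------------
# Repository corpus + metadata


@dataclass
class RepositoryTruth:
    """Ground truth for a simulated public corpus."""

    planted: pd.DataFrame  # query_id, file, scan, head, tail
    file_metadata: pd.DataFrame  # file_id, taxonomy, body_part, disease, role
    decoy_files: List[str]


def _decoy_spectrum(
    rng: np.random.Generator,
    library_mz: np.ndarray,
    n_peaks: int,
    frag_tol: float = 0.02,
    provenance: str = "",
) -> Spectrum:
    """Random spectrum sharing at most 2 coincident ions with the library.

    Peaks are drawn uniformly and any beyond the first two that collide with
    a library peak (within ``frag_tol``) are resampled, so a decoy can never
    reach the 3-matched-ion search floor against any library spectrum.
    """
    peaks: List[float] = []
    coincident = 0
    while len(peaks) < n_peaks:
        mz = float(rng.uniform(60.0, 900.0))
        near = np.any(np.abs(library_mz - mz) <= 2 * frag_tol) if library_mz.size else False
        if near:
            if coincident >= 2:
                continue
            coincident += 1
        peaks.append(mz)
    intensity = 100.0 * np.exp(0.5 * rng.standard_normal(n_peaks))
    precursor = float(rng.uniform(150.0, 600.0))
    return Spectrum(
        peaks_mz=np.asarray(peaks),
        peaks_intensity=intensity,
        ms_level=2,
        precursor_mz=precursor,
        provenance=provenance,
    )


def simulate_repository(
    library: Sequence[LibraryEntry],
    config: CorpusConfig,
    noise: NoiseConfig,
    seed: int,
    min_copy_cosine: float = 0.9,
) -> Tuple[List[Spectrum], RepositoryTruth]:
    """A multi-file corpus with planted library copies, decoys and metadata.

    Planted files embed noisy copies of library spectra whose raw cosine to
    the original is verified >= ``min_copy_cosine`` at generation time (the
    guarantee is checked, not assumed, so downstream recall tests are sound).
    Decoy files share fewer than 3 coincident ions with any library spectrum.
    Every file receives taxonomy / body part / disease drawn from the config.
    """
    if not library:
        raise ValueError("library must be non-empty")
    rng = np.random.default_rng(seed)
    all_library_mz = np.sort(np.concatenate([e.spectrum.peaks_mz for e in library]))
    n_planted_files = int(round(config.planted_fraction * config.n_files))
    corpus: List[Spectrum] = []
    planted_rows: List[dict] = []
    metadata_rows: List[dict] = []
    decoy_files: List[str] = []

    for file_idx in range(config.n_files):
        file_id = f"corpus_{file_idx:04d}.mzML"
        is_planted = file_idx < n_planted_files
        taxonomy = config.taxa[file_idx % len(config.taxa)]
        organ = config.organs[file_idx % len(config.organs)]
        disease = config.diseases[file_idx % len(config.diseases)]
        metadata_rows.append(
            {
                "filename": file_id,
                "NCBITaxonomy": taxonomy,
                "UBERONBodyPartName": organ,
                "DOIDCommonName": disease,
                "SampleType": "sample",
            }
        )
        scan = 1
        if is_planted:
            n_copies = int(rng.integers(1, config.copies_per_file + 1))
            entry_indices = rng.choice(len(library), size=n_copies, replace=False)
            for entry_idx in entry_indices:
                entry = library[int(entry_idx)]
                original = entry.spectrum
                for _attempt in range(20):
                    mz = original.peaks_mz + noise.mz_sd * rng.standard_normal(original.n_peaks)
                    intensity = original.peaks_intensity * np.exp(
                        0.5 * noise.intensity_sigma * rng.standard_normal(original.n_peaks)
                    )
                    copy = Spectrum(
                        peaks_mz=mz,
                        peaks_intensity=intensity,
                        ms_level=2,
                        precursor_mz=original.precursor_mz
                        + float(rng.normal(0.0, noise.mz_sd)),
                        provenance=f"{file_id}:{scan}",
                    )
                    cos, _n = raw_cosine(original, copy, frag_tol=0.02)
                    if cos >= min_copy_cosine:
                        break
                else:  # pragma: no cover - noise defaults never get here
                    raise RuntimeError("could not generate a high-cosine planted copy")
                corpus.append(copy)
                planted_rows.append(
                    {
                        "query_id": entry.query_id,
                        "file": file_id,
                        "scan": scan,
                        "head": entry.target.head.name,
                        "tail": entry.target.tail.name,
                        "planted_cosine": cos,
                    }
                )
                scan += 1
        else:
            decoy_files.append(file_id)
            for _ in range(3):
                corpus.append(
                    _decoy_spectrum(
                        rng,
                        all_library_mz,
                        config.decoy_peaks,
                        provenance=f"{file_id}:{scan}",
                    )
                )
                scan += 1

    truth = RepositoryTruth(
        planted=pd.DataFrame(
            planted_rows, columns=["query_id", "file", "scan", "head", "tail", "planted_cosine"]
        ),
        file_metadata=pd.DataFrame(metadata_rows),
        decoy_files=decoy_files,
    )
    return corpus, truth


# ---------------------------------------------------------------------------
# Feature tables


@dataclass
class FeatureTableTruth:
    """Planted structure of a simulated two-group feature table."""

    affected: Dict[str, float]  # feature_id -> signed log10 effect (A vs B)
    contaminants: List[str]


def simulate_feature_table(
    effects: EffectConfig, seed: int
) -> Tuple[FeatureTable, FeatureTableTruth]:
    """Two-group feature table with planted effects and blank contaminants.

    Unaffected features share one log-normal distribution across groups;
    affected features are shifted in group A by the configured log10 effect
    (alternating sign, so both enrichment and depletion are exercised).
    Contaminant features are equally abundant in blanks and samples, which
    the blank filter should remove; all other features are absent in blanks.
    """
    if effects.n_group_a < 3 or effects.n_group_b < 3:
        raise ValueError("group sizes must be >= 3")
    rng = np.random.default_rng(seed)
    n = effects.n_features
    n_affected = min(effects.n_affected, n)
    n_contaminants = min(effects.n_contaminants, n - n_affected)
    feature_ids = [f"F{i:05d}" for i in range(n)]
    sample_ids = (
        [f"A{i:03d}" for i in range(effects.n_group_a)]
        + [f"B{i:03d}" for i in range(effects.n_group_b)]
        + [f"BLK{i:02d}" for i in range(effects.n_blanks)]
    )
    groups = (
        ["A"] * effects.n_group_a + ["B"] * effects.n_group_b + [""] * effects.n_blanks
    )
    roles = (
        ["sample"] * (effects.n_group_a + effects.n_group_b) + ["blank"] * effects.n_blanks
    )
    samples = pd.DataFrame({"group": groups, "role": roles}, index=sample_ids)

    base_log10 = rng.normal(effects.base_log10_mean, 0.5, size=n)
    affected_ids = feature_ids[:n_affected]
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n_affected)])

    log_areas = rng.normal(
        base_log10[:, None], effects.base_log10_sigma, size=(n, len(sample_ids))
    )
    n_a = effects.n_group_a
    for row, sign in enumerate(signs):
        log_areas[row, :n_a] += sign * effects.effect_log10
    areas = np.power(10.0, log_areas)

    # blanks: near-zero except for contaminant features, which match samples
    blank_slice = slice(n_a + effects.n_group_b, None)
    areas[:, blank_slice] = 0.0
    contaminant_ids = feature_ids[n - n_contaminants :]
    for row in range(n - n_contaminants, n):
        areas[row, blank_slice] = np.power(
            10.0, rng.normal(base_log10[row], effects.base_log10_sigma, size=effects.n_blanks)
        )

    features = pd.DataFrame(
        {
            "mz": rng.uniform(150.0, 600.0, size=n).round(4),
            "rt": rng.uniform(0.5, 10.0, size=n).round(3),
        },
        index=feature_ids,
    )
    table = FeatureTable(
        features=features,
        samples=samples,
        areas=pd.DataFrame(areas, index=feature_ids, columns=sample_ids),
    )
    truth = FeatureTableTruth(
        affected={fid: float(s * effects.effect_log10) for fid, s in zip(affected_ids, signs)},
        contaminants=list(contaminant_ids),
    )
    return table, truth
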