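# revmet

A reverse-metabolomics toolkit for **3-hydroxy *N*-acyl amides** —
conjugates of an amine head group (amino acids, polyamines,
neurotransmitters) with a β-hydroxylated fatty-acid tail, a lipid class
produced by gut bacteria and largely missing from public spectral
libraries. It is written for computational metabolomics researchers who
want to build targeted MS2 reference libraries from crude reaction
mixtures and then mine public LC-MS/MS corpora for where those molecules
occur.

The workflow inverts the usual direction of untargeted metabolomics.
Instead of annotating acquired spectra against a library, it:

1. **Enumerates** all head × tail amide condensation products
   (head + tail − H2O, one positional isomer per primary amine site) with
   exact monoisotopic masses and adduct m/z values
   ([M+H]+, [M+Na]+, [M+K]+, [M+NH4]+, [M−H2O+H]+).
2. **Curates a spectral library** from LC-MS/MS runs of reaction mixtures:
   candidates within 10 ppm of an adduct mass, MS1 intensity ≥ 5·10⁴,
   XIC feature height ≥ 10⁵, MS2 explained-intensity fraction ≥ 0.6
   (against exact sub-formula enumeration of the parent), head-group
   diagnostic fragments present, and non-protonated adducts admitted only
   alongside an accepted [M+H]+ / [M+NH4]+ anchor.
3. **Searches** the library across a spectral corpus with cosine
   similarity. The core statistic is the cosine over an *optimal*
   one-to-one peak assignment within a 0.02 Da tolerance,

       cos(A, B) = Σ_{(i,j)∈M*} √(a_i b_j) / (‖√a‖ ‖√b‖),

   with M* the maximum-weight matching; the *modified* cosine additionally
   allows peaks shifted by the precursor mass difference. Matches require
   cosine ≥ 0.7, ≥ 3 matched ions, precursor Δ ≤ 0.02 Da. Molecular
   networks (modified cosine ≥ 0.7, ≥ 2 peaks) support chain-length-analog
   annotation propagation along CH2 / C2H4 / H2 mass deltas under a
   retention-time ordering rule.
4. **Joins matches to harmonized metadata** (taxonomy, body part, disease)
   and aggregates: three-state head × tail presence matrices, match-count
   matrices, per-group tallies, chain parity/saturation summaries.
5. **Compares feature abundances** between sample groups: blank filtering,
   two-sided Wilcoxon rank-sum tests (exact for small tie-free samples),
   log10 fold changes, and MSI level-1/2 confidence assignment from
   retention-time and ion-mobility drift agreement with standards.

A seeded synthetic-data module simulates every input — reaction runs with
planted conjugate spectra, a repository corpus with planted copies and
decoys, metadata, and feature tables with planted effects — each with a
ground-truth manifest, so the whole pipeline is testable end to end
without downloads. See `docs/methods.md` for the model details and
limitations.

## Worked example

```bash
revmet simulate --seed 5 --n-heads 4 --n-tails 3 --out fixtures/
revmet enumerate --heads fixtures/heads.tsv --tails fixtures/tails.tsv \
    --out targets.tsv
# -> 12 targets over 12 distinct head-tail pairs -> targets.tsv
revmet search --library fixtures/library.mgf --corpus fixtures_corpus/ \
    --out matches.tsv
```

Or from Python, running the full pipeline on a simulated world:

```python
from revmet.conjugates import enumerate_conjugates
from revmet.library import GateConfig, build_library
from revmet.search import fasst_search
from revmet.simulate import (CorpusConfig, GeneratorConfig, generate_heads,
                             generate_tails, simulate_reaction_run,
                             simulate_repository)

world = GeneratorConfig(seed=1, n_heads=6, n_tails=5)
heads, tails = generate_heads(world), generate_tails(world)
targets = enumerate_conjugates(heads, tails)
run, _ = simulate_reaction_run(targets, world.noise, seed=2,
                               adducts=("[M+H]+", "[M+Na]+"))
library = build_library([run], targets, GateConfig())
print(library.summary)
corpus, truth = simulate_repository(library.entries, CorpusConfig(n_files=40),
                                    world.noise, seed=3)
matches = fasst_search(library.entries, corpus, min_cos=0.7, min_matched=3)
print(len(matches), "matches")
```

This prints

```
{'candidates': 172, 'accepted': 80, 'rejected_ms1_intensity': 0,
 'rejected_feature_height': 0, 'rejected_explanation_score': 0,
 'rejected_diagnostic': 92, 'rejected_adduct_inclusion': 0}
77 matches
```

Reading: 172 candidate (target, adduct, scan) triples fell inside the
10 ppm window — more than were planted, because conjugates of the same
elemental formula (positional isomers, and isobaric head/tail trade-offs
such as alanine+C4:0 vs glycine+C5:0) claim each other's scans. The
diagnostic-fragment gate rejects the wrong-head claims (92), leaving 80
accepted entries. Searching the simulated 40-file corpus recovers every
planted spectrum copy (77 matches, recall 1.0) and nothing from the decoy
files, whose spectra are constructed to share fewer than 3 ions with any
library spectrum.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline from scratch at each run: full-scale enumeration
(42 heads × 19 tails), reaction-run simulation and library curation,
repository search with planted-recall and decoy accounting, metadata
aggregation with chain-class summaries, and the blank-filtered two-group
comparison with planted effects. Stage summaries go to stdout and the JSON
result object to `--out`.
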