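# Methods

`revmet` implements a reverse-metabolomics workflow for 3-hydroxy
*N*-acyl amides: amide conjugates of an amine head group (amino acids,
polyamines, neurotransmitters and related metabolites) with a
β-hydroxylated fatty-acid tail. Instead of acquiring samples and searching
them against reference libraries, the workflow starts from reference MS2
spectra of combinatorially enumerated conjugates and searches those spectra
across a corpus of untargeted LC-MS/MS files, then mines per-file sample
metadata for biological context. This note records the models, parameter
choices, and numerical decisions; everything empirical it mentions is
computed by the test suite or `scripts/acceptance.py`, not asserted.

## Conjugate enumeration

A conjugate is the condensation product head + tail − H2O, formed at a
primary amine. Heads with several primary amines (ornithine, lysine,
putrescine, ...) yield one positional isomer per site; isomers share
elemental formula and monoisotopic mass and differ only in structure, so a
head with *k* primary amines contributes *k* targets per tail while the
head × tail pair count stays |heads| × |tails|.

Primary-amine detection uses the SMARTS pattern `[NX3H2;$(N[CX4,c]);
!$(N[CX3]=[O,S,N])]`: an NH2 on an sp3 or aryl carbon, excluding amide,
thioamide, amidine and guanidino nitrogens and aromatic ring NH (histamine's
imidazole is not a conjugation site; its ethylamine is). Amide assembly is a
deterministic RWMol edit — bond the chosen amine nitrogen to the unique
carboxyl carbon and delete the hydroxyl oxygen — rather than a SMARTS
reaction, so site indexing is explicit and reproducible.

Masses are sums of NIST monoisotopic atomic masses (C, H, N, O, S, P, Na,
K). Adduct m/z values are M plus a fixed singly-charged offset with the
electron mass folded into the proton: +H 1.007276, +Na 22.989218,
+K 38.963158, +NH4 18.033823, −H2O+H −17.003289 Da. The water-loss
in-source fragment is handled as an adduct-like ion form throughout.

Tail names follow the `3OH-Cn:m` convention (n carbons, m unsaturations,
hydroxyl fixed at C3). The name encodes only the counts; the SMILES in the
tail table is authoritative for double-bond position, and the parser
verifies name/formula consistency (CnH(2n−2m)O3).

## Library curation gates

Reference spectra are extracted from (simulated or real) reaction-mixture
runs by a cascade of gates, applied in a fixed order so each rejected
candidate is labeled with the first gate it failed:

1. **Precursor window** — MS2 precursor within 10 ppm of the theoretical
   adduct m/z.
2. **MS1 intensity ≥ 5e4** — the extracted-ion intensity at the MS2 scan's
   retention time.
3. **Feature height ≥ 1e5** — "feature" is defined internally as a
   contiguous nonzero region of the ±10 ppm XIC at least 0.2 min wide, and
   its height is the region's maximum; this stands in for an external
   feature finder.
4. **MS2 explanation score ≥ 0.6** — the fraction of total MS2 intensity
   assignable to protonated element-wise sub-formulas of the parent within
   0.01 Da. Sub-formula enumeration is an exact element-count grid walk
   with mass pruning (parents here are ≤ C60, so the grid is small). The
   score is an explained-intensity fraction; treating the 0.6 gate this way
   preserves its role as a "does the spectrum belong to this formula"
   filter without modeling fragmentation.
5. **Diagnostic fragments** — every curated head-group fragment (e.g. the
   glutamic acid 84.04 / 102.06 / 130.05 triplet) must appear within
   0.01 Da; configurable to a minimum count. Heads without a curated list
   pass vacuously and are flagged `uncurated`.
6. **Adduct inclusion** — sodiated, potassiated and water-loss entries are
   kept only if the same conjugate target also has an accepted [M+H]+ or
   [M+NH4]+ entry; anchor adducts are never removed by this rule.

The curation fragment tolerance (0.01 Da) is deliberately tighter than the
0.02 Da repository-search tolerance: reference spectra come from
high-resolution instruments, while corpus spectra are heterogeneous.

A consequence of formula-gated extraction worth knowing: positional isomers
and genuinely isobaric conjugates (alanine + C4:0 has the same formula as
glycine + C5:0) cannot be distinguished by precursor mass, so both targets
can claim the same MS2 scan; the diagnostic-fragment gate is what separates
heads, and same-head isomers are all retained.

## Spectral similarity and search

Peak matching is an exact maximum-weight one-to-one assignment on the
tolerance-feasible bipartite graph (solved with the Hungarian algorithm),
not a greedy pass; on small spectra it provably equals exhaustive
enumeration, which the tests exploit. Raw cosine matches fragments directly
within 0.02 Da; modified cosine additionally allows matches shifted by the
precursor mass difference and is therefore never smaller than raw cosine on
the same pair. Intensities are square-root weighted before normalization
(configurable to unweighted). Ties between equal-total assignments cannot
change the cosine value; the assignment solver's deterministic output fixes
the reported pairing. No peak preprocessing (precursor-window removal,
top-N filtering) is applied by default; both are available since repository
tools differ.

Repository search gates matches at raw cosine ≥ 0.7, ≥ 3 matched ions, and
precursor delta ≤ 0.02 Da. Candidates are pruned with a sorted precursor
index widened by the tolerance, so the indexed result set equals an
exhaustive all-pairs scan. Molecular networking uses modified cosine ≥ 0.7
with ≥ 2 matched peaks — lower than search because short-chain and sodiated
conjugate spectra carry very few fragments.

Annotation propagation walks network edges whose mass delta matches a
homolog difference (CH2 14.01565, C2H4 28.03130, H2 2.01565 Da) within the
fragment tolerance, subject to a retention-time rule: the heavier (longer
or more saturated) homolog may not elute more than 0.05 min earlier than
its neighbor. Propagated annotations are single-hop by default, labeled
putative (MSI level 2), and conflicting names on one node are all kept and
flagged ambiguous rather than resolved silently.

## Aggregation conventions

A "unique compound" is a distinct (head, tail) pair — adducts, positional
isomers and water-loss forms collapse. The presence matrix is three-state:
`no_spectrum` (the pair has no library spectrum; count undefined, not
zero), `no_match`, `matched`. Chain-class summaries partition matches by
carbon parity and saturation; a tail's percentage is its share of its
parity class, rounded half-away-from-zero for report tables with full
precision kept alongside. Matches that cannot be resolved to a compound are
tallied under `unknown`, never dropped, so partitions always conserve
totals. Body-part synonym collapsing (e.g. feces + anal → feces-anal) is a
caller-supplied map, not hard-coded.

## Feature-table statistics

Blank filtering retains a feature iff mean(sample areas) / max(mean blank
area, 1.0) ≥ 3 by default; the ratio is common practice rather than a
published constant, and calling the filter on a table without blanks is an
error so that skipping it is an explicit decision. Two-group comparisons
use the two-sided Wilcoxon rank-sum test: exact enumeration when the
smaller group has ≤ 8 observations and the data are tie-free, otherwise the
normal approximation with tie and continuity corrections (delegated to
scipy's Mann-Whitney implementation under exactly that policy; the test
suite checks it against an independent full-enumeration oracle). Fold
changes are log10((mean_A + 1) / (mean_B + 1)); the unit pseudo-area keeps
zero-abundance groups finite. Significance is uncorrected p < 0.05 by
default, mirroring reanalysis practice; Benjamini–Hochberg is opt-in. The
monotone time-trend helper reports both a first-vs-last-bin rank-sum test
and a Spearman rank correlation because no single trend test is standard.

MSI confidence assignment grants level 1 only with an MS2 match plus
retention-time agreement within 0.1 min and drift-time (1/K0) agreement
within 0.02 V·s/cm² against an authentic standard; these tolerances are
instrument-typical defaults, not published values. A feature without an MS2
match is never upgraded, and a compound missing from the standards table
stays level 2 with the reason recorded.

## Synthetic data: what it emulates and what it does not

The generators stand in for synthesis, instruments and repositories, and
their defaults are the stated world of the workflow: 42 amine heads
(a curated catalogue of real amino acids, polyamines and amine metabolites)
× 19 tails (saturated C3–C18 plus mid-chain monounsaturated forms), 10 ppm
/ 5e4 / 1e5 / 0.6 gates, 0.7 / 3-ion search, and 20 vs 20 sample groups
with a 10-fold planted effect for the feature tables.

Planted MS2 peaks are protonated sub-formula masses — head diagnostics, the
protonated head and its water loss, the acyl fragment, the water-loss
precursor and the protonated molecule — jittered by a 0.002 Da m/z noise
(kept under a third of the curation tolerance so planted peaks survive the
gates by construction), plus uniform spurious peaks at low relative
intensity. Reaction-run features are triangular XIC profiles 0.5 min wide.
Corpus files embed noisy copies of library spectra whose cosine to the
original is verified ≥ 0.9 at generation time, and decoy files are
constructed to share fewer than 3 coincident ions with any library
spectrum; both guarantees are checked when generating, not assumed, so the
downstream recall and rejection tests are sound rather than circular.

The model deliberately omits: physical fragmentation chemistry and
intensity realism, isotope envelopes, chimeric MS2, chromatographic peak
shapes and alignment across runs, and profile-mode data. A green test
therefore establishes that the pipeline's logic (gates, matching,
bookkeeping, statistics) is correct on data with known structure — not that
the gates are optimally tuned for any particular instrument.

## Known limitations

- Isobaric head/tail trade-offs (head +CH2 vs tail +CH2) are inherent to
  this compound class; formula-gated extraction and precursor-gated search
  cannot separate them, and only diagnostic fragments or orthogonal
  evidence (RT, drift) do.
- Negative ionization mode is out of scope.
- The internal XIC feature finder is a minimal stand-in; real data should
  come through a dedicated feature finder and enter via the feature-table
  and MGF interfaces.
- mzML input is not supported in this build (no mzML reader among the
  pinned dependencies); centroided peak lists travel as MGF, and the
  in-memory `LCMSRun` container carries MS1 traces where the intensity
  gates need them.
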