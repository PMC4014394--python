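# Methods

`scestruct` tests whether protein segments encoded by multi-functional
coding regions — synonymous constraint elements (SCEs) and exonic
splicing-factor binding sites (SFBSs) — are structurally less constrained
than length-matched random segments: enriched in intrinsic disorder and low
sequence complexity, depleted in regular secondary structure and domain
annotations.  This note records the models, parameter choices, and the
design decisions that were genuinely open.

## Coordinate model and mapping

All in-memory intervals are 0-based half-open; GTF, PfamScan and 1-based
site tables are converted exactly once at parse time (`io_formats`).

An element is mapped to a protein by projecting its genomic interval(s)
through the transcript's CDS blocks into spliced CDS coordinates and
expanding to residues so that **every residue with at least one overlapping
nucleotide is included**: CDS range `[a, b)` becomes residues
`[floor(a/3), floor((b-1)/3) + 1)`.  A 9-codon element that starts
mid-codon therefore yields a 10-residue segment.  The canonical transcript
(flagged in the GTF, else longest CDS, ties by transcript id) is tried
first, the rest in CDS-length-descending order, and exactly one segment is
accepted per element.  Proteins longer than 10,000 residues are skipped for
all analyses (the titin-scale consistency rule).

When the recorded element sequence disagrees with the transcript
(assembly/annotation drift), a gapped local alignment relocates it
(match +1, mismatch −2, gap open −5, gap extend −2).  A match is accepted
iff identity over the element is ≥ 0.9 and the longest gap run is ≤ 1 nt.
The source analysis states only that elements with "multiple consecutive
gaps" were excluded; these two cutoffs are our operationalisation and are
parameters of `map_element_to_protein`.  A local alignment trims ragged
element ends, so terminal mismatches lower the identity — intended, as such
elements are the unreliable ones.

SFBS sites are filtered (mutant-gene sites dropped, chromosomal-location
duplicates collapsed, 4 < length < 50 nt kept) and may map to **two**
transcripts when those encode distinct peptides from shifted reading frames
(dual-coding regions); distinctness is judged on the encoded peptide.

## Structural tracks

Each protein carries four independent per-residue tracks; segments are
always excised from full-length-protein tracks, never re-predicted in
isolation (this avoids artificial termini effects).

* **Low complexity** — Wootton–Federhen window entropy
  `K2 = −Σ (n_i/L)·log2(n_i/L)` over a sliding window of `L = 12` residues.
  Windows with K2 ≤ 2.2 bits seed contigs; maximal runs of windows with
  K2 ≤ 2.5 bits containing a seed become low-complexity contigs whose
  spanned residues are masked.  The canonical SEG refinement stage
  (minimal-probability subsequence optimisation) is deliberately not
  implemented: the analyses consume SEG as a boolean residue mask, which
  the two-threshold contig logic reproduces; the mask function is
  pluggable if a different definition is needed.
* **Disorder** — by default the published TOP-IDP per-residue propensity
  scale (shipped as `data/top_idp_scale.tsv`), smoothed by a 21-residue
  moving average and mapped to [0, 1] by a logistic calibration
  (midpoint 0.225, steepness 15, stored in `data/defaults.yaml`).  The
  midpoint sits halfway between the expected smoothed propensity of a
  uniform background (≈ 0.027) and of the disorder-promoting residue set
  A,R,G,Q,S,P,E,K (≈ 0.422), so ordered compositions score < 0.5 and
  disorder-promoting compositions > 0.5 in expectation.  A 20×20 pairwise
  energy matrix can be loaded instead (symmetrized on load); the true
  IUPred matrix is not public and is never invented — real-data runs
  should parse genuine IUPred output files through
  `io_formats.read_annotation_tracks`.  Ambiguous residues (X, U, B)
  contribute nothing to compositions and inherit the local window mean.
* **Secondary structure** and **domains** are consumed as parsed external
  tracks (PSIPRED `.ss2`, PfamScan tabular with only class-"A" entries
  retained); no neural network or profile HMM is reimplemented.

A residue is *disordered* when its score is ≥ 0.5 (a residue at exactly
0.5 counts); *structured* when its state is H or E.  A segment is assigned
a property when ≥ 50% of its residues carry it.

## Reference null and descriptive values

For every observed segment length a random same-length segment is drawn
from a candidate protein population without crossing protein boundaries:
host uniform among proteins long enough (`--ref-weighting protein`,
default; `residue` weights hosts by their number of valid start positions —
the source text says only "randomly picked", so both are exposed), start
uniform.  The output length multiset equals the observed one exactly and
the draw is reproducible from the seed.  SCE references come from the
SCE-containing proteins only; SFBS references from the whole canonical
proteome.  `ref_replicates` pools several independent reference sets for
stability; the default is one set, matching the original single-draw
design.

Descriptive values per property distribution: 75th percentile for
disorder, median for secondary structure, 90th percentile for low
complexity (linear-interpolation percentiles, the spreadsheet-era
definition).  Domain content is binary-like and gets no single descriptive
value, so it is excluded from the window-size correlation.

## Statistics

* `yates_chi_square` — goodness-of-fit with the clamped Yates correction
  `Σ max(|O−E|−0.5, 0)² / E`; used where the expected counts are (near-)
  deterministic: the validated-disorder overlap test (expected = median of
  five control repetitions) and the SFBS residue-level test (expected from
  proteome-wide fractions).
* `yates_chi_square_2x2` — contingency form used for the segment-count
  comparisons.  Treating a single random reference draw as fixed expected
  counts doubles the variance of O−E and inflates the false-positive rate
  several-fold; the 2×2 form accounts for both margins and is what desktop
  statistics packages compute for a 2×2 table with Yates' correction.
  This is the package's own calibration choice and the end-to-end null
  check depends on it.
* `mann_whitney_u` — two-sided, U = min(U_x, U_y); exact by enumeration of
  C(n+m, n) labelings for tie-free n, m ≤ 8 (p = P(min-U ≤ observed), both
  tails folded by the min), otherwise normal approximation with
  tie-corrected variance and 0.5 continuity correction.
* `kruskal_wallis` (tie-corrected) and `dunn_pairwise`
  (z on mean-rank differences, tie-corrected pooled variance, Bonferroni
  over all pairs — the conservative, documented family; unadjusted output
  behind a flag).
* `bonferroni_threshold(alpha, m) = alpha/m`: 0.05/5 = 0.01 for the
  five proteome-level comparisons, 0.05/4 = 0.0125 for the four
  per-property comparisons.
* `ks_normality` — Lilliefors-style D with Monte-Carlo p (parameters
  re-estimated per simulated sample), reproducible via seed.

**Residue-level SFBS caveat.**  The residue-level test counts residues as
independent draws, but residues of one site stand or fall together — a
site lies wholly inside or outside a domain or disordered run.  The raw
chi-square is therefore anticonservative (measured family false-positive
rate ≈ 44% on null synthetic data).  `run_sfbs_analysis` reports both the
raw statistics (matching the original arithmetic) and an adjusted variant
whose statistic is divided by the cluster design effect `Σl²/Σl` (exact
under full within-site correlation, conservative under partial); the
adjusted variant is calibrated (0/50 null false positives).

## The synthetic world

The generator emulates every input the pipeline touches; its defaults are
the stated study conditions and are not tuned per-test.

* 300 genes, 1–4 exons, both strands, proteins 100–300 residues,
  background composition uniform over the 20 amino acids, uniform
  synonymous codon choice (nothing downstream depends on codon bias).
* Planted SCEs: 300 per resolution.  Within a window each codon follows
  the mixture `(1−δ)·background + δ·disorder-promoting-only` with
  `δ(w) = δ0 · 9/w` (default δ0 = 0.5), encoding "smaller window ⇒
  stronger bias".  The background branch *keeps* the residue already in
  place — distributionally identical, but it leaves null-study (δ0 = 0)
  windows exchangeable with reference segments; redrawing would erase
  planted background features inside windows and bias the null.  The
  disorder-promoting branch concentrates (weight 0.8) on one
  window-specific favored residue, giving planted windows the homorepeat
  character of real low-complexity IDRs; without this correlation no
  i.i.d. compositional bias at δ0 = 0.5 drops a 12-mer window below the
  2.2-bit entropy trigger and the low-complexity arm would be untestable.
  Codons taking this branch are the ground-truth disordered residues.
* Background features: ~25% of proteins carry a 10–16-residue homorepeat;
  ~50% carry a 20–60-residue disordered region (disorder-promoting
  composition, fully masked as disordered), a fraction of which is listed
  in the DisProt-style table.  Secondary-structure runs and domain spans
  (30–80 residues, mostly class "A" with some "B" to exercise the parser
  filter) are planted only inside ground-truth ordered regions.
* Emitted tracks: disorder scores are the 3-residue-smoothed true mask
  plus Gaussian noise (default sd 0.2), clamped and rounded to 3 decimals
  so the file round trip is lossless; SS and domains are the planted
  truth; low complexity is always recomputed from the sequence.
* SFBS sites (40 plus the special cases: one mutant-flagged, one
  duplicated location, lengths 4 and 50, and a dual-frame pair inside a
  single-exon gene whose second transcript reads the same DNA shifted by
  one nucleotide) and DisProt peptides are placed uniformly — **no effect
  is planted for those two analyses**, so they demonstrate machinery and
  calibration, not enrichment.
* `mutation_rate` substitutes nucleotides in the recorded element
  sequences only, emulating assembly drift; exclusions are 0 without it
  and grow monotonically with it.

What a green end-to-end test establishes: that the pipeline recovers the
direction and significance of effects planted at realistic magnitudes, and
that it reports none when nothing is planted.  What it does not establish:
agreement with the published human-genome numbers, which require the
external SCE tables, Ensembl 54 gene models and genuine predictor runs;
real sequence biology (codon usage, GC structure, splice-site motifs,
realistic domain architectures) is out of the generator's scope.

## Numerical and degenerate-input conventions

Every parser rejects malformed rows (logged with reasons) rather than
repairing them.  Elements clipped to fewer than 3 CDS nt are rejected;
elements overlapping UTR/intron are clipped, not discarded.  Multi-match
peptides in the validated-disorder analysis count once with their best
overlap class (complete > partial > none).  The "+5%" control length band
is one-sided `[L, 1.05·L]`, with a symmetric option; the
annotated protein itself is excluded from its own control candidates
(self-selection would leak signal at toy scale).  Constant descriptive
vectors make the rank correlation undefined and are reported as "no
trend".  All randomness derives from explicit integer seeds through
`numpy.random.SeedSequence`; identical configuration and seeds reproduce
every number bit-identically, recorded via the config hash in the run
manifest.

## Known limitations

* The low-complexity descriptive value (90th percentile) can tie at the
  coarser windows in small studies, making its window correlation −0.87
  instead of −1; the disorder trend is the robust acceptance quantity.
* The internal disorder predictor is a propensity-scale stand-in for a
  pairwise-energy method; on real data, parse genuine predictor output.
* No liftover, no network retrieval, no SAM/VCF support, no
  matched-composition or dinucleotide-preserving nulls (possible
  extensions of the sampler).
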