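# Methods

## Relative quantification model

The pipeline assumes label-free site/peptide intensities with
sample-multiplicative systematic error: what is measured for peptide *j* in
sample *i* is approximately

    I_ij = (true abundance)_j · (condition effect)_j^[i treated] · s_i · ε_ij

where s_i is a per-sample loading/instrument factor and ε_ij is
multiplicative noise. Quantification proceeds exactly in the order the
underlying protocol prescribes:

1. **Centralization.** R_ij = I_ij / mean_i(I_ij), the mean taken over the
   samples where the peptide was observed. Missing intensities stay
   missing; they are never zero (a search engine writes 0 for
   "not quantified", and the readers map 0 and blank cells to missing
   before any arithmetic, because zeros would corrupt the row means and
   column medians).
2. **Median normalization.** NR_ij = R_ij / median_j(R_ij) per sample.
   After this step every sample's median relative value is exactly 1.
3. **Aggregation.** A unit k (a site, or a protein) gets
   R_ik = median(NR_ij, j ∈ k) over its observed peptides. With one
   quantified peptide form per site — the default, and what the simulator
   emits — this is an identity pass-through; a multi-peptide mapping
   exercises the median.
4. **Fold change.** FC_k = mean(R_ik, i ∈ treated) / mean(R_ik, i ∈ control).
5. **Significance.** Two-sided two-sample Student's t-test (equal
   variances pooled) on the per-group R_ik values. The protocol names only
   "t-test"; Student-on-raw-values is the literal reading, and a `log2`
   flag offers the common log-scale variant. No multiple-testing
   correction is applied by default because the decision rule filters on
   raw p; Benjamini–Hochberg is available behind a `bh` flag and reported
   alongside.
6. **Calling.** up if FC > 1.5 and p < 0.05; down if FC < 0.67 and
   p < 0.05; otherwise unchanged. All inequalities are strict, so FC
   exactly 1.5 or 0.67, or p exactly 0.05, is "unchanged". A site observed
   in fewer than `min_obs_per_group = 2` replicates of either group is
   reported as `not_testable`, not dropped — the floor echoes the source
   study's rule of keeping sites identified in at least two independent
   samples.

### What the normalization does and does not cancel

The per-sample median division is exactly invariant to rescaling its input
columns — multiply any sample by c > 0 between centralization and
normalization and the output is bit-for-bit unchanged up to rounding. For
the *composed* pipeline, however, exact cancellation of per-sample factors
holds only when the data really are sample-multiplicative: centralization
runs first, and rescaling one sample shifts each row's mean by a
row-dependent amount on arbitrary matrices. On pure-scaling data (the
generator with `noise_cv=0`) the estimated fold change equals the planted
truth exactly, for any scaling factors and any further rescaling; with
noise the cancellation is approximate, which is the realistic regime the
recovery tests probe (mean recovered FC within [1.8, 2.2] for a planted
2.0 at noise CV 0.1, n = 3 per group).

### Degenerate inputs

Zero within-group variance in both groups makes the t statistic 0/0. The
implementation short-circuits: equal group means give p = 1, unequal means
give the smallest positive float, and the row is flagged `degenerate`.
"Zero variance" is judged with a 1e-9 *relative* spread tolerance so that
replicates equal up to floating-point rounding (exactly what noiseless
synthetic data produces after normalization) do not feed a catastrophically
cancelling t statistic.

## Synthetic-data generator

The generator emulates the study design the pipeline targets: two groups
("0h" control, "8h" treated) × 3 biological replicates. Defaults, chosen
once as conventional values for enrichment-based label-free data where the
protocol itself states none:

| parameter | default | meaning |
|---|---|---|
| n_proteins | 300 | proteome size |
| protein_length | 80–600 aa | uniform length range |
| sites_per_protein | ≈0.570 single-site, 17.2% / 9.4% / 6.6% / 3.9% with 2–5, 15/256 spread over 6–13 | published succinylome shape |
| base intensity | log-uniform 1e5–1e9 | LC–MS dynamic range |
| noise_cv | 0.1 | multiplicative log-normal, mean-one |
| sample_scaling | log-uniform 0.5–2 (or user-fixed) | loading factors the normalization must remove |
| missing_rate | 0.05 | missing completely at random; an `mnar` flag makes dropout intensity-dependent (rank-based, low signals first) |

Amino-acid composition follows UniProtKB average frequencies (lysine
≈5.8%), so the number of candidate K positions per protein is realistic.
Sequences are redrawn until they hold enough lysines for their assigned
site count (bounded retries, then a hard error). All randomness flows from
explicit `numpy` generators derived from `(seed, stream)` pairs — the
proteome and site stages share the per-protein site counts by construction,
and identical configs are byte-identical on re-run.

What the generator does *not* emulate: peptide-level digestion variability
(one quantified form per site by default), correlated noise between sites
of one protein, retention-time or spectral artifacts, and isotope labeling.
Passing recovery tests therefore show the *statistical* pipeline behaves
correctly under the stated noise model, not that search-engine output on
real spectra would be error-free.

## Sequence windows and motifs

Windows are 21-mers (±10 residues, center = modified K), padded with `X`
at sequence termini; pad characters never enter a frequency denominator.
The background is every lysine in the proteome ("all potential sites").
Per (residue, offset) cell the enrichment test is the one-sided binomial
upper tail of the foreground count at the background rate — the motif-x
choice — and the displayed log2 fold ratios use 0.5-count additive
smoothing (never applied to the tests). Motif extraction is the greedy
motif-x loop: fix the cell with the smallest binomial p provided
p < 1e-6 and at least 21 windows still match (ties broken by smaller p,
then alphabetical residue, then offset closest to the center — the
published algorithm leaves ties unspecified); recurse on the matching
windows; emit the consensus; remove matched windows; restart. An empty
motif list is a legitimate outcome, and the one the source study reports.

## Enrichment, networks

Term enrichment is the one-sided Fisher's exact test, computed as the
hypergeometric upper tail of the 2×2 table over a user-chosen universe
(default: all proteins in the annotation file; the original study does not
state its background set, so nothing is guessed as "the" original).
Interaction edges accept both STRING score conventions — values above 1
are taken as 0–1000 integers and rescaled — and the high-confidence filter
keeps scores strictly above 0.7. Degrees are plain undirected counts;
isolated proteins are kept at degree 0.

## Conservation mapping

Each reference protein is aligned pairwise against each homolog
(Needleman–Wunsch, BLOSUM62, gap of length L scoring −10 − 0.5·(L−1));
pairwise alignment replaces a progressive multiple alignment because site
mapping only needs the reference/homolog columns, and a pre-aligned input
mode accepts gapped pairs from Clustal/MAFFT users directly. Non-standard
residues are treated as `X` and score 0 against everything. When several
alignments are co-optimal the first traceback is used; every reported
quantity (score, mapped position monotonicity, conservation flags) is
invariant to that choice. A site is conserved in a homolog when the
aligned residue is also K; the report emits per-homolog residues, the
conserved fraction, and a domain flag (1-based inclusive interval
containment) without imposing a "highly conserved" verdict threshold,
which the field does not define numerically.

## Problem sizes

The bundled analyses and checks run at deliberately moderate scale — a few
hundred proteins (≈600–2000 sites), 2000-window motif backgrounds,
alignment oracles on sequences of length ≤ 6 — sizes at which every
brute-force cross-check is exact and the full suite completes in well
under a minute, while the statistical behaviour (fold-change recovery,
nominal false-positive rate) is already stable.

## Known limitations

- No protein-abundance correction: a fold change in site intensity mixes
  modification-stoichiometry and protein-level changes.
- No imputation and no moderated (limma-style) variance estimation; with
  n = 3 per group the plain t-test is noisy, which is faithful to the
  method being implemented rather than optimal practice.
- The wide-format reader accepts a sites-table dialect
  (`Protein`, `Position`, `Intensity <sample>`), not full search-engine
  evidence files.
- The Table-of-nine worked example re-applies the decision rule to printed
  fold changes; the underlying replicate intensities are not published at
  desk scale, so its p-values are below threshold by construction rather
  than recomputed.
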