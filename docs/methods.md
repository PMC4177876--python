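# Methods

This note documents the models, numerical choices and limitations behind
each stage of the pipeline, and what the synthetic-data generator does and
does not emulate.

## Covariation (mutual information)

MI between alignment columns is the plug-in estimator over the empirical
joint distribution of amino-acid pairs, in bits.  Gaps are excluded
pairwise by default (only rows non-gap at both columns enter the
contingency table), which avoids alignment-artifact MI; a flag treats the
gap as a 21st symbol instead.  No APC or entropy normalization is applied;
raw MI is reported together with per-column occupancy so callers can filter
gappy columns.  Users should keep the finite-sample bias in mind: for
independent columns with |A| and |B| observed symbols the expected plug-in
MI is ≈ (|A|−1)(|B|−1)/(2 n ln 2) bits, i.e. ~0.26 bits for two 20-symbol
columns at n = 1000.  Rankings of strongly co-varying pairs are robust to
this bias when column alphabets are comparable; absolute MI values are not.

## Structure-templated specificity prediction

The prediction contract is thread → sample → ensemble → PWM:

1. **Threading.** The query is aligned to the template protein
   (Smith–Waterman, BLOSUM62, gap open −11 / extend −1); template backbone
   positions inherit the aligned query residues.  Positions in gaps keep
   the template residue and are flagged unresolved.  If identity over
   contact-bearing positions falls below 15% the template is refused as
   inapplicable (family members are expected in the ~25–40% identity range
   where threading is meaningful).
2. **Energy model.** A deliberately simplified pairwise contact energy
   replaces the original protocol's all-atom force field:
   E = Σ_contacts w·ε(residue, base) + Σ_bp η(base, hydration).
   Side-chain rotamer sampling is absorbed into the ε table; the binary
   per-base hydration state is kept as an explicit degree of freedom.  The
   bundled default (`data/fl11_like_template_synthetic.json`) is a
   synthetic stand-in shaped after an Lrp/AsnC dimer–DNA complex: nine
   contact positions over a 15-bp duplex and a residue–base propensity
   table (Asn/Gln→A, Ser/Thr/Tyr→T, Arg/Lys→G, Asp/Glu→C, lower = more
   favourable).  It produces A/T-rich core motifs, as expected for this
   family, but carries no claim of physical accuracy; all quantitative
   validation uses planted tables.
3. **Annealing.** Metropolis sampling over (sequence, hydration) with
   proposals = single base substitution (probability 0.8, uniform among the
   3 alternatives) or single hydration flip (0.2); geometric temperature
   ladder.  Schedule defaults: t₀ = 2.0 score units, cooling 0.95, 50
   sweeps (of W proposals) per temperature, 60 temperatures, 5 restarts.
   Every *evaluated* state — accepted or rejected — is recorded in a
   ledger keyed by unique DNA sequence, keeping the minimum energy seen.
   On ≤ 4⁷ landscapes the returned top entry matches exhaustive enumeration
   in ≥ 95% of seeded runs with these defaults (verified in the acceptance
   suite).
4. **Ensemble → PWM.** The PWM is the per-column base frequency among the
   100 lowest-energy *unique* sequences (duplicates collapsed; sequences
   tied with the 100th entry are all included), plus a pseudocount of 0.5
   per cell, renormalized.  The PWM is reported on the template's reference
   strand; the scanner handles the reverse complement downstream.

## Motif operations

* **Scanning.**  Scores are log₂(p_col(base)/q(base)) summed over the
  window; p-values are exact tail probabilities of this score under the
  background, computed by DP over an integer score lattice with bin width
  10⁻⁴ bits.  The window score is computed on the same lattice, so p-values
  are exact at that resolution (the acceptance suite verifies agreement
  with 4⁵ enumeration to < 10⁻⁹).  Order-0 and order-1 backgrounds are
  supported (order-1 via a 4-state DP; log-odds always use the order-0
  marginal).  Windows containing N, or a zero-probability motif cell, are
  skipped.  All overlapping hits are reported; no greedy masking.
* **Comparison.**  Best gapless alignment over all offsets (≥ 4 overlapping
  columns) and both target orientations, scored by mean per-column Pearson
  distance (1 − r between 4-vectors) or Euclidean distance.  The p-value is
  a permutation null — random query motifs assembled from the pooled
  columns of the comparison universe — so comparisons are rank-faithful to,
  but not p-identical with, tools using analytic nulls.  Reciprocal mean
  p restores symmetry.  Benjamini–Hochberg adjustment is the standard
  step-up procedure.

## ChIP targets, regulons, refinement

* A gene is a ChIP target iff a peak with p < p_max (default 0.10) lies
  within window_bp (default 100) upstream of its reference point (TSS,
  falling back to the strand-aware CDS start).  The distance interval is
  closed: a peak exactly at the window edge counts; downstream peaks never
  do.  One peak may serve two divergently transcribed genes.
* Refinement mixes the empirical hit matrix into the *current* matrix each
  iteration (not the original seed): M ← (1−w)·M + w·M_emp, w linear
  0.25 → 0.75, scan threshold linear 5·10⁻⁴ → 10⁻⁴ over 5 iterations
  (count defaults configurable; a log-spaced threshold schedule is
  available by flag).  Zero-hit iterations leave the matrix unchanged; if
  no iteration finds hits the seed is returned with a failure flag.
  Minus-strand hits are reverse-complemented at scan time, so the count
  matrix is always in motif orientation.
* Overlap significance is the upper-tail hypergeometric P(X ≥ k) via
  scipy; edges in the assembled network are labelled pwm_only / chip_only /
  pwm+chip.

## Comparative genomics

Reciprocal best hits with all three filters applied in both directions:
query ≥ 50 aa, contiguous coverage (span of a single local alignment on
the query / query length) ≥ 70%, identity ≥ 50%.  A tie at the best bit
score rejects the pair as ambiguous.  The internal aligner
(Smith–Waterman, BLOSUM62) is for test-scale proteomes; real proteomes
should import BLAST outfmt-6-like tabular hits, which take the same path
through the filters.  Promoter windows are strand-aware ((−u, +d) relative
to CDS start or TSS; minus-strand sequences reverse-complemented so
position −1 abuts the reference point), with contig-edge truncation
flagged.

## Co-expression

Pearson correlation over arrays; the null for both the empirical p-value
and the per-condition Z-scores is a sample of random gene *pairs* (not
permutations of one gene), because the reference distribution of interest
is the spread of conditional correlations across pairs.  The empirical p
uses +1 smoothing: p = (1 + #{r_null ≥ r_obs})/(n_null + 1).  Conditions
with < 3 arrays are skipped.  Baselines are reported for co-operonic
pairs, adjacent non-operonic pairs, and random pairs; on synthetic
defaults their means order as ~0.7 > ~0 ≈ 0.

## Synthetic worlds

The generator produces, from one seed, a genome laid out as one
promoter+CDS block per gene (strands alternating, so every gene owns an
intergenic promoter window); per-TF regulons with binding sites sampled
column-independently from a ground-truth PWM, planted at non-overlapping
random offsets and strands (every site recoverable by exact string match
at its recorded coordinate); ChIP-style peaks (sensitivity 0.8, false-peak
rate 0.1 per gene, positional jitter; false-peak p-values are drawn below
0.10 so they *pass* the target rule, deliberately stressing refinement);
a latent-factor expression compendium in which co-operonic pairs have
population correlation exactly operon_rho (default 0.7) and TF/regulon
pairs regulon_rho (0.6), decoupled in a designated stress condition; and
divergent sister proteomes (point substitutions to a target identity,
hard-truncated fragments to exercise the RBH filters).

What it does **not** emulate: read-level ChIP noise and peak-shape
artifacts, tree-structured phylogenetic divergence (species are
independent draws from one ancestor), codon structure, indirect readout or
sequence-dependent DNA flexibility in binding (the PWM *is* the generative
truth), and operon membership is a statistical label rather than a strand
arrangement.  Passing tests therefore demonstrate internal consistency and
statistical power of the inference chain under its own assumptions, not
performance on real genomes.

## Problem sizes and design points

The demo/end-to-end world uses 1 TF, 200 genes, 150-bp promoters, width-12
motifs with 0.9 consensus mass, and a light annealing schedule (cooling
0.93, 20 sweeps, 40 temperatures, 2 restarts), chosen so that a full run
takes seconds and 20-seed replicate studies stay desk-scale.  The 0.9/12
design point comes from a power calculation: at the 10⁻⁴ scan threshold
with ~280 windows per promoter, a site sampled from such a PWM is
recovered with probability ≈ 0.93–0.95, so planted regulons are
recoverable but not trivially saturated.  The RBH study uses 18 species ×
12 proteins × 150 aa ("test scale" for the internal aligner).  The default
`generate_world` parameters (2000 genes, 8 TFs, width 15, 18 species,
250-bp promoters) match the full study conditions and remain minutes-scale.

## Known limitations

* The energy model is a caricature; predicted PWMs inherit its biases and
  should be refined against binding data (as the pipeline does) before use.
* Annealer optimality guarantees are empirical and small-W; wide motifs
  rely on the schedule's redundancy (restarts × temperatures).
* Motif-comparison p-values depend on the chosen comparison universe.
* The internal protein aligner does not reproduce BLAST statistics
  (bit-score scale differs); filters operate on identity/coverage, which
  are scale-free, and tabular import is preferred at scale.
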