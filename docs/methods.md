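# Methods

This note documents the models, conventions and numerical choices
behind `genefam`, and what the synthetic-data tests do and do not show
about real data.

## Coordinates and formats

Gene coordinates are 0-based, end-exclusive everywhere, so a gene's
length is `end - start`; GFF3 input (1-based, end-inclusive) is shifted
on import. This convention was chosen because the transcribed survey
table satisfies `length = end - start` on every row. Chromosome `"0"`
is a legal label meaning *unassigned* and is reported separately from
the named chromosomes; chromosome labels are otherwise opaque strings
(the source tables are internally inconsistent about the chromosome
count, so the package takes no position on it). Chromosome percentages
are computed over the genes with a known chromosome, rounded to the
nearest integer (ties away from zero), which reproduces the published
"27% on chromosome 3" for the fixture table.

## Family identification

Redundancy reduction is the classical greedy scheme: proteins are
processed in descending length order (ties by id) and each record joins
the first kept representative whose global-alignment identity reaches
the cutoff (default 1.0, i.e. only effectively identical sequences
collapse). Domain detection is a transparent consensus-pattern scanner
(`X` matches anything; a window is a hit when the match count reaches
`min_score`; overlapping hits of one profile merge to the best window).
It deliberately is not a profile HMM — the published surveys delegate
this step to Pfam/SMART, and a scanner with an exact planted-truth
contract keeps the stage testable; results from an external HMM tool
can be substituted through the same file interface.

## Protein properties

Molecular weight is the sum of average (not monoisotopic) residue
masses plus one water (18.0153 Da), the ProtParam convention, reported
in kDa. The isoelectric point solves `charge(pH) = 0` by bisection on
[0, 14] to |charge| < 1e-4, with Henderson–Hasselbalch terms for the
termini and the D, E, C, Y, H, K, R side chains using the EMBOSS pKa
set (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8,
R 12.5, Y 10.1). The model is composition-only, so pI is invariant
under sequence permutation. Because published tables rarely state
their pKa set, computed pI values are comparable to, not bit-identical
with, table values; the fixture tests therefore assert on the
transcribed column, not on recomputation. Note the tolerance contract
is on the *charge residual*, not the pH: near-flat charge curves (e.g.
termini-only peptides) map 1e-4 of charge to roughly 0.01 pH units.

## Alignment and e-values

Global (not local) alignment throughout, because family members are
full-length homologs and the identity rule of pair calling is over
whole genes; affine-gap optimisation is delegated to
`Bio.Align.PairwiseAligner` (BLOSUM62, open 10, extend 1 by default).
Identity is identical columns over aligned columns excluding terminal
gaps, so large length variation (the fixture family spans 294–2188 aa)
is not penalised. The e-value is an explicit proxy with the
Karlin–Altschul shape `E = k·m·n·N·exp(−λs)` using gapped-BLOSUM62
folklore constants (λ = 0.267, k = 0.041, config-exposed); it exists
to apply the conventional 1e-10 cutoff, not to reproduce BLAST
statistics. The progressive MSA (NJ guide tree + profile-profile
Needleman–Wunsch, linear gap 8, gap-vs-residue −4) is documented as
approximate; an externally built MSA can be passed to any downstream
stage.

## Neighbour joining and bootstrap

Saitou–Nei agglomeration with the Q-criterion; ties in Q break by the
label-sorted pair, and negative branch-length estimates are clamped to
zero with the raw value logged. On additive matrices NJ recovers
topology and branch lengths exactly — this is the primary oracle (50
random 6–10-leaf trees, 1e-9 tolerance) plus the three-taxon closed
form. Bootstrap resamples alignment columns with replacement, rebuilds
the tree per replicate, and annotates each internal edge of the
full-data tree with `round(100 · count / n_reps)`. Replicates in which
some pair of rows shares no comparable column are discarded and logged;
more than 50% discards aborts. The two-group presentation of the family
tree (main group vs subgroup) has no published criterion, so the
analysis script reports the two sides of the longest internal edge and
labels it a heuristic.

## Ka/Ks and duplication dating

Nei–Gojobori (1986) counting with Jukes–Cantor correction, chosen
because it is fully specifiable (the original study names only the
software it used). Sites: each sense codon's nine single-nucleotide
neighbours contribute 1/3 each, synonymous or nonsynonymous, so
s + n = 3 exactly; neighbours that are stop codons count as
nonsynonymous sites. Differences: per differing codon pair, all
minimal mutational pathways are averaged with equal weight, excluding
pathways that pass through a stop; a pair whose every pathway is
stop-blocked is skipped and logged. `pS = Sd/S` and `pN = Nd/N` are
corrected as `K = −(3/4)·ln(1 − 4p/3)`; p ≥ 3/4 is an error
(saturation). ω = Ka/Ks, defined as 0 when both are 0 and flagged
undefined when Ks = 0 < Ka. Codon alignments are obtained by threading
CDSs through the protein alignment; columns with gaps, ambiguous bases
or stops are excluded.

Duplication classes: a pair on the same (known) chromosome with
nearest-edge distance ≤ 5 Mb is tandem; everything else — beyond 5 Mb,
different chromosomes, or any unassigned location — is segmental. The
published rules ("contiguous genes" tandem, "> 5 Mb" segmental) leave
the in-between case open; making 5 Mb the single boundary is the
simplest rule consistent with both, and nearest-edge (not midpoint)
distance is used because contiguity is physical adjacency.

Divergence dates follow T = Ks/(2λ), λ = 6.5×10⁻⁹ substitutions per
synonymous site per year. The transcribed duplication tables' printed
time columns sit uniformly ≈ 0.9% below Ks/(2λ) recomputed from their
printed Ks (ratio ≈ 0.9908), suggesting the original dates were taken
from unrounded Ks values; the package implements the stated formula
and the acceptance suite asserts the ratio band (0.985, 0.995) rather
than pretending the columns reproduce exactly. The tables also leave
"34 tandem genes" vs 34 tandem *rows* ambiguous, so outputs report
both counts.

## Promoter scanning

Promoters are the 2000 bp upstream of the transcription start: plus
strand `[start−2000, start)`, minus strand the reverse complement of
`[end, end+2000)`, truncated (and flagged) at contig edges. Counting is
positional — every start offset is tested, so overlapping matches all
count — and both strands are scanned by default, summing forward and
reverse-complement hits. A palindromic pattern therefore double-counts
on both-strand scans; forward-only mode exists for that case. The
shipped library holds the elements whose sequences the source survey
prints (S000415 ACGTG drought, S000453 GAAAAA salinity, S000030 CCAAT
heat); other accessions it names without sequences must come from a
user-supplied library.

## Expression and physiology

Livak 2^−ΔΔCt with amplification efficiency fixed at 2: Ct is averaged
over replicates first, ΔCt normalises the target to the reference gene
per condition, ΔΔCt subtracts the flagged control level. Significance
uses Welch's two-sided t on per-replicate ΔCt (treatment vs control),
the standard qPCR practice when the original analysis names only a "5%
level"; marks are `**` < 0.01, `*` < 0.05, `ns` otherwise; groups with
fewer than 2 replicates are not assessable, and noise-free degenerate
groups short-circuit to p ∈ {0, 1}. No multiple-testing correction is
applied to the marks (mirroring per-cell reporting conventions); a
Benjamini–Hochberg column is emitted alongside. Direction is "up" for
FC > 1, "down" for FC < 1, "unchanged" only at exactly 1. The heat
matrix is log2(FC) with average-linkage Euclidean hierarchical
clustering cut at k groups. RWC = 100·(WF−WD)/(WS−WD) and Na⁺/K⁺ are
direct formula evaluations with validity checks.

## Synthetic data: what it emulates and what it does not

The generator plants a family on a small multi-chromosome genome:
tandem clusters (members a few kb apart on one chromosome, well inside
the 5 Mb cutoff) and segmental pairs (on different chromosomes —
either placement satisfies the classification rule, and
cross-chromosome placement keeps chromosomes small). Defaults: 4
chromosomes of 120 kb, two tandem clusters of three, two segmental
pairs, three decoys, 220-aa proteins, ω = 0.2 with 0.04 proposal
events per codon (keeping within-family identity safely above the 80%
pair-calling cutoff); estimator-recovery runs use 300 codons at 0.3
proposals per codon so divergence is informative without saturating.

dN/dS is imposed by acceptance-rejection on single-nucleotide
proposals (synonymous accepted, nonsynonymous accepted with
probability min(ω, 1), stop-creating proposals rejected) rather than a
full codon-model CTMC — transparent and sufficient for
estimator-recovery testing. Planted domains are frozen during
evolution, so membership scanning has an exact truth. Promoter
backgrounds are built element-free (left-to-right generation with
suffix repair, both strands), then exactly the planted copies are
inserted at non-overlapping positions and the window is re-scanned to
reject junction artefacts — so planted counts are exact ground truth,
not a statistical expectation. Ct tables put the fold change in the
treated-vs-control Ct shift with Gaussian replicate noise and a
reference gene constant in expectation.

Passing these recovery tests shows the estimators invert the generative
conventions they assume. It does not show robustness to what the
generator omits: indels and alignment error, codon-usage and
composition bias, transition/transversion asymmetry (the JC correction
is the matching choice for the uniform proposal scheme), promoter base
composition, qPCR efficiency ≠ 2, or genome-scale redundancy
structure. Real-data runs inherit those caveats.

## Fixture tables

The three survey tables ship as TSVs transcribed from print. The
printed text runs columns together, so the transcription was recovered
with arithmetic constraints (length = end − start; time column ≈
0.9908·Ks/2λ; mass-per-residue plausibility) and frozen; the fixtures
reproduce the published summary statistics (133 genes, lengths
294–2188 aa, 34 tandem rows with Ka/Ks mean 0.885, 25 segmental pairs
with mean ≈ 1.009) including the source's own internal inconsistencies
(e.g. a printed MW maximum and pI maximum that disagree with the
table's rows; two duplicated segmental rows), which are preserved as
printed rather than corrected.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make the
checks exact or statistically decisive: 50 additive matrices of 6–10
leaves; 20 seeds × 300 codons per ω level; a 13-gene synthetic family;
50 noisy Ct seeds. All randomness flows from a single seed per run.

## Known limitations

- The domain scanner is position-specific-scoring-free; weak or
  diverged domains that an HMM would find can be missed.
- The progressive MSA is a guide-tree profile aligner without iterative
  refinement; for publication-grade trees use an external aligner and
  pass the MSA in.
- The e-value proxy's constants are not calibrated per scoring system;
  only the relative ordering and the conventional cutoff are meaningful.
- NG86 is a counting method; for ω near or above 1 on long branches a
  maximum-likelihood estimator (outside scope) is preferable.
- Bootstrap supports divide by the requested replicate count, so
  discarded replicates (all-gap pairs) depress supports slightly rather
  than renormalising.
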