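# Methods

This note documents the statistical machinery in `silentbias`: the
definitions it implements, the null models behind them, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Genetic code and degeneracy

All statistics are built on the standard nuclear genetic code (61 sense
codons, 3 stops). For every sense codon and codon position we precompute
the *synonymous nucleotide set*: the nucleotides at that position that
preserve the amino acid with the other two positions held fixed. Its size
is the position's degeneracy class (1–4). Third positions partition into
2 onefold (ATG, TGG), 24 twofold, 3 threefold (Ile), and 32 fourfold
codons; the fourfold set includes the NNN-box halves of the sixfold
families Leu, Ser and Arg, whose two-codon halves are twofold. Degeneracy
at positions 1–2 is computed the same way (needed by the SSDU strata);
only Leu, Ser and Arg vary synonymously there. Non-standard codes are not
shipped: the organisms this package targets use the standard code, and the
code object is the single point of extension if that changes.

## Composition metrics

- **GC4**: G+C fraction at third positions of codons in the fourfold set.
  Threefold Ile sites are excluded — only strict fourfold boxes qualify,
  so GC4 is free of any twofold/threefold asymmetry.
- **GC3S**: G+C at third positions of all sense codons except ATG and
  TGG.
- **GC12**: G+C over positions 1–2 of all sense codons (largely
  non-synonymous, hence a proxy for amino-acid-level composition).
- **Skews**: AT skew (A−T)/(A+T) and GC skew (G−C)/(G+C), reported over
  silent third positions (degeneracy > 1) for ORFs and over whole UTRs.
- Terminal stop codons are recorded for stop-usage analysis but excluded
  from every composition and codon statistic. Codons containing N are
  excluded from all counts; transcripts over 10% N are rejected at load
  time. Trailing partial codons are dropped.
- A metric whose defining site set is empty is NaN, never 0.
- Per-taxon summaries use the **median** over transcripts (medians are
  robust to the heavy right tail of transcript lengths); means are also
  emitted for the cross-taxon regressions, which operate on means.
- Bias categories by median GC4: AT-biased < 0.15, intermediate < 0.40,
  non-biased ≤ 0.60, GC-biased above. The positional GC3S profile window
  defaults to 50 codons (configurable; long enough to span the boundary
  effect, short enough that most transcripts cover it).

## Effective number of codons (ENc)

Wright's estimator. For amino acid a with nₐ ≥ 2 occurrences and synonym
proportions pᵢ, the codon "homozygosity" is
F̂ₐ = (nₐ·Σpᵢ² − 1)/(nₐ − 1). Class means are taken over the 9 twofold
families, Ile (threefold), the 5 fourfold families, and the 3 sixfold
families (Leu/Ser/Arg pooled over all six synonyms), giving

    ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,

capped at 61. Families with nₐ < 2 are excluded from their class mean; if
the threefold class is empty, F̄₃ = (F̄₂ + F̄₄)/2 (Wright's own fallback);
a missing twofold, fourfold or sixfold class yields NaN with a reason.
ENc is 20 when every amino acid uses a single codon and approaches 61
under uniform usage. Per-transcript ENc is only reported for transcripts
with at least 100 analyzable codons (default, configurable): below that,
family homozygosities are dominated by sampling noise.

The composition-only null is ENc*(s) = 2 + s + 29/(s² + (1−s)²) for
silent-site GC content s: 31 expected codons at s = 0 (only the A/T-side
codon repertoire in use), a maximum of 60.5 at s = 0.5, and 32 at s = 1.

Reported percentages round half-to-even at two decimals.

## SSDU: site-specific synonymous dinucleotide usage

SSDU asks whether a dinucleotide h is over- or under-used at a codon
frame position p beyond what amino-acid content and single-nucleotide
usage explain. Frame positions: pos1 (codon positions 1–2), pos2 (2–3)
and bridge (position 3 with the next codon's position 1). Synonymous
groups g are amino acids for pos1/pos2 and ordered amino-acid pairs for
the bridge. With o_g the observed fraction of g's occurrences hosting h
at p, e_g the null probability, and n_g the occurrence count,

    SSDU(h, p) = Σ_g n_g (o_g / e_g) / Σ_g n_g

over informative groups (0 < e_g < 1). Groups with fewer than 10
occurrences in a cell are dropped (configurable): o/e ratios explode at
tiny n and would dominate the weighted mean with noise.

**The null.** Single-nucleotide frequencies are estimated separately for
each (codon position, degeneracy class) stratum — "the frequency of
single nucleotides at onefold, twofold, threefold and fourfold sites" —
because extreme composition differs sharply between silent and constrained
positions. The null probability of a codon given its amino acid is the
product over its three positions of the stratum frequency of its own
nucleotide, renormalised over the amino acid's synonyms. Two properties
anchor this construction:

1. With all strata uniform it reduces *exactly* to the equal-usage
   synonymous dinucleotide usage (SDU) estimator it generalises (every
   synonym gets weight (1/4)³, hence 1/k after renormalisation). An
   alternative formulation that renormalises each positional factor within
   the synonymous nucleotide set does not have this property for the split
   sixfold families and was rejected for that reason.
2. Data drawn codon-by-codon from the null (given any amino-acid
   sequence) calibrates to SSDU = 1 in expectation when evaluated with
   the generating frequency table. This is verified at 10⁵ codons in the
   test suite (mean over all dinucleotide × frame cells within
   [0.98, 1.02]).

Plug-in re-estimation of the strata from the observed data (what the
pipeline does by default, as any application to real data must) is exactly
consistent for strata whose contributing sites share one synonymous
nucleotide set, and only approximately consistent at onefold strata and
for the split families Leu/Ser/Arg, where the empirical stratum mix also
reflects the amino-acid profile. The discrepancy is confined to groups
hosting those families; calibration tests therefore evaluate against the
generating table, and SSDU values for Leu/Ser/Arg-dominated cells on real
data should be read with this caveat.

The bridge null takes adjacent codons as independent — a single-nucleotide
null has no pair coupling by definition; the bridge statistic exists
precisely to detect departures from it. Bridges never extend into the
terminal stop. Strata are pooled per cell (not per transcript): the null
is a cell-level description of nucleotide usage. SSDU is reported as a
ratio (1 = unbiased) and as log₂ ratio for heat-map output.

## Expression statistics

- **TPM** uses the raw transcript length (CDS plus any UTRs), not an
  effective length: TPMᵢ = 10⁶ (cᵢ/Lᵢ)/Σⱼ(cⱼ/Lⱼ) per cell, summing to
  10⁶ by construction.
- **Deciles** use minimum ranks, so tied values share the lower bin;
  deciles require ≥ 10 transcripts with positive TPM.
- **Regressions** report the OLS slope with significance from Spearman
  rank correlation; log-TPM regressions use base 10 and drop TPM = 0
  rows rather than add an arbitrary pseudocount. BH correction batches
  follow what each analysis tests: across the 59 multi-codon codons
  within a cell for codon-frequency slopes, across cells within a subset
  for neutrality slopes, across amino acids for cross-taxon slopes.
  "Significant" labels use q < 0.05.
- **Neutrality plots** regress per-transcript GC12 on GC4 (all genes,
  bottom decile, top decile): slope 1 is the pure-substitution-bias
  limit, 0 the full-constraint limit.
- Codon-frequency slopes use per-transcript within-family frequencies,
  defined only where the transcript uses the amino acid at least once
  (NaN rows are dropped); binned-mean alternatives would trade variance
  for bias and are not implemented.

## Curation

Rule order: cross-contamination → within-cell dedup → structural filters
→ composition outliers → UTR eligibility. Thresholds (all CLI-overridable):

- **Cross-contamination**: members of cross-cell pairs ≥ 99% identical
  are removed when coverage < 10 with a same-cell family partner above
  20, or coverage < 20 with a partner above 100.
- **Dedup**: same-cell pairs > 95% identical or sharing a 50-bp run of
  100% identity lose the lower-coverage member (ties: shorter sequence,
  then lexicographically later id).
- **Structural**: ungapped length < 25% of the family mean; same-cell
  paralogs < 50% of the mean; same-cell ≥ 95%-identity paralog groups
  keep only the highest-coverage member; alignment rows with ≥ 30% gap
  columns are dropped (the boundary is inclusive).
- **Composition outliers**: per cell, |robust z| > 3 (median/MAD) on
  GC3S or ENc, removed when coverage < 10 or a same-cell, same-family
  non-outlying transcript with higher coverage exists. Cells under 20
  transcripts skip the rule. The robust-z criterion is a reproducible
  stand-in for by-eye outlier calls.
- **UTR eligibility**: length strictly between 50 and 500 bp; a 5′ UTR
  additionally needs the CDS start methionine to align with a methionine
  in another family row, a 3′ UTR a stop codon in the same alignment
  column as another row.

Design choices where the procedure was genuinely open: pairwise identity
is computed from shared ungapped alignment columns (alignments are already
inputs; no separate identity tool is assumed), and identity is nucleotide
identity. The 50-bp test is a longest-common-substring on unaligned
sequences. "Clade average" is the per-family mean ungapped length —
families stand in for clades at this granularity, since trees are not
inputs. Paralog "clades" are approximated as connected components of
same-cell ≥ 95%-identity pairs, a tree-free surrogate isolated behind one
function. The length-based rules iterate to a fixpoint within a run so
the battery is idempotent (re-curating survivors removes nothing); the
outlier rule is single-pass, mirroring one round of manual inspection,
and is stable on data without planted outliers.

## Synthetic data generator

The generator produces what the analysis assumes and nothing more. Gene
families are shared across taxa: each family fixes one protein drawn from
a shared amino-acid profile (Leu/Lys/Ile-rich, Met/His/Cys/Trp-poor), so
cross-taxon amino-acid conservation holds by construction and family
alignments are gap-free. Per taxon: transcript lengths are log-normal
(median 250 codons, σ = 0.45), expression log-normal (σ_ln = 1.8), k-mer
coverage log-normal (median 60, σ_ln = 0.5), stop codons drawn with
weights (0.55, 0.10, 0.35) for TAA/TAG/TGA (TAG rare), and UTR lengths
log-normal within the 50–500 bp eligibility window. UTR composition is
~40% GC with opposite skews in 5′ (A/C-preferring) and 3′ (T/G-preferring)
UTRs.

Codons are drawn from the same stratified single-nucleotide null SSDU
tests, with the target silent distribution in every stratum; the target
distribution carries mild skews (A:T = 55:45 of the AT mass, C:G = 55:45
of the GC mass) so that G+C equals the configured GC4 target. The default
panel spans GC4 targets {0.03, 0.10, 0.25, 0.45, 0.72}, one cell per
category boundary of interest. Selection is an exponential tilt:
P(codon) ∝ null × exp(s_sel · log₁₀(expression)) for the designated
optimal codon (default: the most AT-rich synonym), a modelling choice,
not an inference from data. Two neutrality regimes exist for regime-
recovery tests: `silent_only` (fixed amino acids, per-transcript jitter of
the silent GC target → neutrality slope ≈ 0) and `all_positions`
(per-transcript GC applied to every position of stop-free random codons →
slope ≈ 1). Contaminants are near-identical (≥ 99%) copies of donor
transcripts planted in recipient cells whose own family member has
healthy coverage, with coverage scaled by the configured ratio (default
0.05) — the index-hopping signature the cross-contamination rule targets.

What the generator does **not** emulate: phylogenetically correlated
evolution, indels and alignment uncertainty, assembly chimeras beyond
coverage-asymmetric duplicates, context-dependent mutation, UTR
regulatory structure, and any coupling between amino-acid usage and
expression. Tests passing on synthetic data therefore demonstrate the
statistics recover what they are defined to measure under the stated
model — not that the model captures every force in real transcriptomes.

In the `silent_only` regime a small positive neutrality slope (~0.05–0.09)
is structural, not a bug: the split sixfold families let silent-site
composition leak into positions 1–2 (e.g. TTR vs CTN for Leu), which is
also a real phenomenon in data.

## Numerical conventions and sizes

Tables are written as TSV with six-decimal floats in deterministic row
and column order; re-running on identical input is byte-identical.
Simulation is fully reproducible from the config seed (a single PCG64
stream consumed in fixed order). Test and acceptance problem sizes —
10⁵ codons for SSDU calibration, 300 transcripts per taxon for panel
recovery, 20 replicates for regime and specificity checks, 100 replicates
for selection sign recovery — were chosen so each Monte-Carlo band is a
few standard errors wide at desk scale.

## Known limitations

- One genetic code; no rare-codon or tRNA-adaptation indices (CAI/tAI
  need tRNA data that does not exist for these taxa).
- The SSDU plug-in null's split-family caveat above.
- The curation identity measure depends on the supplied alignments being
  reasonable; badly misaligned families degrade both the contamination
  and dedup rules.
- Neutrality-plot slopes on few transcripts with narrow GC4 ranges are
  noisy; the pipeline reports n alongside every slope for this reason.
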