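# Methods

This note documents the statistical model, the conventions and numerical
choices behind `regulonscan`, what the synthetic-data generator does and
does not emulate, and the known limitations.  Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Search space: transcription units and upstream regions

The scanned unit is the transcription unit (TU): an operon or a
singleton gene.  TU assignments are an *input* (TSV of tu_id → gene
ids), because proper operon prediction is a separate problem; a clearly
non-canonical fallback heuristic (consecutive same-strand genes with
intergenic gap ≤ 50 bp, singletons allowed) exists so the pipeline can
run on bare annotations.

For each TU the scanner extracts the upstream **inter-TU region**: the
sequence between the TU's first gene and the nearest annotated gene
body of another TU, *irrespective of the neighbour's strand* (inter-TU
sequence is defined purely positionally).  When this region exceeds
800 bp only the immediate upstream 800 bp are kept; the first 40 bp of
the leading gene's coding sequence are then appended, so a region is at
most 840 bp.  The cap is read as applying to the inter-TU portion only,
with the coding extension appended afterwards; regions are reported
5'→3' on the TU's coding strand (minus-strand TUs are
reverse-complemented).  A TU with zero upstream inter-TU sequence
yields only the coding extension and is flagged.

Coordinates are 1-based inclusive internally (GFF3 convention); BED
output is 0-based half-open.

The background model q(b) is the base composition of the aggregated
inter-TU sequence of the genome (the appended coding extensions are
excluded), N's ignored, with one pseudocount per base so every q(b) > 0.

## Profile and scoring

Natural logarithms throughout; scores are in nats.

Columns get pseudocounted frequencies p(i,b) = (counts(i,b)+1)/(n+4).
The pseudocount is fixed at 1 (not configurable) because the analytic
normalization below depends on the n+4 structure.

Column weight: the relative entropy Î_i = Σ_b p(i,b) ln(p(i,b)/q(b)) is
divided by its upper bound

    a = (n+1)/(n+4)·ln(n+1) − ln(n+4) − 1/(n+4)·Σ_b ln q(b) − n/(n+4)·ln q₀

with q₀ = min_b q(b), attained exactly by a column in which all n sites
carry the rarest background base.  This keeps I_i = Î_i/a in [0,1].
The bound is property-tested on 10,000 fuzzed columns; the attaining
column is checked to give I = 1 to 1e-12.

Window score: s_M(t) = max over all l-mers h of Σ_i I_i·ln(p(i,h(i))/q(h(i))).
By default both orientations are scanned (the reference motif is a
near-palindrome, so the orientation max is the safe reading); a
`both_strands=False` / `--single-strand` escape hatch preserves the
single-strand alternative.  Ties break to the lower offset, then the
'+' orientation.  Windows containing N are excluded; a region shorter
than l, or with every window containing an N, yields a no-hit sentinel
that is excluded from statistics rather than scored −∞.  The scanner is
tested for exact equality against brute-force enumeration.

The profile's I_i vector is fixed when the profile is built (from a
caller-supplied background — the pipeline uses the pooled inter-TU
composition of all input genomes); when scoring genome G, the
denominator q(h(i)) is G's own background.  This honours the
per-organism background while keeping cross-genome score terms on one
scale.

## Orthology and the conservation bonus

Orthology is bidirectional best hit (BDBH) on externally produced
protein hit tables (BLASTP outfmt-6-like): a pair is kept when each
protein is the other's best (minimum E-value) hit and both E-values are
≤ 1e-10.  Best-hit ties break by higher bitscore, then lexicographic
subject id — a documented convention chosen to make the map independent
of input row order.  Self-hits are ignored.

For a TU U(g₁…g_n), each gene g_i with orthologs in m_i genomes
contributes

    A(g_i) = (1/m_i) Σ_k [(l − d_ik)/l] · s_M(o_k(g_i))

where o_k(g_i) is the upstream region of the TU containing the ortholog
in genome k (scored against genome k's background) and d_ik the Hamming
distance between the candidate site and that region's best site, both
spelled in profile orientation (equivalently: if the two windows
matched opposite orientations, one is reverse-complemented before the
distance).  The refined score is s(t) = s_M(t) + max_i A(g_i).  Genes
with m_i = 0 contribute 0 to the max — so the bonus is never negative
unless *every* gene of the TU has orthologs and all their averages are
negative (negative per-ortholog terms enter the averages as-is).
Orthologs of the genes of one TU may lie in different TUs of another
genome; the per-gene evaluation above is exactly what handles that.

## Null model, p-values, LOR

For every real region (length L) the null draws 300 coding substrings
of length L — uniformly over all positions of single CDSs long enough,
falling back to the concatenated coding pool (flagged) when no CDS is
long enough — and scores each exactly as the real region is scored.
The ortholog slot structure of the real TU (which genomes, which region
lengths) is kept; only sequence content is randomized, i.e. each slot
is filled with a random length-matched coding substring from the slot's
genome.  Scores are pooled per genome.  All sampling is driven by one
mandatory seed (default 1729, logged).

The empirical p-value of a score s is the fraction of pooled null
scores **strictly greater** than s; p = 0 is reported with a "< 1/N"
flag.  The score cutoff at a target p is the smallest observed null
score whose p-value is below the target; targets below the 1/N
resolution are flagged unachievable.

The genome-level curve LOR(s) = ln(p(S_IU>s)/p(S_CU>s)) is evaluated on
the sorted unique observed region scores, where p(S_IU>s) counts
*regions* (TUs with a valid hit), not windows.  Inside the log both
fractions are smoothed as (count+1)/(N+1) to stay finite at the tails;
raw fractions and raw counts are reported alongside.  Under a true null
(no planted sites, inter-TU composition matched to coding composition)
the p<0.01 call rate is checked to sit in the 95% binomial band around
1% and the mean |LOR| stays below 0.15.

## Regulons, conservation, tree

The regulon at threshold p is the union of member genes of every TU
whose hit has p-value < p (gene-level membership, since conservation is
counted through ortholog pairs).  Defaults: p < 0.01 primary, p < 0.05
secondary (both appear in the pipeline summary).

Conservation: c_ij = |R_i∩R_j| / (|R_i|+|R_j|−|R_i∩R_j|), the
intersection being the number of ortholog pairs with one member in each
regulon.  Distance: d_ij = 1/c_ij off-diagonal.  The diagonal is forced
to 0 (neighbor joining needs it; the reciprocal rule is read as
off-diagonal only).  Pairs with c = 0 get a finite capped distance,
default 10× the largest finite off-diagonal distance, configurable and
logged — infinities would break NJ, and the cap keeps zero-overlap
genomes as clear outgroups.  The source formula's "reciprocal of 1cij"
is typographically ambiguous; d = 1/c is implemented, and the
alternative reading d = (1−c)/c is noted here without being adopted
(the two differ by a constant −1 off-diagonal and produce very similar
NJ topologies).  A pair of *empty* regulons has undefined conservation:
the pairwise function returns NaN with a warning, and the matrix
builder fails listing the offending pairs.

The NJ tree is delegated to scikit-bio's implementation; negative
branch lengths are clamped to zero with the deficit moved to the
adjacent branch.  NJ is verified against a least-squares brute force
over all 4-taxon topologies on additive input, and on 6 synthetic
genomes carrying two disjoint planted regulon groups the two groups are
required to separate into two clades.

## Synthetic data: what it emulates, what it does not

The generator emulates the statistical structure the scan assumes:
multiple genomes with TU-structured layouts (shared gene counts per TU
slot across genomes, so slots define ortholog families), per-genome
strands/gene lengths/intergenic gaps, codon-structured coding sequence
(uniform over the 61 non-stop codons — deliberately no codon bias),
intergenic sequence at a configured GC content, an ortholog map from
family labels (a fraction `ortholog_coverage` of families is linked
across all genomes), and planted motif instances: one PWM-sampled site
per planted TU, mutated per genome at `planting_fidelity` per base and
written into the upstream gap of the same TU slot in every genome
carrying it.  Planted TU slots are chosen non-adjacent so no two sites
share an intergenic gap, and each planted site is verified at
generation time to fall inside the extractable upstream window.

Defaults are the conditions the validation experiments use: 4 genomes
(one target, three references), 1,000 TUs per genome, gene counts per
TU of 1–4 with probabilities (0.6, 0.25, 0.1, 0.05), gene lengths
300–900 bp, intergenic gaps 80–400 bp, GC 0.5, 20 planted TUs, 2%
per-base site divergence, 75% ortholog coverage.  Gap and gene-length
ranges are chosen to look like compact bacterial genomes while keeping
every gap able to hold a 14-bp site; they are not fitted to any genome.

Not emulated: realistic codon usage or GC skew, genome rearrangement
and gene order evolution, indels in planted sites, ortholog detection
noise (families are labels; a toy hit-table writer exists only to
exercise the RBH reader), multiple sites per region, and regulatory
turnover beyond the group-structured planting switch.  Passing the
recovery tests therefore shows the machinery is correct and the bonus
behaves as designed — not that real genomes with skewed composition,
horizontal transfer or diverged motifs will yield the same recall.

## Problem sizes used by the tests and the acceptance script

Scanner/brute-force equivalence uses 1,000 random 60-bp regions; the
information bound 10,000 fuzzed columns; null calibration one unplanted
1,000-TU genome with intergenic composition drawn from the coding
model; recovery one 4-genome set (1,000 TUs each, 20 planted TUs); the
regulon-tree check six 60-TU genomes with two planted groups of 8 TUs
at 50% ortholog coverage.  The null uses 300 samples per region
throughout.  These sizes keep the full validation run to a few minutes
on one CPU while leaving the binomial and Monte-Carlo error bands well
inside the asserted tolerances.

## Known limitations

- Only the best window per region is reported; a region with several
  true sites yields one hit.
- Gapped or variable-length motifs are out of scope.
- The empirical p-value is per-genome; no multiple-testing correction
  across TUs or genomes is applied (the LOR curve is the genome-level
  confidence instrument instead).
- Pooling null scores across regions of different lengths makes the
  *average* call rate correct but individual p-values slightly
  conservative for short regions and slightly liberal for long ones.
- BDBH orthology is pairwise only; no clustering into families, no
  paralog resolution beyond the best-hit rule.
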