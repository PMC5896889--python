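# Methods

This note documents the models behind `duplimap`, the defaults that
matter, what the synthetic data do and do not emulate, and the design
choices made where more than one construction was defensible.

## Genetic model

Individuals are phased diplotypes over a linkage map: per locus an ordered
pair of parental-origin alleles, G (*M. guttatus*) or N (*M. nasutus*),
plus a maternal cytoplasm label. The default map has 14 chromosomes of
100 cM with the hybrid-lethality loci at chr13:90 cM (*hl13*, distal) and
chr14:50 cM (*hl14*); physical coordinates use a uniform 200 kb/cM scale
(the real genome's ~430 Mb over ~1,400 cM is of this order, and nothing
downstream depends on the exact constant).

**Meiosis.** Crossovers per chromosome are Poisson with mean length/100
Morgans, placed uniformly, with a fair starting strand — the Haldane
(no-interference) model, giving recombinant fraction
r(d) = (1 − e^(−d/50))/2. No map function was stated for the original
analysis; Haldane is the simplest defensible choice and the one whose
closed form the tests verify against simulation. Real meiosis shows
positive interference, so simulated double crossovers at short distances
are slightly more common than in real data; this only makes the
fine-mapping tests conservative.

**Founders.** The N founder is homozygous N everywhere (a natural
selfer). The G founder starts fully heterozygous and is selfed three
generations, leaving residual heterozygosity with expectation
(1/2)^3 = 12.5% (`expected_homozygosity(g) = 1 − (1/2)^g`). Both founders
are forced homozygous for their own allele at the causal loci — the real
lines were verified fixed there — and at any loci declared
*fixed-difference loci*. The latter matter: SNP panels and mapping
markers are ascertained **as** differences between the lineages, so the G
founder must read G there; its residual heterozygosity lives at sites the
panel does not see. Without this distinction, serial selfing from a fully
heterozygous founder fixes the N-coded allele at ~44% of loci and pooled
allele frequencies at unlinked SNPs drift far from the 50% the pooling
design guarantees.

**Lethality predicates.** An incompatibility model lists (locus,
incompatible allele) pairs with dominance flags and an optional required
cytoplasm. The retained model is recessive-recessive:
white ⇔ GG at *hl13* and NN at *hl14*. The screen's catalog adds
one-locus recessive, dominant-by-recessive, and cyto-nuclear recessive
variants; it is extensible by constructing further `IncompatibilitySpec`
objects. Expected phenotype fractions per cross class are computed by
exact enumeration in rational arithmetic (unlinked causal loci); parental
selfs are 0 for every model by construction, because hybrid
incompatibility alleles are only exposed on the heterospecific background
and both parental lines are observed viable. F3 expectations marginalize
over green F2 parents (lethal genotypes never reproduce).

**Pooled sequencing.** Per SNP, total depth ~ Poisson(μ) and alternate
reads ~ Binomial(depth, p′), p′ = p(1−ε) + (1−p)ε with symmetric
per-read error ε (default 0.005, a typical post-filter short-read
substitution rate). Zero-depth SNPs are emitted as missing. A
configurable fraction of panel SNPs (default 0.02) violates the
shared-SNP assumption — the G founder carries the alternate allele, so
both pools read fixed-alternate there — emulating a panel called against
a reference that is a different accession of the G species.

## Statistical procedures

- **Model screen**: Pearson chi-squared goodness of fit on {white, green},
  df = 1, no continuity correction, α = 0.05 (no level was stated; 0.05 is
  the field default, and the decisive comparisons are far from the
  boundary). Boundary expectations (0 or 1) use the exact rule: any
  discordant observation rejects. Reciprocal F2s are compared by a 2×2
  Pearson test; homogeneous directions are pooled, a significant
  difference raises the cyto-nuclear flag.
- **Window scan**: windows are defined in SNP-index space (200 SNPs,
  step 100), matching the published definition; the statistic is the
  unweighted mean of per-SNP frequency differences (no depth weighting was
  described), alongside the mean absolute difference. SNPs under
  min_depth = 4 reads in either pool are masked before windowing (a
  minimal-coverage guard; logged in outputs). Trailing short windows are
  dropped. Region calling thresholds |signed mean| at the top quantile
  (default 5%) and the mean absolute difference at the bottom quantile
  (default 0.5%), then merges runs of ≥ 3 consecutive flagged windows into
  half-open bp intervals (BED convention). Both the merged regions and the
  individual flagged windows are returned: at desk scale (20,000 SNPs,
  ~180 windows) each window spans ~14 cM, the bottom 0.5% tail holds fewer
  windows than the contiguity requirement, and the flagged-window list is
  the right granularity for locating the least-divergent trough.
- **Marker BSA**: a marker is associated when all white replicate pools —
  minus a tolerance of one, the "only (or mostly)" rule — are fixed for
  one parental allele while green pools are mixed; markers missing in more
  than half the pools are excluded.
- **Progeny test**: any white F3 proves a heterozygous parent; an
  all-green family proves a compatible homozygote once 0.75^n < α
  (exact binomial tail), i.e. n ≥ 11 at α = 0.05; smaller all-green
  families are ambiguous.
- **Interval narrowing**: each informative recombinant implies a causal
  genotype class (white ⇒ incompatible homozygote; green resolved by its
  progeny test); a marker gap is consistent with a record when either
  flanking marker matches the implied class, with missing calls as
  wildcards. This is deliberately conservative: intervals may be slightly
  wide, never wrongly narrow. The result is the span of gaps consistent
  with every record, clipped to the current search interval; an empty
  intersection raises an inconsistency error naming the records (the
  symptom of genotyping error, a double crossover inside a bracket, or a
  wrong model). Assembly gaps are markers with unknown bp; intervals
  spanning one carry a flag.
- **Copy placement**: presence is dominant (PCR amplifies a copy from
  either homolog); a haplotype is assigned the unique (locus, allele)
  candidate with zero presence mismatches, otherwise reported unplaced
  with best candidates. Haplotype calling uses set containment over
  superposed diagnostic states, with ambiguity flags for haplotypes
  indistinguishable at the observed positions or wholly covered by the
  other candidates.
- **Frameshift detection**: global alignment (match 1, mismatch −1, gap
  open 10, extend 0.5 — conventional defaults, configurable); a net
  length offset ≢ 0 (mod 3) is a frameshift; the query is translated from
  the position aligned to the reference start and stops whose codons end
  before the alignment-projected reference terminal stop are premature.
- **Expression summaries**: genes count as misexpressed when flagged in
  all three white-vs-green comparisons; sign consistency is *not*
  required (only significance was required in the original analysis) but
  discordant signs are surfaced. Row Z-scores use the population (divisor
  n) standard deviation — the figure convention was unstated; either
  divisor is defensible and it is a parameter. Constant rows map to zero.

## The synthetic data, and what passing tests mean

The generators reproduce the *statistical structure* each stage assumes:
Mendelian segregation with linkage, the 1/16 white F2 rate, 3:1 / 1:0 F3
families, pool allele-frequency structure (50% at unlinked SNPs in the F3
pooling design; fixed divergence at the causal locus; a fixed-identical
trough at the controlled partner locus), the nine-genotype-class copy
panel (10 replicates × 8 green classes + 16 white = 96), and planted DE
signals with independent false positives. They do **not** emulate:
variable SNP density and recombination-rate heterogeneity, segregation
distortion, genotyping error in marker assays (exposed instead as explicit
flips/offsets), read mapping artifacts around duplicated sequence, or
library-size effects in expression. Passing tests therefore demonstrate
correctness of the inference machinery under the stated model, not
robustness to every artifact of real data.

Default study conditions mirror the experiments: 34-white / 26-green F3
pools at depth 30; F2 populations of 516 and 661 for the printed-ratio
consistency checks; a 96-member copy panel. The genome-wide SNP panel is
scaled to 20,000 SNPs (the real panel had 235,922) so the full scan runs
in about a second; window counts scale accordingly (~180 vs ~2,300), which
is why the flagged-window granularity discussed above exists. The
acceptance script uses 10,000 simulated populations for the interval
checks, 50 replicates of the pooling design at 3,000 SNPs for the
unlinked-frequency check, and 10^4 unlinked loci for the selfing
cross-check.

## Numerical notes and edge cases

- All randomness flows through one NumPy generator per entry point; child
  seeds are derived deterministically (`SeedSequence`), and a fixed seed
  reproduces populations and pool counts bit for bit.
- Genotype arrays are int8 (n × 2 × loci); meiosis is vectorized per
  chromosome with a memory-capped broadcast.
- Degenerate inputs have defined behavior: empty pools and zero-depth
  SNPs yield missing records; an empty white class makes concordance NaN;
  chromosomes with fewer SNPs than a window yield no windows; a
  single-genotype-class copy panel and a gene-universe mismatch raise.
- Quantile thresholds use `numpy.quantile` interpolation; ties at the
  threshold are included (≥ / ≤).

## Known limitations

- The Haldane model ignores crossover interference (see above).
- Interval narrowing assumes the causal locus lies strictly within the
  genotyped marker span; it cannot extend beyond the outermost markers.
- The placement test requires at least two genotype classes and gains
  identifiability from all nine; panels sampling few classes return
  unplaced haplotypes rather than guessing.
- Real bp coordinates (e.g. the published 72.2 kb / 51.6 kb intervals)
  require the reference assembly and are out of scope; simulated maps use
  the uniform cM→bp scale.
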