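# Methods

This note documents the models, parameter choices and numerical decisions in
sweepscan, and what the simulation-based tests do and do not establish.

## The analysis

The pipeline compares a pooled wild sample against a cultivar sample that is
only a few sexual generations removed from it. After SNP filtering, all
statistics are computed in 50-kb sliding windows with 20-kb steps; per-bp
quantities divide by the true window span, so truncated windows at chromosome
ends are on the correct scale. Windows with fewer than 10 SNPs (configurable)
carry undefined statistics and are excluded from percentile ranking.

**Filters.** Sites are kept if biallelic, QUAL ≥ 30, site-mean depth in
[4, 60], missing-call fraction ≤ 0.10 and pooled minor-allele frequency
≥ 0.05. Depth is also enforced per genotype: calls with DP outside [4, 60]
are set to missing *before* the missingness and MAF tests, covering both
readings of a site-versus-genotype depth rule. Removal counts attribute each
dropped site to its first failing rule in the fixed order biallelic → QUAL →
depth → missingness → MAF, so the counts always sum to sites-in − sites-out.

**Diversity statistics.** π uses the unbiased per-site estimator
2p̂q̂·n/(n−1) with n the non-missing allele count at the site. θ_W uses the
modal n across segregating sites. Tajima's *D* uses the standard 1989
normalization; under missing data the constants use the *minimum* non-missing
allele count across the sites in the window (conservative), and sites with
fewer than 4 alleles are excluded. *D* is reported as undefined (NaN), never
0, when S = 0. F_ST is the Weir–Cockerham (1984) two-population estimator
with the ratio-of-sums ("weighted") window aggregation; negative estimates
are reported as computed. The folded SFS is computed at a fixed allele count
(default: all haplotypes of the population); sites with missing calls are
dropped rather than projected — at the simulator's missingness levels
projection buys nothing and complicates the counts. LD decay is the
genotype-dosage (composite, phase-free) r², appropriate for unphased
short-read genotypes; missing dosages are mean-imputed per site.

**XP-CLR-style scan.** The cultivar (object) allele count k₂ of m₂ at a SNP
with wild (reference) frequency p₁ is modeled as binomial given a drifted
frequency q. Neutrally, q has mean p₁ and variance ω·p₁(1−p₁), with ω a
genome-wide drift coefficient estimated by method of moments (the expected
binomial sampling variance, mean[1/m₁ + 1/m₂], is subtracted; the estimate is
floored at 10⁻⁴). Under a sweep at the window midpoint, a lineage at
recombination distance r escapes with probability c = 1 − ε^(r/s)
(ε = 5×10⁻⁵, clamped to [10⁻⁶, 1]); the pre-drift frequency is the two-point
mixture {(1−c) + c·p₁ with weight p₁, c·p₁ with weight 1−p₁}. Drift is a
censored normal on (0,1): truncated-normal density plus point masses at the
boundaries equal to the clipped tails. p₁ carries a pseudocount of 0.5 per
allele class so the likelihood stays finite. The window score is
CLR = 2·max over the selection grid {0.001, 0.005, 0.01, 0.05, 0.1, 0.5} of
the summed site log-ratios, floored at 0, with equal SNP weights. Scores are
comparable in rank, not absolute value, to other implementations of the
statistic (no LD down-weighting, focal points at window midpoints only).

*Numerics.* The drift integral is evaluated by fixed-order Gauss–Legendre
quadrature (default 128 nodes) in the standardized variable t = (q − m)/σ,
truncated at |t| = 8, which resolves narrow densities (small c, extreme
mixture means) as well as wide ones; components with σ < 10⁻⁶ collapse to a
binomial point mass at the mean. Against adaptive quadrature the site
likelihood agrees to ~13 digits, and doubling the node count moves window
CLRs by far less than 0.1%.

**Composite call.** A window is called when it sits at or above the
genome-wide 95th percentile (linear interpolation, inclusive of ties) of both
XP-CLR and F_ST *and* its Tajima's *D* is strictly negative in cultivars and
strictly positive in wild accessions, per window. Percentiles are genome-wide
over defined windows. The pre-*D* two-statistic overlap is reported as a
diagnostic stage. Called windows merge into maximal blocks when overlapping
or book-ended (the simplest deterministic rule given step < window size);
genes are assigned to blocks on ≥ 1 bp overlap of half-open intervals.

**Terminal ROH.** SNPs are masked to single-copy gene intervals (paralog
collapse cannot fake homozygosity there). Per sample and chromosome, runs are
maximal greedy left-to-right stretches of homozygous calls allowing up to
`max_het` (default 0) heterozygous interruptions; missing calls are
transparent — they neither break nor count toward a run, which avoids
fragmenting runs over call-rate artifacts. Runs below 25 SNPs or 10 kb are
dropped. A run is terminal when it contains the first or last retained SNP of
the chromosome; it is "extensive" when it covers ≥ 25% of the retained-SNP
extent. Because the clonal ('one-step') signature is genome-wide, a sample is
flagged only when at least half of its reportable chromosomes carry an
extensive terminal run. The run definition is this package's own — the
analysis it implements names no algorithm — and every threshold is
configurable.

**Dating.** T = Ks/(2r) in years. With the Ks peak 0.35 and the proxy rate
r = 4.175×10⁻⁹ substitutions/site/year this gives 41.9 MYA; published
accounts of the same peak print slightly different ages (42.3 or 46.8 MYA),
implying an unstated r, so the formula rather than any particular age is the
contract here.

## The synthetic-data generator

The generator emulates the domestication history of a clonally propagated nut
tree: a structured wild species from which a handful of founder trees were
taken, a few generations of seedling selection, then clonal propagation.

**Wild side.** Three demes of N = 200 diploids exchanging migrants
(island model, m = 1.7×10⁻³ per generation, chosen for strong regional
divergence, inter-deme F_ST ≈ 0.25) are initialized with a neutral coalescent
(msprime) — the sanctioned fast replacement for a forward burn-in. Pooling
the wild sample across demes makes genome-wide wild Tajima's *D* positive,
which is the regime the *D*-sign filter of the composite call presumes.

**Desk-scale rescaling.** Sizes are O(10²) with mutation and recombination
rates inflated by the same factor (~40): mu = 1.75×10⁻⁷/bp/generation so that
4·(3N)·mu ≈ 4.2×10⁻⁴ matches the per-bp diversity of such crops, and
rrate = 4×10⁻⁷ Morgans/bp (from 1 cM/Mb), preserving both θ = 4Nμ and
ρ = 4Nr. Rescaling r as well as μ is essential: with literal r a desk-scale
chromosome has a ~0.01-Morgan map and the entire chromosome hitchhikes with
any sweep. The literal rates (μ = 4.175×10⁻⁹, generation time 8 years) are
carried in the config as metadata for real-data work.

**Domestication.** Six founders are drawn from deme 1. Each implanted sweep
locus is seeded on one founder haplotype (frequency 1/(2·n_founders));
if it is lost during the forward stage the stage restarts (up to 100 times,
then an error names the locus). Each of the (default 4) generations, 400
seedlings are produced by random mating with recombination (Poisson
crossovers) and de novo mutation at the rescaled μ; then the 25
highest-scoring seedlings become the next parents, where
score = Σ s_l·dosage_l + N(0, 0.5²) — truncation selection on a highly
heritable trait, which is how orchard selections were actually made. *s* is
therefore the phenotypic effect of one allele copy in units of twice the
residual SD. The classical viability model (fitness 1, 1+s/2, 1+s per locus,
multiplicative across loci) is available as `selection_mode="fitness"`, but
with 2–4 generations its per-generation response (≈ s·p·q/2) cannot move a
rare allele to sweep frequencies, so it cannot implant detectable hard sweeps
and is not the default. The final cohort is unselected and the cultivar
sample (default 59, against 42 wild) is drawn from it.

**Emission.** VCF v4.2 with phased GT and per-call Poisson DP, QUAL drawn so
a configured fraction of sites falls below 30, and a configured fraction of
calls masked; GFF3 genes tiled along each chromosome with a Bernoulli
single-copy flag; truth as BED plus a JSON config snapshot. Identical config
and seed give byte-identical outputs.

**What the simulator does not emulate.** Real read alignment and genotyping
error (QUAL/DP are parametric, independent of genotype), gene conversion,
varying recombination or mutation rate along chromosomes (no pericentromeric
low-recombination deserts), clonal propagation with mitotic recombination
(the ROH test uses engineered tracts as the positive control instead),
admixture between wild demes beyond symmetric migration, and multiallelic or
indel variation. Passing tests therefore establish the statistical machinery
and its calibration under a faithful neutral/sweep demography, not robustness
to alignment artifacts.

## Study conditions used by the tests

Neutral calibration: 50 replicates of the default conditions (5 chromosomes ×
1 Mb); the fraction of windows passing the full composite call is ≤ 0.05 by
construction (it is bounded by each marginal top-5% rule) and lands near
0.003. Sweep power and recovery: 50 replicates per s ∈ {0.1, 0.5, 1.0} on the
same 5 × 1 Mb genome with one sweep at chr1:500000 (so the footprint is a
small fraction of the ranked windows, as in real data); mean XP-CLR at the
truth window rises monotonically with s, and ≥ 70% of s ≥ 0.5 loci fall
inside called blocks (measured ≈ 0.9 at s = 0.5 and ≈ 0.65 at s = 1.0 — complete
fixation can extinguish cultivar variation in the focal window, leaving its
*D* undefined, so recovery is not monotone in s). Localization: the
top-scoring window always lies on the swept chromosome and the truth window
sits in the genome-wide top-5% XP-CLR tail in > 80% of strong-sweep
replicates; the top-1 window itself lands on the truth window in only ~70% —
a ≤ 4-generation sweep drags the whole carrier haplotype, so the argmax
among its windows is weakly identified. ROH: 50 neutral replicates; an
engineered clone with terminal homozygous tracts over 40% of masked SNPs on
every chromosome is flagged, the unmodified sample is not, each in ≥ 90% of
replicates. Replicate counts and genome sizes are the package's chosen desk
scale; all are configurable.
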