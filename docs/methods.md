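# Methods

## Problem and design

`driftprint` re-creates, as a tested pipeline, the comparative-genomics
workflow used to detect a recent population bottleneck from whole-genome
genotype data: a landlocked (isolated) deme is compared against stable
anadromous demes on four footprints — per-site heterozygosity (and the
effective size it implies), runs of homozygosity (RoH), the
nonsynonymous/synonymous diversity ratio, and the zygosity of deleterious
variants — plus a neighbor-joining phylogeny with SNV-bootstrap supports.
Because the original cohort is tens of whole genomes, every stage is made
verifiable at desk scale by a forward Wright–Fisher simulator that emits
the complete input bundle (VCF, sample table, GFF3 coding annotation,
conservation-score BED, outgroup alleles, reference FASTA) together with a
per-variant truth record.

## Heterozygosity and effective size

H is the count of heterozygous genotypes at retained biallelic SNVs divided
by the sample's callable-site count. The denominator is taken from the
user-supplied per-sample coverage accounting when available; otherwise the
count of non-missing genotyped sites stands in and the report flags the
fallback. Population summaries are mean ± SEM (sd/√n, ddof = 1); SEM is
reported as undefined for single-sample populations.

Two Ne conversions are implemented behind a required explicit flag, because
the relation stated with the published analysis (Ne = H/4μ) and the
effective sizes it prints (120,000 and 206,000 at H ≈ 0.00037,
μ = 3×10⁻⁹/site/generation) are mutually inconsistent: `textbook` computes
Ne = H/(4μ) from H = 4Neμ, while `paper-calibrated` computes Ne = H/μ, the
relation that reproduces the printed values. The replication preset uses
`paper-calibrated`; neither convention is asserted as the original intent.

## Runs of homozygosity

Site filtering mirrors the genotype-QC filters (`geno` ≤ 0.01 missingness;
minor-allele frequency ≥ 0.05 computed over the study samples, outgroup
excluded; a site exactly at the MAF threshold is retained). The scan is a
plink-style SNV sliding window: windows of 50 consecutive SNVs are
homozygous when they contain at most 0 heterozygous and 5 missing calls; a
SNV is run-eligible when ≥ 5% of the windows covering it are homozygous;
maximal stretches of eligible, observed-homozygous SNVs are split at
heterozygous or missing calls and at inter-SNV gaps above 1 Mb, then kept
if they span more than 0.5 Mb (strict, configurable), contain ≥ 100 SNVs
and satisfy 50 kb/SNV density. Segment coordinates are SNV-to-SNV spans —
no extension into flanking unobserved sequence — so results are
reproducible from the VCF alone. Only `geno`, `maf`, the window-het
allowance and the 0.5 Mb floor are fixed by the replication configuration;
the remaining knobs default to the conventions the scanning tool family
uses and are configurable. A missing call never extends a run; it
terminates it (the window stage already tolerates missingness, and the
1% missingness filter makes the distinction marginal). Size classes follow
the medium (0.2–1 Mb, inclusive) and long (> 2 Mb, strict) convention.

The scanner is validated by exact equivalence against an explicit
window-enumeration oracle (plain loops, no shared code) on hundreds of
random chromosomes up to 5,000 SNVs.

## Mutational load

Site totals use Nei–Gojobori counting: each codon position contributes f/3
synonymous sites, f being the number of the three single-base changes that
preserve the amino acid; changes creating a stop count as nonsynonymous;
stop codons themselves are excluded; ambiguous codons are skipped and
logged. Variant classification extracts the codon in transcript
orientation (minus-strand transcripts are reverse-complemented), translates
ref and alt with the standard genetic code, and assigns synonymous /
missense / LoF (stop_gained, stop_lost, start_lost, splice_donor,
splice_acceptor — splice sites being the 2 bp dinucleotide positions at
each intron end). One codon table, built from Biopython's standard table,
backs both site counting and classification. When a variant hits several
transcripts the most severe effect wins (LoF > missense > synonymous).

Per-genome dN/dS divides carried nonsynonymous and synonymous SNV counts by
the respective site totals. "Carried" means het or hom-alt; by default a
carried variant counts once regardless of zygosity (`presence`), with an
allele-count weighting (het = ½) available behind a flag — the published
description does not say which was used, so both are exposed. Stop/start
LoF changes are codon changes and enter the nonsynonymous numerator;
splice variants do not. Deleterious means conservation (GERP) score
strictly above 4. Polarization uses the outgroup base: equal to ref → alt
is derived; equal to alt → ref is derived; anything else → unpolarizable,
excluded from derived-allele statistics but counted. In zygosity
partitioning, "homozygous" means both copies derived where polarizable and
hom-alt otherwise (flagged), so the partition is always complete.

## Phylogeny

The default pairwise metric is the allele-sharing distance: per
co-genotyped site, mismatch = (2 − shared alleles)/2, i.e. |g_i − g_j|/2 on
dosage codes, averaged over sites (a genotype p-distance is available).
The published analysis does not name its metric; population-level distances
are means over between-population sample pairs, and both a sample-level and
a population-level tree are emitted. Neighbor joining is the classic
Q-matrix agglomeration; negative branch lengths are clamped to zero with
the deficit shifted to the sibling edge (logged). NJ is exact on additive
matrices, which the tests exploit: random trees with known path-length
matrices must be recovered identically. Bootstrap pseudoreplicates resample
site columns with replacement (resample size = site count); the support of
an internal edge of the full-data tree is the integer percentage of
replicate trees containing the same bipartition; the resampling stream
depends only on the seed and site indices, making supports invariant to
taxon order. Trees are rooted on the outgroup's pendant edge; rooting
preserves the bipartition set and hence the supports.

## Significance machinery

Two-sample Z tests on means: Z = (m₁ − m₂)/√(SEM₁² + SEM₂²) against the
standard normal, two-tailed. Correlation significance converts Pearson r to
t = r√(n−2)/√(1−r²) with n−2 df (two-tailed); at r = 0.79, n = 29 this
yields P ≈ 4×10⁻⁷, under the published "P < 0.000001" bound. A Fisher-z
alternative is available behind a flag. No multiple-testing correction is
applied, matching the original analysis.

## The synthetic cohort generator

Forward-in-time diploid Wright–Fisher simulation was chosen over a
coalescent because selection on nonsynonymous classes and per-individual
RoH mosaics are both required; a coalescent simulation (msprime) serves
only as a neutral cross-check oracle in the tests. One chromosome;
discrete generations; Poisson crossovers (rate r per bp); Poisson
infinite-sites mutation (rate μ per site; colliding positions skipped);
viability selection 1, 1+hs, 1+2s for 0/1/2 copies of a deleterious allele
(s stored negative, multiplicative across sites). After a burn-in of
8·N_anc generations the trunk deme continues and further demes split from
it at their stated times; one deme may carry the bottleneck. Sampled
diploids are written as VCF against the ancestral sequence, which doubles
as the reference FASTA, so the truth record knows the exact ancestral
allele of every variant.

Coding layout: equal-length single-exon genes (ATG + random sense codons +
stop, 999 bp), evenly spaced and alternating strand, covering 30% of the
chromosome. The synonymous/nonsynonymous/LoF class of every new mutation is
determined from the actual codon change, and nonsynonymous changes are
deleterious with probability 0.8 (most new amino-acid changes are
deleterious in distribution-of-fitness-effects studies) at the scenario's
s. Conservation scores emulate threshold behaviour only: deleterious-truth
sites score uniform(4.01, 6) with probability p_hit = 0.9, neutral sites
with p_false = 0.02, everything else uniform(−2, 4). The outgroup is the
ancestral sequence plus Poisson mutation along a 15,000-generation branch,
so the emitted outgroup track carries realistic polarization error (~0.5%
of sites hit; tests require ≥ 95% agreement with truth at polarizable
sites).

Scaling: population sizes are a few hundred and rates are inflated
(μ = 3×10⁻⁷/site/gen, r = 2×10⁻⁷/bp/gen on a 10 Mb chromosome for the
two-deme scenario; 4 Mb for the six-deme cohort) so that 4Nμ and 4Nr per
site sit in a realistic range (θ ≈ 1.2×10⁻⁴) while a full replicate runs in
roughly ten seconds. The generator is seed-deterministic down to the bytes
of the emitted VCF.

What the generator does not emulate: gene conversion, migration after
splits, introns in the simulated genes (the classifier supports multi-exon
transcripts; the generator does not emit them), linked-read or calling
artefacts, tetraploid salmonid ancestry, and any realistic karyotype —
passing tests therefore demonstrate correctness of the statistics on an
idealized genome, not robustness to calling noise.

### The unlinked-loci calibration mode

The diffusion-equilibrium check (E[H] = θ/(1+θ) at θ = 0.02) concerns
infinite-alleles loci; it is implemented as a dedicated vectorized
Wright–Fisher over 2,000 unlinked loci (each mutating to a fresh allele at
μ = θ/4N) rather than by forcing free recombination through the crossover
machinery. Forward results agree with the closed form within 15% and with
an msprime coalescent simulation within Monte-Carlo error.

## The two-deme recovery scenario and its power

The standard test condition is N_stable = 100, N_bottleneck = 10, split 50
generations before present, s = −0.01, h = 0.5, ten samples per deme,
twenty seeded replicates. Heterozygosity, RoH count, RoH total length and
the homozygous-deleterious fraction all point the expected way in
essentially every replicate at this scale.

The diversity-ratio footprint is different in kind. Over only 50
generations the expected contrast is the purging differential
≈ h|s|·Σ_t(F_stable(t) − F_bottleneck(t)) ≈ 0.13 on deleterious allele
frequencies, which dilutes to a few percent on the ratio. Worse, the
per-genome carried count is 1−(1−p)², a concave function of frequency, so
the strong drift of the bottleneck *lowers* presence-counted burdens of
rare (disproportionately deleterious) variants — at short divergence this
cancellation makes the presence-counted dN/dS contrast essentially
directionless. The recovery harness therefore scores the allele-frequency-
weighted ratio (the πN/πS form, exposed by the `allele-count` weighting),
which responds to relaxed purging directly; even so, the expected shift
(~+0.01–0.03) is of the same order as between-replicate drift noise
(SD ≈ 0.02 at 10 Mb), and the measured recovery rate is ~60–85% rather
than the ~100% of the other footprints. Resolving it reliably would need
roughly four times more recombinationally independent sequence, i.e.
minutes-per-replicate simulations. This is a genuine property of the
scenario's effect size at desk scale, reported as such rather than hidden;
over longer divergence times (hundreds of generations) the contrast grows
and the ambiguity disappears.

## Numerical and degenerate-input choices

Genotype codes are dosage-valued int8 (0/1/2, −1 missing); half-calls and
non-diploid genotypes on biallelic records become missing with a logged
count. Boundary rules: missingness filter is ≤ geno; MAF filter drops
strictly below the threshold; RoH length floor is strictly greater than
0.5 Mb; the deleterious threshold is strictly greater than 4; all four are
configurable. Newick round trips preserve lengths to 1e-9 and integer
supports. Empty categories, zero carried synonymous SNVs, and
single-sample populations produce NaN plus a warning, never silent zeros.
Bootstrap tie-breaking inside NJ is deterministic (first minimum of the Q
matrix in row-major order).

## Problem sizes used by the test suite

Unit tests run on hand-built matrices and sub-second simulations; the
session-scoped fixtures are one 10 Mb two-deme replicate, a twenty-replicate
recovery run of the same scenario, and one six-deme 4 Mb cohort driven
through the full pipeline with 25 bootstrap replicates. The acceptance
script reruns the recovery and calibration computations from scratch at the
same sizes. These sizes are the package's standard desk-scale conditions;
all are parameters, not hard limits.
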