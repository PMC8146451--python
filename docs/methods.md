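# Methods

This note documents the models, defaults and numerical choices behind
`introbsa`, and what the synthetic data do and do not establish about real
sequencing experiments.

## The mapping model

Bulked-segregant analysis pools DNA from individuals sharing a recessive
phenotype so that allele frequencies near the causal locus diverge between
contrasting pools. At each variant position the SNP-index is the alternate
read fraction, alt/(ref+alt); it is undefined (and the position excluded)
when no reads align. The ΔSNP-index is defined here as

Δ = SNP-index(mutant bulk) − SNP-index(normal bulk),

so a region where the mutant bulk is fixed for the mutant allele and the
normal bulk carries none of it approaches +1, a region fixed for the normal
parent approaches −1, and shared regions sit at 0. (The subtraction order
is chosen to match this interpretation; the opposite convention merely
flips the sign of every plot.)

Before Δ is computed, positions are filtered on the mutant bulk's records:
the defaults drop a position when its SNP-index is below 0.3 **or** its
depth falls below 0.7× the bulk's median depth. A raw-depth cutoff of 0.7
reads is not meaningful, so the depth threshold is interpreted on the
median-normalized scale; a literal AND combination of the two criteria is
available via `FilterConfig(combine="and")`. The filter is applied to the
mutant bulk only, because mutant-specific sites legitimately have index ≈ 0
in the normal bulk and must not be discarded for it.

## Null confidence bands

Windowed Δ tracks (default 100 kb windows, 25 kb step on the synthetic
genome; both configurable — on a real genome Mb-scale windows are typical)
are compared against empirical two-sided quantile bands simulated under a
null of no causal locus, at levels 0.05 and 0.01. Two null models are
provided:

- **binomial** (default): each bulk's alternate count at a position is
  Binomial(observed depth, ½), the no-selection expectation for a bulk of
  segregants;
- **lineage**: for small pooled bulks (default 9 members), the bulk's true
  allele frequency is first resampled as Binomial(18, ½)/18 across its
  haplotypes, adding the haplotype-sampling variance a 9-line pool really
  has; this band is wider.

Band estimation and the observed track use the same windows and the same
depth profile, so the bands are conditional on the realized coverage.
Windows without positions are undefined and never called. Replicate count
defaults to 1000 for region calling and 10⁴ for calibration checks; the
Monte-Carlo seed is an explicit, required parameter everywhere.

Candidate regions are maximal runs of consecutive windows whose Δ exceeds
the upper 0.05 band, merging runs separated by at most one sub-threshold
window, ranked by peak windowed Δ. The exceedance rule is an implementer
definition: published peak intervals of this kind are often read off plots,
so the region boundaries here should be treated as reproducible
approximations of that practice, not a canonical algorithm.

## The synthetic experiment

`simulate_bulk_experiment` emulates the introgression design end to end
with these defaults, chosen once as a realistic scaled-down configuration:

| parameter | default | meaning |
|---|---|---|
| chromosomes | 2 × 500 kb | one causal chromosome, one unlinked |
| recurrent-parent SNV rate | 2×10⁻⁴ /bp | private natural variation per parent |
| donor variant rate | 10⁻³ per G/C site | EMS load plus donor line background, all G→A / C→T |
| lineages | 9, one per recurrent parent | the pooled mutant bulk |
| pedigree | BC₂ then 4 selfing rounds | BC₂F₅-like near-inbreds |
| crossovers | Poisson(2)/chromosome/meiosis | uniform breakpoints, no interference |
| depth | Poisson(30×) per position per bulk | with Binomial alternate sampling |
| sequencing error | 0 | configurable up to 5% |

Meioses are simulated at the segment level. Selection mimics phenotypic
screening: during backcrossing every transmitted gamete must carry the
donor causal allele; during selfing both gametes must, so lineages are
homozygous mutant at the causal position, and donor segments are retained
around it with a length that decays over meioses. The normal bulk is the
nine recurrent parents themselves, which places each parent's private SNVs
at frequency 1/9 there. Bulk allele frequencies are exact haplotype
arithmetic (carriers among 2 × members haplotypes), and read counts are
Poisson/Binomial on top of them; all draws are reproducible from the seed.

The mixed-allele scenario (`mixed_allele_bulk`) splits the nine members
across three different causal alleles of one locus in a 5:3:1 ratio. Because
members homozygous for one allele carry neither of the others, no single
variant can exceed bulk frequency 5/9 ≈ 0.56 — reproducing the known
failure mode of this analysis when a mutant bulk mixes alleles, with
per-allele read fractions converging to the lineage fractions as depth
grows.

What the generator does **not** model: read-level artifacts (mapping error,
base quality, indel realignment), linked natural structural variation,
segregation distortion, residual heterozygosity in the recurrent parents,
and genome-scale marker densities. Passing tests therefore demonstrate the
statistical logic of the method under its own assumptions — not robustness
to alignment pathology on a real genome.

## Consensus construction

Confident calls default to depth ≥ 10 and alternate fraction ≥ 0.9; both
are explicit parameters because "confident" is a policy, not a fact of the
data. Only SNVs are substituted into the reference — applying indels would
shift the coordinate system shared by all bulks — and any ref-base mismatch
rejects the whole operation with the offending position named, so a
consensus can never be built from stale coordinates (re-applying the same
calls to their own consensus fails for the same reason).

## Consequence prediction and ranking

Gene models are ordered CDS intervals with strand and phase; minus-strand
genes are evaluated on the reverse-complemented CDS so one codon routine
serves both strands, and this equivalence is enforced by a strand-mirror
test. Translation uses the standard nuclear codon table. SNVs are
classified synonymous/missense/nonsense by codon comparison; CDS indels are
frameshift unless their length change is a multiple of three.

Residue chemical-class labels are data-driven. Informal class vocabularies
overlap (valine is called both "nonpolar" and "hydrophobic" in practice),
so the default map assigns each residue an ordered tuple of classes and the
transition labeller prefers a class the two residues share — a conservative
substitution then reads "nonpolar → nonpolar" — falling back to each
residue's primary class otherwise. The map is user-overridable.

Candidate ranking inside a mapped region keeps variants fixed in the mutant
bulk (index ≥ 1.0 by default; 0.98/0.02 bounds are the suggested setting
when the error rate is nonzero), absent from the normal bulk, coding and
non-synonymous, and not present in the exclusion panel of resequenced
lines (a causal allele for a phenotype absent from every panel line cannot
be in the panel). Severity order — frameshift/nonsense, then
class-changing missense, then other missense — is a documented heuristic,
configurable, not a biological law.

## ARMS-PCR model

The in-silico PCR engine uses the minimal binding rule consistent with
tetra-primer ARMS behavior: a primer extends only if its 3′-terminal base
matches the template, and at most one internal mismatch (the deliberate one
placed at 3′−2) is tolerated. Product size is the inclusive span between
convergent bound primers. The packaged demo assay (233 bp control, 162 bp
mutant-A product, 124 bp wildtype-G product) is synthetic: the template and
primers are engineered so the engine emits those sizes, for illustration
and testing; they are not a reproduction of any published primer set.
Thermodynamics (Tm, dimers) are out of scope.

## Segregation statistics

The χ² goodness-of-fit uses Σ(obs−exp)²/exp with expected counts from the
hypothesized ratio and p from the χ² survival function at categories−1
degrees of freedom. No Yates continuity correction is applied by default —
the uncorrected statistic is the one that reproduces hand-checked values on
two-category 3:1 data — with the correction available as a flag. The
cosegregation check reports every individual whose marker genotype and
phenotype disagree under a recessive single-locus model, skipping and
counting rows with missing data.

## Problem sizes and determinism

Simulation-heavy checks run at deliberately scaled-down sizes chosen as the
package's own defaults: the recovery study uses 100 independent seeds of
the default experiment (~2k segregating sites each), band calibration uses
10⁴ replicates on a 200-position window, and backcross expectations use
250–500 replicate lineages. Every stochastic routine takes a seed or
`numpy.random.Generator`; identical seeds give identical outputs, and this
determinism is itself under test.

## Known limitations

- The region-calling rule and ranking heuristic are implementer
  definitions (see above); alternative rules can move region boundaries.
- The depth filter can occasionally discard the causal position itself at
  low coverage (Poisson fluctuation below 0.7× median); this mirrors the
  behavior of the filter it implements and shows up as rare ranking misses
  in the recovery study.
- Donor divergence is modelled entirely as G→A / C→T transitions; real
  donor lines also differ by transversions and indels.
- The binomial null band assumes F2-style segregation; for 9-line pooled
  bulks the lineage-resampling null is the better-calibrated choice and the
  default band is anti-conservative in that setting.
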