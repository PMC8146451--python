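# introbsa

Bulked-segregant SNP-index mapping for introgression-line mutant bulks.

`introbsa` is a tested, reusable implementation of the whole-genome
bulked-segregant analysis used to map recessive mutations — for example the
brown midrib (*bmr*) lignin mutants of sorghum — when the mutant "bulk" is a
pool of introgression lineages (BC<sub>n</sub>F<sub>m</sub> lines carrying
one donor allele in several recurrent-parent backgrounds) rather than a
classic F2 pool. It is aimed at plant geneticists and genomics analysts who
want to run, stress-test or teach this mapping strategy without sequencing
data: a synthetic-data module generates every input (parental genomes,
backcross lineages, pooled bulks, read counts, F2 populations) with the
statistical structure the analysis assumes.

## What it computes

For each position with reference/alternate read counts in two bulks:

- **SNP-index** = (alternate reads) / (reads aligned); ≈ 1 near a causal
  mutation in the mutant bulk, ≈ 0.5 at unlinked segregating sites.
- **ΔSNP-index** = SNP-index(mutant bulk) − SNP-index(normal bulk), so the
  causal region approaches +1.
- Positions with SNP-index < 0.3 or depth < 0.7× the bulk median are
  filtered before Δ calculation (both thresholds and the AND/OR semantics
  are configurable).
- Sliding-window Δ means are compared against **Monte-Carlo confidence
  bands** simulated under a null of no causal locus (binomial at allele
  frequency ½ per bulk, or a small-pool haplotype-resampling null); maximal
  runs of windows above the 0.05 band are called as candidate regions.
- Variants inside the top region are annotated against gene models
  (synonymous / missense / nonsense / frameshift, with residue
  chemical-class transitions such as "negative → positive"), screened
  against a resequenced-line variant panel, and ranked by consequence
  severity and bulk fixation (mutant index 1.0, normal index 0.0).

Companion modules cover the surrounding bench work in silico: consensus
construction by substituting confident SNV calls into a reference,
tetra-primer ARMS-PCR genotyping (allele-specific amplicon sizes, band →
genotype calls, F1-authenticity checks), indel size markers, and χ²
segregation tests with cosegregation reports.

## Worked example

```python
from introbsa import synthetic_data as sd
from introbsa import workflow as wf

exp = sd.simulate_bulk_experiment(seed=1)       # 9 lineages, 30x, 2 x 500 kb
res = wf.map_experiment(exp, seed=2, panel=wf.decoy_panel(exp, 5))

print("causal SNV:   ", exp.causal.chrom, exp.causal.pos,
      exp.causal.ref, ">", exp.causal.alt)
print("top region:   ", res.top_region.chrom,
      res.top_region.start, "-", res.top_region.end)
print("top candidate:", res.report.ranked[0].variant.pos,
      res.report.ranked[0].consequence.residue_change,
      res.report.ranked[0].class_transition)
```

prints

```
causal SNV:    chr1 250010 C > T
top region:    chr1 1 - 450000
top candidate: 250010 A2V hydrophobic → hydrophobic
```

The simulated experiment plants one EMS-style causal transition near the
middle of chr1; the windowed ΔSNP-index track exceeds the null band across
the linked region, and after panel exclusion the planted SNV is recovered
as the single fixed, coding, non-synonymous candidate — here a missense
change reported with its codon number and chemical-class transition.

A χ² segregation check on a simulated F2:

```python
from introbsa import segregation as sg
t = sg.phenotype_ratio_test(216, 69)            # non-brown, brown
print(f"chi2={t.chi_square:.3f} p={t.p_value:.3f}")
# chi2=0.095 p=0.758
```

There is also a thin CLI (`introbsa simulate | consensus | regions | arms |
segregation`); run `introbsa --help`.

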