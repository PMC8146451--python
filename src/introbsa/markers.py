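"""In-silico PCR for tetra-primer ARMS assays and indel size markers.

Tetra-primer ARMS-PCR converts a SNP into an amplicon-size polymorphism:
two outer primers give a control product from every template, while two
allele-specific inner primers terminate (3′) on the SNP from opposite
strands and each carries a deliberate mismatch near its 3′ end. A primer
extends only if its 3′-terminal base pairs with the template, and a single
internal mismatch (the deliberate one) is tolerated; the combination of the
3′-terminal SNP mismatch with the deliberate mismatch blocks the wrong
allele's inner primer. Genotypes are read off the resulting band pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Primer:
    """An oriented primer. ``orientation`` 'F' primers match the template
    plus strand; 'R' primers match the minus strand (their reverse
    complement appears in the template as written)."""

    name: str
    seq: str
    orientation: str

    def __post_init__(self):
        if self.orientation not in "FR":
            raise ValueError("orientation must be 'F' or 'R'")
        if len(self.seq) < 15:
            raise ValueError(f"primer {self.name} shorter than 15 nt")


@dataclass
class TetraPrimerSet:
    """A tetra-primer ARMS assay and its expected product sizes.

    ``allele_products`` maps each allele base to the expected
    allele-specific amplicon size; ``inner_alleles`` maps each inner primer
    name to the allele whose presence it reports.
    """

    outer_f: Primer
    outer_r: Primer
    inner_f: Primer
    inner_r: Primer
    control_size: int
    allele_products: dict[str, int]
    inner_alleles: dict[str, str]
    snp_desc: str = ""

    def __post_init__(self):
        sizes = list(self.allele_products.values())
        if len(set(sizes)) != len(sizes):
            raise ValueError("allele product sizes must differ")
        if any(s >= self.control_size for s in sizes):
            raise ValueError("control product must be the largest amplicon")

    @property
    def primers(self) -> list[Primer]:
        return [self.outer_f, self.outer_r, self.inner_f, self.inner_r]


def binding_sites(
    template: str, primer: Primer, max_internal_mismatch: int = 1
) -> list[int]:
    """0-based template start offsets where the primer can prime.

    Binding requires an exact match at the 3′-terminal base and at most
    ``max_internal_mismatch`` mismatches elsewhere (accommodating the
    deliberate ARMS mismatch).
    """
    probe = primer.seq if primer.orientation == "F" else revcomp(primer.seq)
    # for an R primer the 3' end sits at the start (lowest coordinate) of probe
    three_prime = len(probe) - 1 if primer.orientation == "F" else 0
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(probe.encode(), dtype=np.uint8)
    n, m = len(t), len(p)
    sites = []
    for i in range(n - m + 1):
        window = t[i:i + m]
        if window[three_prime] != p[three_prime]:
            continue
        if int((window != p).sum()) <= max_internal_mismatch:
            sites.append(i)
    return sites


def insilico_pcr(
    templates: str | Sequence[str],
    primers: Sequence[Primer],
    max_internal_mismatch: int = 1,
    max_product: int = 5000,
) -> list[int]:
    """Amplicon sizes from all convergent primer pairs over the template(s).

    A heterozygote is modelled as two template strings; products are pooled
    across templates (sizes deduplicated and sorted, as on a gel).
    """
    if isinstance(templates, str):
        templates = [templates]
    sizes: set[int] = set()
    for template in templates:
        fwd_sites = [
            (p, i) for p in primers if p.orientation == "F"
            for i in binding_sites(template, p, max_internal_mismatch)
        ]
        rev_sites = [
            (p, i) for p in primers if p.orientation == "R"
            for i in binding_sites(template, p, max_internal_mismatch)
        ]
        for pf, i in fwd_sites:
            for pr, j in rev_sites:
                end = j + len(pr.seq)  # exclusive plus-strand end of product
                if i < end and end - i <= max_product:
                    sizes.add(end - i)
    return sorted(sizes)


# ---------------------------------------------------------------------------
# band-pattern interpretation
# ---------------------------------------------------------------------------

@dataclass
class BandCall:
    genotype: str  # "mut/mut", "WT/WT", "het" or "invalid"
    matched: dict[str, int] = field(default_factory=dict)
    notes: str = ""


def _match_band(size: int, observed: Iterable[int], tol: int) -> int | None:
    hits = [b for b in observed if abs(b - size) <= tol]
    return hits[0] if hits else None


def genotype_from_bands(
    bands: Iterable[int],
    assay: TetraPrimerSet,
    mutant_allele: str,
    tol: int = 5,
) -> BandCall:
    """Call a genotype from observed amplicon sizes (gel tolerance ±tol bp).

    Control + mutant-allele product → mut/mut; control + wildtype product →
    WT/WT; all three → het. A missing control band, or bands not accounted
    for by the assay, give an invalid call.
    """
    bands = sorted(set(int(b) for b in bands))
    matched: dict[str, int] = {}
    control = _match_band(assay.control_size, bands, tol)
    if control is None:
        return BandCall("invalid", notes="control band missing")
    matched["control"] = control
    present = {}
    for allele, size in assay.allele_products.items():
        hit = _match_band(size, bands, tol)
        if hit is not None:
            present[allele] = hit
            matched[allele] = hit
    accounted = set(matched.values())
    extras = [b for b in bands if b not in accounted]
    if extras:
        return BandCall("invalid", matched, notes=f"unrecognized bands {extras}")
    wt_alleles = [a for a in assay.allele_products if a != mutant_allele]
    has_mut = mutant_allele in present
    has_wt = any(a in present for a in wt_alleles)
    if has_mut and has_wt:
        return BandCall("het", matched)
    if has_mut:
        return BandCall("mut/mut", matched)
    if has_wt:
        return BandCall("WT/WT", matched)
    return BandCall("invalid", matched, notes="no allele-specific band")


def f1_authenticity(
    patterns: Sequence[Iterable[int]],
    assay: TetraPrimerSet,
    mutant_allele: str,
    tol: int = 5,
) -> list[str]:
    """Classify progeny of a mutant × mutant allelism-test cross.

    When the second parent's allele matches the wildtype base at the assayed
    SNP, a true F1 is heterozygous there (three bands, like an F2
    heterozygote) while progeny of accidental self-pollination of the
    assayed mutant show only the control and mutant-allele products.
    """
    calls = []
    for bands in patterns:
        c = genotype_from_bands(bands, assay, mutant_allele, tol)
        if c.genotype == "het":
            calls.append("true_F1")
        elif c.genotype == "mut/mut":
            calls.append("self")
        else:
            calls.append("invalid")
    return calls


# ---------------------------------------------------------------------------
# indel markers
# ---------------------------------------------------------------------------

def indel_marker_sizes(
    template_a: str,
    template_b: str,
    forward: Primer,
    reverse: Primer,
    max_internal_mismatch: int = 0,
) -> tuple[int | None, int | None, int | None]:
    """Amplicon sizes on two templates flanking an indel, and their difference.

    Returns (size_a, size_b, size_a − size_b); a template without a product
    yields None.
    """
    def one(template):
        sizes = insilico_pcr(template, [forward, reverse], max_internal_mismatch)
        return sizes[0] if sizes else None

    a, b = one(template_a), one(template_b)
    diff = a - b if a is not None and b is not None else None
    return a, b, diff


# ---------------------------------------------------------------------------
# packaged demo assays (synthetic, illustrative)
# ---------------------------------------------------------------------------

def design_tetra_primers(
    template: str,
    snp_offset: int,
    alleles: tuple[str, str],
    control_size: int,
    product_sizes: tuple[int, int],
    outer_len: int = 20,
    inner_len: int = 27,
) -> TetraPrimerSet:
    """Place tetra primers on a template so the assay emits the given sizes.

    ``snp_offset`` is the 0-based template offset of the SNP; ``alleles`` is
    (allele detected by the inner F primer, allele detected by the inner R
    primer); ``product_sizes`` the matching allele-product sizes. Inner
    primers end on the SNP with the deliberate mismatch at the 3′−2
    position.
    """
    allele_f, allele_r = alleles
    size_f, size_r = product_sizes
    amp_start = snp_offset - (size_r - inner_len)  # outer-F 5' offset
    amp_end = amp_start + control_size             # exclusive
    if amp_start < 0 or amp_end > len(template):
        raise ValueError("template too short for the requested amplicon layout")
    if amp_start + (control_size - size_f) + inner_len - 1 != snp_offset:
        raise ValueError(
            "inconsistent sizes: inner-F must end on the SNP "
            f"(need size_f + size_r == control + {2 * inner_len - 1})"
        )

    outer_f = Primer("outer-F", template[amp_start:amp_start + outer_len], "F")
    outer_r = Primer("outer-R", revcomp(template[amp_end - outer_len:amp_end]), "R")

    def mismatched(base: str) -> str:
        return {"A": "C", "C": "A", "G": "T", "T": "G"}[base]

    # inner F: plus-strand sequence ending on the SNP, 3' base = allele_f
    f_start = snp_offset - inner_len + 1
    f_seq = list(template[f_start:snp_offset + 1])
    f_seq[-1] = allele_f
    f_seq[-3] = mismatched(f_seq[-3])
    inner_f = Primer(f"inner({allele_f})-F", "".join(f_seq), "F")

    # inner R: minus-strand primer whose 3' base pairs with the SNP
    r_plus = list(template[snp_offset:snp_offset + inner_len])
    r_plus[0] = allele_r
    r_plus[2] = mismatched(r_plus[2])
    inner_r = Primer(f"inner({allele_r})-R", revcomp("".join(r_plus)), "R")

    return TetraPrimerSet(
        outer_f=outer_f, outer_r=outer_r, inner_f=inner_f, inner_r=inner_r,
        control_size=control_size,
        allele_products={allele_f: size_f, allele_r: size_r},
        inner_alleles={inner_f.name: allele_f, inner_r.name: allele_r},
    )


def demo_tetra_assay(seed: int = 20) -> tuple[TetraPrimerSet, dict[str, str]]:
    """Synthetic tetra-primer assay emitting a 233 bp control, a 162 bp
    mutant (A) product and a 124 bp wildtype (G) product, mirroring a
    G→A point-mutation genotyping assay. Returns the assay and the two
    homozygous template sequences keyed by allele ('A' mutant, 'G' wildtype).
    """
    rng = np.random.default_rng(seed)
    length = 320
    while True:
        template = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
        snp_offset = 150  # leaves >= 124-27 upstream and 162 downstream room
        t_g = template[:snp_offset] + "G" + template[snp_offset + 1:]
        t_a = template[:snp_offset] + "A" + template[snp_offset + 1:]
        try:
            assay = design_tetra_primers(
                t_g, snp_offset, alleles=("A", "G"),
                control_size=233, product_sizes=(162, 124),
            )
        except ValueError:
            continue
        assay.snp_desc = "G>A at template offset 150 (synthetic demo)"
        # accept only templates without spurious primer sites
        if insilico_pcr([t_a, t_g], assay.primers) == sorted({233, 162, 124}):
            return assay, {"A": t_a, "G": t_g}


def demo_indel_templates(kind: str = "retrotransposon", seed: int = 7):
    """Synthetic indel-marker templates: a 348 bp insertion ('retrotransposon')
    or an 8 bp SSR contraction ((TATC)10 vs (TATC)8). Returns (template with
    the longer allele, template with the shorter allele, forward, reverse)."""
    rng = np.random.default_rng(seed)

    def rand(n):
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])

    left, right = rand(80), rand(80)
    forward = Primer("ind-F", left[10:31], "F")
    reverse = Primer("ind-R", revcomp(right[50:71]), "R")
    if kind == "retrotransposon":
        insert = rand(348)
        spacer = rand(40)
        longer = left + spacer[:20] + insert + spacer[20:] + right
        shorter = left + spacer + right
    elif kind == "ssr":
        longer = left + "TATC" * 10 + right
        shorter = left + "TATC" * 8 + right
    else:
        raise ValueError("kind must be 'retrotransposon' or 'ssr'")
    return longer, shorter, forward, reverse
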