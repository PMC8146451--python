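"""Variant consequence prediction, residue-class annotation, panel exclusion
and causal-candidate ranking.

Gene models are minimal CDS-interval structures (1-based, inclusive); minus
strand models are evaluated on the reverse-complemented CDS so the same
codon logic serves both strands. Translation uses the standard nuclear
codon table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .synthetic_data import VariantSite

CONSEQUENCES = (
    "synonymous", "missense", "nonsense", "frameshift", "inframe_indel", "non_coding",
)

#: Consequence severity used for candidate ranking: truncating changes first,
#: then missense that alters the residue's chemical class, then other
#: missense. Synonymous/non-coding variants are not ranked at all.
SEVERITY = {"frameshift": 3, "nonsense": 3, "missense_class_change": 2, "missense": 1}


@dataclass
class GeneModel:
    """A protein-coding gene as ordered CDS intervals on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]]  # 1-based inclusive, sorted by start
    phase: int = 0  # phase of the first (5'-most) CDS piece

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(cds, cds[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
        for s, e in cds:
            if s > e or s < 1:
                raise ValueError(f"{self.gene_id}: malformed CDS interval ({s},{e})")
        self.cds = cds

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_phases(self) -> list[int]:
        """GFF3 phase column for each CDS interval in genomic order."""
        order = self.cds if self.strand == "+" else self.cds[::-1]
        phases, ph = {}, self.phase
        for s, e in order:
            phases[(s, e)] = ph
            ph = (3 - ((e - s + 1 - ph) % 3)) % 3
        return [phases[iv] for iv in self.cds]

    def cds_sequence(self, reference: Mapping[str, str]) -> str:
        """Coding-strand CDS sequence (reverse-complemented for −)."""
        seq = "".join(reference[self.chrom][s - 1:e] for s, e in self.cds)
        return str(Seq(seq).reverse_complement()) if self.strand == "-" else seq


@dataclass(frozen=True)
class CdsHit:
    """Location of a genomic position within a gene's coding sequence."""

    offset: int       # 1-based offset into the coding-strand CDS
    codon_index: int  # 1-based residue number
    codon_pos: int    # 0, 1 or 2 within the codon


@dataclass(frozen=True)
class ConsequenceCall:
    variant: VariantSite
    gene_id: str
    consequence: str
    codon_change: str | None = None       # e.g. "GGA>GAA"
    residue_change: str | None = None     # e.g. "G240E", "Q132stop"
    residue_position: int | None = None

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")


def map_to_cds(variant: VariantSite, gene: GeneModel) -> CdsHit | None:
    """CDS offset and codon context of a variant, or None if non-coding.

    For minus-strand genes the offset is computed on the reverse-complemented
    CDS, mirroring the genomic coordinate.
    """
    if variant.chrom != gene.chrom:
        return None
    offset = 0  # 0-based genomic offset into concatenated plus-strand CDS
    hit = None
    for s, e in gene.cds:
        if s <= variant.pos <= e:
            hit = offset + (variant.pos - s)
            break
        offset += e - s + 1
    if hit is None:
        return None
    if gene.strand == "-":
        hit = gene.cds_length - 1 - hit
    hit -= gene.phase
    if hit < 0:
        return None  # within the incomplete leading codon
    return CdsHit(offset=hit + 1, codon_index=hit // 3 + 1, codon_pos=hit % 3)


class ReferenceMismatchError(ValueError):
    pass


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def predict_consequence(
    variant: VariantSite, gene: GeneModel, reference: Mapping[str, str]
) -> ConsequenceCall:
    """Classify a variant against one gene model.

    SNVs compare translated codons (synonymous / missense / nonsense); CDS
    indels are frameshift when the length change is not a multiple of three,
    otherwise in-frame.
    """
    ref_base = reference[variant.chrom][variant.pos - 1:variant.pos - 1 + len(variant.ref)]
    if ref_base != variant.ref:
        raise ReferenceMismatchError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"expected {variant.ref}, found {ref_base}"
        )

    hit = map_to_cds(variant, gene)
    if hit is None:
        return ConsequenceCall(variant, gene.gene_id, "non_coding")

    if not variant.is_snv:
        delta = len(variant.alt) - len(variant.ref)
        kind = "inframe_indel" if delta % 3 == 0 else "frameshift"
        return ConsequenceCall(
            variant, gene.gene_id, kind, residue_position=hit.codon_index
        )

    cds = gene.cds_sequence(reference)
    alt = variant.alt if gene.strand == "+" else variant.alt.translate(_COMPLEMENT)
    codon_from = cds[gene.phase:][(hit.codon_index - 1) * 3:(hit.codon_index - 1) * 3 + 3]
    codon_to = codon_from[:hit.codon_pos] + alt + codon_from[hit.codon_pos + 1:]
    aa_from = str(Seq(codon_from).translate())
    aa_to = str(Seq(codon_to).translate())

    if aa_from == aa_to:
        kind = "synonymous"
    elif aa_to == "*":
        kind = "nonsense"
    else:
        kind = "missense"
    notation = f"{aa_from}{hit.codon_index}{'stop' if aa_to == '*' else aa_to}"
    return ConsequenceCall(
        variant, gene.gene_id, kind,
        codon_change=f"{codon_from}>{codon_to}",
        residue_change=notation,
        residue_position=hit.codon_index,
    )


# ---------------------------------------------------------------------------
# residue chemical classes
# ---------------------------------------------------------------------------

#: Residue → ordered tuple of chemical-class labels. Several residues
#: legitimately belong to more than one informal class (valine is both
#: nonpolar and hydrophobic); the transition labeller prefers a class the
#: two residues share, which is how these overlapping labels are used in
#: practice when describing conservative substitutions.
DEFAULT_RESIDUE_CLASSES: dict[str, tuple[str, ...]] = {
    "A": ("hydrophobic", "nonpolar"),
    "V": ("nonpolar", "hydrophobic"),
    "L": ("nonpolar", "hydrophobic"),
    "I": ("nonpolar", "hydrophobic"),
    "M": ("nonpolar", "hydrophobic"),
    "F": ("nonpolar", "hydrophobic"),
    "W": ("nonpolar", "hydrophobic"),
    "P": ("nonpolar",),
    "G": ("nonpolar",),
    "C": ("polar",),
    "S": ("polar",),
    "T": ("polar",),
    "Y": ("polar",),
    "N": ("polar",),
    "Q": ("polar",),
    "D": ("negative",),
    "E": ("negative",),
    "K": ("positive",),
    "R": ("positive",),
    "H": ("positive",),
}


def classify_residue_change(
    aa_from: str,
    aa_to: str,
    class_map: Mapping[str, tuple[str, ...]] | None = None,
) -> str:
    """Label an amino-acid substitution as "class(from) → class(to)".

    If the two residues share a class, both are labelled with the first
    shared class in the source residue's order (a conservative substitution
    reads e.g. "nonpolar → nonpolar"); otherwise each residue's primary
    class is used.
    """
    classes = DEFAULT_RESIDUE_CLASSES if class_map is None else class_map
    for aa in (aa_from, aa_to):
        if aa not in classes:
            raise ValueError(f"unknown residue {aa!r}")
    from_classes, to_classes = classes[aa_from], classes[aa_to]
    shared = next((c for c in from_classes if c in to_classes), None)
    if shared is not None:
        return f"{shared} → {shared}"
    return f"{from_classes[0]} → {to_classes[0]}"


# ---------------------------------------------------------------------------
# panel exclusion and ranking
# ---------------------------------------------------------------------------

def panel_exclude(
    candidates: Iterable[VariantSite],
    panel: set[tuple[str, int, str]],
) -> list[VariantSite]:
    """Drop candidates present in a resequenced-line variant panel.

    A causal allele for a phenotype absent from every panel line cannot be in
    the panel, so shared variants are background polymorphism.
    """
    return [v for v in candidates if (v.chrom, v.pos, v.alt) not in panel]


@dataclass
class RankedCandidate:
    variant: VariantSite
    consequence: ConsequenceCall
    index_mut: float
    index_normal: float
    class_transition: str | None
    severity: int


@dataclass
class CandidateReport:
    ranked: list[RankedCandidate]
    filtered_out: dict[str, list[VariantSite]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": rc.variant.chrom,
                "pos": rc.variant.pos,
                "ref": rc.variant.ref,
                "alt": rc.variant.alt,
                "gene": rc.consequence.gene_id,
                "consequence": rc.consequence.consequence,
                "residue_change": rc.consequence.residue_change,
                "class_transition": rc.class_transition,
                "index_mut": rc.index_mut,
                "index_normal": rc.index_normal,
            }
            for rc in self.ranked
        ]
        return pd.DataFrame(rows)


def rank_candidates(
    variants: Sequence[VariantSite],
    indices: Mapping[tuple[str, int, str, str], tuple[float, float]],
    consequences: Mapping[tuple[str, int, str, str], ConsequenceCall],
    panel: set[tuple[str, int, str]] = frozenset(),
    min_index_mut: float = 1.0,
    max_index_normal: float = 0.0,
    class_map: Mapping[str, tuple[str, ...]] | None = None,
) -> CandidateReport:
    """Filter and order candidate causal variants within a mapped region.

    Keeps variants fixed in the mutant bulk (index ≥ ``min_index_mut``),
    absent from the normal bulk (index ≤ ``max_index_normal``), with a coding
    non-synonymous consequence, and not present in the panel. Orders by
    consequence severity (truncating > class-changing missense > missense),
    then mutant index. ``indices`` maps variant key → (index_mut,
    index_normal).
    """
    report = CandidateReport(ranked=[], filtered_out={
        "index": [], "panel": [], "consequence": [],
    })
    for v in variants:
        idx_mut, idx_norm = indices[v.key]
        if not (idx_mut >= min_index_mut and idx_norm <= max_index_normal):
            report.filtered_out["index"].append(v)
            continue
        if (v.chrom, v.pos, v.alt) in panel:
            report.filtered_out["panel"].append(v)
            continue
        call = consequences.get(v.key)
        if call is None or call.consequence in ("non_coding", "synonymous", "inframe_indel"):
            report.filtered_out["consequence"].append(v)
            continue
        transition = None
        severity_key = call.consequence
        if call.consequence == "missense":
            aa_from, aa_to = call.residue_change[0], call.residue_change[-1]
            transition = classify_residue_change(aa_from, aa_to, class_map)
            left, right = (part.strip() for part in transition.split("→"))
            if left != right:
                severity_key = "missense_class_change"
        report.ranked.append(
            RankedCandidate(
                variant=v, consequence=call, index_mut=idx_mut,
                index_normal=idx_norm, class_transition=transition,
                severity=SEVERITY[severity_key],
            )
        )
    report.ranked.sort(key=lambda rc: (-rc.severity, -rc.index_mut,
                                       rc.variant.chrom, rc.variant.pos))
    return report
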