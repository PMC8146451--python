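"""Synthetic introgression-bulk data generation.

Emulates the experimental design behind bulked-segregant mapping of a
recessive EMS-induced mutation: a mutagenized donor line carrying G→A / C→T
transitions (one designated causal) is backcrossed into several recurrent
parents with phenotypic selection, the resulting lineages are pooled into a
mutant bulk, the recurrent parents themselves form the normal bulk, and both
bulks are "sequenced" by Poisson read depth with binomial alternate-read
sampling.

Coordinates are 1-based throughout; reference bases are stored on the
forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
#: EMS mutagenesis produces almost exclusively these transitions.
EMS_TRANSITIONS = {"G": "A", "C": "T"}

DONOR, RECURRENT = 1, 0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSite:
    """A single variant relative to the shared base reference."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    label: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if len(self.ref) == 1 and len(self.alt) == 1:
            if self.ref not in BASES or self.alt not in BASES:
                raise ValueError(
                    f"SNV bases must be in {BASES}: {self.ref}>{self.alt}"
                )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ParentGenome:
    """A parental haplotype set: base reference plus private variants.

    Parents are fully inbred, so a single variant list describes both
    haplotypes.
    """

    id: str
    chromosomes: list[tuple[str, int]]
    variants: list[VariantSite] = field(default_factory=list)

    def __post_init__(self):
        lengths = dict(self.chromosomes)
        seen: set[tuple[str, int]] = set()
        for v in self.variants:
            if v.chrom not in lengths:
                raise ValueError(f"{self.id}: unknown chromosome {v.chrom}")
            if not 1 <= v.pos <= lengths[v.chrom]:
                raise ValueError(f"{self.id}: {v.chrom}:{v.pos} outside chromosome")
            if (v.chrom, v.pos) in seen:
                raise ValueError(f"{self.id}: duplicate variant at {v.chrom}:{v.pos}")
            seen.add((v.chrom, v.pos))

    def carries(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}


@dataclass
class ParentSet:
    """Base reference plus the recurrent parents and the mutagenized donor."""

    reference: dict[str, str]
    recurrents: list[ParentGenome]
    donor: ParentGenome
    causal: VariantSite

    @property
    def chromosomes(self) -> list[tuple[str, int]]:
        return [(name, len(seq)) for name, seq in self.reference.items()]


# A haplotype is, per chromosome, a pair of parallel arrays: segment end
# positions (1-based, inclusive, last == chromosome length) and segment
# origins (DONOR/RECURRENT).
Haplotype = dict[str, tuple[np.ndarray, np.ndarray]]


@dataclass
class Lineage:
    """A mosaic introgression line produced by backcrossing with selection."""

    id: str
    donor_id: str
    recurrent_id: str
    n_backcross: int
    n_self: int
    haplotypes: tuple[Haplotype, Haplotype]
    causal: VariantSite

    def origin_at(self, chrom: str, pos: int) -> tuple[int, int]:
        return tuple(_origin_at(h, chrom, pos) for h in self.haplotypes)

    def is_causal_homozygous(self) -> bool:
        return self.origin_at(self.causal.chrom, self.causal.pos) == (DONOR, DONOR)

    def donor_fraction(self, chrom: str | None = None) -> float:
        """Genome-wide (or per-chromosome) fraction of donor-derived sequence."""
        total = donor = 0.0
        for hap in self.haplotypes:
            for name, (ends, origins) in hap.items():
                if chrom is not None and name != chrom:
                    continue
                starts = np.concatenate([[0], ends[:-1]])
                seg_len = ends - starts
                total += float(ends[-1])
                donor += float(seg_len[origins == DONOR].sum())
        return donor / total


@dataclass(frozen=True)
class F2Individual:
    """One F2 plant: genotype at the focal locus and midrib phenotype."""

    genotype: str  # "mut/mut", "WT/mut" or "WT/WT"
    phenotype: str  # "brown" or "normal"

    def __post_init__(self):
        if self.genotype not in {"mut/mut", "WT/mut", "WT/WT"}:
            raise ValueError(f"bad genotype {self.genotype!r}")
        expected = "brown" if self.genotype == "mut/mut" else "normal"
        if self.phenotype != expected:
            raise ValueError(
                "phenotype must be recessive with full penetrance: "
                f"{self.genotype} -> {expected}, got {self.phenotype}"
            )


@dataclass
class ReadCountTable:
    """Per-position, per-bulk reference/alternate read counts.

    ``df`` columns: chrom, pos, ref, alt, then ``{bulk}_ref`` / ``{bulk}_alt``
    for each bulk in ``bulks``.
    """

    df: pd.DataFrame
    bulks: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for b in self.bulks:
            for col in (f"{b}_ref", f"{b}_alt"):
                if col not in self.df.columns:
                    raise ValueError(f"missing column {col}")
                vals = self.df[col].to_numpy()
                if (vals < 0).any():
                    raise ValueError(f"negative counts in {col}")

    def depth(self, bulk: str) -> np.ndarray:
        return (self.df[f"{bulk}_ref"] + self.df[f"{bulk}_alt"]).to_numpy()


# ---------------------------------------------------------------------------
# parent construction
# ---------------------------------------------------------------------------

def random_reference(chromosomes: Sequence[tuple[str, int]],
                     rng: np.random.Generator) -> dict[str, str]:
    """Uniform-composition base reference for the given chromosome layout."""
    ref = {}
    for name, length in chromosomes:
        if length <= 0:
            raise ValueError(f"zero/negative length chromosome {name}")
        ref[name] = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
    return ref


def _bernoulli_positions(length: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """1-based positions of per-site Bernoulli(rate) successes."""
    return np.flatnonzero(rng.random(length) < rate) + 1


def build_parents(
    n_recurrent: int,
    chromosomes: Sequence[tuple[str, int]],
    snp_rate: float,
    seed: int | np.random.Generator,
    causal_chrom: str | None = None,
    causal_pos: int | None = None,
    donor_snp_rate: float | None = None,
) -> ParentSet:
    """Create the base reference, ``n_recurrent`` recurrent parents and one
    EMS-mutagenized donor.

    Each recurrent parent carries private SNVs at per-site rate ``snp_rate``
    (any substitution). The donor carries G→A / C→T transitions at rate
    ``donor_snp_rate`` (default: ``snp_rate``) per G/C site, including one
    designated causal SNV near the middle of the first chromosome (or at
    ``causal_chrom:causal_pos``). The donor's divergence bundles its EMS
    load with its line background, modelled uniformly as transitions.
    """
    if donor_snp_rate is None:
        donor_snp_rate = snp_rate
    if not (0 <= snp_rate <= 0.1 and 0 <= donor_snp_rate <= 0.1):
        raise ValueError(f"snp rates must be in [0, 0.1]")
    if n_recurrent < 1:
        raise ValueError("need at least one recurrent parent")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chromosomes = list(chromosomes)
    for name, length in chromosomes:
        if length < 1:
            raise ValueError(f"zero-length chromosome {name}")

    reference = random_reference(chromosomes, rng)

    # donor: EMS transitions at G/C sites, plus the designated causal SNV
    causal = _pick_causal(reference, chromosomes, causal_chrom, causal_pos)
    donor_variants = [causal]
    taken = {(causal.chrom, causal.pos)}
    for name, length in chromosomes:
        seq = np.frombuffer(reference[name].encode(), dtype="S1")
        for pos in _bernoulli_positions(length, donor_snp_rate, rng):
            base = seq[pos - 1].decode()
            if base not in EMS_TRANSITIONS or (name, int(pos)) in taken:
                continue
            donor_variants.append(
                VariantSite(name, int(pos), base, EMS_TRANSITIONS[base])
            )
            taken.add((name, int(pos)))
    donor = ParentGenome("donor", chromosomes, donor_variants)

    recurrents = []
    for i in range(n_recurrent):
        variants = []
        for name, length in chromosomes:
            for pos in _bernoulli_positions(length, snp_rate, rng):
                if (name, int(pos)) in taken:
                    continue  # keep the site catalog biallelic
                base = reference[name][pos - 1]
                alt = BASES[(BASES.index(base) + int(rng.integers(1, 4))) % 4]
                variants.append(VariantSite(name, int(pos), base, alt))
        recurrents.append(ParentGenome(f"parent{i + 1}", chromosomes, variants))

    return ParentSet(reference, recurrents, donor, causal)


def _pick_causal(reference, chromosomes, chrom, pos) -> VariantSite:
    if chrom is None:
        chrom = chromosomes[0][0]
    seq = reference[chrom]
    if pos is None:
        # middle-most G/C preceded by a G, so a gene model placed over it
        # yields a Gly->Glu/Asp missense (GGx -> GAx) like a classic EMS hit
        mid = len(seq) // 2
        candidates = [
            i + 1
            for i in range(max(1, mid - len(seq) // 4), min(len(seq), mid + len(seq) // 4))
            if seq[i] in EMS_TRANSITIONS and seq[i - 1] == "G"
        ]
        if not candidates:  # pragma: no cover - tiny degenerate references
            candidates = [i + 1 for i, b in enumerate(seq) if b in EMS_TRANSITIONS]
        pos = min(candidates, key=lambda p: abs(p - mid))
    base = seq[pos - 1]
    if base not in EMS_TRANSITIONS:
        raise ValueError(f"causal site {chrom}:{pos} is {base}, not G/C")
    return VariantSite(chrom, int(pos), base, EMS_TRANSITIONS[base], label="causal")


# ---------------------------------------------------------------------------
# meiosis and backcross simulation
# ---------------------------------------------------------------------------

def pure_haplotype(chromosomes: Sequence[tuple[str, int]], origin: int) -> Haplotype:
    return {
        name: (np.array([length], dtype=np.int64), np.array([origin], dtype=np.int8))
        for name, length in chromosomes
    }


def _origin_at(hap: Haplotype, chrom: str, pos: int) -> int:
    ends, origins = hap[chrom]
    return int(origins[np.searchsorted(ends, pos)])


def _slice_hap(ends, origins, lo, hi):
    """Segments of (ends, origins) covering 1-based interval (lo, hi]."""
    i = np.searchsorted(ends, lo + 1)
    j = np.searchsorted(ends, hi)
    sub_ends = np.append(ends[i:j], hi).astype(np.int64)
    sub_orig = np.append(origins[i:j], origins[min(j, len(origins) - 1)]).astype(np.int8)
    return sub_ends, sub_orig


def _merge_adjacent(ends, origins):
    if len(ends) <= 1:
        return ends, origins
    keep = np.append(origins[1:] != origins[:-1], True)
    return ends[keep], origins[keep]


def meiosis(hap_a: Haplotype, hap_b: Haplotype, rng: np.random.Generator,
            crossover_rate: float = 2.0) -> Haplotype:
    """One gamete from a diploid (hap_a, hap_b).

    Crossover count per chromosome is Poisson(``crossover_rate``) with
    uniform breakpoints and no interference; the starting haplotype is chosen
    at random.
    """
    gamete: Haplotype = {}
    for chrom in hap_a:
        length = int(hap_a[chrom][0][-1])
        n_co = rng.poisson(crossover_rate)
        breaks = np.sort(rng.integers(1, length, size=n_co)) if n_co else np.array([], dtype=np.int64)
        bounds = np.concatenate([[0], breaks, [length]]).astype(np.int64)
        current = int(rng.integers(0, 2))
        ends_parts, orig_parts = [], []
        pair = (hap_a[chrom], hap_b[chrom])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi > lo:
                e, o = _slice_hap(*pair[current], int(lo), int(hi))
                ends_parts.append(e)
                orig_parts.append(o)
            current ^= 1
        ends = np.concatenate(ends_parts)
        origins = np.concatenate(orig_parts)
        gamete[chrom] = _merge_adjacent(ends, origins)
    return gamete


def simulate_lineage(
    donor: ParentGenome,
    recurrent: ParentGenome,
    n_backcross: int,
    n_self: int,
    causal: VariantSite,
    crossover_rate: float = 2.0,
    seed: int | np.random.Generator = 0,
    max_tries: int = 10_000,
) -> Lineage:
    """Simulate one BC_nF_m introgression lineage under phenotypic selection.

    During backcrossing every transmitted gamete must carry the donor causal
    allele (heterozygote selection); during selfing both gametes must, so the
    returned lineage is homozygous donor at the causal position.
    """
    if n_backcross < 0 or n_self < 1:
        raise ValueError("need n_backcross >= 0 and n_self >= 1")
    if causal.chrom not in dict(donor.chromosomes):
        raise ValueError(f"causal position {causal.chrom}:{causal.pos} outside genome")
    if not 1 <= causal.pos <= dict(donor.chromosomes)[causal.chrom]:
        raise ValueError(f"causal position {causal.chrom}:{causal.pos} outside genome")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    chromosomes = donor.chromosomes
    recurrent_hap = pure_haplotype(chromosomes, RECURRENT)
    individual = (pure_haplotype(chromosomes, DONOR), recurrent_hap)  # F1

    def selected_gamete(ind):
        for _ in range(max_tries):
            g = meiosis(ind[0], ind[1], rng, crossover_rate)
            if _origin_at(g, causal.chrom, causal.pos) == DONOR:
                return g
        raise RuntimeError("selection failed to find a causal-carrying gamete")

    for _ in range(n_backcross):
        individual = (selected_gamete(individual), recurrent_hap)
    for _ in range(n_self):
        individual = (selected_gamete(individual), selected_gamete(individual))

    return Lineage(
        id=f"({donor.id} x {recurrent.id})BC{n_backcross}F{n_self + 1}",
        donor_id=donor.id,
        recurrent_id=recurrent.id,
        n_backcross=n_backcross,
        n_self=n_self,
        haplotypes=individual,
        causal=causal,
    )


def parent_as_lineage(parent: ParentGenome, causal: VariantSite) -> Lineage:
    """Wrap a pure recurrent parent as a trivial all-recurrent lineage, so the
    normal bulk (the recurrent parents themselves) shares the bulk machinery."""
    hap = pure_haplotype(parent.chromosomes, RECURRENT)
    return Lineage(
        id=parent.id,
        donor_id="",
        recurrent_id=parent.id,
        n_backcross=0,
        n_self=1,
        haplotypes=(hap, {k: (v[0].copy(), v[1].copy()) for k, v in hap.items()}),
        causal=causal,
    )


# ---------------------------------------------------------------------------
# bulks
# ---------------------------------------------------------------------------

def variant_catalog(genomes: Iterable[ParentGenome]) -> pd.DataFrame:
    """Union of variant sites across genomes, sorted by (chrom, pos)."""
    rows = {}
    for g in genomes:
        for v in g.variants:
            rows.setdefault(v.key, v.label)
    df = pd.DataFrame(
        [(c, p, r, a, rows[(c, p, r, a)]) for (c, p, r, a) in rows],
        columns=["chrom", "pos", "ref", "alt", "label"],
    )
    return df.sort_values(["chrom", "pos", "alt"], ignore_index=True)


def assemble_bulk(
    lineages: Sequence[Lineage],
    genomes_by_id: Mapping[str, ParentGenome],
    catalog: pd.DataFrame,
    role: str = "mutant",
) -> pd.DataFrame:
    """True bulk alternate-allele frequency at every catalog position.

    The frequency is exact haplotype arithmetic: the number of haplotypes
    (2 per member) whose parent-of-origin at the position carries the variant,
    divided by 2 × members.
    """
    if len(lineages) < 1:
        raise ValueError("a bulk needs at least one member lineage")
    chrom_sets = {tuple(sorted(h.keys())) for ln in lineages for h in ln.haplotypes}
    if len(chrom_sets) != 1:
        raise ValueError("lineages have inconsistent chromosome sets")

    n_hap = 2 * len(lineages)
    counts = np.zeros(len(catalog), dtype=np.int64)
    for chrom, idx in catalog.groupby("chrom").groups.items():
        idx = np.asarray(idx)
        pos = catalog.loc[idx, "pos"].to_numpy()
        keys = list(zip(
            catalog.loc[idx, "chrom"],
            catalog.loc[idx, "pos"],
            catalog.loc[idx, "ref"],
            catalog.loc[idx, "alt"],
        ))
        for ln in lineages:
            donor_carry = _carry_mask(genomes_by_id.get(ln.donor_id), keys)
            rec_carry = _carry_mask(genomes_by_id.get(ln.recurrent_id), keys)
            for hap in ln.haplotypes:
                ends, origins = hap[chrom]
                origin = origins[np.searchsorted(ends, pos)]
                counts[idx] += np.where(origin == DONOR, donor_carry, rec_carry)

    out = catalog.copy()
    out["freq"] = counts / n_hap
    out["role"] = role
    return out


def _carry_mask(genome: ParentGenome | None, keys) -> np.ndarray:
    if genome is None:
        return np.zeros(len(keys), dtype=np.int64)
    carried = genome.carries()
    return np.fromiter((k in carried for k in keys), dtype=np.int64, count=len(keys))


# ---------------------------------------------------------------------------
# sequencing emulation
# ---------------------------------------------------------------------------

def sample_read_counts(
    tracks: Mapping[str, pd.DataFrame],
    mean_depth: float = 30.0,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> ReadCountTable:
    """Poisson/binomial read-count sampling for one or more bulks.

    ``tracks`` maps bulk name → frequency DataFrame (chrom, pos, ref, alt,
    freq), all sharing the same site catalog. Per position and bulk,
    depth ~ Poisson(mean_depth) and alt ~ Binomial(depth, f(1−e) + (1−f)e).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    bulks = list(tracks)
    first = tracks[bulks[0]]
    base = first[["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    out = base.copy()
    for b in bulks:
        t = tracks[b].reset_index(drop=True)
        if not t[["chrom", "pos", "ref", "alt"]].equals(base):
            raise ValueError("bulk tracks do not share a site catalog")
        f = t["freq"].to_numpy(dtype=float)
        if ((f < 0) | (f > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")
        depth = rng.poisson(mean_depth, size=len(t))
        p = f * (1 - error_rate) + (1 - f) * error_rate
        alt = rng.binomial(depth, p)
        out[f"{b}_ref"] = depth - alt
        out[f"{b}_alt"] = alt
    return ReadCountTable(
        out, bulks,
        metadata={"mean_depth": mean_depth, "error_rate": error_rate},
    )


# ---------------------------------------------------------------------------
# F2 populations and F2-style bulks
# ---------------------------------------------------------------------------

def simulate_f2(n: int, seed: int | np.random.Generator = 0) -> list[F2Individual]:
    """Single-locus recessive F2 population: genotypes 1:2:1, brown iff mut/mut."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = rng.choice(3, size=n, p=[0.25, 0.5, 0.25])
    genotypes = np.array(["mut/mut", "WT/mut", "WT/WT"])[codes]
    return [
        F2Individual(g, "brown" if g == "mut/mut" else "normal") for g in genotypes
    ]


def f2_recessive_bulk_track(
    n_individuals: int,
    n_unlinked: int,
    seed: int | np.random.Generator = 0,
    causal_chrom: str = "chr1",
    causal_pos: int = 500_000,
    unlinked_chrom: str = "chr2",
) -> pd.DataFrame:
    """True allele-frequency track of a bulk of F2 recessive homozygotes.

    All members are mut/mut at the causal site (frequency 1.0). At each of
    ``n_unlinked`` unlinked segregating sites, every one of the 2n haplotypes
    carries the alternate allele independently with probability 1/2, so the
    bulk frequency is Binomial(2n, 0.5)/2n.
    """
    if n_individuals < 1 or n_unlinked < 0:
        raise ValueError("need n_individuals >= 1 and n_unlinked >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_hap = 2 * n_individuals
    freqs = rng.binomial(n_hap, 0.5, size=n_unlinked) / n_hap
    rows = [(causal_chrom, causal_pos, "G", "A", "causal", 1.0)]
    rows += [
        (unlinked_chrom, 1000 * (i + 1), "C", "T", None, freqs[i])
        for i in range(n_unlinked)
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "label", "freq"])


# ---------------------------------------------------------------------------
# whole-experiment scenarios
# ---------------------------------------------------------------------------

@dataclass
class BulkExperiment:
    """Everything one bulked-segregant mapping run needs."""

    parents: ParentSet
    lineages: list[Lineage]
    counts: ReadCountTable
    mutant_track: pd.DataFrame
    normal_track: pd.DataFrame

    @property
    def causal(self) -> VariantSite:
        return self.parents.causal


def simulate_bulk_experiment(
    seed: int,
    n_lineages: int = 9,
    chromosomes: Sequence[tuple[str, int]] = (("chr1", 500_000), ("chr2", 500_000)),
    snp_rate: float = 2e-4,
    n_backcross: int = 2,
    n_self: int = 4,
    crossover_rate: float = 2.0,
    mean_depth: float = 30.0,
    error_rate: float = 0.0,
    donor_snp_rate: float = 1e-3,
) -> BulkExperiment:
    """Default study conditions: nine introgression lineages sharing one donor
    causal allele, each paired with a distinct recurrent parent; the normal
    bulk is the nine recurrent parents themselves."""
    rng = np.random.default_rng(seed)
    parents = build_parents(
        n_lineages, chromosomes, snp_rate, rng, donor_snp_rate=donor_snp_rate
    )
    lineages = [
        simulate_lineage(
            parents.donor, parents.recurrents[i], n_backcross, n_self,
            parents.causal, crossover_rate, rng,
        )
        for i in range(n_lineages)
    ]
    genomes = {g.id: g for g in [parents.donor, *parents.recurrents]}
    catalog = variant_catalog(genomes.values())
    mutant_track = assemble_bulk(lineages, genomes, catalog, role="mutant")
    normal_members = [parent_as_lineage(p, parents.causal) for p in parents.recurrents]
    normal_track = assemble_bulk(normal_members, genomes, catalog, role="normal")
    counts = sample_read_counts(
        {"mutant": mutant_track, "normal": normal_track},
        mean_depth=mean_depth, error_rate=error_rate, seed=rng,
    )
    return BulkExperiment(parents, lineages, counts, mutant_track, normal_track)


def mixed_allele_bulk(
    seed: int,
    fractions: Sequence[int] = (5, 3, 1),
    n_lineages: int = 9,
    chromosomes: Sequence[tuple[str, int]] = (("chr1", 200_000),),
    locus_positions: Sequence[int] | None = None,
    mean_depth: float = 100.0,
) -> tuple[ReadCountTable, list[VariantSite]]:
    """Mutant bulk whose members carry different causal alleles at one locus.

    ``fractions`` gives the lineage split across the alleles (default 5:3:1
    of 9). Each allele is a distinct SNV within the same locus; a member
    homozygous for one allele carries neither of the others, so no single
    variant can reach bulk frequency 1.
    """
    if sum(fractions) != n_lineages:
        raise ValueError("fractions must sum to the number of lineages")
    rng = np.random.default_rng(seed)
    chrom = chromosomes[0][0]
    length = chromosomes[0][1]
    if locus_positions is None:
        mid = length // 2
        locus_positions = [mid, mid + 50, mid + 100]
    if len(locus_positions) != len(fractions):
        raise ValueError("need one locus position per allele")

    reference = random_reference(chromosomes, rng)
    alleles = []
    for i, pos in enumerate(locus_positions):
        base = reference[chrom][pos - 1]
        alt = EMS_TRANSITIONS.get(base, "A" if base != "A" else "G")
        alleles.append(VariantSite(chrom, pos, base, alt, label=f"allele{i + 1}"))

    # exact haplotype arithmetic: members homozygous for their own allele
    rows = []
    for i, allele in enumerate(alleles):
        freq = 2 * fractions[i] / (2 * n_lineages)
        rows.append((allele.chrom, allele.pos, allele.ref, allele.alt,
                     allele.label, freq))
    track = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "label", "freq"]
    )
    counts = sample_read_counts(
        {"mutant": track}, mean_depth=mean_depth, error_rate=0.0, seed=rng
    )
    return counts, alleles


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------

def write_fixture_set(out_dir, seed: int = 0) -> dict[str, str]:
    """Emit a complete small fixture set to ``out_dir``.

    Writes the base reference FASTA, a toy gene model GFF3 over the causal
    site, per-bulk counts as both TSV and VCF (AD field), a decoy variant
    panel VCF and an F2 genotype/phenotype TSV. All files round-trip through
    this package's own readers. Returns the path of each file by name.
    """
    from pathlib import Path

    from . import io as iom
    from .effects import GeneModel

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exp = simulate_bulk_experiment(
        seed, chromosomes=(("chr1", 100_000), ("chr2", 100_000)), snp_rate=2e-4
    )
    causal = exp.causal

    paths = {
        "reference": out / "reference.fa",
        "genes": out / "genes.gff3",
        "counts_tsv": out / "counts.tsv",
        "counts_vcf": out / "counts.vcf",
        "panel": out / "panel.vcf",
        "f2": out / "f2.tsv",
    }
    iom.write_fasta(exp.parents.reference, paths["reference"])

    gene = GeneModel(
        gene_id="toy_fpgs",
        chrom=causal.chrom,
        strand="+",
        cds=[(causal.pos - 4, causal.pos + 7)],
        phase=0,
    )
    iom.write_gff3([gene], paths["genes"])
    iom.write_counts_tsv(exp.counts, paths["counts_tsv"])
    iom.write_counts_vcf(exp.counts, paths["counts_vcf"])

    donor_others = [
        v for v in exp.parents.donor.variants
        if v.chrom == causal.chrom and v.pos != causal.pos
    ]
    decoys = sorted(donor_others, key=lambda v: abs(v.pos - causal.pos))[:5]
    iom.write_panel_vcf(decoys, paths["panel"])
    iom.write_f2_tsv(simulate_f2(60, seed=seed + 1), paths["f2"])
    return {k: str(v) for k, v in paths.items()}
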