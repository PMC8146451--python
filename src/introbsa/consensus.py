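"""Reference-based consensus assembly by substituting confident SNV calls.

A resequenced parent's reads aligned to the base reference yield variant
calls; the confident ones are substituted into the reference so downstream
bulks are compared against the parent's own genome rather than the base
reference. Only SNVs are substituted, which preserves the coordinate system
shared by every bulk; confident indels are reported but left unapplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .bsa_stats import snp_index
from .synthetic_data import ReadCountTable, VariantSite


@dataclass(frozen=True)
class ConfidentCall:
    variant: VariantSite
    depth: int
    fraction: float

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("a confident call needs depth >= 1")
        if not 0 <= self.fraction <= 1:
            raise ValueError("alternate fraction must be in [0, 1]")


def select_confident_calls(
    counts: ReadCountTable,
    bulk: str,
    min_depth: int = 10,
    min_fraction: float = 0.9,
) -> list[ConfidentCall]:
    """SNVs with depth ≥ min_depth and alternate fraction ≥ min_fraction,
    sorted by (chrom, pos)."""
    if bulk not in counts.bulks:
        raise KeyError(f"unknown bulk {bulk!r}; have {counts.bulks}")
    if min_depth < 1 or not 0 <= min_fraction <= 1:
        raise ValueError("thresholds out of range")
    calls = []
    for row in counts.df.itertuples(index=False):
        ref_n = getattr(row, f"{bulk}_ref")
        alt_n = getattr(row, f"{bulk}_alt")
        depth = ref_n + alt_n
        if depth < min_depth:
            continue
        frac = snp_index(ref_n, alt_n)
        if frac < min_fraction:
            continue
        if len(row.ref) != 1 or len(row.alt) != 1:
            continue  # indels reported upstream, never substituted
        calls.append(
            ConfidentCall(
                VariantSite(row.chrom, int(row.pos), row.ref, row.alt),
                depth=int(depth),
                fraction=float(frac),
            )
        )
    calls.sort(key=lambda c: (c.variant.chrom, c.variant.pos))
    return calls


class ReferenceMismatchError(ValueError):
    pass


def apply_snvs_to_reference(
    reference: Mapping[str, str],
    calls: Sequence[ConfidentCall | VariantSite],
) -> dict[str, str]:
    """Substitute SNV calls into the reference, returning a new sequence set.

    Every call's ref base must match the reference at its position; any
    mismatch rejects the whole operation (so a consensus is never built from
    stale coordinates). Sequence lengths are preserved and exactly the
    called positions change.
    """
    variants = [c.variant if isinstance(c, ConfidentCall) else c for c in calls]
    for v in variants:
        if v.chrom not in reference:
            raise ReferenceMismatchError(f"unknown chromosome {v.chrom}")
        found = reference[v.chrom][v.pos - 1]
        if found != v.ref:
            raise ReferenceMismatchError(
                f"reference mismatch at {v.chrom}:{v.pos}: "
                f"call says {v.ref}, reference has {found}"
            )
    out = {chrom: list(seq) for chrom, seq in reference.items()}
    for v in variants:
        out[v.chrom][v.pos - 1] = v.alt
    return {chrom: "".join(seq) for chrom, seq in out.items()}
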