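"""End-to-end mapping workflow: counts → Δ track → candidate region →
ranked causal candidates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bsa_stats
from .effects import CandidateReport, GeneModel, predict_consequence, rank_candidates
from .synthetic_data import BulkExperiment, VariantSite


def causal_gene_model(exp: BulkExperiment, gene_id: str = "candidate_gene") -> GeneModel:
    """A toy single-CDS gene model over the experiment's causal SNV.

    The CDS places the causal base at the second position of its codon, so
    the planted G→A / C→T transition is guaranteed non-synonymous.
    """
    causal = exp.causal
    length = dict(exp.parents.chromosomes)[causal.chrom]
    start = max(1, causal.pos - 4)
    end = min(length, start + 11)
    return GeneModel(gene_id, causal.chrom, "+", [(start, end)], phase=0)


@dataclass
class MappingResult:
    deltas: pd.DataFrame
    windows: pd.DataFrame
    bands: pd.DataFrame
    regions: list
    report: CandidateReport | None

    @property
    def top_region(self):
        return self.regions[0] if self.regions else None


def map_experiment(
    exp: BulkExperiment,
    window_size: int = 100_000,
    step: int = 25_000,
    n_reps: int = 1000,
    seed: int = 0,
    level: float = 0.05,
    panel: set[tuple[str, int, str]] = frozenset(),
    genes: list[GeneModel] | None = None,
    min_index_mut: float = 1.0,
    max_index_normal: float = 0.0,
) -> MappingResult:
    """Run the full mapping analysis on a simulated (or loaded) experiment.

    Region calling uses the Monte-Carlo null band at ``level``; candidate
    ranking is restricted to variants inside the top-ranked region, using
    the supplied gene models (default: a toy gene over the causal site) and
    exclusion panel.
    """
    chrom_lengths = dict(exp.parents.chromosomes)
    deltas, windows = bsa_stats.delta_pipeline(
        exp.counts, window_size=window_size, step=step, chrom_lengths=chrom_lengths
    )
    bands = bsa_stats.null_ci_bands(
        deltas, window_size=window_size, step=step, n_reps=n_reps, seed=seed,
        chrom_lengths=chrom_lengths,
    )
    regions = bsa_stats.call_candidate_regions(windows, bands, level=level)
    report = None
    if regions:
        top = regions[0]
        if genes is None:
            genes = [causal_gene_model(exp)]
        in_region = deltas.loc[
            (deltas["chrom"] == top.chrom)
            & (deltas["pos"] >= top.start)
            & (deltas["pos"] <= top.end)
        ]
        variants = [
            VariantSite(r.chrom, int(r.pos), r.ref, r.alt)
            for r in in_region.itertuples(index=False)
        ]
        indices = {
            v.key: (float(r.index_mut), float(r.index_normal))
            for v, r in zip(variants, in_region.itertuples(index=False))
        }
        consequences = {}
        for v in variants:
            for gene in genes:
                call = predict_consequence(v, gene, exp.parents.reference)
                if call.consequence != "non_coding":
                    consequences[v.key] = call
                    break
            else:
                if genes:
                    consequences[v.key] = predict_consequence(
                        v, genes[0], exp.parents.reference
                    )
        report = rank_candidates(
            variants, indices, consequences, panel=panel,
            min_index_mut=min_index_mut, max_index_normal=max_index_normal,
        )
    return MappingResult(deltas, windows, bands, regions, report)


def decoy_panel(exp: BulkExperiment, n_decoys: int = 5) -> set[tuple[str, int, str]]:
    """Panel containing the ``n_decoys`` donor variants nearest the causal
    site (background polymorphism shared with resequenced lines)."""
    causal = exp.causal
    others = [
        v for v in exp.parents.donor.variants
        if v.chrom == causal.chrom and v.pos != causal.pos
    ]
    others.sort(key=lambda v: abs(v.pos - causal.pos))
    return {(v.chrom, v.pos, v.alt) for v in others[:n_decoys]}


def linked_unlinked_indices(
    seed: int,
    n_individuals: int = 20,
    n_unlinked: int = 1000,
    mean_depth: float = 30.0,
    error_rate: float = 0.0,
):
    """SNP-index at the causal site vs. unlinked sites in an F2-style bulk.

    Simulates a bulk of recessive homozygotes and returns (causal index,
    mean index over the unlinked sites, Monte-Carlo standard error of that
    mean). The causal index is 1.0 at zero error; the unlinked mean hovers
    around 1/2.
    """
    from .synthetic_data import f2_recessive_bulk_track, sample_read_counts

    rng = np.random.default_rng(seed)
    track = f2_recessive_bulk_track(n_individuals, n_unlinked, seed=rng)
    counts = sample_read_counts(
        {"mutant": track}, mean_depth=mean_depth, error_rate=error_rate, seed=rng
    )
    idx = bsa_stats.snp_index(
        counts.df["mutant_ref"].to_numpy(), counts.df["mutant_alt"].to_numpy()
    )
    causal_mask = counts.df["pos"].eq(track.loc[0, "pos"]) & counts.df["chrom"].eq(
        track.loc[0, "chrom"]
    )
    causal_index = float(idx[causal_mask.to_numpy()][0])
    unlinked = idx[~causal_mask.to_numpy()]
    unlinked = unlinked[~np.isnan(unlinked)]
    return causal_index, float(unlinked.mean()), float(
        unlinked.std(ddof=1) / np.sqrt(len(unlinked))
    )
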