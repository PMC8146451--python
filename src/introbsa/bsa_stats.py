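"""SNP-index / ΔSNP-index statistics for bulked-segregant mapping.

The SNP-index at a position is the fraction of aligned reads carrying the
alternate base; ΔSNP-index is the mutant bulk's index minus the normal
bulk's, so a region fixed for the mutant allele in the mutant bulk and
absent from the normal bulk approaches +1. Windowed Δ tracks are compared
against Monte-Carlo confidence bands simulated under a null of no causal
locus, and maximal runs of windows above the band are called as candidate
regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_data import ReadCountTable


# ---------------------------------------------------------------------------
# per-position statistics
# ---------------------------------------------------------------------------

def snp_index(ref_count, alt_count):
    """Alternate-read fraction alt/(ref+alt); NaN where no reads align.

    Accepts scalars or arrays; negative counts are rejected.
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read counts must be non-negative")
    total = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, alt / np.where(total > 0, total, 1), np.nan)
    return float(out) if out.ndim == 0 else out


def delta_snp_index(index_mut, index_normal):
    """ΔSNP-index = mutant-bulk index − normal-bulk index (in [−1, 1])."""
    return np.asarray(index_mut, dtype=float) - np.asarray(index_normal, dtype=float)


def snp_index_table(counts: ReadCountTable, bulk: str) -> pd.DataFrame:
    """Per-position SNP-index records for one bulk.

    ``normalized_depth`` is depth divided by the bulk's median depth across
    all positions (the scale on which the depth filter is expressed).
    """
    if bulk not in counts.bulks:
        raise KeyError(f"unknown bulk {bulk!r}; have {counts.bulks}")
    depth = counts.depth(bulk)
    median = float(np.median(depth)) or 1.0
    df = counts.df[["chrom", "pos", "ref", "alt"]].copy()
    df["bulk"] = bulk
    df["depth"] = depth
    df["normalized_depth"] = depth / median
    df["snp_index"] = snp_index(
        counts.df[f"{bulk}_ref"].to_numpy(), counts.df[f"{bulk}_alt"].to_numpy()
    )
    return df


@dataclass
class FilterConfig:
    """Position filter ahead of ΔSNP-index calculation.

    ``combine="any"`` (default) drops a position failing either criterion;
    ``combine="and"`` drops only positions failing both, the literal reading
    of the low-index-and-low-depth rule.
    """

    min_snp_index: float = 0.3
    min_normalized_depth: float = 0.7
    combine: str = "any"

    def __post_init__(self):
        if self.min_snp_index < 0 or self.min_normalized_depth < 0:
            raise ValueError("thresholds must be non-negative")
        if self.combine not in ("any", "and"):
            raise ValueError("combine must be 'any' or 'and'")


def filter_positions(records: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Drop positions failing the filter predicate; undefined indices drop too."""
    config = config or FilterConfig()
    low_index = (records["snp_index"] < config.min_snp_index) | records["snp_index"].isna()
    low_depth = records["normalized_depth"] < config.min_normalized_depth
    fail = (low_index | low_depth) if config.combine == "any" else (low_index & low_depth)
    return records.loc[~fail].reset_index(drop=True)


def delta_table(mut_records: pd.DataFrame, normal_records: pd.DataFrame) -> pd.DataFrame:
    """Join the two bulks' records and compute Δ; positions with an undefined
    index in either bulk are excluded."""
    merged = mut_records.merge(
        normal_records,
        on=["chrom", "pos", "ref", "alt"],
        suffixes=("_mut", "_normal"),
    )
    merged = merged.rename(
        columns={"snp_index_mut": "index_mut", "snp_index_normal": "index_normal"}
    )
    merged = merged.dropna(subset=["index_mut", "index_normal"])
    merged["delta"] = delta_snp_index(merged["index_mut"], merged["index_normal"])
    keep = ["chrom", "pos", "ref", "alt", "index_mut", "index_normal", "delta",
            "depth_mut", "depth_normal"]
    return merged[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def window_starts(length: int, window_size: int, step: int) -> np.ndarray:
    last = max(1, length - window_size + 1)
    starts = np.arange(1, last + 1, step, dtype=np.int64)
    if starts[-1] != last and length > window_size:
        starts = np.append(starts, last)
    return starts


def sliding_window(
    records: pd.DataFrame,
    value_col: str = "delta",
    window_size: int = 2_000_000,
    step: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean of ``value_col`` in sliding windows per chromosome.

    Windows with no positions get NaN and n=0. ``chrom_lengths`` defaults to
    the maximum observed position per chromosome.
    """
    if not (window_size >= step > 0):
        raise ValueError("need window_size >= step > 0")
    out = []
    for chrom, grp in records.groupby("chrom", sort=True):
        length = (chrom_lengths or {}).get(chrom, int(grp["pos"].max()))
        pos = grp["pos"].to_numpy()
        vals = grp[value_col].to_numpy(dtype=float)
        order = np.argsort(pos)
        pos, vals = pos[order], vals[order]
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        for start in window_starts(length, window_size, step):
            end = min(start + window_size - 1, length)
            i = np.searchsorted(pos, start, side="left")
            j = np.searchsorted(pos, end, side="right")
            n = j - i
            mean = (csum[j] - csum[i]) / n if n else np.nan
            out.append((chrom, int(start), int(end), (start + end) // 2, mean, int(n)))
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "mid", value_col, "n"]
    )


# ---------------------------------------------------------------------------
# Monte-Carlo null confidence bands
# ---------------------------------------------------------------------------

def null_ci_bands(
    positions: pd.DataFrame,
    window_size: int = 2_000_000,
    step: int = 100_000,
    levels: Sequence[float] = (0.05, 0.01),
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    null: str = "binomial",
    n_members: int = 9,
    error_rate: float = 0.0,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed ΔSNP-index confidence bands under a null of no causal locus.

    ``positions`` needs chrom, pos, depth_mut, depth_normal (the observed
    depth profile). Per replicate, each bulk's alternate counts are drawn at
    null allele frequency: ``null="binomial"`` uses frequency 0.5 per bulk
    (two bulks of segregants with no selection differential), while
    ``null="lineage"`` first resamples the bulk's 2×``n_members`` haplotypes
    (each alternate with probability 0.5) so the bulk frequency itself varies
    around 0.5, as in a small pooled bulk. Two-sided empirical quantiles of
    the windowed Δ give the band at each level.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if null not in ("binomial", "lineage"):
        raise ValueError("null must be 'binomial' or 'lineage'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pos_df = positions.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    n_pos = len(pos_df)
    deltas = np.empty((n_reps, n_pos))
    for col, bulk_sign in ((f"depth_mut", 1.0), (f"depth_normal", -1.0)):
        depth = pos_df[col].to_numpy(dtype=np.int64)
        if null == "lineage":
            n_hap = 2 * n_members
            freq = rng.binomial(n_hap, 0.5, size=(n_reps, n_pos)) / n_hap
        else:
            freq = 0.5
        p = freq * (1 - error_rate) + (1 - np.asarray(freq)) * error_rate
        alt = rng.binomial(
            np.broadcast_to(depth[None, :], (n_reps, n_pos)),
            np.broadcast_to(p, (n_reps, n_pos)),
        )
        with np.errstate(invalid="ignore"):
            idx = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
        if bulk_sign > 0:
            deltas = idx.copy()
        else:
            deltas -= idx

    rows = []
    for chrom, grp in pos_df.groupby("chrom", sort=True):
        length = (chrom_lengths or {}).get(chrom, int(grp["pos"].max()))
        pos = grp["pos"].to_numpy()
        cols = grp.index.to_numpy()
        for start in window_starts(length, window_size, step):
            end = min(start + window_size - 1, length)
            i = np.searchsorted(pos, start, side="left")
            j = np.searchsorted(pos, end, side="right")
            row = {"chrom": chrom, "start": int(start), "end": int(end),
                   "mid": (start + end) // 2, "n": int(j - i)}
            if j > i:
                wmeans = np.nanmean(deltas[:, cols[i:j]], axis=1)
                for level in levels:
                    lo, hi = np.quantile(wmeans, [level / 2, 1 - level / 2])
                    row[f"lower_{level}"] = float(lo)
                    row[f"upper_{level}"] = float(hi)
            else:
                for level in levels:
                    row[f"lower_{level}"] = np.nan
                    row[f"upper_{level}"] = np.nan
            rows.append(row)
    bands = pd.DataFrame(rows)
    bands.attrs["n_reps"] = n_reps
    bands.attrs["levels"] = tuple(levels)
    return bands


# ---------------------------------------------------------------------------
# candidate regions
# ---------------------------------------------------------------------------

@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    peak_delta: float
    n_windows: int

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


def call_candidate_regions(
    windows: pd.DataFrame,
    bands: pd.DataFrame,
    level: float = 0.05,
    max_gap: int = 1,
) -> list[CandidateRegion]:
    """Maximal runs of windows whose Δ exceeds the upper null band.

    Runs separated by at most ``max_gap`` non-exceeding windows are merged;
    regions are ranked by peak windowed Δ, highest first.
    """
    upper_col = f"upper_{level}"
    merged = windows.merge(
        bands[["chrom", "start", "end", upper_col]], on=["chrom", "start", "end"]
    )
    regions: list[CandidateRegion] = []
    for chrom, grp in merged.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        exceeding = grp.loc[
            grp["delta"].notna()
            & grp[upper_col].notna()
            & (grp["delta"] > grp[upper_col])
        ]
        if exceeding.empty:
            continue
        idx = exceeding.index.to_numpy()
        ordinal = {ix: k for k, ix in enumerate(grp.index)}
        run = [idx[0]]
        for prev, cur in zip(idx, idx[1:]):
            if ordinal[cur] - ordinal[prev] <= max_gap + 1:
                run.append(cur)
            else:
                regions.append(_make_region(chrom, grp.loc[run]))
                run = [cur]
        regions.append(_make_region(chrom, grp.loc[run]))
    regions.sort(key=lambda r: -r.peak_delta)
    return regions


def _make_region(chrom: str, run: pd.DataFrame) -> CandidateRegion:
    return CandidateRegion(
        chrom=chrom,
        start=int(run["start"].min()),
        end=int(run["end"].max()),
        peak_delta=float(run["delta"].max()),
        n_windows=len(run),
    )


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------

def delta_pipeline(
    counts: ReadCountTable,
    mut_bulk: str = "mutant",
    normal_bulk: str = "normal",
    filter_config: FilterConfig | None = None,
    window_size: int = 100_000,
    step: int = 25_000,
    chrom_lengths: dict[str, int] | None = None,
):
    """Counts → filtered Δ records → windowed Δ track.

    The index filter is applied to the mutant bulk's records: the decisive
    signal is mutant-bulk fixation, and mutant-specific sites legitimately
    have index ≈ 0 in the normal bulk.
    """
    mut = snp_index_table(counts, mut_bulk)
    normal = snp_index_table(counts, normal_bulk)
    kept = filter_positions(mut, filter_config)
    deltas = delta_table(kept, normal)
    windows = sliding_window(
        deltas, "delta", window_size, step, chrom_lengths=chrom_lengths
    )
    return deltas, windows
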