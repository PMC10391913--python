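"""Joint top-quantile sweep calling and gene annotation.

Candidate divergent ("potentially selected") regions are the windows that
fall simultaneously in the upper tail of windowed FST and of the windowed
log2 pi ratio — the intersection of the two marginal top-q sets (default
q = 0.05), not their union. Flagged windows are merged into regions and
annotated with overlapping genes; genes collected over all regions of a
scan direction form the candidate (PSG) list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_genotypes import GeneSet


@dataclass
class SweepCall:
    """One merged divergent region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    member_windows: int
    max_fst: float
    max_log2_ratio: float
    genes: list[str] = field(default_factory=list)


def top_quantile_threshold(values: np.ndarray, q: float) -> float:
    """Empirical order-statistic threshold: the k-th largest value with
    k = ceil(q * N), so that {x >= threshold} has exactly k members when
    values are all distinct (ties at the threshold are included).
    """
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    if len(v) == 0:
        raise ValueError("no values to rank")
    k = max(1, math.ceil(q * len(v)))
    return float(v[k - 1])


def select_top_windows(windows: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Flag usable windows in the joint top-q of FST and log2 pi ratio.

    ``windows`` is the table from :func:`divscan.window_stats.window_divergence`.
    Returns the table with an added boolean ``flagged`` column and the two
    thresholds stored in ``.attrs``.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    usable = windows["usable"].to_numpy(dtype=bool)
    if not usable.any():
        raise ValueError("no usable windows to rank")
    fst = windows["fst"].to_numpy(dtype=float)
    lr = windows["log2_pi_ratio"].to_numpy(dtype=float)
    fst_thr = top_quantile_threshold(fst[usable], q)
    lr_thr = top_quantile_threshold(lr[usable], q)
    flagged = usable & (fst >= fst_thr) & (lr >= lr_thr)
    out = windows.copy()
    out["flagged"] = flagged
    out.attrs["fst_threshold"] = fst_thr
    out.attrs["ratio_threshold"] = lr_thr
    return out


def merge_flagged(windows: pd.DataFrame, gap: int = 0) -> list[SweepCall]:
    """Merge flagged windows within ``gap`` bp on the same chromosome.

    Summary statistics of a region are maxima over its member windows.
    """
    t = windows.loc[windows["flagged"]].sort_values(["chrom", "start"])
    regions: list[SweepCall] = []
    for _, row in t.iterrows():
        if (
            regions
            and regions[-1].chrom == row["chrom"]
            and row["start"] - regions[-1].end <= gap
        ):
            r = regions[-1]
            r.end = max(r.end, int(row["end"]))
            r.member_windows += 1
            r.max_fst = max(r.max_fst, float(row["fst"]))
            r.max_log2_ratio = max(r.max_log2_ratio, float(row["log2_pi_ratio"]))
        else:
            regions.append(
                SweepCall(
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    member_windows=1,
                    max_fst=float(row["fst"]),
                    max_log2_ratio=float(row["log2_pi_ratio"]),
                )
            )
    return regions


def annotate_genes(regions: list[SweepCall], genes: GeneSet) -> list[SweepCall]:
    """Attach to each region the genes whose half-open interval intersects
    it (shared length >= 1 bp). Returns the same list, mutated.
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.table.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.gene_id)
    for r in regions:
        tree = trees.get(r.chrom)
        hits = sorted(iv.data for iv in tree.overlap(r.start, r.end)) if tree else []
        r.genes = hits
    return regions


def psg_list(regions: list[SweepCall]) -> list[str]:
    """Deduplicated, sorted candidate-gene list over all regions."""
    return sorted({g for r in regions for g in r.genes})


def call_sweeps(
    windows: pd.DataFrame,
    genes: GeneSet | None = None,
    q: float = 0.05,
    gap: int = 0,
) -> tuple[list[SweepCall], list[str]]:
    """Full sweep call: flag, merge, annotate. Returns (regions, PSG list)."""
    flagged = select_top_windows(windows, q=q)
    regions = merge_flagged(flagged, gap=gap)
    if genes is not None:
        annotate_genes(regions, genes)
    return regions, psg_list(regions)


def regions_to_frame(regions: list[SweepCall]) -> pd.DataFrame:
    """BED-like table of merged regions."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "member_windows": r.member_windows,
                "max_fst": r.max_fst,
                "max_log2_ratio": r.max_log2_ratio,
                "genes": ",".join(r.genes),
            }
            for r in regions
        ],
        columns=[
            "chrom", "start", "end", "member_windows",
            "max_fst", "max_log2_ratio", "genes",
        ],
    )
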