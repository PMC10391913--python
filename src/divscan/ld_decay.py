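"""Linkage-disequilibrium decay from genotype dosages.

r-squared between two sites is the squared Pearson correlation of their
dosage vectors over pairwise-complete samples (the composite, Rogers-Huff
style measure — no phasing required). All intra-chromosomal site pairs up
to a maximum separation are binned by physical distance; the curve of
per-bin mean r2 yields the study-style linkage summary: half_max is
r2_max / 2 exactly, and the linkage distance is the midpoint of the first
bin whose mean r2 has dropped to half_max or below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io_genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class LDCurve:
    bins: np.ndarray       # (n_bins, 2) half-open bp intervals, uniform width
    mean_r2: np.ndarray    # per-bin mean r2 (NaN for empty bins)
    n_pairs: np.ndarray    # per-bin pair count

    @property
    def midpoints(self) -> np.ndarray:
        return self.bins.mean(axis=1)

    @property
    def r2_max(self) -> float:
        if np.all(np.isnan(self.mean_r2)):
            return float("nan")
        return float(np.nanmax(self.mean_r2))

    @property
    def half_max(self) -> float:
        return self.r2_max / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bins[:, 0].astype(int),
                "bin_end": self.bins[:, 1].astype(int),
                "midpoint": self.midpoints,
                "n_pairs": self.n_pairs,
                "mean_r2": self.mean_r2,
            }
        )


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors
    (pairwise-complete samples). Undefined (ValueError) when fewer than two
    shared samples or either site is monomorphic among them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        raise ValueError("genotype_r2 needs >= 2 pairwise-complete samples")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("genotype_r2 undefined for a monomorphic site")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _pairs_complete(pos: np.ndarray, X: np.ndarray, max_dist: int, grid_end: int):
    """Vectorised (bin-distance, r2) pairs for a fully genotyped block."""
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc**2).sum(axis=1))
    poly = sd > 0
    Xn = np.zeros_like(Xc)
    Xn[poly] = Xc[poly] / sd[poly, None]
    dists, r2s = [], []
    n = len(pos)
    for a in range(n - 1):
        if not poly[a]:
            continue
        upper = int(np.searchsorted(pos, pos[a] + max_dist, side="right"))
        if upper <= a + 1:
            continue
        b = slice(a + 1, upper)
        d = (pos[b] - pos[a]).astype(np.int64)
        keep = poly[b] & (d > 0) & (d < grid_end)
        if not keep.any():
            continue
        r = Xn[b][keep] @ Xn[a]
        dists.append(d[keep])
        r2s.append(r * r)
    if not dists:
        return np.empty(0, dtype=np.int64), np.empty(0)
    return np.concatenate(dists), np.concatenate(r2s)


def _pairs_with_missing(pos: np.ndarray, X: np.ndarray, max_dist: int, grid_end: int):
    """Pair loop honouring pairwise-complete samples (small inputs only)."""
    dists, r2s = [], []
    n = len(pos)
    for a in range(n - 1):
        upper = int(np.searchsorted(pos, pos[a] + max_dist, side="right"))
        for b in range(a + 1, upper):
            d = int(pos[b] - pos[a])
            if d == 0 or d >= grid_end:
                continue
            ok = (X[a] != MISSING) & (X[b] != MISSING)
            if ok.sum() < 2:
                continue
            xa, xb = X[a][ok], X[b][ok]
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            dists.append(d)
            r2s.append(r * r)
    return np.array(dists, dtype=np.int64), np.array(r2s)


def ld_decay_curve(
    gm: GenotypeMatrix,
    max_dist: int = 500_000,
    bin_width: int = 5000,
    subsample: int | None = None,
    seed: int | None = None,
) -> LDCurve:
    """Distance-binned mean r2 over intra-chromosomal site pairs.

    Pairs separated by up to ``max_dist`` bp contribute to the half-open
    bin containing their separation. ``subsample`` caps the number of pairs
    per bin by uniform random selection (seeded). Pairs monomorphic among
    shared samples are skipped.
    """
    n_bins = int(np.ceil(max_dist / bin_width))
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width, dtype=np.int64)
    grid_end = int(edges[-1])
    rng = np.random.default_rng(seed)

    all_d, all_r2 = [], []
    for ch in pd.unique(gm.chrom):
        rows = np.nonzero(gm.chrom == ch)[0]
        if len(rows) < 2:
            continue
        pos = gm.pos[rows]
        X = gm.dosage[rows].astype(float)
        if (X == MISSING).any():
            d, r2 = _pairs_with_missing(pos, X, max_dist, grid_end)
        else:
            d, r2 = _pairs_complete(pos, X, max_dist, grid_end)
        all_d.append(d)
        all_r2.append(r2)

    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    if all_d:
        d = np.concatenate(all_d)
        r2 = np.concatenate(all_r2)
        bi = d // bin_width
        if subsample is not None:
            keep = np.zeros(len(bi), dtype=bool)
            for k in range(n_bins):
                members = np.nonzero(bi == k)[0]
                if len(members) > subsample:
                    members = rng.choice(members, size=subsample, replace=False)
                keep[members] = True
            bi, r2 = bi[keep], r2[keep]
        np.add.at(sums, bi, r2)
        np.add.at(counts, bi, 1)

    if counts.sum() == 0:
        logger.warning("ld_decay_curve: no eligible site pairs")
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    bins = np.column_stack([edges[:-1], edges[1:]])
    return LDCurve(bins=bins, mean_r2=mean_r2, n_pairs=counts)


def linkage_distance(curve: LDCurve) -> float | None:
    """Distance (bp) at which LD has decayed to half its maximum.

    Returns the midpoint of the first bin (increasing distance) whose mean
    r2 is <= r2_max / 2, or None if the curve never drops that far.
    """
    if len(curve.mean_r2) == 0 or np.all(np.isnan(curve.mean_r2)):
        raise ValueError("empty LD curve")
    half = curve.half_max
    for mid, m in zip(curve.midpoints, curve.mean_r2):
        if not np.isnan(m) and m <= half:
            return float(mid)
    logger.info("LD curve never decays to half its maximum within range")
    return None


def fit_decay_length(curve: LDCurve) -> float:
    """Correlation length scale (bp) from an exponential fit.

    Under first-order copy correlation the inter-site dosage correlation
    falls off as exp(-d / L), so mean r2 ~ A * exp(-2 d / L) + c; the
    fitted L is returned.
    """
    ok = ~np.isnan(curve.mean_r2) & (curve.n_pairs > 0)
    if ok.sum() < 3:
        raise ValueError("need >= 3 populated bins to fit a decay length")
    x = curve.midpoints[ok]
    y = curve.mean_r2[ok]
    scale = float(x.max())

    def model(d, amp, length, floor):
        return amp * np.exp(-2.0 * d / length) + floor

    a0 = max(y.max() - y.min(), 1e-3)
    l0 = scale / 4.0
    popt, _ = curve_fit(
        model, x, y, p0=(a0, l0, max(y.min(), 0.0)),
        bounds=([0.0, 1.0, 0.0], [1.0, 100 * scale, 1.0]), maxfev=20000,
    )
    return float(popt[1])
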