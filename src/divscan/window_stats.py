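"""Windowed nucleotide diversity, Weir-Cockerham FST and the log2 pi ratio.

Divergence between two populations is scanned in fixed windows (default
5 kb, non-overlapping). Per window we report:

* ``pi_a``, ``pi_b`` — per-bp nucleotide diversity of each population:
  the sum over variant sites of the unbiased per-site heterozygosity
  ``2 p (1-p) n/(n-1)`` (``n`` = non-missing chromosomes), divided by the
  window length in bp, so monomorphic positions contribute zero. This is
  the conventional windowed-pi of VCF tooling.
* ``fst`` — the Weir & Cockerham (1984) two-population estimator in its
  weighted ("ratio of sums") windowed form: sum of the among-population
  variance components ``a`` divided by the sum of ``a + b + c`` over all
  usable sites in the window. Negative estimates are reported unclipped.
* ``log2_pi_ratio`` — log2 of the windowed pi ratio in a configurable
  direction; windows where either pi is zero are marked unusable.

A window must contain a minimum number of usable sites (default 3) to be
ranked by the sweep caller; see :class:`WindowSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_genotypes import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry (bp). Default: 5-kb non-overlapping windows.

    ``step`` must divide ``window_size`` when windows overlap.
    """

    window_size: int = 5000
    step: int = 5000
    min_sites: int = 3  # usable sites required for a window to be ranked

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not 0 < self.step <= self.window_size:
            raise ValueError("step must be in (0, window_size]")
        if self.window_size % self.step != 0:
            raise ValueError("step must divide window_size")
        if self.min_sites < 0:
            raise ValueError("min_sites must be >= 0")


def site_pi(alt_count: int, n_chrom: int) -> float:
    """Unbiased per-site diversity: the fraction of chromosome pairs that
    differ at the site, ``2 p (1-p) n/(n-1)``.
    """
    if n_chrom < 2:
        raise ValueError("site_pi needs >= 2 non-missing chromosomes")
    if not 0 <= alt_count <= n_chrom:
        raise ValueError("alt_count out of range")
    p = alt_count / n_chrom
    return 2.0 * p * (1.0 - p) * n_chrom / (n_chrom - 1)


def _pop_site_arrays(gm: GenotypeMatrix, population: str):
    """Per-site (n_diploid, alt_count, het_count) for one population."""
    sub = gm.dosage[:, gm.sample_indices(population)]
    miss = sub == MISSING
    n = (~miss).sum(axis=1)
    alt = np.where(miss, 0, sub).sum(axis=1)
    het = (sub == 1).sum(axis=1)
    return n, alt, het


def _site_pi_vector(n_dip: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Vectorised site_pi; sites with < 2 chromosomes get NaN."""
    nc = 2 * n_dip.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nc > 0, alt / np.maximum(nc, 1), 0.0)
        pi = 2.0 * p * (1.0 - p) * nc / np.maximum(nc - 1, 1)
    pi[nc < 2] = np.nan
    return pi


def wc_fst_site(
    pop_a: tuple[int, int, int], pop_b: tuple[int, int, int]
) -> tuple[float, float, float]:
    """Weir-Cockerham (1984) variance components for one site, two pops.

    Each population is summarised as ``(n_diploid, alt_allele_count,
    het_individual_count)``. Returns the among-population (a),
    among-individual-within-population (b) and within-individual (c)
    components; the site estimate is ``a / (a + b + c)``.
    """
    comps = _wc_components(
        np.array([[pop_a[0]], [pop_b[0]]], dtype=float),
        np.array([[pop_a[1]], [pop_b[1]]], dtype=float),
        np.array([[pop_a[2]], [pop_b[2]]], dtype=float),
    )
    a, b, c = (float(x[0]) for x in comps)
    return a, b, c


def _wc_components(n: np.ndarray, alt: np.ndarray, het: np.ndarray):
    """Vectorised WC84 components. Arrays are shaped (2, sites): row 0 is
    population A, row 1 population B. Sites where either population has
    fewer than 2 genotyped diploids yield NaN components.
    """
    r = 2.0
    n = n.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)            # allele frequency per pop
        h = het / n                    # observed het frequency per pop
        nbar = n.mean(axis=0)
        nsum = n.sum(axis=0)
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2
            - (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    bad = (n < 2).any(axis=0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def _window_index(pos0: np.ndarray, spec: WindowSpec):
    """(window_start, site_row) pairs for every window containing each site.

    ``pos0`` is the 0-based position of each site. With step == window_size
    each site maps to exactly one window.
    """
    n_cover = spec.window_size // spec.step
    starts, rows = [], []
    for off in range(n_cover):
        k = pos0 // spec.step - off
        start = k * spec.step
        valid = (k >= 0) & (start + spec.window_size > pos0)
        starts.append(start[valid])
        rows.append(np.nonzero(valid)[0])
    return np.concatenate(starts), np.concatenate(rows)


def window_divergence(
    gm: GenotypeMatrix,
    spec: WindowSpec | None = None,
    pop_a: str | None = None,
    pop_b: str | None = None,
    ratio_direction: str = "a_over_b",
) -> pd.DataFrame:
    """Per-window pi (both populations), FST and log2 pi ratio.

    ``ratio_direction`` is ``"a_over_b"`` (log2(pi_a / pi_b)) or
    ``"b_over_a"``. Windows are emitted for every window containing at
    least one variant site plus all empty windows up to the last site of
    each chromosome (empty windows report pi = 0 and missing FST).

    Returns a DataFrame with columns chrom, start, end, n_sites, pi_a,
    pi_b, fst, log2_pi_ratio, usable.
    """
    spec = spec or WindowSpec()
    pops = gm.populations
    if pop_a is None or pop_b is None:
        if len(pops) != 2:
            raise ValueError("need exactly two population labels (or pass pop_a/pop_b)")
        pop_a, pop_b = pops
    if ratio_direction not in {"a_over_b", "b_over_a"}:
        raise ValueError("ratio_direction must be 'a_over_b' or 'b_over_a'")

    na, alta, heta = _pop_site_arrays(gm, pop_a)
    nb, altb, hetb = _pop_site_arrays(gm, pop_b)
    pi_a_site = _site_pi_vector(na, alta)
    pi_b_site = _site_pi_vector(nb, altb)
    a, b, c = _wc_components(
        np.stack([na, nb]).astype(float),
        np.stack([alta, altb]).astype(float),
        np.stack([heta, hetb]).astype(float),
    )
    # a site is usable for FST when both pops have >=2 diploids and the
    # site is not monomorphic across both populations together
    denom = a + b + c
    fst_ok = ~np.isnan(denom) & (denom != 0.0)

    out = []
    for ch in pd.unique(gm.chrom):
        sel = np.nonzero(gm.chrom == ch)[0]
        pos0 = gm.pos[sel] - 1
        w_start, rows = _window_index(pos0, spec)
        rows = sel[rows]
        last = int(pos0.max()) if len(pos0) else 0
        all_starts = np.arange(0, last + 1, spec.step)
        all_starts = all_starts[all_starts + spec.window_size > 0]
        idx = {s: k for k, s in enumerate(all_starts)}
        nwin = len(all_starts)
        wi = np.array([idx[s] for s in w_start], dtype=np.intp)

        n_sites = np.zeros(nwin, dtype=int)
        np.add.at(n_sites, wi, 1)
        sum_pa = np.zeros(nwin)
        np.add.at(sum_pa, wi, np.nan_to_num(pi_a_site[rows]))
        sum_pb = np.zeros(nwin)
        np.add.at(sum_pb, wi, np.nan_to_num(pi_b_site[rows]))
        ok = fst_ok[rows]
        sum_a = np.zeros(nwin)
        np.add.at(sum_a, wi[ok], a[rows][ok])
        sum_abc = np.zeros(nwin)
        np.add.at(sum_abc, wi[ok], denom[rows][ok])
        n_usable = np.zeros(nwin, dtype=int)
        np.add.at(n_usable, wi[ok], 1)

        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(sum_abc != 0.0, sum_a / sum_abc, np.nan)
        fst[n_usable == 0] = np.nan
        pi_a = sum_pa / spec.window_size
        pi_b = sum_pb / spec.window_size
        num, den = (pi_a, pi_b) if ratio_direction == "a_over_b" else (pi_b, pi_a)
        with np.errstate(invalid="ignore", divide="ignore"):
            lr = np.where((num > 0) & (den > 0), np.log2(np.maximum(num, 1e-300) / np.maximum(den, 1e-300)), np.nan)
        usable = (
            (n_usable >= max(spec.min_sites, 1))
            & ~np.isnan(fst)
            & (pi_a > 0)
            & (pi_b > 0)
        )
        out.append(
            pd.DataFrame(
                {
                    "chrom": ch,
                    "start": all_starts,
                    "end": all_starts + spec.window_size,
                    "n_sites": n_sites,
                    "pi_a": pi_a,
                    "pi_b": pi_b,
                    "fst": fst,
                    "log2_pi_ratio": lr,
                    "usable": usable,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def windowed_pi(
    gm: GenotypeMatrix, spec: WindowSpec | None = None, population: str | None = None
) -> pd.DataFrame:
    """Per-window per-bp pi for one population (chrom, start, end, pi)."""
    spec = spec or WindowSpec()
    if population is None:
        if not gm.pop_of:
            gm = GenotypeMatrix(
                gm.chrom, gm.pos, gm.ref_allele, gm.alt_allele, gm.dosage,
                gm.samples, {s: "all" for s in gm.samples},
            )
            population = "all"
        elif len(gm.populations) == 1:
            population = gm.populations[0]
        else:
            raise ValueError("several populations present; pass `population`")
    n, alt, _ = _pop_site_arrays(gm, population)
    pi_site = _site_pi_vector(n, alt)
    out = []
    for ch in pd.unique(gm.chrom):
        sel = np.nonzero(gm.chrom == ch)[0]
        pos0 = gm.pos[sel] - 1
        w_start, rows = _window_index(pos0, spec)
        last = int(pos0.max()) if len(pos0) else 0
        all_starts = np.arange(0, last + 1, spec.step)
        idx = {s: k for k, s in enumerate(all_starts)}
        wi = np.array([idx[s] for s in w_start], dtype=np.intp)
        acc = np.zeros(len(all_starts))
        np.add.at(acc, wi, np.nan_to_num(pi_site[sel[rows]]))
        out.append(
            pd.DataFrame(
                {
                    "chrom": ch,
                    "start": all_starts,
                    "end": all_starts + spec.window_size,
                    "pi": acc / spec.window_size,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def windowed_fst(gm: GenotypeMatrix, spec: WindowSpec | None = None) -> pd.DataFrame:
    """Per-window ratio-of-sums WC84 FST (chrom, start, end, fst)."""
    t = window_divergence(gm, spec)
    return t[["chrom", "start", "end", "n_sites", "fst"]]


def log2_pi_ratio(pi_num: float, pi_den: float) -> float:
    """log2(pi_num / pi_den); NaN (unusable) when either pi is zero."""
    if pi_num < 0 or pi_den < 0:
        raise ValueError("pi values must be non-negative")
    if pi_num == 0.0 or pi_den == 0.0:
        return float("nan")
    return float(np.log2(pi_num / pi_den))
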