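"""Mixed-linear-model association scan (EMMAX-style).

Model per SNP:  y = X a + g b + u + e,  u ~ N(0, sg2 K),  e ~ N(0, se2 I)

* ``K`` is a centered-genotype relationship matrix (kinship) capturing the
  polygenic random effect.
* ``X`` holds the fixed effects: an intercept plus, by default, the top
  eigenvectors of K as population-structure covariates (a categorical
  population indicator is an alternative).
* The variance ratio lambda = se2 / sg2 is estimated once by REML on the
  null model (no SNP) through a single eigendecomposition of K and a 1-D
  search in log lambda, then held fixed for all SNP tests — the EMMAX
  approximation. An exact per-SNP refit is available for cross-checks.
* Each SNP is tested by generalized least squares under covariance
  sg2 (K + lambda I); the Wald statistic (b/se)^2 is referred to
  chi-square(1), two-sided.

SNPs with -log10(p) strictly greater than 4 are flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .io_genotypes import MISSING, GeneSet, GenotypeMatrix

logger = logging.getLogger(__name__)

SIGNIFICANCE_NEG_LOG10_P = 4.0  # strict: -log10(p) > 4


@dataclass
class Kinship:
    labels: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        w = np.linalg.eigvalsh(self.K)
        if w.min() < -1e-8 * max(1.0, abs(w.max())):
            raise ValueError("kinship matrix is not positive semi-definite")


@dataclass
class NullModelFit:
    """REML variance components of the no-SNP model."""

    sigma_g2: float
    sigma_e2: float
    lam: float            # sigma_e2 / sigma_g2
    loglik: float         # restricted log-likelihood at the optimum
    eigvals: np.ndarray   # eigenvalues of K (ascending)
    eigvecs: np.ndarray


@dataclass
class AssocResult:
    table: pd.DataFrame   # chrom, pos, beta, se, wald_p, neg_log10_p, significant
    null_fit: NullModelFit | None = None
    n_skipped: int = 0
    gene_column: bool = field(default=False)


def _imputed_dosage(gm: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with missing entries mean-imputed per site."""
    D = gm.dosage.astype(float)
    miss = gm.dosage == MISSING
    if miss.any():
        ok = ~miss
        denom = np.maximum(ok.sum(axis=1), 1)
        means = np.where(miss, 0.0, D).sum(axis=1) / denom
        D = np.where(miss, means[:, None], D)
    return D


def kinship_matrix(gm: GenotypeMatrix) -> Kinship:
    """Centered-genotype relationship matrix.

    K = (1/m) sum_sites (x - xbar)(x - xbar)^T over the m polymorphic
    sites, with missing dosages mean-imputed per site.
    """
    D = _imputed_dosage(gm)
    Z = D - D.mean(axis=1, keepdims=True)
    poly = (Z != 0).any(axis=1)
    m = int(poly.sum())
    if m == 0:
        raise ValueError("kinship undefined: no polymorphic sites")
    Z = Z[poly]
    return Kinship(list(gm.samples), (Z.T @ Z) / m)


def structure_covariates(gm_or_kin: GenotypeMatrix | Kinship, n_pc: int = 2) -> np.ndarray:
    """Fixed-effect design: intercept plus the top ``n_pc`` eigenvectors of
    the kinship matrix, sign-fixed so the largest-magnitude entry of each
    eigenvector is positive.
    """
    kin = gm_or_kin if isinstance(gm_or_kin, Kinship) else kinship_matrix(gm_or_kin)
    n = kin.K.shape[0]
    if n_pc >= n:
        raise ValueError("n_pc must be smaller than the sample count")
    cols = [np.ones(n)]
    if n_pc > 0:
        w, U = np.linalg.eigh(kin.K)
        for k in range(1, n_pc + 1):
            v = U[:, -k]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            cols.append(v)
    return np.column_stack(cols)


def _reml_neg_loglik(log_lam: float, w: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    lam = np.exp(log_lam)
    v = w + lam
    sw = 1.0 / np.sqrt(v)
    Xw = Xt * sw[:, None]
    yw = yt * sw
    n, p = Xt.shape
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    if rss <= 0:
        return np.inf
    sigma_g2 = rss / (n - p)
    _, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
    ll = -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma_g2) + 1.0)
        + np.log(v).sum()
        + logdet_xx
    )
    return -ll


def fit_null_lmm(y: np.ndarray, X: np.ndarray, kin: Kinship) -> NullModelFit:
    """REML fit of the variance ratio lambda = se2/sg2 on the null model.

    A coarse grid over log lambda in [log 1e-5, log 1e5] brackets the
    optimum; a bounded 1-D minimization refines it. Deterministic.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y) or kin.K.shape[0] != len(y):
        raise ValueError("y, X and K must be row-aligned")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design X is rank-deficient")
    w, U = np.linalg.eigh(kin.K)
    w = np.clip(w, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    grid = np.linspace(np.log(1e-5), np.log(1e5), 81)
    vals = np.array([_reml_neg_loglik(g, w, yt, Xt) for g in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(w, yt, Xt), method="bounded",
        options={"xatol": 1e-8},
    )
    log_lam = float(res.x) if res.fun <= vals[k] else float(grid[k])
    lam = float(np.exp(log_lam))

    v = w + lam
    sw = 1.0 / np.sqrt(v)
    Xw = Xt * sw[:, None]
    yw = yt * sw
    n, p = Xt.shape
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    sigma_g2 = rss / (n - p)
    return NullModelFit(
        sigma_g2=sigma_g2,
        sigma_e2=lam * sigma_g2,
        lam=lam,
        loglik=-_reml_neg_loglik(log_lam, w, yt, Xt),
        eigvals=w,
        eigvecs=U,
    )


def assoc_scan(
    gm: GenotypeMatrix,
    y: np.ndarray,
    X: np.ndarray | None = None,
    kin: Kinship | None = None,
    null_fit: NullModelFit | None = None,
    per_snp_reml: bool = False,
) -> AssocResult:
    """Per-SNP GLS association under the EMMAX approximation.

    ``y`` must be aligned with ``gm.samples`` (drop unphenotyped samples
    with :meth:`GenotypeMatrix.take_samples` first). Missing genotypes are
    mean-imputed; SNPs monomorphic among the scanned samples are skipped.
    ``per_snp_reml`` re-estimates lambda for every SNP (slow; for
    cross-checks on small panels).
    """
    y = np.asarray(y, dtype=float)
    kin = kin or kinship_matrix(gm)
    X = structure_covariates(kin) if X is None else np.atleast_2d(np.asarray(X, dtype=float))
    null_fit = null_fit or fit_null_lmm(y, X, kin)

    w, U = null_fit.eigvals, null_fit.eigvecs
    D = _imputed_dosage(gm)
    poly = D.std(axis=1) > 0
    n_skipped = int((~poly).sum())

    n, p = X.shape
    df = n - p - 1
    if df <= 0:
        raise ValueError("not enough samples for the design")

    yt = U.T @ y
    Xt = U.T @ X
    Gt = U.T @ D.T  # n x sites

    def gls_stats(lam: float, cols: np.ndarray):
        sw = 1.0 / np.sqrt(w + lam)
        Xw = Xt * sw[:, None]
        yw = yt * sw
        Gw = Gt * sw[:, None]
        Q, _ = np.linalg.qr(Xw)
        ry = yw - Q @ (Q.T @ yw)
        RG = Gw[:, cols] - Q @ (Q.T @ Gw[:, cols])
        gg = (RG**2).sum(axis=0)
        gy = RG.T @ ry
        yy = float(ry @ ry)
        return gg, gy, yy

    idx = np.nonzero(poly)[0]
    if per_snp_reml:
        betas, ses = np.empty(len(idx)), np.empty(len(idx))
        for k, s in enumerate(idx):
            fit_s = fit_null_lmm(y, np.column_stack([X, D[s]]), kin)
            gg, gy, yy = gls_stats(fit_s.lam, np.array([s]))
            b = gy[0] / gg[0]
            sigma2 = (yy - b * gy[0]) / df
            betas[k], ses[k] = b, np.sqrt(sigma2 / gg[0])
    else:
        gg, gy, yy = gls_stats(null_fit.lam, idx)
        usable = gg > 1e-12
        n_skipped += int((~usable).sum())
        idx = idx[usable]
        gg, gy = gg[usable], gy[usable]
        betas = gy / gg
        rss = yy - betas * gy
        sigma2 = rss / df
        ses = np.sqrt(sigma2 / gg)

    wald = (betas / ses) ** 2
    pvals = stats.chi2.sf(wald, df=1)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    nlp = -np.log10(pvals)
    table = pd.DataFrame(
        {
            "chrom": gm.chrom[idx],
            "pos": gm.pos[idx],
            "beta": betas,
            "se": ses,
            "wald_p": pvals,
            "neg_log10_p": nlp,
            "significant": nlp > SIGNIFICANCE_NEG_LOG10_P,
        }
    )
    if n_skipped:
        logger.info("assoc_scan: skipped %d monomorphic SNPs", n_skipped)
    return AssocResult(table=table, null_fit=null_fit, n_skipped=n_skipped)


def significant_snps(res: AssocResult) -> AssocResult:
    """SNPs with -log10(p) strictly greater than 4."""
    t = res.table
    return AssocResult(
        table=t.loc[t["neg_log10_p"] > SIGNIFICANCE_NEG_LOG10_P].reset_index(drop=True),
        null_fit=res.null_fit,
        n_skipped=res.n_skipped,
        gene_column=res.gene_column,
    )


def annotate_hits(res: AssocResult, genes: GeneSet, flank: int = 0) -> AssocResult:
    """Assign each SNP every gene whose (flank-extended) interval contains
    its position; SNPs outside all genes get an empty assignment.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for row in genes.table.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(
            max(row.start - flank, 0), row.end + flank, row.gene_id
        )
    assigned = []
    for row in res.table.itertuples():
        tree = trees.get(row.chrom)
        pos0 = row.pos - 1
        hits = sorted(iv.data for iv in tree.at(pos0)) if tree else []
        assigned.append(",".join(hits))
    out = res.table.copy()
    out["genes"] = assigned
    return AssocResult(table=out, null_fit=res.null_fit, n_skipped=res.n_skipped, gene_column=True)


def hit_genes(res: AssocResult) -> list[str]:
    """Deduplicated, sorted genes over significant, annotated SNPs."""
    if "genes" not in res.table.columns:
        raise ValueError("run annotate_hits first")
    sig = res.table.loc[res.table["significant"], "genes"]
    return sorted({g for cell in sig for g in cell.split(",") if g})
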