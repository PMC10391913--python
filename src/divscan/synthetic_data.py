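"""Two-population synthetic genotype, phenotype and expression data.

The generator emulates the study design every pipeline stage is tested
against: two diploid populations (default 32 + 32 individuals) diverged at
a controllable background level, with optional planted sweep regions,
distance-decaying linkage disequilibrium, and a continuous trait with
known causal SNPs.

Model summary
-------------
* Ancestral allele frequency per SNP: p ~ Uniform(0.05, 0.95).
* Population frequency: Balding-Nichols, q ~ Beta(p(1-F)/F, (1-p)(1-F)/F)
  with F the divergence coefficient — the parameter the Weir-Cockerham
  estimator targets.
* Sweep regions: inside a planted region both populations are drawn at an
  elevated F_local; the target population's frequency is then pushed
  toward the nearer boundary so that its per-site heterozygosity is
  divided exactly by the configured reduction factor.
* LD: haplotypes carry a latent uniform "frequency quantile" that
  persists from one site to the next with probability exp(-d / L), giving
  inter-site allele correlation exp(-d / L) (up to a frequency-mismatch
  factor) and hence approximately exponential r2 decay with length ~L.
* Phenotype: y = sum(effect * dosage) + polygenic term (variance fraction
  h2_background, covariance proportional to the kinship of the generated
  genotypes) + Gaussian noise. If ``causal_var_frac`` is set the noise is
  scaled so that the causal component explains exactly that fraction of
  the total variance; otherwise polygenic + noise have unit variance and
  causal effects act on top at face value.

All randomness flows from the mandatory seed; identical configs give
byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_genotypes import GenotypeMatrix

_BASES = "ACGT"


@dataclass(frozen=True)
class SweepRegion:
    chrom: str
    start: int                      # 0-based half-open bp
    end: int
    f_local: float
    diversity_reduction: float      # >= 1; target pop het divided by this
    target_pop: str                 # "a" or "b"


@dataclass
class SimConfig:
    """Study-condition defaults: 32 + 32 diploids, 5-kb-window-scale genome."""

    seed: int
    n_pop_a: int = 32
    n_pop_b: int = 32
    n_chrom_sim: int = 1
    chrom_length: int = 1_000_000
    snp_density: float = 0.006          # SNPs per bp (resequencing-panel scale)
    f_background: float = 0.10
    sweep_regions: tuple[SweepRegion, ...] = ()
    ld_decay_length: float = 20_000.0   # bp; 0 disables copy correlation
    causal_snps: tuple[tuple[int, float], ...] = ()  # (site index, effect)
    causal_var_frac: float | None = None
    h2_background: float = 0.0
    gene_spacing: int = 10_000
    gene_length: int = 3_000
    pop_a: str = "A"
    pop_b: str = "B"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 < self.f_background < 1.0:
            raise ValueError("f_background must be in (0, 1)")
        for r in self.sweep_regions:
            if not 0.0 < r.f_local < 1.0:
                raise ValueError("f_local must be in (0, 1)")
            if r.diversity_reduction < 1.0:
                raise ValueError("diversity_reduction must be >= 1")
            if r.target_pop not in ("a", "b"):
                raise ValueError("target_pop must be 'a' or 'b'")
        if not 0.0 <= self.h2_background < 1.0:
            raise ValueError("h2_background must be in [0, 1)")
        regs = sorted(
            (r for r in self.sweep_regions), key=lambda r: (r.chrom, r.start)
        )
        for r1, r2 in zip(regs, regs[1:]):
            if r1.chrom == r2.chrom and r2.start < r1.end:
                raise ValueError("sweep regions overlap")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{k + 1}" for k in range(self.n_chrom_sim)]


@dataclass
class GroundTruth:
    chrom: np.ndarray
    pos: np.ndarray                 # 1-based
    p_ancestral: np.ndarray
    freq_a: np.ndarray
    freq_b: np.ndarray
    sweep_regions: tuple[SweepRegion, ...]
    causal_snps: tuple[tuple[int, float], ...]
    f_background: float

    def in_sweep(self) -> np.ndarray:
        """Boolean per-site mask of membership in any planted region."""
        mask = np.zeros(len(self.pos), dtype=bool)
        for r in self.sweep_regions:
            mask |= (self.chrom == r.chrom) & (self.pos - 1 >= r.start) & (self.pos - 1 < r.end)
        return mask


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: np.ndarray) -> np.ndarray:
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def _reduce_het(q: np.ndarray, factor: float) -> np.ndarray:
    """Push frequencies toward the nearer boundary so q'(1-q') = q(1-q)/factor."""
    het = q * (1.0 - q) / factor
    low = 0.5 * (1.0 - np.sqrt(np.clip(1.0 - 4.0 * het, 0.0, 1.0)))
    return np.where(q <= 0.5, low, 1.0 - low)


def simulate_frequencies(cfg: SimConfig) -> GroundTruth:
    """Draw ancestral and population allele frequencies per SNP site."""
    rng = np.random.default_rng(cfg.seed)
    chroms, poss = [], []
    n_per = int(round(cfg.chrom_length * cfg.snp_density))
    for name in cfg.chrom_names:
        pos = np.sort(rng.choice(cfg.chrom_length, size=n_per, replace=False)) + 1
        chroms.append(np.full(n_per, name, dtype=object))
        poss.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)

    p = rng.uniform(0.05, 0.95, size=len(pos))
    F = np.full(len(pos), cfg.f_background)
    target_a = np.zeros(len(pos), dtype=bool)
    target_b = np.zeros(len(pos), dtype=bool)
    for r in cfg.sweep_regions:
        inside = (chrom == r.chrom) & (pos - 1 >= r.start) & (pos - 1 < r.end)
        F[inside] = r.f_local
        (target_a if r.target_pop == "a" else target_b)[inside] = True

    qa = _balding_nichols(rng, p, F)
    qb = _balding_nichols(rng, p, F)
    for r in cfg.sweep_regions:
        inside = (chrom == r.chrom) & (pos - 1 >= r.start) & (pos - 1 < r.end)
        if r.target_pop == "a":
            qa[inside] = _reduce_het(qa[inside], r.diversity_reduction)
        else:
            qb[inside] = _reduce_het(qb[inside], r.diversity_reduction)
    return GroundTruth(
        chrom=chrom, pos=pos, p_ancestral=p, freq_a=qa, freq_b=qb,
        sweep_regions=cfg.sweep_regions, causal_snps=cfg.causal_snps,
        f_background=cfg.f_background,
    )


def _haplotypes(
    rng: np.random.Generator,
    pos: np.ndarray,
    freq: np.ndarray,
    n_hap: int,
    decay: float,
) -> np.ndarray:
    """n_hap x sites boolean alleles with first-order copy correlation."""
    n_sites = len(pos)
    out = np.empty((n_hap, n_sites), dtype=bool)
    u = rng.random(n_hap)
    for k in range(n_sites):
        if k > 0:
            if decay > 0:
                keep_p = np.exp(-(pos[k] - pos[k - 1]) / decay)
            else:
                keep_p = 0.0
            redraw = rng.random(n_hap) >= keep_p
            u[redraw] = rng.random(int(redraw.sum()))
        out[:, k] = u < freq[k]
    return out


def simulate_genotypes(truth: GroundTruth, cfg: SimConfig) -> GenotypeMatrix:
    """Diploid dosages from population haplotypes (no missing calls)."""
    rng = np.random.default_rng(cfg.seed + 1)
    samples = [f"{cfg.pop_a}{i + 1:03d}" for i in range(cfg.n_pop_a)] + [
        f"{cfg.pop_b}{i + 1:03d}" for i in range(cfg.n_pop_b)
    ]
    pop_of = {s: (cfg.pop_a if s.startswith(cfg.pop_a) else cfg.pop_b) for s in samples}

    dosage = np.empty((len(truth.pos), len(samples)), dtype=np.int8)
    for name in pd.unique(truth.chrom):
        sel = np.nonzero(truth.chrom == name)[0]
        pos = truth.pos[sel]
        for freq, n_dip, col0 in (
            (truth.freq_a[sel], cfg.n_pop_a, 0),
            (truth.freq_b[sel], cfg.n_pop_b, cfg.n_pop_a),
        ):
            hap = _haplotypes(rng, pos, freq, 2 * n_dip, cfg.ld_decay_length)
            dos = hap[0::2].astype(np.int8) + hap[1::2].astype(np.int8)
            dosage[np.ix_(sel, np.arange(col0, col0 + n_dip))] = dos.T

    ref_idx = rng.integers(0, 4, size=len(truth.pos))
    alt_shift = rng.integers(1, 4, size=len(truth.pos))
    ref = np.array([_BASES[i] for i in ref_idx], dtype=object)
    alt = np.array([_BASES[(i + s) % 4] for i, s in zip(ref_idx, alt_shift)], dtype=object)
    return GenotypeMatrix(
        chrom=truth.chrom.copy(), pos=truth.pos.copy(),
        ref_allele=ref, alt_allele=alt, dosage=dosage,
        samples=samples, pop_of=pop_of,
    )


def simulate_phenotypes(
    gm: GenotypeMatrix, truth: GroundTruth, cfg: SimConfig
) -> pd.DataFrame:
    """Continuous trait table (sample, trait) with known genetic signal."""
    rng = np.random.default_rng(cfg.seed + 2)
    n = gm.n_samples
    g = np.zeros(n)
    for idx, eff in cfg.causal_snps:
        if not 0 <= idx < gm.n_sites:
            raise IndexError(f"causal site index {idx} out of range")
        g += eff * gm.dosage[idx].astype(float)
    g -= g.mean()
    var_c = float(g.var())

    if cfg.causal_snps and cfg.causal_var_frac is not None:
        if var_c <= 0:
            raise ValueError("causal SNPs are monomorphic; cannot scale variance")
        v_tot = var_c / cfg.causal_var_frac
        v_g = cfg.h2_background * v_tot
        v_e = v_tot - var_c - v_g
        if v_e <= 0:
            raise ValueError("causal_var_frac + h2_background leave no noise variance")
    else:
        v_g = cfg.h2_background
        v_e = 1.0 - cfg.h2_background

    u = np.zeros(n)
    if v_g > 0:
        from .gwas_lmm import kinship_matrix

        K = kinship_matrix(gm).K
        w, U = np.linalg.eigh(K)
        w = np.clip(w, 0.0, None)
        raw = U @ (np.sqrt(w) * rng.standard_normal(n))
        raw -= raw.mean()
        s = raw.std()
        if s > 0:
            u = raw * np.sqrt(v_g) / s

    e = rng.standard_normal(n) * np.sqrt(v_e)
    y = g + u + e
    return pd.DataFrame({"sample": gm.samples, "trait": y}).set_index("sample")


def _tiled_genes(cfg: SimConfig) -> pd.DataFrame:
    rec = []
    k = 0
    for name in cfg.chrom_names:
        for start in range(0, cfg.chrom_length - cfg.gene_length, cfg.gene_spacing):
            k += 1
            rec.append((f"gene{k:05d}", name, start, start + cfg.gene_length, "+"))
    return pd.DataFrame(rec, columns=["gene_id", "chrom", "start", "end", "strand"])


def _deg_table(cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic differential-expression table: genes inside planted sweep
    regions get strong fold changes; the background is null."""
    in_sweep = np.zeros(len(genes), dtype=bool)
    for r in cfg.sweep_regions:
        in_sweep |= (
            (genes["chrom"] == r.chrom)
            & (genes["start"] < r.end)
            & (genes["end"] > r.start)
        ).to_numpy()
    lfc = rng.normal(0.0, 0.5, size=len(genes))
    pv = rng.uniform(0.0, 1.0, size=len(genes))
    sign = np.where(rng.random(in_sweep.sum()) < 0.5, -1.0, 1.0)
    lfc[in_sweep] = sign * rng.uniform(2.5, 4.0, size=in_sweep.sum())
    pv[in_sweep] = rng.uniform(1e-6, 1e-3, size=in_sweep.sum())
    return pd.DataFrame({"gene": genes["gene_id"], "log2fc": lfc, "pvalue": np.clip(pv, 1e-300, 1.0)})


def write_vcf(gm: GenotypeMatrix, path: str | Path, chrom_length: int | None = None) -> None:
    """Minimal VCF 4.2 with GT only."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for ch in pd.unique(gm.chrom):
            length = chrom_length or int(gm.pos[gm.chrom == ch].max()) + 1
            fh.write(f"##contig=<ID={ch},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        for s in range(gm.n_sites):
            gts = "\t".join(gt_str[int(d)] for d in gm.dosage[s])
            fh.write(
                f"{gm.chrom[s]}\t{gm.pos[s]}\t.\t{gm.ref_allele[s]}\t{gm.alt_allele[s]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            # 0-based half-open back to GFF3 1-based closed
            fh.write(
                f"{row.chrom}\tdivscan_sim\tgene\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\tID={row.gene_id}\n"
            )


def write_fixture(outdir: str | Path, cfg: SimConfig) -> dict[str, Path]:
    """Generate and write a complete fixture set.

    Emits sim.vcf, genes.gff3, pops.tsv, pheno.tsv, deg.tsv and
    truth.json under ``outdir``; returns the paths keyed by kind.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_frequencies(cfg)
    gm = simulate_genotypes(truth, cfg)
    pheno = simulate_phenotypes(gm, truth, cfg)
    genes = _tiled_genes(cfg)
    rng = np.random.default_rng(cfg.seed + 3)
    deg = _deg_table(cfg, genes, rng)

    paths = {
        "vcf": outdir / "sim.vcf",
        "gff3": outdir / "genes.gff3",
        "pops": outdir / "pops.tsv",
        "pheno": outdir / "pheno.tsv",
        "deg": outdir / "deg.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(gm, paths["vcf"], chrom_length=cfg.chrom_length)
    write_gff3(genes, paths["gff3"])
    with open(paths["pops"], "w") as fh:
        for s in gm.samples:
            fh.write(f"{s}\t{gm.pop_of[s]}\n")
    pheno.reset_index().to_csv(paths["pheno"], sep="\t", index=False)
    deg.to_csv(paths["deg"], sep="\t", index=False)
    sidecar = {
        "f_background": truth.f_background,
        "sweep_regions": [asdict(r) for r in truth.sweep_regions],
        "causal_snps": [[int(i), float(e)] for i, e in truth.causal_snps],
        "chrom": truth.chrom.tolist(),
        "pos": truth.pos.tolist(),
        "p_ancestral": np.round(truth.p_ancestral, 6).tolist(),
        "freq_a": np.round(truth.freq_a, 6).tolist(),
        "freq_b": np.round(truth.freq_b, 6).tolist(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(sidecar, fh)
    return paths
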