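"""Genotype, annotation and phenotype input.

Reads biallelic SNP genotypes from VCF into a dosage matrix, applies the
hard site filters used for resequencing panels (missingness < 10 %,
MAF > 5 %, optional per-genotype depth >= 2), and loads gene annotation
(GFF3 or BED) and phenotype tables.

Internally all genomic intervals are 0-based half-open; VCF positions stay
1-based at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing diploid dosage

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages, sites x samples.

    ``dosage[s, i]`` is the count of alternate alleles (0, 1, 2) carried by
    sample ``i`` at site ``s``, or :data:`MISSING`. Positions are 1-based as
    in the source VCF and strictly increasing within each chromosome.
    """

    chrom: np.ndarray          # str per site
    pos: np.ndarray            # int, 1-based per site
    ref_allele: np.ndarray     # single-base str per site
    alt_allele: np.ndarray     # single-base str per site
    dosage: np.ndarray         # int8, sites x samples, MISSING allowed
    samples: list[str]
    pop_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError("dosage shape does not match sites x samples")
        ok = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or MISSING")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if self.pop_of:
            missing = [s for s in self.samples if s not in self.pop_of]
            if missing:
                raise KeyError(f"samples without population label: {missing}")

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in sorted order."""
        return sorted(set(self.pop_of.values()))

    def sample_indices(self, population: str) -> np.ndarray:
        """Column indices of the samples belonging to ``population``."""
        idx = np.array(
            [k for k, s in enumerate(self.samples) if self.pop_of.get(s) == population],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise KeyError(f"no samples in population {population!r}")
        return idx

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the selected sites (order preserved)."""
        return replace(
            self,
            chrom=self.chrom[mask_or_index],
            pos=self.pos[mask_or_index],
            ref_allele=self.ref_allele[mask_or_index],
            alt_allele=self.alt_allele[mask_or_index],
            dosage=self.dosage[mask_or_index],
        )

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        """New matrix restricted to the named samples (given order)."""
        lookup = {s: k for k, s in enumerate(self.samples)}
        try:
            cols = [lookup[s] for s in names]
        except KeyError as e:
            raise KeyError(f"unknown sample {e.args[0]!r}") from None
        return replace(
            self,
            dosage=self.dosage[:, cols],
            samples=list(names),
            pop_of={s: self.pop_of[s] for s in names} if self.pop_of else {},
        )


@dataclass(frozen=True)
class SiteFilterConfig:
    """Hard site filters: strict inequalities, as conventionally printed
    ("missing < 10 %", "MAF > 5 %"), so boundary sites are removed."""

    max_missing_frac: float = 0.10
    min_maf: float = 0.05
    min_depth: int = 2  # applied only when FORMAT/DP was present in the VCF

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class GeneSet:
    """Gene intervals, 0-based half-open, with unique identifiers."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        t = self.table
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene identifier: {dup}")
        if (t["start"] >= t["end"]).any():
            raise ValueError("gene intervals must satisfy start < end")

    def __len__(self) -> int:
        return len(self.table)


def read_pop_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``sample<TAB>population`` (no header)."""
    t = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    if t["sample"].duplicated().any():
        raise ValueError("duplicate sample in population map")
    return dict(zip(t["sample"], t["population"]))


def read_vcf(
    path: str | Path,
    pop_map: dict[str, str] | None = None,
    min_depth: int | None = None,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept; others are skipped with a logged
    count. Half-missing genotypes (e.g. ``0/.``) become MISSING; phased and
    unphased separators are equivalent. When ``min_depth`` is given and the
    record carries FORMAT/DP, genotypes supported by fewer than ``min_depth``
    reads are set to MISSING; VCFs without DP are unaffected.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if pop_map is not None:
        absent = [s for s in samples if s not in pop_map]
        if absent:
            raise KeyError(f"VCF samples absent from population map: {absent}")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if var.REF not in "ACGT" or var.ALT[0] not in "ACGT":
            n_skipped += 1
            continue
        gt = np.array([g[:2] for g in var.genotypes], dtype=np.int16)
        dos = gt.sum(axis=1).astype(np.int8)
        dos[(gt < 0).any(axis=1)] = MISSING
        if min_depth is not None and min_depth > 0:
            dp = var.format("DP")
            if dp is not None:
                dos[dp.reshape(-1) < min_depth] = MISSING
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(dos)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    dosage = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        dosage=dosage,
        samples=samples,
        pop_of=dict(pop_map) if pop_map else {},
    )


def minor_allele_freq(dosages: np.ndarray) -> float:
    """MAF from diploid dosages, ignoring MISSING entries.

    Returns ``min(p, 1 - p)`` with ``p`` the alternate-allele frequency over
    non-missing calls. All-missing input raises ``ValueError``.
    """
    d = np.asarray(dosages)
    ok = d != MISSING
    n = int(ok.sum())
    if n == 0:
        raise ValueError("MAF undefined: all calls missing")
    p = float(d[ok].sum()) / (2 * n)
    return min(p, 1.0 - p)


def site_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site missing fraction and MAF (vectorised over all sites)."""
    miss = gm.dosage == MISSING
    n_miss = miss.sum(axis=1)
    n_ok = gm.n_samples - n_miss
    alt = np.where(miss, 0, gm.dosage).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_ok > 0, alt / (2.0 * np.maximum(n_ok, 1)), np.nan)
    maf = np.minimum(p, 1.0 - p)
    return pd.DataFrame(
        {"missing_frac": n_miss / gm.n_samples, "maf": maf, "n_called": n_ok}
    )


def filter_sites(gm: GenotypeMatrix, cfg: SiteFilterConfig | None = None) -> GenotypeMatrix:
    """Keep sites with missing fraction < ``max_missing_frac`` and
    MAF > ``min_maf`` (both strict). Site order is preserved; removal
    counts per rule are logged. An all-removed result is returned (with a
    warning), not raised.
    """
    cfg = cfg or SiteFilterConfig()
    if gm.n_sites == 0:
        raise ValueError("filter_sites: empty genotype matrix")
    st = site_stats(gm)
    miss_ok = st["missing_frac"].to_numpy() < cfg.max_missing_frac
    maf = st["maf"].to_numpy()
    maf_ok = np.where(np.isnan(maf), False, maf > cfg.min_maf)
    keep = miss_ok & maf_ok
    logger.info(
        "filter_sites: %d/%d kept (%d failed missingness, %d failed MAF)",
        int(keep.sum()), gm.n_sites, int((~miss_ok).sum()), int((~maf_ok).sum()),
    )
    if not keep.any():
        logger.warning("filter_sites: all sites removed")
    return gm.take_sites(keep)


def _genes_from_gff3(path: Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    rec = []
    for g in db.features_of_type("gene"):
        # GFF3 is 1-based closed; store 0-based half-open
        rec.append((g.id, g.seqid, g.start - 1, g.end, g.strand or "."))
    return pd.DataFrame(rec, columns=["gene_id", "chrom", "start", "end", "strand"])


def _genes_from_bed(path: Path) -> pd.DataFrame:
    rec = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line with fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer BED coordinates") from None
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "."
            rec.append((name, parts[0], start, end, strand))
    return pd.DataFrame(rec, columns=["gene_id", "chrom", "start", "end", "strand"])


def read_genes(path: str | Path) -> GeneSet:
    """Load gene intervals from GFF3 (records of type ``gene``) or BED.

    GFF3 coordinates are converted from 1-based closed to 0-based half-open;
    BED is taken as-is. Duplicate gene identifiers raise.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"} or path.name.endswith((".gff.gz", ".gff3.gz")):
        table = _genes_from_gff3(path)
    else:
        table = _genes_from_bed(path)
    return GeneSet(table)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV with a header: ``sample`` column plus >= 1 trait column.

    Returns a DataFrame indexed by sample id; missing values allowed.
    """
    t = pd.read_csv(path, sep="\t")
    first = t.columns[0]
    t = t.rename(columns={first: "sample"}).set_index("sample")
    if t.shape[1] < 1:
        raise ValueError("phenotype table needs at least one trait column")
    if t.index.duplicated().any():
        raise ValueError("duplicate sample id in phenotype table")
    return t
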