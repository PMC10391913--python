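import numpy as np
import pytest
from hypothesis import settings

from divscan import GenotypeMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_gm(
    dosage,
    pos=None,
    chrom="chr1",
    samples=None,
    pops=None,
    ref=None,
    alt=None,
):
    """Build a GenotypeMatrix from a dosage array (sites x samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if pops is None:
        pops = {s: "A" for s in samples}
    elif isinstance(pops, (list, tuple)):
        pops = dict(zip(samples, pops))
    return GenotypeMatrix(
        chrom=np.full(n_sites, chrom, dtype=object) if isinstance(chrom, str) else np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        ref_allele=np.array(ref if ref is not None else ["A"] * n_sites, dtype=object),
        alt_allele=np.array(alt if alt is not None else ["C"] * n_sites, dtype=object),
        dosage=dosage,
        samples=list(samples),
        pop_of=pops,
    )


@pytest.fixture
def two_pop_gm():
    """Moderate two-population matrix with independent sites (F = 0.2)."""
    from divscan import SimConfig, simulate_frequencies, simulate_genotypes

    cfg = SimConfig(
        seed=42, n_pop_a=12, n_pop_b=12, chrom_length=100_000,
        snp_density=0.006, f_background=0.2, ld_decay_length=0,
    )
    truth = simulate_frequencies(cfg)
    return simulate_genotypes(truth, cfg)
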