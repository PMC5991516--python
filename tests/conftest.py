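import numpy as np
import pytest

from rhinopop.diversity import PopulationPanel
from rhinopop.simulate import SimConfig, simulate_split_genotypes
from rhinopop.variants import VariantTable

NAN = float("nan")


def build_table(samples, scaffold_lengths, rows):
    """Construct a VariantTable from per-record tuples
    (scaffold, pos, ref, alts, qual, ranksum_p, alt_support, genotypes)."""
    scaffolds, pos, ref, alts, qual, rp, ac, genos = [], [], [], [], [], [], [], []
    for r in rows:
        scaffolds.append(r[0])
        pos.append(r[1])
        ref.append(r[2])
        alts.append(tuple(r[3]) if not isinstance(r[3], str) else (r[3],))
        qual.append(r[4])
        rp.append(r[5])
        ac.append(r[6])
        genos.append(np.array(r[7], dtype=np.int8))
    genotypes = (
        np.stack(genos) if genos else np.zeros((0, len(samples), 2), dtype=np.int8)
    )
    return VariantTable(samples, scaffold_lengths, scaffolds, pos, ref, alts,
                        qual, rp, ac, genotypes)


def snp(scaffold, pos, genos, qual=50.0, rp=NAN, ac=NAN, ref="A", alt="T"):
    return (scaffold, pos, ref, (alt,), qual, rp, ac, genos)


def indel(scaffold, pos, genos, qual=50.0, rp=NAN, ac=NAN):
    return (scaffold, pos, "A", ("AT",), qual, rp, ac, genos)


@pytest.fixture(scope="session")
def small_sim():
    """A 1-Mbp two-population simulation with labelled filter violations."""
    config = SimConfig(scaffolds=(("scaffold_1", 1_000_000),), seed=11)
    table, truth = simulate_split_genotypes(config)
    return config, table, truth


@pytest.fixture(scope="session")
def small_panel(small_sim):
    config, table, _ = small_sim
    return PopulationPanel(
        {s: (config.pop1 if s.startswith(config.pop1) else config.pop2)
         for s in table.samples}
    )


def random_table(rng, n_samples=4, n_sites=30, length=150_000, missing_rate=0.0):
    """A random fully-genotyped biallelic SNP table for oracle comparisons."""
    samples = [f"s{i}" for i in range(n_samples)]
    pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_sites, replace=False))
    genotypes = rng.integers(0, 2, size=(n_sites, n_samples, 2)).astype(np.int8)
    if missing_rate:
        mask = rng.random((n_sites, n_samples)) < missing_rate
        genotypes[mask] = -1
    rows = [
        ("sc1", int(p), "A", ("G",), 50.0, NAN, NAN, genotypes[i])
        for i, p in enumerate(pos)
    ]
    return build_table(samples, {"sc1": length}, rows)
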