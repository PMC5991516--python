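"""Synthetic two-population variant data with known ground truth.

The genotype generator emulates the statistical structure of two diploid
populations (default 9 + 4 individuals, the northern/southern white
rhinoceros design) recently descended from a common ancestor:

* per segregating site an ancestral alternate-allele frequency ``p`` is drawn
  uniformly on a configurable range (default [0.05, 0.95]);
* each population's frequency is drawn from the Balding-Nichols beta
  distribution ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with differentiation
  coefficient ``F`` (``F = 0`` means both populations keep ``p`` exactly);
* diploid genotypes are binomial(2, f_pop) draws, unphased.

Because sites are independent, expectations are analytic: the per-site
heterozygosity of an individual is ``density * E[2f(1-f)] =
density * 2p(1-p)(1-F)`` averaged over the ancestral distribution, which the
generator inverts to hit a target heterozygosity (default 0.001/bp).

A fraction of records are indels and a labelled handful deliberately violate
each hard-filter rule, so the filtering stage is exactly checkable.  Known
autozygous tracts can be stamped into chosen samples for ROH recovery tests.
A separate single-population neutral coalescent simulator (exponential
coalescence times, infinite-sites Poisson mutations) provides windows with
known E[S] = theta * a1 for calibrating Tajima's D.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .variants import FILTER_RULES, VariantTable

__all__ = [
    "SimConfig",
    "TruthSet",
    "expected_het_per_site",
    "simulate_split_genotypes",
    "simulate_coalescent_window",
    "insert_roh_tracts",
    "write_gene_fixture",
]

_BASES = np.array(list("ACGT"))
_ISOLATION_BP = 26  # min distance to neighbours for indel / labelled sites


@dataclass
class SimConfig:
    """Parameters of the two-population genotype generator."""

    n_pop1: int = 9
    n_pop2: int = 4
    scaffolds: tuple[tuple[str, int], ...] = (("scaffold_1", 10_000_000),)
    target_het: float = 0.001  # expected per-site heterozygosity per bp
    seg_site_density: float | None = None  # derived from target_het when None
    divergence_f: float = 0.1  # Balding-Nichols differentiation in [0, 1)
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    indel_fraction: float = 0.01
    violation_fraction: float = 0.002  # labelled filter violations per rule
    roh_tracts: tuple[tuple[str, str, int, int], ...] = ()  # sample, scaffold, start, end (0-based half-open)
    pop1: str = "pop1"
    pop2: str = "pop2"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.divergence_f < 1):
            raise ValueError("divergence_f must be in [0, 1)")
        for v in (self.target_het, self.indel_fraction, self.violation_fraction):
            if v < 0:
                raise ValueError("densities and fractions must be >= 0")
        lengths = dict(self.scaffolds)
        for sample, scaffold, start, end in self.roh_tracts:
            if scaffold not in lengths or not (0 <= start < end <= lengths[scaffold]):
                raise ValueError(f"tract {(sample, scaffold, start, end)} outside scaffold bounds")

    @property
    def samples(self) -> list[str]:
        return [f"{self.pop1}_{i + 1}" for i in range(self.n_pop1)] + [
            f"{self.pop2}_{i + 1}" for i in range(self.n_pop2)
        ]

    @property
    def density(self) -> float:
        if self.seg_site_density is not None:
            return self.seg_site_density
        return self.target_het / expected_het_per_site(
            self.ancestral_range, self.divergence_f
        )


def expected_het_per_site(
    ancestral_range: tuple[float, float], divergence_f: float
) -> float:
    """E[2 f (1-f)] for f ~ Balding-Nichols around p ~ U(a, b).

    E[f] = p and E[f^2] = p^2 + F p(1-p), so E[2f(1-f)] = 2 p(1-p)(1-F);
    averaging over the uniform ancestral distribution is closed-form.
    """
    a, b = ancestral_range
    ep = (a + b) / 2.0
    ep2 = (b**3 - a**3) / (3.0 * (b - a))
    return 2.0 * (ep - ep2) * (1.0 - divergence_f)


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated table (record-aligned)."""

    seed: int
    divergence_f: float
    target_het: float
    ancestral_freq: np.ndarray  # per record; NaN for engineered extras
    pop_freqs: np.ndarray  # (n_records, 2); NaN for engineered extras
    roh_tracts: list[tuple[str, str, int, int]] = field(default_factory=list)
    filter_labels: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def expected_removals(self) -> dict[str, int]:
        return {rule: len(self.filter_labels.get(rule, [])) for rule in FILTER_RULES}

    def to_json(self, path: str) -> None:
        payload = {
            "seed": self.seed,
            "divergence_f": self.divergence_f,
            "target_het": self.target_het,
            "roh_tracts": [list(t) for t in self.roh_tracts],
            "filter_labels": {
                k: [[s, int(p)] for s, p in v] for k, v in self.filter_labels.items()
            },
            "n_records": int(len(self.ancestral_freq)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _draw_unique_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct 1-based positions, uniform over [1, length], sorted."""
    if n > length:
        raise ValueError("site density too high: positions collide")
    pool = np.unique(rng.integers(1, length + 1, size=int(n * 1.05) + 16))
    while pool.size < n:
        pool = np.unique(
            np.concatenate([pool, rng.integers(1, length + 1, size=n)])
        )
    return np.sort(rng.choice(pool, size=n, replace=False))


def simulate_split_genotypes(config: SimConfig) -> tuple[VariantTable, TruthSet]:
    """Simulate the two-population variant table and its ground truth."""
    rng = np.random.default_rng(config.seed)
    lengths = dict(config.scaffolds)
    samples = config.samples
    n_samples = len(samples)
    pop_of = np.array([0] * config.n_pop1 + [1] * config.n_pop2)
    a, b = config.ancestral_range
    F = config.divergence_f

    all_scaf: list[str] = []
    all_pos: list[int] = []
    all_ref: list[str] = []
    all_alts: list[tuple[str, ...]] = []
    all_qual: list[float] = []
    all_rp: list[float] = []
    all_ac: list[float] = []
    all_geno: list[np.ndarray] = []
    all_p: list[float] = []
    all_f: list[tuple[float, float]] = []
    labels: dict[str, list[tuple[str, int]]] = {r: [] for r in FILTER_RULES}

    def emit(scaffold, pos, ref, alts, qual, rp, ac, geno, p, fpair):
        all_scaf.append(scaffold)
        all_pos.append(int(pos))
        all_ref.append(ref)
        all_alts.append(alts)
        all_qual.append(qual)
        all_rp.append(rp)
        all_ac.append(ac)
        all_geno.append(geno)
        all_p.append(p)
        all_f.append(fpair)

    def draw_site(rng, is_indel: bool):
        """Alleles, frequencies and genotypes for one site."""
        p = rng.uniform(a, b)
        if F == 0:
            f1 = f2 = p
        else:
            alpha, beta = p * (1 - F) / F, (1 - p) * (1 - F) / F
            f1 = rng.beta(alpha, beta)
            f2 = rng.beta(alpha, beta)
        counts = rng.binomial(2, np.where(pop_of == 0, f1, f2))
        geno = np.stack([(counts == 2).astype(np.int8),
                         (counts >= 1).astype(np.int8)], axis=1)
        ref_base = str(rng.choice(_BASES))
        alt_base = str(rng.choice([x for x in _BASES if x != ref_base]))
        if not is_indel:
            ref, alt = ref_base, alt_base
        elif rng.random() < 0.5:
            ref, alt = ref_base, ref_base + alt_base  # insertion
        else:
            ref, alt = ref_base + alt_base, ref_base  # deletion
        qual = rng.uniform(20.0, 60.0)
        rp = rng.uniform(0.0, 1.0)
        ac = float(rng.poisson(2.5 * counts.sum()))
        return ref, (alt,), qual, rp, ac, geno, p, (f1, f2)

    for scaffold, length in config.scaffolds:
        n_sites = int(rng.poisson(config.density * length))
        if n_sites == 0:
            continue
        pos = _draw_unique_positions(rng, n_sites, length)

        gaps_ok = np.ones(n_sites, dtype=bool)
        gaps_ok[1:] &= np.diff(pos) >= _ISOLATION_BP
        gaps_ok[:-1] &= np.diff(pos) >= _ISOLATION_BP
        gaps_ok &= (pos > _ISOLATION_BP) & (pos < length - _ISOLATION_BP)
        isolated = np.nonzero(gaps_ok)[0]
        rng.shuffle(isolated)
        cursor = 0

        def take_isolated(k: int) -> np.ndarray:
            nonlocal cursor
            got = isolated[cursor:cursor + k]
            cursor += k
            return got

        n_indel = int(round(config.indel_fraction * n_sites))
        n_viol = int(round(config.violation_fraction * n_sites))
        indel_idx = set(take_isolated(n_indel).tolist())
        prox_indels = take_isolated(n_viol)      # rule 1: SNP added nearby
        cluster_indels = take_isolated(n_viol)   # rule 2: partner indel added
        lowq_idx = set(take_isolated(n_viol).tolist())     # rule 3
        ranksum_idx = set(take_isolated(n_viol).tolist())  # rule 4
        altsupp_idx = set(take_isolated(n_viol).tolist())  # rule 5
        indel_idx |= set(prox_indels.tolist()) | set(cluster_indels.tolist())

        for i in range(n_sites):
            ref, alts, qual, rp, ac, geno, p, fpair = draw_site(
                rng, is_indel=i in indel_idx
            )
            if i in lowq_idx:
                qual = rng.uniform(2.0, 9.5)
                labels["low_quality"].append((scaffold, int(pos[i])))
            elif i in ranksum_idx:
                qual = rng.uniform(10.5, 14.5)
                rp = rng.uniform(0.001, 0.09)
                labels["ranksum_bias"].append((scaffold, int(pos[i])))
            elif i in altsupp_idx:
                qual = rng.uniform(10.5, 14.5)
                rp = rng.uniform(0.2, 1.0)
                ac = float(rng.integers(0, 2))
                labels["low_alt_support"].append((scaffold, int(pos[i])))
            emit(scaffold, pos[i], ref, alts, qual, rp, ac, geno, p, fpair)

        # rule 1: a SNP 2 bp from an isolated indel
        for i in prox_indels:
            ref, alts, qual, rp, ac, geno, p, fpair = draw_site(rng, is_indel=False)
            emit(scaffold, pos[i] + 2, ref, alts, qual, rp, ac, geno, np.nan,
                 (np.nan, np.nan))
            labels["indel_proximity"].append((scaffold, int(pos[i]) + 2))
        # rule 2: a lower-quality partner indel 6 bp away
        for i in cluster_indels:
            ref, alts, _, _, ac, geno, p, fpair = draw_site(rng, is_indel=True)
            emit(scaffold, pos[i] + 6, ref, alts, 20.0, rng.uniform(0.2, 1.0),
                 ac, geno, np.nan, (np.nan, np.nan))
            labels["indel_cluster"].append((scaffold, int(pos[i]) + 6))
            all_qual[int(np.nonzero(
                (np.array(all_scaf, dtype=object) == scaffold)
                & (np.array(all_pos) == pos[i])
            )[0][0])] = 30.0  # the kept indel outranks its partner

    order = np.lexsort((np.array(all_pos), np.array(all_scaf, dtype=object).astype(str)))
    genotypes = (
        np.stack(all_geno)[order]
        if all_geno else np.zeros((0, n_samples, 2), dtype=np.int8)
    )
    table = VariantTable(
        samples,
        lengths,
        [all_scaf[i] for i in order],
        [all_pos[i] for i in order],
        [all_ref[i] for i in order],
        [all_alts[i] for i in order],
        [all_qual[i] for i in order],
        [all_rp[i] for i in order],
        [all_ac[i] for i in order],
        genotypes,
        sort=False,
    )
    truth = TruthSet(
        seed=config.seed,
        divergence_f=F,
        target_het=config.target_het,
        ancestral_freq=np.array(all_p)[order],
        pop_freqs=np.array(all_f)[order],
        filter_labels=labels,
    )
    if config.roh_tracts:
        table = insert_roh_tracts(table, config.roh_tracts, truth)
    return table, truth


def insert_roh_tracts(
    table: VariantTable,
    tracts: Sequence[tuple[str, str, int, int]],
    truth: TruthSet,
) -> VariantTable:
    """Force a sample homozygous inside each tract (0-based half-open coords).

    At heterozygous sites one of the two alleles is duplicated, chosen
    deterministically from the truth seed.  Overlapping tracts for one sample
    are merged with a warning.  Truth is updated in place.
    """
    # merge per (sample, scaffold)
    grouped: dict[tuple[str, str], list[list[int]]] = {}
    for sample, scaffold, start, end in tracts:
        ivs = grouped.setdefault((sample, scaffold), [])
        ivs.append([start, end])
    merged: list[tuple[str, str, int, int]] = []
    for (sample, scaffold), ivs in grouped.items():
        ivs.sort()
        acc = [ivs[0]]
        for s, e in ivs[1:]:
            if s <= acc[-1][1]:
                warnings.warn(
                    f"overlapping ROH tracts for {sample} on {scaffold}; merging"
                )
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged.extend((sample, scaffold, s, e) for s, e in acc)

    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x5EED]))
    genotypes = table.genotypes.copy()
    names = table.scaffolds.astype(str)
    for sample, scaffold, start, end in merged:
        j = table.sample_index(sample)
        sel = (names == scaffold) & (table.pos - 1 >= start) & (table.pos - 1 < end)
        for i in np.nonzero(sel)[0]:
            g = genotypes[i, j]
            if g[0] != g[1] and g[0] >= 0 and g[1] >= 0:
                keep = g[int(rng.integers(0, 2))]
                genotypes[i, j] = (keep, keep)
    truth.roh_tracts = list(merged)
    return VariantTable(
        table.samples, table.scaffold_lengths, table.scaffolds, table.pos,
        table.ref, table.alts, table.qual, table.ranksum_p, table.alt_support,
        genotypes, sort=False,
    )


def simulate_coalescent_window(
    n: int, theta: float, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """One neutral coalescent genealogy with infinite-sites mutations.

    While k > 1 lineages remain, an exponential waiting time with rate
    k(k-1)/2 elapses and a uniformly chosen pair merges; each branch then
    receives Poisson(theta/2 * length) mutations, each a new segregating
    column.  Returns an (n, S) 0/1 haplotype matrix (columns in random order
    of branch processing).  E[S] = theta * a1(n).
    """
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    lineages: list[tuple[frozenset[int], float]] = [
        (frozenset([i]), 0.0) for i in range(n)
    ]
    branches: list[tuple[frozenset[int], float]] = []
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False), reverse=True)
        leaves_i, birth_i = lineages.pop(int(i))
        leaves_j, birth_j = lineages.pop(int(j))
        branches.append((leaves_i, t - birth_i))
        branches.append((leaves_j, t - birth_j))
        lineages.append((leaves_i | leaves_j, t))
    cols: list[np.ndarray] = []
    for leaves, length in branches:
        for _ in range(int(rng.poisson(theta / 2.0 * length))):
            col = np.zeros(n, dtype=np.int8)
            col[list(leaves)] = 1
            cols.append(col)
    if not cols:
        return np.zeros((n, 0), dtype=np.int8)
    return np.stack(cols, axis=1)


def write_gene_fixture(
    scaffolds: Sequence[tuple[str, int]],
    n_genes: int,
    length_range: tuple[int, int] = (2_000, 20_000),
    seed: int | None = None,
    path: str | None = None,
) -> list[tuple[str, int, int, str]]:
    """Non-overlapping gene intervals (0-based half-open), optionally as BED.

    Genes are assigned to scaffolds proportionally to length; within a
    scaffold, gene starts are offset by sorted uniform draws over the free
    space, so intervals never overlap.  Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    lengths = [l for _, l in scaffolds]
    total = sum(lengths)
    if total == 0 and n_genes > 0:
        raise ValueError("no scaffold space for genes")
    assignment = rng.choice(
        len(scaffolds), size=n_genes, p=np.array(lengths) / total
    ) if n_genes else np.array([], dtype=int)
    out: list[tuple[str, int, int, str]] = []
    gene_no = 0
    for si, (scaffold, length) in enumerate(scaffolds):
        k = int((assignment == si).sum())
        if k == 0:
            continue
        glens = rng.integers(length_range[0], length_range[1] + 1, size=k)
        free = length - int(glens.sum())
        if free < 0:
            raise ValueError(
                f"cannot pack {k} genes totalling {glens.sum()} bp into "
                f"{scaffold} ({length} bp)"
            )
        offsets = np.sort(rng.integers(0, free + 1, size=k))
        start = 0
        prev_total = 0
        for g in range(k):
            start = int(offsets[g]) + prev_total
            end = start + int(glens[g])
            gene_no += 1
            out.append((scaffold, start, end, f"gene_{gene_no}"))
            prev_total += int(glens[g])
    if path is not None:
        with open(path, "w") as fh:
            for scaffold, start, end, gid in out:
                fh.write(f"{scaffold}\t{start}\t{end}\t{gid}\n")
    return out
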