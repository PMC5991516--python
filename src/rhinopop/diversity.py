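"""Per-individual heterozygosity, d_xy, SNP partitioning, joint SFS, LD thinning.

All statistics operate on a :class:`~rhinopop.variants.VariantTable` plus a
two-population sample panel.  Sites absent from the table are treated as
homozygous-reference, so proportions are taken over a callable genome length
supplied by the caller (defaulting to the total scaffold length), not over the
number of table records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import MISSING, VariantTable

__all__ = [
    "PopulationPanel",
    "HeterozygosityResult",
    "DivergenceResult",
    "SNPPartition",
    "SFS2D",
    "individual_heterozygosity",
    "pairwise_divergence",
    "partition_snps",
    "joint_sfs",
    "ld_thin",
]


@dataclass
class PopulationPanel:
    """Sample -> population assignment (two populations for cross-population
    statistics, e.g. northern vs southern white rhinoceros)."""

    assignments: dict[str, str]
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for p in self.assignments.values():
            if p not in seen:
                seen.append(p)
        if not self.populations:
            self.populations = seen
        missing = set(seen) - set(self.populations)
        if missing:
            raise ValueError(f"assignments use unlisted populations {sorted(missing)}")
        for p in self.populations:
            if not self.members(p):
                raise ValueError(f"population {p!r} has no samples")

    def members(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def require_two(self) -> tuple[str, str]:
        if len(self.populations) != 2:
            raise ValueError(
                f"exactly two populations required, got {self.populations}"
            )
        return self.populations[0], self.populations[1]

    def indices(self, table: VariantTable, population: str) -> list[int]:
        return [table.sample_index(s) for s in self.members(population)]

    @classmethod
    def from_tsv(cls, path: str) -> "PopulationPanel":
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["sample", "population"], dtype=str)
        return cls(dict(zip(df["sample"], df["population"])))

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for s, p in self.assignments.items():
                fh.write(f"{s}\t{p}\n")


@dataclass
class HeterozygosityResult:
    per_sample: dict[str, float]
    denominator_bp: dict[str, int]
    population_means: dict[str, float]

    def to_tsv(self, path: str, panel: PopulationPanel | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tpopulation\theterozygosity\tdenominator_bp\n")
            for s, v in self.per_sample.items():
                pop = panel.assignments.get(s, ".") if panel else "."
                fh.write(f"{s}\t{pop}\t{v:.6g}\t{self.denominator_bp[s]}\n")


@dataclass
class DivergenceResult:
    dxy: float
    n_pairs: int


@dataclass
class SNPPartition:
    """Disjoint classification of biallelic sites by the two populations'
    alternate-allele frequencies.  ``fixed_one_polymorphic_other`` holds sites
    fixed for the alternate in one population while still segregating in the
    other, so the categories are collectively exhaustive over classified
    sites."""

    shared_polymorphic: int
    fixed_both: int
    unique: dict[str, int]
    fixed_one_polymorphic_other: int
    invariant_total: int
    skipped: int  # all-missing in a population, or multiallelic

    @property
    def total_classified(self) -> int:
        return (
            self.shared_polymorphic + self.fixed_both
            + sum(self.unique.values())
            + self.fixed_one_polymorphic_other + self.invariant_total
        )

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\n")
            fh.write(f"shared_polymorphic\t{self.shared_polymorphic}\n")
            fh.write(f"fixed_both\t{self.fixed_both}\n")
            for pop, n in self.unique.items():
                fh.write(f"unique_{pop}\t{n}\n")
            fh.write(f"fixed_one_polymorphic_other\t{self.fixed_one_polymorphic_other}\n")
            fh.write(f"invariant\t{self.invariant_total}\n")
            fh.write(f"skipped\t{self.skipped}\n")


@dataclass
class SFS2D:
    """Joint (two-dimensional) site-frequency spectrum.

    ``counts[i, j]`` is the number of sites carrying exactly ``i`` alternate
    alleles among the ``2*n1`` population-1 alleles and ``j`` among the
    ``2*n2`` population-2 alleles.
    """

    counts: np.ndarray
    n1: int
    n2: int
    pop1: str
    pop2: str
    n_skipped: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def marginal(self, which: int) -> np.ndarray:
        return self.counts.sum(axis=1 if which == 1 else 0)

    def folded(self) -> np.ndarray:
        """Fold by total minor allele across both populations."""
        c = self.counts.astype(float)
        out = np.zeros_like(c)
        tot = 2 * self.n1 + 2 * self.n2
        for i in range(c.shape[0]):
            for j in range(c.shape[1]):
                ri, rj = 2 * self.n1 - i, 2 * self.n2 - j
                if i + j < tot - (i + j):
                    out[i, j] = c[i, j] + c[ri, rj]
                elif i + j == tot - (i + j):
                    out[i, j] = c[i, j]
        return out

    def to_dadi(self, path: str) -> None:
        """Plain-text spectrum layout readable by dadi (corners masked)."""
        shape = self.counts.shape
        mask = np.zeros(shape, dtype=int)
        mask[0, 0] = mask[-1, -1] = 1
        with open(path, "w") as fh:
            fh.write(f"{shape[0]} {shape[1]} unfolded \"{self.pop1}\" \"{self.pop2}\"\n")
            fh.write(" ".join(str(int(v)) for v in self.counts.ravel()) + "\n")
            fh.write(" ".join(str(v) for v in mask.ravel()) + "\n")


# -- operations ---------------------------------------------------------------


def _denominators(
    table: VariantTable,
    denominator_bp: int | Mapping[str, int] | None,
) -> dict[str, int]:
    if denominator_bp is None:
        denominator_bp = sum(table.scaffold_lengths.values())
    if isinstance(denominator_bp, Mapping):
        out = {s: int(denominator_bp[s]) for s in table.samples}
    else:
        out = {s: int(denominator_bp) for s in table.samples}
    for s, d in out.items():
        if d <= 0:
            raise ValueError(f"denominator for {s} must be > 0")
    return out


def individual_heterozygosity(
    table: VariantTable,
    denominator_bp: int | Mapping[str, int] | None = None,
    panel: PopulationPanel | None = None,
) -> HeterozygosityResult:
    """Proportion of heterozygous sites per individual.

    The denominator is the callable genome length (global, per-sample, or the
    total scaffold length by default); sites absent from the table count as
    homozygous-reference.
    """
    denoms = _denominators(table, denominator_bp)
    het = table.het_mask().sum(axis=0)
    per_sample: dict[str, float] = {}
    for j, s in enumerate(table.samples):
        if het[j] > denoms[s]:
            raise ValueError(
                f"denominator {denoms[s]} smaller than het count {het[j]} for {s}"
            )
        per_sample[s] = het[j] / denoms[s]
    means: dict[str, float] = {}
    if panel is not None:
        for pop in panel.populations:
            vals = [per_sample[s] for s in panel.members(pop) if s in per_sample]
            means[pop] = float(np.mean(vals)) if vals else float("nan")
    return HeterozygosityResult(per_sample, denoms, means)


def pairwise_divergence(
    table: VariantTable,
    panel: PopulationPanel,
    denominator_bp: int | None = None,
) -> DivergenceResult:
    """Mean cross-population d_xy per callable bp.

    Each diploid genotype is treated as an allele frequency (0, 1/2, 1) and a
    site contributes ``p1*(1-p2) + p2*(1-p1)`` to a pair's difference count;
    sites missing in either member of a pair are excluded for that pair.
    """
    pop1, pop2 = panel.require_two()
    if denominator_bp is None:
        denominator_bp = sum(table.scaffold_lengths.values())
    if denominator_bp <= 0:
        raise ValueError("denominator_bp must be > 0")
    i1 = panel.indices(table, pop1)
    i2 = panel.indices(table, pop2)
    d = table.dosage() / 2.0  # per-sample allele frequency, NaN = missing
    total = 0.0
    n_pairs = 0
    for a in i1:
        pa = d[:, a]
        for b in i2:
            pb = d[:, b]
            diff = pa * (1 - pb) + pb * (1 - pa)
            total += np.nansum(diff) / denominator_bp
            n_pairs += 1
    return DivergenceResult(dxy=total / n_pairs, n_pairs=n_pairs)


def _pop_alt_freqs(
    table: VariantTable, indices: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """(alt frequency, observed allele count) per site over non-missing
    alleles of the given samples; frequency NaN where no alleles observed."""
    g = table.genotypes[:, indices, :]
    obs = (g != MISSING).sum(axis=(1, 2))
    alt = (g > 0).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(obs > 0, alt / np.maximum(obs, 1), np.nan)
    return f, obs


def partition_snps(table: VariantTable, panel: PopulationPanel) -> SNPPartition:
    """Classify biallelic sites by both populations' alt-allele frequencies."""
    pop1, pop2 = panel.require_two()
    f1, obs1 = _pop_alt_freqs(table, panel.indices(table, pop1))
    f2, obs2 = _pop_alt_freqs(table, panel.indices(table, pop2))
    usable = table.is_biallelic & (obs1 > 0) & (obs2 > 0)
    skipped = int(table.n_records - usable.sum())
    f1, f2 = f1[usable], f2[usable]

    poly1 = (f1 > 0) & (f1 < 1)
    poly2 = (f2 > 0) & (f2 < 1)
    fixed1 = f1 == 1
    fixed2 = f2 == 1
    absent1 = f1 == 0
    absent2 = f2 == 0

    return SNPPartition(
        shared_polymorphic=int((poly1 & poly2).sum()),
        fixed_both=int((fixed1 & fixed2).sum()),
        unique={
            pop1: int(((f1 > 0) & absent2).sum()),
            pop2: int(((f2 > 0) & absent1).sum()),
        },
        fixed_one_polymorphic_other=int(
            ((fixed1 & poly2) | (fixed2 & poly1)).sum()
        ),
        invariant_total=int((absent1 & absent2).sum()),
        skipped=skipped,
    )


def joint_sfs(
    table: VariantTable,
    panel: PopulationPanel,
    subset: Sequence[str] | None = None,
) -> SFS2D:
    """Joint SFS over the given sample subset (default: all panel samples).

    Sites with any missing genotype in the subset, and multiallelic sites,
    are excluded and counted in ``n_skipped``.  The spectrum is polarized on
    the reference/alternate axis; use :meth:`SFS2D.folded` for the
    minor-allele version.
    """
    pop1, pop2 = panel.require_two()
    if subset is None:
        subset = [s for s in table.samples if s in panel.assignments]
    for s in subset:
        if s not in panel.assignments:
            raise KeyError(f"subset sample {s!r} not in panel")
    s1 = [s for s in subset if panel.assignments[s] == pop1]
    s2 = [s for s in subset if panel.assignments[s] == pop2]
    i1 = [table.sample_index(s) for s in s1]
    i2 = [table.sample_index(s) for s in s2]
    n1, n2 = len(i1), len(i2)
    if n1 == 0 or n2 == 0:
        raise ValueError("subset must contain samples from both populations")

    g1 = table.genotypes[:, i1, :]
    g2 = table.genotypes[:, i2, :]
    complete = (
        (g1 != MISSING).all(axis=(1, 2))
        & (g2 != MISSING).all(axis=(1, 2))
        & table.is_biallelic
    )
    i = (g1 > 0).sum(axis=(1, 2))[complete]
    j = (g2 > 0).sum(axis=(1, 2))[complete]
    counts = np.zeros((2 * n1 + 1, 2 * n2 + 1), dtype=np.int64)
    np.add.at(counts, (i, j), 1)
    return SFS2D(
        counts=counts, n1=n1, n2=n2, pop1=pop1, pop2=pop2,
        n_skipped=int(table.n_records - complete.sum()),
    )


def _r2(dosage: np.ndarray, a: int, b: int) -> float:
    """Squared Pearson correlation of two dosage columns over
    pairwise-complete samples; 0 when either is monomorphic."""
    x, y = dosage[a], dosage[b]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2:
        return 0.0
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return 0.0
    c = np.mean((x - x.mean()) * (y - y.mean()))
    return float(c * c / (vx * vy))


def ld_thin(
    table: VariantTable,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.1,
) -> VariantTable:
    """Greedy LD thinning: per scaffold, slide a ``window_snps``-SNP window
    ``step_snps`` SNPs at a time; within each window remove the later SNP of
    any surviving pair with dosage r^2 above ``r2_max``."""
    if not (window_snps > step_snps > 0):
        raise ValueError("require window_snps > step_snps > 0")
    dosage = table.dosage()  # (n_sites, n_samples): one row per SNP
    removed = np.zeros(table.n_records, dtype=bool)
    for sl in table.scaffold_slices().values():
        m = sl.stop - sl.start
        start = 0
        while True:
            win = range(sl.start + start, sl.start + min(start + window_snps, m))
            alive = [i for i in win if not removed[i]]
            for ai, a in enumerate(alive):
                if removed[a]:
                    continue
                for b in alive[ai + 1:]:
                    if removed[b]:
                        continue
                    if _r2(dosage, a, b) > r2_max:
                        removed[b] = True
            if start + window_snps >= m:
                break
            start += step_snps
    return table.take(~removed)
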