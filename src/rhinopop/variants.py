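"""Multi-sample variant container, VCF I/O and hard filtering.

The filtering stage reproduces the five hard-filter rules commonly applied to
``bcftools``-style multiallelic calls from low/medium-coverage mammalian
genomes:

1. non-indel variants within a fixed distance (default 3 bp) of an indel;
2. clusters of indels separated by <= 10 bp, keeping a single indel per
   cluster;
3. site quality below 10;
4. rank-sum (Mann-Whitney U) bias p-value below 0.1 at quality below 15;
5. fewer than 2 high-quality alternate-supporting observations at quality
   below 15.

A record that matches several rules is attributed to the first matching rule
so that removal counts are deterministic and conserve the input total.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pysam

__all__ = [
    "VariantRecord",
    "VariantTable",
    "FilterConfig",
    "FilterReport",
    "FILTER_RULES",
    "read_variants",
    "write_variants",
    "flag_indel_proximity",
    "collapse_indel_clusters",
    "apply_filters",
]

#: rule identifiers, in application order
FILTER_RULES = (
    "indel_proximity",
    "indel_cluster",
    "low_quality",
    "ranksum_bias",
    "low_alt_support",
)

MISSING = -1  # genotype allele code for "."


@dataclass(frozen=True)
class VariantRecord:
    """A read-only per-site view onto a :class:`VariantTable` row."""

    scaffold: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qual: float  # NaN when absent
    ranksum_p: float  # NaN when absent
    alt_support: float  # NaN when absent
    is_indel: bool
    genotypes: np.ndarray  # (n_samples, 2) int8, -1 = missing


class VariantTable:
    """Sites x individuals genotype matrix with per-site metadata.

    Genotypes are stored as an ``(n_sites, n_samples, 2)`` ``int8`` array of
    allele indices (0 = ref, 1.. = alt, -1 = missing).  Per-site annotations
    that may be absent (qual, rank-sum p, alt support) use NaN for absence so
    that "missing" is never conflated with 0.  Records are kept sorted by
    (scaffold, pos).
    """

    def __init__(
        self,
        samples: Sequence[str],
        scaffold_lengths: Mapping[str, int],
        scaffolds: Sequence[str],
        pos: Sequence[int],
        ref: Sequence[str],
        alts: Sequence[tuple[str, ...]],
        qual: Sequence[float],
        ranksum_p: Sequence[float],
        alt_support: Sequence[float],
        genotypes: np.ndarray,
        *,
        sort: bool = True,
    ) -> None:
        self.samples = list(samples)
        self.scaffold_lengths = dict(scaffold_lengths)
        self.scaffolds = np.asarray(scaffolds, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alts = [tuple(a) for a in alts]
        self.qual = np.asarray(qual, dtype=np.float64)
        self.ranksum_p = np.asarray(ranksum_p, dtype=np.float64)
        self.alt_support = np.asarray(alt_support, dtype=np.float64)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        n = len(self.pos)
        if self.genotypes.shape != (n, len(self.samples), 2):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{n} records x {len(self.samples)} samples x 2"
            )
        if n and self.pos.min() < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        if sort:
            self._sort_in_place()
        self.is_indel = self._compute_is_indel()

    # -- construction helpers -------------------------------------------------

    def _sort_in_place(self) -> None:
        order = np.lexsort((self.pos, self.scaffolds.astype(str)))
        if np.array_equal(order, np.arange(len(order))):
            return
        self.scaffolds = self.scaffolds[order]
        self.pos = self.pos[order]
        self.ref = self.ref[order]
        self.alts = [self.alts[i] for i in order]
        self.qual = self.qual[order]
        self.ranksum_p = self.ranksum_p[order]
        self.alt_support = self.alt_support[order]
        self.genotypes = self.genotypes[order]

    def _compute_is_indel(self) -> np.ndarray:
        out = np.zeros(len(self.pos), dtype=bool)
        for i, (r, alts) in enumerate(zip(self.ref, self.alts)):
            out[i] = len(r) != 1 or any(len(a) != 1 for a in alts)
        return out

    # -- basic API ------------------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __len__(self) -> int:
        return self.n_records

    def record(self, i: int) -> VariantRecord:
        return VariantRecord(
            scaffold=str(self.scaffolds[i]),
            pos=int(self.pos[i]),
            ref_allele=str(self.ref[i]),
            alt_alleles=self.alts[i],
            qual=float(self.qual[i]),
            ranksum_p=float(self.ranksum_p[i]),
            alt_support=float(self.alt_support[i]),
            is_indel=bool(self.is_indel[i]),
            genotypes=self.genotypes[i],
        )

    def __iter__(self) -> Iterator[VariantRecord]:
        return (self.record(i) for i in range(self.n_records))

    def take(self, indices: np.ndarray) -> "VariantTable":
        """Subset records (boolean mask or index array), preserving order."""
        idx = np.asarray(indices)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return VariantTable(
            self.samples,
            self.scaffold_lengths,
            self.scaffolds[idx],
            self.pos[idx],
            self.ref[idx],
            [self.alts[i] for i in idx],
            self.qual[idx],
            self.ranksum_p[idx],
            self.alt_support[idx],
            self.genotypes[idx],
            sort=False,
        )

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    @property
    def is_biallelic(self) -> np.ndarray:
        return np.array([len(a) == 1 for a in self.alts], dtype=bool)

    def dosage(self, sample_indices: Sequence[int] | None = None) -> np.ndarray:
        """Alt-dosage matrix (n_sites, k) as float, NaN where any allele missing.

        Any non-reference allele counts toward the dosage (for biallelic
        records this is the usual 0/1/2 coding).
        """
        g = self.genotypes if sample_indices is None else self.genotypes[:, sample_indices, :]
        d = (g > 0).sum(axis=2).astype(float)
        d[(g == MISSING).any(axis=2)] = np.nan
        return d

    def het_mask(self) -> np.ndarray:
        """Boolean (n_sites, n_samples): two distinct non-missing alleles."""
        g = self.genotypes
        return (g[:, :, 0] != g[:, :, 1]) & (g != MISSING).all(axis=2)

    def scaffold_slices(self) -> dict[str, slice]:
        """Contiguous record slice per scaffold (table is sorted)."""
        out: dict[str, slice] = {}
        if self.n_records == 0:
            return out
        names = self.scaffolds.astype(str)
        change = np.nonzero(names[1:] != names[:-1])[0] + 1
        bounds = [0, *change.tolist(), self.n_records]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            out[names[lo]] = slice(lo, hi)
        return out

    def equals(self, other: "VariantTable", *, float_rtol: float = 1e-5) -> bool:
        """Field-wise equality; float annotations compared with tolerance
        (VCF INFO floats round-trip through 32-bit storage)."""

        def close(a, b):
            return np.allclose(a, b, rtol=float_rtol, atol=1e-8, equal_nan=True)

        return (
            self.samples == other.samples
            and self.scaffold_lengths == other.scaffold_lengths
            and np.array_equal(self.scaffolds, other.scaffolds)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and self.alts == other.alts
            and close(self.qual, other.qual)
            and close(self.ranksum_p, other.ranksum_p)
            and close(self.alt_support, other.alt_support)
            and np.array_equal(self.genotypes, other.genotypes)
        )


# -- VCF I/O ------------------------------------------------------------------


def read_variants(
    path: str,
    *,
    scaffold_lengths: Mapping[str, int] | None = None,
    ranksum_key: str = "RPB",
    alt_support_key: str = "ANC",
) -> VariantTable:
    """Read a VCF (plain or bgzipped) into a :class:`VariantTable`.

    ``ranksum_key`` and ``alt_support_key`` name the INFO fields carrying the
    rank-sum bias p-value and the alternate-support count; absent fields are
    stored as NaN, never as 0.  Contig lengths are taken from the header
    unless ``scaffold_lengths`` is supplied.
    """
    scaffolds: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alts: list[tuple[str, ...]] = []
    qual: list[float] = []
    ranksum: list[float] = []
    support: list[float] = []
    genos: list[np.ndarray] = []

    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        if scaffold_lengths is None:
            scaffold_lengths = {
                name: contig.length
                for name, contig in vf.header.contigs.items()
                if contig.length is not None
            }
        for rec in vf:
            scaffolds.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref if rec.ref is not None else "N")
            alts.append(tuple(rec.alts) if rec.alts else ())
            qual.append(rec.qual if rec.qual is not None else np.nan)
            rp = rec.info.get(ranksum_key)
            ranksum.append(float(rp) if rp is not None else np.nan)
            ac = rec.info.get(alt_support_key)
            support.append(float(ac) if ac is not None else np.nan)
            row = np.full((len(samples), 2), MISSING, dtype=np.int8)
            for j, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None:
                    continue
                if len(gt) != 2:
                    raise ValueError(
                        f"non-diploid genotype for sample {s} at {rec.chrom}:{rec.pos}"
                    )
                for k, allele in enumerate(gt):
                    row[j, k] = MISSING if allele is None else allele
            genos.append(row)

    n = len(pos)
    genotypes = (
        np.stack(genos) if n else np.zeros((0, len(samples), 2), dtype=np.int8)
    )
    return VariantTable(
        samples, scaffold_lengths, scaffolds, pos, ref, alts,
        qual, ranksum, support, genotypes,
    )


def write_variants(
    table: VariantTable,
    path: str,
    *,
    ranksum_key: str = "RPB",
    alt_support_key: str = "ANC",
) -> None:
    """Write a table as VCF v4.2; re-reading reproduces all modeled fields."""
    header = pysam.VariantHeader()
    for name, length in table.scaffold_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add(ranksum_key, 1, "Float", "Rank-sum (Mann-Whitney U) bias p-value")
    header.info.add(alt_support_key, 1, "Integer",
                    "High-quality alternate-supporting observation count")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in table.samples:
        header.add_sample(s)

    with pysam.VariantFile(path, "w", header=header) as out:
        for i in range(table.n_records):
            rec = out.new_record(
                contig=str(table.scaffolds[i]),
                start=int(table.pos[i]) - 1,
                alleles=(str(table.ref[i]), *table.alts[i]),
            )
            if not np.isnan(table.qual[i]):
                rec.qual = float(table.qual[i])
            if not np.isnan(table.ranksum_p[i]):
                rec.info[ranksum_key] = float(table.ranksum_p[i])
            if not np.isnan(table.alt_support[i]):
                rec.info[alt_support_key] = int(table.alt_support[i])
            for j, s in enumerate(table.samples):
                g = table.genotypes[i, j]
                rec.samples[s]["GT"] = tuple(
                    None if a == MISSING else int(a) for a in g
                )
                rec.samples[s].phased = False
            out.write(rec)


# -- filtering ----------------------------------------------------------------


@dataclass
class FilterConfig:
    """Thresholds for the five hard-filter rules (all inclusive of defaults
    used for bcftools-style calls)."""

    indel_proximity_bp: int = 3
    indel_cluster_gap_bp: int = 10
    qual_min: float = 10.0
    ranksum_p_max: float = 0.1
    qual_ranksum: float = 15.0
    min_alt_count: int = 2
    qual_altcount: float = 15.0
    #: INFO keys consumed by read_variants when this config drives a pipeline
    ranksum_key: str = "RPB"
    alt_support_key: str = "ANC"

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")


@dataclass
class FilterReport:
    removed_by_rule: dict[str, int]
    n_input: int
    n_passed: int

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("rule\tcount\n")
            for rule in FILTER_RULES:
                fh.write(f"{rule}\t{self.removed_by_rule.get(rule, 0)}\n")
            fh.write(f"input\t{self.n_input}\n")
            fh.write(f"passed\t{self.n_passed}\n")


def flag_indel_proximity(table: VariantTable, window: int) -> set[int]:
    """Indices of non-indel records within ``window`` bp (inclusive) of any
    indel on the same scaffold.  Indels themselves are never flagged."""
    if window < 0:
        raise ValueError("window must be >= 0")
    flagged: set[int] = set()
    for sl in table.scaffold_slices().values():
        idx = np.arange(sl.start, sl.stop)
        indel = table.is_indel[sl]
        ipos = table.pos[sl][indel]
        if ipos.size == 0:
            continue
        spos = table.pos[sl][~indel]
        sidx = idx[~indel]
        # distance to the nearest indel via the sorted indel positions
        right = np.searchsorted(ipos, spos)
        left = np.clip(right - 1, 0, ipos.size - 1)
        right = np.clip(right, 0, ipos.size - 1)
        dist = np.minimum(
            np.abs(spos - ipos[left]), np.abs(ipos[right] - spos)
        )
        flagged.update(sidx[dist <= window].tolist())
    return flagged


def collapse_indel_clusters(table: VariantTable, gap: int) -> set[int]:
    """Indices of surplus indels in clusters of indels <= ``gap`` bp apart.

    Clusters are formed transitively over consecutive indels; in each
    multi-indel cluster the highest-quality indel survives (ties broken toward
    the smallest position), the rest are returned for removal.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    removed: set[int] = set()
    for sl in table.scaffold_slices().values():
        idx = np.arange(sl.start, sl.stop)[table.is_indel[sl]]
        if idx.size < 2:
            continue
        ipos = table.pos[idx]
        breaks = np.nonzero(np.diff(ipos) > gap)[0] + 1
        for cluster in np.split(idx, breaks):
            if cluster.size < 2:
                continue
            quals = np.nan_to_num(table.qual[cluster], nan=-np.inf)
            keep = cluster[np.argmax(quals)]  # argmax ties -> first = leftmost
            removed.update(int(i) for i in cluster if i != keep)
    return removed


def apply_filters(
    table: VariantTable, config: FilterConfig | None = None
) -> tuple[VariantTable, FilterReport]:
    """Apply the five hard-filter rules in order and report removals.

    Rules requiring an annotation skip records where that annotation is
    absent.  A record matching several rules counts once, under the first
    matching rule.
    """
    if config is None:
        config = FilterConfig()
    n = table.n_records
    masks = np.zeros((len(FILTER_RULES), n), dtype=bool)

    prox = flag_indel_proximity(table, config.indel_proximity_bp)
    if prox:
        masks[0, list(prox)] = True
    clus = collapse_indel_clusters(table, config.indel_cluster_gap_bp)
    if clus:
        masks[1, list(clus)] = True
    q = table.qual
    has_q = ~np.isnan(q)
    masks[2] = has_q & (q < config.qual_min)
    rp = table.ranksum_p
    masks[3] = (
        ~np.isnan(rp) & (rp < config.ranksum_p_max)
        & has_q & (q < config.qual_ranksum)
    )
    ac = table.alt_support
    masks[4] = (
        ~np.isnan(ac) & (ac < config.min_alt_count)
        & has_q & (q < config.qual_altcount)
    )

    removed_any = masks.any(axis=0)
    first_rule = np.argmax(masks, axis=0)  # valid only where removed_any
    counts = {
        rule: int(np.sum(removed_any & (first_rule == r)))
        for r, rule in enumerate(FILTER_RULES)
    }
    passed = table.take(~removed_any)
    report = FilterReport(
        removed_by_rule=counts,
        n_input=n,
        n_passed=passed.n_records,
    )
    return passed, report
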