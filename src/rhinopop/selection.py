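"""Windowed Watterson's theta, pi, Tajima's D and outlier-region scanning.

Tajima's D for a window with S segregating sites over n haplotypes is

    D = (theta_pi - theta_W) / sqrt(e1*S + e2*S*(S-1))

with the standard constants a1 = sum_{i<n} 1/i, a2 = sum_{i<n} 1/i^2,
b1 = (n+1)/(3(n-1)), b2 = 2(n^2+n+3)/(9n(n-1)), c1 = b1 - 1/a1,
c2 = b2 - (n+2)/(a1 n) + a2/a1^2, e1 = c1/a1, e2 = c2/(a1^2 + a2).

theta_pi and S need allele counts only, so diploid genotypes are never
assumed phased.  At sites with missing genotypes the haplotype count n is
taken per site; the variance constants for a window use the lower median of
the per-site n over its segregating sites (or a fixed n when configured),
which reduces exactly to 2 x samples on fully-called data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .diversity import PopulationPanel, _pop_alt_freqs
from .variants import MISSING, VariantTable

__all__ = [
    "TajimaConstants",
    "WindowStat",
    "OutlierRegion",
    "CodingSNPRecord",
    "tajima_constants",
    "tajima_d_from_counts",
    "window_stats",
    "outlier_windows",
    "read_gene_intervals",
    "coding_snps_in_outliers",
]

DEFAULT_SCAN_WINDOW = 50_000
DEFAULT_QUANTILE = 0.01


@dataclass(frozen=True)
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> TajimaConstants:
    """Normalizing constants of Tajima's D for n haplotypes (n >= 2)."""
    if n < 2:
        raise ValueError(f"need at least 2 haplotypes, got {n}")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class WindowStat:
    scaffold: str
    start: int  # 0-based half-open
    end: int
    S: int
    theta_w: float
    theta_pi: float
    tajima_d: float | None


@dataclass
class OutlierRegion:
    scaffold: str
    start: int
    end: int
    tajima_d: float  # most extreme D among merged windows
    tail: str  # "lower" | "upper"


@dataclass(frozen=True)
class CodingSNPRecord:
    scaffold: str
    pos: int  # 1-based
    gene_id: str
    fixation_class: str  # fixed-in-<pop> | fixed-both | polymorphic


def tajima_d_from_counts(
    n: int, alt_counts: Sequence[int]
) -> tuple[int, float, float, float | None]:
    """(S, theta_W, theta_pi, D) from derived/alternate allele counts at a
    fixed haplotype count n.  Counts of 0 or n do not segregate."""
    k = tajima_constants(n)
    j = np.asarray(alt_counts, dtype=np.float64)
    seg = (j > 0) & (j < n)
    j = j[seg]
    S = int(seg.sum())
    theta_w = S / k.a1
    theta_pi = float(np.sum(2.0 * j * (n - j) / (n * (n - 1))))
    var = k.e1 * S + k.e2 * S * (S - 1)
    d = (theta_pi - theta_w) / np.sqrt(var) if S >= 1 and var > 0 else None
    return S, theta_w, theta_pi, d


def window_stats(
    table: VariantTable,
    samples: Sequence[str],
    window: int = DEFAULT_SCAN_WINDOW,
    fixed_n: int | None = None,
) -> list[WindowStat]:
    """Per-window S, theta_W, theta_pi and Tajima's D over a sample subset.

    Windows tile every scaffold without overlap; windows without segregating
    sites get theta_w = theta_pi = 0 and D absent.  Multiallelic sites are
    excluded.  With ``fixed_n`` the haplotype count is forced (sites with
    fewer observed alleles still use their own n for theta terms).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    idx = [table.sample_index(s) for s in samples]
    g = table.genotypes[:, idx, :]
    n_obs = (g != MISSING).sum(axis=(1, 2))
    alt = (g > 0).sum(axis=(1, 2))
    usable = table.is_biallelic & (n_obs >= 2)
    seg = usable & (alt > 0) & (alt < n_obs)

    # accumulate per (scaffold, window index)
    stats: dict[tuple[str, int], dict] = {}
    for scaffold, length in table.scaffold_lengths.items():
        for w in range(0, length, window):
            stats[(scaffold, w // window)] = {
                "start": w, "end": min(w + window, length),
                "S": 0, "tw": 0.0, "tp": 0.0, "ns": [],
            }
    names = table.scaffolds.astype(str)
    for i in np.nonzero(seg)[0]:
        key = (names[i], int((table.pos[i] - 1) // window))
        if key not in stats:
            raise ValueError(
                f"record at {names[i]}:{table.pos[i]} outside declared scaffold length"
            )
        n_i = int(n_obs[i])
        j = int(alt[i])
        st = stats[key]
        st["S"] += 1
        st["tw"] += 1.0 / tajima_constants(n_i).a1
        st["tp"] += 2.0 * j * (n_i - j) / (n_i * (n_i - 1))
        st["ns"].append(n_i)

    out: list[WindowStat] = []
    for (scaffold, _), st in stats.items():
        S = st["S"]
        d = None
        if S >= 1:
            if fixed_n is not None:
                n_d = fixed_n
            else:
                ns = sorted(st["ns"])
                n_d = ns[(len(ns) - 1) // 2]  # lower median
            k = tajima_constants(n_d)
            var = k.e1 * S + k.e2 * S * (S - 1)
            if var > 0:
                d = (st["tp"] - st["tw"]) / float(np.sqrt(var))
        out.append(
            WindowStat(scaffold, st["start"], st["end"], S, st["tw"], st["tp"], d)
        )
    out.sort(key=lambda w: (w.scaffold, w.start))
    return out


def outlier_windows(
    stats: Sequence[WindowStat], q: float = DEFAULT_QUANTILE
) -> list[OutlierRegion]:
    """Windows in the outlying q-quantile of Tajima's D, two-tailed.

    Cutoffs are numpy linear-interpolation quantiles (R type 7); ties at a
    cutoff are included.  Adjacent outlier windows of the same tail merge
    into one region carrying the most extreme D.
    """
    if not (0 < q < 0.5):
        raise ValueError("q must be in (0, 0.5)")
    defined = [w for w in stats if w.tajima_d is not None]
    if not defined:
        warnings.warn("no windows with defined Tajima's D; no outliers")
        return []
    ds = np.array([w.tajima_d for w in defined])
    lo = np.quantile(ds, q)
    hi = np.quantile(ds, 1 - q)
    regions: list[OutlierRegion] = []
    for w in defined:
        tail = None
        if w.tajima_d <= lo:
            tail = "lower"
        elif w.tajima_d >= hi:
            tail = "upper"
        if tail is None:
            continue
        prev = regions[-1] if regions else None
        if (
            prev is not None
            and prev.tail == tail
            and prev.scaffold == w.scaffold
            and prev.end == w.start
        ):
            prev.end = w.end
            if tail == "lower":
                prev.tajima_d = min(prev.tajima_d, w.tajima_d)
            else:
                prev.tajima_d = max(prev.tajima_d, w.tajima_d)
        else:
            regions.append(
                OutlierRegion(w.scaffold, w.start, w.end, w.tajima_d, tail)
            )
    return regions


def read_gene_intervals(
    path: str, feature_types: Sequence[str] = ("gene",)
) -> list[tuple[str, int, int, str]]:
    """Gene intervals as (scaffold, start, end, gene_id), 0-based half-open.

    BED input (``.bed``) is used as-is; GFF3 (``.gff``/``.gff3``) rows of the
    requested feature types are converted from 1-based inclusive coordinates,
    with the ID attribute (or ``<type>:<pos>``) as the gene id.
    """
    if path.endswith((".gff", ".gff3")):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["seqid", "source", "type", "start", "end",
                   "score", "strand", "phase", "attributes"],
        )
        df = df[df["type"].isin(feature_types)]
        out = []
        for _, row in df.iterrows():
            gid = f"{row['type']}:{row['seqid']}:{row['start']}"
            for part in str(row["attributes"]).split(";"):
                if part.startswith("ID="):
                    gid = part[3:]
                    break
            out.append((str(row["seqid"]), int(row["start"]) - 1, int(row["end"]), gid))
        return out
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    return [
        (str(r[0]), int(r[1]), int(r[2]), str(r[3]) if len(r) > 3 else f"gene_{i}")
        for i, r in df.iterrows()
    ]


def coding_snps_in_outliers(
    outliers: Sequence[OutlierRegion],
    genes: Sequence[tuple[str, int, int, str]],
    table: VariantTable,
    panel: PopulationPanel,
) -> list[CodingSNPRecord]:
    """SNPs inside (outlier region AND gene interval), with fixation class.

    Per population the alt frequency is computed over non-missing alleles:
    fixed-in-P iff f_P = 1 and f_other < 1; fixed-both iff both are 1; else
    polymorphic.  Gene intervals beyond the declared scaffold length raise,
    catching coordinate-system mismatches.
    """
    pop1, pop2 = panel.require_two()
    for scaffold, start, end, gid in genes:
        length = table.scaffold_lengths.get(scaffold)
        if length is not None and (start < 0 or end > length):
            raise ValueError(
                f"gene {gid} [{start},{end}) outside scaffold {scaffold} "
                f"(length {length}); coordinate-system mismatch?"
            )
    gene_trees: dict[str, IntervalTree] = {}
    for scaffold, start, end, gid in genes:
        gene_trees.setdefault(scaffold, IntervalTree()).addi(start, end, gid)
    out_trees: dict[str, IntervalTree] = {}
    for r in outliers:
        out_trees.setdefault(r.scaffold, IntervalTree()).addi(r.start, r.end)

    f1, obs1 = _pop_alt_freqs(table, panel.indices(table, pop1))
    f2, obs2 = _pop_alt_freqs(table, panel.indices(table, pop2))

    records: list[CodingSNPRecord] = []
    names = table.scaffolds.astype(str)
    for i in range(table.n_records):
        if table.is_indel[i]:
            continue
        scaffold = names[i]
        p0 = int(table.pos[i]) - 1
        ot = out_trees.get(scaffold)
        if ot is None or not ot.overlaps(p0):
            continue
        gt = gene_trees.get(scaffold)
        if gt is None:
            continue
        hits = gt[p0]
        if not hits or obs1[i] == 0 or obs2[i] == 0:
            continue
        if f1[i] == 1 and f2[i] == 1:
            klass = "fixed-both"
        elif f1[i] == 1 and f2[i] < 1:
            klass = f"fixed-in-{pop1}"
        elif f2[i] == 1 and f1[i] < 1:
            klass = f"fixed-in-{pop2}"
        else:
            klass = "polymorphic"
        for hit in sorted(hits):
            records.append(
                CodingSNPRecord(scaffold, int(table.pos[i]), hit.data, klass)
            )
    return records
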