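"""Conserved-noncoding-sequence calling, categorization and annotation.

The calling pipeline order is fixed:

1. mask CDS-labeled bases;
2. take maximal runs of non-CDS bases with score >= threshold;
3. merge runs separated by <= ``merge_gap`` bp, provided the gap contains no
   CDS base (merging never bridges coding sequence);
4. drop merged fragments shorter than ``min_len``.

Defaults (0.7 / 3 bp / 6 bp) are the calling convention this toolkit is
built around; every one is a parameter.  The mean score of a merged CNS
averages over *all* its bases, sub-threshold gap bases included.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median_low
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alnio import ConfigError, Gene, GeneModels, GenomeDict
from .conscore import ScoreTrack, as_fraction

# Region label codes. Painting precedence (high to low): CDS, UTR5, UTR3,
# intron, intergenic.
INTERGENIC, CDS, UTR5, UTR3, INTRON = 0, 1, 2, 3, 4
LABEL_NAMES = {INTERGENIC: "intergenic", CDS: "CDS", UTR5: "UTR5",
               UTR3: "UTR3", INTRON: "intron"}
# CNS categories never include CDS; ties break by this order.
CATEGORY_PRIORITY = (UTR5, UTR3, INTRON, INTERGENIC)


@dataclass
class RegionIndex:
    """Disjoint per-base partition of the reference into region classes."""

    labels: dict[str, np.ndarray]

    def counts(self) -> dict[str, int]:
        out = {name: 0 for name in LABEL_NAMES.values()}
        for arr in self.labels.values():
            codes, n = np.unique(arr, return_counts=True)
            for c, k in zip(codes, n):
                out[LABEL_NAMES[int(c)]] += int(k)
        return out


def build_region_index(models: GeneModels, genome: GenomeDict) -> RegionIndex:
    """Label every reference base as CDS/UTR5/UTR3/intron/intergenic.

    Overlapping transcripts resolve by precedence: a base that is CDS in any
    transcript is CDS; else UTR5 anywhere wins over UTR3, over intron.
    """
    labels = {c: np.zeros(n, dtype=np.uint8) for c, n in genome.lengths.items()}
    # paint in ascending precedence so later (higher) classes overwrite
    for code in (INTRON, UTR3, UTR5, CDS):
        for gene in models:
            arr = labels[gene.chrom]
            for t in gene.transcripts:
                if code == INTRON:
                    ivs = t.introns
                elif code == CDS:
                    ivs = t.cds
                else:
                    u5, u3 = t.utrs()
                    ivs = u5 if code == UTR5 else u3
                for s, e in ivs:
                    arr[s:e] = code
    return RegionIndex(labels)


@dataclass
class CNSInterval:
    chrom: str
    start: int
    end: int
    mean_score: float
    category: str

    @property
    def length(self) -> int:
        return self.end - self.start


def call_cns(
    track: ScoreTrack,
    regions: RegionIndex,
    threshold=0.7,
    merge_gap: int = 3,
    min_len: int = 6,
) -> list[CNSInterval]:
    """Call CNS intervals from a score track (see module docstring for the
    fixed pipeline order). Output is sorted and disjoint."""
    frac = as_fraction(threshold)
    if not 0 <= frac <= 1:
        raise ConfigError(f"threshold {threshold} outside [0, 1]")
    out: list[CNSInterval] = []
    for chrom in sorted(track.matched):
        labels = regions.labels[chrom]
        ok = track.meets(chrom, frac) & (labels != CDS)
        runs = _runs(ok)
        merged = _merge_runs(runs, labels, merge_gap)
        n = track.n_species
        m = track.matched[chrom]
        for s, e in merged:
            if e - s < min_len:
                continue
            mean = float(m[s:e].sum()) / (n * (e - s))
            out.append(CNSInterval(chrom, s, e, mean,
                                   categorize((s, e), labels)))
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    brk = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[brk + 1]))
    ends = np.concatenate((idx[brk] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs(runs, labels, merge_gap) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        gap = s - pe
        if gap <= merge_gap and not np.any(labels[pe:s] == CDS):
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def categorize(interval: tuple[int, int], labels: np.ndarray) -> str:
    """Majority non-CDS label of an interval; ties break UTR5 > UTR3 >
    intron > intergenic."""
    s, e = interval
    codes, counts = np.unique(labels[s:e], return_counts=True)
    by_code = dict(zip(codes.tolist(), counts.tolist()))
    by_code.pop(CDS, None)
    if not by_code:
        raise ValueError(f"interval [{s},{e}) is entirely CDS")
    best = max(CATEGORY_PRIORITY, key=lambda c: (by_code.get(c, 0),
                                                 -CATEGORY_PRIORITY.index(c)))
    return LABEL_NAMES[best]


@dataclass
class CNSSummary:
    clade: str
    total_number: int
    mean_length: int
    median_length: int
    total_length: int
    pct_by_category: dict[str, float]


def summarize(cns_list: Sequence[CNSInterval], clade: str) -> CNSSummary:
    """Count/length/category summary. Mean length is rounded to the nearest
    bp; the median is the lower middle element for even counts."""
    n = len(cns_list)
    if n == 0:
        return CNSSummary(clade, 0, 0, 0, 0,
                          {LABEL_NAMES[c]: float("nan") for c in CATEGORY_PRIORITY})
    lengths = [c.length for c in cns_list]
    total = sum(lengths)
    pct = {}
    for code in CATEGORY_PRIORITY:
        name = LABEL_NAMES[code]
        k = sum(1 for c in cns_list if c.category == name)
        pct[name] = 100.0 * k / n
    return CNSSummary(clade, n, round(total / n), median_low(lengths), total, pct)


def constrained_fraction(
    track: ScoreTrack,
    regions: RegionIndex,
    threshold=0.7,
) -> tuple[float, dict[str, int]]:
    """Raw per-base constrained fraction, before any merge/length rule.

    Returns (genome-wide fraction of bases at score >= threshold, constrained
    bp per region class including CDS).
    """
    frac = as_fraction(threshold)
    per_class = {name: 0 for name in LABEL_NAMES.values()}
    hit = total = 0
    for chrom, labels in regions.labels.items():
        meets = track.meets(chrom, frac)
        hit += int(meets.sum())
        total += meets.size
        for code, name in LABEL_NAMES.items():
            per_class[name] += int((meets & (labels == code)).sum())
    return (hit / total if total else 0.0), per_class


# ---------------------------------------------------------------------------
# CNS-to-gene and CNS-to-feature association
# ---------------------------------------------------------------------------

def genes_downstream_of_cns(
    cns_list: Sequence[CNSInterval],
    models: GeneModels,
    window: int = 1000,
    mode: str = "gene_downstream",
) -> set[str]:
    """Genes whose TSS lies within ``window`` bp downstream of a CNS on the
    gene's strand (default), i.e. the CNS sits up to 1 kb upstream of the
    gene.  ``mode='cns_downstream'`` flips the direction: the CNS starts
    within ``window`` bp downstream of the TSS.
    """
    if mode not in ("gene_downstream", "cns_downstream"):
        raise ConfigError(f"mode {mode!r}")
    hits: set[str] = set()
    by_chrom: dict[str, list[CNSInterval]] = {}
    for c in cns_list:
        by_chrom.setdefault(c.chrom, []).append(c)
    for gene in models:
        tss = gene.tss
        for c in by_chrom.get(gene.chrom, ()):
            if mode == "gene_downstream":
                gap = tss - c.end if gene.strand == "+" else c.start - tss - 1
            else:
                gap = c.start - tss - 1 if gene.strand == "+" else tss - c.end
            if 0 <= gap <= window:
                hits.add(gene.gid)
                break
    return hits


def bigfoot_genes(
    models: GeneModels,
    cns_list: Sequence[CNSInterval],
    span_min: int = 4000,
    min_cns: int = 6,
    window: int = 1000,
) -> set[str]:
    """Genes with span > span_min carrying >= min_cns CNSs within the span
    extended by ``window`` on both sides."""
    out: set[str] = set()
    for gene in models:
        if gene.span <= span_min:
            continue
        lo, hi = gene.start - window, gene.end + window
        k = sum(1 for c in cns_list
                if c.chrom == gene.chrom and c.start < hi and c.end > lo)
        if k >= min_cns:
            out.add(gene.gid)
    return out


def feature_overlap(
    cns_list: Sequence[CNSInterval],
    features: Sequence[tuple],
) -> tuple[float | None, dict[str, float]]:
    """Fraction of CNSs with >= 1 bp overlap of any feature, plus per-class
    fractions keyed by the feature name column. None if there are no CNSs."""
    if not cns_list:
        return None, {}
    classes: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for feat in features:
        chrom, s, e = feat[0], int(feat[1]), int(feat[2])
        name = str(feat[3]) if len(feat) > 3 else "feature"
        classes.setdefault(name, {}).setdefault(chrom, []).append((s, e))
    indexed = {name: {c: _overlap_index(ivs) for c, ivs in by_chrom.items()}
               for name, by_chrom in classes.items()}
    n_any = 0
    n_by_class = {name: 0 for name in classes}
    for c in cns_list:
        hit_any = False
        for name, by_chrom in indexed.items():
            idx = by_chrom.get(c.chrom)
            if idx is not None and _overlaps(idx, c.start, c.end):
                n_by_class[name] += 1
                hit_any = True
        n_any += hit_any
    n = len(cns_list)
    return n_any / n, {name: k / n for name, k in n_by_class.items()}


def _overlap_index(intervals):
    starts = np.array(sorted(s for s, _ in intervals))
    ends = np.array([e for _, e in sorted(intervals)])
    return starts, np.maximum.accumulate(ends)


def _overlaps(index, start, end) -> bool:
    starts, max_ends = index
    i = int(np.searchsorted(starts, end, side="left"))
    return i > 0 and max_ends[i - 1] > start


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def cns_to_bed(cns_list: Sequence[CNSInterval]) -> list[tuple]:
    """BED6 rows: name = category, score = round(1000 * mean_score)."""
    return [(c.chrom, c.start, c.end, c.category, round(1000 * c.mean_score), "+")
            for c in cns_list]


def summary_to_frame(summaries: Sequence[CNSSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"clade": s.clade, "total_number": s.total_number,
               "mean_length": s.mean_length, "median_length": s.median_length,
               "total_length": s.total_length}
        for name, pct in s.pct_by_category.items():
            row[f"pct_{name}"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
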