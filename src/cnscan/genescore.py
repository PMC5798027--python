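"""Gene-level conservation: mean scores, conserved gene sets, meta-profiles."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alnio import ConfigError, GeneModels
from .conscore import ScoreTrack


@dataclass
class GeneScore:
    gid: str
    chrom: str
    start: int
    end: int
    mean_score: float
    n_bases: int


def gene_scores(track: ScoreTrack, models: GeneModels,
                exon_only: bool = False) -> list[GeneScore]:
    """Mean conservation score per gene.

    The default averages over the whole gene span (TSS to TES, introns and
    UTRs included); ``exon_only`` restricts to the union of exon bases.
    """
    out = []
    for gene in models:
        m = track.matched[gene.chrom]
        if exon_only:
            mask = np.zeros(gene.span, dtype=bool)
            for t in gene.transcripts:
                for s, e in t.exons:
                    mask[s - gene.start:e - gene.start] = True
            vals = m[gene.start:gene.end][mask]
        else:
            vals = m[gene.start:gene.end]
        n = int(vals.size)
        mean = float(vals.sum()) / (track.n_species * n) if n else float("nan")
        out.append(GeneScore(gene.gid, gene.chrom, gene.start, gene.end, mean, n))
    return out


def highly_conserved(scores: Sequence[GeneScore], cutoff: float = 0.9) -> set[str]:
    """Genes with mean score >= cutoff (inclusive)."""
    return {s.gid for s in scores if s.mean_score >= cutoff}


def clade_exclusive(sets_by_clade: Mapping[str, set[str]]
                    ) -> tuple[dict[str, set[str]], set[str]]:
    """(per-clade exclusive sets, common intersection).

    exclusive(c) = set(c) minus the union of every other clade's set.
    """
    exclusive = {}
    for clade, genes in sets_by_clade.items():
        others: set[str] = set()
        for other, g in sets_by_clade.items():
            if other != clade:
                others |= g
        exclusive[clade] = set(genes) - others
    common = None
    for genes in sets_by_clade.values():
        common = set(genes) if common is None else common & genes
    return exclusive, common if common is not None else set()


@dataclass
class MetaProfile:
    anchor: str
    flank: int
    offsets: np.ndarray
    mean: np.ndarray
    n: np.ndarray


def meta_profile(track: ScoreTrack, models: GeneModels, anchor: str = "TSS",
                 flank: int = 1000) -> MetaProfile:
    """Average score around gene TSS or TES, strand-aware.

    Offset 0 is the anchor base; positive offsets run in the gene's 5'->3'
    direction.  Positions off the chromosome are skipped, with per-offset n
    bookkeeping.
    """
    if anchor not in ("TSS", "TES"):
        raise ConfigError(f"anchor {anchor!r}")
    width = 2 * flank + 1
    total = np.zeros(width)
    n = np.zeros(width, dtype=np.int64)
    offsets = np.arange(-flank, flank + 1)
    for gene in models:
        m = track.matched[gene.chrom]
        a = gene.tss if anchor == "TSS" else gene.tes
        sign = 1 if gene.strand == "+" else -1
        pos = a + sign * offsets
        ok = (pos >= 0) & (pos < m.size)
        total[ok] += m[pos[ok]] / track.n_species
        n[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return MetaProfile(anchor, flank, offsets, mean, n)


def exon_rank_profile(track: ScoreTrack, models: GeneModels
                      ) -> dict[str, tuple[float, int]]:
    """Mean score for first/internal/last exons and UTR exon parts.

    Exon rank is strand-aware (first = 5'-most). Transcripts with fewer than
    3 exons contribute no internal exons. Returns class -> (mean, n_bases),
    mean NaN when a class has no bases.
    """
    sums = {k: 0.0 for k in ("first_exon", "internal_exon", "last_exon", "utr_exon")}
    nb = {k: 0 for k in sums}

    def add(key, chrom, ivs):
        m = track.matched[chrom]
        for s, e in ivs:
            sums[key] += float(m[s:e].sum()) / track.n_species
            nb[key] += e - s

    for gene in models:
        for t in gene.transcripts:
            exons = t.exons if t.strand == "+" else t.exons[::-1]
            if len(exons) >= 2:
                add("first_exon", t.chrom, [exons[0]])
                add("last_exon", t.chrom, [exons[-1]])
            elif exons:
                add("first_exon", t.chrom, [exons[0]])
            if len(exons) >= 3:
                add("internal_exon", t.chrom, exons[1:-1])
            u5, u3 = t.utrs()
            add("utr_exon", t.chrom, u5 + u3)
    return {k: ((sums[k] / nb[k]) if nb[k] else float("nan"), nb[k]) for k in sums}


def scores_to_frame(scores: Sequence[GeneScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": s.gid, "mean_score": s.mean_score, "n_bases": s.n_bases}
         for s in scores])


def profile_to_frame(profile: MetaProfile) -> pd.DataFrame:
    return pd.DataFrame({"offset": profile.offsets, "mean": profile.mean,
                         "n": profile.n})
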