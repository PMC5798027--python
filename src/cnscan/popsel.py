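"""Population-level evidence of purifying selection on conserved sequence.

Conservation classes partition scored sites into nonconserved [0, 0.2],
conserved [0.7, 0.9) and extremely conserved [0.9, 1.0]; sites in (0.2, 0.7)
stay unclassified.  The 0.9 boundary belongs to the extreme class and 0.2 to
nonconserved, so the classes are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .alnio import ConfigError, GeneModels, SNPRecord
from .conscore import ScoreTrack

NONCONSERVED = "nonconserved"
CONSERVED = "conserved"
EXTREME = "extreme"
UNCLASSIFIED = "unclassified"
CLASSES = (NONCONSERVED, CONSERVED, EXTREME)


def classify_score(matched: int, n_species: int) -> str:
    s = Fraction(matched, n_species)
    if s <= Fraction(1, 5):
        return NONCONSERVED
    if s >= Fraction(9, 10):
        return EXTREME
    if s >= Fraction(7, 10):
        return CONSERVED
    return UNCLASSIFIED


def classify_snp_sites(snps: Iterable[SNPRecord], track: ScoreTrack
                       ) -> dict[int, str]:
    """Map each SNP (by sequence index) to its site's conservation class."""
    out = {}
    for i, snp in enumerate(snps):
        m = int(track.matched[snp.chrom][snp.pos])
        out[i] = classify_score(m, track.n_species)
    return out


def default_maf_bins() -> np.ndarray:
    """[0, 0.01) 'rare' bin followed by ten equal bins of (0.01, 0.5]."""
    return np.concatenate(([0.0], np.linspace(0.01, 0.5, 11)))


def maf_spectrum(
    snps: Sequence[SNPRecord],
    classes: Mapping[int, str],
    bin_edges: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-conservation-class histogram of folded MAF.

    Bins are half-open [lo, hi) except the last, which includes 0.5.  Counts
    per class sum to the class's SNP count.
    """
    edges = default_maf_bins() if bin_edges is None else np.asarray(bin_edges)
    out = {cls: np.zeros(len(edges) - 1, dtype=np.int64)
           for cls in (*CLASSES, UNCLASSIFIED)}
    for i, snp in enumerate(snps):
        maf = snp.maf
        j = int(np.searchsorted(edges, maf, side="right")) - 1
        j = min(max(j, 0), len(edges) - 2)
        out[classes[i]][j] += 1
    return out


def snp_depletion(
    snps: Sequence[SNPRecord],
    constrained: Mapping[str, Sequence[tuple[int, int]]],
    genome,
) -> float:
    """Fold depletion = genome-wide SNP density / density inside constrained
    regions. Infinite if the constrained regions carry no SNPs."""
    constrained_bp = sum(e - s for ivs in constrained.values() for s, e in ivs)
    if constrained_bp == 0:
        raise ConfigError("empty constrained region set")
    masks = {}
    for chrom, ivs in constrained.items():
        mask = np.zeros(genome.lengths[chrom], dtype=bool)
        for s, e in ivs:
            mask[s:e] = True
        masks[chrom] = mask
    n_in = sum(1 for s in snps if masks.get(s.chrom) is not None
               and masks[s.chrom][s.pos])
    d_genome = len(snps) / genome.total_bp
    if n_in == 0:
        return float("inf")
    d_in = n_in / constrained_bp
    return d_genome / d_in


def invariant_sites(track: ScoreTrack) -> dict[str, np.ndarray]:
    """Positions whose column shows zero mismatches at full clade coverage
    (matched == clade size)."""
    return {chrom: np.flatnonzero(track.matched[chrom] == track.n_species)
            for chrom in track.matched}


@dataclass
class EffectTabulation:
    counts: dict[str, int]
    percentages: dict[str, float]
    total: int


def effect_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentage of total per effect type, rounded to 2 decimals."""
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: round(100.0 * v / total, 2) for k, v in counts.items()}


def tabulate_effects(
    snps: Sequence[SNPRecord],
    invariant: Mapping[str, np.ndarray],
) -> EffectTabulation:
    """Count effect annotations of SNPs falling on invariant sites.

    A SNP carrying several effect records contributes each of them once.
    """
    inv_sets = {chrom: set(pos.tolist()) for chrom, pos in invariant.items()}
    counts: dict[str, int] = {}
    for snp in snps:
        if snp.pos not in inv_sets.get(snp.chrom, ()):  # not invariant
            continue
        for effect, _impact in snp.effects:
            counts[effect] = counts.get(effect, 0) + 1
    return EffectTabulation(counts, effect_percentages(counts),
                            sum(counts.values()))


def variation_correlation(
    models: GeneModels,
    snps: Sequence[SNPRecord],
    track: ScoreTrack,
    inter_mode: str = "positions",
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-gene intra- vs interspecific variation and their Pearson r.

    intra = SNP count within the gene span.  inter = number of gene-span
    positions with at least one aligned species mismatching the reference
    (``inter_mode='positions'``), or the sum of mismatching species over
    positions (``'species_sum'``).  Returns (intra, inter, r, p); r is NaN
    when either vector is constant.
    """
    if inter_mode not in ("positions", "species_sum"):
        raise ConfigError(f"inter_mode {inter_mode!r}")
    snp_pos: dict[str, list[int]] = {}
    for s in snps:
        snp_pos.setdefault(s.chrom, []).append(s.pos)
    snp_sorted = {c: np.array(sorted(p)) for c, p in snp_pos.items()}
    intra = np.zeros(len(models), dtype=np.int64)
    inter = np.zeros(len(models), dtype=np.int64)
    for i, gene in enumerate(models):
        pos = snp_sorted.get(gene.chrom)
        if pos is not None:
            intra[i] = int(np.searchsorted(pos, gene.end)
                           - np.searchsorted(pos, gene.start))
        m = track.matched[gene.chrom][gene.start:gene.end]
        a = track.aligned[gene.chrom][gene.start:gene.end]
        mism = (a >= 1) & (m < a)
        if inter_mode == "positions":
            inter[i] = int(mism.sum())
        else:
            inter[i] = int((a - m)[mism].sum())
    if len(models) < 2 or np.all(intra == intra[0]) or np.all(inter == inter[0]):
        return intra, inter, float("nan"), float("nan")
    r, p = stats.pearsonr(intra, inter)
    return intra, inter, float(r), float(p)


def outlier_genes(
    models: GeneModels,
    snps: Sequence[SNPRecord],
    track: ScoreTrack,
    maf_min: float = 0.05,
    mode: str = "relaxed_in_reference",
    intra_floor: int = 0,
    inter_ceiling: int = 1,
) -> dict[str, list[SNPRecord]] | set[str]:
    """Outlier genes under two modes.

    ``relaxed_in_reference``: SNPs of MAF >= maf_min at invariant sites,
    grouped by overlapping gene (dict gene -> SNP list; SNPs outside any gene
    group under '.').  ``conserved_in_reference_only``: gene ids with intra
    count <= intra_floor and inter count >= inter_ceiling.
    """
    if mode == "relaxed_in_reference":
        inv = invariant_sites(track)
        inv_sets = {c: set(p.tolist()) for c, p in inv.items()}
        flagged = [s for s in snps
                   if s.maf >= maf_min and s.pos in inv_sets.get(s.chrom, ())]
        by_gene: dict[str, list[SNPRecord]] = {}
        for s in flagged:
            hit = None
            for gene in models:
                if gene.chrom == s.chrom and gene.start <= s.pos < gene.end:
                    hit = gene.gid
                    break
            by_gene.setdefault(hit or ".", []).append(s)
        return by_gene
    if mode == "conserved_in_reference_only":
        intra, inter, _, _ = variation_correlation(models, snps, track)
        return {gene.gid for gene, a, b in zip(models, intra, inter)
                if a <= intra_floor and b >= inter_ceiling}
    raise ConfigError(f"mode {mode!r}")
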