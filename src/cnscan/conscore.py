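"""Per-base conservation scoring over reference-anchored alignment blocks.

The score of a reference position under a clade is

    matched / n_species

where ``matched`` is the number of clade species whose aligned base is
identical (case-insensitive) to the reference base, and ``n_species`` is the
fixed clade size (non-reference species only).  A score of 1 means the site
is identical across every compared species; 0 means no species supports it.
Threshold comparisons are done on the exact rational (``matched * q >= p *
n_species`` for a threshold ``p/q``) so no floating-point artifact can move a
site across a cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np

from .alnio import AlignmentBlock, CladeMap, ConfigError, FormatError, GenomeDict

_ACGT = frozenset("ACGT")


def as_fraction(threshold) -> Fraction:
    """Exact rational form of a threshold given as float, str or Fraction.

    Floats are interpreted through their shortest decimal repr, so 0.7 means
    7/10 rather than its binary approximation.
    """
    if isinstance(threshold, Fraction):
        return threshold
    return Fraction(str(threshold))


@dataclass
class ScoreTrack:
    """Per-base matched/aligned counts for one clade over a genome.

    ``matched[c][i]`` counts clade species identical to the reference at
    position ``i`` of chromosome ``c``; ``aligned[c][i]`` counts clade
    species with any non-gap base there.
    """

    clade: str
    n_species: int
    matched: dict[str, np.ndarray]
    aligned: dict[str, np.ndarray]

    @classmethod
    def zeros(cls, clade: str, n_species: int, genome: GenomeDict) -> "ScoreTrack":
        return cls(
            clade,
            n_species,
            {c: np.zeros(n, dtype=np.int32) for c, n in genome.lengths.items()},
            {c: np.zeros(n, dtype=np.int32) for c, n in genome.lengths.items()},
        )

    def score(self, chrom: str) -> np.ndarray:
        """Score array in [0, 1] for one chromosome."""
        return self.matched[chrom] / self.n_species

    def meets(self, chrom: str, threshold) -> np.ndarray:
        """Boolean mask of positions with score >= threshold (exact)."""
        frac = as_fraction(threshold)
        return (self.matched[chrom] * frac.denominator
                >= frac.numerator * self.n_species)

    def validate(self) -> None:
        for chrom in self.matched:
            m, a = self.matched[chrom], self.aligned[chrom]
            if not (np.all(m >= 0) and np.all(m <= a) and np.all(a <= self.n_species)):
                raise ValueError(f"count invariants violated on {chrom}")


def score_column(
    ref_base: str,
    aligned_bases: Mapping[str, str | None],
    clade_species: Iterable[str],
) -> tuple[int, int]:
    """Score one alignment column: (matched, aligned) over the clade.

    ``aligned_bases`` maps species to its base, ``'-'`` for a gap, or is
    simply missing for unaligned species.  'N' (or any non-ACGT character)
    never matches, in either the reference or a species row.
    """
    ref = ref_base.upper()
    matched = aligned = 0
    for sp in clade_species:
        base = aligned_bases.get(sp)
        if base is None or base == "-":
            continue
        base = base.upper()
        aligned += 1
        if ref in _ACGT and base == ref:
            matched += 1
    return matched, aligned


def score_genome(
    blocks: Iterable[AlignmentBlock],
    clade: str,
    clade_map: CladeMap,
    genome: GenomeDict,
    match_mode: str = "identity",
) -> ScoreTrack:
    """Accumulate a ScoreTrack for one clade from a stream of blocks.

    ``match_mode='identity'`` counts a species as matched only when its base
    equals the reference base; ``'aligned'`` counts any non-gap base as a
    match (sensitivity-analysis mode).  If two blocks align one species twice
    to the same reference position, the earlier block wins and a warning with
    a running count is emitted at the end.
    """
    if match_mode not in ("identity", "aligned"):
        raise ConfigError(f"match_mode {match_mode!r}")
    species = sorted(clade_map.species(clade))
    track = ScoreTrack.zeros(clade, len(species), genome)
    occupied = {sp: {} for sp in species}
    n_dup = 0

    for blk in blocks:
        if blk.ref_chrom not in genome.lengths:
            raise FormatError(f"block at {blk.ref_chrom}:{blk.ref_start}: "
                              f"unknown chromosome")
        if blk.ref_end > genome.lengths[blk.ref_chrom]:
            raise FormatError(
                f"block at {blk.ref_chrom}:{blk.ref_start} extends past "
                f"chromosome end ({genome.lengths[blk.ref_chrom]})"
            )
        ref = np.frombuffer(blk.ref_aligned.upper().encode(), dtype="S1")
        ref_nongap = ref != b"-"
        # reference coordinate of each non-gap reference column
        pos = blk.ref_start + np.cumsum(ref_nongap) - 1
        ref_is_acgt = np.isin(ref, [b"A", b"C", b"G", b"T"])
        chrom = blk.ref_chrom
        clen = genome.lengths[chrom]
        for sp in species:
            row_text = blk.rows.get(sp)
            if row_text is None:
                continue
            row = np.frombuffer(row_text.upper().encode(), dtype="S1")
            cols = ref_nongap & (row != b"-")
            if not cols.any():
                continue
            p = pos[cols]
            occ = occupied[sp].setdefault(chrom, np.zeros(clen, dtype=bool))
            new = ~occ[p]
            n_dup += int((~new).sum())
            occ[p[new]] = True
            if match_mode == "identity":
                match = (row == ref) & ref_is_acgt & np.isin(row, [b"A", b"C", b"G", b"T"])
            else:
                match = np.ones(len(ref), dtype=bool)
            mcols = match[cols]
            np.add.at(track.aligned[chrom], p[new], 1)
            np.add.at(track.matched[chrom], p[new & mcols], 1)

    if n_dup:
        warnings.warn(f"{n_dup} doubly-aligned species/position pairs ignored "
                      "(first block wins)", stacklevel=2)
    track.validate()
    return track


def coverage_by_region(
    track: ScoreTrack,
    regions,
    min_score,
) -> dict[str, float | None]:
    """Fraction of each region class at score >= min_score.

    Returns None (undefined) for classes with zero bp rather than 0.
    """
    from . import cnscall

    frac = as_fraction(min_score)
    if not 0 <= frac <= 1:
        raise ConfigError("min_score must be in [0, 1]")
    hit_bp = {name: 0 for name in cnscall.LABEL_NAMES.values()}
    tot_bp = {name: 0 for name in cnscall.LABEL_NAMES.values()}
    for chrom, labels in regions.labels.items():
        meets = track.meets(chrom, frac)
        for code, name in cnscall.LABEL_NAMES.items():
            mask = labels == code
            tot_bp[name] += int(mask.sum())
            hit_bp[name] += int((mask & meets).sum())
    return {name: (hit_bp[name] / tot_bp[name] if tot_bp[name] else None)
            for name in tot_bp}


def write_score_track(track: ScoreTrack, bedgraph_path, counts_path=None) -> None:
    """Export the score as bedGraph; optionally per-base counts as TSV."""
    from .alnio import write_bedgraph

    write_bedgraph({c: np.round(track.score(c), 6) for c in track.matched},
                   bedgraph_path)
    if counts_path is not None:
        with open(counts_path, "w") as fh:
            fh.write("chrom\tpos\tmatched\taligned\n")
            for chrom in track.matched:
                m, a = track.matched[chrom], track.aligned[chrom]
                covered = np.flatnonzero(a > 0)
                for i in covered:
                    fh.write(f"{chrom}\t{i}\t{m[i]}\t{a[i]}\n")
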