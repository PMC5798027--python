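"""Synthetic fixture generator: reference, alignments, gene models, SNPs,
motifs, and the truth records the recovery tests check against.

Every output stream draws from its own child of the master seed, so adding
or removing one output never perturbs the others, and two runs with the same
seed are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import alnio
from .alnio import (AlignmentBlock, CladeMap, ConfigError, Gene, GeneModels,
                    GenomeDict, SNPRecord, Transcript)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# child-stream order for SeedSequence.spawn; fixed so outputs stay stable
_STREAMS = ("ref", "elements", "genes", "aln", "snps", "motifs")


@dataclass
class SimConfig:
    seed: int
    genome_length: int = 50_000
    chrom: str = "chr1"
    ref_name: str = "refsp"
    n_species: int = 10
    clades: dict[str, list[str]] | None = None
    background_match: float = 0.5
    element_match: float = 0.95
    n_elements: int = 20
    element_length: int = 50
    elements: list[tuple[int, int]] | None = None
    element_min_gap: int = 50
    block_length: int = 1000
    gap_rate: float = 0.0
    n_genes: int = 0
    n_exons: int = 3
    exon_length: int = 150
    intron_length: int = 100
    utr5_length: int = 50
    utr3_length: int = 50
    gene_spacing: int = 500
    snp_density: float = 0.005
    depletion: float = 1.0
    an: int = 6000
    maf_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"background": (0.6, 4.0), "element": (0.2, 8.0)})
    effect_types: dict[str, float] | None = None
    motifs: list[tuple[str, str]] | None = None
    motif_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for p in (self.background_match, self.element_match, self.gap_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.depletion < 1.0:
            raise ConfigError("depletion factor must be >= 1")

    @property
    def species(self) -> list[str]:
        return [f"sp{i:02d}" for i in range(1, self.n_species + 1)]

    def clade_map(self) -> CladeMap:
        if self.clades is not None:
            return CladeMap({k: frozenset(v) for k, v in self.clades.items()},
                            ref_name=self.ref_name)
        return CladeMap({"all": frozenset(self.species)}, ref_name=self.ref_name)

    def genome(self) -> GenomeDict:
        return GenomeDict({self.chrom: self.genome_length}, self.ref_name)


@dataclass
class SimTruth:
    elements: list[tuple[int, int]]
    background_match: float
    element_match: float
    gene_models: GeneModels
    snp_classes: list[tuple[int, str, float]]  # pos, element|background, maf
    motif_hits: list[tuple[str, int, int]]     # motif name, start, end

    def element_mask(self, length: int) -> np.ndarray:
        mask = np.zeros(length, dtype=bool)
        for s, e in self.elements:
            mask[s:e] = True
        return mask


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_STREAMS, children)}


def _random_ref(rng, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _make_genes(cfg: SimConfig) -> GeneModels:
    """Deterministic tiling of gene models from the left end of the genome,
    alternating strand."""
    genes = []
    pos = cfg.gene_spacing
    gene_len = (cfg.utr5_length + cfg.utr3_length + cfg.n_exons * cfg.exon_length
                + (cfg.n_exons - 1) * cfg.intron_length)
    for i in range(cfg.n_genes):
        start = pos
        end = start + gene_len
        if end > cfg.genome_length:
            break
        strand = "+" if i % 2 == 0 else "-"
        exons, cds = [], []
        cur = start
        for j in range(cfg.n_exons):
            elen = cfg.exon_length
            if j == 0:
                elen += cfg.utr5_length
            if j == cfg.n_exons - 1:
                elen += cfg.utr3_length
            exons.append((cur, cur + elen))
            cur += elen
            if j < cfg.n_exons - 1:
                cur += cfg.intron_length
        cds_lo = start + cfg.utr5_length
        cds_hi = end - cfg.utr3_length
        for s, e in exons:
            cs, ce = max(s, cds_lo), min(e, cds_hi)
            if ce > cs:
                cds.append((cs, ce))
        if strand == "-":  # swap UTR sides by shifting the CDS window
            cds_lo = start + cfg.utr3_length
            cds_hi = end - cfg.utr5_length
            cds = [(max(s, cds_lo), min(e, cds_hi)) for s, e in exons
                   if min(e, cds_hi) > max(s, cds_lo)]
        gid = f"gene{i + 1:03d}"
        t = Transcript(f"{gid}.t1", cfg.chrom, strand, start, end, exons, cds)
        genes.append(Gene(gid, cfg.chrom, strand, [t]))
        pos = end + cfg.gene_spacing
    return GeneModels(genes)


def _place_elements(cfg: SimConfig, models: GeneModels, rng) -> list[tuple[int, int]]:
    if cfg.elements is not None:
        elements = sorted((int(s), int(e)) for s, e in cfg.elements)
        for (s0, e0), (s1, e1) in zip(elements, elements[1:]):
            if s1 < e0:
                raise ConfigError(f"planted elements overlap: [{s0},{e0}) and "
                                  f"[{s1},{e1})")
        return elements
    # avoid CDS so planted elements stay noncoding
    forbidden = np.zeros(cfg.genome_length, dtype=bool)
    for gene in models:
        for t in gene.transcripts:
            for s, e in t.cds:
                forbidden[s:e] = True
    elements: list[tuple[int, int]] = []
    attempts = 0
    while len(elements) < cfg.n_elements and attempts < 50 * cfg.n_elements:
        attempts += 1
        s = int(rng.integers(0, cfg.genome_length - cfg.element_length))
        e = s + cfg.element_length
        if forbidden[s:e].any():
            continue
        if any(s < ee + cfg.element_min_gap and e > ss - cfg.element_min_gap
               for ss, ee in elements):
            continue
        elements.append((s, e))
    if len(elements) < cfg.n_elements:
        raise ConfigError("could not place all elements; genome too crowded")
    return sorted(elements)


def _plant_motifs(cfg: SimConfig, ref: np.ndarray, elements, rng
                  ) -> list[tuple[str, int, int]]:
    if not cfg.motifs or cfg.motif_rate <= 0:
        return []
    from .motifscan import MotifPattern, IUPAC

    hits = []
    patterns = [MotifPattern(n, p) for n, p in cfg.motifs]
    for s, e in elements:
        k = rng.poisson(cfg.motif_rate * (e - s))
        used: list[tuple[int, int]] = []
        for _ in range(k):
            m = patterns[rng.integers(0, len(patterns))]
            if e - s < len(m):
                continue
            off = int(rng.integers(s, e - len(m) + 1))
            if any(off < ue and off + len(m) > us for us, ue in used):
                continue  # overlapping copies would corrupt earlier hits
            used.append((off, off + len(m)))
            concrete = "".join(
                ch if ch in "ACGT" else
                IUPAC[ch].replace("N", "")[
                    int(rng.integers(0, len(IUPAC[ch].replace("N", ""))))]
                for ch in m.pattern)
            ref[off:off + len(m)] = np.frombuffer(concrete.encode(), dtype="S1")
            hits.append((m.name, off, off + len(m)))
    return hits


def _make_blocks(cfg: SimConfig, ref: np.ndarray, elements, rng
                 ) -> list[AlignmentBlock]:
    L = cfg.genome_length
    p = np.full(L, cfg.background_match)
    for s, e in elements:
        p[s:e] = cfg.element_match
    rows_full = {}
    for sp in cfg.species:
        match = rng.random(L) < p
        # mismatches: shift by 1-3 in the 4-letter alphabet, never identity
        codes = np.searchsorted(_BASES, ref)
        shift = rng.integers(1, 4, size=L)
        mutated = _BASES[(codes + shift) % 4]
        row = np.where(match, ref, mutated)
        if cfg.gap_rate > 0:
            gap = np.array(b"-", dtype="S1")
            row = np.where(rng.random(L) < cfg.gap_rate, gap, row)
        rows_full[sp] = row
    blocks = []
    for start in range(0, L, cfg.block_length):
        end = min(start + cfg.block_length, L)
        blocks.append(AlignmentBlock(
            cfg.chrom, start, ref[start:end].tobytes().decode(),
            {sp: rows_full[sp][start:end].tobytes().decode()
             for sp in cfg.species},
            block_score=1000.0,
        ))
    return blocks


_EFFECT_IMPACT = {
    "missense_variant": "MODERATE", "synonymous_variant": "LOW",
    "stop_gained": "HIGH", "stop_lost": "HIGH", "start_lost": "HIGH",
    "splice_acceptor_variant": "HIGH", "splice_donor_variant": "HIGH",
}


def _make_snps(cfg: SimConfig, ref: np.ndarray, elements, rng
               ) -> tuple[list[SNPRecord], list[tuple[int, str, float]]]:
    L = cfg.genome_length
    rate = np.full(L, cfg.snp_density)
    in_element = np.zeros(L, dtype=bool)
    for s, e in elements:
        in_element[s:e] = True
    rate[in_element] = cfg.snp_density / cfg.depletion
    positions = np.flatnonzero(rng.random(L) < rate)
    snps, classes = [], []
    effect_names = list(cfg.effect_types) if cfg.effect_types else []
    effect_probs = (np.array([cfg.effect_types[k] for k in effect_names])
                    if effect_names else None)
    if effect_probs is not None:
        effect_probs = effect_probs / effect_probs.sum()
    for pos in positions:
        cls = "element" if in_element[pos] else "background"
        a, b = cfg.maf_beta[cls]
        maf = float(np.clip(rng.beta(a, b) * 0.5, 1e-9, 0.5))
        ac = max(1, int(round(maf * cfg.an)))
        ac = min(ac, cfg.an // 2)  # keep the alt the minor allele
        refb = ref[pos].decode()
        code = int(np.searchsorted(_BASES, ref[pos]))
        alt = _BASES[(code + int(rng.integers(1, 4))) % 4].decode()
        effects = []
        if effect_names:
            eff = effect_names[int(rng.choice(len(effect_names), p=effect_probs))]
            effects = [(eff, _EFFECT_IMPACT.get(eff, "MODIFIER"))]
        snps.append(SNPRecord(cfg.chrom, int(pos), refb, alt, cfg.an, ac,
                              effects=effects))
        classes.append((int(pos), cls, maf))
    return snps, classes


def simulate(cfg: SimConfig, outdir=None):
    """Generate the full fixture bundle.

    Returns (paths-or-None, SimTruth, in-memory objects dict).  With
    ``outdir`` set, writes ref.fa, aln.maf, genes.gff3, snps.vcf, motifs.tsv,
    clades.tsv and truth/ files.
    """
    rngs = _rngs(cfg.seed)
    ref = _random_ref(rngs["ref"], cfg.genome_length)
    models = _make_genes(cfg)
    elements = _place_elements(cfg, models, rngs["elements"])
    motif_hits = _plant_motifs(cfg, ref, elements, rngs["motifs"])
    blocks = _make_blocks(cfg, ref, elements, rngs["aln"])
    snps, snp_classes = _make_snps(cfg, ref, elements, rngs["snps"])
    truth = SimTruth(elements, cfg.background_match, cfg.element_match,
                     models, snp_classes, motif_hits)
    objects = {
        "ref": {cfg.chrom: ref.tobytes().decode()},
        "blocks": blocks,
        "models": models,
        "snps": snps,
        "genome": cfg.genome(),
        "clade_map": cfg.clade_map(),
    }
    if outdir is None:
        return None, truth, objects

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    paths = {name: outdir / name for name in
             ("ref.fa", "aln.maf", "genes.gff3", "snps.vcf", "motifs.tsv",
              "clades.tsv")}
    alnio.write_fasta(objects["ref"], paths["ref.fa"])
    alnio.write_maf(blocks, paths["aln.maf"], cfg.ref_name,
                    src_sizes={cfg.chrom: cfg.genome_length})
    alnio.write_gff3(models, paths["genes.gff3"])
    alnio.write_vcf(snps, paths["snps.vcf"], cfg.genome())
    with open(paths["motifs.tsv"], "w") as fh:
        for name, pat in (cfg.motifs or []):
            fh.write(f"{name}\t{pat}\n")
    alnio.write_clade_map(cfg.clade_map(), paths["clades.tsv"])

    alnio.write_bed([(cfg.chrom, s, e, "element") for s, e in elements],
                    outdir / "truth" / "elements.bed")
    with open(outdir / "truth" / "snp_classes.tsv", "w") as fh:
        fh.write("pos\tclass\tmaf\n")
        for pos, cls, maf in snp_classes:
            fh.write(f"{pos}\t{cls}\t{maf:.6f}\n")
    alnio.write_bed([(cfg.chrom, s, e, name) for name, s, e in motif_hits],
                    outdir / "truth" / "motif_hits.bed")
    with open(outdir / "truth" / "params.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=1, default=list)
    paths["truth"] = outdir / "truth"
    return paths, truth, objects
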