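"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open.  Conversion to and from the
1-based conventions of GFF3 and VCF happens here and only here; MAF, BED and
bedGraph are already 0-based.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ConfigError(ValueError):
    """Raised for invalid parameters or configuration."""


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Core domain types
# ---------------------------------------------------------------------------

@dataclass
class AlignmentBlock:
    """One reference-anchored alignment block.

    ``ref_aligned`` is the reference row including gap characters; ``rows``
    maps non-reference species name to an aligned row of identical length.
    """

    ref_chrom: str
    ref_start: int
    ref_aligned: str
    rows: dict[str, str]
    block_score: float | None = None

    @property
    def ref_span(self) -> int:
        """Number of reference bases covered (gaps consume no coordinate)."""
        return len(self.ref_aligned) - self.ref_aligned.count("-")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span

    def validate(self) -> None:
        width = len(self.ref_aligned)
        for sp, row in self.rows.items():
            if len(row) != width:
                raise FormatError(
                    f"ragged row for species {sp!r} in block at "
                    f"{self.ref_chrom}:{self.ref_start}: {len(row)} != {width}"
                )


@dataclass
class GenomeDict:
    """Chromosome lengths plus the reference species name."""

    lengths: dict[str, int]
    ref_name: str

    def __post_init__(self) -> None:
        for chrom, n in self.lengths.items():
            if n <= 0:
                raise ConfigError(f"non-positive length for chromosome {chrom!r}")

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())


@dataclass
class CladeMap:
    """Ordered clade name -> set of non-reference species. Clades may nest."""

    clades: dict[str, frozenset[str]]
    ref_name: str | None = None

    def __post_init__(self) -> None:
        self.clades = {k: frozenset(v) for k, v in self.clades.items()}
        for name, spp in self.clades.items():
            if not spp:
                raise ConfigError(f"clade {name!r} is empty")
            if self.ref_name is not None and self.ref_name in spp:
                raise ConfigError(
                    f"reference {self.ref_name!r} appears in clade {name!r}"
                )

    def species(self, clade: str) -> frozenset[str]:
        try:
            return self.clades[clade]
        except KeyError:
            raise ConfigError(f"unknown clade {clade!r}") from None

    @property
    def names(self) -> list[str]:
        return list(self.clades)

    @property
    def all_species(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for spp in self.clades.values():
            out |= spp
        return out


@dataclass
class SNPRecord:
    """A biallelic population SNP in internal (0-based) coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str
    an: int
    ac: int
    effects: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.ac <= self.an:
            raise ConfigError(
                f"SNP {self.chrom}:{self.pos}: AC={self.ac} outside [0, AN={self.an}]"
            )

    @property
    def maf(self) -> float:
        """Folded minor allele frequency in [0, 0.5]."""
        f = self.ac / self.an
        return min(f, 1.0 - f)


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

_MAF_SPECIES_RE = re.compile(r"^([^.]+)")


def read_maf(
    path,
    ref_name: str,
    clade_map: CladeMap | None = None,
    species_regex: str | re.Pattern = _MAF_SPECIES_RE,
    min_block_score: float | None = None,
) -> Iterator[AlignmentBlock]:
    """Stream alignment blocks from a MAF 1.0 file.

    The species of an ``s`` line is the text its source name yields under
    ``species_regex`` (default: everything before the first ``.``, the UCSC
    convention).  Exactly one row per block must belong to ``ref_name`` and it
    must be on the forward strand.  Species absent from ``clade_map`` trigger
    a warning but are kept.
    """
    pattern = re.compile(species_regex) if isinstance(species_regex, str) else species_regex
    known = None
    if clade_map is not None:
        known = set(clade_map.all_species) | {ref_name}
    warned: set[str] = set()

    with open(path) as fh:
        block_lines: list[str] = []
        score: float | None = None
        index = 0
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#"):
                continue
            if line.startswith("a"):
                if block_lines:
                    blk = _parse_block(block_lines, score, ref_name, pattern, index)
                    index += 1
                    if _block_passes(blk, min_block_score):
                        _warn_unknown(blk, known, warned)
                        yield blk
                block_lines = []
                score = _parse_score(line)
            elif line.startswith("s"):
                block_lines.append(line)
            elif not line.strip():
                continue
        if block_lines:
            blk = _parse_block(block_lines, score, ref_name, pattern, index)
            if _block_passes(blk, min_block_score):
                _warn_unknown(blk, known, warned)
                yield blk


def _parse_score(a_line: str) -> float | None:
    m = re.search(r"score=([-\d.eE+]+)", a_line)
    return float(m.group(1)) if m else None


def _block_passes(blk: AlignmentBlock, min_score: float | None) -> bool:
    if min_score is None or blk.block_score is None:
        return True
    return blk.block_score >= min_score


def _warn_unknown(blk: AlignmentBlock, known: set | None, warned: set) -> None:
    if known is None:
        return
    for sp in blk.rows:
        if sp not in known and sp not in warned:
            warned.add(sp)
            warnings.warn(f"species {sp!r} not in clade map; row kept", stacklevel=3)


def _parse_block(lines, score, ref_name, pattern, index) -> AlignmentBlock:
    ref_row = None
    rows: dict[str, str] = {}
    for line in lines:
        parts = line.split()
        if len(parts) != 7:
            raise FormatError(f"malformed s line in block {index}: {line!r}")
        _, src, start, size, strand, src_size, text = parts
        m = pattern.match(src)
        species = m.group(1) if m else src
        if species == ref_name:
            if ref_row is not None:
                raise FormatError(f"multiple reference rows in block {index}")
            if strand != "+":
                raise FormatError(
                    f"reference row on '-' strand in block {index}; "
                    "reference must be forward strand"
                )
            chrom = src[len(species) + 1:] if src.startswith(species + ".") else src
            ref_row = (chrom, int(start), text)
        else:
            if species in rows:
                raise FormatError(f"duplicate species {species!r} in block {index}")
            rows[species] = text
    if ref_row is None:
        raise FormatError(f"block {index} has no reference ({ref_name!r}) row")
    chrom, start, text = ref_row
    blk = AlignmentBlock(chrom, start, text, rows, block_score=score)
    try:
        blk.validate()
    except FormatError as exc:
        raise FormatError(f"block {index}: {exc}") from None
    return blk


def write_maf(blocks: Iterable[AlignmentBlock], path, ref_name: str,
              src_sizes: dict[str, int] | None = None) -> None:
    """Write blocks as MAF 1.0. Non-reference rows get forward-strand
    pseudo-coordinates (the scorer never uses them)."""
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for blk in blocks:
            score = blk.block_score if blk.block_score is not None else 0
            fh.write(f"a score={score}\n")
            size = blk.ref_span
            src = f"{ref_name}.{blk.ref_chrom}"
            src_size = (src_sizes or {}).get(blk.ref_chrom, blk.ref_end)
            fh.write(f"s {src} {blk.ref_start} {size} + {src_size} {blk.ref_aligned}\n")
            for sp, row in blk.rows.items():
                sp_size = len(row) - row.count("-")
                fh.write(f"s {sp}.{blk.ref_chrom} {blk.ref_start} {sp_size} + "
                         f"{src_size} {row}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    tid: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return out

    def utrs(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(5'-UTR intervals, 3'-UTR intervals), derived as exon minus CDS."""
        if not self.cds:
            return [], []
        cds_lo = self.cds[0][0]
        cds_hi = self.cds[-1][1]
        left, right = [], []
        for s, e in self.exons:
            if s < cds_lo:
                left.append((s, min(e, cds_lo)))
            if e > cds_hi:
                right.append((max(s, cds_hi), e))
        if self.strand == "+":
            return left, right
        return right, left


@dataclass
class Gene:
    gid: str
    chrom: str
    strand: str
    transcripts: list[Transcript]

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start position (0-based) on the gene's strand."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GeneModels:
    genes: list[Gene]

    def __post_init__(self) -> None:
        self.by_id = {g.gid: g for g in self.genes}

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def read_gff3(path, genome: GenomeDict) -> GeneModels:
    """Load gene/mRNA/exon/CDS features into 0-based half-open gene models.

    UTRs and introns are derived (exon minus CDS; inter-exon gaps), so
    explicit UTR features in the file are ignored.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for gf in db.features_of_type("gene"):
        transcripts = []
        for tf in db.children(gf, featuretype=("mRNA", "transcript"), level=1):
            exons = [(f.start - 1, f.end) for f in db.children(tf, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(tf, featuretype="CDS")]
            t = Transcript(tf.id, tf.seqid, tf.strand, tf.start - 1, tf.end,
                           exons, cds)
            _check_transcript(t, genome)
            transcripts.append(t)
        if transcripts:
            genes.append(Gene(gf.id, gf.seqid, gf.strand, transcripts))
    return GeneModels(genes)


def _check_transcript(t: Transcript, genome: GenomeDict) -> None:
    limit = genome.lengths.get(t.chrom)
    if limit is None:
        raise FormatError(f"transcript {t.tid}: unknown chromosome {t.chrom!r}")
    if t.end > limit or t.start < 0:
        raise FormatError(
            f"transcript {t.tid} extends beyond chromosome {t.chrom} "
            f"(length {limit})"
        )
    for cs, ce in t.cds:
        if not any(es <= cs and ce <= ee for es, ee in t.exons):
            raise FormatError(
                f"transcript {t.tid}: CDS [{cs},{ce}) outside any exon"
            )


def write_gff3(models: GeneModels, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            fh.write(f"{g.chrom}\tcnscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gid}\n")
            for t in g.transcripts:
                fh.write(f"{t.chrom}\tcnscan\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                         f"{t.strand}\t.\tID={t.tid};Parent={g.gid}\n")
                for i, (s, e) in enumerate(t.exons, 1):
                    fh.write(f"{t.chrom}\tcnscan\texon\t{s + 1}\t{e}\t.\t"
                             f"{t.strand}\t.\tID={t.tid}.exon{i};Parent={t.tid}\n")
                for i, (s, e) in enumerate(t.cds, 1):
                    fh.write(f"{t.chrom}\tcnscan\tCDS\t{s + 1}\t{e}\t.\t"
                             f"{t.strand}\t0\tID={t.tid}.cds{i};Parent={t.tid}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

class VCFReader:
    """Iterator over biallelic SNPRecords from a VCF 4.x file.

    Multiallelic records are skipped (default) or split into per-alt records;
    skip counts are kept on the reader (``n_multiallelic``, ``n_non_snp``).
    """

    def __init__(self, path, multiallelic: str = "skip"):
        if multiallelic not in ("skip", "split"):
            raise ConfigError(f"multiallelic mode {multiallelic!r}")
        self.path = str(path)
        self.multiallelic = multiallelic
        self.n_multiallelic = 0
        self.n_non_snp = 0

    def __iter__(self) -> Iterator[SNPRecord]:
        from cyvcf2 import VCF

        vcf = VCF(self.path)
        for v in vcf:
            alts = v.ALT
            if len(alts) > 1:
                self.n_multiallelic += 1
                if self.multiallelic == "skip":
                    continue
            an = v.INFO.get("AN")
            acs = v.INFO.get("AC")
            if isinstance(acs, (int, float)):
                acs = (int(acs),)
            if an is None or acs is None:
                an = 2 * len(vcf.samples)
                acs = tuple(int(round(v.aaf * an)) for _ in alts)
            effects = _parse_ann(v.INFO.get("ANN") or v.INFO.get("EFF"))
            use = alts if self.multiallelic == "split" else alts[:1]
            for alt, ac in zip(use, acs):
                if len(v.REF) != 1 or len(alt) != 1:
                    self.n_non_snp += 1
                    continue
                yield SNPRecord(v.CHROM, v.POS - 1, v.REF, alt, int(an), int(ac),
                                effects=effects)
        if self.n_multiallelic and self.multiallelic == "skip":
            warnings.warn(
                f"{self.n_multiallelic} multiallelic records skipped in "
                f"{self.path}", stacklevel=2)


def read_vcf(path, multiallelic: str = "skip") -> VCFReader:
    return VCFReader(path, multiallelic=multiallelic)


_IMPACTS = {"HIGH", "MODERATE", "LOW", "MODIFIER"}


def _parse_ann(raw) -> list[tuple[str, str]]:
    """Parse SnpEff v4 ANN entries to (effect, impact) pairs; unparseable
    entries are reported as ('unknown', 'MODIFIER')."""
    if raw is None:
        return []
    out = []
    for entry in str(raw).split(","):
        fields = entry.split("|")
        if len(fields) >= 3 and fields[2] in _IMPACTS:
            out.append((fields[1], fields[2]))
        elif len(fields) >= 2 and fields[1]:
            out.append((fields[1], "MODIFIER"))
        else:
            out.append(("unknown", "MODIFIER"))
    return out


def write_vcf(snps: Sequence[SNPRecord], path, genome: GenomeDict) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, n in genome.lengths.items():
            fh.write(f"##contig=<ID={chrom},length={n}>\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n')
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Effect annotation">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda r: (r.chrom, r.pos)):
            info = f"AC={s.ac};AN={s.an}"
            if s.effects:
                ann = ",".join(f"{s.alt}|{eff}|{imp}|" for eff, imp in s.effects)
                info += f";ANN={ann}"
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t{info}\n")


# ---------------------------------------------------------------------------
# BED / bedGraph / FASTA / motif table
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            rest = parts[3:]
            if len(rest) >= 2:
                try:
                    rest[1] = float(rest[1])
                except ValueError:
                    pass
            out.append((chrom, start, end, *rest))
    return out


def write_bedgraph(values_by_chrom: dict[str, np.ndarray], path) -> None:
    """Write per-base values as bedGraph, merging runs of equal value."""
    with open(path, "w") as fh:
        for chrom, vals in values_by_chrom.items():
            vals = np.asarray(vals)
            if not np.all(np.isfinite(vals)):
                raise FormatError(f"non-finite bedGraph values on {chrom}")
            if vals.size == 0:
                continue
            change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vals.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{vals[s]:g}\n")


def read_bedgraph(path, genome: GenomeDict) -> dict[str, np.ndarray]:
    out = {c: np.zeros(n) for c, n in genome.lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split()
            out[chrom][int(s):int(e)] = float(v)
    return out


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, build_index=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_motifs(path) -> list:
    """Read a two-column (name, IUPAC pattern) TSV of motifs."""
    from .motifscan import MotifPattern

    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"motif line needs 2 columns: {line!r}")
            out.append(MotifPattern(parts[0], parts[1]))
    return out


def write_motifs(motifs: Iterable, path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f"{m.name}\t{m.pattern}\n")


def read_clade_map(path, ref_name: str | None = None) -> CladeMap:
    """Clade map TSV: clade name, comma-separated species list."""
    clades: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, spp = line.rstrip("\n").split("\t")[:2]
            clades[name] = frozenset(s for s in spp.split(",") if s)
    return CladeMap(clades, ref_name=ref_name)


def write_clade_map(clade_map: CladeMap, path) -> None:
    with open(path, "w") as fh:
        for name, spp in clade_map.clades.items():
            fh.write(f"{name}\t{','.join(sorted(spp))}\n")
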