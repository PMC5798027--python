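import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cnscan import alnio, conscore
from cnscan.simgen import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A written-to-disk fixture bundle exercising every reader."""
    cfg = SimConfig(
        seed=42, genome_length=30_000, n_species=10, n_genes=6,
        background_match=0.2, element_match=0.95, n_elements=15,
        element_length=40, snp_density=0.01, depletion=2.0,
        motifs=[("TATABOX", "TATAWAW"), ("GBOX", "CACGTG")], motif_rate=0.01,
        effect_types={"missense_variant": 0.4, "synonymous_variant": 0.3,
                      "upstream_gene_variant": 0.3},
    )
    outdir = tmp_path_factory.mktemp("sim")
    paths, truth, objects = simulate(cfg, outdir)
    return cfg, paths, truth, objects


@pytest.fixture(scope="session")
def sim_track(sim_bundle):
    cfg, paths, truth, objects = sim_bundle
    track = conscore.score_genome(objects["blocks"], "all", cfg.clade_map(),
                                  cfg.genome())
    return track


def random_blocks(rng, n_species=4, chrom_len=60, n_blocks=3, gap_p=0.15):
    """Random reference-anchored blocks over a toy chromosome (in memory)."""
    species = [f"sp{i}" for i in range(n_species)]
    bases = "ACGT"
    blocks = []
    for _ in range(n_blocks):
        start = int(rng.integers(0, chrom_len - 10))
        span = int(rng.integers(3, min(12, chrom_len - start)))
        ref = "".join(rng.choice(list(bases), span))
        rows = {}
        for sp in species:
            if rng.random() < 0.2:   # species absent from this block
                continue
            row = "".join(
                "-" if rng.random() < gap_p else
                (ref[i] if rng.random() < 0.6 else rng.choice(list(bases)))
                for i in range(span))
            rows[sp] = row
        blocks.append(alnio.AlignmentBlock("chr1", start, ref, rows))
    return species, blocks


def write_gff(path, lines):
    text = "##gff-version 3\n" + "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return path


TWO_EXON_GFF = [
    # exons [0,100) and [200,300), CDS [50,250), forward strand, 1-based here
    "chr1\t.\tgene\t1\t300\t.\t{strand}\t.\tID=g1",
    "chr1\t.\tmRNA\t1\t300\t.\t{strand}\t.\tID=t1;Parent=g1",
    "chr1\t.\texon\t1\t100\t.\t{strand}\t.\tID=t1.e1;Parent=t1",
    "chr1\t.\texon\t201\t300\t.\t{strand}\t.\tID=t1.e2;Parent=t1",
    "chr1\t.\tCDS\t51\t100\t.\t{strand}\t0\tID=t1.c1;Parent=t1",
    "chr1\t.\tCDS\t201\t250\t.\t{strand}\t0\tID=t1.c2;Parent=t1",
]


@pytest.fixture
def two_exon_models(tmp_path):
    def make(strand="+", chrom_len=1000):
        gff = tmp_path / f"two_exon_{strand}.gff3"
        write_gff(gff, [l.format(strand=strand) for l in TWO_EXON_GFF])
        genome = alnio.GenomeDict({"chr1": chrom_len}, "ref")
        return alnio.read_gff3(gff, genome), genome
    return make


def make_track(matched_by_chrom, n_species, clade="all", aligned=None):
    """Build a ScoreTrack directly from matched-count arrays."""
    matched = {c: np.asarray(v, dtype=np.int32)
               for c, v in matched_by_chrom.items()}
    if aligned is None:
        aligned_d = {c: v.copy() for c, v in matched.items()}
    else:
        aligned_d = {c: np.asarray(v, dtype=np.int32)
                     for c, v in aligned.items()}
    return conscore.ScoreTrack(clade, n_species, matched, aligned_d)
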