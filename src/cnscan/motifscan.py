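"""IUPAC motif scanning and enrichment statistics.

Hits are counted per (position, strand) window; overlapping hits all count
and palindromes therefore count once per strand.  Enrichment uses a
binomial-per-position null: with background hit rate p estimated from a
disjoint background scan, the expected count in a set of n scanned windows
is n*p and z = (obs - n*p) / sqrt(n*p*(1-p)).  The chi-squared statistic
comes from the 2x2 hit/non-hit x CNS/background table with 1 df and no
continuity correction.  'Enriched' means z strictly greater than 2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alnio import ConfigError, FormatError, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}


@dataclass(frozen=True)
class MotifPattern:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        bad = [ch for ch in pat if ch not in IUPAC]
        if bad:
            raise FormatError(
                f"motif {self.name!r}: non-IUPAC letter(s) {''.join(bad)!r}")
        if len(pat) < 4:
            raise FormatError(f"motif {self.name!r}: length {len(pat)} < 4")

    def __len__(self) -> int:
        return len(self.pattern)

    def regex(self) -> re.Pattern:
        # lookahead makes overlapping hits visible
        body = "".join(f"[{IUPAC[ch]}]" for ch in self.pattern)
        return re.compile(f"(?={body})")


def scan(seq: str, motif: MotifPattern, both_strands: bool = True) -> int:
    """Count motif hits in a sequence; an N in the sequence only satisfies a
    pattern N."""
    rx = motif.regex()
    seq = seq.upper()
    n = len(rx.findall(seq))
    if both_strands:
        n += len(rx.findall(revcomp(seq)))
    return n


def scan_positions(seq: str, motif: MotifPattern) -> list[int]:
    """Forward-strand hit offsets (for truth bookkeeping)."""
    return [m.start() for m in motif.regex().finditer(seq.upper())]


@dataclass
class MotifEnrichment:
    motif: str
    category: str
    observed: int
    scanned: int
    bg_observed: int
    bg_scanned: int
    bg_rate: float
    expected: float
    z: float
    chi2: float
    chi2_p: float
    fold: float

    @property
    def enriched(self) -> bool:
        return self.z > 2


def enrichment(obs_cns: int, bp_cns: int, obs_bg: int, bp_bg: int,
               motif: str = "", category: str = "") -> MotifEnrichment:
    """Enrichment of a motif in a CNS scan against a disjoint background
    scan; see module docstring for the null model."""
    if bp_bg <= 0:
        raise ConfigError("background scan is empty")
    if bp_cns == 0:
        nan = float("nan")
        return MotifEnrichment(motif, category, obs_cns, 0, obs_bg, bp_bg,
                               obs_bg / bp_bg, nan, nan, nan, nan, nan)
    p = obs_bg / bp_bg
    expected = p * bp_cns
    if p == 0 or p == 1:
        z = float("inf") if obs_cns > expected else (
            float("-inf") if obs_cns < expected else 0.0)
    else:
        z = (obs_cns - expected) / np.sqrt(bp_cns * p * (1 - p))
    table = np.array([[obs_cns, bp_cns - obs_cns], [obs_bg, bp_bg - obs_bg]])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        chi2 = chi2_p = float("nan")
    else:
        chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    fold = obs_cns / expected if expected > 0 else float("inf")
    return MotifEnrichment(motif, category, obs_cns, bp_cns, obs_bg, bp_bg,
                           p, expected, float(z), float(chi2), float(chi2_p),
                           float(fold))


def n_windows(seqs: Iterable[str], k: int, both_strands: bool = True) -> int:
    total = sum(max(0, len(s) - k + 1) for s in seqs)
    return total * (2 if both_strands else 1)


def enrichment_table(
    cns_seqs_by_category: Mapping[str, Sequence[str]],
    background_seqs: Sequence[str],
    motifs: Sequence[MotifPattern],
    both_strands: bool = True,
) -> pd.DataFrame:
    """Fold/z matrix over (motif, CNS category) against a background scan.

    Windows extending past element ends are never scanned or counted, on
    either side of the contingency table.
    """
    rows = []
    bg_hits = {m.name: sum(scan(s, m, both_strands) for s in background_seqs)
               for m in motifs}
    for category, seqs in cns_seqs_by_category.items():
        for m in motifs:
            obs = sum(scan(s, m, both_strands) for s in seqs)
            e = enrichment(obs, n_windows(seqs, len(m), both_strands),
                           bg_hits[m.name],
                           n_windows(background_seqs, len(m), both_strands),
                           motif=m.name, category=category)
            rows.append({"motif": e.motif, "category": e.category,
                         "observed": e.observed, "scanned": e.scanned,
                         "expected": e.expected, "fold": e.fold, "z": e.z,
                         "chi2": e.chi2, "chi2_p": e.chi2_p,
                         "enriched": e.enriched})
    return pd.DataFrame(rows)


def extract_sequences(genome_seqs: Mapping[str, str],
                      intervals: Iterable[tuple[str, int, int]]) -> list[str]:
    return [genome_seqs[c][s:e] for c, s, e in intervals]


def background_intervals(genome_lengths: Mapping[str, int],
                         exclude: Iterable[tuple[str, int, int]]
                         ) -> list[tuple[str, int, int]]:
    """Complement of the excluded intervals: the non-CNS genome."""
    mask = {c: np.zeros(n, dtype=bool) for c, n in genome_lengths.items()}
    for c, s, e in exclude:
        mask[c][s:e] = True
    out = []
    for c, m in mask.items():
        free = ~m
        idx = np.flatnonzero(free)
        if idx.size == 0:
            continue
        brk = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([idx[0]], idx[brk + 1]))
        ends = np.concatenate((idx[brk] + 1, [idx[-1] + 1]))
        out.extend((c, int(s), int(e)) for s, e in zip(starts, ends))
    return out
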