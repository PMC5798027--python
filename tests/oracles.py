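"""Independent brute-force oracles, written against the definitions only.

These deliberately avoid numpy vectorization and share no code with the
package implementations they check.
"""

from fractions import Fraction

ACGT = set("ACGT")


def score_column_oracle(ref_base, bases, clade_species):
    """(matched, aligned) for one column, by direct per-species counting."""
    matched = 0
    aligned = 0
    for sp in clade_species:
        b = bases.get(sp)
        if b is None or b == "-":
            continue
        aligned += 1
        if ref_base.upper() in ACGT and b.upper() == ref_base.upper():
            matched += 1
    return matched, aligned


def score_blocks_oracle(blocks, clade_species, chrom_len):
    """Per-position (matched, aligned) lists for a single chromosome, walking
    every block column by column with per-species first-wins bookkeeping."""
    matched = [0] * chrom_len
    aligned = [0] * chrom_len
    seen = {sp: set() for sp in clade_species}
    for blk in blocks:
        pos = blk.ref_start
        for col in range(len(blk.ref_aligned)):
            ref_char = blk.ref_aligned[col]
            if ref_char == "-":
                continue
            for sp in clade_species:
                row = blk.rows.get(sp)
                if row is None or row[col] == "-":
                    continue
                if pos in seen[sp]:
                    continue
                seen[sp].add(pos)
                aligned[pos] += 1
                if (ref_char.upper() in ACGT
                        and row[col].upper() == ref_char.upper()):
                    matched[pos] += 1
            pos += 1
    return matched, aligned


def call_cns_oracle(matched, n_species, cds_mask, threshold, merge_gap,
                    min_len):
    """Naive left-to-right CNS caller over per-base matched counts.

    Returns a list of (start, end) intervals. Threshold comparison is exact
    (Fraction), matching the definition rather than the implementation.
    """
    thr = Fraction(str(threshold))
    L = len(matched)
    above = [(not cds_mask[i]) and Fraction(matched[i], n_species) >= thr
             for i in range(L)]
    runs = []
    i = 0
    while i < L:
        if above[i]:
            j = i
            while j < L and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    merged = []
    for s, e in runs:
        if merged:
            ps, pe = merged[-1]
            gap_has_cds = any(cds_mask[k] for k in range(pe, s))
            if s - pe <= merge_gap and not gap_has_cds:
                merged[-1] = (ps, e)
                continue
        merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= min_len]


def gene_mean_oracle(matched, n_species, start, end):
    vals = [matched[i] / n_species for i in range(start, end)]
    return sum(vals) / len(vals)


def set_algebra_oracle(sets_by_clade):
    """(exclusive per clade, common) by literal definition."""
    exclusive = {}
    for clade in sets_by_clade:
        others = set()
        for other, s in sets_by_clade.items():
            if other != clade:
                others.update(s)
        exclusive[clade] = {g for g in sets_by_clade[clade] if g not in others}
    common = None
    for s in sets_by_clade.values():
        common = set(s) if common is None else {g for g in common if g in s}
    return exclusive, common or set()


IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T", "N"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def scan_oracle(seq, pattern, both_strands=True):
    """Regex-free sliding-window motif hit count."""
    seq = seq.upper()

    def count(s):
        k = len(pattern)
        n = 0
        for i in range(len(s) - k + 1):
            if all(s[i + j] in IUPAC_SETS[pattern[j]] for j in range(k)):
                n += 1
        return n

    total = count(seq)
    if both_strands:
        rc = "".join(_COMP.get(c, "N") for c in reversed(seq))
        total += count(rc)
    return total


def profile_oracle(score_by_pos, genes, anchor, flank):
    """Direct gather-and-average meta-profile oracle.

    ``genes`` is a list of (start, end, strand); score_by_pos a plain list.
    """
    L = len(score_by_pos)
    sums = [0.0] * (2 * flank + 1)
    ns = [0] * (2 * flank + 1)
    for start, end, strand in genes:
        if strand == "+":
            a = start if anchor == "TSS" else end - 1
            sign = 1
        else:
            a = end - 1 if anchor == "TSS" else start
            sign = -1
        for k, off in enumerate(range(-flank, flank + 1)):
            p = a + sign * off
            if 0 <= p < L:
                sums[k] += score_by_pos[p]
                ns[k] += 1
    return [s / n if n else float("nan") for s, n in zip(sums, ns)], ns
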