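"""Independent brute-force oracle for NG86-style codon counting.

Deliberately written from first principles and independently of the
package: its own hardcoded genetic code, direct enumeration of
single-nucleotide mutants for site counts, and explicit enumeration of
all substitution orderings for pathway difference counts.
"""

import itertools
import math

# standard genetic code, written out by hand ('*' = stop)
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
SENSE = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def oracle_sites(codon):
    """(synonymous, nonsynonymous) site counts by direct mutant enumeration."""
    aa = GENETIC_CODE[codon]
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base != codon[pos]:
                mutant = codon[:pos] + base + codon[pos + 1:]
                if GENETIC_CODE[mutant] == aa:
                    syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def oracle_diffs(ca, cb):
    """(syn, nonsyn) step counts averaged over stop-free minimal pathways."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    all_paths = []
    for order in itertools.permutations(positions):
        steps = []
        cur = ca
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                through_stop = True
                steps.append("N")
            elif GENETIC_CODE[cur] != "*" and GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                steps.append("S")
            else:
                steps.append("N")
            cur = nxt
        all_paths.append((steps, through_stop))
    kept = [s for s, bad in all_paths if not bad]
    if not kept:
        kept = [s for s, _ in all_paths]
    sd = sum(s.count("S") for s in kept) / len(kept)
    nd = sum(s.count("N") for s in kept) / len(kept)
    return sd, nd


def oracle_pair_counts(seq_a, seq_b):
    """(S, N, Sd, Nd, n_codons) for an aligned pair, codon by codon."""
    S = N = Sd = Nd = 0.0
    used = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if any(c not in "ACGT" for c in ca + cb):
            continue
        if GENETIC_CODE.get(ca) == "*" or GENETIC_CODE.get(cb) == "*":
            continue
        sa, na = oracle_sites(ca)
        sb, nb = oracle_sites(cb)
        ds, dn = oracle_diffs(ca, cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += ds
        Nd += dn
        used += 1
    return S, N, Sd, Nd, used


def oracle_jc(p):
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
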