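"""Independent brute-force oracles, written literally from first principles.

These deliberately share no code with the package internals: the design
oracle enumerates EVERY 23-nt window on both strands and applies the
discrimination rules verbatim; the off-target oracle slides a window over
every position of every contig counting mismatches character by character;
the threshold oracle computes median and MAD by sorting.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(_COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# median / MAD / AF_cut
# ---------------------------------------------------------------------------

def sort_median(xs):
    s = sorted(xs)
    n = len(s)
    if n == 0:
        raise ValueError("median of empty list")
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2.0


def af_cut_oracle(het_afs, mad_constant=1.0):
    med = sort_median(het_afs)
    mad = sort_median([abs(x - med) for x in het_afs])
    return med + mad_constant * mad


# ---------------------------------------------------------------------------
# Design sites
# ---------------------------------------------------------------------------

def design_sites_oracle(wt, mut, k, seed_window=12):
    """All allele-discriminating placements as a set of
    (protospacer_start, strand, design_class, snv_position_in_spacer,
    spacer_mut) with context_start = 1."""
    L = len(mut)
    found = set()
    for strand in "+-":
        w = wt if strand == "+" else rc(wt)
        m = mut if strand == "+" else rc(mut)
        kk = k if strand == "+" else L - 1 - k
        for i in range(0, L - 23 + 1):
            spacer = m[i:i + 20]
            pam = m[i + 20:i + 23]
            if any(c not in "ACGT" for c in spacer + pam):
                continue
            if not (pam[1] == "G" and pam[2] == "G"):
                continue
            if strand == "+":
                g_start = 1 + i
            else:
                g_start = (1 + (L - 1 - i)) - 19
            if i <= kk < i + 20:
                q = kk - i + 1
                if q >= 21 - seed_window:
                    found.add((g_start, strand, "snv_in_seed", q, spacer))
            elif kk == i + 21 or kk == i + 22:
                wpam = w[i + 20:i + 23]
                if not (wpam[1] == "G" and wpam[2] == "G"):
                    found.add((g_start, strand, "snv_in_pam", 0, spacer))
            # kk == i + 20 (PAM position 1, the N) never discriminates
    return found


# ---------------------------------------------------------------------------
# Off-target scan
# ---------------------------------------------------------------------------

def _pam_matches(pam, motifs):
    iupac = {"N": "ACGT", "A": "A", "C": "C", "G": "G", "T": "T",
             "R": "AG", "Y": "CT"}
    for motif in motifs:
        if all(b in iupac[m] for b, m in zip(pam, motif)):
            return True
    return False


def off_targets_oracle(spacer, seqs, max_mismatches, pam_motifs=("NGG",),
                       exclude=None):
    """Hit set as {(chrom, start, end, strand, n_mismatches)} by literal
    full scan of every window on both strands."""
    hits = set()
    for chrom in sorted(seqs):
        seq = seqs[chrom].upper()
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else rc(seq)
            for i in range(L - 23 + 1):
                win = s[i:i + 23]
                if any(c not in "ACGT" for c in win):
                    continue
                if not _pam_matches(win[20:23], pam_motifs):
                    continue
                mm = sum(a != b for a, b in zip(win[:20], spacer))
                if mm > max_mismatches:
                    continue
                if strand == "+":
                    start, end = i + 1, i + 20
                else:
                    end = L - i
                    start = end - 19
                if exclude is not None and chrom == exclude[0] \
                        and start <= exclude[2] and end >= exclude[1]:
                    continue
                hits.add((chrom, start, end, strand, mm))
    return hits


def cfd_oracle(spacer, site, pam, model):
    """CFD by explicit hand multiplication over mismatched positions."""
    value = model.pam_penalty.get(pam[1:3], 0.0)
    for p in range(20):
        if spacer[p] != site[p]:
            value = value * model.mismatch_penalty[(p + 1, spacer[p], site[p])]
    return value
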