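"""Independent brute-force oracles shared across test modules."""

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_orfs(seq: str, min_nt: int):
    """Enumerate maximal stop-free codon runs in all six frames.

    Returns a set of (strand, frame, forward_start, forward_end) tuples;
    runs truncated by the sequence end are included, stop codons excluded.
    """
    out = set()
    length = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            codon_starts = list(range(frame, length - 2, 3))
            run = []
            for i in codon_starts + [None]:
                if i is None or s[i : i + 3] in _STOPS:
                    if run and (run[-1] + 3 - run[0]) >= min_nt:
                        rs, re = run[0], run[-1] + 3
                        if strand == "+":
                            out.add((strand, frame, rs, re))
                        else:
                            out.add((strand, frame, length - re, length - rs))
                    run = []
                else:
                    run.append(i)
    return out


def brute_force_bh(p_values):
    """BH adjusted p_i = min over ranks j >= rank(i) of m * p_(j) / j."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = [m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)]
        adjusted[i] = min(1.0, min(candidates))
    return adjusted
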