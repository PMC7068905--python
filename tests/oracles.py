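"""Independent brute-force reference implementations used only by tests.

These deliberately re-derive results the package computes, by the most
naive route available, so agreement is meaningful.
"""

_STOPS = {"TAA", "TAG", "TGA"}


def brute_force_uorfs(seq, morf_start, morf_end, start_codons=("ATG",)):
    """Position-by-position leader walk with codon-wise translation.

    Returns a list of (start, stop_end_or_None, type) sorted by start.
    """
    starts = set(start_codons)
    out = []
    for i in range(morf_start):
        if seq[i : i + 3] not in starts:
            continue
        j = i + 3
        stop_end = None
        while j + 3 <= len(seq):
            if seq[j : j + 3] in _STOPS:
                stop_end = j + 3
                break
            j += 3
        if stop_end is None:
            utype = "unterminated"
        elif stop_end <= morf_start:
            utype = "Type1"
        elif (morf_start - i) % 3 == 0 and stop_end == morf_end:
            utype = "Type3"
        else:
            utype = "Type2"
        out.append((i, stop_end, utype))
    return out


_ORIGIN_RANK = {
    "reference": 0,
    "snp-only": 0,
    "deletion-bearing": 1,
    "insertion-bearing": 2,
}


def brute_force_identifiers(forms):
    """Composite-key sort over the full deduplicated form set.

    Level1 key: (anchor, length, origin rank, group's smallest variant
    position tuple); Level2 key: (SNP count, variant positions, sequence).
    Returns {(anchor, sequence): "L1.L2"}.
    """
    unique = {}
    for f in forms:
        unique.setdefault((f.anchor, f.sequence), f)
    group_keys = sorted(
        {(f.anchor, f.length, _ORIGIN_RANK[f.origin]) for f in unique.values()},
        key=lambda g: (
            g[0],
            g[1],
            g[2],
            min(
                f.variant_positions
                for f in unique.values()
                if (f.anchor, f.length, _ORIGIN_RANK[f.origin]) == g
            ),
        ),
    )
    out = {}
    for l1, gkey in enumerate(group_keys, start=1):
        members = sorted(
            (
                f
                for f in unique.values()
                if (f.anchor, f.length, _ORIGIN_RANK[f.origin]) == gkey
            ),
            key=lambda f: (f.n_snps, f.variant_positions, f.sequence),
        )
        for l2, f in enumerate(members, start=1):
            out[(f.anchor, f.sequence)] = f"{l1}.{l2}"
    return out


def random_cdna(rng, max_len=500):
    """A random A/C/G/T cDNA with a random in-frame mORF placement."""
    n = rng.randrange(30, max_len + 1)
    seq = "".join("ACGT"[rng.randrange(4)] for _ in range(n))
    morf_start = rng.randrange(0, n - 8)
    max_codons = (n - morf_start) // 3
    n_codons = rng.randrange(2, max_codons + 1)
    morf_end = morf_start + 3 * n_codons
    return seq, morf_start, morf_end
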