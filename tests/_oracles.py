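"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the ORF oracle
slides each frame codon by codon and splits on stops; the clustering
oracle is a naive agglomerative complete-linkage implementation.
"""

from __future__ import annotations

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")

# stop codons in all six frames; used to build contigs whose longest ORF
# is known by construction
STOP_CASSETTE = "TTAATTAATTAA"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_orfs(sequence: str, min_codons: int = 1) -> set[tuple[int, int, int]]:
    """All maximal stop-free codon runs as (frame, fwd_start, fwd_end).

    Terminal runs without a bounding stop are included.  Coordinates are
    0-based half-open on the forward strand.
    """
    seq = sequence.upper()
    length = len(seq)
    out: set[tuple[int, int, int]] = set()
    for sign, s in ((1, seq), (-1, revcomp(seq))):
        for offset in range(3):
            frame = sign * (offset + 1)
            run_start = None
            i = offset
            while i + 3 <= len(s):
                codon = s[i : i + 3]
                if codon in STOPS:
                    if run_start is not None and (i - run_start) // 3 >= min_codons:
                        out.add(_fwd(frame, run_start, i, length))
                    run_start = None
                else:
                    if run_start is None:
                        run_start = i
                i += 3
            if run_start is not None and (i - run_start) // 3 >= min_codons:
                out.add(_fwd(frame, run_start, i, length))
    return out


def _fwd(frame: int, s: int, e: int, length: int) -> tuple[int, int, int]:
    if frame > 0:
        return (frame, s, e)
    return (frame, length - e, length - s)


def longest_orf_codons(sequence: str) -> int:
    orfs = brute_force_orfs(sequence, 1)
    return max(((e - s) // 3 for _, s, e in orfs), default=0)


def complete_linkage_leaf_order(points: np.ndarray) -> list[int]:
    """Leaf order of naive agglomerative complete-linkage clustering.

    Follows the standard dendrogram conventions: merged clusters get the
    next index n, n+1, ...; each linkage row stores (lo, hi) cluster
    indices; the leaf order is a pre-order traversal visiting the
    lower-index child first.  Distances must be distinct for the order
    to be unambiguous.
    """
    n = len(points)
    members = {i: [i] for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d = max(
                    float(np.linalg.norm(points[x] - points[y]))
                    for x in members[a]
                    for y in members[b]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        members[nxt] = members[a] + members[b]
        children[nxt] = (min(a, b), max(a, b))
        active = [c for c in active if c not in (a, b)] + [nxt]
        nxt += 1

    def leaves(c: int) -> list[int]:
        if c < n:
            return [c]
        lo, hi = children[c]
        return leaves(lo) + leaves(hi)

    return leaves(nxt - 1)
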