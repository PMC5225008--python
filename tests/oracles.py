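"""Independent brute-force reference implementations used to check the package.

Everything here is deliberately naive: coordinate-set enumeration, exhaustive
split enumeration, BFS connected components, all-substring comparison. None
of it shares code with the package paths it validates.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Set, Tuple


def overlap_by_enumeration(a, b) -> int:
    """Shared bases of two closed intervals by enumerating coordinates."""
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end + 1)) & set(range(b.start, b.end + 1)))


def split_decompositions(
    junction: str, ref_a: str, anchor_a: int, ref_b: str, anchor_b_end: int
) -> dict:
    """Enumerate every decomposition of a junction into A-prefix ⊕ insert ⊕ B-suffix.

    ``anchor_a`` is the offset in ref_a where the junction's first base sits;
    ``anchor_b_end`` is the offset in ref_b of the junction's last base.
    Returns the set of admissible blunt/overlap split indices (insertion-free
    placements) and, when none exists, the minimal-insertion decompositions.
    """
    n = len(junction)
    prefix_ok = [True]
    for i in range(n):
        off = anchor_a + i
        prefix_ok.append(
            prefix_ok[-1] and off < len(ref_a) and junction[i] == ref_a[off]
        )
    suffix_ok = [True] * (n + 1)
    for j in range(n - 1, -1, -1):
        off = anchor_b_end - (n - 1 - j)
        suffix_ok[j] = suffix_ok[j + 1] and off >= 0 and junction[j] == ref_b[off]
    placements = [i for i in range(n + 1) if prefix_ok[i] and suffix_ok[i]]
    if placements:
        return {"placements": placements, "insertion": None}
    pairs = [
        (i, j)
        for i in range(n + 1)
        if prefix_ok[i]
        for j in range(i, n + 1)
        if suffix_ok[j]
    ]
    min_gap = min(j - i for i, j in pairs)
    minimal = [(i, j) for i, j in pairs if j - i == min_gap]
    return {"placements": [], "insertion": {
        "length": min_gap,
        "pairs": minimal,
        "strings": sorted({junction[i:j] for i, j in minimal}),
    }}


def connected_component_clusters(
    items: Sequence, compatible
) -> List[Set[int]]:
    """BFS connected components under a pairwise compatibility predicate."""
    n = len(items)
    seen = [False] * n
    comps: List[Set[int]] = []
    for s in range(n):
        if seen[s]:
            continue
        comp = {s}
        seen[s] = True
        frontier = [s]
        while frontier:
            u = frontier.pop()
            for v in range(n):
                if not seen[v] and (compatible(items[u], items[v]) or compatible(items[v], items[u])):
                    seen[v] = True
                    comp.add(v)
                    frontier.append(v)
        comps.append(comp)
    return comps


def brute_longest_shared_run(a: str, b: str, min_identity: float) -> int:
    """Longest equal-length substring pair with Hamming identity >= threshold."""
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            limit = min(len(a) - i, len(b) - j)
            matches = 0
            for k in range(limit):
                if a[i + k] == b[j + k]:
                    matches += 1
                length = k + 1
                if matches >= min_identity * length and length > best:
                    best = length
    return best


def brute_known_filter(prediction_span, sv_type: str, catalogue, threshold: float) -> bool:
    """True if the prediction should be removed (>= threshold one-sided overlap)."""
    for rec in catalogue:
        if rec.attributes.get("sv_type") not in (None, sv_type):
            continue
        shared = overlap_by_enumeration(prediction_span, rec.interval)
        if shared / prediction_span.width >= threshold:
            return True
    return False
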