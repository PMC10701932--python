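"""Independent reference implementations used only as test oracles.

These are deliberately written from first principles, sharing no code
with the package's alignment path (which is C-backed): a brute-force
enumerator over all global alignments, a plain three-state affine-gap
DP, a hairpin enumerator, and helpers for tree-topology comparison.
"""

from __future__ import annotations

import itertools

NEG_INF = float("-inf")


def score_alignment(a: str, b: str, moves: str, match: float, mismatch: float,
                    gap_open: float, gap_extend: float, free_end_gaps: bool) -> float:
    """Score one explicit alignment given as a move string (M/D/I).

    D consumes a base of ``a`` against a gap, I consumes a base of ``b``.
    A run of k consecutive gap columns in one sequence costs
    gap_open + k*gap_extend; runs touching either end cost 0 when end
    gaps are free.
    """
    i = j = 0
    score = 0.0
    runs: list[tuple[str, int, bool, bool]] = []  # (kind, len, at_start, at_end)
    pos = 0
    for kind, grp in itertools.groupby(moves):
        k = len(list(grp))
        at_start = pos == 0
        pos += k
        at_end = pos == len(moves)
        if kind == "M":
            for _ in range(k):
                score += match if a[i] == b[j] else mismatch
                i += 1
                j += 1
        else:
            if kind == "D":
                i += k
            else:
                j += k
            if not (free_end_gaps and (at_start or at_end)):
                score -= gap_open + k * gap_extend
    return score


def enumerate_best_score(a: str, b: str, match: float = 5.0, mismatch: float = -4.0,
                         gap_open: float = 10.0, gap_extend: float = 0.5,
                         free_end_gaps: bool = True) -> float:
    """Exhaustive enumeration of every global alignment (tiny inputs only)."""
    m, n = len(a), len(b)
    best = NEG_INF
    stack = [("", 0, 0)]
    while stack:
        moves, i, j = stack.pop()
        if i == m and j == n:
            s = score_alignment(a, b, moves, match, mismatch, gap_open, gap_extend,
                                free_end_gaps)
            if s > best:
                best = s
            continue
        if i < m and j < n:
            stack.append((moves + "M", i + 1, j + 1))
        if i < m and not moves.endswith("I"):  # canonical order: D-runs before I-runs
            stack.append((moves + "D", i + 1, j))
        if j < n:
            stack.append((moves + "I", i, j + 1))
    return best


def gotoh_score(a: str, b: str, match: float = 5.0, mismatch: float = -4.0,
                gap_open: float = 10.0, gap_extend: float = 0.5,
                free_end_gaps: bool = True) -> float:
    """Plain three-state affine-gap global alignment score.

    A gap of length k costs gap_open + k*gap_extend; leading/trailing
    gaps are free when ``free_end_gaps``.
    """
    m, n = len(a), len(b)
    open_cost = gap_open + gap_extend
    M = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    X = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # gap in b (consumes a)
    Y = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = 0.0 if free_end_gaps else -(gap_open + i * gap_extend)
    for j in range(1, n + 1):
        Y[0][j] = 0.0 if free_end_gaps else -(gap_open + j * gap_extend)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - open_cost, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - open_cost)
            Y[i][j] = max(M[i][j - 1] - open_cost, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - open_cost)
    if not free_end_gaps:
        return max(M[m][n], X[m][n], Y[m][n])
    best = NEG_INF
    for i in range(m + 1):
        best = max(best, M[i][n], X[i][n], Y[i][n])
    for j in range(n + 1):
        best = max(best, M[m][j], X[m][j], Y[m][j])
    return best


def hairpin_enumerate(seq: str, window: int, min_stem: int, max_loop: int,
                      max_mismatch: int, min_loop: int = 3) -> set[tuple[int, int, int]]:
    """All (start, stem, loop) inverted repeats in the 3' window (re-derived)."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    w0 = len(seq) - window
    found = set()
    for start in range(w0, len(seq)):
        for stem in range(min_stem, window):
            for loop in range(min_loop, max_loop + 1):
                end = start + 2 * stem + loop
                if end > len(seq):
                    continue
                arm1 = seq[start : start + stem]
                arm2 = seq[start + stem + loop : end]
                mm = sum(1 for x, y in zip(arm1, arm2[::-1]) if comp.get(x) != y)
                if mm <= max_mismatch:
                    found.add((start, stem, loop))
    return found


# ---------------------------------------------------------------------------
# Tree-topology helpers

def tree_splits(adjacency: dict, leaves: list[str]) -> set[frozenset]:
    """Non-trivial leaf bipartitions induced by the tree's internal edges."""
    leafset = set(leaves)
    splits = set()
    seen_edges = set()
    for node, nbrs in adjacency.items():
        for other, _ in nbrs:
            edge = frozenset((node, other))
            if edge in seen_edges:
                continue
            seen_edges.add(edge)
            side = _leaves_on_side(adjacency, node, other, leafset)
            if 1 < len(side) < len(leafset) - 1:
                splits.add(frozenset(side))
    return {min(s, frozenset(leafset - s), key=sorted) for s in splits}


def _leaves_on_side(adjacency: dict, start: str, blocked: str, leafset: set) -> set:
    out, stack, visited = set(), [start], {blocked}
    while stack:
        node = stack.pop()
        if node in visited:
            continue
        visited.add(node)
        if node in leafset:
            out.add(node)
        stack.extend(o for o, _ in adjacency[node] if o not in visited)
    return out


def random_additive_tree(rng, labels: list[str]):
    """A random binary unrooted tree with positive lengths + its distance matrix.

    Returns (distance matrix as dict-of-dict, splits of the true tree).
    """
    import itertools as it

    nodes = list(labels)
    adjacency: dict[str, list[tuple[str, float]]] = {l: [] for l in labels}
    nxt = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[int(i)], nodes[int(j)]
        new = f"x{nxt}"
        nxt += 1
        la, lb = rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)
        adjacency[new] = [(a, la), (b, lb)]
        adjacency[a].append((new, la))
        adjacency[b].append((new, lb))
        nodes = [x for x in nodes if x not in (a, b)] + [new]
    a, b = nodes
    l = rng.uniform(0.05, 1.0)
    adjacency[a].append((b, l))
    adjacency[b].append((a, l))

    def path_len(u, v):
        stack = [(u, 0.0, None)]
        while stack:
            node, d, prev = stack.pop()
            if node == v:
                return d
            for o, w in adjacency[node]:
                if o != prev:
                    stack.append((o, d + w, node))
        raise RuntimeError

    D = {u: {v: (0.0 if u == v else path_len(u, v)) for v in labels} for u in labels}
    return D, tree_splits(adjacency, labels)
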