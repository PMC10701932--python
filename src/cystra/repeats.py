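"""Tandem repeat-unit decomposition and cross-accession structure calls.

A tandem tRNA gene cluster is decomposed into repeating units anchored at
the gene starts: unit i spans [start of gene i, start of gene i+1), and
the last unit extends by the median of the earlier unit lengths (clipped
to the region end).  Units from different accessions are grouped by
neighbor-joining on alignment-identity distances, and structural
differences between accessions (whole-unit gains/losses, partial
deletions) are called from the global alignment of the full cluster
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import numpy as np

from cystra.align import DEFAULT_SCORING, ScoringScheme, identity_matrix, needleman_wunsch
from cystra.io import GeneAnnotation, SequenceRecord, revcomp

__all__ = [
    "RepeatUnit",
    "StructuralEvent",
    "NJTree",
    "UnitPanel",
    "decompose_cluster",
    "nj_tree",
    "group_units",
    "call_structural_events",
    "build_unit_panel",
]


@dataclass
class RepeatUnit:
    """One tandem unit: interval on the (oriented) cluster region plus sequence."""

    accession: str
    cluster_id: str
    index: int  # 1-based, 5'->3' in tRNA transcription direction
    start: int
    end: int
    gene: GeneAnnotation | None
    seq: str
    clipped: bool = False

    @property
    def key(self) -> str:
        return f"{self.accession}.u{self.index}"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class StructuralEvent:
    """A structural difference of one accession relative to the reference."""

    accession: str
    kind: str  # {whole_unit_insertion, whole_unit_deletion, partial_deletion, partial_insertion}
    affected_units: list[int]
    size: int
    position: int = -1  # coordinate on the reference (deletions) / accession (insertions) region


def decompose_cluster(
    region: SequenceRecord,
    genes: list[GeneAnnotation],
    pseudogene: GeneAnnotation | None = None,
    orientation: str | None = None,
    cluster_id: str = "cluster",
) -> list[RepeatUnit]:
    """Decompose a cluster region into gene-anchored repeating units.

    The region is first put into tRNA transcription orientation: if the
    majority of genes lie on '-', the region is reverse-complemented and
    coordinates are flipped.  An even strand split requires an explicit
    ``orientation`` ('+' or '-').
    """
    genes = [g for g in genes if g.category == "gene"]
    if not genes:
        raise ValueError("decompose_cluster: no tRNA genes supplied")
    for g in genes:
        if g.end > len(region.seq):
            raise ValueError(f"gene {g.gene_id} extends past region {region.id}")

    n_plus = sum(1 for g in genes if g.strand == "+")
    n_minus = len(genes) - n_plus
    if orientation is None:
        if n_plus == n_minus:
            raise ValueError(
                "equal numbers of genes on both strands; pass orientation='+'/'-'"
            )
        orientation = "+" if n_plus > n_minus else "-"

    seq = region.seq
    if orientation == "-":
        L = len(seq)
        seq = revcomp(seq)
        genes = [
            GeneAnnotation(
                seqid=g.seqid,
                start=L - g.end,
                end=L - g.start,
                strand="+" if g.strand == "-" else "-",
                gene_id=g.gene_id,
                isotype=g.isotype,
                anticodon=g.anticodon,
                category=g.category,
                high_confidence=g.high_confidence,
            )
            for g in genes
        ]
    genes = sorted(genes, key=lambda g: g.start)

    starts = [g.start for g in genes]
    units: list[RepeatUnit] = []
    lengths = [starts[i + 1] - starts[i] for i in range(len(starts) - 1)]
    for i, g in enumerate(genes):
        if i < len(genes) - 1:
            u_start, u_end, clipped = starts[i], starts[i + 1], False
        else:
            ext = round(median(lengths)) if lengths else len(seq) - starts[i]
            u_end = starts[i] + ext
            clipped = u_end > len(seq)
            u_end = min(u_end, len(seq))
            u_start = starts[i]
        units.append(
            RepeatUnit(
                accession=region.id,
                cluster_id=cluster_id,
                index=i + 1,
                start=u_start,
                end=u_end,
                gene=g,
                seq=seq[u_start:u_end],
                clipped=clipped,
            )
        )
    return units


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou–Nei)

@dataclass
class NJTree:
    """An unrooted NJ tree as an adjacency map with branch lengths."""

    adjacency: dict[str, list[tuple[str, float]]]
    leaves: list[str]

    def newick(self) -> str:
        """Newick string, rooted arbitrarily at the last internal node."""
        internal = [n for n in self.adjacency if n not in set(self.leaves)]
        root = internal[-1] if internal else self.leaves[0]

        def render(node: str, parent: str | None) -> str:
            children = [(c, l) for c, l in self.adjacency[node] if c != parent]
            if not children:
                return node
            inner = ",".join(f"{render(c, node)}:{l:.6f}" for c, l in children)
            return f"({inner})" if node != root or parent is None else f"({inner})"

        return render(root, None) + ";"


def nj_tree(distance_matrix, labels: list[str] | None = None) -> NJTree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Iteratively joins the pair minimizing Q(i,j) = (n−2)·d(i,j) − r_i − r_j,
    with branch lengths from the standard two-point formula; negative branch
    lengths are clamped to 0.  Ties break deterministically on the smallest
    (i, j) pair in node-creation order.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(D - D.T).max() > 1e-9:
        raise ValueError("distance matrix is asymmetric beyond 1e-9")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distance matrix diagonal must be zero")
    if n < 3:
        raise ValueError("nj_tree requires at least 3 taxa")
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    if len(labels) != n or len(set(labels)) != n:
        raise ValueError("labels must be unique and match matrix size")

    adjacency: dict[str, list[tuple[str, float]]] = {lab: [] for lab in labels}
    active = list(labels)  # creation order = tie-break order
    dist = {(a, b): D[i, j] for i, a in enumerate(labels) for j, b in enumerate(labels)}
    next_internal = 0

    def d(a: str, b: str) -> float:
        return 0.0 if a == b else dist[(a, b)]

    while len(active) > 2:
        m = len(active)
        r = {a: sum(d(a, b) for b in active) for a in active}
        best = None
        best_q = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        a, b = active[i], active[j]
        dij = d(a, b)
        la = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dij - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = f"_nj{next_internal}"
        next_internal += 1
        adjacency[new] = [(a, la), (b, lb)]
        adjacency[a].append((new, la))
        adjacency[b].append((new, lb))
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d(a, c) + d(b, c) - dij)
            dist[(new, c)] = dist[(c, new)] = duc
        active = [c for c in active if c not in (a, b)]
        active.append(new)

    a, b = active
    dab = max(d(a, b), 0.0)
    adjacency[a].append((b, dab))
    adjacency[b].append((a, dab))
    return NJTree(adjacency=adjacency, leaves=list(labels))


def _tree_groups(tree: NJTree, cut: float) -> list[set[str]]:
    """Connected leaf sets after removing branches longer than ``cut``."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for node, nbrs in tree.adjacency.items():
        parent.setdefault(node, node)
        for other, length in nbrs:
            parent.setdefault(other, other)
            if length <= cut:
                union(node, other)
    comps: dict[str, set[str]] = {}
    for leaf in tree.leaves:
        comps.setdefault(find(leaf), set()).add(leaf)
    return list(comps.values())


def group_units(
    units: list[RepeatUnit],
    cut: float = 0.03,
    scoring: ScoringScheme = DEFAULT_SCORING,
    distance_fn=None,
) -> dict[str, str]:
    """Group corresponding repeat units across accessions.

    Distances are p-distances derived from global-alignment identity,
    d = (100 − %identity)/100 (``distance_fn`` may substitute another
    matrix-valued function of the sequences).  An NJ tree is built and
    branches longer than ``cut`` are removed; leaves left connected form
    one group.  The default cut of 0.03 mirrors the 97%-identity grouping
    convention.  Returns unit key → group label ("g1", "g2", ... in order
    of first appearance).
    """
    if len(units) < 2:
        raise ValueError("group_units needs at least 2 units")
    keys = [u.key for u in units]
    seqs = [u.seq for u in units]
    if distance_fn is not None:
        D = np.asarray(distance_fn(seqs), dtype=float)
    else:
        D = (100.0 - identity_matrix(seqs, scoring)) / 100.0
        np.fill_diagonal(D, 0.0)

    if len(units) == 2:
        comps = (
            [{keys[0], keys[1]}] if D[0, 1] <= cut else [{keys[0]}, {keys[1]}]
        )
    else:
        tree = nj_tree(D, labels=keys)
        comps = _tree_groups(tree, cut)

    by_leaf = {leaf: frozenset(c) for c in comps for leaf in c}
    labels: dict[frozenset, str] = {}
    out: dict[str, str] = {}
    for key in keys:
        comp = by_leaf[key]
        if comp not in labels:
            labels[comp] = f"g{len(labels) + 1}"
        out[key] = labels[comp]
    return out


# ---------------------------------------------------------------------------
# Structural event calling

def _internal_gap_runs(aligned_ref: str, aligned_acc: str):
    """Yield (which, ref_pos, acc_pos, length) for internal gap runs.

    ``which`` is "acc" when the gap is in the accession string (a deletion
    relative to the reference) and "ref" for an insertion.  Positions are
    ungapped coordinates of the run start on each sequence.  Leading and
    trailing gap runs (end gaps) are skipped.
    """
    n = len(aligned_ref)
    lead = 0
    while lead < n and (aligned_ref[lead] == "-" or aligned_acc[lead] == "-"):
        lead += 1
    tail = n
    while tail > lead and (aligned_ref[tail - 1] == "-" or aligned_acc[tail - 1] == "-"):
        tail -= 1
    ref_pos = aligned_ref[:lead].replace("-", "")
    acc_pos = aligned_acc[:lead].replace("-", "")
    rp, ap = len(ref_pos), len(acc_pos)
    i = lead
    while i < tail:
        if aligned_acc[i] == "-":
            start_rp, start_ap = rp, ap
            j = i
            while j < tail and aligned_acc[j] == "-":
                rp += 1
                j += 1
            yield ("acc", start_rp, start_ap, j - i)
            i = j
        elif aligned_ref[i] == "-":
            start_rp, start_ap = rp, ap
            j = i
            while j < tail and aligned_ref[j] == "-":
                ap += 1
                j += 1
            yield ("ref", start_rp, start_ap, j - i)
            i = j
        else:
            rp += 1
            ap += 1
            i += 1


def call_structural_events(
    regions: dict[str, SequenceRecord],
    units: dict[str, list[RepeatUnit]],
    reference: str | None = None,
    min_event: int = 50,
    unit_length_tol: float = 0.2,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[StructuralEvent]:
    """Call structural differences of each accession against a reference.

    Each accession's cluster region is globally aligned to the reference
    region (free end gaps; the flanks anchor the alignment).  Internal gap
    runs of at least ``min_event`` bp are events: a gap on the accession
    side is a deletion, on the reference side an insertion.  A gap within
    ``unit_length_tol`` of k × (median reference unit length) is a
    whole-unit event covering k units; a smaller gap is a partial event
    with size equal to the gap length.

    ``reference`` defaults to the accession with the most units (ties:
    lexicographically smallest name), matching the convention that the
    longest clusters define the full unit complement.
    """
    if reference is None:
        reference = min(units, key=lambda a: (-len(units[a]), a))
    if reference not in regions or reference not in units:
        raise ValueError(f"reference accession {reference!r} absent from panel")

    ref_units = units[reference]
    unit_len = median(len(u) for u in ref_units)
    ref_seq = regions[reference].seq

    events: list[StructuralEvent] = []
    for acc in sorted(regions):
        if acc == reference:
            continue
        aln = needleman_wunsch(ref_seq, regions[acc].seq, scoring)
        for which, ref_pos, acc_pos, size in _internal_gap_runs(aln.aligned_a, aln.aligned_b):
            if size < min_event:
                continue
            k = max(1, round(size / unit_len))
            whole = abs(size - k * unit_len) <= unit_length_tol * unit_len
            if which == "acc":
                kind = "whole_unit_deletion" if whole else "partial_deletion"
                affected = _affected_units(ref_units, ref_pos, size, snap=whole)
                events.append(
                    StructuralEvent(acc, kind, affected, size, position=ref_pos)
                )
            else:
                kind = "whole_unit_insertion" if whole else "partial_insertion"
                affected = _affected_units(units[acc], acc_pos, size, snap=whole)
                events.append(
                    StructuralEvent(acc, kind, affected, size, position=acc_pos)
                )
    return events


def _affected_units(unit_list: list[RepeatUnit], pos: int, size: int, snap: bool) -> list[int]:
    """Unit indices covered by a gap.

    For whole-unit events the gap start is snapped to the nearest unit
    boundary first: sequence similarity between adjacent units lets the
    optimal alignment slide a whole-unit gap a few tens of bp off the
    true boundary, which must not change which units are called affected.
    """
    if snap and unit_list:
        boundaries = [u.start for u in unit_list] + [unit_list[-1].end]
        pos = min(boundaries, key=lambda b: abs(b - pos))
    return [u.index for u in unit_list if u.start < pos + size and u.end > pos]


@dataclass
class UnitPanel:
    """Units of several accessions with group labels and structural events."""

    accessions: list[str]
    units: dict[str, list[RepeatUnit]]
    correspondence: dict[str, str]
    events: list[StructuralEvent]
    reference: str
    tree: NJTree | None = None


def build_unit_panel(
    regions: dict[str, SequenceRecord],
    units: dict[str, list[RepeatUnit]],
    reference: str | None = None,
    cut: float = 0.03,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> UnitPanel:
    """Convenience: group units across accessions and call events."""
    all_units = [u for acc in sorted(units) for u in units[acc]]
    correspondence = group_units(all_units, cut=cut, scoring=scoring)
    if reference is None:
        reference = min(units, key=lambda a: (-len(units[a]), a))
    events = call_structural_events(regions, units, reference=reference, scoring=scoring)
    tree = None
    if len(all_units) >= 3:
        D = (100.0 - identity_matrix([u.seq for u in all_units], scoring)) / 100.0
        np.fill_diagonal(D, 0.0)
        tree = nj_tree(D, labels=[u.key for u in all_units])
    return UnitPanel(
        accessions=sorted(units),
        units=units,
        correspondence=correspondence,
        events=events,
        reference=reference,
        tree=tree,
    )
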