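"""tRNA gene cluster detection, orientation classification and spacers.

A cluster is a maximal run of tRNA genes on one sequence where every
adjacent pair is separated by at most ``max_gap`` bp (the conventional
1 kbp rule).  Pseudogenes do not count toward membership by default but
are reported as flanking features when they sit within ``max_gap`` of a
cluster edge — the conserved pseudogene upstream of the chromosome-5
cluster is exactly such a feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cystra.io import GeneAnnotation

__all__ = ["ClusterRegion", "find_clusters", "classify_orientation", "spacer_lengths"]


@dataclass
class ClusterRegion:
    """An ordered run of tRNA genes with spacers and an orientation label."""

    seqid: str
    genes: list[GeneAnnotation]
    max_gap: int
    flanking_pseudogenes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("a cluster needs at least 2 genes")
        self.genes = sorted(self.genes, key=lambda g: g.start)

    @property
    def start(self) -> int:
        return self.genes[0].start

    @property
    def end(self) -> int:
        return self.genes[-1].end

    @property
    def spacers(self) -> list[int]:
        return spacer_lengths(self)

    @property
    def has_overlaps(self) -> bool:
        return any(s < 0 for s in self.spacers)

    @property
    def orientation(self) -> str:
        return classify_orientation(self)

    @property
    def isotypes(self) -> set[str]:
        return {g.isotype for g in self.genes if g.isotype}


def find_clusters(
    annotations: list[GeneAnnotation],
    max_gap: int = 1000,
    min_genes: int = 2,
    same_isotype: bool = False,
    include_pseudogenes: bool = False,
) -> list[ClusterRegion]:
    """Find maximal runs of tRNA genes with adjacent gaps ≤ ``max_gap``.

    Strand is ignored for membership.  When ``same_isotype`` is set, runs
    additionally break at isotype changes.  Runs shorter than ``min_genes``
    are dropped.  Pseudogenes are excluded from membership (unless
    ``include_pseudogenes``) but attached as flanking features when within
    ``max_gap`` of a cluster edge.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    genes = [a for a in annotations if include_pseudogenes or a.category == "gene"]
    pseudo = [a for a in annotations if a.category == "pseudogene"]
    genes = sorted(genes, key=lambda g: (g.seqid, g.start, g.end, g.gene_id))

    runs: list[list[GeneAnnotation]] = []
    current: list[GeneAnnotation] = []
    for g in genes:
        if not current:
            current = [g]
            continue
        prev = current[-1]
        gap = g.start - prev.end
        breaks = (
            g.seqid != prev.seqid
            or gap > max_gap
            or (same_isotype and g.isotype != prev.isotype)
        )
        if breaks:
            runs.append(current)
            current = [g]
        else:
            current.append(g)
    if current:
        runs.append(current)

    clusters = []
    for run in runs:
        if len(run) < min_genes or len(run) < 2:
            continue
        region = ClusterRegion(seqid=run[0].seqid, genes=run, max_gap=max_gap)
        if not include_pseudogenes:
            region.flanking_pseudogenes = [
                p
                for p in pseudo
                if p.seqid == region.seqid
                and (
                    0 <= region.start - p.end <= max_gap
                    or 0 <= p.start - region.end <= max_gap
                )
            ]
        clusters.append(region)
    return clusters


def classify_orientation(cluster: ClusterRegion) -> str:
    """Orientation pattern of a cluster's genes, by ascending coordinate.

    head_to_tail: all genes on one strand (tandem).  For 2-gene clusters,
    head_to_head when transcription starts face each other — strands
    (−, +) — and tail_to_tail when (+, −).  Anything else is mixed.
    """
    strands = [g.strand for g in cluster.genes]
    if len(set(strands)) == 1:
        return "head_to_tail"
    if len(strands) == 2:
        if strands == ["-", "+"]:
            return "head_to_head"
        if strands == ["+", "-"]:
            return "tail_to_tail"
    return "mixed"


def spacer_lengths(cluster: ClusterRegion) -> list[int]:
    """Intergenic distances: ``genes[i+1].start − genes[i].end``.

    A gap of k intervening bases yields k; overlapping genes yield a
    negative value (see :attr:`ClusterRegion.has_overlaps`).
    """
    genes = cluster.genes
    return [genes[i + 1].start - genes[i].end for i in range(len(genes) - 1)]
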