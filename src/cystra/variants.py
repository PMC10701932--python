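"""Mature tRNA variant deduplication, greedy identity clustering, and
cloverleaf stem-mispair assessment.

Greedy clustering follows the centroid convention of USEARCH-style tools:
sequences are processed longest-first, each joins the best centroid it
matches at or above the identity threshold, otherwise it seeds a new
centroid.  Identity here is matches over alignment columns from the
package's global aligner.

Stem assessment transfers a reference cloverleaf pairing map onto a
variant through a global alignment and counts positions that can no
longer pair.  G·U wobble pairs (G:T in DNA space) count as valid: they
are structurally tolerated in tRNA stems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cystra.align import DEFAULT_SCORING, ScoringScheme, needleman_wunsch

__all__ = [
    "VariantGroup",
    "PairingMap",
    "dedupe_mature",
    "greedy_cluster",
    "stem_mispair_check",
    "VALID_PAIRS",
]

#: base pairs accepted in a stem (DNA alphabet; GT/TG is the G·U wobble)
VALID_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@dataclass
class VariantGroup:
    centroid_id: str
    centroid_seq: str
    member_ids: list[str]
    threshold: float


@dataclass(frozen=True)
class PairingMap:
    """Cloverleaf stem pairing on a reference tRNA sequence.

    ``stems`` maps a stem name to its list of (i, j) paired position
    indices on the reference (0-based); ``anticodon_positions`` are the
    three anticodon indices.  The canonical layout has 7 acceptor-stem,
    4 D-stem, 5 anticodon-stem and 5 T-stem pairs.
    """

    stems: dict[str, tuple[tuple[int, int], ...]]
    anticodon_positions: tuple[int, int, int]
    reference_length: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, pairs in self.stems.items():
            for i, j in pairs:
                if not (0 <= i < self.reference_length and 0 <= j < self.reference_length):
                    raise ValueError(f"{name}: pair ({i},{j}) outside reference")
                if i in seen or j in seen:
                    raise ValueError(f"{name}: position in two pairs")
                seen.update((i, j))
        for p in self.anticodon_positions:
            if not 0 <= p < self.reference_length:
                raise ValueError("anticodon position outside reference")


def dedupe_mature(genes: list[tuple[str, str]]) -> list[tuple[str, list[str]]]:
    """Collapse mature tRNA body sequences to exact-string variants.

    ``genes`` is a list of (gene_id, sequence).  Returns one
    (variant sequence, member gene_ids) tuple per distinct sequence, in
    order of first appearance; the variant is named downstream by its
    first member.
    """
    by_seq: dict[str, list[str]] = {}
    for gene_id, seq in genes:
        by_seq.setdefault(seq, []).append(gene_id)
    return [(seq, members) for seq, members in by_seq.items()]


def _fraction_identity(a: str, b: str, scoring: ScoringScheme) -> float:
    aln = needleman_wunsch(a, b, scoring)
    return aln.identities / aln.length


def greedy_cluster(
    seqs: list[tuple[str, str]],
    threshold: float = 0.97,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[VariantGroup]:
    """Greedy centroid clustering at a fractional identity threshold.

    Sequences (id, seq) are sorted by (length desc, sequence asc, id asc)
    and processed in that fixed order, making the result deterministic.
    Each sequence joins the centroid with the highest identity ≥ threshold
    (earliest centroid wins ties), else becomes a new centroid.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(seqs, key=lambda kv: (-len(kv[1]), kv[1], kv[0]))
    groups: list[VariantGroup] = []
    for sid, seq in ordered:
        best_idx, best_ident = None, -1.0
        for idx, grp in enumerate(groups):
            ident = (
                1.0
                if seq == grp.centroid_seq
                else _fraction_identity(seq, grp.centroid_seq, scoring)
            )
            if ident >= threshold and ident > best_ident + 1e-12:
                best_idx, best_ident = idx, ident
        if best_idx is None:
            groups.append(VariantGroup(sid, seq, [sid], threshold))
        else:
            groups[best_idx].member_ids.append(sid)
    return groups


def stem_mispair_check(
    variant_seq: str,
    reference_seq: str,
    pairing: PairingMap,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> dict:
    """Count stem mispairs of a variant against a reference cloverleaf.

    The variant is globally aligned to the reference and the reference's
    stem pairing positions are transferred through the alignment.  A
    transferred pair is a mispair unless it is Watson–Crick or G·U wobble.
    A stem position landing in an alignment gap sets that stem's indel
    flag (structure not evaluable there).  Returns per-stem mispair
    counts, per-stem indel flags, and an overall ``canonical`` verdict.
    """
    if pairing.reference_length != len(reference_seq):
        raise ValueError("pairing map does not match reference length")
    aln = needleman_wunsch(reference_seq, variant_seq, scoring)
    # reference position -> variant character ('-' if deleted in variant)
    ref_to_var: dict[int, str] = {}
    rp = 0
    for rc, vc in zip(aln.aligned_a, aln.aligned_b):
        if rc != "-":
            ref_to_var[rp] = vc
            rp += 1
    counts: dict[str, int] = {}
    indel: dict[str, bool] = {}
    for name, pairs in pairing.stems.items():
        c, flag = 0, False
        for i, j in pairs:
            x, y = ref_to_var[i], ref_to_var[j]
            if x == "-" or y == "-":
                flag = True
                continue
            if (x, y) not in VALID_PAIRS:
                c += 1
        counts[name] = c
        indel[name] = flag
    canonical = not any(indel.values()) and all(v == 0 for v in counts.values())
    return {"mispairs": counts, "indel": indel, "canonical": canonical}
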