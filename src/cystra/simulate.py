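"""Seeded generators for genomes, annotations and read libraries with truth.

The cluster generator emulates the structure of a tandem tRNA gene
cluster as found across *A. thaliana* accessions: a ~420 bp repeating
unit carrying one tRNA-Cys-GCA gene, four to six units per accession
differing by whole-unit gains/losses, one accession with a partial
deletion spanning a unit junction (95 bp of one unit's tail plus the
next unit's 72 nt gene = 167 bp), a conserved upstream pseudogene, and
identical flanking sequence carrying the cluster-spanning PCR primer
sites.  The read simulator draws mature (CCA-tailed) and precursor
(genomically flanked) reads from a known per-gene expression vector for
a control and a deacylated library, with sequencing error and
contaminants.  Every emitted sequence and read has a truth entry.

All randomness flows from one top-level seed through named child
streams, so the same seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from cystra.io import GeneAnnotation, SequenceRecord
from cystra.expression import ReferenceLocus
from cystra.variants import PairingMap

__all__ = [
    "ClusterSpec",
    "PartialDeletionSpec",
    "ReadSimSpec",
    "PanelAccession",
    "ReadTruth",
    "make_trna_template",
    "make_cluster_panel",
    "make_reference_loci",
    "default_expression",
    "default_charged",
    "simulate_reads",
]

BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: cluster-spanning primer pair planted in the synthetic flanks
CHR5_FWD_PRIMER = "CTGATCGTTTGACTTGACACG"
CHR5_REV_PRIMER = "ATGGTACCTAGGTGTTTGACC"

TRNA_LEN = 72
ANTICODON = "GCA"
ANTICODON_POSITIONS = (33, 34, 35)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.36) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _mutate(seq: str, rng: np.random.Generator, rate: float, protected=()) -> str:
    """Substitute each unprotected position with probability ``rate``."""
    chars = list(seq)
    protected = set(protected)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        if int(i) in protected:
            continue
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def _mutate_n(seq: str, rng: np.random.Generator, n: int, protected=()) -> str:
    """Substitute exactly ``n`` distinct unprotected positions."""
    chars = list(seq)
    candidates = [i for i in range(len(chars)) if i not in set(protected)]
    for i in rng.choice(len(candidates), size=n, replace=False):
        pos = candidates[int(i)]
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# tRNA template

def make_trna_template(seed: int) -> tuple[str, PairingMap]:
    """A 72 nt tRNA-Cys-GCA-like sequence with a self-consistent cloverleaf.

    Stems: acceptor 7 bp (0..6 / 65..71), D 4 bp (9..12 / 21..24),
    anticodon 5 bp (26..30 / 38..42), T 5 bp (48..52 / 60..64); the
    anticodon at 33–35 is GCA.  Every stem pair is Watson–Crick
    complementary by construction.
    """
    rng = _rng(seed, 0)
    seq = list(_random_dna(rng, TRNA_LEN, gc=0.5))
    for pos, base in zip(ANTICODON_POSITIONS, ANTICODON):
        seq[pos] = base
    stems = {
        "acceptor": tuple((i, 71 - i) for i in range(7)),
        "D": tuple((9 + k, 24 - k) for k in range(4)),
        "anticodon": tuple((26 + k, 42 - k) for k in range(5)),
        "T": tuple((48 + k, 64 - k) for k in range(5)),
    }
    for pairs in stems.values():
        for i, j in pairs:
            seq[j] = _COMP[seq[i]]
    pairing = PairingMap(
        stems=stems,
        anticodon_positions=ANTICODON_POSITIONS,
        reference_length=TRNA_LEN,
    )
    return "".join(seq), pairing


# ---------------------------------------------------------------------------
# Cluster panel

@dataclass(frozen=True)
class PartialDeletionSpec:
    """A deletion of ``size`` bp starting ``offset`` bp into the cluster.

    The default (offset None) places the deletion so that it removes the
    final 95 bp of the accession's penultimate unit and the 72 nt tRNA
    gene of its last unit — a 167 bp cut across the unit junction.
    """

    accession: str
    size: int = 167
    offset: int | None = None


@dataclass(frozen=True)
class ClusterSpec:
    """Conditions for the synthetic multi-accession cluster panel."""

    unit_length: int = 420
    n_units: dict[str, int] = field(
        default_factory=lambda: {
            "Col-like": 4,
            "Est-like": 4,
            "Cvi-like": 4,
            "Ler-like": 5,
            "Kn-like": 6,
        }
    )
    group_divergence: float = 0.06  # per-group substitution rate vs the ancestral unit
    within_divergence: float = 0.01  # per-unit substitution rate vs its group template
    partial_deletion: PartialDeletionSpec | None = PartialDeletionSpec("Cvi-like")
    pseudogene: bool = True
    flank_length: int = 500
    pseudo_spacer: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (("group_divergence", self.group_divergence),
                           ("within_divergence", self.within_divergence)):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.unit_length <= TRNA_LEN:
            raise ValueError("unit_length must exceed the tRNA gene length")
        for acc, n in self.n_units.items():
            if not 1 <= n <= 6:
                raise ValueError(f"{acc}: n_units must be in 1..6")
        if self.partial_deletion is not None:
            pd = self.partial_deletion
            if pd.accession not in self.n_units:
                raise ValueError(f"partial_deletion accession {pd.accession!r} unknown")
            if pd.size >= 2 * self.unit_length:
                raise ValueError("partial deletion size must be < 2 unit lengths")


@dataclass
class PanelAccession:
    """One synthetic accession: genome record, annotations and truth."""

    accession: str
    record: SequenceRecord
    annotations: list[GeneAnnotation]
    unit_boundaries: list[tuple[int, int]]  # genomic coords of units with a surviving gene
    unit_groups: list[str]  # group label per unit ("g1".."g6")
    unit_intact: list[bool]  # False when a partial deletion damaged the unit
    cluster_start: int
    cluster_end: int
    deletion: tuple[int, int] | None = None  # genomic (start, size) of the applied deletion


# an accession with n units carries the first n unit groups; accessions are
# then collinear with the longest (reference) cluster and differ by whole
# units at the downstream end, as tandem gain/loss produces
_GROUP_SETS = {n: list(range(1, n + 1)) for n in range(1, 7)}

#: CTAG[TC] Helitron-like motif planted at this offset inside every unit spacer
_MOTIF = "CTAGT"
_MOTIF_OFFSET = 50  # bp into the spacer (after the 72 nt gene)


def make_cluster_panel(spec: ClusterSpec = ClusterSpec()) -> dict[str, PanelAccession]:
    """Generate the per-accession genomes of a tandem-cluster panel.

    The ancestral unit is a template tRNA gene plus random spacer.  Six
    group templates diverge from it at ``group_divergence``; an accession
    with n units carries a fixed n-subset of the groups, each copy further
    diverged at ``within_divergence``.  Flanks and primer sites are
    identical across accessions, an upstream tRNA pseudogene (template
    with 3 planted substitutions, anticodon loop intact) precedes the
    first unit, and one CTAG[TC] motif is planted per unit spacer.
    """
    template, _pairing = make_trna_template(spec.seed)
    rng = _rng(spec.seed, 1)

    spacer_len = spec.unit_length - TRNA_LEN
    ancestral_spacer = _random_dna(rng, spacer_len)
    ancestral_unit = template + ancestral_spacer
    protected_gene = set(ANTICODON_POSITIONS)

    group_templates = {
        g: _mutate(ancestral_unit, rng, spec.group_divergence, protected=protected_gene)
        for g in range(1, 7)
    }

    left_flank = list(_random_dna(rng, spec.flank_length))
    left_flank[100 : 100 + len(CHR5_FWD_PRIMER)] = CHR5_FWD_PRIMER
    left_flank = "".join(left_flank)
    right_flank = list(_random_dna(rng, spec.flank_length))
    rev_site = "".join(_COMP[b] for b in reversed(CHR5_REV_PRIMER))
    right_flank[300 : 300 + len(rev_site)] = rev_site
    right_flank = "".join(right_flank)

    # pseudogene: shared 3 substitutions, anticodon loop (31..37) left intact
    pseudo_base = _mutate_n(template, rng, 3, protected=set(range(31, 38)))

    panel: dict[str, PanelAccession] = {}
    for acc in sorted(spec.n_units):
        acc_rng = _rng(spec.seed, 2, _stable_hash(acc))
        n = spec.n_units[acc]
        groups = _GROUP_SETS[n]
        units = []
        for g in groups:
            unit = _mutate(group_templates[g], acc_rng, spec.within_divergence,
                           protected=protected_gene)
            unit = list(unit)
            pos = TRNA_LEN + _MOTIF_OFFSET
            unit[pos : pos + len(_MOTIF)] = _MOTIF
            units.append("".join(unit))

        pseudo = _mutate(pseudo_base, acc_rng, spec.within_divergence,
                         protected=set(range(31, 38)))
        prefix = left_flank + (pseudo + _random_dna(acc_rng, spec.pseudo_spacer)
                               if spec.pseudogene else "")
        cluster_start = len(prefix)
        seq = prefix + "".join(units) + right_flank
        cluster_end = cluster_start + n * spec.unit_length

        boundaries = [
            (cluster_start + k * spec.unit_length, cluster_start + (k + 1) * spec.unit_length)
            for k in range(n)
        ]
        labels = [f"g{g}" for g in groups]
        annotations = [
            GeneAnnotation(
                seqid=acc,
                start=b[0],
                end=b[0] + TRNA_LEN,
                strand="+",
                gene_id=f"{acc}.trna{k + 1}",
                isotype="Cys",
                anticodon=ANTICODON,
                category="gene",
                high_confidence=True,
            )
            for k, b in enumerate(boundaries)
        ]
        deletion = None
        intact = [True] * n
        if spec.partial_deletion is not None and spec.partial_deletion.accession == acc:
            pd = spec.partial_deletion
            offset = pd.offset
            if offset is None:
                offset = (n - 1) * spec.unit_length - 95
            del_start = cluster_start + offset
            seq = seq[:del_start] + seq[del_start + pd.size :]
            deletion = (del_start, pd.size)
            kept_ann, kept_b, kept_l, kept_i = [], [], [], []
            for ann, b, lab in zip(annotations, boundaries, labels):
                if ann.start < del_start + pd.size and ann.end > del_start:
                    continue  # gene removed by the deletion
                shift = pd.size if ann.start >= del_start + pd.size else 0
                kept_ann.append(replace_coords(ann, -shift))
                b_shift = pd.size if b[0] >= del_start + pd.size else 0
                kept_b.append((b[0] - b_shift, b[1] - b_shift))
                kept_l.append(lab)
                # a unit whose span overlaps the cut is damaged even if its gene survives
                kept_i.append(not (b[0] < del_start + pd.size and b[1] > del_start))
            annotations, boundaries, labels, intact = kept_ann, kept_b, kept_l, kept_i
            cluster_end -= pd.size

        if spec.pseudogene:
            annotations = [
                GeneAnnotation(
                    seqid=acc,
                    start=spec.flank_length,
                    end=spec.flank_length + TRNA_LEN,
                    strand="+",
                    gene_id=f"{acc}.pseudo1",
                    isotype="Cys",
                    anticodon=ANTICODON,
                    category="pseudogene",
                    high_confidence=False,
                )
            ] + annotations

        panel[acc] = PanelAccession(
            accession=acc,
            record=SequenceRecord(acc, seq, description=f"synthetic accession seed={spec.seed}"),
            annotations=annotations,
            unit_boundaries=boundaries,
            unit_groups=labels,
            unit_intact=intact,
            cluster_start=cluster_start,
            cluster_end=cluster_end,
            deletion=deletion,
        )
    return panel


def replace_coords(ann: GeneAnnotation, shift: int) -> GeneAnnotation:
    return GeneAnnotation(
        seqid=ann.seqid,
        start=ann.start + shift,
        end=ann.end + shift,
        strand=ann.strand,
        gene_id=ann.gene_id,
        isotype=ann.isotype,
        anticodon=ann.anticodon,
        category=ann.category,
        high_confidence=ann.high_confidence,
    )


def _stable_hash(name: str) -> int:
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % 2_147_483_647
    return h


# ---------------------------------------------------------------------------
# Reference loci and read simulation

def make_reference_loci(
    seed: int = 0,
    n_genes: int = 16,
    n_variants: int = 13,
    leader: int = 30,
) -> list[ReferenceLocus]:
    """A locus panel emulating a 16-gene / 13-mature-variant tRNA family.

    Variants diverge from the template by 1–3 substitutions (anticodon
    kept); the surplus genes duplicate the first variants at distinct
    genomic locations, so duplicated pairs share a mature sequence but
    have distinct precursor flanks.
    """
    if n_variants > n_genes:
        raise ValueError("n_variants cannot exceed n_genes")
    template, _ = make_trna_template(seed)
    rng = _rng(seed, 3)
    bodies: list[str] = []
    while len(bodies) < n_variants:
        n_subs = int(rng.integers(1, 4))
        cand = _mutate_n(template, rng, n_subs, protected=set(ANTICODON_POSITIONS))
        if cand not in bodies:
            bodies.append(cand)
    loci = []
    n_dups = n_genes - n_variants
    variant_of_gene = list(range(n_variants)) + list(range(n_dups))
    for g_idx, v_idx in enumerate(variant_of_gene):
        body = bodies[v_idx]
        loci.append(
            ReferenceLocus(
                gene_id=f"gene{g_idx + 1:02d}",
                variant_id=f"var{v_idx + 1:02d}",
                mature_ref=body + "CCA",
                precursor_ref=_random_dna(rng, leader) + body + _random_dna(rng, leader),
                leader=leader,
            )
        )
    return loci


def default_expression(loci: list[ReferenceLocus], zero_variants: int = 2,
                       seed: int = 0) -> dict[str, float]:
    """A per-gene expression vector with ``zero_variants`` silent variants.

    The silent variants are singletons (variants encoded by exactly one
    gene), emulating transcriptionally silent cluster-internal genes; the
    remaining genes get reproducible log-spread positive levels.
    """
    rng = _rng(seed, 4)
    by_variant: dict[str, list[str]] = {}
    for l in loci:
        by_variant.setdefault(l.variant_id, []).append(l.gene_id)
    singletons = sorted(v for v, genes in by_variant.items() if len(genes) == 1)
    silent_variants = set(singletons[-zero_variants:]) if zero_variants else set()
    expr: dict[str, float] = {}
    for l in loci:
        if l.variant_id in silent_variants:
            expr[l.gene_id] = 0.0
        else:
            expr[l.gene_id] = float(np.round(2.0 ** rng.uniform(0, 6), 2))
    return expr


def default_charged(loci: list[ReferenceLocus], factor: float = 2.0) -> dict[str, float]:
    """Alternate charged (``factor``) and uncharged (1.0) genes by panel order."""
    return {l.gene_id: (factor if i % 2 == 0 else 1.0) for i, l in enumerate(loci)}


@dataclass(frozen=True)
class ReadSimSpec:
    """Conditions for simulated control / deacylated read libraries."""

    expression: dict[str, float] | None = None  # per gene; None -> default_expression
    precursor_fraction: float = 0.1
    error_rate: float = 0.01
    min_len: int = 55
    max_len: int = 110
    # deacylated-vs-control up-weighting; None -> default_charged (half the
    # genes charged at 2.0).  A uniform factor on every gene is absorbed by
    # depth normalization, so a contrast needs charged and uncharged genes
    # to coexist.
    charged_factor: dict[str, float] | float | None = None
    contaminant_fraction: float = 0.1
    depth: int = 20000  # reads per library
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in (("precursor_fraction", self.precursor_fraction),
                           ("error_rate", self.error_rate),
                           ("contaminant_fraction", self.contaminant_fraction)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class ReadTruth:
    """Truth for one simulated read set."""

    expression: dict[str, float]
    charged: dict[str, float]  # per-gene deacylated up-weighting factor
    source: dict[str, list[str]]  # per library: source gene_id or "contaminant", per read
    klass: dict[str, list[str]]  # per library: {"mature", "precursor", "contaminant"}


def _add_errors(read: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return read
    return _mutate(read, rng, rate)


def simulate_reads(
    loci: list[ReferenceLocus],
    spec: ReadSimSpec = ReadSimSpec(),
) -> tuple[dict[str, list[str]], ReadTruth]:
    """Simulate control and deacylated tRNA-seq libraries with truth.

    Reads per gene are multinomial draws proportional to the expression
    vector (deacylated libraries up-weight charged genes by their charged
    factor).  Mature reads are the CCA-tailed mature reference with a
    small random 3' truncation; precursor reads extend ≥ 5 nt into one
    genomic flank and carry no CCA.  Contaminants are random sequences.
    """
    expr = spec.expression if spec.expression is not None else default_expression(loci, seed=spec.seed)
    if set(expr) != {l.gene_id for l in loci}:
        raise ValueError("expression vector keys must match locus gene_ids")
    total_expr = sum(expr.values())
    if total_expr <= 0:
        raise ValueError("expression vector is all zero")
    if spec.charged_factor is None:
        charged = default_charged(loci)
    elif isinstance(spec.charged_factor, dict):
        charged = dict(spec.charged_factor)
    else:
        charged = {l.gene_id: float(spec.charged_factor) for l in loci}
    rng = _rng(spec.seed, 5)
    loci_by_gene = {l.gene_id: l for l in loci}
    gene_ids = [l.gene_id for l in loci]

    libraries: dict[str, list[str]] = {}
    source: dict[str, list[str]] = {}
    klass: dict[str, list[str]] = {}
    for lib in ("control", "deacylated"):
        weights = np.array(
            [
                expr[g] * (charged.get(g, 1.0) if lib == "deacylated" else 1.0)
                for g in gene_ids
            ]
        )
        n_contam = int(round(spec.depth * spec.contaminant_fraction))
        n_real = spec.depth - n_contam
        counts = rng.multinomial(n_real, weights / weights.sum())
        reads, src, cls = [], [], []
        for g, n_reads in zip(gene_ids, counts):
            locus = loci_by_gene[g]
            body = locus.mature_ref[:-3]
            n_prec = rng.binomial(n_reads, spec.precursor_fraction)
            for _ in range(int(n_reads - n_prec)):
                trunc = int(rng.integers(0, 6))
                read = locus.mature_ref[: len(locus.mature_ref) - trunc]
                reads.append(_add_errors(read, rng, spec.error_rate))
                src.append(g)
                cls.append("mature")
            for _ in range(int(n_prec)):
                ext = int(rng.integers(5, locus.leader + 1))
                if rng.random() < 0.5:
                    read = locus.precursor_ref[locus.leader - ext : locus.leader + len(body)]
                else:
                    read = locus.precursor_ref[locus.leader : locus.leader + len(body) + ext]
                reads.append(_add_errors(read, rng, spec.error_rate))
                src.append(g)
                cls.append("precursor")
        for _ in range(n_contam):
            length = int(rng.integers(spec.min_len, spec.max_len + 1))
            reads.append(_random_dna(rng, length, gc=0.45))
            src.append("contaminant")
            cls.append("contaminant")
        order = rng.permutation(len(reads))
        libraries[lib] = [reads[i] for i in order]
        source[lib] = [src[i] for i in order]
        klass[lib] = [cls[i] for i in order]
    return libraries, ReadTruth(expression=dict(expr), charged=charged, source=source, klass=klass)
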