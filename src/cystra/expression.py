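"""tRNA-seq expression quantification.

The pipeline stages, in the order they are run:

1. ``collapse_unique`` — exact-sequence collapse of each read library
   into one table of unique reads with per-library counts;
2. ``tmm_factors`` — between-library scaling factors by the trimmed mean
   of M-values (computed on the unique-read table);
3. ``length_filter`` — keep reads of 55–110 nt (mature tRNAs plus
   precursors);
4. ``contamination_filter`` — drop reads that a supplied matcher does not
   recognize (stand-in for a BLAST screen against a clade database);
5. ``assign_reads`` — score every read against each locus's mature
   (CCA-tailed) and precursor (genomically flanked) references with a
   local affine aligner and keep only best-scoring, uniquely mapped
   reads; ties spanning loci that share one mature variant are rescued at
   the variant level (this is what lets precursor-containing reads, and
   only those, discriminate identical-mature gene copies);
6. ``compare_libraries`` — flag variants as undetected / low / charged
   from normalized control-vs-deacylated counts (higher counts after
   deacylation indicate aminoacyl-charged tRNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from cystra.align import DEFAULT_SCORING, ScoringScheme, local_align, local_score
from cystra.io import read_reads

__all__ = [
    "ReferenceLocus",
    "TMMFactors",
    "ExpressionTable",
    "SequenceSetMatcher",
    "collapse_unique",
    "length_filter",
    "tmm_factors",
    "normalize_counts",
    "contamination_filter",
    "assign_reads",
    "compare_libraries",
    "blastn_contamination_command",
]


@dataclass(frozen=True)
class ReferenceLocus:
    """A tRNA gene with mature and precursor reference sequences.

    ``mature_ref`` is the gene body plus the post-transcriptional 3'-CCA;
    ``precursor_ref`` is the genomic sequence with ``leader`` nt of 5'
    leader and trailer (no CCA).  Loci sharing an identical mature
    sequence share a ``variant_id``.
    """

    gene_id: str
    variant_id: str
    mature_ref: str
    precursor_ref: str
    leader: int = 30
    seqid: str = ""
    start: int = -1
    end: int = -1

    def __post_init__(self) -> None:
        if not self.mature_ref.endswith("CCA"):
            raise ValueError(f"{self.gene_id}: mature_ref must end in CCA")
        body = self.mature_ref[:-3]
        if self.precursor_ref[self.leader : self.leader + len(body)] != body:
            raise ValueError(
                f"{self.gene_id}: precursor_ref must contain the gene body at offset {self.leader}"
            )


# ---------------------------------------------------------------------------
# Unique-read table

def collapse_unique(libraries: dict[str, object]) -> pd.DataFrame:
    """Collapse read libraries to unique sequences.

    ``libraries`` maps library id to either a list of read sequences or a
    FASTA/FASTQ path.  Returns a DataFrame indexed by read sequence with
    one integer count column per library; column totals equal the input
    read counts exactly.
    """
    import warnings

    columns: dict[str, pd.Series] = {}
    for lib, src in libraries.items():
        reads = read_reads(src) if isinstance(src, (str, bytes)) or hasattr(src, "__fspath__") else list(src)
        if not reads:
            warnings.warn(f"library {lib!r} contains zero reads")
            columns[lib] = pd.Series(dtype=int)
        else:
            columns[lib] = pd.Series(reads).value_counts()
    table = pd.DataFrame(columns).fillna(0).astype(int)
    table.index.name = "read_seq"
    return table.sort_index()


def length_filter(table: pd.DataFrame, min_len: int = 55, max_len: int = 110) -> pd.DataFrame:
    """Keep rows whose read length is within [min_len, max_len], inclusive."""
    if not 0 < min_len <= max_len:
        raise ValueError("require 0 < min_len <= max_len")
    lengths = table.index.str.len()
    return table.loc[(lengths >= min_len) & (lengths <= max_len)]


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)

@dataclass(frozen=True)
class TMMFactors:
    """Per-library scaling factors; geometric mean adjusted to 1."""

    factors: dict[str, float]
    reference_library: str

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("TMM factors must be positive")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, sum_trim: float) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, var = log_r[finite], abs_e[finite], var[finite]
    if log_r.size == 0:
        raise ValueError("TMM: no rows positive in both libraries")
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)  # average ties, as in R
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    denom = np.sum(1.0 / var[keep])
    f = np.sum(log_r[keep] / var[keep]) / denom if denom > 0 else 0.0
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame, logratio_trim: float = 0.30, sum_trim: float = 0.05
) -> TMMFactors:
    """Trimmed-mean-of-M-values scaling factors across libraries.

    The reference library is the one whose upper-quartile/library-size
    ratio is closest to the mean of those ratios.  For every library, rows
    with a zero in either compared library are removed, M (log2 ratio of
    proportions) and A (mean log2 proportion) are doubly trimmed (30% of
    the M tails, 5% of the A tails) and the factor is 2 to the
    inverse-variance-weighted mean M.  Factors are rescaled so their
    geometric mean is 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 libraries")
    X = counts.to_numpy(dtype=float)
    libs = list(counts.columns)
    lib_size = X.sum(axis=0)
    if np.any(lib_size <= 0):
        raise ValueError("TMM: a library has zero total counts")
    f75 = np.array([np.quantile(X[:, i], 0.75) for i in range(len(libs))]) / lib_size
    if np.median(f75) < 1e-20:
        ref_idx = int(np.argmax(np.sqrt(X).sum(axis=0)))
    else:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    raw = np.array(
        [
            _tmm_pair(X[:, i], X[:, ref_idx], lib_size[i], lib_size[ref_idx],
                      logratio_trim, sum_trim)
            for i in range(len(libs))
        ]
    )
    raw = raw / np.exp(np.mean(np.log(raw)))
    return TMMFactors(factors=dict(zip(libs, raw.tolist())), reference_library=libs[ref_idx])


def normalize_counts(
    counts: pd.DataFrame,
    factors: TMMFactors,
    lib_sizes: dict[str, float] | None = None,
    scale: float = 1e6,
) -> pd.DataFrame:
    """Counts per million over TMM-effective library sizes.

    ``lib_sizes`` defaults to the column sums of ``counts`` but should be
    the totals of the table the factors were estimated from.
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).to_dict()
    out = counts.astype(float).copy()
    for lib in counts.columns:
        eff = lib_sizes[lib] * factors.factors[lib]
        out[lib] = counts[lib] * (scale / eff)
    return out


# ---------------------------------------------------------------------------
# Contamination filtering

class SequenceSetMatcher:
    """Reference-set matcher for the contamination screen.

    A read matches when its best local alignment against any reference
    covers at least ``min_length`` columns at ≥ ``min_identity`` fractional
    identity — the package-native stand-in for a permissive BLAST screen
    (65% identity, short word size).
    """

    def __init__(
        self,
        references: list[str],
        min_identity: float = 0.65,
        min_length: int = 20,
        scoring: ScoringScheme = DEFAULT_SCORING,
    ) -> None:
        if not references:
            raise ValueError("matcher needs at least one reference sequence")
        self.references = list(references)
        self.min_identity = min_identity
        self.min_length = min_length
        self.scoring = scoring

    def __call__(self, read_seq: str) -> bool:
        for ref in self.references:
            _score, _rs, _re, idents, cols = local_align(ref, read_seq, self.scoring)
            if cols >= self.min_length and idents / cols >= self.min_identity:
                return True
        return False


def blastn_contamination_command(query_fasta: str, database: str, out_path: str) -> str:
    """The documented external-BLAST equivalent of the contamination screen.

    Returned as a command string (adapter contract only; never executed by
    the package).
    """
    return (
        f"blastn -task blastn -query {query_fasta} -db {database} "
        f"-word_size 6 -perc_identity 65 -dust no -soft_masking false "
        f"-outfmt 6 -out {out_path}"
    )


def contamination_filter(
    table: pd.DataFrame, matcher
) -> tuple[pd.DataFrame, list[str]]:
    """Remove rows the matcher rejects.  Returns (kept table, removed reads)."""
    keep, removed = [], []
    for seq in table.index:
        try:
            ok = bool(matcher(seq))
        except Exception as exc:  # never silently keep on matcher failure
            raise RuntimeError(f"contamination matcher failed on {seq[:20]}...") from exc
        (keep if ok else removed).append(seq)
    return table.loc[keep], removed


# ---------------------------------------------------------------------------
# Read assignment

@dataclass
class ExpressionTable:
    """Per-gene and per-variant raw counts plus read accounting.

    ``genes`` holds uniquely (gene-level) assigned counts; ``variants``
    holds variant totals (gene-assigned reads roll up to their variant,
    plus variant-level rescues of multi-locus ties within one variant).
    ``accounting`` records, per library, reads in / gene-assigned /
    variant-only / multimapped / unassigned; the five categories sum to
    reads in, exactly.
    """

    genes: pd.DataFrame
    variants: pd.DataFrame
    accounting: dict[str, dict[str, int]]
    gene_to_variant: dict[str, str]
    normalized_genes: pd.DataFrame | None = None
    normalized_variants: pd.DataFrame | None = None

    def normalize(self, factors: TMMFactors, lib_sizes: dict[str, float]) -> None:
        self.normalized_genes = normalize_counts(self.genes, factors, lib_sizes)
        self.normalized_variants = normalize_counts(self.variants, factors, lib_sizes)


def assign_reads(
    table: pd.DataFrame,
    loci: list[ReferenceLocus],
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_score: float = 60.0,
    tie_tol: float = 1e-6,
) -> ExpressionTable:
    """Best-hit unique assignment of unique reads to tRNA loci.

    Every read is scored locally against each locus's mature and precursor
    reference; the locus score is the larger of the two.  A read is
    assigned at gene level iff exactly one locus attains the best score;
    when several tie but all share one mature variant, the read still
    counts at variant level.  Reads whose best score falls below
    ``min_score`` are left unassigned (non-specific fragments).
    """
    if not loci:
        raise ValueError("assign_reads: empty locus list")
    libs = list(table.columns)
    gene_ids = [l.gene_id for l in loci]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene_id in loci")
    variant_ids = sorted({l.variant_id for l in loci})
    gene_counts = pd.DataFrame(0, index=gene_ids, columns=libs, dtype=int)
    var_counts = pd.DataFrame(0, index=variant_ids, columns=libs, dtype=int)
    acct = {
        lib: {"input": int(table[lib].sum()), "gene_assigned": 0, "variant_only": 0,
              "multimapped": 0, "unassigned": 0}
        for lib in libs
    }
    g2v = {l.gene_id: l.variant_id for l in loci}

    for seq, row in zip(table.index, table.to_numpy()):
        scores = np.empty(len(loci))
        for k, locus in enumerate(loci):
            s_m = local_score(locus.mature_ref, seq, scoring)
            s_p = local_score(locus.precursor_ref, seq, scoring)
            scores[k] = max(s_m, s_p)
        best = scores.max()
        if best < min_score:
            for lib, c in zip(libs, row):
                acct[lib]["unassigned"] += int(c)
            continue
        winners = [loci[k] for k in np.flatnonzero(scores >= best - tie_tol)]
        if len(winners) == 1:
            g = winners[0].gene_id
            gene_counts.loc[g] += row
            var_counts.loc[g2v[g]] += row
            for lib, c in zip(libs, row):
                acct[lib]["gene_assigned"] += int(c)
        elif len({w.variant_id for w in winners}) == 1:
            var_counts.loc[winners[0].variant_id] += row
            for lib, c in zip(libs, row):
                acct[lib]["variant_only"] += int(c)
        else:
            for lib, c in zip(libs, row):
                acct[lib]["multimapped"] += int(c)
    return ExpressionTable(
        genes=gene_counts, variants=var_counts, accounting=acct, gene_to_variant=g2v
    )


# ---------------------------------------------------------------------------
# Library comparison

def compare_libraries(
    expr: ExpressionTable,
    control: str = "control",
    deacylated: str = "deacylated",
    low_quantile: float = 0.10,
) -> pd.DataFrame:
    """Flag variants from normalized control-vs-deacylated counts.

    undetected: zero in both libraries; ambiguous: zero in exactly one;
    charged: deacylated > control (aminoacylated fraction protected from
    the control's charge loss); low: detected but total below the
    ``low_quantile`` quantile of detected variants.
    """
    if expr.normalized_variants is None:
        raise ValueError("normalize() must be called before compare_libraries")
    df = expr.normalized_variants
    for lib in (control, deacylated):
        if lib not in df.columns:
            raise ValueError(f"missing library {lib!r}")
    ctrl, deac = df[control], df[deacylated]
    undetected = (ctrl == 0) & (deac == 0)
    ambiguous = ((ctrl == 0) | (deac == 0)) & ~undetected
    charged = deac > ctrl
    totals = ctrl + deac
    detected = totals[~undetected]
    low_cut = detected.quantile(low_quantile) if len(detected) else 0.0
    low = ~undetected & (totals < low_cut)
    return pd.DataFrame(
        {
            "control": ctrl,
            "deacylated": deac,
            "undetected": undetected,
            "ambiguous": ambiguous,
            "charged": charged & ~undetected,
            "low": low,
        }
    )
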