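"""Helitron terminal-signal and hairpin scanning; in-silico PCR.

Helitron rolling-circle transposons carry a 5'-terminal TC and a
3'-terminal CTRR (R = A/G) signal and often a short subterminal hairpin
near the 3' end.  The scanners here report all exact occurrences on both
strands and leave interpretation to the caller; the CTAG-followed-by-T/C
motif is reported as its own class.  In-silico PCR confirms cluster-size
differences the way a gel would: the product length includes both primer
footprints.
"""

from __future__ import annotations

from dataclasses import dataclass

from cystra.io import VALID_BASES, revcomp

__all__ = ["MotifHit", "HairpinCandidate", "PcrProduct",
           "scan_helitron_signals", "hairpin_scan", "in_silico_pcr"]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "N": "ACGT",
}


@dataclass(frozen=True)
class MotifHit:
    motif: str  # pattern class, e.g. "TC", "CTRR", "CTAG[TC]"
    position: int  # 0-based start on the forward strand
    strand: str
    context: str  # up to 10 nt window around the hit


@dataclass(frozen=True)
class HairpinCandidate:
    start: int  # 0-based start of the 5' stem arm
    stem: int
    loop: int
    mismatches: int
    distance_from_3prime: int  # sequence end minus hairpin end


@dataclass(frozen=True)
class PcrProduct:
    seqid: str
    start: int
    end: int
    fwd_site: int
    rev_site: int
    mismatches: int

    @property
    def size(self) -> int:
        return self.end - self.start


def _iupac_match(seq: str, pos: int, pattern: str) -> bool:
    if pos + len(pattern) > len(seq):
        return False
    return all(seq[pos + k] in _IUPAC[p] for k, p in enumerate(pattern))


def _scan_forward(seq: str, pattern: str) -> list[int]:
    return [
        i
        for i in range(len(seq) - len(pattern) + 1)
        if _iupac_match(seq, i, pattern)
    ]


def scan_helitron_signals(seq: str) -> list[MotifHit]:
    """All occurrences of the Helitron terminal signals on both strands.

    Reports TC (5' signal), CTRR (3' signal, R = A/G) and CTAG followed by
    T or C as a distinct class.  Positions are 0-based starts on the
    forward strand (for '-' hits, the start of the motif's footprint).
    """
    patterns = [("TC", "TC"), ("CTRR", "CTRR"), ("CTAG[TC]", "CTAGY")]
    hits: list[MotifHit] = []
    rc = revcomp(seq)

    def context(pos: int, length: int) -> str:
        return seq[max(0, pos - 3) : pos + length + 3]

    for label, pat in patterns:
        for i in _scan_forward(seq, pat):
            hits.append(MotifHit(label, i, "+", context(i, len(pat))))
        for i in _scan_forward(rc, pat):
            pos = len(seq) - i - len(pat)
            hits.append(MotifHit(label, pos, "-", context(pos, len(pat))))
    hits.sort(key=lambda h: (h.position, h.motif, h.strand))
    return hits


def hairpin_scan(
    seq: str,
    window_from_3prime: int = 60,
    min_stem: int = 6,
    max_loop: int = 10,
    max_mismatch: int = 1,
    min_loop: int = 3,
) -> list[HairpinCandidate]:
    """Exhaustive inverted-repeat search within a 3'-terminal window.

    Every (start, stem, loop) combination inside the window is tested; a
    candidate is reported when at most ``max_mismatch`` of the stem
    positions fail to pair (complementary bases).  Brute force is fine at
    this window size.
    """
    if len(seq) < window_from_3prime:
        raise ValueError("sequence shorter than the 3' window")
    w_start = len(seq) - window_from_3prime
    window = seq[w_start:]
    n = len(window)
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    out = []
    for stem in range(min_stem, n // 2 + 1):
        for loop in range(min_loop, max_loop + 1):
            total = 2 * stem + loop
            for i in range(0, n - total + 1):
                arm1 = window[i : i + stem]
                arm2 = window[i + stem + loop : i + total]
                mm = sum(1 for x, y in zip(arm1, reversed(arm2)) if comp.get(x) != y)
                if mm <= max_mismatch:
                    out.append(
                        HairpinCandidate(
                            start=w_start + i,
                            stem=stem,
                            loop=loop,
                            mismatches=mm,
                            distance_from_3prime=n - (i + total),
                        )
                    )
    return out


def _find_sites(seq: str, primer: str, max_mismatch: int) -> list[int]:
    if max_mismatch == 0:
        sites, i = [], seq.find(primer)
        while i != -1:
            sites.append(i)
            i = seq.find(primer, i + 1)
        return sites
    sites = []
    for i in range(len(seq) - len(primer) + 1):
        mm = sum(1 for a, b in zip(seq[i : i + len(primer)], primer) if a != b)
        if mm <= max_mismatch:
            sites.append(i)
    return sites


def in_silico_pcr(
    genome,
    fwd_primer: str,
    rev_primer: str,
    max_product: int = 5000,
    max_mismatch: int = 0,
) -> list[PcrProduct]:
    """Predict PCR products of a primer pair on a genome sequence.

    The forward primer anneals on the + strand and the reverse primer on
    the − strand (its reverse complement appears on the + strand); the
    symmetric orientation is also searched.  Product size spans the two
    primers' outer 5' ends, so both footprints are included — the length
    a gel band would show.
    """
    records = genome if isinstance(genome, list) else [genome]
    for name, p in (("fwd", fwd_primer), ("rev", rev_primer)):
        if not 15 <= len(p) <= 35:
            raise ValueError(f"{name} primer must be 15-35 nt")
        if set(p) - (VALID_BASES - {"N"}):
            raise ValueError(f"{name} primer contains non-ACGT symbols")
    products = []
    for rec in records:
        seq = rec.seq
        for left, right in ((fwd_primer, rev_primer), (rev_primer, fwd_primer)):
            left_sites = _find_sites(seq, left, max_mismatch)
            right_sites = _find_sites(seq, revcomp(right), max_mismatch)
            for fs in left_sites:
                for rs in right_sites:
                    end = rs + len(right)
                    if fs < rs and end - fs <= max_product:
                        products.append(
                            PcrProduct(
                                seqid=rec.id,
                                start=fs,
                                end=end,
                                fwd_site=fs,
                                rev_site=rs,
                                mismatches=0,
                            )
                        )
            if fwd_primer == rev_primer:
                break
    products.sort(key=lambda p: (p.seqid, p.start, p.end))
    return products
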