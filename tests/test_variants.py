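import numpy as np
import pytest

from cystra.simulate import make_reference_loci, make_trna_template
from cystra.variants import (
    PairingMap,
    dedupe_mature,
    greedy_cluster,
    stem_mispair_check,
)


def point_mutant(seq, pos):
    alt = {"A": "G", "G": "A", "C": "T", "T": "C"}
    return seq[:pos] + alt[seq[pos]] + seq[pos + 1 :]


class TestDedupe:
    def test_sixteen_genes_thirteen_variants(self, loci_panel):
        genes = [(l.gene_id, l.mature_ref[:-3]) for l in loci_panel]
        variants = dedupe_mature(genes)
        assert len(genes) == 16
        assert len(variants) == 13
        sizes = sorted(len(m) for _, m in variants)
        assert sizes == [1] * 10 + [2] * 3

    def test_all_identical(self):
        variants = dedupe_mature([(f"g{i}", "ACGTACGT") for i in range(5)])
        assert len(variants) == 1
        assert len(variants[0][1]) == 5

    def test_empty_input(self):
        assert dedupe_mature([]) == []


class TestGreedyCluster:
    def test_identical_pair_one_group(self):
        groups = greedy_cluster([("a", "ACGT" * 18), ("b", "ACGT" * 18)])
        assert len(groups) == 1

    def test_identity_arithmetic_around_threshold(self, template):
        seq = template[0]  # 72-mer
        one_sub = point_mutant(seq, 5)
        three_subs = point_mutant(point_mutant(one_sub, 10), 20)
        # 71/72 = 0.986 >= 0.97 -> one group
        assert len(greedy_cluster([("a", seq), ("b", one_sub)])) == 1
        # 69/72 = 0.958 < 0.97 -> two groups
        assert len(greedy_cluster([("a", seq), ("b", three_subs)])) == 2

    def test_six_template_families_recovered(self, template):
        rng = np.random.default_rng(2)
        base = template[0]
        families = []
        # families at >=6 substitutions from each other, members at ~1%
        positions = rng.permutation(72)
        for f in range(6):
            fam = base
            for p in positions[f * 6 : f * 6 + 6]:
                fam = point_mutant(fam, int(p))
            families.append(fam)
        seqs = []
        for f, fam in enumerate(families):
            for m in range(3):
                member = point_mutant(fam, int(positions[40 + (f + m) % 10]))
                seqs.append((f"f{f}m{m}", member))
        groups = greedy_cluster(seqs, threshold=0.97)
        assert len(groups) == 6
        for g in groups:
            prefixes = {m.split("m")[0] for m in g.member_ids}
            assert len(prefixes) == 1

    def test_threshold_one_matches_dedupe_partition(self, loci_panel):
        genes = [(l.gene_id, l.mature_ref[:-3]) for l in loci_panel]
        groups = greedy_cluster(genes, threshold=1.0)
        greedy_partition = sorted(sorted(g.member_ids) for g in groups)
        dedupe_partition = sorted(sorted(m) for _, m in dedupe_mature(genes))
        assert greedy_partition == dedupe_partition

    def test_group_count_non_increasing_in_threshold(self, loci_panel):
        genes = [(l.gene_id, l.mature_ref[:-3]) for l in loci_panel]
        counts = [
            len(greedy_cluster(genes, threshold=t)) for t in (1.0, 0.99, 0.97, 0.90, 0.70)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            greedy_cluster([("a", "ACGT")], threshold=0.0)


class TestStemMispair:
    def test_reference_against_itself_clean(self, template):
        seq, pairing = template
        res = stem_mispair_check(seq, seq, pairing)
        assert res["canonical"]
        assert all(v == 0 for v in res["mispairs"].values())
        assert not any(res["indel"].values())

    def test_single_t_stem_substitution(self, template):
        seq, pairing = template
        i, j = pairing.stems["T"][2]
        # choose a base that can neither Watson-Crick nor wobble pair with j
        bad = "C" if seq[j] in "AT" else "A"
        variant = seq[:i] + bad + seq[i + 1 :]
        res = stem_mispair_check(variant, seq, pairing)
        assert res["mispairs"]["T"] == 1
        assert all(res["mispairs"][s] == 0 for s in ("acceptor", "D", "anticodon"))
        assert not res["canonical"]

    def test_wobble_pair_not_a_mispair(self, template):
        seq, pairing = template
        # find a stem pair whose 5' base is G or can become G against a T/C...
        # force a G:T wobble: set i to G where j is T (T pairs A canonically)
        chars = list(seq)
        target = None
        for name, pairs in pairing.stems.items():
            for i, j in pairs:
                if chars[j] == "T" and chars[i] == "A":
                    target = (name, i)
                    break
            if target:
                break
        assert target is not None
        name, i = target
        variant = seq[:i] + "G" + seq[i + 1 :]
        res = stem_mispair_check(variant, seq, pairing)
        assert res["mispairs"][name] == 0

    def test_eleven_nt_deletion_flags_t_stem(self, template):
        seq, pairing = template
        # remove the T-loop plus two T-stem pairs' worth of sequence:
        # positions 51..61 (11 nt) span two 5' T-stem pairs and the loop
        variant = seq[:51] + seq[62:]
        res = stem_mispair_check(variant, seq, pairing)
        assert res["indel"]["T"]
        assert not res["canonical"]

    def test_flank_padding_invariance(self, template):
        seq, pairing = template
        variant = point_mutant(seq, pairing.stems["acceptor"][0][0])
        res1 = stem_mispair_check(variant, seq, pairing)
        res2 = stem_mispair_check("TTGCA" + variant + "ACGTT", seq, pairing)
        assert res1["mispairs"] == res2["mispairs"]

    def test_pairing_map_validation(self):
        with pytest.raises(ValueError):
            PairingMap(stems={"acceptor": ((0, 80),)}, anticodon_positions=(33, 34, 35),
                       reference_length=72)
        with pytest.raises(ValueError, match="two pairs"):
            PairingMap(stems={"a": ((0, 71), (0, 70))}, anticodon_positions=(33, 34, 35),
                       reference_length=72)
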