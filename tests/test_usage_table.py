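import math

import numpy as np
import pytest

from codoncraft.records import ALL_CODONS, SYNONYM_FAMILIES, SequenceRecord, STOP_SYMBOL
from codoncraft.synth import BiasSpec, generate_cds_set, skewed_bias
from codoncraft.usage_table import (
    CodonUsageTable,
    FrameError,
    TableFormatError,
    cai,
    compute_usage_table,
    rank_top_genes,
    read_usage_table,
    write_usage_table,
)

from oracles import cai_product


def dna(seq, name="x"):
    return SequenceRecord(name, seq, "dna")


class TestRankTopGenes:
    def test_tie_broken_lexicographically(self):
        assert rank_top_genes({"g1": 10, "g2": 5, "g3": 10}, 2) == ["g1", "g3"]

    def test_single_gene(self):
        assert rank_top_genes({"g1": 1}, 1) == ["g1"]

    def test_matches_exhaustive_sort(self):
        rng = np.random.default_rng(7)
        values = rng.permutation(1000).astype(float)
        table = {f"gene{i:04d}": float(v) for i, v in enumerate(values)}
        top = rank_top_genes(table, 100)
        oracle = [g for g, _ in sorted(table.items(), key=lambda kv: -kv[1])[:100]]
        assert top == oracle

    @pytest.mark.parametrize(
        "table,n,msg",
        [({"g": 1.0}, 2, "requested top"), ({}, 1, "empty"),
         ({"g": -1.0}, 1, "finite"), ({"g": math.nan}, 1, "finite")],
    )
    def test_errors(self, table, n, msg):
        with pytest.raises(ValueError, match=msg):
            rank_top_genes(table, n)


class TestComputeUsageTable:
    def test_single_synonym_observed(self):
        t = compute_usage_table([dna("ATGAAAAAATAA")])
        assert t.counts["AAA"] == 2
        assert t.freq["AAA"] == 1.0
        assert t.weight["AAA"] == 1.0

    def test_hand_counted_leucine_family(self):
        t = compute_usage_table([dna("ATGTTGCTGCTGTAA")])
        assert t.counts["TTG"] == 1 and t.counts["CTG"] == 2
        assert t.freq["CTG"] == pytest.approx(2 / 3)
        assert t.weight["CTG"] == 1.0
        assert t.weight["TTG"] == pytest.approx(0.5)

    def test_family_frequencies_sum_to_one(self, usage_table):
        for aa, fam in SYNONYM_FAMILIES.items():
            assert sum(usage_table.freq[c] for c in fam) == pytest.approx(1.0, abs=1e-9)
            assert max(usage_table.weight[c] for c in fam) == 1.0
            assert all(0 < usage_table.weight[c] <= 1 for c in fam)

    def test_permutation_invariant_and_additive(self, biased_cds_set):
        a, b = biased_cds_set[:30], biased_cds_set[30:]
        whole = compute_usage_table(biased_cds_set)
        shuffled = compute_usage_table(list(reversed(biased_cds_set)))
        assert whole.counts == shuffled.counts
        ta, tb = compute_usage_table(a), compute_usage_table(b)
        assert whole.counts == {c: ta.counts[c] + tb.counts[c] for c in ALL_CODONS}

    def test_frame_error_names_record(self):
        with pytest.raises(FrameError, match="badrec"):
            compute_usage_table([dna("ATGA", name="badrec")])

    def test_internal_stop_noted_but_counted(self):
        t = compute_usage_table([dna("ATGTAAAAATAA")])
        assert any("internal stop" in n for n in t.notes)
        assert t.counts["TAA"] == 2

    def test_unobserved_family_uniform_and_flagged(self):
        t = compute_usage_table([dna("ATGAAATAA")])
        assert "L" in t.unobserved
        fam = SYNONYM_FAMILIES["L"]
        for c in fam:
            assert t.freq[c] == pytest.approx(1 / len(fam))
            assert t.weight[c] == pytest.approx(1 / len(fam))

    def test_recovers_generating_frequencies(self):
        bias = skewed_bias(0.35)
        spec = BiasSpec(frequencies=bias, n_genes=200, min_codons=300,
                        max_codons=300, seed=5)
        t = compute_usage_table(generate_cds_set(spec))
        for aa, vec in bias.items():
            if aa == STOP_SYMBOL:
                continue
            for codon, p in vec.items():
                assert t.freq[codon] == pytest.approx(p, abs=0.03)


class TestCai:
    def test_all_maximal_codons_give_one(self, usage_table):
        seq = "".join(
            usage_table.max_weight_codon(aa) for aa in "MKVLDERF"
        ) + usage_table.preferred_stop()
        assert cai(dna(seq), usage_table) == pytest.approx(1.0)

    def test_two_codon_geometric_mean(self):
        counts = {c: 0 for c in ALL_CODONS}
        counts.update({"AAA": 4, "AAG": 1, "GAA": 1})  # w(AAG)=0.25, w(GAA)=1
        t = CodonUsageTable(counts=counts)
        assert cai(dna("GAAAAG"), t) == pytest.approx(0.5)

    def test_matches_log_domain_product(self, usage_table):
        rng = np.random.default_rng(3)
        sense = [c for c in ALL_CODONS if c not in SYNONYM_FAMILIES[STOP_SYMBOL]]
        seq = "".join(rng.choice(sense, size=100))
        assert cai(dna(seq), usage_table) == pytest.approx(
            cai_product(seq, usage_table), abs=1e-12
        )

    def test_undefined_without_includable_codons(self, usage_table):
        with pytest.raises(ValueError, match="undefined"):
            cai(dna("ATGTGGTAA"), usage_table)  # Met + Trp + stop only


class TestSerialization:
    def test_round_trip(self, usage_table, tmp_path):
        path = tmp_path / "usage.tsv"
        write_usage_table(usage_table, path)
        back = read_usage_table(path)
        assert back.counts == usage_table.counts
        for c in ALL_CODONS:
            assert back.freq[c] == pytest.approx(usage_table.freq[c], abs=1e-6)
            assert back.weight[c] == pytest.approx(usage_table.weight[c], abs=1e-6)
        assert back.source == usage_table.source

    def test_missing_codon_rejected(self, usage_table):
        text = write_usage_table(usage_table)
        truncated = "\n".join(text.splitlines()[:-1])
        with pytest.raises(TableFormatError, match="64"):
            read_usage_table(truncated)

    def test_bad_family_normalization_rejected(self, usage_table):
        text = write_usage_table(usage_table)
        # inflate one lysine frequency so the family sums to > 1
        bad = text.replace(
            f"AAA\tK\t{usage_table.counts['AAA']}\t{usage_table.freq['AAA']:.6f}",
            f"AAA\tK\t{usage_table.counts['AAA']}\t{usage_table.freq['AAA'] + 0.02:.6f}",
        )
        assert bad != text
        with pytest.raises(TableFormatError, match="sum"):
            read_usage_table(bad)
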