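"""G scores, CAI, C scores, and codon-optimality classification."""

import math

import numpy as np
import pandas as pd
import pytest

from codonsel.codon_model import GeneModel, MutationalSpectrum
from codonsel.selection_scores import (
    CodonWeightTable,
    build_codon_weights,
    c_score,
    cai,
    classify_optimality,
    expected_counts,
    g_score_table,
    g_scores,
    synonymous_neighbors,
)

from .conftest import SENSE_CODONS, random_gene
from .helpers import exhaustive_synonymous_neighbors


class TestExpectedCounts:
    def two_gene_table(self):
        return pd.DataFrame(
            {"gene_id": ["a", "b"], "L": [300, 600], "P_S": [0.2, 0.3], "M_S": [3, 6], "M_N": [5, 7]}
        )

    def test_two_gene_toy(self):
        t = expected_counts(self.two_gene_table())
        # ⟨P_S⟩ = 0.25, ΣM_S/ΣL = 0.01; expectation is not count-conserving
        assert t["E_S"].tolist() == pytest.approx([2.4, 7.2])
        assert t["E_S"].sum() == pytest.approx(9.6)

    def test_e_n_from_e_s(self):
        t = expected_counts(self.two_gene_table())
        assert t["E_N"].iloc[0] == pytest.approx((0.8 / 0.2) * 2.4)

    def test_homogeneous_genome_conserves_counts(self):
        t = pd.DataFrame(
            {"gene_id": list("abcd"), "L": [300] * 4, "P_S": [0.25] * 4,
             "M_S": [1, 2, 3, 4], "M_N": [0] * 4}
        )
        out = expected_counts(t)
        assert out["E_S"].nunique() == 1
        assert out["E_S"].sum() == pytest.approx(out["M_S"].sum())

    def test_zero_ps_gene_excluded_with_warning(self, caplog):
        t = self.two_gene_table()
        t.loc[2] = ["c", 300, 0.0, 1, 1]
        with caplog.at_level("WARNING"):
            out = expected_counts(t)
        assert list(out["gene_id"]) == ["a", "b"]
        assert any("P_S=0" in r.message for r in caplog.records)

    def test_length_weighted_mean_switch(self):
        t = self.two_gene_table()
        unweighted = expected_counts(t)["E_S"].iloc[0]
        weighted = expected_counts(t, weighted_mean_ps=True)["E_S"].iloc[0]
        # length-weighted ⟨P_S⟩ = (300·0.2 + 600·0.3)/900 = 0.2667 > 0.25
        assert weighted < unweighted


class TestGScores:
    def test_observed_equal_expected_gives_zero(self):
        g = g_scores("g", m_s=2, m_n=4, e_s=2.0, e_n=4.0, L=300, p_s=0.25)
        assert g.g_s == 0.0 and g.g_n == 0.0

    def test_accelerated_gene_spot_value(self):
        g = g_scores("g", m_s=4, m_n=0, e_s=2.0, e_n=1.0, L=300, p_s=0.25)
        assert g.g_s == pytest.approx(4 / 75 * math.log(2))  # ≈ 0.036968

    def test_suppressed_gene_spot_value(self):
        g = g_scores("g", m_s=1, m_n=0, e_s=2.0, e_n=1.0, L=300, p_s=0.25)
        assert g.g_s == pytest.approx(1 / 75 * math.log(0.5))  # ≈ −0.0092420

    def test_zero_counts_give_zero_by_limit_convention(self):
        g = g_scores("g", m_s=0, m_n=0, e_s=2.0, e_n=4.0, L=300, p_s=0.25)
        assert g.g_s == 0.0 and g.g_n == 0.0

    def test_sign_follows_observed_minus_expected(self, rng):
        for _ in range(50):
            m = int(rng.integers(0, 10))
            e = float(rng.uniform(0.5, 8.0))
            g = g_scores("g", m_s=m, m_n=m, e_s=e, e_n=e, L=300, p_s=0.4)
            if m == 0:
                assert g.g_s == 0.0
            else:
                assert np.sign(g.g_s) == np.sign(m - e)

    def test_g_score_table_pipeline(self):
        t = pd.DataFrame(
            {"gene_id": ["a", "b"], "L": [300, 600], "P_S": [0.2, 0.3],
             "M_S": [3, 6], "M_N": [5, 7]}
        )
        out = g_score_table(t)
        assert {"E_S", "E_N", "G_S", "G_N"} <= set(out.columns)
        assert out["G_S"].iloc[0] == pytest.approx(3 / 60 * math.log(3 / 2.4))


def _genes_of(codon_lists):
    return [GeneModel(f"g{i}", "".join(cods)) for i, cods in enumerate(codon_lists)]


def _expr_for(genes, values):
    return pd.Series(values, index=[g.gene_id for g in genes], dtype=float)


class TestCodonWeights:
    def test_single_codon_reference_pseudocount(self):
        genes = _genes_of([["AAA"] * 60])
        w = build_codon_weights(genes, _expr_for(genes, [10.0]), top_n=1)
        assert w.w["AAA"] == 1.0
        # AAG unobserved: f = 0.5 pseudocount / total, w = f(AAG)/f(AAA)
        assert w.w["AAG"] == pytest.approx(0.5 / 60)

    def test_uniform_two_codon_family_both_optimal(self):
        genes = _genes_of([["AAA", "AAG"] * 30])
        w = build_codon_weights(genes, _expr_for(genes, [10.0]), top_n=1)
        assert w.w["AAA"] == 1.0 and w.w["AAG"] == 1.0

    def test_three_to_one_frequency_ratio(self):
        genes = _genes_of([["AAG", "AAG", "AAG", "AAA"] * 15])
        w = build_codon_weights(genes, _expr_for(genes, [10.0]), top_n=1)
        assert w.w["AAA"] == pytest.approx(1 / 3)
        assert w.w["AAG"] == 1.0

    def test_reference_is_top_n_by_expression(self):
        genes = _genes_of([["AAA"] * 30, ["AAG"] * 30, ["AAT"] * 30])
        w = build_codon_weights(genes, _expr_for(genes, [1.0, 9.0, 5.0]), top_n=2)
        assert set(w.reference_genes) == {"g1", "g2"}

    def test_requires_enough_expressed_genes(self):
        genes = _genes_of([["AAA"] * 30])
        with pytest.raises(ValueError, match="≥40"):
            build_codon_weights(genes, _expr_for(genes, [1.0]), top_n=40)


class TestCai:
    def weights(self, mapping):
        w = {c: 1.0 for c in SENSE_CODONS}
        w.update(mapping)
        return CodonWeightTable(w=w, f={}, reference_genes=())

    def test_all_optimal_codons(self):
        gene = GeneModel("g", "AAA" * 10)
        assert cai(gene, self.weights({})) == pytest.approx(1.0)

    def test_geometric_mean_of_two(self):
        gene = GeneModel("g", "AAAAAG")
        assert cai(gene, self.weights({"AAG": 0.25})) == pytest.approx(0.5)

    def test_constant_weight(self):
        gene = GeneModel("g", "AAG" * 7)
        assert cai(gene, self.weights({"AAG": 0.5})) == pytest.approx(0.5)

    def test_concatenation_betweenness(self, rng):
        w = self.weights({c: float(rng.uniform(0.1, 1.0)) for c in SENSE_CODONS})
        a, b = random_gene(rng, 30, "a"), random_gene(rng, 50, "b")
        both = GeneModel("ab", a.cds + b.cds)
        lo, hi = sorted([cai(a, w), cai(b, w)])
        assert lo - 1e-12 <= cai(both, w) <= hi + 1e-12


class TestCScore:
    def toy_weights(self):
        w = {c: 1.0 for c in SENSE_CODONS}
        w.update({"CTT": 1.0, "CTC": 0.5, "CTG": 0.25, "TTA": 0.125})
        return CodonWeightTable(w=w, f={}, reference_genes=())

    def test_single_synonymous_neighbor_is_zero(self):
        # His: S_CAT = {CAC} only
        rec = c_score("CAT", "CAC", self.toy_weights(), MutationalSpectrum.uniform())
        assert rec.c == pytest.approx(0.0, abs=1e-15)

    def test_leucine_toy_value(self):
        # brute-force: ln 0.25 − mean(ln 1, ln 0.5, ln 0.25, ln 0.125)
        rec = c_score("CTA", "CTG", self.toy_weights(), MutationalSpectrum.uniform())
        assert rec.c == pytest.approx(-0.3465735902799727)

    def test_nonsynonymous_change_rejected(self):
        with pytest.raises(ValueError, match="synonymous"):
            c_score("AAA", "GAA", self.toy_weights(), MutationalSpectrum.uniform())

    def test_multi_base_change_rejected(self):
        with pytest.raises(ValueError, match="single-base"):
            c_score("AAA", "AGG", self.toy_weights(), MutationalSpectrum.uniform())

    def test_neighbors_match_exhaustive_enumeration(self, code):
        for codon in SENSE_CODONS:
            assert sorted(synonymous_neighbors(codon, code)) == sorted(
                exhaustive_synonymous_neighbors(codon, code)
            )

    def test_zero_mean_over_neighbors_for_every_sense_codon(self, rng, code):
        """Σ P·C over S_a is exactly 0: W_a is the P-weighted mean of ln w."""
        from codonsel.codon_model import classify_substitution

        w = CodonWeightTable(
            w={c: float(rng.uniform(0.05, 1.0)) for c in SENSE_CODONS}, f={}, reference_genes=()
        )
        spectrum = MutationalSpectrum(rng.dirichlet(np.ones(6)))
        for a in SENSE_CODONS:
            neighbors = synonymous_neighbors(a, code)
            if not neighbors:
                continue
            probs, cs = [], []
            for m in neighbors:
                i = next(k for k in range(3) if a[k] != m[k])
                probs.append(spectrum.prob_of(classify_substitution(a[i], m[i])))
                cs.append(c_score(a, m, w, spectrum, code).c)
            probs = np.array(probs)
            if probs.sum() == 0:
                continue
            assert float(probs @ np.array(cs) / probs.sum()) == pytest.approx(0.0, abs=1e-12)


class TestClassifyOptimality:
    def test_ten_percent_tails(self):
        s = pd.Series(np.linspace(0.1, 0.9, 20), index=[f"g{i:02d}" for i in range(20)])
        labels = classify_optimality(s, fraction=0.10)
        assert (labels == "U").sum() == 2 and (labels == "O").sum() == 2
        assert (labels == "M").sum() == 16
        assert labels.loc["g00"] == "U" and labels.loc["g19"] == "O"

    def test_all_equal_cai_uses_gene_id_tie_break(self):
        s = pd.Series(0.5, index=[f"g{i:02d}" for i in range(20)])
        labels = classify_optimality(s, fraction=0.10)
        assert labels.value_counts().to_dict() == {"M": 16, "U": 2, "O": 2}
        assert list(labels[labels == "U"].index) == ["g00", "g01"]

    def test_five_percent_variant(self):
        s = pd.Series(np.arange(100, dtype=float), index=[f"g{i:03d}" for i in range(100)])
        labels = classify_optimality(s, fraction=0.05)
        assert (labels == "U").sum() == 5 and (labels == "O").sum() == 5

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="empty tails"):
            classify_optimality(pd.Series([0.1, 0.2], index=["a", "b"]), fraction=0.10)
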