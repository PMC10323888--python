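import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stromasig import (
    ExpressionMatrix,
    GeneSet,
    derive_invasive_signature,
    dge,
    filter_dge,
    generate_panin_study,
    load_packaged_signatures,
)


def _random_dataset(rng, n_genes=50, na=5, nb=6, shift_first=0.0):
    X = rng.normal(size=(n_genes, na + nb))
    X[:5, na:] += shift_first
    samples = [f"A{i}" for i in range(na)] + [f"B{i}" for i in range(nb)]
    m = ExpressionMatrix(pd.DataFrame(X, index=[f"G{i:03d}" for i in range(n_genes)], columns=samples))
    labels = pd.Series(["A"] * na + ["B"] * nb, index=samples)
    return m, labels


class TestDGE:
    def test_equal_group_means_give_zero_log2fc(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 1.0, 2.0], [5.0, 3.0, 3.0, 5.0]],
            index=["G1", "G2"],
            columns=["a1", "a2", "b1", "b2"],
        )
        labels = pd.Series(["A", "A", "B", "B"], index=df.columns)
        res = dge(ExpressionMatrix(df), labels, groups=("A", "B"), method="welch")
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-15)

    def test_welch_matches_scipy_on_toy(self):
        a = np.array([1.1, 2.3, 0.7])
        b = np.array([3.0, 2.5, 4.1])
        df = pd.DataFrame([np.concatenate([a, b])], index=["G"], columns=list("abcdef"))
        labels = pd.Series(list("AAABBB"), index=df.columns)
        res = dge(ExpressionMatrix(df), labels, groups=("A", "B"), method="welch")
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.loc["G", "t"] == pytest.approx(t_ref, rel=1e-12)
        assert res.loc["G", "p"] == pytest.approx(p_ref, rel=1e-9)
        assert res.loc["G", "log2fc"] == pytest.approx(a.mean() - b.mean())

    @pytest.mark.parametrize("method", ["welch", "moderated"])
    def test_antisymmetric_in_group_order(self, rng, method):
        m, labels = _random_dataset(rng, shift_first=1.0)
        ab = dge(m, labels, groups=("A", "B"), method=method)
        ba = dge(m, labels, groups=("B", "A"), method=method)
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"], atol=1e-12)
        np.testing.assert_allclose(ab["t"], -ba["t"], atol=1e-10)
        np.testing.assert_allclose(ab["p"], ba["p"], atol=1e-12)

    def test_moderated_matches_limma_reference(self, rng, tmp_path):
        """Dual-route check of the empirical-Bayes moderation against the
        reference R implementation on heterogeneous-variance data."""
        n_genes, na, nb = 120, 5, 7
        sd = np.sqrt(0.05 * 4 / rng.chisquare(4, n_genes))
        X = rng.normal(0, sd[:, None], size=(n_genes, na + nb))
        X[:15, na:] += 1.0
        samples = [f"A{i}" for i in range(na)] + [f"B{i}" for i in range(nb)]
        df = pd.DataFrame(X, index=[f"G{i:03d}" for i in range(n_genes)], columns=samples)
        expr_path = tmp_path / "expr.tsv"
        df.to_csv(expr_path, sep="\t")
        r_script = tmp_path / "limma.R"
        r_script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{expr_path}", row.names=1))\n'
            f'group <- factor(c(rep("A",{na}), rep("B",{nb})), levels=c("A","B"))\n'
            'fit <- eBayes(lmFit(x, model.matrix(~group)))\n'
            'out <- topTable(fit, coef=2, number=Inf, sort.by="none")\n'
            f'write.csv(data.frame(t=out$t, p=out$P.Value), "{tmp_path}/limma.csv", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(r_script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.csv")
        labels = pd.Series(["A"] * na + ["B"] * nb, index=samples)
        res = dge(ExpressionMatrix(df), labels, groups=("B", "A"), method="moderated")
        np.testing.assert_allclose(res["t"].to_numpy(), ref["t"].to_numpy(), rtol=1e-6)
        np.testing.assert_allclose(res["p"].to_numpy(), ref["p"].to_numpy(), rtol=1e-6)

    def test_moderated_approaches_pooled_t_under_homogeneous_variance(self, rng):
        # equal true variances -> strong shrinkage; moderated t stays close
        # to the ordinary pooled t and both stay close to welch for balanced n
        m, labels = _random_dataset(rng, n_genes=500, na=20, nb=20)
        mod = dge(m, labels, method="moderated")
        wel = dge(m, labels, method="welch")
        assert np.corrcoef(mod["t"], wel["t"])[0, 1] > 0.99

    def test_small_group_rejected_and_variance_floor(self):
        df = pd.DataFrame([[1.0, 1.0, 2.0, 2.0]], index=["G"], columns=list("abcd"))
        labels = pd.Series(["A", "A", "B", "B"], index=df.columns)
        res = dge(ExpressionMatrix(df), labels, method="welch")  # zero within-group var
        assert np.isfinite(res.loc["G", "t"])
        with pytest.raises(ValueError, match=">=2"):
            dge(ExpressionMatrix(df), pd.Series(["A", "B", "B", "B"], index=df.columns))

    def test_planted_genes_pass_filter_with_high_power(self):
        expr, labels, truth = generate_panin_study(
            n_per_group=10, n_genes=1000, effect_log2fc=2.0, noise_sd=0.5, seed=10
        )
        two_group = labels[labels.isin(["PDAC", "PanIN"])]
        res = dge(expr, two_group, groups=("PDAC", "PanIN"), method="moderated")
        up = filter_dge(res, lfc_min=1.0, q_max=0.05, direction="up")
        planted = truth.planted_up_vs_premalignant.genes
        assert len(up.genes & planted) / len(planted) >= 0.99


class TestFilterDGE:
    @staticmethod
    def _table(lfc, q):
        return pd.DataFrame(
            {"log2fc": lfc, "t": lfc, "p": q, "q": q},
            index=[f"G{i}" for i in range(len(lfc))],
        )

    def test_boundary_log2fc_exactly_one_excluded(self):
        res = self._table([1.0, 1.01], [0.01, 0.01])
        assert filter_dge(res).genes == {"G1"}

    def test_down_mirrors_up_under_negation(self, rng):
        lfc = rng.normal(scale=2, size=100)
        q = rng.uniform(size=100)
        up = filter_dge(self._table(lfc, q), direction="up").genes
        down = filter_dge(self._table(-lfc, q), direction="down").genes
        assert up == down

    def test_matches_brute_force(self, rng):
        res = self._table(rng.normal(scale=2, size=200), rng.uniform(size=200))
        out = filter_dge(res, lfc_min=0.8, q_max=0.1, direction="both")
        brute = {
            g
            for g in res.index
            if abs(res.loc[g, "log2fc"]) > 0.8 and res.loc[g, "q"] < 0.1
        }
        assert out.genes == brute


class TestInvasiveSignature:
    def test_worked_fixture_recovers_seven_genes(self):
        sigs = load_packaged_signatures()
        anchor = sigs["SALL4_CORRELATED_24"]
        seven = sigs["SALL4_INVASIVE_7"].genes
        up_panin = GeneSet(name="up_vs_panin", genes=frozenset(seven | {"TP53", "KRAS", "EGFR"}))
        up_normal = GeneSet(name="up_vs_normal", genes=frozenset(seven | {"MYC", "GAPDH"}))
        out = derive_invasive_signature(up_panin, up_normal, anchor)
        assert out.genes_sorted == [
            "COL11A1", "COL1A1", "COL5A2", "MMP11", "NUAK1", "PTK7", "SERPINH1",
        ]

    def test_empty_input_gives_empty_output(self):
        anchor = GeneSet(name="a", genes=frozenset("ABC"))
        empty = GeneSet(name="e", genes=frozenset())
        assert len(derive_invasive_signature(empty, anchor, anchor)) == 0
        with pytest.raises(ValueError, match="empty"):
            derive_invasive_signature(anchor, anchor, empty)

    def test_matches_brute_force_intersection(self, rng):
        pool = [f"G{i}" for i in range(30)]
        a = frozenset(rng.choice(pool, 15, replace=False))
        b = frozenset(rng.choice(pool, 15, replace=False))
        c = frozenset(rng.choice(pool, 15, replace=False))
        out = derive_invasive_signature(
            GeneSet(name="a", genes=a), GeneSet(name="b", genes=b), GeneSet(name="c", genes=c)
        )
        assert out.genes == a & b & c
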