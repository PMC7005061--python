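"""ANOVA/Tukey, species-by-site variance partitioning and Blomberg's K."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from woodgrad.grouping import (
    blomberg_k,
    blomberg_k_pvalue,
    oneway_anova,
    phylo_vcv,
    simulate_brownian,
    tukey_hsd,
    variance_partition,
)
from woodgrad.synthgen import SimulationConfig, generate_phylogeny, generate_species_pool


class TestOnewayAnova:
    def test_hand_computed_fixture(self):
        res = oneway_anova([1, 2, 3, 4], ["A", "A", "B", "B"])
        assert res.ss_between == pytest.approx(4.0)
        assert res.ss_within == pytest.approx(1.0)
        assert res.F == pytest.approx(8.0)
        assert (res.df_between, res.df_within) == (1, 2)

    def test_identical_groups_give_zero_f(self):
        res = oneway_anova([1, 2, 1, 2], ["A", "A", "B", "B"])
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_total_ss_decomposition(self, rng):
        y = rng.normal(0, 1, 60)
        g = rng.choice(list("ABC"), 60)
        res = oneway_anova(y, g)
        assert res.ss_between + res.ss_within == pytest.approx(
            float(((y - y.mean()) ** 2).sum()), rel=1e-12
        )

    def test_matches_regression_on_dummies_oracle(self, rng):
        y = rng.normal(0, 1, 50)
        g = rng.choice(list("ABCD"), 50)
        res = oneway_anova(y, g)
        # oracle: F from OLS of y on group dummies
        X = np.column_stack([np.ones(50)] + [(g == lv).astype(float) for lv in "BCD"])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = float(((y - X @ beta) ** 2).sum())
        rss0 = float(((y - y.mean()) ** 2).sum())
        F = ((rss0 - rss1) / 3) / (rss1 / (50 - 4))
        assert res.F == pytest.approx(F, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="B"):
            oneway_anova([1, 2, 3], ["A", "A", "B"])


class TestTukeyHsd:
    def test_two_groups_equal_pooled_t_test(self, rng):
        a = rng.normal(0, 1, 9)
        b = rng.normal(0.7, 1, 12)
        table = tukey_hsd(np.concatenate([a, b]), ["A"] * 9 + ["B"] * 12)
        _, p_t = stats.ttest_ind(a, b)
        assert table["p_adj"].iloc[0] == pytest.approx(p_t, abs=1e-10)

    def test_identical_groups_share_a_letter(self):
        y = [1.0, 2.0, 3.0] * 3
        g = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        table = tukey_hsd(y, g)
        assert np.allclose(table["p_adj"], 1.0)
        letters = table.attrs["letters"]
        assert len(set(letters.values())) == 1

    def test_separated_groups_get_distinct_letters(self, rng):
        y = np.concatenate([rng.normal(mu, 0.1, 10) for mu in (0, 5, 10)])
        g = np.repeat(list("ABC"), 10)
        table = tukey_hsd(y, g)
        letters = table.attrs["letters"]
        assert len({letters["A"], letters["B"], letters["C"]}) == 3

    def test_antisymmetric_differences(self, rng):
        y = rng.normal(0, 1, 30)
        g = np.repeat(list("ABC"), 10)
        table = tukey_hsd(y, g).set_index(["group1", "group2"])
        means = {lv: y[g == lv].mean() for lv in "ABC"}
        for (g1, g2), row in table.iterrows():
            assert row["difference"] == pytest.approx(means[g2] - means[g1], rel=1e-12)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd([1, 2, 3, 4], ["A", "A", "B", "B"], alpha=1.5)

    def test_matches_permutation_oracle(self, rng):
        """Adjusted p for the most extreme pair tracks a max-|t| permutation test."""
        y = np.concatenate([rng.normal(0, 1, 8), rng.normal(1.2, 1, 8),
                            rng.normal(0.4, 1, 8)])
        g = np.repeat(list("ABC"), 8)
        table = tukey_hsd(y, g).set_index(["group1", "group2"])
        p_pkg = table.loc[("A", "B"), "p_adj"]

        def max_q(yy):
            msw = sum(((yy[g == lv] - yy[g == lv].mean()) ** 2).sum() for lv in "ABC") / 21
            qs = []
            for g1, g2 in (("A", "B"), ("A", "C"), ("B", "C")):
                d = abs(yy[g == g2].mean() - yy[g == g1].mean())
                qs.append(d / np.sqrt(msw / 2 * (1 / 8 + 1 / 8)))
            return max(qs)

        q_obs = abs(y[g == "B"].mean() - y[g == "A"].mean()) / np.sqrt(
            (sum(((y[g == lv] - y[g == lv].mean()) ** 2).sum() for lv in "ABC") / 21)
            / 2 * (1 / 8 + 1 / 8)
        )
        count = sum(max_q(rng.permutation(y)) >= q_obs for _ in range(600))
        p_perm = (count + 1) / 601
        assert p_pkg == pytest.approx(p_perm, abs=0.07)


class TestVariancePartition:
    def _balanced(self, rng, sp_effect=1.0, site_effect=0.0, noise=0.1):
        rows = []
        for i, sp in enumerate(("sp1", "sp2", "sp3")):
            for j, site in enumerate(("A", "B", "C")):
                for _ in range(5):
                    rows.append(
                        {
                            "y": sp_effect * i + site_effect * j + rng.normal(0, noise),
                            "species": sp,
                            "site": site,
                        }
                    )
        return pd.DataFrame(rows)

    def test_constant_site_contributes_nothing(self, rng):
        df = self._balanced(rng, site_effect=0.0, noise=0.05)
        res = variance_partition(df["y"], df["species"], df["site"])
        assert res.variance_fractions["site"] == pytest.approx(0.0, abs=0.02)

    def test_pure_species_means_capture_everything(self, rng):
        df = self._balanced(rng, noise=0.0)
        res = variance_partition(df["y"], df["species"], df["site"])
        assert res.variance_fractions["species"] == pytest.approx(1.0, abs=1e-10)

    def test_fractions_sum_to_one_and_match_ss_oracle(self, rng):
        df = self._balanced(rng, sp_effect=1.0, site_effect=0.4, noise=0.3)
        res = variance_partition(df["y"], df["species"], df["site"])
        total = sum(r["ss"] for _, r in res.terms.iterrows())
        y = df["y"].to_numpy()
        assert total == pytest.approx(float(((y - y.mean()) ** 2).sum()), rel=1e-10)
        # balanced design: species SS equals the group-mean oracle
        ss_sp = sum(
            15 * (df[df.species == sp]["y"].mean() - y.mean()) ** 2
            for sp in ("sp1", "sp2", "sp3")
        )
        assert res.ss_between == pytest.approx(ss_sp, rel=1e-10)

    def test_min_sites_filter(self, rng):
        df = self._balanced(rng)
        rare = pd.DataFrame(
            {"y": rng.normal(10, 0.1, 4), "species": "rare", "site": "A"}
        )
        df2 = pd.concat([df, rare], ignore_index=True)
        res = variance_partition(df2["y"], df2["species"], df2["site"], min_sites=3)
        assert res.n == len(df)  # the single-site species is excluded

    def test_uncrossed_design_drops_interaction(self, rng):
        df = pd.DataFrame(
            {
                "y": rng.normal(0, 1, 20),
                "species": ["sp1"] * 10 + ["sp2"] * 10,
                "site": ["A"] * 5 + ["B"] * 5 + ["A"] * 5 + ["B"] * 5,
            }
        )
        # interaction estimable here; make it inestimable by nesting sites
        df.loc[df.species == "sp1", "site"] = ["A"] * 10
        df.loc[df.species == "sp2", "site"] = ["B"] * 10
        with pytest.raises(ValueError):
            # after nesting, each species has 1 site -> filter empties the data
            variance_partition(df["y"], df["species"], df["site"], min_sites=2)


@pytest.fixture(scope="module")
def balanced_tree():
    """8-tip fully balanced binary tree, all edges length 1 (depth 3)."""
    return "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);"


class TestBlombergK:
    def test_vcv_of_balanced_tree(self, balanced_tree):
        C, labels = phylo_vcv(balanced_tree)
        i, j = labels.index("a"), labels.index("b")
        assert C[i, i] == pytest.approx(3.0)
        assert C[i, j] == pytest.approx(2.0)
        k = labels.index("h")
        assert C[i, k] == pytest.approx(0.0)

    def test_scale_invariance(self, balanced_tree):
        trait = {t: v for t, v in zip("abcdefgh", [1, 1.2, 3, 2.5, -1, 0, 4, 2])}
        k1 = blomberg_k(trait, balanced_tree)
        scaled = balanced_tree.replace(":1", ":7")
        k2 = blomberg_k(trait, scaled)
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_brownian_traits_center_near_one(self):
        cfg = SimulationConfig(n_species=30, seed=5)
        nwk = generate_phylogeny(generate_species_pool(cfg), cfg)
        rng = np.random.default_rng(77)
        ks = [blomberg_k(simulate_brownian(nwk, rng), nwk) for _ in range(60)]
        assert 0.8 <= np.mean(ks) <= 1.2

    def test_star_tree_null_baseline_is_one(self):
        """On a star phylogeny (no shared branches) the BM null equals iid,
        so K is identically 1 whatever the trait."""
        star = "(" + ",".join(f"t{i}:1" for i in range(40)) + ");"
        rng = np.random.default_rng(3)
        for _ in range(5):
            k = blomberg_k({f"t{i}": rng.normal() for i in range(40)}, star)
            assert k == pytest.approx(1.0, rel=1e-9)

    def test_iid_traits_on_structured_tree_well_below_one(self):
        cfg = SimulationConfig(n_species=40, seed=6)
        nwk = generate_phylogeny(generate_species_pool(cfg), cfg)
        rng = np.random.default_rng(3)
        labels = [f"sp{i + 1:03d}" for i in range(40)]
        ks = [
            blomberg_k({lb: rng.normal() for lb in labels}, nwk) for _ in range(40)
        ]
        assert np.mean(ks) < 0.6

    def test_mismatched_labels_listed(self, balanced_tree):
        trait = {t: 1.0 * i for i, t in enumerate("abcdefg")}  # h missing
        trait["zz"] = 5.0
        with pytest.raises(ValueError, match="h"):
            blomberg_k(trait, balanced_tree)

    def test_zero_variance_trait_rejected(self, balanced_tree):
        with pytest.raises(ValueError, match="zero variance"):
            blomberg_k({t: 1.0 for t in "abcdefgh"}, balanced_tree)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
    def test_matches_picante_oracle(self, tmp_path, balanced_tree):
        """Independent cross-check against R picante's Kcalc."""
        trait = {t: v for t, v in zip("abcdefgh", [1.0, 1.2, 3.0, 2.5, -1.0, 0.0, 4.0, 2.0])}
        (tmp_path / "tree.nwk").write_text(balanced_tree + "\n")
        (tmp_path / "trait.csv").write_text(
            "tip,value\n" + "\n".join(f"{t},{v}" for t, v in trait.items()) + "\n"
        )
        script = textwrap.dedent(
            """
            suppressMessages(library(picante)); suppressMessages(library(ape))
            tr <- read.tree("tree.nwk")
            d <- read.csv("trait.csv")
            x <- setNames(d$value, d$tip)[tr$tip.label]
            cat(sprintf("%.10f", Kcalc(x, tr)))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], cwd=tmp_path, capture_output=True, text=True,
            timeout=120,
        )
        assert out.returncode == 0, out.stderr
        k_r = float(out.stdout.strip().splitlines()[-1])
        assert blomberg_k(trait, balanced_tree) == pytest.approx(k_r, abs=1e-6)


class TestBlombergKPvalue:
    def test_rank_formula_and_determinism(self, balanced_tree):
        trait = {t: v for t, v in zip("abcdefgh", [3, 2.5, 2, 1.5, 1, 0.5, 0, -0.5])}
        a = blomberg_k_pvalue(trait, balanced_tree, n_rand=199, seed=1)
        b = blomberg_k_pvalue(trait, balanced_tree, n_rand=199, seed=1)
        assert a.p == b.p and a.K == b.K
        # rank-based p is (1 + count) / (n_rand + 1), hence bounded below
        assert a.p >= 1.0 / 200.0
        assert 0 < a.p <= 1

    def test_observed_extreme_gives_small_p_and_rank_formula(self, balanced_tree):
        """A trait aligned with the clades beats (almost) every shuffle, and
        the reported p equals the rank formula on the stored null draws."""
        trait = {t: v for t, v in zip("abcdefgh", [0, 0.1, 0.2, 0.3, 10, 10.1, 10.2, 10.3])}
        sig = blomberg_k_pvalue(trait, balanced_tree, n_rand=199, seed=2, tail="upper")
        assert sig.p <= 5.0 / 200.0
        expected = (1 + np.sum(sig.K_random >= sig.K)) / 200.0
        assert sig.p == pytest.approx(expected, abs=1e-12)

    def test_null_p_roughly_uniform(self, balanced_tree):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(40):
            trait = {t: rng.normal() for t in "abcdefgh"}
            ps.append(
                blomberg_k_pvalue(trait, balanced_tree, n_rand=99,
                                  seed=int(rng.integers(2**31)), tail="lower").p
            )
        assert np.mean(np.array(ps) <= 0.05) < 0.25

    def test_invalid_arguments_rejected(self, balanced_tree):
        trait = {t: float(i) for i, t in enumerate("abcdefgh")}
        with pytest.raises(ValueError):
            blomberg_k_pvalue(trait, balanced_tree, n_rand=10)
        with pytest.raises(ValueError):
            blomberg_k_pvalue(trait, balanced_tree, tail="sideways")
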