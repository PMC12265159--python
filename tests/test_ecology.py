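"""Richness, diversity, rclr ordination and the species classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fecalsig.ecology import (
    classify_species,
    group_median_curve,
    rclr,
    rclr_pcoa,
    shannon,
    spearman,
    species_count,
)


class TestRichnessDiversity:
    def test_species_count_examples(self):
        assert species_count([50, 50, 0, 0]) == 2
        assert species_count([0.0] * 10) == 0
        prof = np.zeros(188)
        prof[:60] = 1.0
        assert species_count(prof) == 60

    def test_shannon_closed_forms(self):
        assert shannon([25, 25, 25, 25]) == pytest.approx(np.log(4))
        assert shannon([100, 0, 0]) == 0.0
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.5 * np.log(2))

    def test_shannon_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0, 0])

    def test_species_order_invariance(self):
        rng = np.random.default_rng(0)
        prof = rng.exponential(size=50) * (rng.random(50) < 0.6)
        perm = rng.permutation(50)
        assert species_count(prof) == species_count(prof[perm])
        if prof.sum() > 0:
            assert shannon(prof) == pytest.approx(shannon(prof[perm]))

    def test_shannon_maximal_iff_uniform(self):
        rng = np.random.default_rng(1)
        n = 20
        h_max = np.log(n)
        assert shannon(np.ones(n)) == pytest.approx(h_max)
        for _ in range(10):
            p = rng.dirichlet(np.ones(n))
            if np.allclose(p, 1 / n):
                continue
            assert shannon(p) < h_max


class TestRclrPcoa:
    def test_closed_form_sample(self):
        m = pd.DataFrame({"s": [0.25, 0.25, 0.5]}, index=["a", "b", "c"])
        out = rclr(m)["s"]
        assert out.to_numpy() == pytest.approx([-0.23105, -0.23105, 0.46210], abs=1e-4)
        assert out.sum() == pytest.approx(0.0, abs=1e-9)

    def test_nonzero_entries_sum_to_zero(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(
            rng.exponential(size=(30, 8)) * (rng.random((30, 8)) < 0.7)
        )
        m.columns = [f"S{i}" for i in range(8)]
        m = m.loc[:, m.sum() > 0]
        t = rclr(m)
        assert np.allclose(t.sum(axis=0), 0.0, atol=1e-9)

    def test_duplicated_samples_identical_coordinates(self):
        rng = np.random.default_rng(4)
        base = rng.exponential(size=(20, 5))
        m = pd.DataFrame(
            np.column_stack([base, base[:, 0]]),
            columns=["S0", "S1", "S2", "S3", "S4", "S0dup"],
        )
        res = rclr_pcoa(m)
        assert np.allclose(
            res.coordinates.loc["S0"], res.coordinates.loc["S0dup"], atol=1e-9
        )

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.exponential(size=(40, 12)))
        m.columns = [f"S{i}" for i in range(12)]
        ev = rclr_pcoa(m).explained_variance
        assert (np.diff(ev) <= 1e-12).all()
        assert ev.sum() <= 1.0 + 1e-9

    def test_coordinates_preserve_distances(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.exponential(size=(25, 10)))
        m.columns = [f"S{i}" for i in range(10)]
        X = rclr(m).to_numpy().T
        Xc = X - X.mean(axis=0)
        full = rclr_pcoa(m, n_components=10).coordinates.to_numpy()
        d_orig = np.linalg.norm(Xc[:, None] - Xc[None, :], axis=-1)
        d_proj = np.linalg.norm(full[:, None] - full[None, :], axis=-1)
        assert np.allclose(d_orig, d_proj, atol=1e-8)

    def test_planted_two_cluster_separation(self):
        rng = np.random.default_rng(7)
        n_sp, n_per = 40, 15
        base = rng.exponential(size=n_sp)
        cols = {}
        for i in range(n_per):
            cols[f"A{i}"] = base * rng.lognormal(0, 0.1, n_sp)
        shifted = base.copy()
        shifted[:20] *= 50  # cluster B overexpresses half the species
        for i in range(n_per):
            cols[f"B{i}"] = shifted * rng.lognormal(0, 0.1, n_sp)
        m = pd.DataFrame(cols)
        pc1 = rclr_pcoa(m).coordinates["PC1"]
        labels = np.array([c.startswith("B") for c in m.columns])
        from sklearn.metrics import roc_auc_score

        auc = roc_auc_score(labels, pc1)
        assert max(auc, 1 - auc) == 1.0

    def test_all_zero_sample_rejected(self):
        m = pd.DataFrame({"S0": [1.0, 2.0], "S1": [0.0, 0.0], "S2": [1.0, 1.0]})
        with pytest.raises(ValueError, match="S1"):
            rclr_pcoa(m)


def _matrix(control, cd, uc, species=None):
    """Build a species x sample frame from per-group lists of sample vectors."""
    data, names, groups = [], [], []
    for g, block in (("Control", control), ("CD", cd), ("UC", uc)):
        for i, v in enumerate(block):
            data.append(v)
            names.append(f"{g}_{i}")
            groups.append(g)
    m = pd.DataFrame(
        np.array(data).T, columns=names,
        index=species or [f"sp{i}" for i in range(len(control[0]))],
    )
    return m, pd.Series(groups, index=names)


class TestClassifySpecies:
    def test_exact_one_sided_enumeration(self):
        """{1,2,3} vs {4,5,6}: greater p = 1/20, less p = 1 - 1/20."""
        p_greater = stats.mannwhitneyu(
            [4, 5, 6], [1, 2, 3], alternative="greater", method="exact"
        ).pvalue
        p_less = stats.mannwhitneyu(
            [4, 5, 6], [1, 2, 3], alternative="less", method="exact"
        ).pvalue
        assert p_greater == pytest.approx(1 / 20)
        assert p_less == pytest.approx(1.0)  # P(U <= max) over C(6,3)=20 configs

    def test_planted_ibd_lost_recovered(self):
        rng = np.random.default_rng(11)
        n, n_sp = 50, 30
        base = rng.lognormal(0, 0.5, size=(n, n_sp))
        cd = rng.lognormal(0, 0.5, size=(n, n_sp))
        uc = rng.lognormal(0, 0.5, size=(n, n_sp))
        cd[:, 0] *= 0.05
        uc[:, 0] *= 0.05  # IBD_LOST
        cd[:, 1] *= 20.0  # CD_EXPANDED
        m, groups = _matrix(list(base), list(cd), list(uc))
        out = classify_species(m, groups)
        assert out.loc["sp0", "category"] == "IBD_LOST"
        assert out.loc["sp1", "category"] == "CD_EXPANDED"

    def test_null_species_stay_unchanged(self):
        rng = np.random.default_rng(12)
        n, n_sp = 20, 300
        blocks = [rng.lognormal(0, 1, size=(n, n_sp)) for _ in range(3)]
        m, groups = _matrix(*[list(b) for b in blocks])
        out = classify_species(m, groups)
        frac = (out["category"] != "UNCHANGED").mean()
        assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_sp)

    def test_universe_excludes_all_zero_median_species(self):
        control = [np.array([1.0, 0.0]) for _ in range(4)]
        cd = [np.array([1.0, 0.0]) for _ in range(4)]
        uc = [np.array([1.0, 0.0]) for _ in range(4)]
        # sp1 present in one sample only: median 0 in all groups
        control[0][1] = 5.0
        m, groups = _matrix(control, cd, uc)
        out = classify_species(m, groups)
        assert "sp1" not in out.index

    def test_missing_group_rejected(self):
        m = pd.DataFrame(np.ones((3, 4)), columns=["a", "b", "c", "d"])
        groups = pd.Series(["Control", "Control", "CD", "CD"], index=m.columns)
        with pytest.raises(ValueError, match="UC"):
            classify_species(m, groups)

    def test_label_permutation_fdr_calibration(self):
        """Permuted labels re-categorize only ~alpha-level species fractions."""
        rng = np.random.default_rng(13)
        n, n_sp = 15, 60
        blocks = [rng.lognormal(0, 1, size=(n, n_sp)) for _ in range(3)]
        m, groups = _matrix(*[list(b) for b in blocks])
        fracs = []
        for s in range(20):
            perm = pd.Series(
                np.random.default_rng(s).permutation(groups.to_numpy()),
                index=groups.index,
            )
            out = classify_species(m, perm)
            fracs.append((out["category"] != "UNCHANGED").mean())
        assert np.mean(fracs) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / (20 * n_sp))


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
        rho, _ = spearman(x, x**3)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks(self):
        x = np.arange(8.0)
        rho, _ = spearman(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        rho, p = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)  # 1 - 6*4/(5*24)
        # independent oracle: enumerate all 120 rank permutations
        rx = np.arange(1.0, 6.0) - 3.0
        obs = abs(rx @ (np.array([1, 3, 2, 5, 4]) - 3.0))
        count = sum(
            abs(rx @ (np.array(perm) - 3.0)) >= obs - 1e-12
            for perm in itertools.permutations([1, 2, 3, 4, 5])
        )
        assert p == pytest.approx(count / 120)

    def test_large_n_t_approximation(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestGroupMedianCurve:
    def test_arcsine_closed_forms(self):
        m = pd.DataFrame(
            {"Control_0": [0.0, 100.0, 25.0], "Control_1": [0.0, 100.0, 25.0],
             "CD_0": [0.0, 100.0, 25.0]},
            index=["sp0", "sp1", "sp2"],
        )
        groups = pd.Series(
            ["Control", "Control", "CD"], index=m.columns
        )
        out = group_median_curve(m, groups)
        assert out.loc["sp0", "Control"] == pytest.approx(0.0)
        assert out.loc["sp1", "Control"] == pytest.approx(np.pi / 2)
        assert out.loc["sp2", "Control"] == pytest.approx(np.pi / 6)
        # ordered by Control median descending
        assert list(out.index) == ["sp1", "sp2", "sp0"]

    def test_out_of_range_rejected(self):
        m = pd.DataFrame({"S0": [150.0]}, index=["sp0"])
        groups = pd.Series(["Control"], index=["S0"])
        with pytest.raises(ValueError):
            group_median_curve(m, groups)
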