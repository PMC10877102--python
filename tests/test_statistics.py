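import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fociquant.statistics import (
    compare_conditions,
    dunn_posthoc,
    kruskal_wallis,
    relative_sd,
    variation_reports,
)


def _dunn_oracle(groups, names):
    """Independent Dunn computation from pooled mid-ranks (Bonferroni)."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    split = np.split(ranks, np.cumsum([len(g) for g in groups])[:-1])
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    ties = np.sum(counts**3 - counts)
    var = n * (n + 1) / 12 - ties / (12 * (n - 1))
    k = len(groups)
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        z = (split[i].mean() - split[j].mean()) / np.sqrt(var * (1 / len(groups[i]) + 1 / len(groups[j])))
        out[(names[i], names[j])] = min(1.0, 2 * sps.norm.sf(abs(z)) * (k * (k - 1) / 2))
    return out


class TestKruskalWallis:
    def test_identical_groups_null(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert p > 0.5

    def test_all_tied_degenerate(self):
        h, p = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert h == 0.0 and p == 1.0

    def test_separated_groups_significant(self):
        h, p = kruskal_wallis([[1, 2, 3], [10, 11, 12]])
        assert p < 0.05

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 12, size=rng.integers(5, 15)).astype(float) for _ in range(3)]
        h, p = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        groups = [rng.uniform(0, 1, 12) for _ in range(3)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(5 * g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-10)


class TestDunn:
    def test_identical_groups_p_one(self):
        p = dunn_posthoc([[1, 2, 3]] * 3, names=list("abc"))
        assert all(v == 1.0 for v in p.values())

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 1, 40)
        c = rng.normal(5, 1, 40)
        p = dunn_posthoc([a, b, c], names=["a", "b", "c"])
        assert p[("a", "c")] < 0.05 and p[("b", "c")] < 0.05
        assert p[("a", "b")] > 0.2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 8, size=rng.integers(6, 12)).astype(float) for _ in range(4)]
        names = list("wxyz")
        ours = dunn_posthoc(groups, names=names)
        oracle = _dunn_oracle(groups, names)
        for key in oracle:
            assert ours[key] == pytest.approx(oracle[key], abs=1e-10)

    def test_requires_three_groups(self):
        with pytest.raises(ValueError):
            dunn_posthoc([[1, 2], [3, 4]])

    def test_permutation_symmetric(self):
        rng = np.random.default_rng(9)
        groups = [rng.uniform(size=10) for _ in range(3)]
        p1 = dunn_posthoc(groups, names=["a", "b", "c"])
        p2 = dunn_posthoc(groups[::-1], names=["c", "b", "a"])
        for (x, y), v in p1.items():
            assert p2[(y, x) if (y, x) in p2 else (x, y)] == pytest.approx(v, abs=1e-12)


class TestRelativeSd:
    def test_hand_computed_vector(self):
        assert relative_sd([8, 10, 12]) == pytest.approx(20.0)

    def test_identical_values_zero(self):
        assert relative_sd([3.3, 3.3, 3.3]) == pytest.approx(0.0)

    def test_scale_invariant(self):
        vals = [4.0, 5.5, 6.1, 7.2]
        assert relative_sd(vals) == pytest.approx(relative_sd([10 * v for v in vals]), abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            relative_sd([5.0])
        with pytest.raises(ValueError):
            relative_sd([-1.0, 1.0])


def _table(rng, patients=2, effect=3.0, n_nuclei=40):
    rows = []
    for p in range(patients):
        for cond, dose in (("control", 0.0), ("photon", 5.0)):
            for img in range(4):
                for k in range(n_nuclei):
                    lam = 0.5 + (effect if dose > 0 else 0.0)
                    count = rng.poisson(lam)
                    area = rng.uniform(60, 140)
                    rows.append(
                        {
                            "patient_id": f"P{p}",
                            "condition": cond,
                            "image_index": img,
                            "object_id": img * 1000 + k,
                            "foci_per_um3": count / (area * 3.0),
                            "area_um2": area,
                        }
                    )
    return pd.DataFrame(rows)


class TestCompareConditions:
    def test_dose_effect_significant_per_patient(self):
        table = _table(np.random.default_rng(0), effect=10.0)
        results = compare_conditions(table, "foci_per_um3")
        assert len(results) == 2
        assert all(r.significant for r in results)
        assert all(not r.dunn_p for r in results)  # two conditions → no Dunn

    def test_three_groups_trigger_dunn_when_significant(self):
        rng = np.random.default_rng(1)
        table = _table(rng, patients=1, effect=10.0)
        proton = table[table.condition == "photon"].copy()
        proton["condition"] = "proton"
        proton["foci_per_um3"] *= 2.0
        proton["object_id"] += 500000
        results = compare_conditions(pd.concat([table, proton]), "foci_per_um3")
        assert results[0].significant and len(results[0].dunn_p) == 3

    def test_missing_condition_objects_rejected(self):
        table = _table(np.random.default_rng(2), patients=1)
        table = table[~((table.condition == "photon"))]
        with pytest.raises(ValueError):
            compare_conditions(table, "foci_per_um3")

    def test_variation_reports_match_relative_sd(self):
        table = _table(np.random.default_rng(3), patients=1)
        reports = variation_reports(table, "foci_per_um3")
        for rep in reports:
            sub = table[(table.patient_id == rep.patient_id) & (table.condition == rep.condition)]
            per_image = sub.groupby("image_index")["foci_per_um3"].mean().to_numpy()
            assert rep.relative_sd_percent == pytest.approx(
                100 * per_image.std(ddof=1) / per_image.mean(), abs=1e-10
            )
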