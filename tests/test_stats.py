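"""ANOVA and Tukey HSD against hand computations and projection oracles."""

import numpy as np
import pandas as pd
import pytest

from iseikit.stats import (anova_oneway, anova_twoway, run_paper_design,
                           tukey_hsd)

from _oracles import (anova_f_p, oneway_blocks, sequential_anova_projection,
                      studentized_range_sf, twoway_blocks)


class TestOneWay:
    def test_hand_computed_example(self):
        """Groups {1,2,3} and {2,3,4}: SSB = 1.5, SSW = 4, F = 1.5 on (1,4)."""
        r = anova_oneway({"a": [1, 2, 3], "b": [2, 3, 4]})
        assert r.F == pytest.approx(1.5, abs=1e-9)
        assert (r.effects[0].df_num, r.effects[0].df_den) == (1, 4)

    def test_all_values_equal_flagged_zero_f(self):
        r = anova_oneway({"a": [2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        assert r.F == 0.0 and r.p == 1.0
        assert r.flags

    def test_zero_within_variance_unequal_means(self):
        r = anova_oneway({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert np.isinf(r.F) and r.p < 1e-300
        assert "zero_within_variance" in r.flags

    def test_matches_projection_oracle_on_random_data(self, rng):
        for _ in range(50):
            k = rng.integers(2, 5)
            labels = np.repeat([f"g{i}" for i in range(k)],
                               rng.integers(3, 9, size=k))
            y = rng.normal(size=len(labels)) + rng.normal(size=k)[
                pd.factorize(labels)[0]]
            res = anova_oneway(y, labels)
            (F, p), = anova_f_p(sequential_anova_projection(y, oneway_blocks(labels)))
            assert res.F == pytest.approx(F, rel=1e-8)
            assert res.p == pytest.approx(p, rel=1e-8, abs=1e-12)

    def test_invariance_shift_and_scale(self, rng):
        y = rng.normal(size=24)
        labels = np.repeat(list("abc"), 8)
        f0 = anova_oneway(y, labels).F
        assert anova_oneway(y + 100, labels).F == pytest.approx(f0, rel=1e-9)
        assert anova_oneway(3.5 * y, labels).F == pytest.approx(f0, rel=1e-9)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            anova_oneway({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="two groups"):
            anova_oneway({"a": [1.0, 2.0]})


class TestTwoWay:
    @staticmethod
    def frame(rng, nf=2, nm=2, n_cell=5, interaction=0.0):
        rows = []
        for i in range(nf):
            for j in range(nm):
                mu = i * 1.0 + j * 0.5 + interaction * i * j
                for v in rng.normal(mu, 1.0, n_cell):
                    rows.append({"value": v, "female": f"F{i}", "male": f"M{j}"})
        return pd.DataFrame(rows)

    def test_additive_noise_free_interaction_zero(self):
        rows = []
        for i in range(2):
            for j in range(2):
                for r in range(3):
                    rows.append({"value": i * 2.0 + j * 3.0 + 0.01 * r,
                                 "female": f"F{i}", "male": f"M{j}"})
        res = anova_twoway(pd.DataFrame(rows))
        eff = {e.effect: e for e in res.effects}
        assert eff["female:male"].F == pytest.approx(0.0, abs=1e-9)
        assert eff["female"].F > 100

    def test_balanced_matches_closed_form(self, rng):
        """Balanced 2x2: SS_F = nm * sum (mean_f - grand)^2 etc., the
        textbook decomposition."""
        df = self.frame(rng)
        res = anova_twoway(df)
        y = df.value.to_numpy()
        grand = y.mean()
        n_cell, nm, nf = 5, 2, 2
        fmeans = df.groupby("female")["value"].mean()
        mmeans = df.groupby("male")["value"].mean()
        cmeans = df.groupby(["female", "male"])["value"].mean()
        ss_f = n_cell * nm * ((fmeans - grand) ** 2).sum()
        ss_m = n_cell * nf * ((mmeans - grand) ** 2).sum()
        ss_cells = n_cell * ((cmeans - grand) ** 2).sum()
        ss_int = ss_cells - ss_f - ss_m
        ss_res = ((y - df.groupby(["female", "male"])["value"]
                   .transform("mean")) ** 2).sum()
        ms_res = ss_res / (len(y) - 4)
        eff = {e.effect: e for e in res.effects}
        assert eff["female"].F == pytest.approx(ss_f / ms_res, rel=1e-8)
        assert eff["male"].F == pytest.approx(ss_m / ms_res, rel=1e-8)
        assert eff["female:male"].F == pytest.approx(ss_int / ms_res, rel=1e-8)

    def test_unbalanced_matches_sequential_projection_oracle(self, rng):
        for _ in range(50):
            rows = []
            for i in range(2):
                for j in range(2):
                    for v in rng.normal(i + 0.3 * j, 1.0, rng.integers(2, 8)):
                        rows.append({"value": v, "female": f"F{i}",
                                     "male": f"M{j}"})
            df = pd.DataFrame(rows)
            res = anova_twoway(df)
            blocks = twoway_blocks(df.female.to_numpy(), df.male.to_numpy())
            oracle = anova_f_p(sequential_anova_projection(
                df.value.to_numpy(), blocks))
            for eff, (F, p) in zip(res.effects, oracle):
                assert eff.F == pytest.approx(F, rel=1e-8), eff.effect
                assert eff.p == pytest.approx(p, rel=1e-8, abs=1e-12)

    def test_sequential_ss_sum_to_total(self, rng):
        df = self.frame(rng, n_cell=4)
        blocks = twoway_blocks(df.female.to_numpy(), df.male.to_numpy())
        parts = sequential_anova_projection(df.value.to_numpy(), blocks)
        y = df.value.to_numpy()
        total_ss = ((y - y.mean()) ** 2).sum()
        assert sum(ss for ss, _ in parts) == pytest.approx(total_ss, rel=1e-10)

    def test_empty_cell_error_names_cell(self, rng):
        df = self.frame(rng)
        df = df[~((df.female == "F1") & (df.male == "M0"))]
        with pytest.raises(ValueError, match="F1.*M0|male=M0"):
            anova_twoway(df)


class TestTukey:
    def test_identical_groups_p_one(self):
        tk = tukey_hsd({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        row = tk.table.iloc[0]
        assert row["diff"] == 0.0 and row.p_adj == pytest.approx(1.0)

    def test_adjusted_p_matches_studentized_range_oracle(self):
        groups = {"a": [1.1, 2.0, 2.9, 1.5], "b": [2.2, 3.1, 2.7],
                  "c": [4.0, 5.2, 4.6, 5.0, 4.4]}
        tk = tukey_hsd(groups)
        arrs = {k: np.asarray(v) for k, v in groups.items()}
        dfd = sum(len(v) for v in arrs.values()) - 3
        msw = sum(((v - v.mean()) ** 2).sum() for v in arrs.values()) / dfd
        for row in tk.table.itertuples():
            a, b = arrs[row.group1], arrs[row.group2]
            q = abs(b.mean() - a.mean()) / np.sqrt(
                msw / 2 * (1 / len(a) + 1 / len(b)))
            p_oracle = studentized_range_sf(q, 3, dfd)
            assert row.p_adj == pytest.approx(p_oracle, abs=1e-6)

    def test_pair_order_sign_flip(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        r1 = tukey_hsd({"a": a, "b": b}).table.iloc[0]
        r2 = tukey_hsd({"b": b, "a": a}).table.iloc[0]
        assert r2["diff"] == pytest.approx(-r1["diff"], rel=1e-12)
        assert r2.p_adj == pytest.approx(r1.p_adj, rel=1e-12)
        assert r1.lo < r1["diff"] < r1.hi

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            tukey_hsd({"a": [1.0, 2.0]})


class TestPaperDesign:
    @staticmethod
    def cohort(rng, effect=0.0):
        rows = []
        eid = 0
        for species in ("Pse", "Mir"):
            for si, stage in enumerate(("PN", "2N", "4N", "8N")):
                for _ in range(6):
                    rows.append({
                        "egg_id": f"e{eid}", "female_species": species,
                        "male_species": species, "stage": stage,
                        "arc_length": rng.normal(0.3, 0.02),
                        "net_length": rng.normal(0.1, 0.01),
                        "aspect_ratio": rng.normal(3, 0.2),
                        "average_curvature": rng.normal(90, 5),
                        "total_curvature": rng.normal(27, 2) + effect * si,
                        "sperm_positioning": rng.normal(0.05, 0.005)
                        if stage == "PN" else None,
                        "pronuclei_distance": rng.normal(0.02, 0.002)
                        if stage == "PN" else None,
                    })
                    eid += 1
        from iseikit.pipeline import build_table
        return build_table(rows)

    def test_injected_stage_effect_detected(self, rng):
        res = run_paper_design(self.cohort(rng, effect=6.0))
        a = res["anova"]
        hit = a[(a.family == "within_species")
                & (a.descriptor == "total_curvature")]
        assert hit.significant.all()
        # significant rows got Tukey tables
        assert any(k[2] == "total_curvature" for k in res["tukey"])

    def test_missing_cells_skipped_not_imputed(self, rng):
        tab = self.cohort(rng)
        tab = tab[~((tab.female_species == "Mir") & (tab.stage == "2N"))]
        res = run_paper_design(tab)
        a = res["anova"]
        between_2n = a[(a.family == "between_species") & (a.context == "2N")]
        assert len(between_2n) == 0
        assert any(s[0] == "between_species" and s[1] == "2N"
                   for s in res["skipped"])

    def test_hybrid_family_runs_on_complete_2x2(self, rng):
        rows = []
        eid = 0
        for f in ("Pse", "Per"):
            for m in ("Pse", "Per"):
                for _ in range(5):
                    rows.append({"egg_id": f"h{eid}", "female_species": f,
                                 "male_species": m, "stage": "PN",
                                 "arc_length": rng.normal(0.3, 0.02),
                                 "net_length": rng.normal(0.1, 0.01),
                                 "aspect_ratio": rng.normal(3, 0.2),
                                 "average_curvature": rng.normal(90, 5),
                                 "total_curvature": rng.normal(27, 2)})
                    eid += 1
        from iseikit.pipeline import build_table
        res = run_paper_design(build_table(rows))
        hybrid = res["anova"][res["anova"].family == "hybrid"]
        assert set(hybrid.factor) == {"female", "male", "female:male"}
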