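import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from convoturn.analysis import (
    average_per_condition,
    compare_groups_ranksum,
    correlate_flow_vs_fto,
    find_matched_subset,
    mixed_model_ratings,
)
from convoturn.synthetic import RatingGenParams, generate_stimulus_metadata, generate_synthetic_ratings


@pytest.fixture(scope="module")
def metadata(presentation_lists):
    return generate_stimulus_metadata(presentation_lists, master_seed=5)


@pytest.fixture(scope="module")
def ratings(metadata):
    return generate_synthetic_ratings(metadata, RatingGenParams(), seed=13)


class TestAveragePerCondition:
    def test_identical_values_mean(self):
        df = pd.DataFrame(
            {
                "participant": ["P0"] * 8,
                "gender": ["female"] * 8,
                "scheme": ["NHQ"] * 8,
                "attribute": ["flow"] * 8,
                "value": [3.5] * 8,
            }
        )
        out = average_per_condition(df)
        assert len(out) == 1 and out["value"].iloc[0] == 3.5 and out["n"].iloc[0] == 8

    def test_order_invariance(self, ratings):
        a = average_per_condition(ratings)
        b = average_per_condition(ratings.sample(frac=1.0, random_state=0))
        merged = a.merge(b, on=["participant", "scheme", "attribute"], suffixes=("_a", "_b"))
        assert np.allclose(merged["value_a"], merged["value_b"])

    def test_missing_cell_warns(self, ratings):
        drop = ratings[~((ratings.participant == "P000") & (ratings.scheme == "HIN"))]
        with pytest.warns(UserWarning, match="empty"):
            out = average_per_condition(drop)
        nan_rows = out[out["value"].isna()]
        assert set(nan_rows["participant"]) == {"P000"}


class TestMixedModel:
    def test_planted_effects_recovered(self, ratings):
        cells = average_per_condition(ratings)
        mm = mixed_model_ratings(cells, "flow")
        anova = mm.anova.set_index("effect")
        assert anova.loc["scheme", "p"] < 1e-6
        assert anova.loc["gender", "p"] > 0.05
        est = mm.contrasts.set_index("pair")["estimate"]
        # generator plants HIN - NHQ = -0.8
        assert est["HIN - NHQ"] == pytest.approx(-0.8, abs=0.15)

    def test_interaction_recovered(self, metadata):
        """A gender-specific deficit surfaces as a scheme:gender interaction."""
        params = RatingGenParams(
            condition_effects={},
            interaction_effects={("male", "HIN"): -1.0},
            residual_sd=0.3,
        )
        r = generate_synthetic_ratings(metadata, params, seed=4)
        mm = mixed_model_ratings(average_per_condition(r), "ease_of_following")
        anova = mm.anova.set_index("effect")
        assert anova.loc["scheme:gender", "p"] < 0.001

    def test_incomplete_design_rejected(self, ratings):
        cells = average_per_condition(ratings)
        broken = cells[
            ~((cells.participant == "P001") & (cells.scheme == "NHQ"))
        ]
        with pytest.raises(ValueError, match="condition cells"):
            mixed_model_ratings(broken, "flow")

    def test_summary_mentions_model(self, ratings):
        mm = mixed_model_ratings(average_per_condition(ratings), "naturalness")
        text = mm.summary()
        assert "random intercept" in text and "scheme" in text

    def test_agrees_with_r_lmer(self, ratings, tmp_path):
        """Cross-check fixed effects and Wald F against lme4/lmerTest."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        cells = average_per_condition(ratings)
        df = cells[cells.attribute == "flow"]
        csv = tmp_path / "cells.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages({library(lme4); library(lmerTest)})
            options(contrasts=c("contr.sum", "contr.poly"))
            d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
            # byte-order factor levels, matching patsy's sum coding
            d$scheme <- factor(d$scheme, levels=c("HIN","NHQ","conLow","conNHQ"))
            d$gender <- factor(d$gender, levels=c("female","male"))
            m <- lmer(value ~ scheme * gender + (1|participant), data=d, REML=TRUE)
            a <- anova(m)  # lmerTest: Type III, Satterthwaite ddf
            cat(fixef(m)["(Intercept)"], a["scheme","F value"], a["gender","F value"], "\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        r_int, r_f_scheme, r_f_gender = map(float, out.stdout.split())
        mm = mixed_model_ratings(cells, "flow")
        assert mm.fit.fe_params["Intercept"] == pytest.approx(r_int, rel=1e-3)
        anova = mm.anova.set_index("effect")
        assert anova.loc["scheme", "F"] == pytest.approx(r_f_scheme, rel=0.02)
        assert anova.loc["gender", "F"] == pytest.approx(r_f_gender, rel=0.05, abs=0.05)


class TestSpearman:
    def test_strictly_decreasing_gives_minus_one(self, metadata):
        params = RatingGenParams(
            condition_effects={}, fto_median_slope=-0.001, participant_sd=0.0, residual_sd=0.0
        )
        r = generate_synthetic_ratings(metadata, params, seed=1)
        rho, p, n = correlate_flow_vs_fto(r, "median")
        assert rho == pytest.approx(-1.0)
        assert n == len(r) // 3 // 2  # flow attribute, NHQ+HIN half of schemes

    def test_equals_rank_transform_pearson(self, ratings):
        rho, _, _ = correlate_flow_vs_fto(ratings, "iqr")
        sel = ratings[(ratings.attribute == "flow") & ratings.scheme.isin(["NHQ", "HIN"])]
        pearson = np.corrcoef(
            stats.rankdata(sel["realized_fto_iqr_ms"]), stats.rankdata(sel["value"])
        )[0, 1]
        assert rho == pytest.approx(pearson, abs=1e-12)

    def test_null_is_small(self, metadata):
        params = RatingGenParams(condition_effects={}, residual_sd=0.5)
        r = generate_synthetic_ratings(metadata, params, seed=99)
        rho, p, _ = correlate_flow_vs_fto(r, "median")
        assert abs(rho) < 0.1

    def test_too_few_records(self, ratings):
        with pytest.raises(ValueError, match=">= 5"):
            correlate_flow_vs_fto(ratings.head(3), "median")


class TestRankSum:
    def test_identical_groups(self):
        z, p = compare_groups_ranksum([1, 2, 3, 4], [1, 2, 3, 4])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_disjoint_small_groups_exact(self):
        """Disjoint supports at n=5+5: exact two-sided p = 2/252."""
        z, p = compare_groups_ranksum([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert p == pytest.approx(2 / 252)
        assert z < 0

    def test_degenerate_all_equal(self):
        z, p = compare_groups_ranksum([2.0] * 5, [2.0] * 5)
        assert (z, p) == (0.0, 1.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups_ranksum([1, 2], [3, 4, 5])

    def test_normal_approx_close_to_exact(self):
        """At n = 6+6 the continuity-corrected normal p tracks exact enumeration."""
        rng = np.random.default_rng(0)
        mu = 6 * 13 / 2.0
        sd = np.sqrt(36 / 12 * 13)
        for _ in range(20):
            a = rng.normal(size=6)
            b = rng.normal(loc=rng.uniform(0, 1.5), size=6)
            z, p_exact = compare_groups_ranksum(a, b)
            w = mu + z * sd  # reconstruct W (no ties in continuous data)
            p_norm = 2 * stats.norm.sf(max(abs(w - mu) - 0.5, 0.0) / sd)
            assert abs(p_exact - p_norm) < 0.02

    def test_large_n_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=40)
        b = rng.normal(loc=0.5, size=35)
        z, p = compare_groups_ranksum(a, b)
        z_sp, p_sp = stats.ranksums(a, b)
        assert z == pytest.approx(z_sp, abs=1e-9)  # no ties here
        # scipy applies no continuity correction; at this n it is < 0.01
        assert p == pytest.approx(p_sp, abs=0.01)


def _exhaustive_subset_search(records, col, width, step, alpha, max_diff):
    """Brute-force oracle over every window position."""
    sel = records[records["scheme"].isin(["NHQ", "HIN"])]
    if "attribute" in sel.columns:
        sel = sel[sel["attribute"] == "flow"]
    x = sel[col].to_numpy()
    best = None
    lo = np.floor(x.min() / step) * step
    while lo <= x.max():
        win = sel[(sel[col] >= lo) & (sel[col] <= lo + width)]
        na = (win["scheme"] == "NHQ").sum()
        nb = (win["scheme"] == "HIN").sum()
        if na >= 3 and nb >= 3 and abs(na - nb) <= max_diff:
            _, p = compare_groups_ranksum(
                win.loc[win["scheme"] == "NHQ", col], win.loc[win["scheme"] == "HIN", col]
            )
            if p > alpha and (best is None or na + nb > best[0]):
                best = (na + nb, lo, lo + width)
        lo += step
    return best


class TestMatchedSubset:
    def test_matches_exhaustive_oracle(self, ratings):
        res = find_matched_subset(ratings, "median", window_width_ms=80, step_ms=20)
        oracle = _exhaustive_subset_search(
            ratings, "realized_fto_median_ms", 80, 20, 0.05, 20
        )
        assert oracle is not None and not res.empty
        assert res.n_total == oracle[0]
        assert res.interval == pytest.approx((oracle[1], oracle[2]))
        assert res.n_total == res.n_nhq + res.n_hin

    def test_impossible_balance_returns_empty(self, metadata):
        """With max_count_diff = 0 and odd imbalance everywhere, no window fits."""
        params = RatingGenParams(n_participants=1, n_female=1, condition_effects={})
        r = generate_synthetic_ratings(metadata, params, seed=0)
        # restrict to a slice where counts can never be equal
        r = pd.concat([r[r.scheme == "NHQ"], r[r.scheme == "HIN"].iloc[:3]])
        res = find_matched_subset(r, "median", max_count_diff=0)
        assert res.empty and res.n_total == 0

    def test_median_vs_iqr_dissociation(self, metadata):
        """A flow deficit carried by FTO median alone: matching on median kills
        the contrast, matching on IQR leaves it significant."""
        params = RatingGenParams(
            condition_effects={},
            fto_median_slope=-0.002,
            participant_sd=0.1,
            residual_sd=0.15,
        )
        r = generate_synthetic_ratings(metadata, params, seed=6)
        med = find_matched_subset(r, "median")
        iqr = find_matched_subset(r, "iqr")
        assert not med.empty and not iqr.empty
        assert med.match_test[1] > 0.05  # medians matched
        assert iqr.contrast_test[1] < 0.05  # flow differs when only IQR matched
        assert med.contrast_test[1] > iqr.contrast_test[1]
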