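import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from aerodep.aerosol import DUAL, TRIPLE
from aerodep.errors import InsufficientPairsError, MissingStrataError
from aerodep.stats import (
    SyntheticStatsConfig,
    equivalence_report,
    fit_ratio_model,
    paired_log_ratios,
    synthetic_paired_depositions,
    tost_equivalence,
)


def _paired_table(n=20, ratio_measured=1.2, ratio_optimal=1.2, sigma=0.1, seed=0):
    """Paired lognormal intrathoracic data with known true product ratios."""
    rng = np.random.default_rng(seed)
    rows = []
    b = 0.2 * rng.standard_normal(n)
    for i in range(n):
        for flow, ratio in (("measured", ratio_measured), ("optimal", ratio_optimal)):
            for product, mult in ((DUAL, 1.0), (TRIPLE, ratio)):
                rows.append(
                    {
                        "patient_id": f"P{i:03d}",
                        "api": "BDP",
                        "product": product,
                        "flow_kind": flow,
                        "value": 28.0 * mult * np.exp(b[i] + sigma * rng.standard_normal()),
                    }
                )
    return pd.DataFrame(rows)


class TestFitRatioModel:
    def test_balanced_estimate_equals_exp_mean_log_difference(self):
        table = _paired_table(seed=3)
        res = fit_ratio_model(table)
        logv = np.log(table.set_index(["patient_id", "product", "flow_kind"])["value"])
        for r in res:
            diffs = (
                logv.xs(TRIPLE, level="product").xs(r.flow_kind, level="flow_kind")
                - logv.xs(DUAL, level="product").xs(r.flow_kind, level="flow_kind")
            )
            assert r.ratio == pytest.approx(float(np.exp(diffs.mean())), rel=1e-6)

    def test_label_swap_inverts_ratios(self):
        table = _paired_table(ratio_measured=1.15, ratio_optimal=1.05, seed=5)
        swapped = table.replace({"product": {TRIPLE: DUAL, DUAL: TRIPLE}})
        for a, b in zip(fit_ratio_model(table), fit_ratio_model(swapped)):
            assert b.ratio == pytest.approx(1.0 / a.ratio, rel=1e-9)
            assert b.p == pytest.approx(a.p, abs=1e-12)

    def test_identical_products_give_unity_ratio(self):
        table = _paired_table(seed=7)
        dual = table[table["product"] == DUAL].copy()
        clone = dual.copy()
        clone["product"] = TRIPLE
        res = fit_ratio_model(pd.concat([dual, clone], ignore_index=True))
        for r in res:
            assert r.ratio == pytest.approx(1.0, abs=1e-12)
            assert r.p == pytest.approx(1.0, abs=1e-9) or np.isnan(r.p)

    def test_unbalanced_table_names_offender(self):
        table = _paired_table(seed=1).iloc[1:]
        with pytest.raises(MissingStrataError):
            fit_ratio_model(table)

    def test_fixed_effects_variant_agrees_on_point_estimate(self):
        table = _paired_table(seed=9)
        mixed = fit_ratio_model(table, method="mixed")
        fixed = fit_ratio_model(table, method="fixed")
        for a, b in zip(mixed, fixed):
            assert b.ratio == pytest.approx(a.ratio, rel=1e-9)

    def test_matches_r_lmer_emmeans_oracle(self, tmp_path):
        """Independent oracle: lme4/lmerTest + emmeans on the same table."""
        cfg = SyntheticStatsConfig(center_residuals=False)
        table = synthetic_paired_depositions(20, seed=11, config=cfg)
        it = table[table["region"] == "intrathoracic"]
        mine = {r.flow_kind: r for r in fit_ratio_model(it)}
        csv = tmp_path / "d.csv"
        it.to_csv(csv, index=False)
        script = tmp_path / "m.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages({{library(lme4); library(lmerTest); library(emmeans)}})
                d <- read.csv("{csv}")
                d$product <- relevel(factor(d$product), ref="BDP/FF")
                d$flow_kind <- relevel(factor(d$flow_kind), ref="measured")
                m <- lmer(log(value) ~ product*flow_kind + api + (1|patient_id), data=d)
                em <- emmeans(m, ~ product | flow_kind, lmer.df="satterthwaite")
                ct <- as.data.frame(summary(pairs(em, reverse=TRUE), infer=TRUE))
                write.csv(ct, "{tmp_path / 'out.csv'}", row.names=FALSE)
                """
            )
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        oracle = pd.read_csv(tmp_path / "out.csv")
        for _, row in oracle.iterrows():
            r = mine[row["flow_kind"]]
            assert r.ratio == pytest.approx(float(np.exp(row["estimate"])), rel=1e-5)
            assert r.se / r.ratio == pytest.approx(row["SE"], rel=1e-3)
            assert r.df == pytest.approx(row["df"], abs=2.0)


class TestTostEquivalence:
    def test_null_differences_give_unity_with_degenerate_interval(self):
        res = tost_equivalence(np.zeros(20))
        assert res.ratio == 1.0
        assert res.ci_low == res.ci_high == 1.0
        assert res.equivalent

    def test_mean_at_upper_bound_cannot_be_equivalent(self):
        rng = np.random.default_rng(2)
        x = 0.05 * rng.standard_normal(20)
        x = x - x.mean() + np.log(1.25)  # mean log-ratio exactly at the bound
        res = tost_equivalence(x)
        assert res.tost_p >= 0.5
        assert not res.equivalent

    def test_symmetric_interval_on_null_with_noise(self):
        rng = np.random.default_rng(3)
        x = 0.1 * rng.standard_normal(40)
        x = x - x.mean()
        res = tost_equivalence(x)
        assert res.ratio == pytest.approx(1.0, abs=1e-12)
        assert res.ci_low * res.ci_high == pytest.approx(1.0, rel=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientPairsError):
            tost_equivalence(np.array([0.1, 0.2]))

    def test_type_one_error_at_boundary_controlled(self):
        """Declaring equivalence when the true ratio sits ON the bound."""
        rng = np.random.default_rng(12)
        n, reps, sigma = 20, 2000, 0.08
        hits = 0
        for _ in range(reps):
            x = np.log(1.25) + sigma * rng.standard_normal(n)
            hits += tost_equivalence(x).equivalent
        rate = hits / reps
        mc_err = np.sqrt(0.05 * 0.95 / reps)
        assert rate <= 0.05 + 3 * mc_err


class TestEquivalenceReport:
    def test_cardinality_twelve_tost_rows_two_ratio_rows(self, synth_table):
        equiv, ratios = equivalence_report(synth_table)
        assert len(equiv) == 12
        assert len(ratios) == 2
        assert {e.api for e in equiv} == {"BDP", "FF"}

    def test_label_swap_mirrors_equivalence_intervals(self, synth_table):
        swapped = synth_table.replace({"product": {TRIPLE: DUAL, DUAL: TRIPLE}})
        ea, _ = equivalence_report(synth_table)
        eb, _ = equivalence_report(swapped)
        for a, b in zip(ea, eb):
            assert b.ratio == pytest.approx(1.0 / a.ratio, rel=1e-9)
            assert b.ci_low == pytest.approx(1.0 / a.ci_high, rel=1e-9)
            assert b.ci_high == pytest.approx(1.0 / a.ci_low, rel=1e-9)

    def test_missing_strata_reported_by_name(self, synth_table):
        broken = synth_table[
            ~(
                (synth_table["api"] == "FF")
                & (synth_table["region"] == "central")
                & (synth_table["flow_kind"] == "optimal")
            )
        ]
        with pytest.raises(MissingStrataError, match="FF/central/optimal"):
            equivalence_report(broken)

    def test_intrathoracic_and_central_intervals_within_bioequivalence(self, synth_table):
        equiv, _ = equivalence_report(synth_table)
        for e in equiv:
            if e.region in ("intrathoracic", "central"):
                assert 0.80 <= e.ci_low and e.ci_high <= 1.25


class TestSyntheticGenerator:
    def test_deterministic_under_fixed_seed(self, synth_table):
        again = synthetic_paired_depositions(20, seed=1)
        pd.testing.assert_frame_equal(synth_table, again)

    def test_intrathoracic_is_sum_of_central_and_peripheral(self, synth_table):
        wide = synth_table.pivot_table(
            index=["patient_id", "api", "product", "flow_kind"],
            columns="region",
            values="value",
        )
        np.testing.assert_allclose(
            wide["intrathoracic"], wide["central"] + wide["peripheral"], rtol=1e-12
        )

    def test_centred_cohort_reproduces_cell_geometric_means(self, synth_table):
        cfg = SyntheticStatsConfig()
        gm = cfg.cell_geometric_means()
        grp = synth_table[synth_table["region"] == "central"].groupby(
            ["api", "product", "flow_kind"]
        )["value"]
        for (api, product, flow), vals in grp:
            assert float(np.exp(np.log(vals).mean())) == pytest.approx(
                gm[(api, product, flow)][0], rel=1e-9
            )

    def test_tost_ratio_matches_calibrated_peripheral_ratio(self, synth_table):
        x = paired_log_ratios(synth_table, "BDP", "peripheral", "measured")
        assert float(np.exp(x.mean())) == pytest.approx(1.20, abs=1e-9)
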