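"""Within-subject factorial ANOVA, effect sizes and Fisher LSD.

The four-factor decomposition is checked against a frozen oracle computed
with R's aov() using Error(subject/(condition*movement*tdcs*hemisphere))
strata on a seeded dataset (the generating recipe is reproduced here
verbatim, so the comparison is exact and self-contained).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from muerd.errors import DesignError, ParameterError
from muerd.stats import (
    erd_table_to_design,
    eta_sq_from_f,
    fisher_lsd,
    rm_anova,
)

# F and p per effect from R 4.3.3 aov() on the dataset built by _r_dataset()
R_AOV_ORACLE = {
    "condition": (1.301200717, 0.3056679968),
    "movement": (6.875368642, 0.04697902639),
    "tdcs": (0.6960676668, 0.5211638962),
    "hemisphere": (10.91040711, 0.02140253766),
    "condition:movement": (0.583585798, 0.4793877854),
    "condition:tdcs": (0.09567408444, 0.9095818932),
    "condition:hemisphere": (0.005152460053, 0.9455592681),
    "movement:tdcs": (1.472310753, 0.2751396737),
    "movement:hemisphere": (0.2776994979, 0.6207474327),
    "tdcs:hemisphere": (0.7378169498, 0.5024774498),
    "condition:movement:tdcs": (0.3526853932, 0.71119948),
    "condition:movement:hemisphere": (0.004095252486, 0.9514545324),
    "condition:tdcs:hemisphere": (0.4780413229, 0.6334662798),
    "movement:tdcs:hemisphere": (0.8371886051, 0.4611385097),
    "condition:movement:tdcs:hemisphere": (0.03387951234, 0.9667984377),
}


def _r_dataset():
    rng = np.random.default_rng(20240901)
    rows = []
    for s in range(6):
        for ci, c in enumerate(("observation", "imagery")):
            for mi, m in enumerate(("biological", "nonbiological")):
                for ti, t in enumerate(("anodal", "cathodal", "sham")):
                    for hi, h in enumerate(("C3", "C4")):
                        y = rng.normal() + 0.5 * mi - 0.3 * hi * mi + 0.2 * ti
                        rows.append(
                            dict(subject=s, condition=c, movement=m, tdcs=t,
                                 hemisphere=h, erd=y)
                        )
    return pd.DataFrame(rows)


def _random_design(rng, n_subj=6):
    rows = [
        dict(subject=s, condition=c, movement=m, tdcs=t, hemisphere=h,
             erd=rng.normal())
        for s in range(n_subj)
        for c in ("observation", "imagery")
        for m in ("biological", "nonbiological")
        for t in ("anodal", "cathodal", "sham")
        for h in ("C3", "C4")
    ]
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_agrees_with_r_aov_oracle(self):
        table = rm_anova(_r_dataset())
        assert set(table.index) == set(R_AOV_ORACLE)
        for effect, (F, p) in R_AOV_ORACLE.items():
            assert table.loc[effect, "F"] == pytest.approx(F, rel=1e-6)
            assert table.loc[effect, "p"] == pytest.approx(p, rel=1e-6)

    def test_single_factor_equals_paired_t(self):
        rng = np.random.default_rng(4)
        n = 12
        df = pd.DataFrame(
            [dict(subject=s, A=a, erd=rng.normal() + 0.4 * (a == "a2"))
             for s in range(n) for a in ("a1", "a2")]
        )
        table = rm_anova(df, within=["A"])
        wide = df.pivot(index="subject", columns="A", values="erd")
        t, p = sps.ttest_rel(wide["a1"], wide["a2"])
        assert table.loc["A", "F"] == pytest.approx(t**2, rel=1e-12)
        assert table.loc["A", "p"] == pytest.approx(p, rel=1e-12)
        assert table.loc["A", "df_effect"] == 1
        assert table.loc["A", "df_error"] == n - 1

    def test_ss_decomposition_sums_to_total(self):
        rng = np.random.default_rng(7)
        table = rm_anova(_random_design(rng))
        assert abs(table.attrs["decomposition_residual"]) < 1e-8 * table.attrs["ss_total"]

    def test_df_structure(self):
        table = rm_anova(_random_design(np.random.default_rng(0), n_subj=21))
        assert tuple(table.loc["movement", ["df_effect", "df_error"]]) == (1, 20)
        assert tuple(table.loc["tdcs:hemisphere", ["df_effect", "df_error"]]) == (2, 40)

    def test_zero_error_stratum_reports_infinite_f(self):
        # identical subjects: effect present, no subject x effect variability
        df = pd.DataFrame(
            [dict(subject=s, A=a, erd=1.0 if a == "a2" else 0.0)
             for s in range(5) for a in ("a1", "a2")]
        )
        table = rm_anova(df, within=["A"])
        assert table.loc["A", "ss_error"] == pytest.approx(0.0)
        assert np.isinf(table.loc["A", "F"])
        assert table.loc["A", "p"] == 0.0

    def test_missing_cell_is_design_error(self):
        df = _random_design(np.random.default_rng(0)).iloc[:-1]
        with pytest.raises(DesignError, match="missing cells"):
            rm_anova(df)

    def test_duplicate_cell_is_design_error(self):
        df = _random_design(np.random.default_rng(0))
        df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(DesignError, match="more than one observation"):
            rm_anova(df)

    def test_gg_epsilon_is_one_for_two_level_factor(self):
        table = rm_anova(_random_design(np.random.default_rng(2)), gg=True)
        assert table.loc["movement", "gg_epsilon"] == pytest.approx(1.0)
        assert 1.0 / 2 <= table.loc["tdcs", "gg_epsilon"] <= 1.0


class TestEtaSquared:
    @pytest.mark.parametrize(
        "F, df1, df2, printed, decimals",
        [
            (10.2, 1, 20, 0.3, 1),
            (3.4, 2, 40, 0.1, 1),
            (4.2, 2, 40, 0.2, 1),
            (1.05, 1, 20, 0.05, 2),
            (3.66, 2, 40, 0.15, 2),
        ],
    )
    def test_reported_effect_sizes_reproduced(self, F, df1, df2, printed, decimals):
        assert round(eta_sq_from_f(F, df1, df2), decimals) == pytest.approx(printed)

    def test_zero_f_gives_zero(self):
        assert eta_sq_from_f(0.0, 2, 40) == 0.0

    def test_identity_with_ss_based_value(self):
        table = rm_anova(_random_design(np.random.default_rng(11)))
        for effect, row in table.iterrows():
            assert eta_sq_from_f(
                row.F, int(row.df_effect), int(row.df_error)
            ) == pytest.approx(row.partial_eta_sq, rel=1e-12)


class TestFisherLsd:
    def test_identical_cells_give_t0_p1(self):
        df = pd.DataFrame(
            [dict(subject=s, A=a, erd=float(s)) for s in range(5) for a in ("a1", "a2")]
        )
        out = fisher_lsd(df, within=["A"], effect=["A"])
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p"] == 1.0

    def test_antisymmetry_under_relabeling(self):
        rng = np.random.default_rng(3)
        df = _random_design(rng)
        out = fisher_lsd(df, effect=["tdcs"])
        flipped = df.copy()
        flipped["tdcs"] = flipped["tdcs"].map(
            {"anodal": "cathodal", "cathodal": "anodal", "sham": "sham"}
        )
        out_f = fisher_lsd(flipped, effect=["tdcs"])

        def oriented_t(table):
            """t for anodal-vs-cathodal regardless of stored pair order."""
            for _, r in table.iterrows():
                if {r.cell_a, r.cell_b} == {("anodal",), ("cathodal",)}:
                    return r.t if r.cell_a == ("anodal",) else -r.t
            raise AssertionError("pair not found")

        assert oriented_t(out) == pytest.approx(-oriented_t(out_f), rel=1e-12)

    def test_single_factor_lsd_matches_paired_t(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            [dict(subject=s, A=a, erd=rng.normal() + (a == "a2"))
             for s in range(9) for a in ("a1", "a2")]
        )
        out = fisher_lsd(df, within=["A"], effect=["A"])
        wide = df.pivot(index="subject", columns="A", values="erd")
        t, p = sps.ttest_rel(wide["a1"], wide["a2"])
        assert out.loc[0, "t"] == pytest.approx(t, rel=1e-12)
        assert out.loc[0, "p"] == pytest.approx(p, rel=1e-12)

    def test_full_interaction_cells_use_subject_count(self):
        df = _random_design(np.random.default_rng(1))
        anova = rm_anova(df)
        out = fisher_lsd(df, anova=anova)
        assert out.attrs["n_obs_per_cell"] == 6
        se = np.sqrt(
            2 * anova.loc["condition:movement:tdcs:hemisphere", "ms_error"] / 6
        )
        assert out.loc[0, "se"] == pytest.approx(se)

    def test_pair_outside_effect_rejected(self):
        df = _random_design(np.random.default_rng(1))
        with pytest.raises(ParameterError, match="not in the design"):
            fisher_lsd(df, effect=["electrode"])


class TestNullCalibrationOnTables:
    def test_p_values_uniform_under_null(self):
        """ERD-table-level calibration: iid normal cells, 500 simulated
        two-factor designs; pooled type-I error near alpha and per-effect
        Kolmogorov-Smirnov consistent with Uniform(0, 1)."""
        rng = np.random.default_rng(0)
        pvals = {e: [] for e in ("A", "B", "A:B")}
        for _ in range(500):
            df = pd.DataFrame(
                [dict(subject=s, A=a, B=b, erd=rng.normal())
                 for s in range(8) for a in ("a1", "a2") for b in ("b1", "b2", "b3")]
            )
            table = rm_anova(df, within=["A", "B"])
            for e in pvals:
                pvals[e].append(table.loc[e, "p"])
        pooled = np.concatenate([np.array(v) for v in pvals.values()])
        assert (pooled < 0.05).mean() == pytest.approx(0.05, abs=0.02)
        for e, v in pvals.items():
            assert sps.kstest(v, "uniform").pvalue > 0.01


class TestErdTableToDesign:
    def test_main_model_restriction(self, layout21):
        table = pd.DataFrame(
            dict(subject=[0, 0], session=["sham", "sham"],
                 task=["imagery", "imagery"],
                 movement=["biological", "biological"],
                 unit=["C3", "surroundC4"], erd=[0.1, 0.2])
        )
        main = erd_table_to_design(table, "main")
        assert list(main.columns) == ["subject", "condition", "movement", "tdcs", "hemisphere", "erd"]
        assert set(main.hemisphere) == {"C3"}
        surround = erd_table_to_design(table, "surround")
        assert set(surround.electrodes) == {"surroundC4"}
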