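import numpy as np
import pandas as pd
import pytest

from connfroi.evaluation import (
    anova_selectivity,
    bonferroni_threshold,
    compare_methods,
    one_sample_ttest,
    paired_ttest,
    selectivity_table,
)
from connfroi.synth import default_registry


class TestPairedTTest:
    def test_closed_form_oracle(self):
        # diffs [1,2,3]: mean 2, sd 1 -> t = 2 / (1/sqrt(3)) = 3.4641
        res = paired_ttest([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(np.sqrt(12.0), abs=1e-4)
        assert res.t == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2
        assert res.mean_diff == pytest.approx(2.0)

    def test_p_matches_scipy(self):
        from scipy import stats as sps

        x = np.array([1.3, 2.1, 0.4, 0.9, 1.8])
        y = np.array([0.6, 1.1, 0.8, 0.2, 1.1])
        res = paired_ttest(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_sign_flip_negates_t_keeps_p(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        y = np.array([0.5, 1.0, 2.5, 3.0])
        a = paired_ttest(x, y)
        b = paired_ttest(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [1.0])

    def test_one_sample_against_zero(self):
        res = one_sample_ttest([0.5, 1.5, 1.0, 2.0])
        assert res.n == 4
        assert res.df == 3
        assert res.mean_diff == pytest.approx(1.25)


class TestBonferroni:
    def test_18_regions(self):
        thr = bonferroni_threshold(0.05, 18)
        assert thr == pytest.approx(0.05 / 18)
        assert round(thr, 5) == 0.00278

    def test_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_two_tests(self):
        assert bonferroni_threshold(0.05, 2) == 0.025

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 3)


def _records(n_subjects, values=None, seed=0):
    """Complete subject x 18-region selectivity table."""
    registry = default_registry()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for e in registry:
            rows.append(
                {
                    "subject": f"s{i:02d}",
                    "froi": e.froi_id,
                    "method": "connectivity",
                    "category": e.category,
                    "hemisphere": e.hemisphere,
                    "selectivity": rng.normal() if values is None else values(i, e),
                }
            )
    return pd.DataFrame(rows)


def _anova_oracle(records):
    """Independent Type III oracle via explicit projection matrices."""
    y = records["selectivity"].to_numpy(dtype=float)
    n = len(y)

    def dummies(col):
        labels = records[col].to_numpy()
        levels = sorted(set(labels))
        M = np.zeros((n, len(levels) - 1))
        for j, lev in enumerate(levels[:-1]):
            M[labels == lev, j] = 1.0
        M[labels == levels[-1], :] = -1.0
        return M

    D, H, S = dummies("category"), dummies("hemisphere"), dummies("subject")

    def inter(A, B):
        return np.einsum("ni,nj->nij", A, B).reshape(n, -1)

    terms = {
        "Domain": D, "Hemisphere": H, "Subject": S,
        "Domain*Hemisphere": inter(D, H), "Domain*Subject": inter(D, S),
        "Hemisphere*Subject": inter(H, S),
    }

    def proj(mats):
        X = np.column_stack([np.ones(n)] + mats)
        return X @ np.linalg.pinv(X)

    P_full = proj(list(terms.values()))
    out = {"Error": y @ (np.eye(n) - P_full) @ y}
    for name in terms:
        P_red = proj([m for t, m in terms.items() if t != name])
        out[name] = y @ (P_full - P_red) @ y
    return out


class TestAnova:
    def test_40_subject_dfs_match_published_structure(self):
        res = anova_selectivity(_records(40))
        tab = res.table
        assert tab.loc["Total", "df"] == 719
        assert tab.loc["Error", "df"] == 517
        assert tab.loc["Domain", "df"] == 3
        assert tab.loc["Hemisphere", "df"] == 1
        assert tab.loc["Subject", "df"] == 39
        assert tab.loc["Domain*Subject", "df"] == 117

    def test_df_identity_sums_to_n_minus_1(self):
        for n_subj in (2, 5, 11):
            tab = anova_selectivity(_records(n_subj)).table
            terms = tab.drop(index="Total")
            assert terms["df"].sum() == tab.loc["Total", "df"]

    def test_ss_nonnegative_and_total_decomposes(self):
        tab = anova_selectivity(_records(6, seed=3)).table
        assert (tab["ss"] >= -1e-9).all()
        parts = tab.drop(index="Total")["ss"].sum()
        # Type III parts need not sum exactly to total on unbalanced
        # designs, but must stay in the same ballpark
        assert parts == pytest.approx(tab.loc["Total", "ss"], rel=0.35)

    def test_pure_hemisphere_effect(self):
        records = _records(4, values=lambda i, e: 1.0 if e.hemisphere == "rh" else 0.0)
        tab = anova_selectivity(records).table
        assert tab.loc["Domain", "ss"] == pytest.approx(0.0, abs=1e-9)
        assert tab.loc["Hemisphere", "ss"] > 0.1
        assert tab.loc["Error", "ss"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_projection_oracle_small(self):
        records = _records(2, seed=9)
        tab = anova_selectivity(records).table
        oracle = _anova_oracle(records)
        for name, ss in oracle.items():
            assert tab.loc[name, "ss"] == pytest.approx(ss, abs=1e-8)

    def test_matches_projection_oracle_2x4_toy(self):
        # 2 subjects x 4 regions (2 categories x 2 hemispheres)
        rng = np.random.default_rng(4)
        rows = []
        for s in ("s0", "s1"):
            for cat in ("face", "scene"):
                for hemi in ("lh", "rh"):
                    rows.append(
                        {
                            "subject": s, "category": cat, "hemisphere": hemi,
                            "froi": f"{hemi[0]}{cat}", "method": "m",
                            "selectivity": rng.normal(),
                        }
                    )
        records = pd.DataFrame(rows)
        tab = anova_selectivity(records).table
        oracle = _anova_oracle(records)
        for name, ss in oracle.items():
            assert tab.loc[name, "ss"] == pytest.approx(ss, abs=1e-8)

    def test_type3_equals_sequential_on_balanced_toy(self):
        # balanced: 2 categories x 2 hemispheres x 2 replicates per cell
        rng = np.random.default_rng(8)
        rows = []
        for s in ("s0", "s1", "s2"):
            for cat in ("face", "scene"):
                for hemi in ("lh", "rh"):
                    for rep in range(2):
                        rows.append(
                            {
                                "subject": s, "category": cat, "hemisphere": hemi,
                                "froi": f"{hemi}{cat}{rep}", "method": "m",
                                "selectivity": rng.normal(),
                            }
                        )
        records = pd.DataFrame(rows)
        tab = anova_selectivity(records).table

        # sequential oracle: add terms in order, difference the SSEs
        y = records["selectivity"].to_numpy()
        n = len(y)

        def dummies(col):
            labels = records[col].to_numpy()
            levels = sorted(set(labels))
            M = np.zeros((n, len(levels) - 1))
            for j, lev in enumerate(levels[:-1]):
                M[labels == lev, j] = 1.0
            M[labels == levels[-1], :] = -1.0
            return M

        D, H, S = dummies("category"), dummies("hemisphere"), dummies("subject")

        def inter(A, B):
            return np.einsum("ni,nj->nij", A, B).reshape(n, -1)

        order = [("Domain", D), ("Hemisphere", H), ("Subject", S),
                 ("Domain*Hemisphere", inter(D, H)),
                 ("Domain*Subject", inter(D, S)),
                 ("Hemisphere*Subject", inter(H, S))]

        def sse(mats):
            X = np.column_stack([np.ones(n)] + mats)
            r = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            return r @ r

        prev = sse([])
        for name, M in order:
            cur = sse([m for _, m in order[: [o[0] for o in order].index(name) + 1]])
            assert tab.loc[name, "ss"] == pytest.approx(prev - cur, abs=1e-8)
            prev = cur

    def test_incomplete_design_lists_missing_cells(self):
        records = _records(3).iloc[:-2]
        with pytest.raises(ValueError, match="missing cells"):
            anova_selectivity(records)

    def test_mixed_denominators_flag(self):
        records = _records(10, seed=5)
        err = anova_selectivity(records, denominators="error").table
        mix = anova_selectivity(records, denominators="mixed").table
        assert err.loc["Domain", "F"] != mix.loc["Domain", "F"]
        assert mix.loc["Domain", "F"] == pytest.approx(
            mix.loc["Domain", "ms"] / mix.loc["Domain*Subject", "ms"]
        )
        assert err.loc["Domain", "F"] == pytest.approx(
            err.loc["Domain", "ms"] / err.loc["Error", "ms"]
        )

    def test_invalid_denominators_rejected(self):
        with pytest.raises(ValueError):
            anova_selectivity(_records(2), denominators="bogus")


class TestSelectivityTable:
    def test_record_count_and_selectivity(self, tiny_cohort):
        from connfroi.glm import HRFParams, build_glm_design, fit_glm, flag_motion_frames

        registry = tiny_cohort.registry
        betamaps = {}
        for subj in tiny_cohort.subjects:
            run = subj.task_runs[1]
            design = build_glm_design(run.design, HRFParams(), run.motion,
                                      flag_motion_frames(run))
            betamaps[subj.subject_id] = fit_glm(run, design)
        sets = {
            (subj.subject_id, e.froi_id): subj.ground_truth.froi_vertices[e.froi_id]
            for subj in tiny_cohort.subjects
            for e in registry
        }
        table = selectivity_table(registry, {"ground-truth": sets}, betamaps)
        assert len(table) == tiny_cohort.n_subjects * 18
        e = registry["rFFA"]
        row = table[(table.subject == "sub-000") & (table.froi == "rFFA")].iloc[0]
        assert row["selectivity"] == pytest.approx(
            row[f"psc_{e.preferred_condition}"] - row[f"psc_{e.contrast_condition}"]
        )

    def test_missing_froi_skipped_with_warning(self, tiny_cohort, caplog):
        import logging

        from connfroi.glm import HRFParams, build_glm_design, fit_glm

        subj = tiny_cohort.subjects[0]
        run = subj.task_runs[1]
        design = build_glm_design(run.design, HRFParams(), run.motion, ())
        betamaps = {subj.subject_id: fit_glm(run, design)}
        sets = {(subj.subject_id, "lFFA"): subj.ground_truth.froi_vertices["lFFA"]}
        with caplog.at_level(logging.WARNING, logger="connfroi.evaluation"):
            table = selectivity_table(tiny_cohort.registry, {"m": sets}, betamaps)
        assert len(table) == 1
        assert any("missing" in r.message for r in caplog.records)


class TestCompareMethods:
    def _table(self, n=6, seed=0, methods=("connectivity", "atlas")):
        registry = default_registry()
        rng = np.random.default_rng(seed)
        rows = []
        for m in methods:
            boost = 1.0 if m == "connectivity" else 0.0
            for i in range(n):
                for e in registry:
                    rows.append(
                        {
                            "subject": f"s{i}", "froi": e.froi_id, "method": m,
                            "category": e.category, "hemisphere": e.hemisphere,
                            "selectivity": boost + 0.3 * rng.normal(),
                        }
                    )
        return pd.DataFrame(rows)

    def test_counts_bookkeeping(self):
        comp = compare_methods(self._table())
        assert set(comp.summary["method"]) == {"connectivity", "atlas"}
        assert (comp.summary["n_frois"] == 18).all()
        assert len(comp.pairwise) == 18

    def test_connectivity_beats_null_method(self):
        comp = compare_methods(self._table(n=12, seed=2))
        sel = comp.selectivity_tests
        conn = sel[sel.method == "connectivity"]
        atlas = sel[sel.method == "atlas"]
        assert conn["selective"].sum() > atlas["selective"].sum()
        assert (comp.pairwise["mean_diff"] > 0).mean() > 0.9

    def test_identical_methods_reported_as_no_difference(self):
        table = self._table(methods=("connectivity",))
        dup = table.copy()
        dup["method"] = "copy"
        comp = compare_methods(pd.concat([table, dup], ignore_index=True))
        assert comp.pairwise["t"].isna().all()
        assert (comp.pairwise["note"] == "no difference").all()
        assert not comp.pairwise["significant"].any()

    def test_missing_reference_rejected(self):
        table = self._table(methods=("atlas",))
        with pytest.raises(ValueError):
            compare_methods(table, reference="connectivity")
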