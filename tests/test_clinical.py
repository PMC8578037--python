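"""Volumetric and demographic statistics."""

import numpy as np
import pandas as pd
import pytest

from subscn import ROIVolumeTable, demographic_tests, mancova, per_roi_ancova
from subscn.clinical import StatsError, roi_psychometric_correlations


def _three_group_table(n_per=40, p=6, shifts=None, seed=0):
    """Gaussian volumes with optional per-(roi, group) mean shifts."""
    rng = np.random.default_rng(seed)
    rows, vols = [], []
    for g in ("cMDD", "RD", "HC"):
        for i in range(n_per):
            rows.append({"id": f"{g}{i}", "group": g,
                         "age": rng.uniform(18, 40),
                         "icv": rng.normal(1.45e6, 1.3e5)})
    part = pd.DataFrame(rows).set_index("id")
    base = 1000.0
    v = rng.normal(base, 50.0, (len(part), p))
    v += 0.0005 * (part["icv"].to_numpy()[:, None] - 1.45e6)
    if shifts:
        for (j, g), delta in shifts.items():
            v[(part["group"] == g).to_numpy(), j] += delta
    vols = pd.DataFrame(v, index=part.index, columns=[f"roi{j}" for j in range(p)])
    return ROIVolumeTable(part, vols)


class TestMancova:
    def test_duplicated_groups_show_no_effect(self):
        # two groups that are literal copies of each other: the group term
        # explains nothing, so lambda = 1 and p = 1
        rng = np.random.default_rng(1)
        n, p = 40, 4
        v = rng.normal(1000, 50, (n, p))
        age = rng.uniform(18, 40, n)
        icv = rng.normal(1.45e6, 1.3e5, n)
        part = pd.DataFrame({
            "group": ["cMDD"] * n + ["HC"] * n,
            "age": np.tile(age, 2), "icv": np.tile(icv, 2),
        }, index=[f"P{i}" for i in range(2 * n)])
        vols = pd.DataFrame(np.vstack([v, v]), index=part.index,
                            columns=[f"roi{j}" for j in range(p)])
        res = mancova(ROIVolumeTable(part, vols))
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-9)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_planted_shift_detected_with_power(self):
        hits = 0
        for s in range(20):
            shifts = {(j, "cMDD"): 75.0 for j in range(5)}  # 1.5 sd in 5 ROIs
            table = _three_group_table(n_per=100, shifts=shifts, seed=s)
            if mancova(table).p < 0.01:
                hits += 1
        assert hits >= 18

    def test_matches_eigendecomposition_oracle(self):
        # 2 DVs, 3 groups: lambda from an explicit E^-1 H eigendecomposition
        table = _three_group_table(n_per=30, p=2, shifts={(0, "HC"): 40.0}, seed=3)
        res = mancova(table)
        y = table.volumes.to_numpy()
        part = table.participants
        groups = sorted(part["group"].unique())
        dummies = pd.get_dummies(part["group"], drop_first=True).to_numpy(float)
        covs = np.column_stack([
            part["age"].to_numpy() - part["age"].mean(),
            part["icv"].to_numpy() - part["icv"].mean(),
        ])
        x_full = np.column_stack([np.ones(len(y)), dummies, covs])
        x_red = np.column_stack([np.ones(len(y)), covs])

        def resid_sscp(x):
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            r = y - x @ beta
            return r.T @ r

        e = resid_sscp(x_full)
        h = resid_sscp(x_red) - e
        eig = np.linalg.eigvals(np.linalg.solve(e, h))
        lam_oracle = float(np.prod(1.0 / (1.0 + np.real(eig))))
        assert res.wilks_lambda == pytest.approx(lam_oracle, abs=1e-10)

    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        table = _three_group_table(n_per=30, p=3, shifts={(1, "RD"): 60.0}, seed=4)
        res = mancova(table)
        df = table.participants.join(table.volumes)
        mv = MANOVA.from_formula("roi0 + roi1 + roi2 ~ C(group) + age + icv", data=df)
        sm_tbl = mv.mv_test().results["C(group)"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(sm_tbl.loc["Wilks' lambda", "Value"]), abs=1e-6
        )

    def test_underdetermined_design_refused(self):
        table = _three_group_table(n_per=3, p=20, seed=5)
        with pytest.raises(StatsError, match="participants"):
            mancova(table)


class TestPerRoiAncova:
    def test_trait_marker_posthoc_pattern(self):
        # equal deficit in both patient groups: patient-vs-control contrasts
        # significant, patient-vs-patient not (majority over datasets; the
        # null contrast false-positives at its nominal rate)
        good = 0
        for s in range(8):
            shifts = {(0, "cMDD"): -80.0, (0, "RD"): -80.0}
            table = _three_group_table(n_per=80, shifts=shifts, seed=60 + s)
            row = per_roi_ancova(table)[0]
            good += (
                row.p_fdr < 0.05
                and row.posthoc_p["cMDD-HC"] < 0.05
                and row.posthoc_p["RD-HC"] < 0.05
                and row.posthoc_p["cMDD-RD"] > 0.05
            )
        assert good >= 6

    def test_state_marker_posthoc_pattern(self):
        good = 0
        for s in range(8):
            shifts = {(2, "RD"): -90.0}
            table = _three_group_table(n_per=80, shifts=shifts, seed=70 + s)
            row = next(r for r in per_roi_ancova(table) if r.roi == "roi2")
            good += (
                row.p_fdr < 0.05
                and row.posthoc_p["RD-HC"] < 0.05
                and row.posthoc_p["cMDD-HC"] > 0.05
            )
        assert good >= 6

    def test_null_data_rarely_discovers(self):
        discoveries = 0
        for s in range(10):
            table = _three_group_table(n_per=40, seed=100 + s)
            discoveries += sum(r.p_fdr < 0.05 for r in per_roi_ancova(table))
        assert discoveries <= 2

    def test_fdr_not_below_raw(self):
        table = _three_group_table(seed=8)
        for r in per_roi_ancova(table):
            assert r.p_fdr >= r.p_raw - 1e-12


class TestDemographics:
    @staticmethod
    def _participants(seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, n in (("cMDD", 40), ("RD", 30), ("HC", 50)):
            for i in range(n):
                rows.append({
                    "id": f"{g}{i}", "group": g,
                    "gender": "male" if rng.random() < 0.5 else "female",
                    "age": rng.uniform(18, 40), "education": rng.uniform(10, 20),
                    "rrs": rng.normal(50, 10),
                    "hamd17": max(0.0, rng.normal(10, 5)),
                    "illness_duration": rng.uniform(1, 30) if g != "HC" else np.nan,
                })
        return pd.DataFrame(rows).set_index("id")

    def test_printed_gender_table_value(self):
        """The worked example: males/females 59/72, 29/38, 113/122 give
        chi-square 0.63 with 2 degrees of freedom."""
        rows = []
        for g, (m, f) in {"cMDD": (59, 72), "RD": (29, 38), "HC": (113, 122)}.items():
            rows += [{"id": f"{g}m{i}", "group": g, "gender": "male"} for i in range(m)]
            rows += [{"id": f"{g}f{i}", "group": g, "gender": "female"} for i in range(f)]
        df = pd.DataFrame(rows).set_index("id")
        out = demographic_tests(df)
        gender = out[out["variable"] == "gender"].iloc[0]
        assert round(gender["statistic"], 2) == 0.63
        assert gender["df"] == 2

    def test_chi_square_invariant_to_label_permutation(self):
        df = self._participants()
        out1 = demographic_tests(df)
        swapped = df.copy()
        swapped["gender"] = swapped["gender"].map({"male": "female", "female": "male"})
        out2 = demographic_tests(swapped)
        v1 = out1[out1["variable"] == "gender"]["statistic"].iloc[0]
        v2 = out2[out2["variable"] == "gender"]["statistic"].iloc[0]
        assert v1 == pytest.approx(v2)

    def test_identical_groups_u_is_half_product(self):
        df = self._participants(seed=1)
        dur = df.loc[df["group"] == "cMDD", "illness_duration"].to_numpy()
        df.loc[df["group"] == "RD", "illness_duration"] = np.resize(dur, 30)
        # U for identical-ish samples sits near n1*n2/2; exact when tied data
        df2 = df.copy()
        df2.loc[df2["group"].isin(["cMDD", "RD"]), "illness_duration"] = 5.0
        out = demographic_tests(df2)
        u = out[out["variable"] == "illness_duration"]["statistic"].iloc[0]
        assert u == pytest.approx(40 * 30 / 2)

    def test_constant_scores_give_zero_h(self):
        df = self._participants(seed=2)
        df["hamd17"] = 4.0
        out = demographic_tests(df)
        h = out[out["variable"] == "hamd17"]["statistic"].iloc[0]
        assert h == pytest.approx(0.0)

    def test_anova_matches_summary_statistic_form(self):
        # F from raw data equals F recomputed from per-group (mean, sd, n)
        df = self._participants(seed=3)
        out = demographic_tests(df)
        f_raw = out[out["variable"] == "age"]["statistic"].iloc[0]
        stats_by_g = df.groupby("group")["age"].agg(["mean", "std", "count"])
        grand = (stats_by_g["mean"] * stats_by_g["count"]).sum() / stats_by_g["count"].sum()
        ss_between = (stats_by_g["count"] * (stats_by_g["mean"] - grand) ** 2).sum()
        ss_within = ((stats_by_g["count"] - 1) * stats_by_g["std"] ** 2).sum()
        k = len(stats_by_g)
        n = stats_by_g["count"].sum()
        f_summary = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert f_raw == pytest.approx(f_summary)


class TestCorrelations:
    @staticmethod
    def _vol_part(y_fn, n=67, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        part = pd.DataFrame({
            "group": ["RD"] * n, "rrs": y_fn(x), "hamd17": y_fn(x),
        }, index=[f"P{i}" for i in range(n)])
        vols = pd.DataFrame({"roiA": x}, index=part.index)
        return vols, part

    def test_exact_linear_gives_pearson_one(self):
        vols, part = self._vol_part(lambda x: 2 * x + 1)
        out = roi_psychometric_correlations(vols, part, ["roiA"])
        r = out[(out["clinical"] == "rrs")]["r"].iloc[0]
        assert r == pytest.approx(1.0)

    def test_monotone_nonlinearity_spearman_vs_pearson(self):
        vols, part = self._vol_part(np.exp)
        out = roi_psychometric_correlations(vols, part, ["roiA"])
        rho = out[out["clinical"] == "hamd17"]["r"].iloc[0]   # spearman
        r = out[out["clinical"] == "rrs"]["r"].iloc[0]        # pearson
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_sampling_distribution_at_small_n(self):
        inside = 0
        for s in range(40):
            rng = np.random.default_rng(s)
            x = rng.normal(0, 1, 67)
            y = 0.3 * x + np.sqrt(1 - 0.09) * rng.normal(0, 1, 67)
            part = pd.DataFrame({"group": ["RD"] * 67, "rrs": y},
                                index=[f"P{i}" for i in range(67)])
            vols = pd.DataFrame({"roiA": x}, index=part.index)
            out = roi_psychometric_correlations(vols, part, ["roiA"])
            if abs(out["r"].iloc[0] - 0.3) < 0.25:
                inside += 1
        assert inside >= 34  # ~95% coverage at this sample size

    def test_constant_vector_named(self):
        vols, part = self._vol_part(lambda x: np.ones_like(x))
        with pytest.raises(StatsError, match="rrs"):
            roi_psychometric_correlations(vols, part, ["roiA"])

    def test_missing_values_pairwise_deleted(self):
        vols, part = self._vol_part(lambda x: 2 * x, n=30)
        part.loc[part.index[:5], "rrs"] = np.nan
        out = roi_psychometric_correlations(vols, part, ["roiA"])
        assert out[out["clinical"] == "rrs"]["n"].iloc[0] == 25
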