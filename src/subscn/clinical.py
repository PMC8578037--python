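"""Volumetric and demographic group statistics.

The volumetric arm: an omnibus MANCOVA (Wilks' lambda with Rao's F
approximation) over all ROI volumes with age and intracranial volume as
covariates; per-ROI ANCOVAs with Benjamini-Hochberg FDR across ROIs;
covariate-adjusted pairwise post-hoc t-tests for FDR-surviving ROIs.  The
demographic arm: chi-square for gender, one-way ANOVA for continuous
scores, Kruskal-Wallis for skewed scores, Mann-Whitney U for two-group
comparisons.  The correlation arm: Pearson or Spearman ROI-psychometric
correlations with pairwise deletion of missing clinical values.

The trait/state-marker logic of the post-hoc table: an ROI whose
currently-depressed-vs-control and remitted-vs-control contrasts are both
significant (patients-vs-patients not) shows a trait pattern; an ROI with
exactly one patient-vs-control contrast significant shows a
state-dependent pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ROIVolumeTable

__all__ = [
    "MancovaResult",
    "RoiComparisonRow",
    "StatsError",
    "mancova",
    "per_roi_ancova",
    "demographic_tests",
    "roi_psychometric_correlations",
]


class StatsError(ValueError):
    """Raised for under-determined or degenerate statistical designs."""


@dataclass(frozen=True)
class MancovaResult:
    """Multivariate group effect adjusting for covariates.

    ``partial_eta_squared`` uses the multivariate convention
    1 - lambda^(1/s) (recorded in ``eta_convention``).
    """

    wilks_lambda: float
    f_statistic: float
    p: float
    partial_eta_squared: float
    df_effect: float
    df_error: float
    eta_convention: str = "1 - lambda**(1/s)"

    def __post_init__(self) -> None:
        if not 0 < self.wilks_lambda <= 1 + 1e-12:
            raise StatsError("Wilks' lambda must lie in (0, 1]")


@dataclass
class RoiComparisonRow:
    """One ROI's group comparison: ANCOVA F, FDR p, effect size, post-hocs."""

    roi: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    f: float
    p_raw: float
    p_fdr: float
    partial_eta_squared: float
    posthoc_p: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_fdr < self.p_raw - 1e-12:
            raise StatsError("FDR-adjusted p cannot be below the raw p")


def _design(table: ROIVolumeTable, covariates=("age", "icv")):
    part = table.participants
    groups = sorted(part["group"].unique())
    n = len(part)
    g_dummies = pd.get_dummies(part["group"], drop_first=True).to_numpy(float)
    covs = np.column_stack(
        [part[c].to_numpy(float) - part[c].to_numpy(float).mean() for c in covariates]
    )
    x_full = np.column_stack([np.ones(n), g_dummies, covs])
    x_reduced = np.column_stack([np.ones(n), covs])
    return groups, x_full, x_reduced


def _sscp_residual(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return r.T @ r


def mancova(table: ROIVolumeTable, covariates=("age", "icv")) -> MancovaResult:
    """Wilks'-lambda MANCOVA for the group effect on all ROI volumes.

    lambda = det(E) / det(E + H) where E is the residual SSCP of the full
    model (group + covariates) and H the extra SSCP explained by group;
    the F approximation is Rao's.  Requires more participants than
    dependent variables + covariates + group levels.
    """
    y = table.volumes.to_numpy(float)
    n, p = y.shape
    groups, x_full, x_reduced = _design(table, covariates)
    q = len(groups) - 1                       # hypothesis df
    n_params = x_full.shape[1]
    if n <= p + n_params:
        raise StatsError(
            f"MANCOVA over {p} dependent variables needs more than "
            f"{p + n_params} participants (got {n}); reduce the DV set or "
            "use the per-ROI ANCOVA arm"
        )
    e = _sscp_residual(y, x_full)
    e_plus_h = _sscp_residual(y, x_reduced)
    sign_e, logdet_e = np.linalg.slogdet(e)
    sign_eh, logdet_eh = np.linalg.slogdet(e_plus_h)
    if sign_e <= 0 or sign_eh <= 0:
        raise StatsError("singular within-group covariance; reduce the DV set")
    lam = float(np.exp(logdet_e - logdet_eh))

    # Rao's F approximation
    v_e = n - n_params                         # error df of the full model
    t = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if p**2 + q**2 - 5 > 0 else 1.0
    w = v_e + q - (p + q + 1) / 2
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2
    lam_t = lam ** (1 / t)
    f = (1 - lam_t) / lam_t * df2 / df1
    p_val = float(stats.f.sf(f, df1, df2))
    eta = float(1 - lam_t)
    return MancovaResult(
        wilks_lambda=lam, f_statistic=float(f), p=p_val,
        partial_eta_squared=eta, df_effect=float(df1), df_error=float(df2),
    )


def _ancova_one(y: np.ndarray, x_full: np.ndarray, x_reduced: np.ndarray,
                q: int) -> tuple[float, float, float]:
    """F test for the group term of one ROI's ANCOVA; partial eta^2."""
    n = len(y)
    beta_f, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    ss_full = float(((y - x_full @ beta_f) ** 2).sum())
    beta_r, *_ = np.linalg.lstsq(x_reduced, y, rcond=None)
    ss_red = float(((y - x_reduced @ beta_r) ** 2).sum())
    df_err = n - x_full.shape[1]
    f = (ss_red - ss_full) / q / (ss_full / df_err)
    p = float(stats.f.sf(f, q, df_err))
    eta = (ss_red - ss_full) / ss_red if ss_red > 0 else 0.0
    return float(f), p, float(eta)


def _adjusted_contrast_p(
    table: ROIVolumeTable, roi: str, pair: tuple[str, str], covariates
) -> float:
    """Covariate-adjusted two-group t-test: t of the group dummy in an
    OLS of the ROI volume on [1, group, age, icv] over the pair."""
    sub = table.select_groups(pair)
    part = sub.participants
    y = sub.volumes[roi].to_numpy(float)
    g = (part["group"] == pair[0]).to_numpy(float)
    covs = np.column_stack(
        [part[c].to_numpy(float) - part[c].to_numpy(float).mean() for c in covariates]
    )
    x = np.column_stack([np.ones(len(y)), g, covs])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = len(y) - x.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = beta[1] / se
    return float(2 * stats.t.sf(abs(t), df))


def per_roi_ancova(
    table: ROIVolumeTable,
    covariates=("age", "icv"),
    q: float = 0.05,
    *,
    posthoc_pairs: tuple[tuple[str, str], ...] | None = None,
) -> list[RoiComparisonRow]:
    """Per-ROI group ANCOVA with BH-FDR across ROIs and gated post-hocs.

    Pairwise covariate-adjusted contrasts are computed only for ROIs that
    survive the ROI-level FDR (the FDR gate lives at the ROI level, not
    the contrast level).
    """
    from .inference import fdr_bh

    part = table.participants
    groups = sorted(part["group"].unique())
    if len(part) <= len(groups) + len(covariates) + 1:
        raise StatsError("too few participants for per-ROI ANCOVA")
    _, x_full, x_reduced = _design(table, covariates)
    n_groups = len(groups)

    rows: list[dict] = []
    pvals = []
    for roi in table.roi_names:
        y = table.volumes[roi].to_numpy(float)
        f, p, eta = _ancova_one(y, x_full, x_reduced, n_groups - 1)
        means = {g: float(table.volumes[roi][part["group"] == g].mean()) for g in groups}
        sds = {g: float(table.volumes[roi][part["group"] == g].std(ddof=1)) for g in groups}
        rows.append(dict(roi=roi, f=f, p_raw=p, eta=eta, means=means, sds=sds))
        pvals.append(p)
    p_fdr, reject = fdr_bh(np.array(pvals), q=q)

    if posthoc_pairs is None:
        from .io import GROUPS

        ordered = sorted(
            groups, key=lambda g: GROUPS.index(g) if g in GROUPS else len(GROUPS)
        )
        # canonical contrast order: patient-vs-control first
        posthoc_pairs = tuple(
            (a, b) for i, a in enumerate(ordered) for b in ordered[i + 1:]
        )
        if set(ordered) == {"cMDD", "RD", "HC"}:
            posthoc_pairs = (("cMDD", "HC"), ("RD", "HC"), ("cMDD", "RD"))
    out = []
    for row, pf, rej in zip(rows, p_fdr, reject):
        posthoc = {}
        if rej:
            for pair in posthoc_pairs:
                posthoc[f"{pair[0]}-{pair[1]}"] = _adjusted_contrast_p(
                    table, row["roi"], pair, covariates
                )
        out.append(
            RoiComparisonRow(
                roi=row["roi"], group_means=row["means"], group_sds=row["sds"],
                f=row["f"], p_raw=row["p_raw"], p_fdr=float(pf),
                partial_eta_squared=row["eta"], posthoc_p=posthoc,
            )
        )
    return out


def demographic_tests(participants: pd.DataFrame) -> pd.DataFrame:
    """Demographic/clinical group tests shaped like a cohort table.

    Gender: Pearson chi-square (no continuity correction) on the
    gender x group table.  Age, education, rumination score: one-way
    ANOVA.  Depression score: Kruskal-Wallis.  Illness duration:
    Mann-Whitney U between the two patient groups.
    """
    df = participants
    groups = sorted(df["group"].unique())
    if len(groups) < 2 or any((df["group"] == g).sum() < 2 for g in groups):
        raise StatsError("need at least 2 groups with at least 2 members")
    rows = []

    contingency = pd.crosstab(df["gender"], df["group"])
    if (contingency.values == 0).any():
        raise StatsError("empty cell in the gender x group table")
    chi2, p, dof, _ = stats.chi2_contingency(contingency.to_numpy(), correction=False)
    rows.append(("gender", "chi-square", float(chi2), float(p), int(dof)))

    for col in ("age", "education", "rrs"):
        if col not in df.columns or df[col].dropna().empty:
            continue
        samples = [df[col][df["group"] == g].dropna().to_numpy(float) for g in groups]
        samples = [s for s in samples if len(s) >= 2]
        if len(samples) < 2:
            continue
        f, p = stats.f_oneway(*samples)
        rows.append((col, "anova", float(f), float(p), len(samples) - 1))

    if "hamd17" in df.columns and not df["hamd17"].dropna().empty:
        samples = [df["hamd17"][df["group"] == g].dropna().to_numpy(float) for g in groups]
        samples = [s for s in samples if len(s) >= 2]
        if len(samples) >= 2:
            if all((s == samples[0][0]).all() for s in samples):
                rows.append(("hamd17", "kruskal-wallis", 0.0, 1.0, len(samples) - 1))
            else:
                h, p = stats.kruskal(*samples)
                rows.append(("hamd17", "kruskal-wallis", float(h), float(p), len(samples) - 1))

    if "illness_duration" in df.columns:
        pat = [g for g in ("cMDD", "RD") if g in groups]
        if len(pat) == 2:
            a = df["illness_duration"][df["group"] == pat[0]].dropna().to_numpy(float)
            b = df["illness_duration"][df["group"] == pat[1]].dropna().to_numpy(float)
            if len(a) >= 2 and len(b) >= 2:
                u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                rows.append(("illness_duration", "mann-whitney-u", float(u), float(p), np.nan))

    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p", "df"])


#: which correlation method pairs with which clinical field
DEFAULT_CORRELATION_METHODS = {
    "rrs": "pearson",
    "illness_remission": "pearson",
    "hamd17": "spearman",
    "illness_duration": "spearman",
}


def roi_psychometric_correlations(
    volumes: pd.DataFrame,
    participants: pd.DataFrame,
    rois: list[str],
    *,
    clinical_fields: list[str] | None = None,
    methods: dict[str, str] | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """ROI-volume vs clinical-score correlations, pairwise-deleting missing.

    Pearson for rumination and illness-remission scores, Spearman for
    depression scores and illness duration (overridable via ``methods``).
    """
    methods = {**DEFAULT_CORRELATION_METHODS, **(methods or {})}
    if clinical_fields is None:
        clinical_fields = [f for f in methods if f in participants.columns]
    part = participants
    vols = volumes
    if group is not None:
        mask = part["group"] == group
        part, vols = part[mask], vols[mask]
    rows = []
    for roi in rois:
        for fld in clinical_fields:
            x = vols[roi].to_numpy(float)
            yv = part[fld].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(yv)
            if ok.sum() < 4:
                continue
            xs, ys = x[ok], yv[ok]
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                raise StatsError(f"constant vector for {roi} vs {fld}")
            method = methods.get(fld, "pearson")
            if method == "pearson":
                r, p = stats.pearsonr(xs, ys)
            else:
                r, p = stats.spearmanr(xs, ys)
            rows.append((roi, fld, method, float(r), float(p), int(ok.sum())))
    return pd.DataFrame(rows, columns=["roi", "clinical", "method", "r", "p", "n"])
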