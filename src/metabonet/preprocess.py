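"""Reference normalization, confound regression, and regional group tests.

Regional uptake is first expressed relative to a preserved reference
structure (brainstem) to avoid the patient/control scaling bias of
global-mean normalization.  A per-region ordinary least squares regression
then removes age, sex, age x sex, total uptake, and regional volume; the
residuals replace the raw values and feed the correlation analysis.
Education is screened first and kept only if it shows a marginal effect in
at least one region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import CohortTable

#: Default confound set, in design order after the intercept.
DEFAULT_CONFOUNDS = ("age", "sex", "age_sex", "total_cmrgl", "volume")

DEFAULT_CONTRASTS = (("NC", "AD"), ("NC", "MCI"), ("MCI", "AD"))


@dataclass
class ResidualMatrix:
    """Residual uptake after confound regression, subjects x regions."""

    values: np.ndarray
    design_description: list[str]
    r_squared: np.ndarray  # per region


@dataclass
class CovariateScreen:
    covariate: str
    p_values: np.ndarray  # per region, raw marginal slope p
    keep: bool
    alpha: float
    bonferroni: bool = True


@dataclass
class RegionalDifferenceReport:
    """Per-region group contrasts on confound-adjusted uptake."""

    table: pd.DataFrame  # region, contrast, t, p, p_bonferroni, direction
    alpha: float

    def significant(self, contrast: tuple[str, str]) -> list[str]:
        t = self.table
        m = (
            (t["group_a"] == contrast[0])
            & (t["group_b"] == contrast[1])
            & (t["p_bonferroni"] <= self.alpha)
        )
        return t.loc[m, "region"].tolist()


def normalize_reference(cohort: CohortTable) -> CohortTable:
    """Divide each subject's regional uptake by their reference-region value.

    Volumes and covariates are untouched; the reference column is kept so
    the operation is explicit in the provenance (applying it twice would
    renormalize again and is the caller's responsibility to avoid).
    """
    bad = np.flatnonzero(~(cohort.reference_value > 0))
    if bad.size:
        raise ValueError(
            f"non-positive reference for subject(s) {[cohort.subject_ids[i] for i in bad]}"
        )
    out = cohort.subset(np.arange(cohort.n_subjects))
    out.cmrgl = cohort.cmrgl / cohort.reference_value[:, None]
    return out


def _base_design(cohort: CohortTable, education: bool = False) -> tuple[np.ndarray, list[str]]:
    age_c = cohort.age - cohort.age.mean()
    sex = cohort.sex_code
    cols = [np.ones(cohort.n_subjects), age_c, sex, age_c * sex, cohort.cmrgl.sum(axis=1)]
    names = ["intercept", "age", "sex", "age_sex", "total_cmrgl"]
    if education:
        cols.append(cohort.education)
        names.append("education")
    return np.column_stack(cols), names


def screen_covariate(
    cohort: CohortTable, covariate_name: str, alpha: float = 0.05,
    bonferroni: bool = True,
) -> CovariateScreen:
    """Marginal per-region screen for a candidate covariate.

    The covariate is kept in the confound design only if some region shows
    a significant simple-regression slope.  By default significance is
    judged on Bonferroni-corrected p-values (over the N regions) so that a
    covariate with no real effect is dropped in about 1 - alpha of
    cohorts; ``bonferroni=False`` compares raw p-values to ``alpha``.
    Raw per-region p-values are always reported.
    """
    values = {
        "education": cohort.education,
        "age": cohort.age,
        "sex": cohort.sex_code,
    }.get(covariate_name)
    if values is None:
        raise ValueError(f"unknown covariate {covariate_name!r}")
    if np.ptp(values) == 0:
        raise ValueError(f"covariate {covariate_name!r} is constant")
    # guard against an alias of an existing design column
    for other, arr in [("age", cohort.age), ("sex", cohort.sex_code)]:
        if other == covariate_name:
            continue
        if np.ptp(arr) > 0 and abs(np.corrcoef(values, arr)[0, 1]) > 1 - 1e-12:
            raise ValueError(
                f"covariate {covariate_name!r} is collinear with {other!r}"
            )
    x = (values - values.mean()) / values.std()
    n = cohort.n_subjects
    y = cohort.cmrgl
    yc = y - y.mean(axis=0)
    r = (x @ yc) / (n * yc.std(axis=0).clip(1e-300))
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p_decide = np.minimum(1.0, p * y.shape[1]) if bonferroni else p
    return CovariateScreen(
        covariate_name, p, keep=bool((p_decide <= alpha).any()), alpha=alpha,
        bonferroni=bonferroni,
    )


def remove_confounds(
    cohort: CohortTable, education: bool = False
) -> ResidualMatrix:
    """Per-region OLS residuals of uptake on the confound design.

    Design: intercept, centered age, sex (M=0/F=1), centered-age x sex,
    total uptake (sum over the N regions, computed on the table as given,
    i.e. after any reference normalization already applied), and the
    region's own volume.  The volume column differs per region, so the fit
    is region-wise.
    """
    X_base, names = _base_design(cohort, education)
    n, N = cohort.cmrgl.shape
    p = X_base.shape[1] + 1  # + volume
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} subjects for {p} regressors; have {n}")
    rank = np.linalg.matrix_rank(X_base)
    if rank < X_base.shape[1]:
        # identify offending columns by greedy QR-style elimination
        bad = []
        kept: list[int] = []
        for j in range(X_base.shape[1]):
            cand = X_base[:, kept + [j]]
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"rank-deficient confound design; collinear column(s): {bad}")
    resid = np.empty((n, N))
    r2 = np.empty(N)
    for j in range(N):
        X = np.column_stack([X_base, cohort.volumes[:, j]])
        y = cohort.cmrgl[:, j]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        resid[:, j] = y - fitted
        tss = ((y - y.mean()) ** 2).sum()
        r2[j] = 0.0 if tss == 0 else 1 - (resid[:, j] ** 2).sum() / tss
    return ResidualMatrix(values=resid, design_description=names + ["volume"], r_squared=r2)


def regional_group_ttests(
    cohort: CohortTable,
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS,
    alpha: float = 0.05,
    education: bool = False,
) -> RegionalDifferenceReport:
    """Group contrasts of confound-adjusted regional uptake.

    Per region, a linear model with group indicators alongside the
    confounds is fitted to all subjects; each pairwise contrast is tested
    with the classical (pooled-variance) t statistic of the group
    coefficient difference.  p-values are Bonferroni-corrected over the N
    regions within each contrast.
    """
    present = sorted(set(cohort.group), key=list(cohort.group).index)
    for a, b in contrasts:
        for g in (a, b):
            if g not in present:
                raise ValueError(f"group {g!r} absent from cohort")
    n, N = cohort.cmrgl.shape
    groups = sorted(present)  # stable coding order
    dummies = np.column_stack([(cohort.group == g).astype(float) for g in groups[1:]])
    age_c = cohort.age - cohort.age.mean()
    sex = cohort.sex_code
    conf_cols = [age_c, sex, age_c * sex]
    if education:
        conf_cols.append(cohort.education)
    X_shared = np.column_stack([np.ones(n), dummies, *conf_cols])
    k_dummy = dummies.shape[1]

    def coef_vector(g: str) -> np.ndarray:
        v = np.zeros(X_shared.shape[1] + 1)  # + volume column appended later
        if g != groups[0]:
            v[1 + groups[1:].index(g)] = 1.0
        return v

    rows = []
    for j in range(N):
        X = np.column_stack([X_shared, cohort.volumes[:, j]])
        y = cohort.cmrgl[:, j]
        XtX_inv = np.linalg.pinv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        dof = n - np.linalg.matrix_rank(X)
        s2 = (resid**2).sum() / dof
        for a, b in contrasts:
            c = coef_vector(a) - coef_vector(b)
            est = c @ beta
            se = np.sqrt(s2 * c @ XtX_inv @ c)
            t = 0.0 if se == 0 else est / se
            p = 2 * stats.t.sf(abs(t), df=dof)
            rows.append(
                dict(
                    region=cohort.atlas.regions[j].abbreviation,
                    group_a=a,
                    group_b=b,
                    t=t,
                    p=p,
                    p_bonferroni=min(1.0, p * N),
                    direction="a>b" if est > 0 else ("a<b" if est < 0 else "none"),
                )
            )
    return RegionalDifferenceReport(table=pd.DataFrame(rows), alpha=alpha)
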