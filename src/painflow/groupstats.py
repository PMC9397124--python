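"""Group-level statistics: ANCOVA group contrast, mixed-effects site contrast, FDR.

Two contrasts are computed per analysis unit (community or node) per
post-onset time point, each treated separately:

* **Group (patients vs controls)** — one-way ANCOVA with the network metric
  as dependent variable, group as the two-level factor and age as covariate;
  the group effect is tested with Type II sums of squares (the extra sum of
  squares of group after age), appropriate for the unbalanced design.
* **Site (joint vs thumb, within patients)** — linear mixed-effects model
  with site and age as fixed effects and random intercepts per subject and
  per site within subject, fitted by REML (Powell optimizer); the site
  fixed effect is tested with the asymptotic Wald test.

Raw p-values are corrected with the Benjamini–Hochberg step-up procedure
over a declared family (by default all units x analysed bins of one
metric/level/contrast table), at a significance level of 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

_TINY = 1e-12


@dataclass
class AncovaResult:
    unit: str
    bin: int
    F: float
    p: float
    df_num: int
    df_den: int
    n_per_group: dict[str, int]
    p_fdr: float | None = None


@dataclass
class MixedModelResult:
    unit: str
    bin: int
    estimate: float
    se: float
    p: float
    var_subject: float
    var_site: float
    var_residual: float
    converged: bool
    p_fdr: float | None = None


def ancova_group(
    values: np.ndarray,
    groups: np.ndarray,
    ages: np.ndarray,
    unit: str = "",
    bin_label: int = 0,
) -> AncovaResult:
    """Type II ANCOVA F-test for the group effect, controlling for age.

    The additive model is ``metric ~ group + age``; the group F is the extra
    sum of squares of group after age over the full-model residual mean
    square, on (1, n - 3) degrees of freedom.  Age is mean-centered before
    fitting (conditioning only; the test is unchanged).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ages = np.asarray(ages, dtype=float)
    if not np.isfinite(ages).all():
        raise ValueError("ages must be finite")
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"group factor must have 2 levels, got {list(levels)}")
    n_per = {str(g): int((groups == g).sum()) for g in levels}
    if min(n_per.values()) < 2:
        raise ValueError(f"need >= 2 subjects per group, got {n_per}")

    n = len(values)
    age_c = ages - ages.mean()
    dummy = (groups == levels[1]).astype(float)
    X_full = np.column_stack([np.ones(n), dummy, age_c])
    X_red = np.column_stack([np.ones(n), age_c])

    fit_full = sm.OLS(values, X_full).fit()
    fit_red = sm.OLS(values, X_red).fit()
    ss_group = fit_red.ssr - fit_full.ssr  # extra SS of group after age
    df_den = n - 3
    if ss_group <= _TINY * max(1.0, float(np.abs(values).max()) ** 2):
        # no between-group signal at all (including all-identical input)
        return AncovaResult(unit, bin_label, 0.0, 1.0, 1, df_den, n_per)
    if fit_full.ssr <= _TINY:
        raise ValueError(
            f"zero residual variance in ANCOVA for unit {unit!r}, bin {bin_label}"
        )
    F = (ss_group / 1.0) / (fit_full.ssr / df_den)
    p = float(stats.f.sf(F, 1, df_den))
    return AncovaResult(unit, bin_label, float(F), p, 1, df_den, n_per)


def mixedmodel_site(
    values: np.ndarray,
    subjects: np.ndarray,
    sites: np.ndarray,
    ages: np.ndarray,
    unit: str = "",
    bin_label: int = 0,
) -> MixedModelResult:
    """REML mixed model for the site effect with subject and site intercepts.

    Fixed effects: site and (mean-centered) age.  Random effects: an
    intercept per subject and an independent intercept per site within
    subject.  Fitted by REML with the Powell optimizer; the site effect is
    the asymptotic Wald test on its coefficient.  Non-convergence is flagged
    (and flagged results are excluded from the FDR family by the callers).
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "subject": np.asarray(subjects),
            "site": np.asarray(sites),
            "age": np.asarray(ages, dtype=float),
        }
    )
    if df["subject"].nunique() < 5:
        raise ValueError("need >= 5 subjects for the mixed model")
    if df["site"].nunique() != 2:
        raise ValueError("site factor must have exactly 2 levels")
    df["age_c"] = df["age"] - df["age"].mean()

    if np.ptp(df["value"].to_numpy()) <= _TINY:
        # degenerate: nothing to fit, zero effect and zero variance components
        return MixedModelResult(unit, bin_label, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, False)

    model = sm.MixedLM.from_formula(
        "value ~ C(site) + age_c",
        groups="subject",
        re_formula="1",
        vc_formula={"site": "0 + C(site)"},
        data=df,
    )
    # Powell first; the site variance component can be weakly identified
    # (one value per subject x site), so fall back to L-BFGS when the
    # Hessian turns singular mid-fit
    fit = None
    caught: list = []
    for method in ("powell", "lbfgs"):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fit = model.fit(reml=True, method=method, maxiter=2000, disp=False)
            break
        except np.linalg.LinAlgError:
            continue
    if fit is None:
        return MixedModelResult(
            unit, bin_label, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False
        )
    # a variance component estimated on the boundary (e.g. zero site
    # variance) is a valid REML solution, not a convergence failure
    failures = [
        w
        for w in caught
        if issubclass(w.category, ConvergenceWarning)
        and "boundary" not in str(w.message).lower()
    ]
    converged = bool(getattr(fit, "converged", True)) and not failures
    site_terms = [name for name in fit.params.index if name.startswith("C(site)")]
    term = site_terms[0]
    vc = fit.vcomp[0] if len(fit.vcomp) else 0.0
    return MixedModelResult(
        unit=unit,
        bin=bin_label,
        estimate=float(fit.params[term]),
        se=float(fit.bse[term]),
        p=float(fit.pvalues[term]),
        var_subject=float(fit.cov_re.iloc[0, 0]),
        var_site=float(vc),
        var_residual=float(fit.scale),
        converged=converged,
    )


def fdr_adjust(pvalues, family_size: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``adj_(i) = min_{j >= i} (p_(j) * m / j)``, capped at 1, where m is the
    family size — by default the number of p-values supplied; an explicit
    ``family_size >= len(pvalues)`` treats the vector as part of a larger
    family of tests (the unobserved members counted as non-discoveries).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if family_size is None or family_size == p.size:
        return multipletests(p, method="fdr_bh")[1]
    if family_size < p.size:
        raise ValueError("family_size cannot be smaller than the number of p-values")
    # step-up over the declared family: rank within the observed vector,
    # scale by the declared m, then enforce monotonicity from the largest rank
    order = np.argsort(p, kind="stable")
    ranked = p[order] * family_size / (np.arange(p.size) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def group_contrast_table(
    elm: pd.DataFrame,
    metric: str,
    level: str,
    site: str,
    manifest: pd.DataFrame,
    analysis_bins: list[int],
    fdr_family: str | int = "per-table",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ANCOVA group contrast for every unit x analysed bin, FDR-corrected.

    ``elm`` is the long-format event-locked table; the family for the BH
    correction is all units x analysed bins of this table (``"per-table"``)
    or an explicit integer m.
    """
    sel = elm[
        (elm["metric"] == metric) & (elm["level"] == level) & (elm["site"] == site)
    ]
    ages = manifest.set_index("subject")["age"]
    results: list[AncovaResult] = []
    for unit in pd.unique(sel["unit"]):
        for b in analysis_bins:
            cell = sel[(sel["unit"] == unit) & (sel["bin"] == b)]
            res = ancova_group(
                cell["value"].to_numpy(),
                cell["group"].to_numpy(),
                ages.loc[cell["subject"]].to_numpy(),
                unit=str(unit),
                bin_label=int(b),
            )
            results.append(res)
    m = len(results) if fdr_family == "per-table" else int(fdr_family)
    adj = fdr_adjust([r.p for r in results], family_size=m)
    rows = []
    for r, a in zip(results, adj):
        r.p_fdr = float(a)
        rows.append(
            {
                "unit": r.unit,
                "bin": r.bin,
                "F": r.F,
                "p": r.p,
                "p_fdr": r.p_fdr,
                "df_num": r.df_num,
                "df_den": r.df_den,
                "significant": r.p_fdr < alpha,
            }
        )
    return pd.DataFrame(rows)


def site_contrast_table(
    elm: pd.DataFrame,
    metric: str,
    level: str,
    group: str,
    manifest: pd.DataFrame,
    analysis_bins: list[int],
    fdr_family: str | int = "per-table",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mixed-model site contrast (within one group) per unit x analysed bin.

    Non-converged cells are reported but excluded from the FDR family, with
    a warning.
    """
    sel = elm[(elm["metric"] == metric) & (elm["level"] == level)]
    sel = sel[sel["group"] == group]
    ages = manifest.set_index("subject")["age"]
    results: list[MixedModelResult] = []
    for unit in pd.unique(sel["unit"]):
        for b in analysis_bins:
            cell = sel[(sel["unit"] == unit) & (sel["bin"] == b)]
            res = mixedmodel_site(
                cell["value"].to_numpy(),
                cell["subject"].to_numpy(),
                cell["site"].to_numpy(),
                ages.loc[cell["subject"]].to_numpy(),
                unit=str(unit),
                bin_label=int(b),
            )
            results.append(res)
    ok = [r for r in results if r.converged]
    if len(ok) < len(results):
        warnings.warn(
            f"{len(results) - len(ok)} mixed-model cells did not converge; "
            "they are excluded from the FDR family"
        )
    m = len(ok) if fdr_family == "per-table" else int(fdr_family)
    if ok:
        adj = fdr_adjust([r.p for r in ok], family_size=max(m, 1))
        for r, a in zip(ok, adj):
            r.p_fdr = float(a)
    rows = [
        {
            "unit": r.unit,
            "bin": r.bin,
            "estimate": r.estimate,
            "se": r.se,
            "p": r.p,
            "p_fdr": r.p_fdr,
            "var_subject": r.var_subject,
            "var_site": r.var_site,
            "var_residual": r.var_residual,
            "converged": r.converged,
            "significant": (r.p_fdr is not None and r.p_fdr < alpha),
        }
        for r in results
    ]
    return pd.DataFrame(rows)
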