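"""Classical trial statistics.

Two-way fixed-effects ANOVA (balanced designs only), entry-mean
broad-sense heritability, signed percent change between treatment
means, Pearson correlation matrices with significance stars, and
post-hoc mean separation by LSD or Duncan's multiple range test.

Broad-sense heritability uses the entry-mean variance-component
formula: within one environment a one-way genotype ANOVA gives
MS_genotype and MS_error; then

    σ²_e = MS_error
    σ²_g = max(0, (MS_genotype − MS_error) / r)
    H²   = σ²_g / (σ²_g + σ²_e / r)

with r the replicate count.  Negative variance-component estimates are
truncated at zero, keeping H² in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AnovaResult, HeritabilityResult, TrialTable, ValidationError


class UnbalancedDesignError(ValueError):
    """The exact sum-of-squares path requires equal cell counts."""


def two_way_anova(trial: TrialTable, trait: str) -> AnovaResult:
    """Balanced two-way fixed-effects ANOVA: genotype x environment.

    Partitions total SS into genotype, environment, interaction and
    residual; F = MS_factor / MS_residual with p from the F
    distribution.  Unbalanced inputs are rejected rather than silently
    resolved into a Type-I/III choice.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = trial.subset(trait=trait)
    if df.empty:
        raise ValidationError(f"trait {trait!r} absent from trial table")
    counts = df.groupby(["genotype", "environment"], observed=True).size()
    n_g = df["genotype"].nunique()
    n_e = df["environment"].nunique()
    if len(counts) < n_g * n_e:
        raise UnbalancedDesignError("every genotype x environment cell needs >= 1 observation")
    if counts.nunique() > 1:
        raise UnbalancedDesignError("unequal replicate counts per cell; only balanced designs supported")
    r = int(counts.iloc[0])
    resid_df = n_g * n_e * (r - 1)
    if resid_df < 1:
        raise ValidationError("zero residual degrees of freedom (single replicate per cell)")

    model = smf.ols("value ~ C(genotype) * C(environment)", data=df).fit()
    # Type I == Type III on a balanced layout; sequential SS are the textbook SS.
    aov = sm.stats.anova_lm(model, typ=1)

    rename = {
        "C(genotype)": "genotype",
        "C(environment)": "environment",
        "C(genotype):C(environment)": "genotype:environment",
        "Residual": "residual",
    }
    table = aov.rename(index=rename)[["df", "sum_sq", "F", "PR(>F)"]]
    table.columns = ["df", "sum_sq", "F", "p"]
    # snap floating dust to zero so degenerate designs report exact SS
    scale = float(df["value"].abs().max()) or 1.0
    tol = len(df) * (np.finfo(float).eps * scale) ** 2 * 1e6
    table.loc[table["sum_sq"].abs() < tol, "sum_sq"] = 0.0
    table.insert(2, "mean_sq", table["sum_sq"] / table["df"])
    if table.loc["residual", "mean_sq"] == 0:
        # zero-noise limit: F is infinite for real effects, undefined (0/0)
        # for absent ones
        factors = table.index != "residual"
        table.loc[factors, "F"] = np.where(table.loc[factors, "sum_sq"] == 0, np.nan, np.inf)
        table.loc[factors, "p"] = np.where(np.isnan(table.loc[factors, "F"]), np.nan, 0.0)
    table.loc["residual", ["F", "p"]] = np.nan
    return AnovaResult(table=table.loc[["genotype", "environment", "genotype:environment", "residual"]])


def broad_sense_heritability(trial: TrialTable, environment: str, trait: str) -> HeritabilityResult:
    """Entry-mean broad-sense heritability within one environment."""
    df = trial.subset(environment=environment, trait=trait)
    if df.empty:
        raise ValidationError(f"no data for {trait!r} in {environment!r}")
    counts = df.groupby("genotype").size()
    n_g = len(counts)
    if n_g < 2:
        raise ValidationError("need >= 2 genotypes to estimate genotypic variance")
    if counts.min() < 2:
        raise ValidationError("need >= 2 replicates per genotype (residual variance inestimable)")
    if counts.nunique() > 1:
        raise UnbalancedDesignError("unequal replicate counts per genotype")
    r = int(counts.iloc[0])

    values = df["value"].to_numpy(float)
    geno_means = df.groupby("genotype")["value"].mean()
    grand = values.mean()
    ss_g = r * float(((geno_means - grand) ** 2).sum())
    ss_e = float(((df["value"] - df["genotype"].map(geno_means)) ** 2).sum())
    ms_g = ss_g / (n_g - 1)
    ms_e = ss_e / (n_g * (r - 1))
    sigma2_e = ms_e
    sigma2_g = max(0.0, (ms_g - ms_e) / r)
    denom = sigma2_g + sigma2_e / r
    h2 = sigma2_g / denom if denom > 0 else 0.0
    return HeritabilityResult(
        environment=environment, trait=trait,
        sigma2_g=sigma2_g, sigma2_e=sigma2_e, n_replicates=r,
        h2=float(np.clip(h2, 0.0, 1.0)),
    )


def percent_change(mean_normal: float, mean_stress: float) -> float:
    """Signed percent change of a stress mean relative to its normal baseline."""
    if mean_normal == 0:
        raise ValidationError("percent change undefined for a zero baseline")
    return 100.0 * (mean_stress - mean_normal) / mean_normal


@dataclass
class CorrelationMatrix:
    """Pearson matrix with two-sided p-values and significance stars."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int

    def formatted(self, digits: int = 2) -> pd.DataFrame:
        """Printed-style table: coefficient to ``digits`` plus stars."""
        out = self.r.copy().astype(object)
        for i in out.index:
            for j in out.columns:
                rij = self.r.loc[i, j]
                if np.isnan(rij):
                    out.loc[i, j] = "NA"
                else:
                    star = self.stars.loc[i, j]
                    out.loc[i, j] = f"{rij:.{digits}f}" + (f" {star}" if star else "")
        return out


def pearson_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson correlations with stars at p < 0.05 (*) and p < 0.01 (**).

    p-values come from the two-sided t transform
    t = r·√((n−2)/(1−r²)); |r| = 1 is reported as p = 0 (the printed
    convention for the exactly collinear SSI–YSI pair).  Zero-variance
    columns yield NaN rows/columns.
    """
    num = table.select_dtypes(include=[np.number])
    n = len(num)
    if n < 3:
        raise ValidationError("need >= 3 complete observations for correlation tests")
    r = num.corr(method="pearson")  # pandas yields NaN for zero-variance columns
    rv = r.to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / (1.0 - rv**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rv) >= 1.0 - 1e-15, 0.0, p)
    p = np.where(np.isnan(rv), np.nan, p)
    np.fill_diagonal(p, 0.0)
    pdf = pd.DataFrame(p, index=r.index, columns=r.columns)
    stars = pd.DataFrame("", index=r.index, columns=r.columns, dtype=object)
    stars = stars.mask((pdf < 0.05) & (pdf >= 0.01), "*")
    stars = stars.mask(pdf < 0.01, "**")
    stars = stars.mask(pdf.isna(), "")
    for c in r.columns:  # a variable is not flagged against itself
        stars.loc[c, c] = ""
    return CorrelationMatrix(r=r, p=pdf, stars=stars.astype(str), n=n)


def _critical_range(span: int, df_error: float, ms_error: float, r: float,
                    method: str, alpha: float) -> float:
    """Least significant range for a span of ranked means."""
    if method == "LSD":
        return stats.t.ppf(1 - alpha / 2, df_error) * np.sqrt(2.0 * ms_error / r)
    if method == "Duncan":
        # Duncan's protection level: alpha_p = 1 - (1-alpha)^(p-1)
        q = stats.studentized_range.ppf((1 - alpha) ** (span - 1), span, df_error)
        return float(q) * np.sqrt(ms_error / r)
    raise ValueError(f"unknown method {method!r}; use 'LSD' or 'Duncan'")


def mean_separation(
    group_means: pd.Series,
    ms_error: float,
    df_error: float,
    r: float,
    method: str = "LSD",
    alpha: float = 0.05,
) -> pd.Series:
    """Compact letter display for post-hoc mean separation.

    Means are ranked descending; maximal runs of means whose extreme
    difference does not exceed the least significant range share a
    letter, letters assigned from ``a`` at the largest mean.  For LSD
    the range is t(1−α/2, df)·√(2·MS_error/r) regardless of span; for
    Duncan it is the studentized-range critical value at protection
    level (1−α)^(span−1) times √(MS_error/r).  For unequal group sizes
    pass the harmonic mean as ``r``.
    """
    if df_error < 1:
        raise ValidationError("df_error must be >= 1")
    if ms_error < 0:
        raise ValidationError("ms_error must be non-negative")
    means = pd.Series(group_means, dtype=float)
    order = means.sort_values(ascending=False, kind="mergesort")
    vals = order.to_numpy()
    n = len(vals)
    tol = 1e-12 * max(1.0, float(np.abs(vals).max(initial=0.0)))

    runs: list[tuple[int, int]] = []
    for i in range(n):
        j = i
        while j + 1 < n:
            span = j + 2 - i
            crit = _critical_range(span, df_error, ms_error, r, method, alpha) if ms_error > 0 else 0.0
            if vals[i] - vals[j + 1] <= crit + tol:
                j += 1
            else:
                break
        if not runs or j > runs[-1][1]:
            runs.append((i, j))

    letters = ["" for _ in range(n)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for li, (i, j) in enumerate(runs):
        letter = alphabet[li % len(alphabet)] * (1 + li // len(alphabet))
        for idx in range(i, j + 1):
            letters[idx] += letter
    return pd.Series(letters, index=order.index).reindex(means.index)
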