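"""Inferential layer: ANOVA, LSD letters, contrasts, correlations, PCA.

The experiment is a randomized complete block design with a genotype ×
water-regime factorial, so the workhorse model is

    value ~ block + genotype + water + genotype:water

fitted by OLS with all factors fixed, Type-II sums of squares (equal to
the classical decomposition on balanced data).  Around it sit the usual
companions of an agronomic trial analysis:

* Shapiro–Wilk and Bartlett checks on residuals / group variances;
* Fisher's LSD with a compact letter display (insert-and-absorb);
* per-genotype regime contrasts using the pooled ANOVA error;
* Pearson correlation matrices with t-based p-values;
* principal component analysis of the trait correlation matrix, the
  standard screening biplot for drought-tolerance traits.

Multiple-testing control beyond the LSD protection is deliberately not
applied; see the package methods note.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "sig_code",
    "AssumptionChecks",
    "assumption_checks",
    "two_way_anova",
    "one_way_anova",
    "lsd_letters",
    "regime_contrast",
    "contrasts_table",
    "correlation_matrix",
    "PCAResult",
    "pca_correlation",
]


def sig_code(p: float) -> str:
    """Star code at the 0.05 / 0.01 / 0.001 thresholds; 'ns' otherwise."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssumptionChecks:
    shapiro_w: float
    shapiro_p: float
    bartlett_stat: float
    bartlett_p: float
    alpha: float = 0.05

    @property
    def normal(self) -> bool:
        return bool(self.shapiro_p >= self.alpha)

    @property
    def homoscedastic(self) -> bool:
        return bool(self.bartlett_p >= self.alpha)


def assumption_checks(residuals, groups=None, alpha: float = 0.05) -> AssumptionChecks:
    """Shapiro–Wilk on residuals, Bartlett across groups.

    ``groups`` is an iterable of per-group samples; groups with fewer
    than 2 observations (or fewer than 2 usable groups) skip the Bartlett
    test with a warning (statistic and p reported as NaN).
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 residuals")
    shapiro = sps.shapiro(residuals)
    bartlett_stat = bartlett_p = float("nan")
    if groups is not None:
        usable = [np.asarray(g, dtype=float) for g in groups]
        usable = [g for g in usable if g.size >= 2]
        if len(usable) >= 2:
            if all(np.ptp(g) == 0 for g in usable):
                # Degenerate: identical constants in every group.
                bartlett_stat, bartlett_p = 0.0, 1.0
            else:
                bartlett = sps.bartlett(*usable)
                bartlett_stat = float(bartlett.statistic)
                bartlett_p = float(bartlett.pvalue)
        else:
            warnings.warn(
                "Bartlett test skipped: need >= 2 groups with >= 2 observations",
                stacklevel=2,
            )
    return AssumptionChecks(
        shapiro_w=float(shapiro.statistic),
        shapiro_p=float(shapiro.pvalue),
        bartlett_stat=bartlett_stat,
        bartlett_p=bartlett_p,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

_TERM_NAMES = {
    "C(block)": "block",
    "C(genotype)": "genotype",
    "C(regime)": "water",
    "C(genotype):C(regime)": "genotype:water",
    "Residual": "residual",
}


def _finish_anova(table: pd.DataFrame) -> pd.DataFrame:
    table = table.rename(
        columns={"sum_sq": "sum_sq", "PR(>F)": "p", "F": "F"}
    )
    table["mean_sq"] = table["sum_sq"] / table["df"]
    table["sig"] = [sig_code(p) for p in table["p"]]
    table.loc[table.index[-1], "sig"] = ""
    return table[["df", "sum_sq", "mean_sq", "F", "p", "sig"]]


def two_way_anova(
    data: pd.DataFrame,
    trait: str,
    *,
    genotype: str = "genotype",
    water: str = "regime",
    block: str = "block",
) -> pd.DataFrame:
    """RCBD factorial ANOVA: trait ~ block + genotype + water + genotype:water.

    Returns a table indexed by term (block, genotype, water,
    genotype:water, residual) with df, SS, MS, F, p and a star code.
    Type-II sums of squares; on a balanced layout these coincide with the
    classical decomposition, and unbalanced data are accepted with a
    warning.
    """
    frame = data[[trait, genotype, water, block]].dropna()
    frame = frame.rename(
        columns={trait: "y", genotype: "genotype", water: "regime", block: "block"}
    )
    for factor in ("genotype", "regime", "block"):
        if frame[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels")
    counts = frame.groupby(["genotype", "regime", "block"]).size()
    if counts.nunique() > 1 or len(counts) < (
        frame["genotype"].nunique() * frame["regime"].nunique() * frame["block"].nunique()
    ):
        warnings.warn("unbalanced layout: Type-II sums of squares used", stacklevel=2)
    model = smf.ols("y ~ C(block) + C(genotype) * C(regime)", data=frame).fit()
    table = anova_lm(model, typ=2)
    table.index = [_TERM_NAMES.get(t, t) for t in table.index]
    table = table.reindex(
        ["block", "genotype", "water", "genotype:water", "residual"]
    )
    out = _finish_anova(table)
    out.attrs["model"] = model
    out.attrs["mse"] = float(out.loc["residual", "mean_sq"])
    out.attrs["df_error"] = float(out.loc["residual", "df"])
    return out


def one_way_anova(values, groups) -> pd.DataFrame:
    """One-way ANOVA table (group / residual) on a single factor."""
    frame = pd.DataFrame({"y": np.asarray(values, dtype=float),
                          "g": np.asarray(groups)}).dropna()
    if frame["g"].nunique() < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    model = smf.ols("y ~ C(g)", data=frame).fit()
    table = anova_lm(model, typ=2)
    table.index = ["group", "residual"]
    out = _finish_anova(table)
    out.attrs["model"] = model
    out.attrs["mse"] = float(out.loc["residual", "mean_sq"])
    out.attrs["df_error"] = float(out.loc["residual", "df"])
    return out


# ---------------------------------------------------------------------------
# Fisher's LSD compact letter display
# ---------------------------------------------------------------------------

def _pairwise_significant(
    means: pd.Series, n: pd.Series, mse: float, df_error: float, alpha: float
) -> dict[tuple[str, str], bool]:
    tcrit = sps.t.ppf(1 - alpha / 2, df_error)
    out = {}
    for a, b in itertools.combinations(means.index, 2):
        lsd_ab = tcrit * np.sqrt(mse * (1.0 / n[a] + 1.0 / n[b]))
        out[(a, b)] = abs(means[a] - means[b]) > lsd_ab
    return out


def lsd_letters(
    means,
    n,
    mse: float,
    df_error: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's LSD compact letter display.

    Parameters
    ----------
    means
        Group means (mapping or Series indexed by group label).
    n
        Per-group sample size (scalar or mapping/Series).
    mse, df_error
        Pooled error mean square and its degrees of freedom from the
        protecting ANOVA.
    alpha
        Two-sided comparison level; LSD = t(1-alpha/2, df) *
        sqrt(MSE * (1/n_a + 1/n_b)).

    Letters are assigned by insert-and-absorb: start with every group in
    one letter column, split a column for each significantly different
    pair it contains, drop columns absorbed by supersets, then letter the
    columns from 'a' at the highest mean downward.  Two groups share a
    letter exactly when their difference is within the LSD.
    """
    means = pd.Series(means, dtype=float)
    if np.isscalar(n):
        n = pd.Series(float(n), index=means.index)
    else:
        n = pd.Series(n, dtype=float).reindex(means.index)
    if mse < 0 or df_error < 1:
        raise ValueError("need MSE >= 0 and df_error >= 1")
    significant = _pairwise_significant(means, n, mse, df_error, alpha)

    columns: list[set] = [set(means.index)]
    order = means.sort_values(ascending=False).index
    for a, b in itertools.combinations(order, 2):
        key = (a, b) if (a, b) in significant else (b, a)
        if not significant[key]:
            continue
        next_columns = []
        for col in columns:
            if a in col and b in col:
                next_columns.extend([col - {a}, col - {b}])
            else:
                next_columns.append(col)
        # absorb columns contained in another column
        columns = [
            c
            for i, c in enumerate(next_columns)
            if c
            and not any(c < other or (c == other and i > j)
                        for j, other in enumerate(next_columns))
        ]
    # letter columns ordered by their best (largest) mean
    columns.sort(key=lambda col: -max(means[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in means.index}
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g] += letter
    tcrit = sps.t.ppf(1 - alpha / 2, df_error)
    nbar = float(n.mean())
    out = pd.DataFrame(
        {
            "mean": means.loc[order],
            "n": n.loc[order],
            "letters": ["".join(sorted(letters[g])) for g in order],
        }
    )
    out.index.name = "group"
    out.attrs["lsd"] = float(tcrit * np.sqrt(2.0 * mse / nbar))
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# regime contrasts
# ---------------------------------------------------------------------------

def regime_contrast(
    data: pd.DataFrame,
    trait: str,
    genotype_label: str,
    *,
    mse: float | None = None,
    df_error: float | None = None,
) -> pd.Series:
    """WW − WD mean contrast for one genotype, tested on the pooled error.

    The estimate is mean(WW) − mean(WD), so a positive value means the
    trait declined under water deficit.  If the pooled error is not
    supplied it is taken from the full two-way ANOVA of ``data``.
    """
    sub = data[data["genotype"] == genotype_label]
    ww = sub.loc[sub["regime"] == "WW", trait].dropna()
    wd = sub.loc[sub["regime"] == "WD", trait].dropna()
    if ww.empty or wd.empty:
        raise ValueError(f"genotype {genotype_label!r} missing a regime")
    if mse is None or df_error is None:
        table = two_way_anova(data, trait)
        mse, df_error = table.attrs["mse"], table.attrs["df_error"]
    estimate = float(ww.mean() - wd.mean())
    se = float(np.sqrt(mse * (1.0 / len(ww) + 1.0 / len(wd))))
    t = estimate / se if se > 0 else float("inf") * np.sign(estimate or 1)
    p = float(2 * sps.t.sf(abs(t), df_error)) if np.isfinite(t) else 0.0
    return pd.Series(
        {
            "genotype": genotype_label,
            "trait": trait,
            "estimate": estimate,
            "se": se,
            "t": t,
            "p": p,
            "sig": sig_code(p),
        }
    )


def contrasts_table(data: pd.DataFrame, traits) -> pd.DataFrame:
    """WW − WD contrasts for every genotype × trait, pooled error per trait."""
    rows = []
    for trait in traits:
        table = two_way_anova(data, trait)
        mse, dfe = table.attrs["mse"], table.attrs["df_error"]
        for genotype_label in data["genotype"].unique():
            try:
                rows.append(
                    regime_contrast(
                        data, trait, genotype_label, mse=mse, df_error=dfe
                    )
                )
            except ValueError as exc:
                warnings.warn(str(exc), stacklevel=2)
    return pd.DataFrame(rows).reset_index(drop=True)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def correlation_matrix(
    frame: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p over the numeric columns.

    Uses pairwise-complete observations; pairs with fewer than 3 complete
    rows or a zero-variance member get NaN (flagged by a warning).
    """
    cols = list(frame.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    np.fill_diagonal(p.values, np.nan)
    for a, b in itertools.combinations(cols, 2):
        sub = frame[[a, b]].dropna()
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if len(sub) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"correlation {a} ~ {b} undefined (n < 3 or zero variance)",
                stacklevel=2,
            )
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        res = sps.pearsonr(x, y)
        r.loc[a, b] = r.loc[b, a] = float(res.statistic)
        p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return r, p


# ---------------------------------------------------------------------------
# correlation-matrix PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition of a trait correlation matrix.

    ``loadings`` holds unit-norm eigenvectors (variables × components),
    so loadings @ diag(eigenvalues) @ loadings.T reconstructs the
    correlation matrix; ``variable_coords`` are the biplot arrows
    (loadings scaled by sqrt(eigenvalue)) and ``scores`` the observation
    coordinates of the standardized data.
    """

    eigenvalues: np.ndarray
    proportion: np.ndarray
    cumulative: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    variable_coords: pd.DataFrame = field(repr=False)
    correlation: pd.DataFrame = field(repr=False)


def pca_correlation(frame: pd.DataFrame) -> PCAResult:
    """PCA of the correlation matrix of ``frame`` (observations × variables).

    Components are sorted by decreasing eigenvalue and sign-fixed so the
    largest-magnitude loading of each component is positive, which makes
    biplots reproducible across platforms.
    """
    frame = frame.dropna()
    if frame.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    if frame.shape[0] < 2:
        raise ValueError("PCA needs at least 2 observations")
    sd = frame.std(ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance variable(s): {dead}")
    z = (frame - frame.mean()) / sd
    corr = z.corr()
    eigenvalues, vectors = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.maximum(eigenvalues[order], 0.0)
    vectors = vectors[:, order]
    for j in range(vectors.shape[1]):
        if vectors[np.argmax(np.abs(vectors[:, j])), j] < 0:
            vectors[:, j] = -vectors[:, j]
    names = [f"PC{j + 1}" for j in range(vectors.shape[1])]
    loadings = pd.DataFrame(vectors, index=frame.columns, columns=names)
    scores = pd.DataFrame(
        z.to_numpy() @ vectors, index=frame.index, columns=names
    )
    variable_coords = loadings * np.sqrt(eigenvalues)
    total = eigenvalues.sum()
    proportion = eigenvalues / total
    return PCAResult(
        eigenvalues=eigenvalues,
        proportion=proportion,
        cumulative=np.cumsum(proportion),
        loadings=loadings,
        scores=scores,
        variable_coords=variable_coords,
        correlation=corr,
    )
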