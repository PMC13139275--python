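"""Survey statistics: spatial ANOVA with assumption checks and post-hoc
grouping, seasonal two-sample tests, inter-metal correlation, and PCA.

Conventions follow common practice for monitoring surveys: one-way ANOVA on
replicate-level concentrations across sites (seasons pooled as replicates
by default), Kolmogorov-Smirnov on standardised residuals and Levene's test
for the assumptions, Tukey HSD post-hoc summarised as a compact letter
display, two-sided Pearson correlation over pairwise-complete observations,
and correlation-matrix (standardised-column) PCA.  Significance level
defaults to 0.05; no multiple-testing correction is applied by default, with
an optional Benjamini-Hochberg flag for the pairwise families.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .data_model import DomainError, SurveyTable

__all__ = [
    "AnovaReport",
    "TTestReport",
    "site_anova",
    "season_ttest",
    "correlation_matrix",
    "PcaReport",
    "pca_biplot",
    "compact_letters",
]


def compact_letters(items: list[str], significant_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Items sharing a letter are *not* significantly different.  ``items``
    should be pre-sorted (e.g. by group mean) so letters read naturally.
    """
    groups: list[set[str]] = [set(items)]
    for a, b in significant_pairs:
        nxt: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                nxt.append(g - {a})
                nxt.append(g - {b})
            else:
                nxt.append(g)
        # absorb: drop any group contained in another, then deduplicate
        groups = [g for g in nxt if g and not any(g < h for h in nxt)]
        uniq: list[set[str]] = []
        for g in groups:
            if g not in uniq:
                uniq.append(g)
        groups = uniq
    letters = {item: "" for item in items}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for item in items:
            if item in g:
                letters[item] += letter
    return letters


@dataclass
class AnovaReport:
    metal: str
    f: float
    p: float
    df_between: int
    df_within: int
    ks_p: float
    levene_p: float
    posthoc: pd.DataFrame
    letters: dict[str, str]
    alpha: float
    dropped_sites: list[str] = field(default_factory=list)


def _uncensored_groups(table: SurveyTable, metal: str, min_n: int = 2):
    df = table.data
    sel = (df["metal"] == metal) & (~df["censored"].astype(bool))
    groups, dropped = {}, []
    for site in table.site_order:
        vals = df.loc[sel & (df["site"] == site), "value"].to_numpy(dtype=float)
        if len(vals) >= min_n:
            groups[site] = vals
        else:
            dropped.append(site)
    return groups, dropped


def site_anova(
    table: SurveyTable,
    metal: str,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> AnovaReport:
    """One-way ANOVA of replicate concentrations across sites (seasons pooled).

    Reports the F statistic, KS normality of standardised residuals,
    Levene homogeneity, and Tukey HSD pairwise p-values condensed into
    compact letters.  Sites with fewer than two uncensored replicates are
    dropped (and listed); fewer than two usable sites is an error rather
    than a silent NaN.
    """
    groups, dropped = _uncensored_groups(table, metal)
    if len(groups) < 2:
        raise DomainError(
            f"ANOVA for {metal} needs >=2 sites with >=2 uncensored replicates; "
            f"usable sites: {sorted(groups)}"
        )
    arrays = list(groups.values())
    values_all = np.concatenate(arrays)
    if np.ptp(values_all) == 0:
        # identical constants everywhere: zero between-group variance
        pairs = list(itertools.combinations(sorted(groups), 2))
        posthoc = pd.DataFrame(
            {"site_a": [a for a, _ in pairs], "site_b": [b for _, b in pairs],
             "p": 1.0, "significant": False}
        )
        return AnovaReport(
            metal=metal, f=0.0, p=1.0, df_between=len(groups) - 1,
            df_within=len(values_all) - len(groups), ks_p=1.0, levene_p=1.0,
            posthoc=posthoc, letters=compact_letters(sorted(groups), set()),
            alpha=alpha, dropped_sites=dropped,
        )
    f, p = sps.f_oneway(*arrays)
    resid = np.concatenate([a - a.mean() for a in arrays])
    sd = resid.std(ddof=1)
    ks_p = sps.kstest(resid / sd, "norm").pvalue if sd > 0 else 1.0
    levene_p = sps.levene(*arrays).pvalue
    n_total = sum(len(a) for a in arrays)

    values = np.concatenate(arrays)
    labels = np.concatenate([[s] * len(a) for s, a in groups.items()])
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairs = list(itertools.combinations(sorted(groups), 2))
    pvals = np.asarray(tk.pvalues, dtype=float)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        reject, pvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    else:
        reject = pvals < alpha
    posthoc = pd.DataFrame(
        {
            "site_a": [a for a, _ in pairs],
            "site_b": [b for _, b in pairs],
            "p": pvals,
            "significant": reject,
        }
    )
    order = sorted(groups, key=lambda s: -groups[s].mean())
    sig_pairs = {
        (row.site_a, row.site_b) for row in posthoc.itertuples() if row.significant
    }
    letters = compact_letters(order, sig_pairs)
    return AnovaReport(
        metal=metal,
        f=float(f),
        p=float(p),
        df_between=len(groups) - 1,
        df_within=n_total - len(groups),
        ks_p=float(ks_p),
        levene_p=float(levene_p),
        posthoc=posthoc,
        letters=letters,
        alpha=alpha,
        dropped_sites=dropped,
    )


@dataclass
class TTestReport:
    site: str
    metal: str
    t: float
    p: float
    df: float
    method: str  # "pooled" or "welch"
    mean_wet: float
    mean_dry: float
    levene_p: float
    ks_p_wet: float
    ks_p_dry: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def _ks_normal(x: np.ndarray) -> float:
    sd = x.std(ddof=1)
    if sd == 0:
        return 1.0
    return float(sps.kstest((x - x.mean()) / sd, "norm").pvalue)


def season_ttest(table: SurveyTable, site: str, metal: str, alpha: float = 0.05) -> TTestReport:
    """Two-sided independent-samples t-test of wet vs dry season.

    Uses the pooled-variance test unless Levene's test rejects equal
    variances at ``alpha``, in which case Welch's correction is applied.
    Both seasons need at least two uncensored replicates.
    """
    df = table.data
    sel = (df["site"] == site) & (df["metal"] == metal) & (~df["censored"].astype(bool))
    wet = df.loc[sel & (df["season"] == "wet"), "value"].to_numpy(dtype=float)
    dry = df.loc[sel & (df["season"] == "dry"), "value"].to_numpy(dtype=float)
    if len(wet) < 2 or len(dry) < 2:
        raise DomainError(
            f"seasonal t-test for {metal} at site {site} needs >=2 uncensored "
            f"replicates per season (got wet={len(wet)}, dry={len(dry)})"
        )
    levene_p = float(sps.levene(wet, dry).pvalue)
    equal_var = levene_p >= alpha
    res = sps.ttest_ind(wet, dry, equal_var=equal_var)
    if equal_var:
        dof = len(wet) + len(dry) - 2
    else:
        dof = float(res.df) if hasattr(res, "df") else np.nan
    return TTestReport(
        site=site,
        metal=metal,
        t=float(res.statistic),
        p=float(res.pvalue),
        df=float(dof),
        method="pooled" if equal_var else "welch",
        mean_wet=float(wet.mean()),
        mean_dry=float(dry.mean()),
        levene_p=levene_p,
        ks_p_wet=_ks_normal(wet),
        ks_p_dry=_ks_normal(dry),
        alpha=alpha,
    )


def correlation_matrix(variables: pd.DataFrame, bh_correct: bool = False) -> pd.DataFrame:
    """Pairwise Pearson correlations over pairwise-complete observations.

    ``variables``: one column per variable, rows aligned (e.g. site-season
    observations).  Returns the long form with one row per unordered pair
    including the diagonal: var_a, var_b, r, p, n.  A constant variable has
    undefined correlations; its pairs get missing r with a note.
    """
    cols = list(variables.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            pair = variables[[a, b]].dropna() if a != b else variables[[a]].dropna()
            n = len(pair)
            if a == b:
                rows.append(dict(var_a=a, var_b=b, r=1.0, p=0.0, n=n, note=""))
                continue
            if n < 3:
                rows.append(dict(var_a=a, var_b=b, r=np.nan, p=np.nan, n=n,
                                 note="fewer than 3 complete pairs"))
                continue
            x = pair[a].to_numpy(dtype=float)
            y = pair[b].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append(dict(var_a=a, var_b=b, r=np.nan, p=np.nan, n=n,
                                 note="constant variable"))
                continue
            r, p = sps.pearsonr(x, y)
            rows.append(dict(var_a=a, var_b=b, r=float(r), p=float(p), n=n, note=""))
    out = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        off = (out["var_a"] != out["var_b"]) & out["p"].notna()
        if off.any():
            out.loc[off, "p_adjusted"] = multipletests(
                out.loc[off, "p"], method="fdr_bh"
            )[1]
    return out


@dataclass
class PcaReport:
    loadings: pd.DataFrame          # variables x components, orthonormal columns
    scores: pd.DataFrame            # observations x components
    explained_variance_ratio: np.ndarray
    dropped_rows: list = field(default_factory=list)

    def reconstruct(self) -> pd.DataFrame:
        """Standardised data matrix rebuilt from all retained components."""
        z = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(z, index=self.scores.index, columns=self.loadings.index)


def pca_biplot(matrix: pd.DataFrame) -> PcaReport:
    """Correlation-matrix PCA of a site-season x variable table.

    Columns are standardised (mean 0, sd 1 with ddof=1) before the
    decomposition, so each variable contributes equal variance.  Rows with
    any missing entry (e.g. below-detection cells) are dropped and listed.
    A zero-variance column is an error naming the column.
    """
    complete = matrix.dropna()
    dropped = [idx for idx in matrix.index if idx not in complete.index]
    if complete.shape[0] < 3 or complete.shape[1] < 2:
        raise DomainError(
            f"PCA needs >=3 complete rows and >=2 variables; got {complete.shape}"
        )
    sds = complete.std(ddof=1)
    flat = sds[sds == 0].index.tolist()
    if flat:
        raise DomainError(f"zero-variance column(s) for PCA: {flat}")
    z = (complete - complete.mean()) / sds
    pca = PCA()
    scores = pca.fit_transform(z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return PcaReport(
        loadings=pd.DataFrame(pca.components_.T, index=complete.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=complete.index, columns=comp_names),
        explained_variance_ratio=np.asarray(pca.explained_variance_ratio_),
        dropped_rows=dropped,
    )
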