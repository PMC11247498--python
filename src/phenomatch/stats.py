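"""Association analysis of phenotype matches.

Three layers, mirroring how match determinants are usually dissected:

* per-disease-category enrichment of matches (2x2 tables, Fisher's exact
  test, sample odds ratio ad/bc with Wald log CI, Benjamini-Hochberg
  adjustment across the category family);
* bivariate comparisons (two-sided Wilcoxon rank-sum for annotation counts
  between matches and non-matches, Pearson correlation for score vs counts);
* a multivariable logistic regression of match status on model-, gene- and
  disease-level features, fitted by unpenalised maximum likelihood on
  standardised continuous covariates, reported on the log-odds scale with
  Wald 95% intervals.

The unit of analysis for the regression is the model-disease *pair*; the
enrichment layer works per *gene* (a gene associated with disorders in
several categories contributes to each category's table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "SeparationError",
    "category_enrichment",
    "gene_category_table",
    "compare_counts",
    "correlate",
    "MatchModelResult",
    "fit_match_model",
    "DEFAULT_CONTINUOUS",
    "DEFAULT_BINARY",
]

DEFAULT_CONTINUOUS = ("n_procedures", "n_mp_terms", "n_hpo_terms")
DEFAULT_BINARY = ("homozygous", "early_death")


class SeparationError(RuntimeError):
    """Complete separation: the MLE does not exist.

    Remove or merge the offending feature, or use a penalised fit.
    """


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def gene_category_table(
    gene_results: pd.DataFrame, diseases: pd.DataFrame
) -> pd.DataFrame:
    """One row per (gene, category) with the gene-level match flag.

    ``gene_results`` needs ``human_gene`` and ``is_match`` columns;
    ``diseases`` needs ``human_gene`` and ``category``.  A gene linked to
    disorders in several categories yields several rows.
    """
    match = gene_results.set_index("human_gene")["is_match"].astype(bool)
    cats = diseases[["human_gene", "category"]].drop_duplicates()
    cats = cats[cats["human_gene"].isin(match.index)].copy()
    cats["is_match"] = match.loc[cats["human_gene"]].to_numpy()
    return cats.reset_index(drop=True)


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """ad/bc with +inf when bc == 0 and a, d > 0; NaN when undefined."""
    if b * c == 0:
        return float("inf") if a > 0 and d > 0 else float("nan")
    return (a * d) / (b * c)


def category_enrichment(table: pd.DataFrame) -> pd.DataFrame:
    """Match enrichment of each disease category against all others.

    Parameters
    ----------
    table
        Rows with ``category`` and boolean-ish ``is_match`` (typically the
        output of :func:`gene_category_table`).

    Returns
    -------
    DataFrame with one row per category: the 2x2 cells (``a`` matches in
    category, ``b`` non-matches in category, ``c`` matches elsewhere,
    ``d`` non-matches elsewhere), the sample odds ratio with Wald 95% CI,
    the two-sided Fisher exact p-value and the BH-adjusted q-value.
    """
    cats = sorted(table["category"].unique())
    if len(cats) < 2:
        raise ValueError("category enrichment needs at least 2 categories")
    is_match = table["is_match"].astype(bool).to_numpy()
    rows = []
    for cat in cats:
        in_cat = (table["category"] == cat).to_numpy()
        a = int(np.sum(in_cat & is_match))
        b = int(np.sum(in_cat & ~is_match))
        c = int(np.sum(~in_cat & is_match))
        d = int(np.sum(~in_cat & ~is_match))
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        odds = _sample_odds_ratio(a, b, c, d)
        if min(a, b, c, d) > 0:
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            ci_low = float(np.exp(np.log(odds) - 1.959963984540054 * se))
            ci_high = float(np.exp(np.log(odds) + 1.959963984540054 * se))
        else:
            ci_low = ci_high = float("nan")
        rows.append(
            {
                "category": cat, "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": odds, "ci_low": ci_low, "ci_high": ci_high,
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# bivariate
# ---------------------------------------------------------------------------

def compare_counts(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing two count samples.

    Exact null distribution for small tie-free samples; midranks with the
    normal approximation (tie-corrected) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "asymptotic" if (has_ties or min(x.size, y.size) > 50) else "exact"
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def correlate(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance sample")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class MatchModelResult:
    """Fitted logistic model of match status (log-odds scale).

    ``params``, ``bse`` and ``conf_int`` are indexed by feature name
    (continuous features are per-standard-deviation effects; categorical
    features are one-hot contrasts against the declared reference level).
    """

    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame    # columns: ci_low, ci_high
    n: int
    converged: bool
    features: list[str]
    llf: float

    def frame(self) -> pd.DataFrame:
        """feature / estimate / ci_low / ci_high / se table."""
        return pd.DataFrame(
            {
                "feature": self.params.index,
                "estimate": self.params.to_numpy(),
                "ci_low": self.conf_int["ci_low"].to_numpy(),
                "ci_high": self.conf_int["ci_high"].to_numpy(),
                "se": self.bse.to_numpy(),
            }
        ).reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            f"Logistic model of match status (n={self.n}, "
            f"converged={self.converged}, llf={self.llf:.2f})",
            f"{'feature':<28}{'estimate':>10}{'ci_low':>10}{'ci_high':>10}",
        ]
        for _, row in self.frame().iterrows():
            lines.append(
                f"{row['feature']:<28}{row['estimate']:>10.3f}"
                f"{row['ci_low']:>10.3f}{row['ci_high']:>10.3f}"
            )
        return "\n".join(lines)


def fit_match_model(
    table: pd.DataFrame,
    *,
    outcome: str = "is_match",
    continuous: tuple[str, ...] = DEFAULT_CONTINUOUS,
    binary: tuple[str, ...] = DEFAULT_BINARY,
    categorical: dict[str, str] | None = None,
) -> MatchModelResult:
    """Maximum-likelihood logistic regression of match status on features.

    Parameters
    ----------
    table
        One row per model-disease pair (or per gene, if that is the chosen
        unit); must contain the outcome and every requested feature.
    outcome
        Binary column (0/1 or bool); both classes must be present.
    continuous
        Columns standardised to z-scores before fitting.
    binary
        0/1 indicator columns entered as-is.
    categorical
        Mapping column -> reference level; one-hot encoded with the
        reference dropped.

    Raises
    ------
    ValueError
        Outcome single-class, or a feature constant.
    SeparationError
        Complete separation detected (the MLE diverges).
    """
    categorical = categorical or {}
    y = table[outcome].astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("outcome has a single class; cannot fit")

    design = {}
    for col in continuous:
        v = table[col].astype(float).to_numpy()
        sd = v.std()
        if sd == 0:
            raise ValueError(f"feature {col!r} is constant")
        design[col] = (v - v.mean()) / sd
    for col in binary:
        v = table[col].astype(int).to_numpy()
        if v.min() == v.max():
            raise ValueError(f"feature {col!r} is constant")
        design[col] = v.astype(float)
    for col, ref in categorical.items():
        levels = sorted(table[col].astype(str).unique())
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from {col!r}")
        if len(levels) < 2:
            raise ValueError(f"feature {col!r} is constant")
        for lev in levels:
            if lev == ref:
                continue
            design[f"{col}[{lev}]"] = (
                (table[col].astype(str) == lev).astype(float).to_numpy()
            )

    X = pd.DataFrame(design)
    X.insert(0, "intercept", 1.0)
    try:
        with warnings.catch_warnings():
            # convergence is checked explicitly below; separation is an error
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as err:
        raise SeparationError(
            "complete separation detected; remove the offending feature "
            "or use a penalised fit"
        ) from err
    converged = bool(fit.mle_retvals.get("converged", False))
    # runaway coefficients are the quasi-separation signature statsmodels
    # sometimes lets through without raising
    if not converged and np.max(np.abs(fit.params.to_numpy())) > 50:
        raise SeparationError(
            "fit did not converge and coefficients diverged; data are "
            "(quasi-)separated"
        )
    ci = fit.conf_int(alpha=0.05)
    ci.columns = ["ci_low", "ci_high"]
    return MatchModelResult(
        params=fit.params,
        bse=fit.bse,
        conf_int=ci,
        n=int(len(y)),
        converged=converged,
        features=list(X.columns),
        llf=float(fit.llf),
    )
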