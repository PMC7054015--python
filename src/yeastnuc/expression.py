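"""Expression statistics: baselines, fold changes and position-expression trends.

The analyses relate measured expression changes (gene x strain log2 fold
changes over a cross-strain baseline) to predicted changes in nuclear
position (delta % peripheral, in percentage points, from the structural
models).  They comprise:

* a robust per-gene baseline: the median across strains in which the gene
  is predicted to move by less than 1 percentage point, of the per-strain
  replicate medians (falling back to the wild-type median when no strain
  qualifies);
* log2 fold changes against that baseline with a configurable pseudocount;
* LOESS and binned-group trends of fold change vs delta % peripheral with
  ANOVA + Tukey HSD contrasts against the non-displaced group;
* counts of predicted movers (|delta %P| > 5 pp) with significant
  per-gene expression changes (Welch t-test, p < 0.05);
* a sequential (type-I) ANOVA asking whether centromere covariates add
  predictive power once delta %P and wild-type expression are in the model;
* moving-window r^2 comparisons of delta %P against distance to the
  deleted telomere as predictors of fold change; and
* resampled correlation contrasts of % peripheral vs distance-to-telomere
  against wild-type expression levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ExpressionTable",
    "baseline_expression",
    "log2_fold_change",
    "position_trend",
    "binned_group_analysis",
    "count_significant_movers",
    "sequential_anova_cen",
    "windowed_r2_comparison",
    "resampled_correlation_comparison",
    "PSEUDOCOUNT_TPM",
]

#: pseudocount added inside log ratios to tame low-TPM noise
PSEUDOCOUNT_TPM = 0.1
#: strains where a gene moves less than this (pp) are baseline-eligible
BASELINE_ELIGIBLE_PP = 1.0
#: genes predicted to move more than this (pp) count as movers
MOVER_THRESHOLD_PP = 5.0


@dataclass
class ExpressionTable:
    """A genes x samples TPM matrix with strain/replicate sample metadata.

    ``values`` is indexed by gene with one column per sample; ``samples``
    maps each column to a ``strain`` and ``replicate``.  NaN marks genes
    absent from a sample's strain (deleted by a fusion).
    """

    values: pd.DataFrame
    samples: pd.DataFrame  # index = sample name; columns: strain, replicate

    def __post_init__(self) -> None:
        if not set(self.values.columns) == set(self.samples.index):
            raise ValueError("sample metadata does not match the matrix columns")
        if (self.values.fillna(0.0) < 0).any().any():
            raise ValueError("abundances must be non-negative")

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.samples["strain"]))

    def strain_columns(self, strain: str) -> list[str]:
        return list(self.samples.index[self.samples["strain"] == strain])

    def strain_medians(self) -> pd.DataFrame:
        """Per-gene median across replicates, one column per strain."""
        return pd.DataFrame(
            {s: self.values[self.strain_columns(s)].median(axis=1) for s in self.strains}
        )

    def to_tsv(self) -> str:
        """Matrix as TSV with ``strain_replicate`` column headers."""
        df = self.values.copy()
        df.columns = [
            f"{self.samples.loc[c, 'strain']}_{self.samples.loc[c, 'replicate']}"
            for c in df.columns
        ]
        return df.to_csv(sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, text_or_path) -> "ExpressionTable":
        """Read a TSV whose headers are ``strain_replicate`` labels."""
        df = pd.read_csv(text_or_path, sep="\t", index_col=0)
        meta = []
        for c in df.columns:
            strain, _, rep = c.rpartition("_")
            meta.append({"sample": c, "strain": strain, "replicate": int(rep)})
        samples = pd.DataFrame(meta).set_index("sample")
        return cls(values=df, samples=samples)


def baseline_expression(
    expr: ExpressionTable,
    delta_pp: pd.DataFrame,
    wt_strain: str = "WT",
    eligible_pp: float = BASELINE_ELIGIBLE_PP,
) -> pd.Series:
    """Cross-strain baseline expression per gene.

    ``delta_pp`` is genes x strains of predicted delta % peripheral
    (strain minus wild type, percentage points).  For each gene the
    baseline is the median over strains with |delta| < ``eligible_pp`` of
    that strain's replicate median; if no strain qualifies the wild-type
    replicate median is used.  Genes absent everywhere are dropped.
    """
    med = expr.strain_medians()
    out = {}
    for gene in expr.values.index:
        if not np.isfinite(med.loc[gene]).any():
            continue  # gene absent everywhere
        vals = []
        for strain in med.columns:
            if strain == wt_strain:
                d = 0.0
            elif strain in delta_pp.columns and gene in delta_pp.index:
                d = delta_pp.loc[gene, strain]
            else:
                continue
            if np.isfinite(d) and abs(d) < eligible_pp and np.isfinite(med.loc[gene, strain]):
                vals.append(med.loc[gene, strain])
        out[gene] = float(np.median(vals)) if vals else float(med.loc[gene, wt_strain])
    return pd.Series(out, name="baseline")


def log2_fold_change(
    expr: ExpressionTable,
    baseline: pd.Series,
    pseudocount: float = PSEUDOCOUNT_TPM,
) -> pd.DataFrame:
    """Per gene x strain log2((strain median + c) / (baseline + c))."""
    med = expr.strain_medians()
    med = med.loc[med.index.intersection(baseline.index)]
    base = baseline.loc[med.index]
    return np.log2(med.add(pseudocount).div(base + pseudocount, axis=0))


def position_trend(
    delta_pp: np.ndarray,
    lfc: np.ndarray,
    window: int = 100,
) -> pd.DataFrame:
    """Robust LOESS trend of fold change over delta % peripheral.

    Points are sorted by delta %P and smoothed with a robust locally
    weighted fit whose span corresponds to ``window`` points (shrunk, with
    a warning, below ``window`` points).  Returns the sorted x with the
    fitted trend.
    """
    x = np.asarray(delta_pp, dtype=float)
    y = np.asarray(lfc, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n == 0:
        raise ValueError("no finite points to smooth")
    if n < window:
        import warnings

        warnings.warn(f"window shrunk from {window} to {n} points")
    frac = min(1.0, window / n)
    fitted = sm.nonparametric.lowess(y, x, frac=frac, it=3, return_sorted=True)
    return pd.DataFrame({"delta_pp": fitted[:, 0], "lfc_trend": fitted[:, 1]})


DEFAULT_GROUP_EDGES = (-np.inf, -15.0, -5.0, -1.0, 1.0)
GROUP_LABELS = ("< -15 pp", "-15 to -5 pp", "-5 to -1 pp", "non-displaced")


def binned_group_analysis(
    delta_pp: np.ndarray,
    lfc: np.ndarray,
    edges: Sequence[float] = DEFAULT_GROUP_EDGES,
    labels: Sequence[str] = GROUP_LABELS,
    reference: str = "non-displaced",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group fold changes by predicted peripheral decrease; ANOVA + Tukey HSD.

    Returns (group summary, Tukey contrasts).  The summary has per-group n,
    mean and SE plus the one-way ANOVA F and p in its attrs; the contrasts
    table keeps only comparisons involving the ``reference``
    (non-displaced) group.
    """
    x = np.asarray(delta_pp, dtype=float)
    y = np.asarray(lfc, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    group = pd.cut(x, bins=list(edges), labels=list(labels), right=True)
    sel = ~group.isna()
    y = y[np.asarray(sel)]
    group = group[sel].astype(str)
    df = pd.DataFrame({"group": group, "lfc": y})
    summary = (
        df.groupby("group", sort=False)["lfc"]
        .agg(n="size", mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reindex(list(labels))
    )
    groups = [df.loc[df["group"] == g, "lfc"].to_numpy() for g in labels if (df["group"] == g).any()]
    if len(groups) >= 2:
        F, p = stats.f_oneway(*groups)
    else:
        F, p = np.nan, np.nan
    summary.attrs["anova_F"] = float(F)
    summary.attrs["anova_p"] = float(p)
    tk = pairwise_tukeyhsd(df["lfc"].to_numpy(), df["group"].to_numpy())
    contrasts = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    contrasts = contrasts[
        (contrasts["group1"] == reference) | (contrasts["group2"] == reference)
    ].reset_index(drop=True)
    return summary, contrasts


def count_significant_movers(
    expr: ExpressionTable,
    delta_pp: pd.DataFrame,
    wt_strain: str = "WT",
    mover_pp: float = MOVER_THRESHOLD_PP,
    alpha: float = 0.05,
    eligible_pp: float = BASELINE_ELIGIBLE_PP,
    pseudocount: float = PSEUDOCOUNT_TPM,
    equal_var: bool = False,
) -> dict:
    """Count predicted movers with significant expression changes.

    A gene x strain pair is a mover when |delta %P| > ``mover_pp``; it is
    tested by a two-sample t-test (Welch by default) on log2(TPM + c)
    between the strain's replicates and the replicates of all
    baseline-eligible strains for that gene.  Pairs with fewer than two
    replicates on either side are skipped (and counted).
    """
    n_movers = n_signif = n_skipped = 0
    tested: list[tuple[str, str, float]] = []
    log_vals = np.log2(expr.values + pseudocount)
    strain_cols = {s: expr.strain_columns(s) for s in expr.strains}
    for strain in delta_pp.columns:
        if strain == wt_strain or strain not in strain_cols:
            continue
        dcol = delta_pp[strain]
        movers = dcol.index[np.abs(dcol) > mover_pp]
        for gene in movers:
            if gene not in log_vals.index:
                continue
            n_movers += 1
            a = log_vals.loc[gene, strain_cols[strain]].dropna().to_numpy()
            ref_cols: list[str] = []
            for s2 in expr.strains:
                if s2 == strain:
                    continue
                d2 = 0.0 if s2 == wt_strain else delta_pp.loc[gene, s2] if s2 in delta_pp.columns else np.nan
                if np.isfinite(d2) and abs(d2) < eligible_pp:
                    ref_cols.extend(strain_cols[s2])
            if not ref_cols:
                ref_cols = strain_cols[wt_strain]
            b = log_vals.loc[gene, ref_cols].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                n_skipped += 1
                continue
            p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
            tested.append((gene, strain, float(p)))
            if p < alpha:
                n_signif += 1
    return {
        "n_movers": n_movers,
        "n_tested": len(tested),
        "n_significant": n_signif,
        "n_skipped": n_skipped,
        "tests": pd.DataFrame(tested, columns=["gene", "strain", "p"]),
    }


CEN_DIST_SUBSETS = (np.inf, 200.0, 100.0, 75.0, 15.0)


def sequential_anova_cen(
    results: pd.DataFrame,
    subsets_kb: Sequence[float] = CEN_DIST_SUBSETS,
) -> dict[str, pd.DataFrame]:
    """Sequential (type-I) ANOVA of fold change on position and CEN covariates.

    ``results`` needs columns ``lfc``, ``delta_pp``, ``wt_expr``,
    ``cen_dist_kb`` and boolean ``cen_lost``.  Terms enter in the order
    delta %P, WT expression, CEN distance, CEN lost, CEN distance x CEN
    lost, so each F tests the marginal gain over the preceding terms.  The
    model is fitted on all genes and on subsets within each
    ``subsets_kb`` distance of the centromere.
    """
    needed = {"lfc", "delta_pp", "wt_expr", "cen_dist_kb", "cen_lost"}
    if not needed <= set(results.columns):
        raise ValueError(f"missing columns: {needed - set(results.columns)}")
    out = {}
    for cut in subsets_kb:
        sub = results[np.isfinite(results["lfc"]) & np.isfinite(results["delta_pp"])]
        sub = sub[sub["cen_dist_kb"] <= cut]
        label = "all" if np.isinf(cut) else f"<={cut:g}kb"
        if len(sub) < 10:
            out[label] = pd.DataFrame()
            continue
        d = sub.assign(cen_lost=sub["cen_lost"].astype(float))
        if d["lfc"].std(ddof=0) == 0:
            tbl = pd.DataFrame(
                {"F": 0.0, "PR(>F)": 1.0},
                index=["delta_pp", "wt_expr", "cen_dist_kb", "cen_lost", "cen_dist_kb:cen_lost"],
            )
            out[label] = tbl
            continue
        model = smf.ols(
            "lfc ~ delta_pp + wt_expr + cen_dist_kb + cen_lost + cen_dist_kb:cen_lost",
            data=d,
        ).fit()
        out[label] = sm.stats.anova_lm(model, typ=1)
    return out


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def windowed_r2_comparison(
    results: pd.DataFrame,
    window_kb: float = 20.0,
    step_kb: float = 5.0,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Moving-window r^2 of two single-predictor models of fold change.

    ``results`` needs ``lfc``, ``delta_pp`` and ``dist_deleted_tel_kb``
    (distance of the gene to the deleted telomere, on fused arms only).
    For each window centre X the genes within X +/- window/2 are fitted by
    lfc ~ delta %P and by lfc ~ log(distance); positive
    ``log2_r2_ratio`` means delta %P is the better predictor there.
    """
    d = results[
        np.isfinite(results["lfc"])
        & np.isfinite(results["delta_pp"])
        & np.isfinite(results["dist_deleted_tel_kb"])
    ]
    dist = d["dist_deleted_tel_kb"].to_numpy()
    half = window_kb / 2.0
    centres = np.arange(half, dist.max() + step_kb, step_kb)
    rows = []
    for c in centres:
        sel = (dist >= c - half) & (dist <= c + half)
        if sel.sum() < min_genes:
            continue
        y = d["lfc"].to_numpy()[sel]
        r2_pp = _r2(d["delta_pp"].to_numpy()[sel], y)
        r2_dist = _r2(np.log(dist[sel] + 1.0), y)
        rows.append(
            {
                "centre_kb": float(c),
                "n_genes": int(sel.sum()),
                "r2_delta_pp": r2_pp,
                "r2_dist_tel": r2_dist,
                "log2_r2_ratio": np.log2(r2_pp / r2_dist)
                if (r2_pp and r2_dist and np.isfinite(r2_pp) and np.isfinite(r2_dist))
                else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["centre_kb", "n_genes", "r2_delta_pp", "r2_dist_tel", "log2_r2_ratio"],
    )


def resampled_correlation_comparison(
    wt_expression: pd.Series,
    percent_peripheral: pd.Series,
    dist_telomere_kb: pd.Series,
    n_resamples: int = 1000,
    frac: float = 0.9,
    seed: int = 0,
    log_expression: bool = True,
    pseudocount: float = PSEUDOCOUNT_TPM,
) -> dict:
    """Resampled |correlation| of expression with position vs telomere distance.

    Draws ``n_resamples`` random subsets of ``frac`` of the genes and, in
    each, records the absolute Pearson correlation of (log) wild-type
    expression with % peripheral, with log distance-to-telomere and with
    linear distance, overall and stratified by expression quartile.
    Also returns binned-median expression curves for the two predictors
    and the standardized bivariate linear model of expression on both.
    """
    genes = wt_expression.index.intersection(percent_peripheral.index).intersection(
        dist_telomere_kb.index
    )
    expr = wt_expression.loc[genes].astype(float)
    e = np.log2(expr + pseudocount) if log_expression else expr
    pp = percent_peripheral.loc[genes].astype(float)
    dk = dist_telomere_kb.loc[genes].astype(float)
    ok = np.isfinite(e) & np.isfinite(pp) & np.isfinite(dk)
    e, pp, dk = e[ok].to_numpy(), pp[ok].to_numpy(), dk[ok].to_numpy()
    logd = np.log(dk + 1.0)
    n = len(e)
    rng = np.random.default_rng(seed)
    quart = pd.qcut(e, 4, labels=False, duplicates="drop")
    strata = {"all": np.arange(n)} | {
        f"expr_q{q + 1}": np.flatnonzero(quart == q) for q in np.unique(quart)
    }
    m = int(round(frac * n))
    recs = []
    for it in range(n_resamples):
        take = rng.choice(n, size=m, replace=False)
        for name, idx in strata.items():
            sub = np.intersect1d(take, idx, assume_unique=False)
            if len(sub) < 5:
                continue
            recs.append(
                {
                    "resample": it,
                    "stratum": name,
                    "abs_corr_pct_peripheral": abs(np.corrcoef(e[sub], pp[sub])[0, 1]),
                    "abs_corr_log_dist": abs(np.corrcoef(e[sub], logd[sub])[0, 1]),
                    "abs_corr_linear_dist": abs(np.corrcoef(e[sub], dk[sub])[0, 1]),
                }
            )
    resamples = pd.DataFrame(recs)

    def _binned_median(x: np.ndarray, nbins: int = 20) -> pd.DataFrame:
        bins = pd.qcut(x, nbins, duplicates="drop")
        return (
            pd.DataFrame({"bin_centre": x, "expr": expr[ok].to_numpy()})
            .groupby(bins, observed=True)
            .median()
            .reset_index(drop=True)
        )

    X = sm.add_constant(
        np.column_stack([(pp - pp.mean()) / pp.std(), (logd - logd.mean()) / logd.std()])
    )
    biv = sm.OLS(e, X).fit()
    bivariate = pd.DataFrame(
        {
            "coef": biv.params[1:],
            "t": biv.tvalues[1:],
            "p": biv.pvalues[1:],
        },
        index=["pct_peripheral_std", "log_dist_tel_std"],
    )
    return {
        "resamples": resamples,
        "binned_by_pct_peripheral": _binned_median(pp),
        "binned_by_dist_tel": _binned_median(dk),
        "bivariate_model": bivariate,
        "full_corr": {
            "pct_peripheral": float(np.corrcoef(e, pp)[0, 1]),
            "log_dist": float(np.corrcoef(e, logd)[0, 1]),
            "linear_dist": float(np.corrcoef(e, dk)[0, 1]),
        },
    }
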