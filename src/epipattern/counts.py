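"""Negative-binomial differential testing for count features.

Used for both RRHP strand-specific CCGG tag counts (differential
hydroxymethylation, DHML) and RNA gene counts (differential expression,
DEG). Counts are normalised by median-of-ratios size factors, per-feature
dispersions are estimated by method of moments and shrunk toward a fitted
mean-dispersion trend d(mu) = a/mu + b, and group differences are tested
with a Wald statistic on the log2 scale. A feature is significant when the
BH-adjusted p-value is below ``alpha`` and |log2 fold change| >= 1 (at
least 2-fold in either direction).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .multitest import benjamini_hochberg

DISPERSION_FLOOR = 1e-8
TREND_SHRINK_K = 4
PSEUDOCOUNT = 0.5  # fold-change point estimate only, never inference


def _as_counts(counts):
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.index), list(counts.columns)
    arr = np.asarray(counts, dtype=float)
    return arr, list(range(arr.shape[0])), list(range(arr.shape[1]))


def size_factors(counts) -> np.ndarray:
    """Median-of-ratios normalisation factors, scaled to geometric mean 1.

    Per sample, the median over features (restricted to features positive in
    every sample) of count / geometric-mean-across-samples. Falls back to
    total-count ratios when no feature is positive everywhere.
    """
    arr, _, _ = _as_counts(counts)
    if arr.ndim != 2 or arr.shape[1] < 1:
        raise ValueError("counts must be a features x samples matrix")
    if np.any(arr.sum(axis=0) == 0):
        raise ValueError("a sample has all-zero counts; cannot normalise")
    all_pos = np.all(arr > 0, axis=1)
    if np.any(all_pos):
        sub = arr[all_pos]
        log_gm = np.mean(np.log(sub), axis=1)
        ratios = np.log(sub) - log_gm[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        totals = arr.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    return factors / np.exp(np.mean(np.log(factors)))


def _fit_trend(mu: np.ndarray, disp: np.ndarray):
    """Least squares of raw dispersion on a/mu + b, a,b > 0.

    The fit is on the raw scale because the method-of-moments estimates are
    approximately unbiased there; a log-scale fit is pulled far below the
    true trend by the very noisy small estimates (Jensen's inequality) and
    makes the downstream Wald test anticonservative.
    """
    use = mu > 0
    if use.sum() < 10:
        return None
    x, y = mu[use], disp[use]

    def resid(theta):
        a, b = np.exp(theta)
        return (a / x + b) - y

    try:
        sol = optimize.least_squares(
            resid, x0=[0.0, np.log(max(float(np.mean(y)), 1e-4))],
            max_nfev=200)
        a, b = np.exp(sol.x)
        if not (np.isfinite(a) and np.isfinite(b)):
            return None
        return a, b
    except Exception:
        return None


def _dispersion_detail(arr: np.ndarray, sf: np.ndarray, groups: np.ndarray):
    """Shrunk dispersion plus the sampling variance of the estimate.

    Returns ``(d, var_d, df)`` where ``var_d`` approximates Var(d_hat) per
    feature from Var(s^2) = sigma^4 * (2/df + kappa/n) with kappa the NB
    excess kurtosis at the fitted (mu, d); used by the Wald test to absorb
    plug-in noise in the denominator.
    """
    uniq = np.unique(groups)
    for g in uniq:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    q = arr / sf[None, :]
    n = arr.shape[1]

    mu = q.mean(axis=1)
    # group-wise moments so genuinely differential features do not inflate
    # their own dispersion: E[sum_s (q_s - qbar_g)^2] =
    # (ng-1)/ng * sum_s (mu_g/sf_s + d mu_g^2)
    resid2 = np.zeros(arr.shape[0])
    shot_part = np.zeros(arr.shape[0])
    d_part = np.zeros(arr.shape[0])
    df = 0
    for g in uniq:
        cols = groups == g
        ng = cols.sum()
        qg = q[:, cols]
        mu_g = qg.mean(axis=1)
        resid2 += ((qg - mu_g[:, None]) ** 2).sum(axis=1)
        shot_part += (ng - 1) / ng * mu_g * np.sum(1.0 / sf[cols])
        d_part += (ng - 1) * mu_g**2
        df += ng - 1
    df = max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_raw = (resid2 - shot_part) / np.maximum(d_part, 1e-12)
    d_raw = np.clip(np.nan_to_num(d_raw), DISPERSION_FLOOR, None)

    fit = _fit_trend(mu, d_raw)
    if fit is None:
        warnings.warn("too few features for a dispersion trend; "
                      "using the global mean dispersion")
        trend = np.full_like(d_raw, max(float(d_raw.mean()), DISPERSION_FLOOR))
    else:
        a, b = fit
        trend = a / np.maximum(mu, 1e-12) + b
    w = n / (n + TREND_SHRINK_K)
    d = np.clip(w * d_raw + (1 - w) * trend, DISPERSION_FLOOR, None)

    mm = np.maximum(mu, 1e-12)
    r = 1.0 / np.maximum(d, DISPERSION_FLOOR)
    p_nb = r / (r + mm)
    kurt = 6.0 / r + p_nb**2 / (r * (1 - p_nb))
    resid2_model = shot_part + d * d_part
    var_d = (w**2 * (2.0 / df + kurt / n) * resid2_model**2
             / np.maximum(d_part, 1e-12) ** 2)
    return d, var_d, df


def nb_dispersion(counts, sf, group_labels) -> np.ndarray:
    """Per-feature NB dispersion with mean-trend shrinkage.

    Method of moments on normalised counts q = K/sf: within-group residual
    variance s2 satisfies s2 ~= mu * mean(1/sf) + d * mu^2, solved for d and
    floored at 1e-8, then shrunk toward the fitted trend d(mu) = a/mu + b
    with weight w = n/(n+4). With fewer than 10 usable features the trend
    falls back to the global mean dispersion (with a warning).
    """
    arr, _, _ = _as_counts(counts)
    d, _, _ = _dispersion_detail(
        arr, np.asarray(sf, dtype=float), np.asarray(group_labels))
    return d


class NegativeBinomialDE:
    """Two-group negative-binomial differential model for count features.

    Parameters
    ----------
    counts : DataFrame or array, features x samples
    group_labels : sequence of two distinct labels, one per sample column;
        log2fc is group B over group A (sorted label order).
    """

    def __init__(self, counts, group_labels):
        self.arr, self.feature_ids, self.sample_ids = _as_counts(counts)
        if np.any(self.arr < 0) or np.any(self.arr != np.round(self.arr)):
            raise ValueError("counts must be non-negative integers")
        self.groups = np.asarray(group_labels)
        uniq = sorted(set(self.groups.tolist()))
        if len(uniq) != 2:
            raise ValueError("exactly two groups required")
        for g in uniq:
            if (self.groups == g).sum() < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
        self.group_a, self.group_b = uniq

    @classmethod
    def from_table(cls, table: pd.DataFrame, group_a: list[str], group_b: list[str]):
        samples = list(group_a) + list(group_b)
        labels = ["A"] * len(group_a) + ["B"] * len(group_b)
        return cls(table[samples], labels)

    def fit(self, alpha: float = 0.05, lfc_threshold: float = 1.0) -> "NBResults":
        arr, groups = self.arr, self.groups
        nonzero = arr.sum(axis=1) > 0
        sub = arr[nonzero]
        sf = size_factors(sub)
        disp, var_disp, _ = _dispersion_detail(sub, sf, groups)
        q = sub / sf[None, :]

        ln2 = np.log(2.0)
        means, variances = {}, {}
        dvar_dd = np.zeros(sub.shape[0])  # d SE^2 / d dispersion (log2 scale)
        for g in (self.group_a, self.group_b):
            cols = groups == g
            ng = cols.sum()
            qg = q[:, cols]
            qbar = qg.mean(axis=1)
            # floor the plug-in mean at "one read in the whole group" so an
            # all-zero group still yields a finite, conservative SE
            mu = np.maximum(qbar, 1.0 / sf[cols].sum())
            var_qbar = (mu[:, None] / sf[None, cols] + disp[:, None] * mu[:, None] ** 2
                        ).sum(axis=1) / ng**2
            means[g] = (qbar, mu)
            variances[g] = var_qbar / (mu * ln2) ** 2
            dvar_dd += (mu**2 * ng) / ng**2 / (mu * ln2) ** 2

        qa, mua = means[self.group_a]
        qb, mub = means[self.group_b]
        log2fc = np.log2((qb + PSEUDOCOUNT) / (qa + PSEUDOCOUNT))
        se2 = variances[self.group_a] + variances[self.group_b]
        # first-order absorption of dispersion-estimation noise into the SE
        se = np.sqrt(se2 * (1.0 + dvar_dd**2 * var_disp / se2**2))
        z = (np.log2(mub) - np.log2(mua)) / se
        p = 2 * stats.norm.sf(np.abs(z))
        padj = benjamini_hochberg(p)
        significant = (padj < alpha) & (np.abs(log2fc) >= lfc_threshold)

        frame = pd.DataFrame(
            {
                "feature_id": [f for f, keep in zip(self.feature_ids, nonzero) if keep],
                "base_mean": q.mean(axis=1),
                "log2fc": log2fc,
                "se": se,
                "wald_z": z,
                "p": p,
                "padj": padj,
                "significant": significant,
                "dispersion": disp,
            }
        )
        return NBResults(frame, alpha=alpha, lfc_threshold=lfc_threshold,
                         size_factors=pd.Series(sf, index=self.sample_ids),
                         n_input=arr.shape[0])


class NBResults:
    """Per-feature NB Wald-test estimates and significance calls."""

    def __init__(self, frame, alpha, lfc_threshold, size_factors, n_input):
        self.frame = frame
        self.alpha = alpha
        self.lfc_threshold = lfc_threshold
        self.size_factors = size_factors
        self.n_input = n_input

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]]

    def summary(self) -> str:
        sig = self.significant
        lines = [
            "Negative-binomial differential test (Wald)",
            "=" * 50,
            f"features tested:   {len(self.frame)} of {self.n_input} "
            "(all-zero features excluded)",
            f"alpha (BH):        {self.alpha}",
            f"min |log2FC|:      {self.lfc_threshold}",
            f"significant:       {len(sig)}",
            f"  up   (log2fc>0): {int((sig['log2fc'] > 0).sum())}",
            f"  down (log2fc<0): {int((sig['log2fc'] < 0).sum())}",
            f"median dispersion: {float(np.median(self.frame['dispersion'])):.4g}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def nb_wald_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Functional wrapper returning the NB Wald-test result frame."""
    model = NegativeBinomialDE.from_table(counts, group_a, group_b)
    return model.fit(alpha=alpha, lfc_threshold=lfc_threshold).frame


def call_dhml(
    tag_table: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Differential hydroxymethylation on strand-specific CCGG tag counts.

    Identical machinery to :func:`nb_wald_test`; features are keyed
    ``chrom:pos:strand`` and the two strands of a CCGG site are tested as
    separate loci, never merged.
    """
    return nb_wald_test(tag_table, group_a, group_b, alpha, lfc_threshold)
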