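"""Differential methylation loci (DML) from RRBS-style counts.

Two-group beta-binomial Wald test with empirical-Bayes dispersion shrinkage.
Per CpG locus the methylated-read count given coverage c is modelled
beta-binomial with mean mu and dispersion phi, i.e. variance
c*mu*(1-mu)*(1+(c-1)*phi). Per-locus method-of-moments dispersions are
shrunk toward the trimmed mean across loci, group means are
coverage-weighted, and the Wald statistic Delta/SE is referred to the
normal distribution. A locus is called a DML when the BH-adjusted p-value
is below ``alpha`` and the methylation difference is at least ``min_delta``
(default 10 percentage points).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .multitest import benjamini_hochberg

DISPERSION_FLOOR = 1e-4
DISPERSION_CAP = 0.5
SHRINKAGE_K = 4  # prior weight: w = n / (n + k)
TRIM_FRACTION = 0.1


def _as_matrices(meth, total):
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    if meth.shape != total.shape:
        raise ValueError("meth and total must have the same shape")
    if np.any(meth < 0) or np.any(total < 0) or np.any(meth > total):
        raise ValueError("need 0 <= methylated <= total at every cell")
    return meth, total


def estimate_locus_dispersion(
    meth,
    total,
    group_labels,
    min_coverage: int = 5,
    _detail: bool = False,
):
    """Shrunk per-locus beta-binomial dispersion.

    Method-of-moments per locus: with p_s = m_s/c_s and group means mu_g,
    Var(p_s) = mu(1-mu) * (1/c_s + phi*(1-1/c_s)), so phi is solved from the
    residual variance, floored at 1e-4. The estimate is then shrunk toward
    the 10%-trimmed mean across loci with weight w = n_l/(n_l+4), n_l being
    the samples meeting ``min_coverage`` at the locus, and clipped to
    (0, 0.5].
    """
    meth, total = _as_matrices(meth, total)
    groups = np.asarray(group_labels)
    uniq = np.unique(groups)
    if len(uniq) < 1 or meth.shape[1] != len(groups):
        raise ValueError("group_labels must label every sample column")
    for g in uniq:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    ok = total >= min_coverage
    n_l = ok.sum(axis=1)
    if not np.any(n_l > 0):
        raise ValueError("all loci fall below the coverage floor")

    with np.errstate(divide="ignore", invalid="ignore"):
        phat = np.where(ok, meth / np.where(total > 0, total, 1), np.nan)
    # group-wise moments so genuinely differential loci do not inflate their
    # own dispersion: E[sum_s (p_s - mu_g)^2] =
    # (ng-1)/ng * mu_g(1-mu_g) * sum_s (1/c_s + phi (1 - 1/c_s))
    resid2 = np.zeros(meth.shape[0])
    binom_part = np.zeros(meth.shape[0])
    phi_part = np.zeros(meth.shape[0])
    df = np.zeros(meth.shape[0])
    for g in uniq:
        cols = groups == g
        okg = ok[:, cols]
        ng = np.maximum(okg.sum(axis=1), 1)
        mg = np.where(okg, meth[:, cols], 0).sum(axis=1)
        cg_tot = np.where(okg, total[:, cols], 0).sum(axis=1)
        mu_g = np.clip(np.divide(mg, np.maximum(cg_tot, 1)), 0.01, 0.99)
        r = np.where(okg, (phat[:, cols] - mu_g[:, None]) ** 2, 0.0)
        resid2 += np.nan_to_num(r).sum(axis=1)
        inv_sum = np.where(okg, 1.0 / np.maximum(total[:, cols], 1), 0.0).sum(axis=1)
        v = mu_g * (1 - mu_g) * (ng - 1) / ng
        binom_part += v * inv_sum
        phi_part += v * (okg.sum(axis=1) - inv_sum)
        df += np.maximum(okg.sum(axis=1) - 1, 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = (resid2 - binom_part) / np.maximum(phi_part, 1e-12)
    phi_raw = np.clip(np.nan_to_num(phi_raw), DISPERSION_FLOOR, DISPERSION_CAP)
    # loci with no usable residual df fall back to the floor before shrinkage
    phi_raw = np.where(df > 0, phi_raw, DISPERSION_FLOOR)

    prior = float(stats.trim_mean(phi_raw[n_l > 0], TRIM_FRACTION))
    w = n_l / (n_l + SHRINKAGE_K)
    phi_hat = np.clip(w * phi_raw + (1 - w) * prior, DISPERSION_FLOOR,
                      DISPERSION_CAP)
    if not _detail:
        return phi_hat
    # sampling variance of phi_hat via Var(resid2) ~= 2 E[resid2]^2 / df
    resid2_model = binom_part + phi_hat * phi_part
    var_phi = (w**2 * 2.0 * resid2_model**2
               / (np.maximum(df, 1) * np.maximum(phi_part, 1e-12) ** 2))
    return phi_hat, var_phi


class BetaBinomialDML:
    """Two-group beta-binomial differential methylation model.

    Parameters
    ----------
    meth, total : array-like or DataFrame, loci x samples
        Methylated and total read counts; columns are samples.
    group_labels : sequence
        Group label per sample column; exactly two distinct labels. The
        first label in sorted order is group A, the second group B, and
        ``delta = mu_B - mu_A``.
    loci : DataFrame, optional
        Locus coordinates (chrom, pos, strand) carried into the results.
    """

    def __init__(self, meth, total, group_labels, loci: pd.DataFrame | None = None):
        if isinstance(meth, pd.DataFrame):
            self.sample_ids = list(meth.columns)
            meth = meth.to_numpy()
        else:
            self.sample_ids = None
        if isinstance(total, pd.DataFrame):
            total = total.to_numpy()
        self.meth, self.total = _as_matrices(meth, total)
        self.groups = np.asarray(group_labels)
        uniq = sorted(set(self.groups.tolist()))
        if len(uniq) != 2:
            raise ValueError("exactly two groups required")
        for g in uniq:
            if (self.groups == g).sum() < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
        self.group_a, self.group_b = uniq
        self.loci = loci

    @classmethod
    def from_table(cls, table: pd.DataFrame, group_a: list[str], group_b: list[str]):
        """Build from a methylation count table with ``meth_<id>`` /
        ``total_<id>`` columns."""
        samples = list(group_a) + list(group_b)
        meth = table[[f"meth_{s}" for s in samples]].to_numpy()
        total = table[[f"total_{s}" for s in samples]].to_numpy()
        labels = ["A"] * len(group_a) + ["B"] * len(group_b)
        return cls(meth, total, labels, loci=table[["chrom", "pos", "strand"]])

    def fit(
        self,
        alpha: float = 0.05,
        min_delta: float = 0.10,
        min_coverage: int = 5,
    ) -> "DMLResults":
        """Wald test per locus; loci with coverage below ``min_coverage`` in
        any sample of the comparison are excluded before BH adjustment."""
        meth, total, groups = self.meth, self.total, self.groups
        retained = np.all(total >= min_coverage, axis=1)
        if not np.any(retained):
            raise ValueError("no locus meets the coverage requirement")
        m, c = meth[retained], total[retained]
        phi, var_phi = estimate_locus_dispersion(m, c, groups, min_coverage,
                                                 _detail=True)

        mus, variances = {}, {}
        dvar_dphi = np.zeros(m.shape[0])
        for g in (self.group_a, self.group_b):
            cols = groups == g
            cg = c[:, cols]
            mg = m[:, cols]
            csum = cg.sum(axis=1)
            mu = mg.sum(axis=1) / csum
            # variance plug-in uses a lightly regularised mean so SE > 0
            mu_v = (mg.sum(axis=1) + 0.5) / (csum + 1.0)
            var = mu_v * (1 - mu_v) * (cg * (1 + (cg - 1) * phi[:, None])).sum(axis=1) / csum**2
            dvar_dphi += mu_v * (1 - mu_v) * (cg * (cg - 1)).sum(axis=1) / csum**2
            mus[g], variances[g] = mu, var

        delta = mus[self.group_b] - mus[self.group_a]
        se2 = variances[self.group_a] + variances[self.group_b]
        # first-order absorption of dispersion-estimation noise into the SE
        se = np.sqrt(se2 * (1.0 + dvar_dphi**2 * var_phi / se2**2))
        z = delta / se
        p = 2 * stats.norm.sf(np.abs(z))
        padj = benjamini_hochberg(p)
        significant = (padj < alpha) & (np.abs(delta) >= min_delta)

        frame = pd.DataFrame(
            {
                "mu_A": mus[self.group_a],
                "mu_B": mus[self.group_b],
                "delta": delta,
                "se": se,
                "wald_z": z,
                "p": p,
                "padj": padj,
                "significant": significant,
                "dispersion": phi,
            }
        )
        if self.loci is not None:
            frame = pd.concat(
                [self.loci.loc[retained].reset_index(drop=True), frame], axis=1
            )
        return DMLResults(frame, alpha=alpha, min_delta=min_delta,
                          min_coverage=min_coverage, n_input=len(retained),
                          n_retained=int(retained.sum()))


class DMLResults:
    """Per-locus differential methylation estimates and calls."""

    def __init__(self, frame, alpha, min_delta, min_coverage, n_input, n_retained):
        self.frame = frame
        self.alpha = alpha
        self.min_delta = min_delta
        self.min_coverage = min_coverage
        self.n_input = n_input
        self.n_retained = n_retained

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]]

    def summary(self) -> str:
        n_sig = int(self.frame["significant"].sum())
        lines = [
            "Beta-binomial differential methylation (Wald test)",
            "=" * 50,
            f"loci tested:        {self.n_retained} of {self.n_input} "
            f"(coverage >= {self.min_coverage} in all samples)",
            f"alpha (BH):         {self.alpha}",
            f"min |delta|:        {self.min_delta}",
            f"significant DML:    {n_sig}",
            f"  gain (delta > 0): {int((self.significant['delta'] > 0).sum())}",
            f"  loss (delta < 0): {int((self.significant['delta'] < 0).sum())}",
            f"median dispersion:  {float(np.median(self.frame['dispersion'])):.4f}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def dml_test(
    table: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    min_delta: float = 0.10,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Functional wrapper: fit :class:`BetaBinomialDML` on a methylation
    count table and return the result frame."""
    model = BetaBinomialDML.from_table(table, group_a, group_b)
    return model.fit(alpha=alpha, min_delta=min_delta,
                     min_coverage=min_coverage).frame
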