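"""Negative-binomial differential expression with mid-parent contrasts.

A self-contained NB Wald engine: median-of-ratios size factors, per-locus
method-of-moments dispersions shrunk toward a fitted mean-dispersion trend,
Wald tests on the log ratio of group means (or on the linear mid-parent
contrast), and Benjamini-Hochberg FDR control.  Exact numerical agreement
with any particular GLM package is a non-goal; the design target is
distributional calibration (near-uniform null p-values at small replicate
numbers).

The NB parameterisation throughout is ``Var = mu + phi * mu^2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage as _linkage
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix

__all__ = [
    "size_factors",
    "qc_filter",
    "sample_qc",
    "SampleQC",
    "bh_adjust",
    "NBExpressionModel",
    "DEResults",
    "nb_test",
    "mpv_test",
]

logger = logging.getLogger(__name__)

DIRECTIONS = ("up_in_first", "up_in_second", "no_de")


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per sample, the median over reference loci (those with a positive
    count in every sample) of count / locus geometric mean; this captures
    both sequencing depth and RNA composition.  When no locus is positive
    everywhere the estimator falls back to total-count scaling with a
    logged warning.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else pd.DataFrame(counts)
    arr = mat.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() >= 1:
        log_geo = np.log(arr[positive]).mean(axis=1)
        ratios = np.log(arr[positive]) - log_geo[:, None]
        log_sf = np.median(ratios, axis=0)
        fallback = False
    else:
        logger.warning("no locus positive in all samples; total-count fallback")
        totals = arr.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total count")
        log_sf = np.log(totals)
        fallback = True
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    out = pd.Series(np.exp(log_sf), index=mat.columns, name="size_factor")
    out.attrs["fallback_total_count"] = fallback
    return out


def qc_filter(
    counts: CountMatrix,
    min_mean_norm: float = 1.0,
    outlier_fold: float = 10.0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Locus-level QC: drop zero-total, low-mean and extreme-outlier loci.

    Outlier rule (applied only with >= 3 samples): a locus is removed when
    any single normalized observation exceeds ``outlier_fold`` times the
    locus' trimmed mean (mean excluding the largest observation).
    Returns the filtered matrix and a removal log (locus_id, reason).
    """
    sf = size_factors(counts)
    norm = counts.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    removed: list[tuple[str, str]] = []
    keep = np.ones(counts.n_loci, dtype=bool)

    zero = counts.counts.sum(axis=1).to_numpy() == 0
    for l in counts.loci[zero]:
        removed.append((l, "zero_total_count"))
    keep &= ~zero

    low = norm.mean(axis=1) < min_mean_norm
    for l in counts.loci[low & keep]:
        removed.append((l, "low_mean_normalized_count"))
    keep &= ~low

    if counts.n_samples >= 3:
        order = np.sort(norm, axis=1)
        trimmed_mean = order[:, :-1].mean(axis=1)
        outlier = (trimmed_mean > 0) & (norm.max(axis=1) > outlier_fold * trimmed_mean)
        for l in counts.loci[outlier & keep]:
            removed.append((l, "extreme_count_outlier"))
        keep &= ~outlier

    log = pd.DataFrame(removed, columns=["locus_id", "reason"])
    return counts.subset_loci(counts.loci[keep]), log


@dataclass
class SampleQC:
    """Sample-level QC output: PCA coordinates, linkage, outlier flags."""

    pca: pd.DataFrame          # samples x components
    explained_variance_ratio: np.ndarray
    linkage: np.ndarray        # scipy hierarchical clustering linkage
    flags: pd.Series           # True where the sample failed to cluster with its group


def sample_qc(counts: CountMatrix, n_components: int = 2) -> SampleQC:
    """PCA and average-linkage clustering of log normalized counts.

    A sample is flagged when, walking the dendrogram bottom-up, the first
    cluster it joins contains no member of its own group — i.e. it pairs
    with another group's samples before any of its own replicates.
    """
    if counts.n_samples < 3:
        raise ValueError("sample QC requires at least 3 samples")
    sf = size_factors(counts)
    logn = np.log2(counts.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    x = logn.T  # samples x loci
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components, len(s))
    coords = pd.DataFrame(
        u[:, :k] * s[:k],
        index=counts.counts.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    evr = (s**2) / (s**2).sum()

    z = _linkage(x, method="average", metric="euclidean")
    n = x.shape[0]
    groups = counts.samples["group"].to_numpy()
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    first_partner: dict[int, set[int]] = {}
    for step, (i, j, _, _) in enumerate(z):
        a, b = members[int(i)], members[int(j)]
        for s_idx in a:
            first_partner.setdefault(s_idx, b)
        for s_idx in b:
            first_partner.setdefault(s_idx, a)
        members[n + step] = a | b
    flags = []
    for idx in range(n):
        partner = first_partner.get(idx, set())
        flags.append(any(groups[p] != groups[idx] for p in partner))
    flags = pd.Series(flags, index=counts.counts.columns, name="outlier")
    return SampleQC(coords, evr[:k], z, flags)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_stats(norm: np.ndarray, inv_sf: np.ndarray, cols: np.ndarray):
    """Group mean, residual SS, and mean inverse size factor per locus."""
    y = norm[:, cols]
    mu = y.mean(axis=1)
    ss = ((y - mu[:, None]) ** 2).sum(axis=1)
    return mu, ss, inv_sf[cols].mean(), y.shape[1]


def _fit_dispersion_trend(mu: np.ndarray, phi: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of phi ~ a0 + a1/mu over informative loci."""
    ok = (phi > 0) & (mu > 1.0)
    if ok.sum() < 10:
        return max(float(np.mean(phi[phi > 0])) if (phi > 0).any() else 0.01, 1e-6), 0.0
    x = 1.0 / mu[ok]
    y = phi[ok]
    a1, a0 = np.polyfit(x, y, 1)
    return max(float(a0), 1e-6), max(float(a1), 0.0)


class NBExpressionModel:
    """NB Wald differential-expression model over a grouped count matrix.

    Parameters
    ----------
    counts
        :class:`CountMatrix` whose sample metadata defines the groups.
    shrinkage_weight
        Weight on the fitted mean-dispersion trend when combining it with
        the per-locus moment estimate (``phi* = w*trend + (1-w)*mom``).
        With 3 replicates per group the moment estimate is noisy, so the
        default leans on the trend.
    alpha
        FDR threshold used for direction calls.
    """

    def __init__(
        self,
        counts: CountMatrix,
        shrinkage_weight: float = 0.8,
        alpha: float = 0.05,
    ) -> None:
        if not 0.0 <= shrinkage_weight <= 1.0:
            raise ValueError("shrinkage_weight must be in [0, 1]")
        self.data = counts
        self.alpha = float(alpha)
        self.shrinkage_weight = float(shrinkage_weight)
        self.size_factors = size_factors(counts)
        self._norm = counts.counts.to_numpy(dtype=float) / self.size_factors.to_numpy()[None, :]
        self._inv_sf = 1.0 / self.size_factors.to_numpy()

    def _cols(self, samples: list[str]) -> np.ndarray:
        idx = self.data.counts.columns.get_indexer(samples)
        if (idx < 0).any():
            missing = [s for s, i in zip(samples, idx) if i < 0]
            raise KeyError(f"unknown samples {missing}")
        return idx

    def _dispersions(self, group_cols: list[np.ndarray]):
        """Trend-shrunk per-locus dispersions from the given groups."""
        num = np.zeros(self.data.n_loci)
        den = np.zeros(self.data.n_loci)
        mus = []
        for cols in group_cols:
            if len(cols) < 2:
                raise ValueError("each group needs >= 2 samples")
            mu, ss, s_inv, n_g = _group_stats(self._norm, self._inv_sf, cols)
            num += ss - (n_g - 1) * mu * s_inv
            den += (n_g - 1) * mu**2
            mus.append(mu)
        mu_all = np.mean(mus, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_mom = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        phi_mom = np.clip(phi_mom, 0.0, None)
        a0, a1 = _fit_dispersion_trend(mu_all, phi_mom)
        phi_trend = a0 + a1 / np.maximum(mu_all, 1e-8)
        w = self.shrinkage_weight
        return np.maximum(w * phi_trend + (1.0 - w) * phi_mom, 1e-8)

    # ------------------------------------------------------------ contrasts
    def fit_contrast(self, group1, group2, label: str | None = None) -> "DEResults":
        """Wald test of equal means between two groups (log-ratio scale)."""
        g1 = self.data.group_samples(group1) if isinstance(group1, str) else list(group1)
        g2 = self.data.group_samples(group2) if isinstance(group2, str) else list(group2)
        c1, c2 = self._cols(g1), self._cols(g2)
        phi = self._dispersions([c1, c2])
        mu1, _, sinv1, n1 = _group_stats(self._norm, self._inv_sf, c1)
        mu2, _, sinv2, n2 = _group_stats(self._norm, self._inv_sf, c2)

        tested = (mu1 > 0) | (mu2 > 0)
        floor1, floor2 = 0.5 / n1, 0.5 / n2
        m1, m2 = np.maximum(mu1, floor1), np.maximum(mu2, floor2)
        # delta method: Var(log mean) ~ (1/mu * s_inv + phi) / n
        var_log = (sinv1 / m1 + phi) / n1 + (sinv2 / m2 + phi) / n2
        b = np.log(m1) - np.log(m2)
        z = b / np.sqrt(var_log)
        p = 2.0 * stats.norm.sf(np.abs(z))
        lfc_display = np.log2(mu1 + 0.5) - np.log2(mu2 + 0.5)
        frame = self._assemble(tested, lfc_display, b, z, p)
        return DEResults(
            frame, label or f"{group1}_vs_{group2}", self.alpha, (group1, group2)
        )

    def fit_mpv(self, polyploid, parentA, parentB, label: str | None = None) -> "DEResults":
        """Wald test of the polyploid mean against the mid-parent value.

        Null hypothesis mu_M = (mu_A + mu_B) / 2 on the normalized scale,
        tested as a linear contrast with delta-method variance (replicate
        variance of all three groups preserved, no pseudo-sample averaging).
        """
        gm = self.data.group_samples(polyploid) if isinstance(polyploid, str) else list(polyploid)
        ga = self.data.group_samples(parentA) if isinstance(parentA, str) else list(parentA)
        gb = self.data.group_samples(parentB) if isinstance(parentB, str) else list(parentB)
        cm_, ca, cb = self._cols(gm), self._cols(ga), self._cols(gb)
        phi = self._dispersions([cm_, ca, cb])
        mu_m, _, sinv_m, n_m = _group_stats(self._norm, self._inv_sf, cm_)
        mu_a, _, sinv_a, n_a = _group_stats(self._norm, self._inv_sf, ca)
        mu_b, _, sinv_b, n_b = _group_stats(self._norm, self._inv_sf, cb)

        tested = (mu_m > 0) | (mu_a > 0) | (mu_b > 0)
        mpv = (mu_a + mu_b) / 2.0
        delta = mu_m - mpv

        def var_mean(mu, sinv, n):
            return (np.maximum(mu, 1e-8) * sinv + phi * mu**2) / n

        var = var_mean(mu_m, sinv_m, n_m) + 0.25 * (
            var_mean(mu_a, sinv_a, n_a) + var_mean(mu_b, sinv_b, n_b)
        )
        z = delta / np.sqrt(np.maximum(var, 1e-300))
        p = 2.0 * stats.norm.sf(np.abs(z))
        lfc_display = np.log2(mu_m + 0.5) - np.log2(mpv + 0.5)
        frame = self._assemble(tested, lfc_display, delta, z, p)
        return DEResults(frame, label or f"{polyploid}_vs_MPV", self.alpha, (polyploid, "MPV"))

    def _assemble(self, tested, lfc, effect, z, p) -> pd.DataFrame:
        idx = self.data.loci[tested]
        p_t = p[tested]
        fdr = bh_adjust(p_t)
        direction = np.where(
            fdr >= self.alpha,
            "no_de",
            np.where(effect[tested] > 0, "up_in_first", "up_in_second"),
        )
        return pd.DataFrame(
            {
                "log2_fc": lfc[tested],
                "stat": z[tested],
                "p_value": p_t,
                "fdr": fdr,
                "direction": direction,
            },
            index=idx,
        )


class DEResults:
    """Per-locus contrast results (log2 FC, Wald p, BH FDR, direction)."""

    def __init__(self, frame: pd.DataFrame, label: str, alpha: float, groups):
        self.frame = frame
        self.label = label
        self.alpha = alpha
        self.groups = groups

    @property
    def direction(self) -> pd.Series:
        return self.frame["direction"]

    def n_de(self) -> int:
        return int((self.frame["direction"] != "no_de").sum())

    def percent_de(self) -> dict:
        """Fraction DE and the directional split, as percentages."""
        n = len(self.frame)
        up1 = int((self.frame["direction"] == "up_in_first").sum())
        up2 = int((self.frame["direction"] == "up_in_second").sum())
        return {
            "n_tested": n,
            "n_de": up1 + up2,
            "percent_de": 100.0 * (up1 + up2) / n if n else float("nan"),
            "percent_up_in_first": 100.0 * up1 / n if n else float("nan"),
            "percent_up_in_second": 100.0 * up2 / n if n else float("nan"),
        }

    def summary(self) -> str:
        s = self.percent_de()
        return (
            f"Contrast {self.label}: {s['n_de']}/{s['n_tested']} loci DE "
            f"({s['percent_de']:.1f}%) at FDR < {self.alpha}; "
            f"{s['percent_up_in_first']:.1f}% up in {self.groups[0]}, "
            f"{s['percent_up_in_second']:.1f}% up in {self.groups[1]}"
        )


def nb_test(counts: CountMatrix, group1, group2, **kwargs) -> DEResults:
    """Functional wrapper: two-group NB Wald test on a count matrix."""
    model_kw = {k: kwargs.pop(k) for k in ("shrinkage_weight", "alpha") if k in kwargs}
    return NBExpressionModel(counts, **model_kw).fit_contrast(group1, group2, **kwargs)


def mpv_test(counts: CountMatrix, polyploid, parentA, parentB, **kwargs) -> DEResults:
    """Functional wrapper: polyploid vs mid-parent-value NB Wald test."""
    model_kw = {k: kwargs.pop(k) for k in ("shrinkage_weight", "alpha") if k in kwargs}
    return NBExpressionModel(counts, **model_kw).fit_mpv(polyploid, parentA, parentB, **kwargs)
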