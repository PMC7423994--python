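"""Bayesian inference of homeolog expression bias in an allopolyploid.

Model
-----
For a locus with replicate-level homeolog-assigned read counts
``(x_A,i, x_B,i)``, each replicate's counts are Poisson with a shared
replicate intensity ``lambda_i`` (given a Gamma prior) split between the
two homeologs by the locus-level homeolog proportion ``theta``:

    x_A,i ~ Poisson(lambda_i * p),   x_B,i ~ Poisson(lambda_i * (1 - p)),
    p = theta * (1 - qA) + (1 - theta) * qB,

where ``qA``/``qB`` are the read-misassignment rates between the two
subgenome references (estimated from diploid cross-mapping).  Conditioning
on the replicate total ``n_i = x_A,i + x_B,i`` integrates the Gamma
intensity out exactly, leaving ``x_A,i | n_i ~ Binomial(n_i, p)``; with a
``Beta(prior_a, prior_b)`` prior on theta the posterior is evaluated by
normalised quadrature on a uniform theta grid.  When ``qA = qB = 0`` this
reduces to the conjugate closed form
``theta | data ~ Beta(prior_a + sum x_A, prior_b + sum x_B)``, which serves
as an exact oracle for the grid computation.

A locus is called ``biased_A``/``biased_B`` when the equal-tailed credible
interval at the configured level excludes 0.5, ``unbiased`` otherwise.
Combining the bias call with the parental differential-expression call
places each locus in one of nine categories grouped as parental legacy
(1-3), absence of bias (4-5) and novel bias (6-9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .containers import validate_homeolog_frame

__all__ = [
    "BiasPosterior",
    "HomeologBiasModel",
    "HomeologBiasResults",
    "theta_posterior",
    "posterior_density",
    "classify_bias",
    "assign_category",
    "assign_categories",
    "compare_forms",
    "bias_balance_test",
    "CATEGORY_TABLE",
    "CATEGORY_GROUPS",
]

# (parental DE call, bias class) -> category number; groups fixed below
CATEGORY_TABLE = {
    ("no_de", "unbiased"): 1,
    ("A_higher", "biased_A"): 2,
    ("B_higher", "biased_B"): 3,
    ("A_higher", "unbiased"): 4,
    ("B_higher", "unbiased"): 5,
    ("no_de", "biased_A"): 6,
    ("no_de", "biased_B"): 7,
    ("A_higher", "biased_B"): 8,
    ("B_higher", "biased_A"): 9,
}
CATEGORY_GROUPS = {
    **{c: "parental_legacy" for c in (1, 2, 3)},
    **{c: "absence_of_bias" for c in (4, 5)},
    **{c: "novel_bias" for c in (6, 7, 8, 9)},
}

BIAS_CLASSES = ("unbiased", "biased_A", "biased_B")


@dataclass
class BiasPosterior:
    """Posterior summary of the homeolog proportion theta for one locus."""

    locus_id: str
    theta_mean: float
    ci_low: float
    ci_high: float
    bias_class: str
    sum_A: int = 0
    sum_B: int = 0


def _grid_posterior(
    sum_A: np.ndarray,
    sum_B: np.ndarray,
    qA: np.ndarray,
    qB: np.ndarray,
    prior_a: float,
    prior_b: float,
    grid_points: int,
    level: float,
):
    """Vectorised grid posterior for many loci at once.

    The binomial likelihood depends on the replicate counts only through
    the totals (p is shared across replicates), so ``sum_A``/``sum_B`` are
    sufficient.  Returns (grid, density, mean, ci_low, ci_high) with
    density normalised by Simpson quadrature on the grid.
    """
    if grid_points < 101:
        raise ValueError("grid_points must be >= 101")
    sum_A = np.atleast_1d(np.asarray(sum_A, dtype=float))
    sum_B = np.atleast_1d(np.asarray(sum_B, dtype=float))
    qA = np.broadcast_to(np.atleast_1d(np.asarray(qA, dtype=float)), sum_A.shape)
    qB = np.broadcast_to(np.atleast_1d(np.asarray(qB, dtype=float)), sum_A.shape)
    if np.any((qA < 0) | (qA >= 0.5) | (qB < 0) | (qB >= 0.5)):
        raise ValueError("misassignment rates must lie in [0, 0.5)")
    if prior_a <= 0 or prior_b <= 0:
        raise ValueError("prior parameters must be positive")

    grid = np.linspace(0.0, 1.0, grid_points)
    p = grid[None, :] * (1.0 - qA - qB)[:, None] + qB[:, None]  # (L, G)
    one_minus_p = (1.0 - grid[None, :]) * (1.0 - qA - qB)[:, None] + qA[:, None]
    # xlogy gives the 0 * log 0 = 0 endpoint convention exactly
    log_like = special.xlogy(sum_A[:, None], p) + special.xlogy(sum_B[:, None], one_minus_p)
    log_prior = special.xlogy(prior_a - 1.0, grid) + special.xlogy(prior_b - 1.0, 1.0 - grid)
    log_post = log_like + log_prior[None, :]
    # a prior with a or b < 1 has an integrable endpoint singularity which
    # the grid truncates to zero mass
    log_post = np.where(np.isnan(log_post), -np.inf, log_post)
    log_post -= np.max(log_post, axis=1, keepdims=True)
    f = np.exp(log_post)
    f[~np.isfinite(f)] = 0.0

    norm = integrate.simpson(f, x=grid, axis=1)
    density = f / norm[:, None]
    mean = integrate.simpson(density * grid[None, :], x=grid, axis=1)

    cdf = integrate.cumulative_trapezoid(density, grid, axis=1, initial=0.0)
    cdf /= cdf[:, -1][:, None]
    alpha = (1.0 - level) / 2.0
    lo = np.empty(len(sum_A))
    hi = np.empty(len(sum_A))
    for i in range(len(sum_A)):
        lo[i] = np.interp(alpha, cdf[i], grid)
        hi[i] = np.interp(1.0 - alpha, cdf[i], grid)
    return grid, density, mean, lo, hi


def posterior_density(
    sum_A: float,
    sum_B: float,
    qA: float = 0.0,
    qB: float = 0.0,
    prior_a: float = 1.0,
    prior_b: float = 1.0,
    grid_points: int = 2001,
):
    """(grid, normalised posterior density) for one locus' homeolog totals."""
    grid, dens, _, _, _ = _grid_posterior(
        [sum_A], [sum_B], [qA], [qB], prior_a, prior_b, grid_points, 0.95
    )
    return grid, dens[0]


def classify_bias(theta_mean: float, ci_low: float, ci_high: float) -> str:
    """Three-way bias call from the credible interval's position vs 0.5."""
    if ci_low > 0.5 or ci_high < 0.5:
        return "biased_A" if theta_mean > 0.5 else "biased_B"
    return "unbiased"


def theta_posterior(
    x_A,
    x_B,
    qA: float = 0.0,
    qB: float = 0.0,
    prior_a: float = 1.0,
    prior_b: float = 1.0,
    grid_points: int = 2001,
    level: float = 0.95,
    locus_id: str = "",
) -> BiasPosterior:
    """Posterior for one locus from replicate homeolog count vectors."""
    x_A = np.atleast_1d(np.asarray(x_A))
    x_B = np.atleast_1d(np.asarray(x_B))
    sa, sb = int(x_A.sum()), int(x_B.sum())
    if sa + sb == 0:
        raise ValueError(f"locus {locus_id!r}: all homeolog counts are zero")
    _, _, mean, lo, hi = _grid_posterior(
        [sa], [sb], [qA], [qB], prior_a, prior_b, grid_points, level
    )
    cls = classify_bias(mean[0], lo[0], hi[0])
    return BiasPosterior(locus_id, float(mean[0]), float(lo[0]), float(hi[0]), cls, sa, sb)


class HomeologBiasModel:
    """Per-locus homeolog proportion model for a set of polyploid replicates.

    Parameters
    ----------
    counts
        Long-format table with columns ``locus_id, replicate, count_A,
        count_B``.
    q
        Misassignment rates: either a ``(qA, qB)`` scalar pair applied to
        every locus or a table with columns ``locus_id, qA, qB``.
    prior_a, prior_b
        Beta prior on theta (flat by default).
    grid_points
        Number of uniform quadrature nodes on [0, 1].
    min_total
        Loci whose homeolog counts sum below this across replicates are
        excluded (prior-dominated posteriors) and logged in the results.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        q=(0.0, 0.0),
        prior_a: float = 1.0,
        prior_b: float = 1.0,
        grid_points: int = 2001,
        min_total: int = 10,
    ) -> None:
        self.counts = validate_homeolog_frame(counts)
        self.prior_a = float(prior_a)
        self.prior_b = float(prior_b)
        self.grid_points = int(grid_points)
        self.min_total = int(min_total)
        totals = self.counts.groupby("locus_id", sort=True)[["count_A", "count_B"]].sum()
        self._totals = totals
        if isinstance(q, pd.DataFrame):
            qtab = q.set_index("locus_id")[["qA", "qB"]]
            self._qA = qtab["qA"].reindex(totals.index).fillna(0.0).to_numpy()
            self._qB = qtab["qB"].reindex(totals.index).fillna(0.0).to_numpy()
        else:
            self._qA = np.full(len(totals), float(q[0]))
            self._qB = np.full(len(totals), float(q[1]))

    def fit(self, level: float = 0.95) -> "HomeologBiasResults":
        totals = self._totals
        keep = (totals["count_A"] + totals["count_B"]) >= self.min_total
        excluded = pd.DataFrame(
            {
                "locus_id": totals.index[~keep],
                "reason": [
                    f"total homeolog count < {self.min_total}"
                ] * int((~keep).sum()),
            }
        )
        kept = totals[keep]
        mask = keep.to_numpy()
        _, _, mean, lo, hi = _grid_posterior(
            kept["count_A"].to_numpy(),
            kept["count_B"].to_numpy(),
            self._qA[mask],
            self._qB[mask],
            self.prior_a,
            self.prior_b,
            self.grid_points,
            level,
        )
        bias = np.where(
            (lo > 0.5) | (hi < 0.5),
            np.where(mean > 0.5, "biased_A", "biased_B"),
            "unbiased",
        )
        post = pd.DataFrame(
            {
                "sum_A": kept["count_A"].to_numpy(),
                "sum_B": kept["count_B"].to_numpy(),
                "theta_mean": mean,
                "ci_low": lo,
                "ci_high": hi,
                "bias_class": bias,
            },
            index=kept.index,
        )
        return HomeologBiasResults(self, post, excluded, level)


class HomeologBiasResults:
    """Fitted per-locus theta posteriors with bias classification."""

    def __init__(self, model, posteriors, excluded, level):
        self.model = model
        self.posteriors = posteriors
        self.excluded = excluded
        self.level = level

    @property
    def bias_class(self) -> pd.Series:
        return self.posteriors["bias_class"]

    def class_counts(self) -> pd.Series:
        counts = self.posteriors["bias_class"].value_counts()
        return counts.reindex(BIAS_CLASSES, fill_value=0)

    def balance_test(self) -> tuple[float, float]:
        """Chi-square goodness-of-fit of biased_A vs biased_B against 1:1."""
        c = self.class_counts()
        return bias_balance_test(int(c["biased_A"]), int(c["biased_B"]))

    def assign_categories(self, parental_de: pd.Series) -> pd.DataFrame:
        """Join with parental DE calls to yield the nine-category table."""
        return assign_categories(parental_de, self.posteriors["bias_class"])

    def summary(self) -> str:
        c = self.class_counts()
        total = int(c.sum())
        lines = [
            "Homeolog expression bias summary",
            "================================",
            f"loci analysed:           {total}",
            f"loci excluded (low count): {len(self.excluded)}",
            f"credible level:          {self.level:.2f}",
        ]
        for cls in BIAS_CLASSES:
            pct = 100.0 * c[cls] / total if total else float("nan")
            lines.append(f"  {cls:<12} {int(c[cls]):>6}  ({pct:.1f}%)")
        if c["biased_A"] + c["biased_B"] > 0:
            chi2, p = self.balance_test()
            lines.append(f"bias balance chi2 = {chi2:.2f}, p = {p:.3g}")
        return "\n".join(lines)


def assign_category(parental_de: str, bias_class: str) -> tuple[int, str]:
    """Map one (parental DE, bias class) pair to its category and group.

    Categories 1-3 are parental legacy (the polyploid bias mirrors the
    parental difference), 4-5 absence of bias, 6-9 novel bias.
    """
    key = (parental_de, bias_class)
    if key not in CATEGORY_TABLE:
        raise KeyError(f"invalid combination {key}")
    cat = CATEGORY_TABLE[key]
    return cat, CATEGORY_GROUPS[cat]


def assign_categories(parental_de: pd.Series, bias_class: pd.Series) -> pd.DataFrame:
    """Vectorised nine-category assignment over loci shared by both calls.

    Loci missing either call are skipped; the count of skipped loci is
    stored in ``frame.attrs['n_skipped']``.
    """
    shared = parental_de.index.intersection(bias_class.index)
    n_skipped = len(parental_de.index.union(bias_class.index)) - len(shared)
    cats = [CATEGORY_TABLE[(parental_de[l], bias_class[l])] for l in shared]
    out = pd.DataFrame(
        {
            "category": cats,
            "group": [CATEGORY_GROUPS[c] for c in cats],
        },
        index=shared,
    )
    out.attrs["n_skipped"] = n_skipped
    return out


def compare_forms(
    calls_form1: pd.Series,
    calls_form2: pd.Series,
    maternal_of_form1: str = "B",
    maternal_of_form2: str = "A",
) -> tuple[pd.DataFrame, list]:
    """Cross-form 3x3 bias-class table and maternal-specific bias list.

    Restricted to loci with a call in both polyploid forms.  The returned
    list holds loci biased toward a form's maternal parent in that form
    while unbiased in the other form (the candidate cytonuclear set);
    loci switching bias direction between forms are counted in the table
    but never listed.
    """
    if {maternal_of_form1, maternal_of_form2} - {"A", "B"}:
        raise ValueError("maternal parents must be 'A' or 'B'")
    shared = calls_form1.index.intersection(calls_form2.index)
    c1, c2 = calls_form1[shared], calls_form2[shared]
    table = pd.crosstab(c1, c2).reindex(
        index=BIAS_CLASSES, columns=BIAS_CLASSES, fill_value=0
    )
    table.index.name = "form1"
    table.columns.name = "form2"
    m1 = f"biased_{maternal_of_form1}"
    m2 = f"biased_{maternal_of_form2}"
    maternal = list(shared[((c1 == m1) & (c2 == "unbiased")) | ((c2 == m2) & (c1 == "unbiased"))])
    return table, maternal


def bias_balance_test(n_biased_A: int, n_biased_B: int) -> tuple[float, float]:
    """1-df chi-square goodness of fit of biased counts against 1:1."""
    if n_biased_A < 0 or n_biased_B < 0:
        raise ValueError("counts must be non-negative")
    if n_biased_A + n_biased_B == 0:
        raise ValueError("balance test undefined for zero biased loci")
    chi2, p = stats.chisquare([n_biased_A, n_biased_B])
    return float(chi2), float(p)
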