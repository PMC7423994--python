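"""Total-expression pattern classification and cross-form statistics.

Each locus' three pairwise direction calls — polyploid vs parent A (M-A),
polyploid vs parent B (M-B), parent A vs parent B (A-B) — are mapped to one
of: no change, additivity (polyploid strictly between differing parents),
expression level dominance toward either parent, transgressive up/down
regulation, or conflict for the logically inconsistent triples the scheme
does not define (reported, never coerced).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .homeolog import bias_balance_test

__all__ = [
    "classify_pattern",
    "classify_patterns",
    "de_directions",
    "summarize_patterns",
    "eld_balance_test",
    "nonadditive_comparison",
    "crosslink",
    "PATTERN_LABELS",
    "NON_ADDITIVE",
]

PATTERN_LABELS = (
    "no_change",
    "additivity",
    "eld_A",
    "eld_B",
    "transgressive_up",
    "transgressive_down",
    "conflict",
)
NON_ADDITIVE = ("eld_A", "eld_B", "transgressive_up", "transgressive_down")

_DIRS = ("first_higher", "second_higher", "no_de")

_DE_TO_DIR = {"up_in_first": "first_higher", "up_in_second": "second_higher", "no_de": "no_de"}


def de_directions(de_results) -> pd.Series:
    """Map a DEResults direction column onto pattern-call direction labels."""
    frame = de_results.frame if hasattr(de_results, "frame") else de_results
    return frame["direction"].map(_DE_TO_DIR)


def classify_pattern(de_MA: str, de_MB: str, de_AB: str) -> str:
    """Pattern label from the three pairwise direction calls.

    Direction semantics: ``first_higher`` in de_MA means the polyploid
    exceeds parent A; in de_AB it means parent A exceeds parent B.

    Decision table (checked in order):

    * no_change:          M = A and M = B
    * transgressive_up:   M > A and M > B
    * transgressive_down: M < A and M < B
    * eld_A:              M = A, M != B, A != B   (dominance toward A)
    * eld_B:              M = B, M != A, A != B
    * additivity:         A != B and M strictly between the parents
                          (both polyploid-parent contrasts significant)
    * conflict:           anything else (e.g. A = B but M differs from
                          exactly one parent)
    """
    for name, d in (("de_MA", de_MA), ("de_MB", de_MB), ("de_AB", de_AB)):
        if d not in _DIRS:
            raise ValueError(f"{name}={d!r} not in {_DIRS}")
    ma = {"first_higher": 1, "second_higher": -1, "no_de": 0}[de_MA]
    mb = {"first_higher": 1, "second_higher": -1, "no_de": 0}[de_MB]
    ab = {"first_higher": 1, "second_higher": -1, "no_de": 0}[de_AB]

    if ma == 0 and mb == 0:
        return "no_change"
    if ma == 1 and mb == 1:
        return "transgressive_up"
    if ma == -1 and mb == -1:
        return "transgressive_down"
    if ma == 0 and mb != 0 and ab != 0:
        return "eld_A"
    if mb == 0 and ma != 0 and ab != 0:
        return "eld_B"
    if ab == 1 and ma == -1 and mb == 1:
        return "additivity"  # B < M < A
    if ab == -1 and ma == 1 and mb == -1:
        return "additivity"  # A < M < B
    return "conflict"


def classify_patterns(
    de_MA: pd.Series, de_MB: pd.Series, de_AB: pd.Series
) -> pd.DataFrame:
    """Vectorised pattern calls over the loci shared by all three contrasts.

    Loci missing any call are skipped; their number is recorded in
    ``frame.attrs['n_skipped']``.
    """
    shared = de_MA.index.intersection(de_MB.index).intersection(de_AB.index)
    union = de_MA.index.union(de_MB.index).union(de_AB.index)
    out = pd.DataFrame(
        {
            "de_MA": de_MA[shared],
            "de_MB": de_MB[shared],
            "de_AB": de_AB[shared],
        },
        index=shared,
    )
    out["pattern"] = [
        classify_pattern(a, b, c)
        for a, b, c in zip(out["de_MA"], out["de_MB"], out["de_AB"])
    ]
    out.attrs["n_skipped"] = len(union) - len(shared)
    return out


def summarize_patterns(patterns: pd.Series) -> pd.DataFrame:
    """Counts and percentages per pattern plus the non-additive total."""
    if len(patterns) == 0:
        raise ValueError("no pattern calls to summarise")
    counts = patterns.value_counts().reindex(PATTERN_LABELS, fill_value=0)
    total = int(counts.sum())
    table = pd.DataFrame(
        {"count": counts, "percent": 100.0 * counts / total}
    )
    non_add = int(counts[list(NON_ADDITIVE)].sum())
    table.loc["non_additive"] = [non_add, 100.0 * non_add / total]
    table.attrs["total"] = total
    return table


def eld_balance_test(n_eld_A: int, n_eld_B: int) -> tuple[float, float]:
    """Chi-square goodness of fit of dominance counts against 1:1."""
    return bias_balance_test(n_eld_A, n_eld_B)


def nonadditive_comparison(
    nonadd1: int, total1: int, nonadd2: int, total2: int
) -> tuple[float, float]:
    """Two-sided Fisher's exact test comparing non-additive proportions.

    Returns (odds ratio, p).  Degenerate tables with a zero margin give
    p = 1 (no evidence either way).
    """
    if not (0 <= nonadd1 <= total1 and 0 <= nonadd2 <= total2):
        raise ValueError("non-additive counts must not exceed totals")
    table = np.array([[nonadd1, total1 - nonadd1], [nonadd2, total2 - nonadd2]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        import warnings

        warnings.warn("degenerate 2x2 table (zero margin); p set to 1")
        return float("nan"), 1.0
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def crosslink(
    de_between_forms,
    patterns_form1: pd.Series,
    patterns_form2: pd.Series,
    bias_form1: pd.Series | None = None,
    bias_form2: pd.Series | None = None,
) -> pd.DataFrame:
    """Link between-form DE loci to their per-form pattern and bias calls.

    ``de_between_forms`` is a :class:`polyexpr.de.DEResults` (form1 as the
    first group) or its frame.  For each locus DE between the two polyploid
    forms the report lists its pattern in each form; the derived column
    ``transgressive_down_in_lower`` marks loci transgressively
    down-regulated in the form where they are expressed lower — the
    signature behind most form-specific expression differences.
    """
    frame = de_between_forms.frame if hasattr(de_between_forms, "frame") else de_between_forms
    de_loci = frame.index[frame["direction"] != "no_de"]
    rows = []
    for locus in de_loci:
        direction = frame.loc[locus, "direction"]
        lower_form = 1 if direction == "up_in_second" else 2
        p1 = patterns_form1.get(locus, "missing")
        p2 = patterns_form2.get(locus, "missing")
        lower_pattern = p1 if lower_form == 1 else p2
        rows.append(
            {
                "locus_id": locus,
                "direction": direction,
                "pattern_form1": p1,
                "pattern_form2": p2,
                "bias_form1": bias_form1.get(locus, "missing") if bias_form1 is not None else "",
                "bias_form2": bias_form2.get(locus, "missing") if bias_form2 is not None else "",
                "lower_form": lower_form,
                "transgressive_down_in_lower": lower_pattern == "transgressive_down",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id", "direction", "pattern_form1", "pattern_form2",
            "bias_form1", "bias_form2", "lower_form", "transgressive_down_in_lower",
        ],
    ).set_index("locus_id") if rows else pd.DataFrame(
        columns=[
            "direction", "pattern_form1", "pattern_form2",
            "bias_form1", "bias_form2", "lower_form", "transgressive_down_in_lower",
        ]
    )
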