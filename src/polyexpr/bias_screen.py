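"""Mapping-bias screening from diploid cross-mapping assignment counts.

Before homeolog-specific expression can be inferred, each ortholog pair is
checked with diploid reads of known origin: if reads from one parent map
predominantly to the other parent's reference, the pair cannot separate
homeologs and is excluded.  The same counts yield per-locus misassignment
rate estimates (qA, qB) consumed by the homeolog posterior model.

Input/output tables use columns ``locus_id, aa, ab, bb, ba`` where ``aa``
counts parent-A diploid reads assigned to the A reference and ``ab`` those
assigned to the B reference (``bb``/``ba`` mirror for parent B).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ASSIGNMENT_COLUMNS = ["locus_id", "aa", "ab", "bb", "ba"]


def _validate(counts: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ASSIGNMENT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"assignment table missing columns {missing}")
    num = counts[["aa", "ab", "bb", "ba"]]
    if (num.to_numpy() < 0).any():
        raise ValueError("assignment counts must be non-negative")
    return counts


def screen_mapping_bias(
    counts: pd.DataFrame, cross_threshold: float = 0.5, min_reads: int = 10
) -> pd.Series:
    """Label each locus ``unbiased_mapping`` / ``biased_mapping`` / ``indeterminate``.

    A locus is ``biased_mapping`` when the cross-assignment fraction of
    either parent's reads exceeds ``cross_threshold`` ("predominantly mapped
    to the other reference"); denominators below ``min_reads`` make the
    locus ``indeterminate``.  Only ``unbiased_mapping`` loci proceed to
    homeolog inference.
    """
    if not 0.0 < cross_threshold <= 1.0:
        raise ValueError("cross_threshold must be in (0, 1]")
    counts = _validate(counts)
    den_a = counts["aa"] + counts["ab"]
    den_b = counts["bb"] + counts["ba"]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_a = counts["ab"] / den_a
        frac_b = counts["ba"] / den_b
    label = np.where(
        (den_a < min_reads) | (den_b < min_reads),
        "indeterminate",
        np.where(
            (frac_a > cross_threshold) | (frac_b > cross_threshold),
            "biased_mapping",
            "unbiased_mapping",
        ),
    )
    return pd.Series(label, index=counts["locus_id"].to_numpy(), name="mapping_label")


def estimate_misassignment(
    counts: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-locus misassignment rates qA = ab/(aa+ab), qB = ba/(bb+ba).

    ``pseudocount`` (default +0.5 per cell) regularises loci with few
    cross-mapped reads; set it to 0 for the raw ratio.  A zero denominator
    (with pseudocount 0) raises, directing the caller to a pooled estimate.
    """
    counts = _validate(counts)
    den_a = counts["aa"] + counts["ab"] + 2 * pseudocount
    den_b = counts["bb"] + counts["ba"] + 2 * pseudocount
    if (den_a == 0).any() or (den_b == 0).any():
        bad = counts.loc[(den_a == 0) | (den_b == 0), "locus_id"].iloc[0]
        raise ValueError(
            f"locus {bad!r} has no assigned reads for one parent; "
            "use pooled_misassignment for a global estimate"
        )
    return pd.DataFrame(
        {
            "locus_id": counts["locus_id"].to_numpy(),
            "qA": (counts["ab"] + pseudocount) / den_a,
            "qB": (counts["ba"] + pseudocount) / den_b,
        }
    )


def pooled_misassignment(counts: pd.DataFrame) -> tuple[float, float]:
    """Global (qA, qB) pooled over all loci; robust fallback for sparse loci."""
    counts = _validate(counts)
    qa = counts["ab"].sum() / max(counts["aa"].sum() + counts["ab"].sum(), 1)
    qb = counts["ba"].sum() / max(counts["bb"].sum() + counts["ba"].sum(), 1)
    return float(qa), float(qb)
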