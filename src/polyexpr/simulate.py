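"""Synthetic allopolyploid RNA-seq data with per-locus ground truth.

Counts are Gamma-Poisson (negative binomial with Var = mu + phi*mu^2).
Each locus carries a true parental log2 fold change, a true homeolog
proportion theta in the polyploid, and a total-expression pattern that
fixes the polyploid mean relative to the parents:

* ``no_change``     -- polyploid mean = both parental means (no parental DE)
* ``additivity``    -- polyploid mean = mid-parent value, parents differ
* ``eld_A``/``eld_B`` -- polyploid mean = one parent's mean (expression
  level dominance), parents differ
* ``transgressive_up``/``down`` -- polyploid mean beyond the extreme parent
  by the configured log2 offset

Homeolog-resolved counts split each polyploid replicate's total with
A-assignment probability ``p = theta*(1-qA) + (1-theta)*qB``, i.e. read
misassignment between subgenomes is applied at the read level, matching
the likelihood used for inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PATTERNS, ConfigError, SimConfig
from .containers import CountMatrix

__all__ = [
    "SimResult",
    "simulate_counts",
    "simulate_hit_table",
    "simulate_assignment_counts",
]


@dataclass
class SimResult:
    """Bundle returned by :func:`simulate_counts`."""

    parent_A: CountMatrix
    parent_B: CountMatrix
    polyploid: CountMatrix
    homeolog_counts: pd.DataFrame  # long format: locus_id, replicate, count_A, count_B
    truth: pd.DataFrame            # indexed by locus_id


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + phi*mu^2 (element-wise)."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=1.0 / phi, scale=np.maximum(mean, 1e-300) * phi)
    return rng.poisson(lam)


def simulate_counts(config: SimConfig) -> SimResult:
    """Simulate parent/polyploid count matrices with known ground truth.

    Returns a :class:`SimResult` whose ``truth`` table records, per locus,
    ``baseline_mean``, ``true_parental_lfc`` (log2, parent A over parent B),
    ``true_theta``, ``true_bias_class`` and ``true_pattern``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_loci
    reps = config.reps_per_group
    loci = pd.Index([f"locus{i:05d}" for i in range(n)], name="locus_id")

    baseline = rng.lognormal(config.mean_log_expression, config.sd_log_expression, size=n)

    # pattern assignment drives the polyploid mean and, for patterns that
    # presuppose parental DE, forces a parental fold change
    names = list(PATTERNS)
    probs = np.array([config.pattern_fractions[p] for p in names])
    pattern = rng.choice(names, size=n, p=probs)

    L = config.parental_lfc_magnitude
    lfc = np.zeros(n)
    sign = rng.choice([-1.0, 1.0], size=n)
    needs_de = np.isin(pattern, ["additivity", "eld_A", "eld_B"])
    lfc[needs_de] = sign[needs_de] * L
    free = pattern == "transgressive_up"
    free |= pattern == "transgressive_down"
    de_draw = rng.random(n) < config.frac_parental_de
    lfc[free & de_draw] = sign[free & de_draw] * L
    # no_change loci keep lfc = 0 (pattern requires polyploid ~ both parents)

    mu_A = baseline * np.exp2(lfc / 2.0)
    mu_B = baseline * np.exp2(-lfc / 2.0)

    mu_M = np.empty(n)
    hi = np.maximum(mu_A, mu_B)
    lo = np.minimum(mu_A, mu_B)
    for pat, val in (
        ("no_change", baseline),
        ("additivity", (mu_A + mu_B) / 2.0),
        ("eld_A", mu_A),
        ("eld_B", mu_B),
        ("transgressive_up", hi * np.exp2(L)),
        ("transgressive_down", lo * np.exp2(-L)),
    ):
        mask = pattern == pat
        mu_M[mask] = np.asarray(val, dtype=float)[mask] if np.ndim(val) else val

    # homeolog proportion theta
    theta = np.full(n, 0.5)
    biased = rng.random(n) < config.frac_biased_theta
    side_A = rng.random(n) < 0.5
    lo_t, hi_t = config.theta_biased_range
    draw = rng.uniform(lo_t, hi_t, size=n)
    theta[biased & side_A] = draw[biased & side_A]
    theta[biased & ~side_A] = 1.0 - draw[biased & ~side_A]
    bias_class = np.where(~biased, "unbiased", np.where(side_A, "biased_A", "biased_B"))

    depth = (
        np.ones(3 * reps)
        if config.depth_factors is None
        else np.asarray(config.depth_factors, dtype=float)
    )
    d_A, d_B, d_M = depth[:reps], depth[reps : 2 * reps], depth[2 * reps :]

    def matrix(mu: np.ndarray, d: np.ndarray, group: str, prefix: str) -> CountMatrix:
        cols = {}
        for j in range(reps):
            cols[f"{prefix}_{j + 1}"] = _nb_draw(rng, mu * d[j], config.dispersion)
        counts = pd.DataFrame(cols, index=loci)
        samples = pd.DataFrame(
            {"group": group, "replicate": np.arange(1, reps + 1)}, index=counts.columns
        )
        return CountMatrix(counts, samples)

    cm_A = matrix(mu_A, d_A, "parentA", "A")
    cm_B = matrix(mu_B, d_B, "parentB", "B")
    cm_M = matrix(mu_M, d_M, "polyploid", "M")

    # split each polyploid replicate's total between homeologs
    p_assign = theta * (1.0 - config.misassign_qA) + (1.0 - theta) * config.misassign_qB
    rows = []
    totals = cm_M.counts.to_numpy()
    for j in range(reps):
        x_a = rng.binomial(totals[:, j], p_assign)
        rows.append(
            pd.DataFrame(
                {
                    "locus_id": loci,
                    "replicate": j + 1,
                    "count_A": x_a,
                    "count_B": totals[:, j] - x_a,
                }
            )
        )
    homeolog = pd.concat(rows, ignore_index=True).sort_values(
        ["locus_id", "replicate"], ignore_index=True
    )

    truth = pd.DataFrame(
        {
            "baseline_mean": baseline,
            "true_parental_lfc": lfc,
            "true_theta": theta,
            "true_bias_class": bias_class,
            "true_pattern": pattern,
            "mu_A": mu_A,
            "mu_B": mu_B,
            "mu_M": mu_M,
        },
        index=loci,
    )
    return SimResult(cm_A, cm_B, cm_M, homeolog, truth)


def simulate_assignment_counts(
    config: SimConfig, mean_reads: float = 200.0
) -> pd.DataFrame:
    """Diploid cross-mapping assignment counts with the configured q rates.

    For each locus, ``aa`` of the parent-A diploid reads map to the A
    reference and ``ab`` to the B reference (``ab ~ Binomial(n, qA)``);
    ``bb``/``ba`` mirror this for parent B.  Used to exercise the mapping
    bias screen and misassignment estimation.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_loci
    loci = [f"locus{i:05d}" for i in range(n)]
    tot_a = rng.poisson(mean_reads, size=n)
    tot_b = rng.poisson(mean_reads, size=n)
    ab = rng.binomial(tot_a, config.misassign_qA)
    ba = rng.binomial(tot_b, config.misassign_qB)
    return pd.DataFrame(
        {"locus_id": loci, "aa": tot_a - ab, "ab": ab, "bb": tot_b - ba, "ba": ba}
    )


BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def simulate_hit_table(config: SimConfig):
    """Generate reciprocal BLAST-tabular hit tables with a known pair list.

    Returns ``(hits_A_vs_B, hits_B_vs_A, true_pairs)`` where each hit table
    is an outfmt-6-shaped DataFrame.  Every true ortholog pair is the
    reciprocal best hit by construction; ``frac_decoy_hits`` controls extra
    lower-scoring hits (which also violate the similarity filters);
    ``frac_A_only`` of loci exist only in parent A and yield no pair.
    """
    if config.n_loci < 1:
        raise ConfigError("n_loci must be >= 1")
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_loci
    a_ids = [f"A|tr{i:05d}" for i in range(n)]
    b_ids = [f"B|tr{i:05d}" for i in range(n)]
    only_a = rng.random(n) < config.frac_A_only

    def hit_row(q, s, pident, length, evalue, bitscore):
        return {
            "qseqid": q, "sseqid": s, "pident": round(pident, 2),
            "length": int(length), "mismatch": int(length * (100 - pident) / 100),
            "gapopen": 0, "qstart": 1, "qend": int(length),
            "sstart": 1, "send": int(length), "evalue": evalue,
            "bitscore": round(bitscore, 1),
        }

    ab_rows, ba_rows, pairs = [], [], []
    for i in range(n):
        if only_a[i]:
            continue
        ident = rng.uniform(85.0, 99.5)
        length = int(rng.integers(250, 1500))
        score = 2.0 * length * ident / 100.0
        ab_rows.append(hit_row(a_ids[i], b_ids[i], ident, length, 1e-180, score))
        ba_rows.append(hit_row(b_ids[i], a_ids[i], ident, length, 1e-180, score))
        pairs.append((a_ids[i], b_ids[i]))
        if rng.random() < config.frac_decoy_hits:
            j = int(rng.integers(0, n))
            if j != i:
                # decoy: low identity, short, weak evalue, strictly lower score
                d_ident = rng.uniform(40.0, 60.0)
                d_len = int(rng.integers(50, 180))
                d_score = 0.5 * d_len * d_ident / 100.0
                ab_rows.append(hit_row(a_ids[i], b_ids[j], d_ident, d_len, 1e-3, d_score))
                ba_rows.append(hit_row(b_ids[i], a_ids[j], d_ident, d_len, 1e-3, d_score))
    hits_ab = pd.DataFrame(ab_rows, columns=BLAST_COLUMNS)
    hits_ba = pd.DataFrame(ba_rows, columns=BLAST_COLUMNS)
    return hits_ab, hits_ba, pairs
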