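"""Configuration objects for simulation and pipeline runs.

``SimConfig`` holds the generative parameters of the synthetic allopolyploid
experiment: negative-binomial (Gamma-Poisson) count noise, per-locus
parental differential expression, per-locus homeolog proportion theta,
total-expression pattern assignment, and homeolog read misassignment rates
(qA, qB) mimicking imperfect read sorting between subgenomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import yaml

PATTERNS = (
    "no_change",
    "additivity",
    "eld_A",
    "eld_B",
    "transgressive_up",
    "transgressive_down",
)

#: Default pattern mix; proportions of the same order as observed in young
#: natural allotetraploids (a no-change majority, ELD mildly unbalanced,
#: transgressive down more common than up).
DEFAULT_PATTERN_FRACTIONS = {
    "no_change": 0.763,
    "additivity": 0.011,
    "eld_A": 0.062,
    "eld_B": 0.072,
    "transgressive_up": 0.033,
    "transgressive_down": 0.059,
}


class ConfigError(ValueError):
    """Raised for invalid simulation or pipeline configuration."""


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic two-parent + polyploid design.

    Parameters
    ----------
    n_loci
        Number of simulated ortholog pairs (loci).
    reps_per_group
        Biological replicates per species/form; the study design uses
        three individuals per population.
    mean_log_expression, sd_log_expression
        Natural-log location/scale of the log-normal baseline mean counts.
    dispersion
        NB dispersion phi with Var = mu + phi * mu**2.
    depth_factors
        Optional per-sample relative sequencing depths (parent A reps,
        parent B reps, polyploid reps, concatenated). ``None`` means equal.
    frac_parental_de
        Fraction of no-pattern-constrained loci with a true parental
        log2 fold change of +/- ``parental_lfc_magnitude``.
    parental_lfc_magnitude
        Magnitude (log2) of simulated parental differential expression and
        of the transgressive offset beyond the extreme parent.
    frac_biased_theta
        Fraction of loci with a biased true homeolog proportion.
    theta_biased_range
        Interval (excluding 0.5) from which biased theta values are drawn;
        the mirrored interval is used for bias toward parent B.
    pattern_fractions
        Mapping pattern name -> fraction, summing to 1.
    misassign_qA, misassign_qB
        Probability that a read from the A (resp. B) homeolog is assigned
        to the other homeolog's reference; must lie in [0, 0.5).
    seed
        Single integer seed; all randomness flows from it.
    """

    n_loci: int = 2000
    reps_per_group: int = 3
    mean_log_expression: float = math.log(100.0)
    sd_log_expression: float = 1.0
    dispersion: float = 0.05
    depth_factors: list[float] | None = None
    frac_parental_de: float = 0.30
    parental_lfc_magnitude: float = 2.0
    frac_biased_theta: float = 0.20
    theta_biased_range: tuple[float, float] = (0.65, 0.90)
    pattern_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_FRACTIONS)
    )
    misassign_qA: float = 0.02
    misassign_qB: float = 0.02
    seed: int = 0
    # hit-table generator knobs
    frac_decoy_hits: float = 0.3
    frac_A_only: float = 0.05

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ConfigError("n_loci must be positive")
        if self.reps_per_group < 2:
            raise ConfigError("reps_per_group must be >= 2")
        if self.sd_log_expression <= 0 or self.dispersion <= 0:
            raise ConfigError("scale parameters must be positive")
        for name in ("frac_parental_de", "frac_biased_theta", "frac_decoy_hits", "frac_A_only"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        lo, hi = self.theta_biased_range
        if not (0.0 < lo <= hi < 1.0) or (lo <= 0.5 <= hi):
            raise ConfigError("theta_biased_range must lie within (0,1) and exclude 0.5")
        for name in ("misassign_qA", "misassign_qB"):
            q = getattr(self, name)
            if not 0.0 <= q < 0.5:
                raise ConfigError(f"{name} must be in [0, 0.5)")
        if set(self.pattern_fractions) != set(PATTERNS):
            raise ConfigError(f"pattern_fractions must have keys {PATTERNS}")
        total = sum(self.pattern_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"pattern_fractions must sum to 1 (got {total})")
        if any(v < 0 for v in self.pattern_fractions.values()):
            raise ConfigError("pattern_fractions must be non-negative")
        if self.depth_factors is not None:
            if any(d <= 0 for d in self.depth_factors):
                raise ConfigError("depth_factors must be positive")
            if len(self.depth_factors) != 3 * self.reps_per_group:
                raise ConfigError("depth_factors must have one entry per sample (3 groups)")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "theta_biased_range" in raw:
            raw["theta_biased_range"] = tuple(raw["theta_biased_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["theta_biased_range"] = list(self.theta_biased_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
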