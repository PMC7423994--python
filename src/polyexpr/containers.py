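"""In-memory containers shared across the pipeline.

The central object is :class:`CountMatrix`, a locus x sample integer count
table with per-sample metadata (species/form, replicate).  Homeolog-resolved
counts travel as a long-format :class:`pandas.DataFrame` with columns
``locus_id, replicate, count_A, count_B`` (see :mod:`polyexpr.homeolog`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOMEOLOG_COLUMNS = ["locus_id", "replicate", "count_A", "count_B"]


@dataclass
class CountMatrix:
    """Locus x sample integer counts plus sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by locus id, one column per sample, integer dtype.
    samples
        DataFrame indexed by sample name with at least a ``group`` column
        (e.g. species or polyploid form); a ``replicate`` column is added
        when absent.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(
                {"group": ["unknown"] * self.counts.shape[1]},
                index=self.counts.columns,
            )
        if not self.counts.columns.equals(self.samples.index):
            missing = set(self.counts.columns) ^ set(self.samples.index)
            raise ValueError(f"sample metadata does not match count columns: {sorted(missing)}")
        if "replicate" not in self.samples.columns:
            self.samples = self.samples.assign(
                replicate=self.samples.groupby("group").cumcount() + 1
            )
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def loci(self) -> pd.Index:
        return self.counts.index

    @property
    def n_loci(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_samples(self, group: str) -> list[str]:
        """Sample names belonging to one group (species or polyploid form)."""
        sel = self.samples.index[self.samples["group"] == group]
        if len(sel) == 0:
            raise KeyError(f"no samples in group {group!r}")
        return list(sel)

    def subset_loci(self, loci) -> "CountMatrix":
        return CountMatrix(self.counts.loc[loci], self.samples.copy())

    def hstack(self, other: "CountMatrix") -> "CountMatrix":
        """Join two matrices on shared loci (inner join, column concat)."""
        shared = self.counts.index.intersection(other.counts.index)
        counts = pd.concat([self.counts.loc[shared], other.counts.loc[shared]], axis=1)
        samples = pd.concat([self.samples, other.samples])
        if counts.columns.duplicated().any():
            raise ValueError("duplicate sample names across matrices")
        return CountMatrix(counts, samples)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "locus_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, samples: pd.DataFrame | None = None) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts, samples)


def validate_homeolog_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format homeolog count table and normalise dtypes."""
    missing = [c for c in HOMEOLOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"homeolog table missing columns {missing}")
    df = df[HOMEOLOG_COLUMNS].copy()
    for col in ("count_A", "count_B"):
        if (df[col] < 0).any():
            raise ValueError(f"negative values in {col}")
        df[col] = df[col].astype(np.int64)
    return df
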