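"""Reciprocal-best-hit ortholog calling between two parental transcript sets.

Operates on BLAST tabular (outfmt 6) hit tables.  A pair (a, b) is retained
when b is a's best hit querying A against B *and* a is b's best hit in the
reverse search; best = maximal bitscore, ties broken by minimal e-value,
then lexicographically smallest subject id.  Retained pairs are then
filtered on similarity (e-value, percent identity, alignment length) of the
designated-direction hit, and optionally intersected with an externally
derived single-copy ortholog group table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
_NUMERIC = {"pident": float, "length": int, "evalue": float, "bitscore": float}


class HitParseError(ValueError):
    """Malformed BLAST tabular row; message carries the 1-based line number."""


@dataclass(frozen=True)
class OrthologPair:
    """One-to-one ortholog pair with the supporting hits from both searches."""

    id_A: str
    id_B: str
    hit_AB: pd.Series  # best A->B hit (query id_A)
    hit_BA: pd.Series  # best B->A hit (query id_B)

    @property
    def key(self) -> frozenset:
        return frozenset((self.id_A, self.id_B))


def read_blast6(path) -> pd.DataFrame:
    """Read a BLAST outfmt-6 table (no header); extra columns are ignored."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise HitParseError(f"line {ln}: expected >= 12 tab-separated fields")
            row = dict(zip(BLAST6_COLUMNS, parts[:12]))
            try:
                for col, typ in _NUMERIC.items():
                    row[col] = typ(float(row[col]))
            except ValueError as exc:
                raise HitParseError(f"line {ln}: {exc}") from None
            rows.append(row)
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


def _best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Best hit per query: max bitscore, then min evalue, then min sseqid."""
    if len(hits) == 0:
        return hits
    hits = hits[hits["qseqid"] != hits["sseqid"]]  # self-hit guard
    ranked = hits.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ranked.drop_duplicates("qseqid", keep="first")


def reciprocal_best_hits(
    hits_A_vs_B: pd.DataFrame, hits_B_vs_A: pd.DataFrame
) -> list[OrthologPair]:
    """Reciprocal best hits between transcript sets A and B.

    Queries with no hits simply yield no pair.  The output is symmetric in
    the roles of A and B (up to pair orientation).
    """
    best_ab = _best_hits(hits_A_vs_B)
    best_ba = _best_hits(hits_B_vs_A)
    if len(best_ab) == 0 or len(best_ba) == 0:
        return []
    ba_map = best_ba.set_index("qseqid")
    pairs = []
    for _, row in best_ab.iterrows():
        a, b = row["qseqid"], row["sseqid"]
        if b in ba_map.index and ba_map.loc[b, "sseqid"] == a:
            pairs.append(OrthologPair(a, b, row, ba_map.loc[b]))
    return pairs


def filter_pairs(
    pairs: list[OrthologPair],
    max_evalue: float = 1e-10,
    min_identity: float = 80.0,
    min_length: int = 200,
    direction: str = "BA",
    require_both: bool = False,
) -> list[OrthologPair]:
    """Similarity filter on RBH pairs (inclusive thresholds).

    ``direction`` selects which search supplies the filtered hit statistics:
    ``"BA"`` uses the B-as-query hit (the default mirrors filtering on the
    search that used the second parent's transcripts as query), ``"AB"`` the
    reverse; ``require_both`` demands both directions pass.
    """
    if direction not in ("AB", "BA"):
        raise ValueError("direction must be 'AB' or 'BA'")

    def ok(hit: pd.Series) -> bool:
        return (
            hit["evalue"] <= max_evalue
            and hit["pident"] >= min_identity
            and hit["length"] >= min_length
        )

    out = []
    for p in pairs:
        hits = [p.hit_BA, p.hit_AB] if direction == "BA" else [p.hit_AB, p.hit_BA]
        passed = ok(hits[0]) and (ok(hits[1]) if require_both else True)
        if passed:
            out.append(p)
    return out


def intersect_with_groups(
    pairs: list[OrthologPair], single_copy_groups: pd.DataFrame
) -> list[OrthologPair]:
    """Keep pairs also present (as an unordered id pair) in a group table.

    ``single_copy_groups`` is a two-column table (one A id and one B id per
    single-copy orthogroup); a duplicate id anywhere in it is a validation
    error because groups must be single copy.
    """
    if single_copy_groups.shape[1] < 2:
        raise ValueError("group table needs two columns")
    col_a, col_b = single_copy_groups.columns[:2]
    ids = pd.concat([single_copy_groups[col_a], single_copy_groups[col_b]])
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate id in single-copy group table: {dup!r}")
    group_keys = {
        frozenset((a, b))
        for a, b in zip(single_copy_groups[col_a], single_copy_groups[col_b])
    }
    return [p for p in pairs if p.key in group_keys]


def pairs_to_frame(pairs: list[OrthologPair]) -> pd.DataFrame:
    """Flatten pairs to a table with the supporting B->A hit statistics."""
    return pd.DataFrame(
        [
            {
                "id_A": p.id_A,
                "id_B": p.id_B,
                "pident": p.hit_BA["pident"],
                "length": p.hit_BA["length"],
                "evalue": p.hit_BA["evalue"],
                "bitscore": p.hit_BA["bitscore"],
            }
            for p in pairs
        ],
        columns=["id_A", "id_B", "pident", "length", "evalue", "bitscore"],
    )
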