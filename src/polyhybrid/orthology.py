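"""Allelic gene pairing by reciprocal best hit (RBH).

Consumes standard 12-column tabular pairwise-similarity tables in both
directions (R->C and C->R) and partitions genes into allelic gene pairs
(AGPs) and species-specific gene (SSG) sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class OrthologyPartition:
    """AGP pairs plus the leftover species-specific gene sets."""

    agps: pd.DataFrame  # columns: gene_r, gene_c
    ssg_r: list[str] = field(default_factory=list)
    ssg_c: list[str] = field(default_factory=list)

    @property
    def n_agps(self) -> int:
        return len(self.agps)


def read_hit_table(path) -> pd.DataFrame:
    """Read a headerless or headered 12-column tabular hit file."""
    first = pd.read_csv(path, sep="\t", nrows=1)
    header = 0 if "qseqid" in first.columns else None
    hits = pd.read_csv(path, sep="\t", header=header)
    if header is None:
        if hits.shape[1] != len(HIT_COLUMNS):
            raise ValueError(
                f"expected {len(HIT_COLUMNS)} columns in {path}, got {hits.shape[1]}"
            )
        hits.columns = HIT_COLUMNS
    return hits


def _best_hits(hits: pd.DataFrame, evalue_max: float) -> pd.Series:
    """Best subject per query: highest bitscore, then lowest e-value,
    then lexicographically smallest subject id."""
    h = hits[hits["evalue"] <= evalue_max]
    if h.empty:
        return pd.Series(dtype=object)
    # collapse duplicate (query, subject) rows to their best-scoring record
    h = (
        h.sort_values(
            ["qseqid", "bitscore", "evalue", "sseqid"],
            ascending=[True, False, True, True],
        )
        .drop_duplicates(["qseqid", "sseqid"])
    )
    best = h.drop_duplicates("qseqid", keep="first")
    return best.set_index("qseqid")["sseqid"]


def reciprocal_best_pairs(
    hits_rc: pd.DataFrame,
    hits_cr: pd.DataFrame,
    catalog: pd.DataFrame | None = None,
    evalue_max: float = 1e-6,
    min_len_bp: int = 300,
) -> OrthologyPartition:
    """Derive AGPs by reciprocal best hit and partition the rest into SSGs.

    (r, c) is an AGP iff c is r's best hit in `hits_rc` and r is c's best
    hit in `hits_cr`, both with e-value <= `evalue_max`.  When a catalog is
    supplied, genes shorter than `min_len_bp` are removed before pairing and
    the SSG sets cover every retained catalog gene not in an AGP; without a
    catalog, SSG sets cover only genes seen as queries in the hit tables.
    """
    required = {"qseqid", "sseqid", "evalue", "bitscore"}
    for name, hits in (("hits_rc", hits_rc), ("hits_cr", hits_cr)):
        missing = required - set(hits.columns)
        if missing:
            raise ValueError(f"{name} lacks required columns {sorted(missing)}")

    if catalog is not None:
        short = set(catalog.index[catalog["length_bp"] < min_len_bp])
        keep_r = set(catalog.index[catalog["subgenome"] == "R"]) - short
        keep_c = set(catalog.index[catalog["subgenome"] == "C"]) - short
        hits_rc = hits_rc[
            hits_rc["qseqid"].isin(keep_r) & hits_rc["sseqid"].isin(keep_c)
        ]
        hits_cr = hits_cr[
            hits_cr["qseqid"].isin(keep_c) & hits_cr["sseqid"].isin(keep_r)
        ]

    best_rc = _best_hits(hits_rc, evalue_max)
    best_cr = _best_hits(hits_cr, evalue_max)

    pairs = []
    for r, c in best_rc.items():
        if best_cr.get(c) == r:
            pairs.append((r, c))
    pairs.sort()
    agps = pd.DataFrame(pairs, columns=["gene_r", "gene_c"])

    in_agp_r = set(agps["gene_r"])
    in_agp_c = set(agps["gene_c"])
    if catalog is not None:
        ssg_r = sorted(keep_r - in_agp_r)
        ssg_c = sorted(keep_c - in_agp_c)
    else:
        ssg_r = sorted(set(hits_rc["qseqid"]) - in_agp_r)
        ssg_c = sorted(set(hits_cr["qseqid"]) - in_agp_c)
    return OrthologyPartition(agps=agps, ssg_r=ssg_r, ssg_c=ssg_c)
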