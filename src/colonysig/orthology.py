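"""Reciprocal-best-hit orthology from tabular similarity hits.

Consumes standard 12-column tabular alignment output (qseqid, sseqid,
pident, length, mismatch, gapopen, qstart, qend, sstart, send, evalue,
bitscore) for both search directions, identifies per-query best hits
(max bitscore, ties broken by min e-value, residual ties dropped as
ambiguous), intersects them into a reciprocal-best-hit map, and
transfers term annotations across it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "HIT_COLUMNS",
    "OrthologMap",
    "best_hits",
    "read_hit_table",
    "reciprocal_best_hits",
    "transfer_annotations",
]

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(path) -> pd.DataFrame:
    """Read a 12-column tabular hit file (no header), or a headered file
    containing at least qseqid/sseqid/evalue/bitscore."""
    first = pd.read_csv(path, sep="\t", nrows=1)
    if {"qseqid", "sseqid", "bitscore"} <= set(first.columns):
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    missing = {"qseqid", "sseqid", "evalue", "bitscore"} - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return df


def best_hits(hits: pd.DataFrame, evalue_ceiling: float | None = None) -> pd.Series:
    """Per-query best subject: maximal bitscore, ties broken by minimal
    e-value; queries still tied after both criteria are dropped as
    ambiguous.  Returns a Series query -> subject."""
    df = hits
    if evalue_ceiling is not None:
        df = df[df["evalue"] <= evalue_ceiling]
    if df.empty:
        return pd.Series(dtype=object)
    best = {}
    for query, sub in df.groupby("qseqid", sort=False):
        top = sub[sub["bitscore"] == sub["bitscore"].max()]
        top = top[top["evalue"] == top["evalue"].min()]
        subjects = top["sseqid"].unique()
        if len(subjects) == 1:
            best[query] = subjects[0]
    return pd.Series(best, dtype=object)


@dataclass
class OrthologMap:
    """A partial bijection between two gene sets with per-direction
    best-hit scores."""

    pairs: pd.DataFrame  # columns gene_A, gene_B, score_AB, score_BA

    def __post_init__(self):
        if self.pairs["gene_A"].duplicated().any() or self.pairs["gene_B"].duplicated().any():
            raise ValueError("ortholog map must be a partial bijection")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict:
        return dict(zip(self.pairs["gene_A"], self.pairs["gene_B"]))

    def flipped(self) -> "OrthologMap":
        df = self.pairs.rename(
            columns={"gene_A": "gene_B", "gene_B": "gene_A",
                     "score_AB": "score_BA", "score_BA": "score_AB"}
        )
        return OrthologMap(df[["gene_A", "gene_B", "score_AB", "score_BA"]].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        return cls(pd.read_csv(path, sep="\t"))


def reciprocal_best_hits(hits_AB: pd.DataFrame, hits_BA: pd.DataFrame,
                         evalue_ceiling: float | None = None) -> OrthologMap:
    """Pairs (a, b) with best_AB(a) = b and best_BA(b) = a."""
    fwd = best_hits(hits_AB, evalue_ceiling)
    rev = best_hits(hits_BA, evalue_ceiling)
    score_ab = hits_AB.groupby(["qseqid", "sseqid"])["bitscore"].max()
    score_ba = hits_BA.groupby(["qseqid", "sseqid"])["bitscore"].max()
    rows = []
    for a, b in fwd.items():
        if rev.get(b) == a:
            rows.append({
                "gene_A": a, "gene_B": b,
                "score_AB": float(score_ab.loc[(a, b)]),
                "score_BA": float(score_ba.loc[(b, a)]),
            })
    pairs = pd.DataFrame(rows, columns=["gene_A", "gene_B", "score_AB", "score_BA"])
    return OrthologMap(pairs)


def transfer_annotations(ortholog_map: OrthologMap, donor_annotations: dict,
                         recipient_genes=None) -> dict:
    """Copy the donor partner's term set to each mapped recipient gene.

    Recipient genes without a partner (or whose partner has no terms)
    get the empty set.  ``recipient_genes`` defaults to the mapped
    genes.
    """
    a_to_b = ortholog_map.as_dict()
    if recipient_genes is None:
        recipient_genes = list(a_to_b)
    out = {}
    for gene in recipient_genes:
        partner = a_to_b.get(gene)
        out[gene] = set(donor_annotations.get(partner, set())) if partner else set()
    return out
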