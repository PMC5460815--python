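"""Tandem / segmental classification of paralog pairs.

A pair is *tandem* when both genes sit on the same chromosome with strictly
fewer than ``tandem_threshold`` (default 5) gene loci between them, counting
every annotated gene. A pair is *segmental* when it appears on a duplicated
(syntenic) chromosomal block listed in the block table. Pairs satisfying
neither rule are *unclassified*. A pair satisfying both rules is labelled
tandem and flagged ``also_on_block`` so no information is lost.
"""

from __future__ import annotations

import pandas as pd

from .errors import ConsistencyError


def rank_loci(loci: pd.DataFrame) -> pd.DataFrame:
    """Attach dense per-chromosome ranks (1..n by ascending start).

    ``loci`` needs columns ``gene_id, chromosome, start, end, strand``.
    Ties broken by (end, gene_id) for determinism; duplicate gene ids are a
    consistency error. Input row order is irrelevant.
    """
    if loci["gene_id"].duplicated().any():
        dup = loci.loc[loci["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ConsistencyError(f"duplicate gene_id {dup!r} in locus table")
    out = loci.sort_values(["chromosome", "start", "end", "gene_id"]).reset_index(
        drop=True
    )
    out["rank"] = out.groupby("chromosome").cumcount() + 1
    return out


def classify_pairs(
    pairs: pd.DataFrame,
    ranked_loci: pd.DataFrame,
    blocks: pd.DataFrame | None = None,
    tandem_threshold: int = 5,
) -> pd.DataFrame:
    """Classify candidate paralog pairs as tandem / segmental / unclassified.

    Parameters
    ----------
    pairs : columns ``gene_a, gene_b``.
    ranked_loci : output of :func:`rank_loci`.
    blocks : columns ``block_id, gene_a, gene_b`` (orientation-free match).
    tandem_threshold : tandem iff same chromosome and intervening loci count
        is strictly below this (the rule is "< 5 gene loci in-between").

    Returns a table with ``gene_a, gene_b, class, intervening_loci, block_id,
    also_on_block``; ``intervening_loci`` is |rank_a - rank_b| - 1 for
    same-chromosome pairs and <NA> otherwise.
    """
    info = ranked_loci.set_index("gene_id")
    missing = (set(pairs["gene_a"]) | set(pairs["gene_b"])) - set(info.index)
    if missing:
        raise ConsistencyError(
            f"pair gene(s) missing from locus table: {sorted(missing)[:5]}"
        )
    block_of: dict[frozenset, str] = {}
    if blocks is not None:
        for row in blocks.itertuples():
            block_of[frozenset((row.gene_a, row.gene_b))] = row.block_id
    records = []
    for row in pairs.itertuples():
        a, b = row.gene_a, row.gene_b
        same_chrom = info.at[a, "chromosome"] == info.at[b, "chromosome"]
        intervening = (
            abs(int(info.at[a, "rank"]) - int(info.at[b, "rank"])) - 1
            if same_chrom
            else None
        )
        block_id = block_of.get(frozenset((a, b)))
        tandem = same_chrom and intervening < tandem_threshold
        if tandem:
            cls = "tandem"
        elif block_id is not None:
            cls = "segmental"
        else:
            cls = "unclassified"
        records.append(
            {
                "gene_a": a,
                "gene_b": b,
                "class": cls,
                "intervening_loci": intervening,
                "block_id": block_id if cls == "segmental" else None,
                "also_on_block": bool(tandem and block_id is not None),
            }
        )
    out = pd.DataFrame(
        records,
        columns=[
            "gene_a",
            "gene_b",
            "class",
            "intervening_loci",
            "block_id",
            "also_on_block",
        ],
    )
    out["intervening_loci"] = out["intervening_loci"].astype("Int64")
    return out


def propose_pairs(
    proteins: dict[str, str], identity_threshold: float = 70.0
) -> pd.DataFrame:
    """Convenience paralog-candidate proposal: all protein pairs whose global
    identity is >= ``identity_threshold`` percent. Quadratic — intended for
    family-sized inputs, not whole proteomes."""
    from .alignment import global_identity

    ids = sorted(proteins)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ident, _ = global_identity(proteins[a], proteins[b])
            if ident >= identity_threshold:
                rows.append({"gene_a": a, "gene_b": b, "protein_identity_pct": ident})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "protein_identity_pct"])
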