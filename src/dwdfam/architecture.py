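"""Domain-architecture typing of candidate DWD proteins.

Candidates (proteins with >= 1 DWD motif) are partitioned into architecture
types keyed by (DWD-motif count, sorted multiset of non-WD40 domain names).
The WD40 repeat count itself is deliberately not part of the key: repeats are
the scaffold every candidate shares, and types are meant to separate
candidates by motif dosage and accessory domains. Type labels (A, B, C, ...)
are assigned in descending member-count order with lexicographic tie-breaks,
so labelling is deterministic for a given cohort.
"""

from __future__ import annotations

import itertools
import string

import pandas as pd

from .errors import ConsistencyError


def _labels():
    """A, B, ..., Z, AA, AB, ... — unbounded deterministic label stream."""
    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(combo)


def signature(dwd_count: int, extra_domains) -> tuple:
    """Canonical type key: motif count plus the sorted multiset of non-WD40
    domain names."""
    return (int(dwd_count), tuple(sorted(extra_domains)))


def assign_types(
    dwd_counts: pd.Series, domains: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition candidates into architecture types.

    Parameters
    ----------
    dwd_counts : per-protein DWD motif counts (index = protein_id); every
        entry must be >= 1 — proteins without a motif are not DWD proteins
        and are rejected.
    domains : domain annotation table (``protein_id, domain_name, start, end``);
        non-WD40 rows define the accessory-domain multiset of each candidate.

    Returns
    -------
    (catalog, assignment) : catalog has one row per type
        (``type_label, dwd_count, extra_domains, member_count``); assignment
        maps each protein to its label (``protein_id, type_label``).
    """
    bad = dwd_counts[dwd_counts < 1]
    if len(bad):
        raise ConsistencyError(
            "candidates without a DWD motif are not DWD proteins: "
            f"{list(bad.index[:5])}"
        )
    extras = {
        pid: tuple(sorted(grp["domain_name"]))
        for pid, grp in domains[domains["domain_name"] != "WD40"].groupby("protein_id")
    }
    keys = {
        pid: signature(dwd_counts[pid], extras.get(pid, ()))
        for pid in dwd_counts.index
    }
    members: dict[tuple, list[str]] = {}
    for pid, key in keys.items():
        members.setdefault(key, []).append(pid)
    # deterministic labelling: by descending size, then lexicographic key
    ordered = sorted(members.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    label_of = {key: lab for (key, _), lab in zip(ordered, _labels())}
    catalog = pd.DataFrame(
        [
            {
                "type_label": label_of[key],
                "dwd_count": key[0],
                "extra_domains": ";".join(key[1]),
                "member_count": len(pids),
            }
            for key, pids in ordered
        ]
    )
    assignment = pd.DataFrame(
        sorted((pid, label_of[key]) for pid, key in keys.items()),
        columns=["protein_id", "type_label"],
    )
    return catalog, assignment


def summarize_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Report table ordered by descending member count then label, with a
    trailing TOTAL row."""
    cols = ["type_label", "dwd_count", "extra_domains", "member_count"]
    if catalog.empty:
        body = pd.DataFrame(columns=cols)
        total = 0
    else:
        body = catalog.sort_values(
            ["member_count", "type_label"], ascending=[False, True]
        )[cols]
        total = int(body["member_count"].sum())
    total_row = pd.DataFrame(
        [{"type_label": "TOTAL", "dwd_count": "", "extra_domains": "", "member_count": total}]
    )
    return pd.concat([body, total_row], ignore_index=True)
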