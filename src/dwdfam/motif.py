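"""Degenerate protein-motif compilation and WD40-restricted scanning.

The DWD box (WDxR motif) is a 16-residue degenerate signature found inside
WD40 repeats of substrate receptors of the CUL4-DDB1 E3 ubiquitin ligase.
Four positions are strongly conserved: an acidic residue (D/E) at position 7,
an aromatic (W/Y) at 13, an acidic (D/E) at 14 and a basic (R/K) at 16.
The scanner works in two steps, mirroring genome-wide family surveys: a
protein is first required to carry annotated WD40 repeats, and the degenerate
pattern is then matched only against windows lying inside those repeats.

Patterns use the PROSITE-flavoured dash-separated dialect, e.g.::

    [IFVL]-[IFVL]-[AGST]-[AGST]-[AGST]-x-[DE]-x(2)-[IFVL]-x-[IFVL]-[WY]-[DE]-[IFVL]-[RK]

where ``[..]`` is an allowed-residue set, ``x`` a wildcard and ``x(n)`` n
consecutive wildcards.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConsistencyError, PatternSyntaxError
from .utils import STANDARD_AA, validate_protein_sequence

#: The canonical 16-residue DWD-box pattern.
DWD_PATTERN = (
    "[IFVL]-[IFVL]-[AGST]-[AGST]-[AGST]-x-[DE]-x(2)-"
    "[IFVL]-x-[IFVL]-[WY]-[DE]-[IFVL]-[RK]"
)

_TOKEN_RE = re.compile(r"^(?:\[(?P<set>[A-Za-z]+)\]|x(?:\((?P<rep>\d+)\))?)$")


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate pattern.

    ``positions[i]`` is either a frozenset of allowed residues or ``None`` for
    a wildcard. Wildcards accept any residue including ambiguity codes;
    constrained positions accept exactly their listed residues, so ambiguity
    codes (B, J, Z, X, U, O) never satisfy a constrained position.
    """

    positions: tuple[frozenset | None, ...]
    source_string: str
    _regex: re.Pattern = field(repr=False, compare=False, default=None)

    @property
    def length(self) -> int:
        return len(self.positions)

    def matches_at(self, sequence: str, start0: int) -> bool:
        """Check the window starting at 0-based ``start0`` against the pattern."""
        if start0 < 0 or start0 + self.length > len(sequence):
            return False
        for pos, allowed in enumerate(self.positions):
            if allowed is not None and sequence[start0 + pos].upper() not in allowed:
                return False
        return True

    def find_all(self, sequence: str) -> list[int]:
        """All 0-based start offsets of (possibly overlapping) matches."""
        seq = sequence.upper()
        return [m.start() for m in self._regex.finditer(seq)]


@dataclass(frozen=True)
class MotifHit:
    """One motif match: 1-based closed coordinates in protein space plus the
    ordinal (N-to-C) of the WD40 repeat containing it."""

    protein_id: str
    start: int
    end: int
    wd40_index: int


def compile_pattern(pattern_string: str) -> MotifPattern:
    """Compile a dash-separated degenerate pattern into a :class:`MotifPattern`.

    Raises :class:`PatternSyntaxError` (carrying the 0-based token index) on a
    malformed token, an empty set, or a letter outside the 20 standard amino
    acids.
    """
    text = pattern_string.strip()
    if text.startswith("(") and text.endswith(")"):
        text = text[1:-1]
    if not text:
        raise PatternSyntaxError("empty pattern", token_index=0)
    positions: list[frozenset | None] = []
    for idx, token in enumerate(text.split("-")):
        m = _TOKEN_RE.match(token.strip())
        if m is None:
            raise PatternSyntaxError(
                f"malformed token {token!r} at position {idx}", token_index=idx
            )
        if m.group("set") is not None:
            letters = m.group("set").upper()
            bad = sorted(set(letters) - STANDARD_AA)
            if bad:
                raise PatternSyntaxError(
                    f"non-standard residue(s) {''.join(bad)} in token {token!r} "
                    f"at position {idx}",
                    token_index=idx,
                )
            positions.append(frozenset(letters))
        else:
            rep = int(m.group("rep") or 1)
            if rep < 1:
                raise PatternSyntaxError(
                    f"non-positive repeat in token {token!r} at position {idx}",
                    token_index=idx,
                )
            positions.extend([None] * rep)
    regex = re.compile(
        "(?=("
        + "".join(
            "." if allowed is None else "[" + "".join(sorted(allowed)) + "]"
            for allowed in positions
        )
        + "))"
    )
    return MotifPattern(tuple(positions), pattern_string, regex)


def merge_wd40_intervals(
    domains: pd.DataFrame, slack: int = 0
) -> list[tuple[int, int]]:
    """Merge WD40 repeat intervals whose gap is <= ``slack`` residues.

    ``domains`` needs columns ``domain_name``, ``start``, ``end`` (1-based
    closed). Returns merged closed intervals sorted by start. A motif window
    spanning two abutting repeats then counts as contained in their union.
    """
    wd = domains[domains["domain_name"] == "WD40"]
    ivals = sorted(zip(wd["start"].astype(int), wd["end"].astype(int)))
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s - merged[-1][1] - 1 <= slack:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _wd40_sorted(domains: pd.DataFrame) -> list[tuple[int, int]]:
    wd = domains[domains["domain_name"] == "WD40"]
    return sorted(zip(wd["start"].astype(int), wd["end"].astype(int)))


def scan_protein(
    protein_id: str,
    sequence: str,
    domains: pd.DataFrame,
    pattern: MotifPattern,
    require_containment: bool = True,
    containment_slack: int = 0,
) -> list[MotifHit]:
    """Scan one protein for motif matches, optionally restricted to WD40 repeats.

    All overlapping matches are reported, in ascending start order. With
    ``require_containment`` (the default) a match is kept only when its full
    window lies inside a WD40 repeat (or inside the union of repeats whose
    gaps are <= ``containment_slack``). ``wd40_index`` is the 1-based ordinal,
    in N-to-C order, of the repeat containing the hit start (0 when
    containment is not required and the hit lies outside every repeat).
    """
    if not sequence:
        raise ConsistencyError(f"empty sequence for protein {protein_id!r}")
    validate_protein_sequence(sequence)
    repeats = _wd40_sorted(domains)
    merged = merge_wd40_intervals(domains, slack=containment_slack)
    hits: list[MotifHit] = []
    for start0 in pattern.find_all(sequence):
        start, end = start0 + 1, start0 + pattern.length
        contained = any(s <= start and end <= e for s, e in merged)
        if require_containment and not contained:
            continue
        index = 0
        for k, (s, e) in enumerate(repeats, start=1):
            if s <= start <= e:
                index = k
                break
        hits.append(MotifHit(protein_id, start, end, index))
    return hits


def scan_proteome(
    proteins: dict[str, str],
    domains: pd.DataFrame,
    pattern: MotifPattern | None = None,
    require_containment: bool = True,
    containment_slack: int = 0,
) -> pd.DataFrame:
    """Scan every protein; returns a hit table with columns
    ``protein_id, start, end, wd40_index``."""
    if pattern is None:
        pattern = compile_pattern(DWD_PATTERN)
    rows = []
    for pid, seq in proteins.items():
        dom = domains[domains["protein_id"] == pid]
        for h in scan_protein(
            pid, seq, dom, pattern, require_containment, containment_slack
        ):
            rows.append((h.protein_id, h.start, h.end, h.wd40_index))
    return pd.DataFrame(rows, columns=["protein_id", "start", "end", "wd40_index"])


def count_motifs_per_protein(
    hits: pd.DataFrame,
    protein_ids: list[str],
    dedupe_overlapping: bool = False,
) -> pd.Series:
    """Per-protein motif counts over the whole proteome (zero included).

    With ``dedupe_overlapping`` a greedy left-to-right pass keeps only
    non-overlapping hits before counting. Proteins with count >= 1 form the
    candidate DWD set. Raises :class:`ConsistencyError` if a hit references a
    protein absent from ``protein_ids``.
    """
    known = set(protein_ids)
    unknown = set(hits["protein_id"]) - known
    if unknown:
        raise ConsistencyError(
            f"hits reference unknown protein(s): {sorted(unknown)[:5]}"
        )
    if dedupe_overlapping and len(hits):
        kept = []
        for pid, grp in hits.sort_values(["protein_id", "start"]).groupby(
            "protein_id", sort=False
        ):
            last_end = 0
            for row in grp.itertuples():
                if row.start > last_end:
                    kept.append(row.Index)
                    last_end = row.end
        hits = hits.loc[kept]
    counts = hits.groupby("protein_id").size()
    return counts.reindex(protein_ids, fill_value=0).astype(int).rename("dwd_count")
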