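"""Nei-Gojobori (1986) Ka/Ks estimation for codon-aligned CDS pairs.

The NG86 counting method estimates nonsynonymous (Ka) and synonymous (Ks)
substitutions per respective site:

* **Sites.** Each codon contributes 3 sites, split into synonymous and
  nonsynonymous fractions by enumerating the 9 single-nucleotide mutations
  of the codon under the standard genetic code. Mutations to stop codons
  count as nonsynonymous (the convention of common implementations), and
  per-codon fractions are normalized so every codon contributes exactly 3
  sites. Site totals are averaged over the two sequences.

* **Differences.** For a codon pair differing at k positions, the k!
  orderings in which the differences could have accumulated are enumerated;
  each step of a pathway is scored synonymous or nonsynonymous in its codon
  context. Pathways passing through a stop codon are excluded and the
  remaining pathways re-weighted equally (if every pathway crosses a stop,
  all are kept — a practical fallback for a case the standard code makes
  vanishingly rare).

* **Rates.** Ka = Na/N, Ks = Ns/S, each optionally Jukes-Cantor corrected
  (d = -3/4 ln(1 - 4p/3)); a proportion at or beyond the JC saturation point
  yields NaN. The ratio Ka/Ks is ``None`` (undefined) when Ks = 0 or not
  finite.

Gap-containing codon columns are dropped before counting; internal stop
codons in either sequence are an input error.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass

from Bio.Data import CodonTable

from .errors import SequenceError

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_AA = dict(_TABLE.forward_table)
_BASES = "ACGT"


def translate_codon(codon: str) -> str | None:
    """Amino acid for a sense codon, ``None`` for a stop."""
    return _AA.get(codon)


@functools.lru_cache(maxsize=None)
def codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site content of one sense codon.

    Enumerates the 9 single-nucleotide neighbours; changes to stops count as
    nonsynonymous; totals normalized to 3 sites per codon.
    """
    aa = _AA[codon]
    syn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1 :]
            if neighbor not in STOP_CODONS and _AA[neighbor] == aa:
                syn += 1
    s = syn / 3.0
    return s, 3.0 - s


@functools.lru_cache(maxsize=None)
def codon_path_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense codons,
    averaged over stop-free mutational pathways with equal weights."""
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        ns = na = 0
        crossed_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                crossed_stop = True
            aa_cur, aa_nxt = _AA.get(current), _AA.get(nxt)
            if aa_cur is not None and aa_cur == aa_nxt:
                ns += 1
            else:
                na += 1  # stop-involving steps score nonsynonymous (fallback only)
            current = nxt
        all_paths.append((ns, na))
        if not crossed_stop:
            valid.append((ns, na))
    paths = valid if valid else all_paths
    ns_avg = sum(p[0] for p in paths) / len(paths)
    na_avg = sum(p[1] for p in paths) / len(paths)
    return ns_avg, na_avg


@dataclass(frozen=True)
class KaKsResult:
    """NG86 output: rates, the ratio (None when undefined), and the raw site
    and difference counts."""

    ka: float
    ks: float
    ratio: float | None
    na: float
    ns: float
    n_sites: float
    s_sites: float
    codons_counted: int
    correction: str

    def purifying(self) -> bool | None:
        """True when Ka/Ks < 1; None when the ratio is undefined."""
        return None if self.ratio is None else self.ratio < 1.0


def _split_codons(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    a = cds_a.upper().replace("U", "T")
    b = cds_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise SequenceError(
            f"CDS lengths differ ({len(a)} vs {len(b)}); a codon alignment is required"
        )
    if len(a) % 3:
        raise SequenceError(f"aligned length {len(a)} is not a multiple of 3")
    pairs = []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue  # gap-containing codon columns are dropped
        for codon, which in ((ca, "first"), (cb, "second")):
            if codon in STOP_CODONS:
                if i + 3 < len(a):
                    raise SequenceError(
                        f"internal stop codon {codon} at nt {i + 1} in {which} CDS"
                    )
            elif codon not in _AA:
                raise SequenceError(
                    f"invalid codon {codon!r} at nt {i + 1} in {which} CDS"
                )
        pairs.append((ca, cb))
    # trailing aligned stop codons (a full-length ORF) are not counted
    if pairs and (pairs[-1][0] in STOP_CODONS or pairs[-1][1] in STOP_CODONS):
        pairs = pairs[:-1]
    return pairs


def _jc_correct(p: float) -> float:
    if p == 0.0:
        return 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return math.nan  # saturated; distance undefined under JC
    return -0.75 * math.log(arg)


def compute_kaks(cds_a: str, cds_b: str, correction: str = "jukes-cantor") -> KaKsResult:
    """NG86 Ka/Ks for a codon-aligned CDS pair.

    ``correction`` is ``"jukes-cantor"`` (default) or ``"none"``. Symmetric
    in its arguments. See the module docstring for conventions.
    """
    if correction not in ("jukes-cantor", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    codons = _split_codons(cds_a, cds_b)
    if not codons:
        raise SequenceError("no gap-free codon columns to count")
    s_sites = n_sites = 0.0
    ns = na = 0.0
    for ca, cb in codons:
        sa, _ = codon_site_fractions(ca)
        sb, _ = codon_site_fractions(cb)
        s_sites += (sa + sb) / 2.0
        d_ns, d_na = codon_path_differences(ca, cb)
        ns += d_ns
        na += d_na
    n_sites = 3.0 * len(codons) - s_sites
    ps = ns / s_sites if s_sites > 0 else 0.0
    pn = na / n_sites if n_sites > 0 else 0.0
    if correction == "jukes-cantor":
        ks, ka = _jc_correct(ps), _jc_correct(pn)
    else:
        ks, ka = ps, pn
    ratio = ka / ks if (ks and math.isfinite(ks) and math.isfinite(ka)) else None
    return KaKsResult(
        ka=ka,
        ks=ks,
        ratio=ratio,
        na=na,
        ns=ns,
        n_sites=n_sites,
        s_sites=s_sites,
        codons_counted=len(codons),
        correction=correction,
    )
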