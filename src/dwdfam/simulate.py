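"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator consumes a *plan* (a validated dataclass with a seed) and
emits both the input files a real analysis would consume and a truth table
recording exactly what was planted, so downstream stages have an exact
acceptance surface:

- :func:`generate_proteome` — proteins with planted WD40 repeats and DWD
  motifs at known coordinates. Background residues are uniform over the 20
  amino acids (the hardest regime for accidental matches); any accidental
  pattern match falling inside a WD40 interval is rejected and resampled, so
  the truth table is exhaustive for in-repeat hits. Accidental matches
  *outside* WD40 intervals are left in place on purpose — the scanner's
  containment rule must ignore them.
- :func:`generate_gene_map` — gene loci on chromosomes with planted tandem
  pairs (controlled intervening-gene counts), segmental pairs on listed
  duplicate blocks, and same-chromosome distractor pairs (>= 5 intervening)
  that must stay unclassified.
- :func:`evolve_codon_pair` — a stop-free ancestor CDS and a derived copy
  produced by site-by-site substitutions with separate synonymous and
  nonsynonymous per-site probabilities; the realized substitution log is a
  valid oracle for NG86 recovery.
- :func:`generate_expression` — an FPKM matrix with planted tissue-specific
  genes at controlled fold changes and multiplicative gamma noise of chosen
  coefficient of variation.

All generators are deterministic: identical plan + seed gives byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidPlanError, PlanInfeasibleError
from .kaks import STOP_CODONS, SENSE_CODONS, translate_codon
from .motif import DWD_PATTERN, MotifPattern, compile_pattern, merge_wd40_intervals

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_WD40_LEN = 40
_BASES = "ACGT"


# ---------------------------------------------------------------- proteome

@dataclass
class ProteomePlan:
    """Plan for a synthetic proteome with planted WD40 repeats and DWD motifs.

    ``motif_counts`` maps protein index -> planted motif count (0..3);
    unlisted proteins get zero. Each planted motif goes into its own WD40
    repeat, so the count may not exceed the repeats of that protein.
    """

    n_proteins: int = 20
    motif_counts: dict[int, int] = field(default_factory=dict)
    wd40_repeats_per_protein: tuple[int, int] = (4, 8)
    protein_length: tuple[int, int] = (280, 450)
    seed: int = 0
    pattern: str = DWD_PATTERN

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise InvalidPlanError("n_proteins must be >= 1")
        lo, hi = self.wd40_repeats_per_protein
        if not (1 <= lo <= hi):
            raise InvalidPlanError("invalid wd40_repeats_per_protein range")
        for idx, cnt in self.motif_counts.items():
            if not 0 <= cnt <= 3:
                raise InvalidPlanError(f"motif count {cnt} for protein {idx} not in 0..3")
            if not 0 <= idx < self.n_proteins:
                raise InvalidPlanError(f"protein index {idx} out of range")
            if cnt > lo:
                # planted motifs must fit the *guaranteed* repeat count
                raise PlanInfeasibleError(
                    f"protein {idx} requests {cnt} motifs but only {lo} repeats "
                    "are guaranteed"
                )


def _feasible_layout(plan: ProteomePlan, n_rep: int, rng) -> tuple[int, list[tuple[int, int]]]:
    """Sample a protein length and non-overlapping WD40 intervals (1-based)."""
    lo, hi = plan.protein_length
    min_needed = 10 + n_rep * (_WD40_LEN + 4)
    if min_needed > hi:
        raise PlanInfeasibleError(
            f"{n_rep} WD40 repeats need >= {min_needed} residues but "
            f"protein_length max is {hi}"
        )
    length = int(rng.integers(max(lo, min_needed), hi + 1))
    spare = length - min_needed
    # distribute spare residues over the n_rep+1 gaps around the repeats
    cuts = np.sort(rng.integers(0, spare + 1, size=n_rep))
    gaps = np.diff(np.concatenate(([0], cuts, [spare])))
    intervals = []
    pos = 10 + int(gaps[0])
    for g in range(n_rep):
        start = pos + 1  # 1-based
        intervals.append((start, start + _WD40_LEN - 1))
        pos += _WD40_LEN + 4 + int(gaps[g + 1])
    return length, intervals


def _plant_motif(seq: np.ndarray, start0: int, pattern: MotifPattern, rng) -> None:
    for k, allowed in enumerate(pattern.positions):
        if allowed is None:
            seq[start0 + k] = _AA20[rng.integers(len(_AA20))]
        else:
            choices = sorted(allowed)
            seq[start0 + k] = choices[rng.integers(len(choices))]


def generate_proteome(
    plan: ProteomePlan,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Returns ``(proteins, domain_table, motif_truth)``.

    ``proteins`` maps id -> sequence; ``domain_table`` has columns
    ``protein_id, domain_name, start, end``; ``motif_truth`` has
    ``protein_id, start, end, wd40_index`` (1-based closed, protein
    coordinates).
    """
    plan.validate()
    pattern = compile_pattern(plan.pattern)
    rng = np.random.default_rng(plan.seed)
    proteins: dict[str, str] = {}
    domain_rows = []
    truth_rows = []
    rep_lo, rep_hi = plan.wd40_repeats_per_protein
    for i in range(plan.n_proteins):
        pid = f"P{i + 1:04d}"
        want = plan.motif_counts.get(i, 0)
        n_rep = int(rng.integers(max(rep_lo, want, 1), rep_hi + 1))
        length, intervals = _feasible_layout(plan, n_rep, rng)
        seq = _AA20[rng.integers(len(_AA20), size=length)].copy()
        chosen = sorted(rng.choice(n_rep, size=want, replace=False).tolist())
        planted: list[tuple[int, int, int]] = []  # (start0, end0, wd40_index)
        for rep_idx in chosen:
            s, e = intervals[rep_idx]
            offset = int(rng.integers(0, _WD40_LEN - pattern.length + 1))
            start0 = (s - 1) + offset
            _plant_motif(seq, start0, pattern, rng)
            planted.append((start0, start0 + pattern.length - 1, rep_idx + 1))
        dom = pd.DataFrame(
            [(pid, "WD40", s, e) for s, e in intervals],
            columns=["protein_id", "domain_name", "start", "end"],
        )
        merged = merge_wd40_intervals(dom)
        planted_starts = {p[0] for p in planted}
        planted_spans = [(p[0], p[1]) for p in planted]
        # reject accidental in-repeat matches: resample free residues until clean
        for _ in range(200):
            text = "".join(seq)
            accidental = [
                st
                for st in pattern.find_all(text)
                if st not in planted_starts
                and any(
                    ms - 1 <= st and st + pattern.length - 1 <= me - 1
                    for ms, me in merged
                )
            ]
            if not accidental:
                break
            for st in accidental:
                for k in range(st, st + pattern.length):
                    if not any(ps <= k <= pe for ps, pe in planted_spans):
                        seq[k] = _AA20[rng.integers(len(_AA20))]
        else:
            raise PlanInfeasibleError(
                f"could not purge accidental motif matches in protein {pid}"
            )
        proteins[pid] = "".join(seq)
        domain_rows.extend(dom.itertuples(index=False))
        for s0, e0, widx in planted:
            truth_rows.append((pid, s0 + 1, e0 + 1, widx))
    domains = pd.DataFrame(
        domain_rows, columns=["protein_id", "domain_name", "start", "end"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "start", "end", "wd40_index"]
    )
    return proteins, domains, truth


# ---------------------------------------------------------------- gene map

@dataclass
class GenomePlan:
    """Plan for a synthetic gene map with planted duplication pairs.

    ``tandem_pairs``: (chromosome, intervening-gene-count in 0..4) per planted
    tandem pair. ``segmental_pairs``: (block_id, chrom_a, chrom_b) per planted
    segmental pair. ``distractor_pairs``: (chromosome, intervening >= 5) pairs
    that must remain unclassified.
    """

    n_chromosomes: int = 4
    genes_per_chromosome: int = 40
    tandem_pairs: list[tuple[str, int]] = field(default_factory=list)
    segmental_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    distractor_pairs: list[tuple[str, int]] = field(default_factory=list)
    seed: int = 0

    def chromosome_names(self) -> list[str]:
        return [f"chr{c + 1:02d}" for c in range(self.n_chromosomes)]

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise InvalidPlanError("need >= 1 chromosome and gene per chromosome")
        chroms = set(self.chromosome_names())
        for chrom, k in self.tandem_pairs:
            if chrom not in chroms:
                raise InvalidPlanError(f"unknown chromosome {chrom!r}")
            if not 0 <= k <= 4:
                raise InvalidPlanError(
                    f"planted tandem pair must have 0..4 intervening loci, got {k}"
                )
        for chrom, k in self.distractor_pairs:
            if chrom not in chroms:
                raise InvalidPlanError(f"unknown chromosome {chrom!r}")
            if k < 5:
                raise InvalidPlanError(
                    f"distractor pair must have >= 5 intervening loci, got {k}"
                )
        seen_blocks = set()
        for block, ca, cb in self.segmental_pairs:
            if block in seen_blocks:
                raise InvalidPlanError(f"duplicate block id {block!r}")
            seen_blocks.add(block)
            if ca not in chroms or cb not in chroms:
                raise InvalidPlanError(f"unknown chromosome in block {block!r}")


def generate_gene_map(
    plan: GenomePlan,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Returns ``(loci, pair_truth, blocks)``.

    ``loci``: ``gene_id, chromosome, start, end, strand`` with strictly
    increasing non-overlapping coordinates per chromosome. ``pair_truth``:
    ``gene_a, gene_b, class`` with class in {tandem, segmental,
    unclassified}. ``blocks``: ``block_id, gene_a, gene_b`` listing every
    planted segmental pair exactly once.
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    chroms = plan.chromosome_names()
    gene_ids: dict[str, list[str]] = {}
    loci_rows = []
    for chrom in chroms:
        pos = 1
        ids = []
        for g in range(plan.genes_per_chromosome):
            start = pos + int(rng.integers(500, 2001))
            end = start + int(rng.integers(1000, 3001))
            gid = f"{chrom}g{g + 1:04d}"
            strand = "+" if rng.integers(2) else "-"
            loci_rows.append((gid, chrom, start, end, strand))
            ids.append(gid)
            pos = end
        gene_ids[chrom] = ids
    loci = pd.DataFrame(
        loci_rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
    )

    used: dict[str, set[int]] = {c: set() for c in chroms}

    def claim_same_chrom_pair(chrom: str, intervening: int) -> tuple[str, str]:
        n = plan.genes_per_chromosome
        span = intervening + 2
        candidates = [
            a
            for a in range(n - span + 1)
            if not ({a, a + span - 1} & used[chrom])
        ]
        if not candidates:
            raise PlanInfeasibleError(
                f"chromosome {chrom} cannot host another pair with "
                f"{intervening} intervening loci"
            )
        a = candidates[int(rng.integers(len(candidates)))]
        b = a + span - 1
        used[chrom].update((a, b))
        return gene_ids[chrom][a], gene_ids[chrom][b]

    def claim_gene(chrom: str) -> str:
        free = [g for g in range(plan.genes_per_chromosome) if g not in used[chrom]]
        if not free:
            raise PlanInfeasibleError(f"chromosome {chrom} has no free gene slots")
        g = free[int(rng.integers(len(free)))]
        used[chrom].add(g)
        return gene_ids[chrom][g]

    truth_rows = []
    block_rows = []
    for chrom, k in plan.tandem_pairs:
        a, b = claim_same_chrom_pair(chrom, k)
        truth_rows.append((a, b, "tandem"))
    for block, ca, cb in plan.segmental_pairs:
        if ca == cb:
            # same-chromosome block pair: keep it far apart so the tandem
            # rule cannot also fire
            a, b = claim_same_chrom_pair(ca, max(8, 5))
        else:
            a, b = claim_gene(ca), claim_gene(cb)
        truth_rows.append((a, b, "segmental"))
        block_rows.append((block, a, b))
    for chrom, k in plan.distractor_pairs:
        a, b = claim_same_chrom_pair(chrom, k)
        truth_rows.append((a, b, "unclassified"))
    pair_truth = pd.DataFrame(truth_rows, columns=["gene_a", "gene_b", "class"])
    blocks = pd.DataFrame(block_rows, columns=["block_id", "gene_a", "gene_b"])
    return loci, pair_truth, blocks


# ---------------------------------------------------------------- codon pairs

@dataclass
class CodonPairPlan:
    """Plan for an ancestor/derived CDS pair with controlled synonymous and
    nonsynonymous per-site substitution probabilities."""

    n_codons: int = 300
    p_syn: float = 0.2
    p_nonsyn: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_codons < 1:
            raise InvalidPlanError("n_codons must be >= 1")
        for name, p in (("p_syn", self.p_syn), ("p_nonsyn", self.p_nonsyn)):
            if not 0.0 <= p < 0.75:
                raise InvalidPlanError(f"{name} must lie in [0, 0.75), got {p}")


def _classify_alternatives(codon: str, pos: int) -> tuple[list[str], list[str]]:
    """Sense single-nucleotide alternatives at ``pos``, split syn/nonsyn.

    Substitutions creating stop codons are never applied (they are excluded
    here), matching a generator that resamples stop-creating changes.
    """
    aa = translate_codon(codon)
    syn, nonsyn = [], []
    for base in _BASES:
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if alt in STOP_CODONS:
            continue
        (syn if translate_codon(alt) == aa else nonsyn).append(alt)
    return syn, nonsyn


def evolve_codon_pair(
    plan: CodonPairPlan,
) -> tuple[str, str, pd.DataFrame]:
    """Returns ``(ancestor_cds, derived_cds, substitution_log)``.

    The ancestor is a uniform draw over sense codons. Each nucleotide site of
    the derived copy is visited once, in order; in its *current* codon
    context the site's synonymous fraction ``s`` (stop changes counted as
    nonsynonymous potential, NG86-style) sets the per-site substitution
    probabilities ``p_syn * s`` (synonymous change) and ``p_nonsyn * (1-s)``
    (nonsynonymous change), so the expected synonymous substitutions per
    NG86 synonymous site equal ``p_syn`` and likewise for ``p_nonsyn``.
    Substitutions that would create a stop are never applied. The log has
    columns ``codon, position, old, new, kind``.
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    codons = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=plan.n_codons)]
    ancestor = "".join(codons)
    derived = list(codons)
    log_rows = []
    for ci in range(plan.n_codons):
        for pos in range(3):
            codon = derived[ci]
            syn, nonsyn = _classify_alternatives(codon, pos)
            n_stop = 3 - len(syn) - len(nonsyn)
            s_frac = len(syn) / 3.0  # stop changes count toward nonsynonymous sites
            n_frac = (len(nonsyn) + n_stop) / 3.0
            u = rng.random()
            if u < plan.p_syn * s_frac and syn:
                alt = syn[int(rng.integers(len(syn)))]
                kind = "synonymous"
            elif u < plan.p_syn * s_frac + plan.p_nonsyn * n_frac and nonsyn:
                alt = nonsyn[int(rng.integers(len(nonsyn)))]
                kind = "nonsynonymous"
            else:
                continue
            log_rows.append((ci, pos, codon[pos], alt[pos], kind))
            derived[ci] = alt
    log = pd.DataFrame(log_rows, columns=["codon", "position", "old", "new", "kind"])
    return ancestor, "".join(derived), log


# ---------------------------------------------------------------- expression

@dataclass
class ExpressionPlan:
    """Plan for an FPKM matrix with planted tissue-specific genes.

    ``specific_genes`` maps gene index -> (tissue, fold): the target tissue's
    mean is ``fold`` times every other tissue's mean for that gene.
    ``noise_cv`` is the coefficient of variation of multiplicative gamma
    noise (0 = noiseless).
    """

    n_genes: int = 30
    tissues: tuple[str, ...] = (
        "root",
        "stem",
        "leaf",
        "flower",
        "pod",
        "seed",
        "sam",
        "nodule",
    )
    specific_genes: dict[int, tuple[str, float]] = field(default_factory=dict)
    baseline_fpkm: tuple[float, float] = (5.0, 50.0)
    noise_cv: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise InvalidPlanError("n_genes must be >= 1")
        if len(self.tissues) != len(set(self.tissues)):
            raise InvalidPlanError("duplicate tissue names")
        if len(self.tissues) < 2:
            raise InvalidPlanError("need at least 2 tissues")
        lo, hi = self.baseline_fpkm
        if not 0 < lo <= hi:
            raise InvalidPlanError("baseline_fpkm range must be positive")
        if self.noise_cv < 0:
            raise InvalidPlanError("noise_cv must be >= 0")
        for idx, (tissue, fold) in self.specific_genes.items():
            if not 0 <= idx < self.n_genes:
                raise InvalidPlanError(f"gene index {idx} out of range")
            if tissue not in self.tissues:
                raise InvalidPlanError(f"unknown tissue {tissue!r}")
            if fold <= 1:
                raise InvalidPlanError(f"planted fold must be > 1, got {fold}")


def generate_expression(plan: ExpressionPlan) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns ``(matrix, truth)``: a genes x tissues FPKM DataFrame and the
    planted-specificity table ``gene_id, tissue, fold``."""
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    genes = [f"EG{i + 1:04d}" for i in range(plan.n_genes)]
    lo, hi = plan.baseline_fpkm
    baseline = rng.uniform(lo, hi, size=plan.n_genes)
    means = np.tile(baseline[:, None], (1, len(plan.tissues)))
    truth_rows = []
    for idx, (tissue, fold) in sorted(plan.specific_genes.items()):
        col = plan.tissues.index(tissue)
        means[idx, col] *= fold
        truth_rows.append((genes[idx], tissue, fold))
    if plan.noise_cv > 0:
        shape = 1.0 / plan.noise_cv**2
        noise = rng.gamma(shape, scale=1.0 / shape, size=means.shape)
        values = means * noise
    else:
        values = means
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                          columns=list(plan.tissues))
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "tissue", "fold"])
    return matrix, truth


# ---------------------------------------------------------------- families

def generate_aligned_family(
    n_taxa: int = 12, n_columns: int = 200, seed: int = 0, mutation_rate: float = 0.1
) -> tuple[list[str], list[str]]:
    """A simple aligned protein family for tree building: sequences evolve
    down a random bifurcating coalescent-style topology by per-column random
    substitutions. Returns ``(ids, rows)`` (gap-free alignment)."""
    rng = np.random.default_rng(seed)
    root = _AA20[rng.integers(len(_AA20), size=n_columns)]
    # random topology by sequential attachment; evolve along each edge
    seqs = [root.copy(), root.copy()]
    for s in seqs:
        _mutate(s, mutation_rate, rng)
    while len(seqs) < n_taxa:
        parent = seqs[int(rng.integers(len(seqs)))]
        child = parent.copy()
        _mutate(child, mutation_rate, rng)
        seqs.append(child)
    ids = [f"T{i + 1:03d}" for i in range(n_taxa)]
    return ids, ["".join(s) for s in seqs]


def _mutate(seq: np.ndarray, rate: float, rng) -> None:
    hits = rng.random(len(seq)) < rate
    seq[hits] = _AA20[rng.integers(len(_AA20), size=int(hits.sum()))]
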