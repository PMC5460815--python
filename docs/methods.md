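# Methods

`dwdfam` implements the standard in-silico workflow for a genome-wide survey
of DWD-motif (WDxR) proteins — the WD40-repeat proteins that can serve as
substrate receptors of the CUL4-DDB1 E3 ubiquitin ligase — together with the
downstream family analyses such surveys report: domain-architecture typing,
duplication classification with Ka/Ks, a distance-based phylogeny, and
tissue-expression statistics. Because the real inputs (a proteome, SMART-style
domain annotations, syntenic block tables, an FPKM matrix) are large,
versioned external resources, the package pairs every stage with a seeded
synthetic generator that plants the relevant feature with known ground truth,
so the whole pipeline is verifiable at desk scale.

## Motif model and scanning

The DWD box is modelled as a PROSITE-style degenerate pattern of 16 ordered
positions, each either an allowed-residue set or a wildcard (`x(n)` expands
to n wildcards). The canonical pattern

```
[IFVL]-[IFVL]-[AGST]-[AGST]-[AGST]-x-[DE]-x(2)-[IFVL]-x-[IFVL]-[WY]-[DE]-[IFVL]-[RK]
```

carries the conserved acidic/aromatic/acidic/basic classes at positions 7,
13, 14 and 16 that mediate DDB1 binding. Scanning is two-step: a protein must
carry annotated WD40 repeats, and a match is reported only when the full
16-residue window lies inside a repeat (`require_containment`, default on).
Implementation detail: the compiled pattern is also rendered as a regular
expression with a capturing lookahead, so all overlapping matches are found
in one linear pass; a position-by-position checker (`matches_at`) backs the
exhaustive validation tests.

Conventions, each surfaced as a parameter:

- **Overlaps.** All overlapping matches are reported; consumers may collapse
  them (`dedupe_overlapping`, default off) with a greedy left-to-right pass.
- **Abutting repeats.** A window spanning two repeats counts as contained if
  it lies in their union; `containment_slack` (default 0 residues) lets
  near-abutting repeats merge, since repeat boundaries from annotation tools
  are approximate.
- **Ambiguity codes** (B, J, Z, X, U, O) satisfy wildcards but never a
  constrained position — the scanner cannot certify a hit through an
  ambiguous residue.
- `wd40_index` is the 1-based ordinal (sorted by start, ties by end) of the
  repeat containing the hit start.

## Architecture typing

Candidates (≥ 1 motif) are partitioned by the key *(DWD-motif count, sorted
multiset of non-WD40 domain names)*. The WD40 repeat count is deliberately
not in the key: repeats are the shared scaffold, and typing is meant to
separate motif dosage and accessory domains. Labels A, B, C, … are assigned
by descending member count with lexicographic tie-breaks, so labelling is a
deterministic function of the cohort; agreement with any particular published
lettering is not claimed. Functional-category labels are curated annotations,
not computable, and are carried as free text only.

## Duplication classification and Ka/Ks

Genes are ranked densely per chromosome by start (ties by end, then id). A
pair is **tandem** when both genes share a chromosome with strictly fewer
than 5 intervening gene loci (`tandem_threshold`; the boundary is exact:
4 intervening ⇒ tandem, 5 ⇒ not). A pair is **segmental** when listed on a
duplicated block. A pair satisfying both is labelled tandem with an
`also_on_block` flag — the classes are conceptually disjoint but the overlap
carries information. Pair discovery is not performed; candidate pairs are an
input (a convenience `propose_pairs` screens by global identity ≥ 70%).

Percent identity uses Needleman–Wunsch with match 1, mismatch 0 and a linear
gap penalty of 1, identity = identical columns / alignment columns (gap
columns count toward the denominator by default). Traceback ties resolve
diagonal > gap-in-second > gap-in-first; argument order is canonicalized so
the function is exactly symmetric.

Ka/Ks uses Nei–Gojobori (1986) counting:

- per-codon synonymous site content from single-nucleotide mutation
  enumeration under the standard code, with mutations to stops counted as
  nonsynonymous and per-codon normalization to exactly 3 sites (the
  convention of common implementations; it preserves N + S = 3 × codons);
  site totals averaged over the two sequences;
- differences in multi-hit codons averaged over the k! mutational pathways,
  excluding pathways through stop codons and re-weighting the remainder
  equally;
- Ka = Na/N, Ks = Ns/S with Jukes–Cantor correction by default
  (d = −¾ ln(1 − 4p/3); NaN at saturation); the ratio is undefined (not
  infinite) when Ks = 0.

Gap-containing codon columns are dropped; a trailing aligned stop codon is
tolerated but not counted; internal stops are input errors.

## Phylogeny

Distances are p-distances (differing / compared sites) with pairwise- or
complete-deletion gap handling. Trees are built by the Saitou–Nei
neighbor-joining agglomeration with Q-ties broken to the smallest (i, j)
index pair and negative branch lengths clamped to zero (the clamped deficit
is recorded on the tree). NJ is consistent on additive matrices, which the
tests exploit: matrices derived from random trees by path-length summation
must be recovered exactly. Branch support is column bootstrap: resample
columns with replacement, rebuild, and score each internal bipartition of
the full-data tree by its replicate frequency; 1000 replicates by default.
This is the conventional resampling surrogate for MEGA-style interior-branch
tests. Midpoint rooting (via dendropy) is a display convention; `cut_clades`
splits a rooted tree into k groups at the k−1 deepest internal edges as a
reading aid, with no claim of reproducing any published manual grouping.

## Expression statistics

For each gene the maximal fold change is max/min FPKM across tissues,
defined only when every tissue exceeds the detection floor (default 0, i.e.
strict positivity); genes undetectable in some tissue are flagged undefined
with a reason rather than given an infinite ratio. Each gene is assigned the
tissue where it peaks (ties to the first tissue in column order) and an
`above_threshold` flag (fold change > 2.0 by default). "Highly expressed in
one or few tissues" has no standard cutoff; it is exposed as a descriptive
`dominant` flag (peak tissue ≥ 50% of the row total, configurable) and never
asserted against external counts. Heatmap normalization across tissues is
row z-score by default (row-max offered); constant rows normalize to zeros
and are flagged.

## Synthetic data: what it emulates and what it does not

- **Proteomes.** Background residues are uniform over the 20 amino acids —
  deliberately unrealistic, because a uniform background maximizes the rate
  of accidental degenerate-pattern matches and therefore stresses the
  rejection sampler hardest. WD40 repeats are fixed 40-residue intervals with
  ≥ 4-residue linkers; each planted motif occupies its own repeat. After
  planting, any accidental match lying fully inside a repeat is destroyed by
  resampling the window's unplanted residues (bounded retry loop); accidental
  matches *outside* repeats are left in place so the containment contract is
  exercised. Passing recovery tests therefore certifies the scanner's logic,
  not its behaviour on β-propeller-like sequence composition.
- **Gene maps.** Coordinates are non-overlapping with random gene lengths
  (1–3 kb) and intergenic gaps (0.5–2 kb); tandem pairs are planted at exact
  intervening-gene counts (0–4), distractor pairs at ≥ 5, segmental pairs on
  listed blocks. No whole-genome-duplication history is simulated — block
  membership is declarative.
- **Codon pairs.** The ancestor is uniform over the 61 sense codons. Each
  nucleotide site of the derived copy is visited once; in its current codon
  context the site's synonymous fraction s sets substitution probabilities
  p_syn·s (synonymous) and p_nonsyn·(1−s) (nonsynonymous), with
  stop-creating changes never applied. Expected synonymous substitutions per
  NG86 synonymous site then equal p_syn, so the realized substitution log is
  itself a valid NG86 oracle, and the plan-implied Ka/Ks is
  p_nonsyn/p_syn. Because each site mutates at most once, the *uncorrected*
  NG86 proportions are the matched estimator for recovery checks; the
  Jukes–Cantor default exists for real data, where multiple hits per site
  are expected. At p_syn = 0.2 the JC-corrected Ks (≈ 0.23) deliberately
  exceeds the planted 0.2 — that is the correction doing its job on data
  that violates its Poisson assumption.
- **Expression.** Gene baselines are uniform in a configurable FPKM range;
  noise is multiplicative gamma with mean 1 and chosen CV (gamma keeps FPKM
  non-negative without clipping bias; CV = 0 degenerates to exactly the
  planted means, making recovery assertions exact). Planted specificity
  multiplies one tissue's mean by the planted fold.

All generators are deterministic: same plan + seed ⇒ byte-identical outputs.

## Problem sizes and numerical choices

Default verification sizes were chosen to make statistical assertions sharp
at interactive cost: 100 seeded proteomes × 200 proteins for motif recovery
(precision = recall = 1 is exact, not approximate); 200 simulated pairs ×
500 codons for Ka/Ks (median within 15% of plan-implied ratio; binomial SE
of Ks at 500 codons ≈ 0.02); 50 random 5–8-leaf additive matrices for NJ
consistency; 1000 bootstrap replicates on 20 taxa × 200 columns. Floating
comparisons in tracebacks use `np.isclose`; all percentages are reported on
the 0–100 scale.

## Known limitations

- The scanner trusts the domain annotation table; it does not predict WD40
  repeats from sequence.
- NG86 is the simplest counting estimator; no transition/transversion or
  codon-frequency weighting (e.g. LWL85, YN00) is provided.
- NJ is O(n³) in pure numpy/Python — comfortable for family-sized trees
  (hundreds of taxa), not for genome-scale ones.
- Multiple sequence alignment is consumed, never constructed.
- `cut_clades` depends on midpoint rooting and branch lengths; it is a
  convenience, not a clustering method with guarantees.
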