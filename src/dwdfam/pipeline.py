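"""End-to-end pipeline orchestration.

``run_pipeline`` takes a :class:`PipelineConfig`, runs whichever stages have
inputs configured, and writes paper-style report tables to the output
directory: the candidate table (per-protein motif counts), the architecture
catalog, the duplication table (class, identities, Ka/Ks), the Newick tree
with bootstrap supports, the expression statistics table, and a JSON run
manifest recording every tunable, seed and the config hash. Stages with
missing inputs are skipped with a logged note; a stage failure aborts the
run naming the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .architecture import assign_types, summarize_catalog
from .alignment import global_identity
from .duplication import classify_pairs, rank_loci
from .errors import DwdfamError
from .expression import normalize_for_heatmap, specificity_calls
from .kaks import compute_kaks
from .motif import DWD_PATTERN, compile_pattern, count_motifs_per_protein, scan_proteome
from .phylogeny import AlignedSet, midpoint_root, resample_support

log = logging.getLogger("dwdfam")


@dataclass
class PipelineConfig:
    """Inputs and tunables for a full run. Any input path may be None; the
    corresponding stage is then skipped. Defaults reproduce the survey
    conventions: the canonical DWD pattern, tandem threshold 5, fold
    threshold 2.0, 1000 bootstrap replicates."""

    proteome_fasta: str | None = None
    domains_tsv: str | None = None
    loci_path: str | None = None          # GFF3 or minimal TSV
    blocks_tsv: str | None = None
    pairs_tsv: str | None = None          # candidate paralog pairs (gene_a, gene_b)
    cds_pairs_fasta: str | None = None
    expression_tsv: str | None = None
    aligned_fasta: str | None = None
    pattern: str = DWD_PATTERN
    require_containment: bool = True
    containment_slack: int = 0
    tandem_threshold: int = 5
    kaks_correction: str = "jukes-cantor"
    fold_threshold: float = 2.0
    detection_floor: float = 0.0
    heatmap_normalization: str = "row-zscore"
    bootstrap_replicates: int = 1000
    bootstrap_seed: int = 0
    output_dir: str = "dwdfam_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise DwdfamError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all configured stages; returns a name -> path map of the outputs."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    skipped: list[str] = []
    candidates = None  # per-protein motif counts for proteins with >= 1 motif

    def stage(name):
        log.info("stage %s", name)

    # --- motif scan + architecture -------------------------------------
    if config.proteome_fasta and config.domains_tsv:
        stage("scan")
        try:
            proteins = io.read_fasta(config.proteome_fasta)
            domains = io.read_domains(config.domains_tsv)
            pattern = compile_pattern(config.pattern)
            hits = scan_proteome(
                proteins,
                domains,
                pattern,
                require_containment=config.require_containment,
                containment_slack=config.containment_slack,
            )
            counts = count_motifs_per_protein(hits, list(proteins))
            candidate_table = (
                counts.to_frame()
                .assign(
                    wd40_indices=[
                        ",".join(
                            map(str, hits.loc[hits["protein_id"] == pid, "wd40_index"])
                        )
                        for pid in counts.index
                    ]
                )
                .rename_axis("protein_id")
            )
            path = outdir / "candidates.tsv"
            io.write_tsv(
                path,
                candidate_table,
                comments=[
                    "per-protein DWD motif counts (candidates have dwd_count >= 1)",
                    f"pattern: {config.pattern}",
                    "wd40_indices: 1-based ordinal of the repeat containing each hit",
                ],
                index=True,
            )
            outputs["candidates"] = path
            path = outdir / "motif_hits.tsv"
            io.write_tsv(
                path, hits,
                comments=["motif hits, 1-based closed protein coordinates"],
            )
            outputs["motif_hits"] = path
            candidates = counts[counts >= 1]
            stage("architecture")
            if len(candidates):
                catalog, assignment = assign_types(candidates, domains)
                path = outdir / "architecture_catalog.tsv"
                io.write_tsv(
                    path,
                    summarize_catalog(catalog),
                    comments=[
                        "architecture types keyed by (dwd_count, non-WD40 domains)"
                    ],
                )
                outputs["architecture_catalog"] = path
                path = outdir / "architecture_assignment.tsv"
                io.write_tsv(path, assignment)
                outputs["architecture_assignment"] = path
        except DwdfamError as exc:
            raise DwdfamError(f"stage scan/architecture failed: {exc}") from exc
    else:
        skipped.append("scan/architecture")

    # --- duplication ---------------------------------------------------
    if config.loci_path and config.pairs_tsv:
        stage("duplication")
        try:
            loci = rank_loci(io.read_loci(config.loci_path))
            pairs = io.read_tsv(config.pairs_tsv)
            blocks = io.read_blocks(config.blocks_tsv) if config.blocks_tsv else None
            table = classify_pairs(
                pairs, loci, blocks, tandem_threshold=config.tandem_threshold
            )
            path = outdir / "duplication.tsv"
            io.write_tsv(
                path,
                table,
                comments=[
                    f"tandem: same chromosome, < {config.tandem_threshold} "
                    "intervening gene loci; segmental: pair on a duplicated block",
                ],
            )
            outputs["duplication"] = path
        except DwdfamError as exc:
            raise DwdfamError(f"stage duplication failed: {exc}") from exc
    else:
        skipped.append("duplication")

    # --- Ka/Ks ----------------------------------------------------------
    if config.cds_pairs_fasta:
        stage("kaks")
        try:
            rows = []
            for id_a, cds_a, id_b, cds_b in io.read_cds_pairs(config.cds_pairs_fasta):
                res = compute_kaks(cds_a, cds_b, correction=config.kaks_correction)
                nt_ident, _ = global_identity(
                    cds_a.replace("-", ""), cds_b.replace("-", "")
                )
                rows.append(
                    {
                        "gene_a": id_a,
                        "gene_b": id_b,
                        "ka": res.ka,
                        "ks": res.ks,
                        "ka_ks": res.ratio,
                        "nucleotide_identity_pct": round(nt_ident, 2),
                        "purifying": res.purifying(),
                    }
                )
            path = outdir / "kaks.tsv"
            io.write_tsv(
                path,
                pd.DataFrame(rows),
                comments=[
                    "NG86 Ka/Ks per codon-aligned CDS pair "
                    f"(correction: {config.kaks_correction}); "
                    "ka_ks empty when Ks = 0 or saturated",
                ],
            )
            outputs["kaks"] = path
        except DwdfamError as exc:
            raise DwdfamError(f"stage kaks failed: {exc}") from exc
    else:
        skipped.append("kaks")

    # --- phylogeny -------------------------------------------------------
    if config.aligned_fasta:
        stage("tree")
        try:
            ids, rows = io.read_aligned_fasta(config.aligned_fasta)
            aligned = AlignedSet(ids, rows)
            tree, supports = resample_support(
                aligned,
                replicates=config.bootstrap_replicates,
                seed=config.bootstrap_seed,
            )
            path = outdir / "tree.nwk"
            path.write_text(midpoint_root(tree.newick(support=True)) + "\n")
            outputs["tree"] = path
            path = outdir / "tree_supports.tsv"
            io.write_tsv(
                path,
                pd.DataFrame(
                    sorted(
                        (";".join(sorted(bp)), pct) for bp, pct in supports.items()
                    ),
                    columns=["bipartition", "support_pct"],
                ),
                comments=[
                    f"column-bootstrap supports, {config.bootstrap_replicates} "
                    f"replicates, seed {config.bootstrap_seed}",
                ],
            )
            outputs["tree_supports"] = path
        except DwdfamError as exc:
            raise DwdfamError(f"stage tree failed: {exc}") from exc
    else:
        skipped.append("tree")

    # --- expression ------------------------------------------------------
    if config.expression_tsv:
        stage("expression")
        try:
            matrix = io.read_expression(config.expression_tsv)
            calls, tissue_counts = specificity_calls(
                matrix,
                fold_threshold=config.fold_threshold,
                detection_floor=config.detection_floor,
            )
            path = outdir / "expression_stats.tsv"
            io.write_tsv(
                path,
                calls.rename_axis("gene_id"),
                comments=[
                    "max_fold_change = max/min FPKM across tissues; undefined "
                    f"when any tissue <= detection floor ({config.detection_floor:g})",
                    f"above_threshold: fold change > {config.fold_threshold:g}",
                ],
                index=True,
            )
            outputs["expression_stats"] = path
            path = outdir / "tissue_peak_counts.tsv"
            io.write_tsv(
                path,
                tissue_counts.rename("n_genes_peaking").rename_axis("tissue"),
                comments=["number of genes peaking in each tissue"],
                index=True,
            )
            outputs["tissue_peak_counts"] = path
            normalized, _ = normalize_for_heatmap(
                matrix, method=config.heatmap_normalization
            )
            path = outdir / "expression_heatmap_matrix.tsv"
            io.write_tsv(
                path,
                normalized.rename_axis("gene_id").round(6),
                comments=[f"normalization: {config.heatmap_normalization}"],
                index=True,
            )
            outputs["expression_heatmap_matrix"] = path
        except DwdfamError as exc:
            raise DwdfamError(f"stage expression failed: {exc}") from exc
    else:
        skipped.append("expression")

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_sha256": config.digest(),
        "stages_skipped": skipped,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = path
    for name in skipped:
        log.info("skipped stage %s (inputs not configured)", name)
    return outputs
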