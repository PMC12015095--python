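"""End-to-end orchestration: scan -> count -> join -> fit -> gene scan -> PCA.

``run_full_analysis`` executes every stage for every species and flank
from one :class:`RunConfig`, writes a summary table shaped like the
species-level model report (one row per scope x HRE class x flank), the
gene-centric outputs, PCA outputs, and a JSON manifest (config hash,
versions, per-stage wall time).  Outputs accumulate under
``outdir/partial/`` and are promoted to ``outdir`` only when every stage
succeeds, so a failure leaves the partial results inspectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gene_scan import direction_summary, export_significant, records_to_frame, scan_genes
from .models import model_ssd, phylo_pca, qc_n50
from .motifs import default_motif_path, parse_motif_file, read_fasta, scan_genome
from .phylo import read_newick, tip_labels
from .traits import build_species_table, read_traits
from .windows import DEFAULT_KEEP, build_windows, count_hits_dedup, count_hits_per_gene, read_annotations

logger = logging.getLogger(__name__)

DEFAULT_FLANKS = (10_000, 50_000, 100_000, 1_000_000)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and species."""


@dataclass
class RunConfig:
    genomes_dir: str
    annotations_dir: str
    traits_file: str
    tree_file: str
    outdir: str
    motifs_file: str | None = None
    flanks: tuple[int, ...] = DEFAULT_FLANKS
    keep_categories: tuple[str, ...] = tuple(sorted(DEFAULT_KEEP))
    hre_classes: tuple[str, ...] = ("ARE", "ERE")
    min_order_n: int = 20
    gene_min_species: int = 10
    lambda_policy: str | float = "ML"
    pca_flank: int | None = None  # default: first flank
    seed: int = 0

    def validate(self) -> None:
        bad = set(self.hre_classes) - {"ARE", "ERE"}
        if bad:
            raise ValueError(f"unknown hre classes: {sorted(bad)}")
        flanks = list(self.flanks)
        if any(f <= 0 for f in flanks) or sorted(set(flanks)) != flanks:
            raise ValueError("flanks must be positive and strictly increasing")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    partial = outdir / "partial"
    partial.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stage_seconds": {},
        "stages": [],
    }
    timings = manifest["stage_seconds"]

    def _stage(name: str, species: str | None = None):
        label = f"{name}({species})" if species else name
        manifest["stages"].append(label)
        return label

    motifs_path = config.motifs_file or default_motif_path()
    motifs = parse_motif_file(motifs_path)
    tree = read_newick(config.tree_file)
    traits = read_traits(config.traits_file)

    genome_files = sorted(Path(config.genomes_dir).glob("*.fa")) + sorted(
        Path(config.genomes_dir).glob("*.fa.gz")
    )
    if not genome_files:
        raise PipelineError(f"no FASTA files found in {config.genomes_dir}")

    # --- per-species scan and count --------------------------------------
    t0 = time.perf_counter()
    count_rows = []
    per_gene_frames: dict[int, list[pd.DataFrame]] = {f: [] for f in config.flanks}
    for fasta in genome_files:
        species = fasta.name.removesuffix(".gz").removesuffix(".fa")
        label = _stage("scan_count", species)
        try:
            genome = read_fasta(fasta)
            contig_lengths = {c: len(s) for c, s in genome.items()}
            hits = scan_genome(genome, motifs)
            ann_path = Path(config.annotations_dir) / f"{species}.tsv"
            genes = read_annotations(ann_path, keep_categories=config.keep_categories)
            for flank in config.flanks:
                windows = build_windows(genes, flank, contig_lengths)
                dedup = count_hits_dedup(hits, windows)
                count_rows.append(
                    {
                        "species": species,
                        "flank": flank,
                        "are_count": dedup["by_class"]["ARE"],
                        "ere_count": dedup["by_class"]["ERE"],
                        "interrogated_bp": windows.interrogated_bp,
                        **{f"motif_{m}": c for m, c in dedup["by_motif"].items()},
                    }
                )
                pg = count_hits_per_gene(hits, genes, flank, contig_lengths)
                pg = pg.reset_index().assign(species=species, flank=flank)
                per_gene_frames[flank].append(pg)
        except Exception as exc:
            raise PipelineError(f"stage {label} failed: {exc}") from exc
    counts = pd.DataFrame(count_rows)
    counts.to_csv(partial / "species_counts.tsv", sep="\t", index=False)
    timings["scan_count"] = round(time.perf_counter() - t0, 3)

    # --- species-level models --------------------------------------------
    t0 = time.perf_counter()
    _stage("species_models")
    tips = set(tip_labels(tree))
    fit_rows = []
    tables: dict[int, pd.DataFrame] = {}
    for flank in config.flanks:
        flank_counts = counts[counts["flank"] == flank][
            ["species", "flank", "are_count", "ere_count", "interrogated_bp"]
        ]
        table = build_species_table(traits, flank_counts, tips)
        tables[flank] = table
        scopes = [("All", None)]
        if "order" in table.columns:
            for order_name, grp in table.groupby("order"):
                if len(grp) >= config.min_order_n:
                    scopes.append((order_name, order_name))
                else:
                    logger.info(
                        "skipping order %s at flank %d: %d < %d species",
                        order_name, flank, len(grp), config.min_order_n,
                    )
        for scope_label, order_name in scopes:
            for cls in config.hre_classes:
                try:
                    fit = model_ssd(
                        table, tree, hre_class=cls, flank=flank,
                        lam=config.lambda_policy, order=order_name,
                        min_n=config.min_order_n,
                    )
                except ValueError as exc:
                    logger.info("skipping %s/%s/%d: %s", scope_label, cls, flank, exc)
                    continue
                count_term = "ln_are" if cls == "ARE" else "ln_ere"
                fit_rows.append(
                    {
                        "scope": scope_label, "hre_class": cls, "flank": flank,
                        "n": fit.n,
                        "hre_effect": fit.params[count_term],
                        "hre_p": fit.pvalues[count_term],
                        "body_effect": fit.params["ln_body"],
                        "body_p": fit.pvalues["ln_body"],
                        "lambda": fit.lam, "r_squared": fit.r_squared,
                    }
                )
    pd.DataFrame(fit_rows).to_csv(partial / "species_models.tsv", sep="\t", index=False)
    timings["species_models"] = round(time.perf_counter() - t0, 3)

    # --- genome-quality check --------------------------------------------
    if "contig_n50" in traits.columns:
        t0 = time.perf_counter()
        _stage("qc_n50")
        qc_rows = []
        for cls in config.hre_classes:
            for flank in config.flanks:
                fit = qc_n50(tables[flank], tree, hre_class=cls, flank=flank,
                             lam=config.lambda_policy)
                qc_rows.append(
                    {
                        "hre_class": cls, "flank": flank, "n": fit.n,
                        "n50_effect": fit.params["ln_n50"],
                        "n50_p": fit.pvalues["ln_n50"],
                        "lambda": fit.lam,
                    }
                )
        pd.DataFrame(qc_rows).to_csv(partial / "qc_n50.tsv", sep="\t", index=False)
        timings["qc_n50"] = round(time.perf_counter() - t0, 3)

    # --- gene-centric scan ------------------------------------------------
    t0 = time.perf_counter()
    _stage("gene_scan")
    traits_aug = tables[config.flanks[0]][["species", "ssd", "body_size"]]
    all_records = []
    for flank in config.flanks:
        per_gene = pd.concat(per_gene_frames[flank], ignore_index=True)
        for cls in config.hre_classes:
            long = per_gene.rename(columns={cls: "count"})[
                ["gene_id", "species", "count"]
            ]
            records = scan_genes(
                long, traits_aug, tree, hre_class=cls, flank=flank,
                min_species=config.gene_min_species, lam=config.lambda_policy,
            )
            all_records.extend(records)
    if all_records:
        frame = records_to_frame(all_records)
        frame.to_csv(partial / "gene_effects.tsv", sep="\t", index=False)
        try:
            direction_summary(all_records).to_csv(
                partial / "gene_direction_summary.tsv", sep="\t", index=False
            )
        except ValueError:
            logger.warning("no successful gene fits; direction summary skipped")
        export_significant(all_records, partial / "significant_genes.txt")
    timings["gene_scan"] = round(time.perf_counter() - t0, 3)

    # --- phylogenetic PCA --------------------------------------------------
    t0 = time.perf_counter()
    _stage("pca")
    pca_flank = config.pca_flank or config.flanks[0]
    motif_cols = [c for c in counts.columns if c.startswith("motif_")]
    mat = (
        counts[counts["flank"] == pca_flank]
        .set_index("species")[motif_cols]
        .fillna(0)
        .astype(float)
    )
    mat = mat.loc[mat.index.isin(tips)]
    if (mat.to_numpy() > 0).all() and mat.shape[1] >= 2:
        scores, loadings, evals = phylo_pca(mat, tree)
        scores.to_csv(partial / "pca_scores.tsv", sep="\t")
        loadings.to_csv(partial / "pca_loadings.tsv", sep="\t")
        pd.Series(evals, index=loadings.columns, name="eigenvalue").to_csv(
            partial / "pca_eigenvalues.tsv", sep="\t"
        )
    else:
        logger.warning("PCA skipped: zero counts or fewer than 2 motifs at flank %d", pca_flank)
    timings["pca"] = round(time.perf_counter() - t0, 3)

    # --- promote and write manifest ---------------------------------------
    for item in sorted(partial.iterdir()):
        target = outdir / item.name
        if target.exists():
            target.unlink()
        shutil.move(str(item), target)
    partial.rmdir()
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
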