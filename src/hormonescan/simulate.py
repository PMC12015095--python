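"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure of the real inputs — per-species
genomes with hormone response elements near gene TSSs, a species
phylogeny, and male/female body masses — while keeping full control of
the truth:

* a Yule (pure-birth) tree rescaled to unit depth;
* per-species log *rates* of planted motifs evolving by Brownian motion
  on the tree, with an optional clade-specific burst (a multiplier on the
  rate of one clade, emulating a lineage-specific explosion of AREs);
* realized per-gene planted counts drawn Poisson at the species rate;
* ln body mass evolving by Brownian motion;
* SSD generated from the linear model
  ``SSD = beta_are * ln(ARE total) + beta_body * ln(body) + eps`` with
  phylogenetically structured noise ``eps ~ MVN(0, sd^2 * V(lambda))``,
  then male/female masses back-solved so that ``ln(m/f) = SSD`` and
  ``(m + f)/2 = body`` exactly;
* optionally, genome sequences with those motifs physically planted in
  TSS-flanking windows, so the scanner and counters can be checked
  against construction.

All randomness flows from one seeded generator per run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import random
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .motifs import (
    CANONICAL_ARE,
    CANONICAL_ERE,
    MotifPattern,
    reverse_complement_iupac,
    scan_genome,
)
from .phylo import pagel_transform, phylo_vcv, tree_depth
from .windows import GeneAnnotation

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults are the standing study conditions."""

    seed: int = 0
    n_species: int = 64
    birth_rate: float = 1.0

    # genome geometry (used only when sequences are emitted)
    n_genes: int = 20
    gc_fraction: float = 0.41
    plant_flank: int = 1_000
    contig_length: int | None = None  # auto-sized from gene count and spacing
    clean_background: bool = True

    # motif-rate model: expected planted motifs per gene window, log scale
    are_root_log_rate: float = float(np.log(2.5))
    ere_root_log_rate: float = float(np.log(0.4))
    rate_bm_var: float = 0.5
    burst_clade: list[str] | None = None
    burst_fraction: float | None = None  # auto-pick a clade of ~this tip share
    burst_multiplier: float = 4.0
    overdispersion: float | None = None  # negative-binomial k; None = Poisson
    #: "shared": one rate per species drives every gene (genes co-vary);
    #: "independent": each gene's log-rate evolves on its own (genes exchangeable)
    gene_rate_mode: str = "shared"

    # trait model
    beta_are: float = 0.5
    beta_body: float = 0.3
    lam: float = 0.5
    residual_sd: float = 0.25
    body_root_ln_mass: float = 0.0  # ln kg
    body_bm_var: float = 1.0

    # genome-quality confounder
    n50_ln_mean: float = float(np.log(1e6))
    n50_ln_sd: float = 1.0
    n50_slope: float = 0.0  # effect of (ln N50 - mean) on log motif rate

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must lie in (0, 1)")
        for name in ("rate_bm_var", "body_bm_var", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.burst_multiplier < 1:
            raise ValueError("burst_multiplier must be >= 1")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline should recover."""

    beta_are: float
    beta_body: float
    lam: float
    log_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    ssd: dict[str, float] = field(default_factory=dict)
    per_gene_counts: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    planted: dict[str, list[dict]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# tree and Brownian motion


def sim_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Ultrametric Yule tree with ``n_species`` tips, depth rescaled to 1.

    The pure-birth process stops at the n-th speciation, which would leave
    the two newest tips on zero-length branches; every tip edge is
    therefore extended by the exponential waiting time to the next event
    before rescaling.  Deterministic given ``seed``.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_species, rng=rng,
    )
    extra = rng.expovariate(n_species * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.seed_node.edge.length = None
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    depth = tree_depth(tree)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return tree


def brownian_on_tree(
    tree: dendropy.Tree, root_value: float, variance: float, rng: np.random.Generator
) -> dict[str, float]:
    """Simulate Brownian motion along branches; returns tip label -> value."""
    values: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = root_value
        else:
            length = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(
                0.0, np.sqrt(variance * length)
            )
    return {
        leaf.taxon.label: values[leaf] for leaf in tree.leaf_node_iter()
    }


def pick_burst_clade(tree: dendropy.Tree, fraction: float = 0.33) -> list[str]:
    """Tip labels of the internal clade whose size is closest to ``fraction``.

    Deterministic: ties broken by preorder position.
    """
    n = len(tree.leaf_nodes())
    target = fraction * n
    best: tuple[float, list[str]] | None = None
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        tips = [l.taxon.label for l in node.leaf_iter()]
        score = abs(len(tips) - target)
        if best is None or score < best[0]:
            best = (score, tips)
    assert best is not None
    return best[1]


# ---------------------------------------------------------------------------
# rates, counts, traits


def sim_rates_and_counts(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator,
    ln_n50: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-species, per-gene planted-motif counts for both HRE classes.

    The log expected count per gene window evolves by Brownian motion from
    the class root rate; a burst clade's ARE log-rate is raised by
    ln(burst_multiplier); an optional N50 confounder shifts log rates by
    ``n50_slope * (ln N50 - mean)``.  Realized counts are Poisson (or
    negative binomial when ``overdispersion`` is set).

    Returns a long DataFrame (species, gene_id, ARE, ERE) and the truth.
    """
    species = [l.taxon.label for l in tree.leaf_node_iter()]
    burst: set[str] = set()
    if config.burst_clade is not None:
        burst = set(config.burst_clade)
    elif config.burst_fraction is not None:
        burst = set(pick_burst_clade(tree, config.burst_fraction))
    truth = GroundTruth(config.beta_are, config.beta_body, config.lam)
    gene_ids = [f"gene{i:03d}" for i in range(config.n_genes)]
    rows: dict[str, dict] = {
        sp: {"species": sp} for sp in species
    }
    counts: dict[str, dict[str, np.ndarray]] = {}
    if config.gene_rate_mode not in ("shared", "independent"):
        raise ValueError(f"unknown gene_rate_mode {config.gene_rate_mode!r}")
    for cls, root in (("ARE", config.are_root_log_rate), ("ERE", config.ere_root_log_rate)):
        if config.gene_rate_mode == "shared":
            gene_log_rates = [brownian_on_tree(tree, root, config.rate_bm_var, rng)]
            gene_log_rates = gene_log_rates * config.n_genes
        else:
            gene_log_rates = [
                brownian_on_tree(tree, root, config.rate_bm_var, rng)
                for _ in range(config.n_genes)
            ]
        shift = {sp: 0.0 for sp in species}
        if cls == "ARE" and burst:
            for sp in burst:
                shift[sp] += float(np.log(config.burst_multiplier))
        if ln_n50 is not None and config.n50_slope != 0.0:
            for sp in species:
                shift[sp] += config.n50_slope * (ln_n50[sp] - config.n50_ln_mean)
        truth.log_rates[cls] = {
            sp: float(np.mean([g[sp] for g in gene_log_rates]) + shift[sp])
            for sp in species
        }
        per_class = {}
        for sp in species:
            mu = np.exp(np.array([g[sp] + shift[sp] for g in gene_log_rates]))
            if config.overdispersion is None:
                per_class[sp] = rng.poisson(mu)
            else:
                k = config.overdispersion
                per_class[sp] = rng.negative_binomial(k, k / (k + mu))
        counts[cls] = per_class
    records = []
    for sp in species:
        for gi, gene_id in enumerate(gene_ids):
            records.append(
                {
                    "species": sp,
                    "gene_id": gene_id,
                    "ARE": int(counts["ARE"][sp][gi]),
                    "ERE": int(counts["ERE"][sp][gi]),
                }
            )
    truth.per_gene_counts = {
        sp: {
            "ARE": {g: int(c) for g, c in zip(gene_ids, counts["ARE"][sp])},
            "ERE": {g: int(c) for g, c in zip(gene_ids, counts["ERE"][sp])},
        }
        for sp in species
    }
    return pd.DataFrame.from_records(records), truth


def sim_traits(
    tree: dendropy.Tree,
    are_totals: Mapping[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
    ln_n50: Mapping[str, float] | None = None,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Body mass, SSD and back-solved male/female masses per species.

    Masses satisfy ``compute_ssd(male, female) == ssd`` and
    ``(male + female)/2 == body`` exactly up to floating point.  A species
    whose realized ARE total is zero takes ``ln(1)`` in the generative
    predictor; such species are excluded downstream by the ln-count rule,
    so the placeholder never reaches a fit.  Negative totals are rejected.
    """
    species = [l.taxon.label for l in tree.leaf_node_iter()]
    totals = np.array([are_totals[sp] for sp in species], dtype=float)
    if (totals < 0).any():
        bad = [sp for sp, t in zip(species, totals) if t < 0]
        raise ValueError(f"species with negative ARE totals: {bad}")
    totals = np.maximum(totals, 1.0)
    ln_body = brownian_on_tree(tree, config.body_root_ln_mass, config.body_bm_var, rng)
    body = np.array([np.exp(ln_body[sp]) for sp in species])
    C, _ = phylo_vcv(tree, order=species)
    V = pagel_transform(C, config.lam)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(species)))
    eps = config.residual_sd * (L @ rng.standard_normal(len(species)))
    ssd = config.beta_are * np.log(totals) + config.beta_body * np.log(body) + eps
    female = 2.0 * body / (1.0 + np.exp(ssd))
    male = female * np.exp(ssd)

    orders = _order_labels(tree)
    if ln_n50 is None:
        ln_n50 = {
            sp: config.n50_ln_mean + config.n50_ln_sd * rng.standard_normal()
            for sp in species
        }
    if truth is not None:
        truth.ssd = {sp: float(v) for sp, v in zip(species, ssd)}
    return pd.DataFrame(
        {
            "species": species,
            "male_mass": male,
            "female_mass": female,
            "order": [orders[sp] for sp in species],
            "contig_n50": [float(np.exp(ln_n50[sp])) for sp in species],
        }
    )


def _order_labels(tree: dendropy.Tree) -> dict[str, str]:
    """Assign pseudo-taxonomic orders: one per child subtree of the root."""
    labels: dict[str, str] = {}
    for i, child in enumerate(tree.seed_node.child_nodes(), start=1):
        for leaf in child.leaf_iter():
            labels[leaf.taxon.label] = f"order{i}"
    return labels


@dataclass
class SpeciesDataset:
    """A complete statistics-level dataset (no genome sequences)."""

    tree: dendropy.Tree
    per_gene_counts: pd.DataFrame
    counts: pd.DataFrame  # species-level totals, build_species_table dialect
    traits: pd.DataFrame
    truth: GroundTruth
    burst_clade: list[str]


def simulate_species_dataset(config: SimulationConfig) -> SpeciesDataset:
    """Tree + counts + traits under the configured generative model."""
    rng = np.random.default_rng(config.seed)
    tree = sim_tree(config.n_species, config.birth_rate, seed=config.seed)
    species = [l.taxon.label for l in tree.leaf_node_iter()]
    ln_n50 = {
        sp: config.n50_ln_mean + config.n50_ln_sd * rng.standard_normal()
        for sp in species
    }
    per_gene, truth = sim_rates_and_counts(tree, config, rng, ln_n50=ln_n50)
    totals = per_gene.groupby("species")[["ARE", "ERE"]].sum()
    # guard against an all-zero total (possible at very low rates)
    totals = totals.clip(lower=0)
    traits = sim_traits(
        tree, totals["ARE"].to_dict(), config, rng, ln_n50=ln_n50, truth=truth
    )
    counts = pd.DataFrame(
        {
            "species": totals.index,
            "flank": config.plant_flank,
            "are_count": totals["ARE"].to_numpy(),
            "ere_count": totals["ERE"].to_numpy(),
            "interrogated_bp": config.n_genes * (2 * config.plant_flank + 1),
        }
    ).reset_index(drop=True)
    burst = sorted(
        set(config.burst_clade or [])
        or (set(pick_burst_clade(tree, config.burst_fraction)) if config.burst_fraction else set())
    )
    return SpeciesDataset(tree, per_gene, counts, traits, truth, burst)


# ---------------------------------------------------------------------------
# genome sequences with planted motifs

_BASES = np.array(list("ACGT"))


def _random_background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _instantiate(motif: MotifPattern, rng: np.random.Generator) -> str:
    """A concrete sequence matching the motif (spacer Ns drawn uniformly)."""
    return "".join(
        ch if ch != "N" else _BASES[rng.integers(4)] for ch in motif.iupac
    )


def sim_genomes(
    tree_or_species: dendropy.Tree | Sequence[str],
    per_gene_counts: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    motifs: Sequence[MotifPattern] = (CANONICAL_ARE, CANONICAL_ERE),
    truth: GroundTruth | None = None,
) -> tuple[dict[str, dict[str, str]], dict[str, list[GeneAnnotation]]]:
    """Emit one single-contig genome per species with motifs planted.

    Genes sit at regular TSS spacing (category Intact); each gene's planted
    ARE/ERE instances are placed uniformly, without overlaps, inside its
    ``plant_flank`` window; non-palindromic motifs alternate strands.
    With ``clean_background`` any spurious motif occurrence created by the
    background (or a planting junction) is resampled, so a scan recovers
    exactly the planted set.

    Returns ``(genomes, annotations)`` keyed by species; planted positions
    are appended to ``truth`` when given.
    """
    if isinstance(tree_or_species, dendropy.Tree):
        species = [l.taxon.label for l in tree_or_species.leaf_node_iter()]
    else:
        species = list(tree_or_species)
    by_class = {m.hre_class: m for m in motifs}
    max_len = max(m.length for m in motifs)
    spacing = 2 * config.plant_flank + max_len + 200
    contig_len = config.contig_length or (config.n_genes * spacing + config.plant_flank + 200)
    genomes: dict[str, dict[str, str]] = {}
    annotations: dict[str, list[GeneAnnotation]] = {}

    for sp in species:
        arr = _random_background(contig_len, config.gc_fraction, rng)
        genes: list[GeneAnnotation] = []
        planted: list[dict] = []
        occupied: list[tuple[int, int]] = []
        sub = per_gene_counts[per_gene_counts["species"] == sp].set_index("gene_id")
        for gi, gene_id in enumerate(sorted(sub.index)):
            tss = config.plant_flank + 100 + gi * spacing
            if tss + config.plant_flank + max_len >= contig_len:
                raise ValueError("contig too short to hold all gene windows")
            genes.append(GeneAnnotation(gene_id, "chr1", "+", tss, "Intact"))
            instances: list[MotifPattern] = []
            for cls in ("ARE", "ERE"):
                motif = by_class.get(cls)
                if motif is not None:
                    instances.extend([motif] * int(sub.loc[gene_id, cls]))
            if not instances:
                continue
            rng.shuffle(instances)
            lo = tss - config.plant_flank
            width = 2 * config.plant_flank + 1
            total = sum(m.length for m in instances)
            slack = width - total
            if slack < 0:
                raise ValueError(
                    f"{sp}/{gene_id}: cannot pack {len(instances)} planted "
                    f"motifs ({total} bp) into a {width} bp window"
                )
            # stars-and-bars: uniform non-overlapping placement in one pass
            gaps = np.sort(rng.integers(0, slack + 1, size=len(instances)))
            cursor = 0
            k_flip = 0
            for motif, gap in zip(instances, gaps):
                start = lo + int(gap) + cursor
                cursor += motif.length
                strand = "+"
                inst = _instantiate(motif, rng)
                if not motif.palindromic and k_flip % 2 == 1:
                    inst = reverse_complement_iupac(inst)
                    strand = "-"
                k_flip += 1
                idx = np.array([("ACGT").index(c) for c in inst])
                arr[start : start + motif.length] = idx
                occupied.append((start, start + motif.length))
                planted.append(
                    {"contig": "chr1", "start": start, "strand": strand,
                     "motif_name": motif.name, "hre_class": motif.hre_class}
                )
        sequence = "".join(_BASES[arr])
        if config.clean_background:
            sequence = _scrub_spurious(sequence, planted, motifs, config, rng)
        genomes[sp] = {"chr1": sequence}
        annotations[sp] = genes
        if truth is not None:
            truth.planted[sp] = sorted(planted, key=lambda d: d["start"])
    return genomes, annotations


def _scrub_spurious(
    sequence: str,
    planted: list[dict],
    motifs: Sequence[MotifPattern],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> str:
    """Resample any motif occurrence that was not deliberately planted."""
    planted_keys = {(d["start"], d["motif_name"]) for d in planted}
    protected = np.zeros(len(sequence), dtype=bool)
    lengths = {m.name: m.length for m in motifs}
    for d in planted:
        protected[d["start"] : d["start"] + lengths[d["motif_name"]]] = True
    seq = np.array(list(sequence))
    for _round in range(1000):
        hits = scan_genome({"chr1": "".join(seq)}, motifs)
        spurious = [h for h in hits if (h.start, h.motif_name) not in planted_keys]
        if not spurious:
            return "".join(seq)
        for h in spurious:
            span = slice(h.start, h.start + lengths[h.motif_name])
            fresh = _BASES[_random_background(lengths[h.motif_name],
                                              config.gc_fraction, rng)]
            keep = protected[span]
            seq[span] = np.where(keep, seq[span], fresh)
    raise RuntimeError("failed to scrub spurious motif matches after 1000 rounds")


# ---------------------------------------------------------------------------
# dataset writer


def write_dataset(outdir: str | Path, config: SimulationConfig, force: bool = False) -> Path:
    """Write a complete synthetic dataset in the dialects the pipeline reads.

    Layout: ``genomes/<species>.fa``, ``annotations/<species>.tsv``,
    ``traits.csv``, ``tree.nwk``, ``ground_truth.json``, ``config.json``.
    Refuses to overwrite a non-empty directory unless ``force``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not force:
            raise FileExistsError(f"{outdir} is not empty (pass force=True)")
        shutil.rmtree(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "annotations").mkdir(exist_ok=True)

    ds = simulate_species_dataset(config)
    rng = np.random.default_rng(config.seed + 1)
    genomes, annotations = sim_genomes(ds.tree, ds.per_gene_counts, config, rng,
                                       truth=ds.truth)
    for sp, genome in genomes.items():
        with open(outdir / "genomes" / f"{sp}.fa", "w") as fh:
            for contig, seq in genome.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(outdir / "annotations" / f"{sp}.tsv", "w") as fh:
            fh.write("gene_id\tcontig\tstrand\ttss\tcategory\n")
            for g in annotations[sp]:
                fh.write(f"{g.gene_id}\t{g.contig}\t{g.strand}\t{g.tss}\t{g.category}\n")
    ds.traits.to_csv(outdir / "traits.csv", index=False)
    ds.tree.write(path=str(outdir / "tree.nwk"), schema="newick",
                  suppress_rooting=True, unquoted_underscores=True)
    (outdir / "ground_truth.json").write_text(ds.truth.to_json())
    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True)
    )
    logger.info("wrote synthetic dataset for %d species to %s", config.n_species, outdir)
    return outdir
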