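"""Gene-centric scan: per-gene phylogenetic regressions of SSD on HRE counts.

Each eligible gene gets its own PGLS fit of
``SSD ~ ln(count + 1) + ln(body_size)`` on the subset of species that
carry the gene (species lacking an annotation are missing data, not
zero-count).  A gene is eligible when at least ``min_species`` species
carry it and the counts take at least two distinct values.  The direction
summary is the proportion of tested genes with a positive count effect,
significance not required; the significance export keeps genes with a
positive effect and uncorrected p below alpha (a Benjamini-Hochberg q is
attached for users, never used for the export filter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .models import PhyloGLS, SingularModelError
from .phylo import phylo_vcv, prune

logger = logging.getLogger(__name__)


@dataclass
class GeneEffectRecord:
    gene_id: str
    hre_class: str
    flank: int
    n_species: int
    effect: float
    p_value: float
    lam: float
    failed: bool = False

    @property
    def direction(self) -> int:
        return int(np.sign(self.effect))


def select_testable(
    counts: pd.DataFrame, min_species: int = 10
) -> list[str]:
    """Eligible genes from a long table (gene_id, species, count).

    A gene qualifies when >= ``min_species`` species carry it and its
    counts among those species take at least two distinct values.
    """
    eligible = []
    for gene_id, grp in counts.groupby("gene_id", sort=True):
        if len(grp) >= min_species and grp["count"].nunique() >= 2:
            eligible.append(gene_id)
    return eligible


def fit_gene(
    gene_id: str,
    counts: pd.DataFrame,
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    hre_class: str = "ARE",
    flank: int = 50_000,
    lam: float | str = "ML",
) -> GeneEffectRecord:
    """PGLS of SSD on ln(count + 1) + ln(body) for one gene's species.

    ``counts`` is the long table restricted or not; ``traits`` must carry
    species, ssd, body_size.  A singular fit yields a record flagged
    ``failed`` (excluded from summaries) rather than an exception.
    """
    sub = counts[counts["gene_id"] == gene_id].merge(traits, on="species", how="inner")
    species = list(sub["species"])
    n = len(species)
    pruned = prune(tree, species)
    C, _ = phylo_vcv(pruned, order=species)
    X = np.column_stack([
        np.log1p(sub["count"].to_numpy(float)),
        np.log(sub["body_size"].to_numpy(float)),
    ])
    y = sub["ssd"].to_numpy(float)
    try:
        est = PhyloGLS(lam=lam).fit(X, y, C=C, feature_names=["ln_count1p", "ln_body"])
    except (SingularModelError, ValueError) as exc:
        logger.warning("gene %s: fit failed (%s)", gene_id, exc)
        return GeneEffectRecord(gene_id, hre_class, flank, n, np.nan, np.nan,
                                np.nan, failed=True)
    return GeneEffectRecord(
        gene_id, hre_class, flank, n,
        float(est.params_["ln_count1p"]), float(est.pvalues_["ln_count1p"]),
        est.lambda_,
    )


def scan_genes(
    counts: pd.DataFrame,
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    hre_class: str = "ARE",
    flank: int = 50_000,
    min_species: int = 10,
    lam: float | str = "ML",
) -> list[GeneEffectRecord]:
    """Fit every eligible gene; failed fits are kept but flagged."""
    eligible = select_testable(counts, min_species=min_species)
    logger.info("%d of %d genes eligible (min_species=%d, variable counts)",
                len(eligible), counts["gene_id"].nunique(), min_species)
    return [
        fit_gene(g, counts, traits, tree, hre_class=hre_class, flank=flank, lam=lam)
        for g in eligible
    ]


def records_to_frame(records: Sequence[GeneEffectRecord]) -> pd.DataFrame:
    """Tabulate records, attach BH q-values, and a volcano-ready column."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "hre_class": [r.hre_class for r in records],
            "flank": [r.flank for r in records],
            "n_species": [r.n_species for r in records],
            "effect": [r.effect for r in records],
            "p_value": [r.p_value for r in records],
            "lambda": [r.lam for r in records],
            "failed": [r.failed for r in records],
        }
    )
    ok = ~df["failed"]
    df["q_value"] = np.nan
    if ok.any():
        df.loc[ok, "q_value"] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
    df["neg_log10_p"] = -np.log10(df["p_value"])
    return df


def direction_summary(records: Sequence[GeneEffectRecord]) -> pd.DataFrame:
    """Proportion of successfully tested genes with a positive effect.

    Grouped by (hre_class, flank); order of the records is immaterial.
    """
    ok = [r for r in records if not r.failed]
    if not ok:
        raise ValueError("no successful gene fits to summarize")
    df = pd.DataFrame(
        {
            "hre_class": [r.hre_class for r in ok],
            "flank": [r.flank for r in ok],
            "positive": [r.effect > 0 for r in ok],
        }
    )
    out = (
        df.groupby(["hre_class", "flank"], sort=True)["positive"]
        .agg(n_genes="size", prop_positive="mean")
        .reset_index()
    )
    return out


def export_significant(
    records: Sequence[GeneEffectRecord],
    path: str | Path,
    alpha: float = 0.05,
) -> list[str]:
    """Write genes with positive effect and uncorrected p < alpha, one per line.

    This is the input list for external GO-enrichment tools.
    """
    genes = sorted(
        r.gene_id
        for r in records
        if not r.failed and r.effect > 0 and r.p_value < alpha
    )
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
    logger.info("exported %d significant positive genes to %s", len(genes), path)
    return genes
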