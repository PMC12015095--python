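"""TSS-flanking windows, interval merging, and HRE counting.

Two counting modes correspond to the two analyses the pipeline supports:

* **dedup** — windows of all retained genes are merged into a disjoint
  union per contig and each motif occurrence is counted at most once per
  HRE class, even when it lies near several genes.  This feeds the
  species-level models.
* **per-gene** — every (gene, hit) pair with the hit inside that gene's
  window counts, so one occurrence may contribute to several genes.  This
  feeds the gene-centric scan.

Windows are symmetric about the TSS irrespective of gene strand
(``[tss - flank, tss + flank + 1)``, clamped to contig bounds) and a hit
belongs to a window when its *start* position lies inside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

from .motifs import HRE_CLASSES, MotifHit

logger = logging.getLogger(__name__)

#: the six TOGA-style gene calls
CATEGORIES = frozenset(
    ["Intact", "PartiallyIntact", "Lost", "Missing", "UncertainLost", "ParalogousProjection"]
)
#: default retained calls: intact genes plus paralogous projections
DEFAULT_KEEP = frozenset(["Intact", "ParalogousProjection"])

ANNOTATION_COLUMNS = ["gene_id", "contig", "strand", "tss", "category"]


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    contig: str
    strand: str
    tss: int  # 0-based
    category: str


class AnnotationError(ValueError):
    """Malformed annotation input."""


def read_annotations(
    path: str | Path, keep_categories: Iterable[str] = DEFAULT_KEEP
) -> list[GeneAnnotation]:
    """Read the canonical 5-column annotation TSV and filter by category.

    Rows whose category is not in ``keep_categories`` are dropped (count
    logged).  Unknown categories or a non-integer TSS raise
    :class:`AnnotationError`.
    """
    keep = frozenset(keep_categories)
    unknown_keep = keep - CATEGORIES
    if unknown_keep:
        raise AnnotationError(f"unknown keep categories: {sorted(unknown_keep)}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing required columns {sorted(missing)}")
    bad_cat = set(df["category"]) - CATEGORIES
    if bad_cat:
        raise AnnotationError(f"{path}: unknown categories {sorted(bad_cat)}")
    try:
        tss = df["tss"].astype(int)
    except (TypeError, ValueError) as exc:
        raise AnnotationError(f"{path}: tss column must be integer") from exc
    keep_mask = df["category"].isin(keep)
    n_dropped = int((~keep_mask).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows outside keep categories", path, n_dropped)
    return [
        GeneAnnotation(r.gene_id, r.contig, r.strand, int(t), r.category)
        for (_, r), t in zip(df[keep_mask].iterrows(), tss[keep_mask])
    ]


def read_annotations_gff3(
    path: str | Path, keep_categories: Iterable[str] = DEFAULT_KEEP
) -> list[GeneAnnotation]:
    """GFF3 adapter: strand-aware 5' end of ``gene`` features becomes the TSS.

    Category is read from a ``toga_status`` attribute and defaults to
    ``Intact`` (logged) when absent.  GFF3 is 1-based inclusive; the TSS is
    converted to a 0-based coordinate.
    """
    genes = []
    n_defaulted = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.featuretype != "gene":
                continue
            tss = feat.start - 1 if feat.strand != "-" else feat.end - 1
            status = feat.attributes.get("toga_status", [None])[0]
            if status is None:
                status = "Intact"
                n_defaulted += 1
            gene_id = feat.attributes.get("ID", [feat.id or f"gene_{len(genes)}"])[0]
            genes.append(GeneAnnotation(gene_id, feat.seqid, feat.strand, tss, status))
    if n_defaulted:
        logger.info("%s: %d gene features lacked toga_status; defaulted to Intact", path, n_defaulted)
    keep = frozenset(keep_categories)
    bad = {g.category for g in genes} - CATEGORIES
    if bad:
        raise AnnotationError(f"{path}: unknown toga_status values {sorted(bad)}")
    return [g for g in genes if g.category in keep]


# ---------------------------------------------------------------------------
# window arithmetic


def tss_window(tss: int, flank: int, contig_length: int) -> tuple[int, int]:
    """Half-open symmetric window about the TSS, clamped to contig bounds.

    The TSS base itself is included, hence the ``+ 1`` on the right bound.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    return max(0, tss - flank), min(contig_length, tss + flank + 1)


@dataclass
class WindowSet:
    """Merged, disjoint TSS-flanking intervals per contig.

    ``intervals`` maps contig → (k, 2) integer array of sorted half-open
    intervals; ``interrogated_bp`` is the total union length.
    """

    flank: int
    intervals: dict[str, np.ndarray]
    interrogated_bp: int


def merge_intervals(per_contig: Mapping[str, Sequence[tuple[int, int]]], flank: int = 0) -> WindowSet:
    """Union of half-open intervals per contig; touching intervals merge."""
    merged: dict[str, np.ndarray] = {}
    total = 0
    for contig, ivals in per_contig.items():
        if len(ivals) == 0:
            merged[contig] = np.empty((0, 2), dtype=np.int64)
            continue
        arr = np.asarray(sorted(ivals), dtype=np.int64)
        out = [list(arr[0])]
        for s, e in arr[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        res = np.asarray(out, dtype=np.int64)
        merged[contig] = res
        total += int((res[:, 1] - res[:, 0]).sum())
    return WindowSet(flank=flank, intervals=merged, interrogated_bp=total)


def build_windows(
    genes: Sequence[GeneAnnotation],
    flank: int,
    contig_lengths: Mapping[str, int],
) -> WindowSet:
    """Merged window set over all genes at one flank size."""
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        clen = contig_lengths[g.contig]
        per_contig.setdefault(g.contig, []).append(tss_window(g.tss, flank, clen))
    return merge_intervals(per_contig, flank=flank)


def _inside(starts: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask: which hit starts fall inside the sorted disjoint intervals."""
    if intervals.shape[0] == 0:
        return np.zeros(len(starts), dtype=bool)
    idx = np.searchsorted(intervals[:, 0], starts, side="right") - 1
    ok = idx >= 0
    ok[ok] = starts[ok] < intervals[idx[ok], 1]
    return ok


def count_hits_dedup(
    hits: Sequence[MotifHit], windows: WindowSet
) -> dict[str, dict[str, int]]:
    """Once-only counts of hits inside the merged windows.

    Returns ``{"by_class": {ARE: n, ERE: n}, "by_motif": {...}}``.  A hit
    whose contig is absent from the window set is counted as outside
    (logged).
    """
    by_class = {c: 0 for c in HRE_CLASSES}
    by_motif: dict[str, int] = {}
    missing_contigs: set[str] = set()
    per_contig: dict[str, list[MotifHit]] = {}
    for h in hits:
        per_contig.setdefault(h.contig, []).append(h)
    for contig, contig_hits in per_contig.items():
        ivals = windows.intervals.get(contig)
        if ivals is None:
            missing_contigs.add(contig)
            continue
        starts = np.asarray([h.start for h in contig_hits], dtype=np.int64)
        for h, ok in zip(contig_hits, _inside(starts, ivals)):
            if ok:
                by_class[h.hre_class] += 1
                by_motif[h.motif_name] = by_motif.get(h.motif_name, 0) + 1
    if missing_contigs:
        logger.warning(
            "hits on %d contig(s) absent from window set counted as outside: %s",
            len(missing_contigs),
            sorted(missing_contigs),
        )
    return {"by_class": by_class, "by_motif": by_motif}


def count_hits_per_gene(
    hits: Sequence[MotifHit],
    genes: Sequence[GeneAnnotation],
    flank: int,
    contig_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-gene ARE/ERE counts; one occurrence may count toward many genes.

    Returns a DataFrame indexed by gene_id with columns ``ARE`` and ``ERE``.
    """
    starts_by_contig: dict[str, np.ndarray] = {}
    class_by_contig: dict[str, np.ndarray] = {}
    for contig in {h.contig for h in hits}:
        contig_hits = [h for h in hits if h.contig == contig]
        order = np.argsort([h.start for h in contig_hits], kind="stable")
        starts_by_contig[contig] = np.asarray(
            [contig_hits[i].start for i in order], dtype=np.int64
        )
        class_by_contig[contig] = np.asarray(
            [contig_hits[i].hre_class == "ARE" for i in order], dtype=bool
        )
    rows = {}
    for g in genes:
        lo, hi = tss_window(g.tss, flank, contig_lengths[g.contig])
        starts = starts_by_contig.get(g.contig)
        if starts is None:
            rows[g.gene_id] = (0, 0)
            continue
        i = np.searchsorted(starts, lo, side="left")
        j = np.searchsorted(starts, hi, side="left")
        is_are = class_by_contig[g.contig][i:j]
        rows[g.gene_id] = (int(is_are.sum()), int(j - i - is_are.sum()))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["ARE", "ERE"])
    df.index.name = "gene_id"
    return df


def windows_to_bed(windows: WindowSet, path: str | Path) -> None:
    """Export merged windows as BED3."""
    with open(path, "w") as fh:
        for contig in sorted(windows.intervals):
            for s, e in windows.intervals[contig]:
                fh.write(f"{contig}\t{s}\t{e}\n")
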