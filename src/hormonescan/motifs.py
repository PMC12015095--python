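"""Hormone response element motifs and degenerate-pattern genome scanning.

Androgen and estrogen receptors bind short, largely palindromic DNA motifs
(hormone response elements, HREs).  The canonical androgen response element
(ARE) is ``AGAACANNNTGTTCT`` — two inverted half-sites around a three-base
spacer — and the canonical estrogen response element (ERE) is
``GGTCANNNTGACC``.  This module defines motif records, validates degenerate
IUPAC strings, and locates every occurrence of each motif in a genome on
both strands.

Conventions
-----------
* Coordinates are 0-based, half-open.  BED output is therefore written
  without further shifting.
* A motif ``N`` is a spacer that matches ``A/C/G/T`` only; it never matches
  an assembly-gap ``N`` in the subject sequence, so unresolved regions
  cannot contribute artifactual counts.
* Overlapping matches are all reported (every valid start position).
* Palindromic motifs are scanned on the forward strand only: a reverse
  scan would report the identical set of sites and double every count.
  Non-palindromic motifs are scanned as themselves (strand ``+``) and as
  their reverse complement (strand ``-``, start still in forward-reference
  coordinates).
* Matching is case-insensitive; soft-masked (lowercase) bases are kept.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

HRE_CLASSES = ("ARE", "ERE")

#: complement table for the supported motif alphabet
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: characters permitted in subject (genome) sequences
_SEQ_ALPHABET = frozenset("ACGTN")


class MotifError(ValueError):
    """Invalid motif definition or malformed motif file."""


def reverse_complement_iupac(iupac: str) -> str:
    """Reverse-complement a degenerate DNA string (``N`` maps to ``N``).

    Raises :class:`MotifError` naming the offending character and its
    0-based position if the string contains an unsupported character.
    """
    out = []
    for pos, ch in enumerate(iupac):
        comp = _COMPLEMENT.get(ch)
        if comp is None:
            raise MotifError(
                f"unsupported character {ch!r} at position {pos} in motif string {iupac!r}"
            )
        out.append(comp)
    return "".join(reversed(out))


@dataclass(frozen=True)
class MotifPattern:
    """A named degenerate DNA motif.

    Attributes
    ----------
    name : str
        Short unique label, e.g. ``ARE_canonical``.
    iupac : str
        Motif string over ``{A, C, G, T, N}``; ``N`` is a spacer matching
        any unambiguous base.
    hre_class : str
        ``"ARE"`` or ``"ERE"``.
    """

    name: str
    iupac: str
    hre_class: str = "ARE"

    def __post_init__(self) -> None:
        if len(self.iupac) < 4:
            raise MotifError(f"motif {self.name!r}: length {len(self.iupac)} < 4")
        # reverse_complement_iupac validates the alphabet as a side effect
        reverse_complement_iupac(self.iupac)
        if self.hre_class not in HRE_CLASSES:
            raise MotifError(
                f"motif {self.name!r}: hre_class must be one of {HRE_CLASSES}, "
                f"got {self.hre_class!r}"
            )

    @property
    def length(self) -> int:
        return len(self.iupac)

    @property
    def palindromic(self) -> bool:
        """True when the motif equals its own reverse complement."""
        return reverse_complement_iupac(self.iupac) == self.iupac


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: leftmost matched base in forward coordinates."""

    contig: str
    start: int
    strand: str
    motif_name: str
    hre_class: str


CANONICAL_ARE = MotifPattern("ARE_canonical", "AGAACANNNTGTTCT", "ARE")
CANONICAL_ERE = MotifPattern("ERE_canonical", "GGTCANNNTGACC", "ERE")


def default_motifs() -> list[MotifPattern]:
    """The two canonical motifs shipped with the package."""
    return [CANONICAL_ARE, CANONICAL_ERE]


def default_motif_path() -> Path:
    """Path of the bundled motif TSV (users append further AREs to a copy)."""
    return Path(str(resources.files("hormonescan").joinpath("data/default_motifs.tsv")))


def parse_motif_file(path: str | Path) -> list[MotifPattern]:
    """Read a motif TSV: ``name<TAB>iupac[<TAB>hre_class]``, '#' comments.

    The third column defaults to ``ARE``.  Empty files, duplicate names and
    invalid IUPAC strings raise :class:`MotifError`.
    """
    motifs: list[MotifPattern] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise MotifError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0].strip()
            iupac = fields[1].strip().upper()
            hre_class = fields[2].strip() if len(fields) == 3 else "ARE"
            if name in seen:
                raise MotifError(f"{path}:{lineno}: duplicate motif name {name!r}")
            seen.add(name)
            try:
                motifs.append(MotifPattern(name, iupac, hre_class))
            except MotifError as exc:
                raise MotifError(f"{path}:{lineno}: {exc}") from exc
    if not motifs:
        raise MotifError(f"{path}: no motif definitions found")
    return motifs


# ---------------------------------------------------------------------------
# scanning


def _encode(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)


def scan_forward(sequence: str, motif: MotifPattern) -> list[int]:
    """All 0-based start positions where ``motif`` matches the forward strand.

    Overlapping matches are all reported; positions are strictly increasing.
    Motif ``N`` matches A/C/G/T only, never an assembly ``N``.
    """
    m = motif.length
    n = len(sequence) - m + 1
    if n <= 0:
        return []
    arr = _encode(sequence)
    ok = np.ones(n, dtype=bool)
    unambiguous = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    for offset, ch in enumerate(motif.iupac):
        if ch == "N":
            ok &= unambiguous[offset : offset + n]
        else:
            ok &= arr[offset : offset + n] == ord(ch)
    return np.flatnonzero(ok).tolist()


def _validate_contig(contig: str, sequence: str) -> str:
    if not sequence.isupper() and any(c.islower() for c in sequence):
        logger.warning("contig %s contains lowercase bases; uppercasing", contig)
        sequence = sequence.upper()
    bad = set(sequence) - _SEQ_ALPHABET
    if bad:
        raise ValueError(
            f"contig {contig}: non-DNA characters {sorted(bad)!r} (allowed: A, C, G, T, N)"
        )
    return sequence


def scan_genome(
    genome: Mapping[str, str], motifs: Iterable[MotifPattern]
) -> list[MotifHit]:
    """Locate every motif occurrence on both strands of every contig.

    Palindromic motifs are matched on the forward strand only (one hit per
    site); non-palindromic motifs additionally contribute reverse-complement
    matches with strand ``-`` and start reported in forward coordinates.
    Hits are sorted by (contig, start, motif_name).
    """
    hits: list[MotifHit] = []
    for contig in sorted(genome):
        sequence = _validate_contig(contig, genome[contig])
        for motif in motifs:
            for start in scan_forward(sequence, motif):
                hits.append(MotifHit(contig, start, "+", motif.name, motif.hre_class))
            if not motif.palindromic:
                rc = MotifPattern(motif.name, reverse_complement_iupac(motif.iupac), motif.hre_class)
                for start in scan_forward(sequence, rc):
                    hits.append(
                        MotifHit(contig, start, "-", motif.name, motif.hre_class)
                    )
    hits.sort(key=lambda h: (h.contig, h.start, h.motif_name))
    return hits


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-contig FASTA (optionally gzipped) as a contig→sequence dict."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
    return {rec.id: str(rec.seq) for rec in records}


def write_bed(
    hits: Iterable[MotifHit], motifs: Iterable[MotifPattern], path: str | Path
) -> None:
    """Write hits as BED6 (0-based half-open; score column fixed at 0)."""
    lengths = {m.name: m.length for m in motifs}
    with open(path, "w") as fh:
        for hit in hits:
            end = hit.start + lengths[hit.motif_name]
            fh.write(
                f"{hit.contig}\t{hit.start}\t{end}\t{hit.motif_name}\t0\t{hit.strand}\n"
            )
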