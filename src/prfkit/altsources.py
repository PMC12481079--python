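"""Alternative-source scanning for chimeric peptides.

A chimeric peptide's primary source is the transcript whose chimeric model
it matched, but short peptides can often arise elsewhere.  This module
scans a sequence database (transcriptome, repeat elements) for

* non-chimeric sources: the whole peptide encoded contiguously in a single
  reading frame, and
* chimeric-split sources: a prefix encoded in frame ``f`` followed, after a
  single shift of value in {-2, -1, +1, +2}, by the suffix in the implied
  frame ``f'``.

Matching is exact at the amino acid level over a six-frame translation
index (three forward frames, and the reverse-complement frames unless
``forward_only`` is set).  The search is brute-force-complete over split
points and shift values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .chimeras import OVERLAP_VALUES
from .orfs import translate_codon

FORWARD_FRAMES = ("1F", "2F", "3F")
REVERSE_FRAMES = ("1R", "2R", "3R")


@dataclass(frozen=True)
class FrameTranslation:
    """One frame of one database record, with a coordinate back-map.

    ``aa_seq`` uses ``*`` for stops and ``X`` for ambiguous codons, so
    peptide matches can never run through a stop.  ``offset`` is the 0-based
    start of the frame in *reading* orientation (the reverse complement for
    R frames); ``nt_span`` converts amino acid windows back to 1-based
    inclusive coordinates on the forward strand.
    """

    locus_id: str
    frame_label: str
    strand: str          # '+' or '-'
    offset: int
    aa_seq: str
    seq_len: int

    def nt_span(self, aa_start: int, n_aa: int) -> tuple[int, int]:
        r1 = self.offset + 3 * aa_start + 1            # reading-space, 1-based
        r2 = self.offset + 3 * (aa_start + n_aa)
        if self.strand == "+":
            return r1, r2
        return self.seq_len - r2 + 1, self.seq_len - r1 + 1


@dataclass(frozen=True)
class SourceHit:
    peptide: str
    locus_id: str
    kind: str                       # "nonchimeric" or "chimeric_split"
    frames: tuple[str, ...]
    coords: tuple[tuple[int, int], ...]   # forward-strand spans, 1-based
    strand: str
    split_index: Optional[int] = None     # aa offset of the shift
    shift_value: Optional[int] = None


def _translate_reading(seq: str, offset: int) -> str:
    n = (len(seq) - offset) // 3
    return "".join(translate_codon(seq[offset + 3 * i:offset + 3 * i + 3]) or "X"
                   for i in range(n))


def sixframe_translate(db: Mapping[str, str],
                       forward_only: bool = False) -> list[FrameTranslation]:
    """Translation index over a sequence database.

    Reverse-complement frames are included unless ``forward_only`` is set
    (repeat elements can act through the reverse complement).
    """
    index: list[FrameTranslation] = []
    for locus in sorted(db):
        seq = db[locus].upper()
        for off in range(3):
            index.append(FrameTranslation(locus, FORWARD_FRAMES[off], "+", off,
                                          _translate_reading(seq, off), len(seq)))
        if not forward_only:
            rc = str(Seq(seq).reverse_complement())
            for off in range(3):
                index.append(FrameTranslation(locus, REVERSE_FRAMES[off], "-", off,
                                              _translate_reading(rc, off), len(seq)))
    return index


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def find_nonchimeric_sources(peptide: str,
                             index: Sequence[FrameTranslation]) -> list[SourceHit]:
    """Loci encoding the whole peptide contiguously in one frame."""
    pep = peptide.upper()
    hits = []
    for ft in index:
        for i in _find_all(ft.aa_seq, pep):
            hits.append(SourceHit(pep, ft.locus_id, "nonchimeric",
                                  (ft.frame_label,), (ft.nt_span(i, len(pep)),),
                                  ft.strand))
    return hits


def find_chimeric_sources(peptide: str, index: Sequence[FrameTranslation],
                          min_flank_aa: int = 2,
                          shifts: Sequence[int] = OVERLAP_VALUES) -> list[SourceHit]:
    """Loci encoding the peptide as prefix + single frameshift + suffix.

    Every split point leaving at least ``min_flank_aa`` residues on each
    side is combined with every shift value; a hit requires the prefix in
    frame ``f`` to end where the suffix begins in the frame implied by the
    shift, on the same locus and strand.
    """
    pep = peptide.upper()
    if len(pep) < 2 * min_flank_aa:
        raise ValueError(f"peptide shorter than two flanks of {min_flank_aa} aa")

    by_strand: dict[tuple[str, str, int], FrameTranslation] = {
        (ft.locus_id, ft.strand, ft.offset): ft for ft in index}
    hits = []
    for ft in index:
        for split in range(min_flank_aa, len(pep) - min_flank_aa + 1):
            prefix, suffix = pep[:split], pep[split:]
            for i in _find_all(ft.aa_seq, prefix):
                prefix_end = ft.offset + 3 * (i + split)    # reading-space, 1-based
                for v in shifts:
                    site = prefix_end + 1 + v
                    if site < 1:
                        continue
                    ft2 = by_strand.get((ft.locus_id, ft.strand, (site - 1) % 3))
                    if ft2 is None:
                        continue
                    j, rem = divmod(site - 1 - ft2.offset, 3)
                    if rem or j < 0:
                        continue
                    if ft2.aa_seq[j:j + len(suffix)] == suffix:
                        hits.append(SourceHit(
                            pep, ft.locus_id, "chimeric_split",
                            (ft.frame_label, ft2.frame_label),
                            (ft.nt_span(i, split), ft2.nt_span(j, len(suffix))),
                            ft.strand, split_index=split, shift_value=v))
    return hits
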