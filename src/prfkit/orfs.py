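"""Stop-free reading-frame extraction on transcripts.

A transcript is scanned in its three forward frames (labelled ``1F``-``3F``;
frame 1F starts at the first nucleotide) for maximal runs of consecutive
non-stop complete codons.  Runs of at least ``min_len_nt`` nucleotides are
reported as alternative ORFs (altORFs) and translated with the standard
genetic code.  No start codon is required: an altORF is any sufficiently
long stop-free region, so its translation (altProt) may begin with any
residue.  The annotated coding region of an mRNA (refORF) is handled
separately from its annotation span.

Coordinates are 1-based and inclusive throughout, in transcript space.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

RNA_TYPES = ("mRNA", "ncRNA", "rRNA", "tRNA")
FRAME_LABELS = ("1F", "2F", "3F")

_VALID_NT = re.compile(r"[ACGTN]*")


class SequenceError(ValueError):
    """Raised for malformed nucleotide input."""


def frame_of_position(start_nt: int) -> int:
    """Forward frame (1-3) of a 1-based transcript position."""
    return (start_nt - 1) % 3 + 1


def translate_codon(codon: str, ambiguous_codon_policy: str = "X-nonstop") -> Optional[str]:
    """Translate one codon; stops give ``'*'``.

    Codons containing ``N`` translate to ``'X'`` under the default
    ``X-nonstop`` policy; under ``break`` they return ``None`` so the caller
    can terminate the current region.
    """
    if codon in STOP_CODONS:
        return "*"
    aa = CODON_TO_AA.get(codon)
    if aa is not None:
        return aa
    if ambiguous_codon_policy == "X-nonstop":
        return "X"
    if ambiguous_codon_policy == "break":
        return None
    raise ValueError(f"unknown ambiguous_codon_policy {ambiguous_codon_policy!r}")


def translate_region(sequence: str, start_nt: int, end_nt: int,
                     ambiguous_codon_policy: str = "X-nonstop") -> str:
    """Translate a codon-aligned region of a transcript (may contain ``*``)."""
    if (end_nt - start_nt + 1) % 3:
        raise ValueError(f"region {start_nt}-{end_nt} is not codon-aligned")
    out = []
    for p in range(start_nt - 1, end_nt, 3):
        aa = translate_codon(sequence[p:p + 3], ambiguous_codon_policy)
        out.append("X" if aa is None else aa)
    return "".join(out)


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence plus the annotation the pipeline needs.

    ``location`` is the chromosome-or-organelle label of the source locus
    (e.g. ``Chr0``-``Chr8``, ``chloroplast``, ``mitochondrion``).
    ``reforf_span`` is the 1-based inclusive coding span of an mRNA,
    excluding the terminal stop codon (a span ending in a stop is trimmed
    by :func:`reforf_record`).
    """

    transcript_id: str
    rna_type: str
    location: str
    sequence: str
    reforf_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.rna_type not in RNA_TYPES:
            raise ValueError(f"{self.transcript_id}: unknown RNA type {self.rna_type!r}")
        if not self.sequence:
            raise SequenceError(f"{self.transcript_id}: empty sequence")
        m = _VALID_NT.match(self.sequence)
        if m is None or m.end() != len(self.sequence):
            pos = m.end() if m else 0
            raise SequenceError(
                f"{self.transcript_id}: invalid nucleotide "
                f"{self.sequence[pos]!r} at position {pos + 1}")
        if self.reforf_span is not None:
            s, e = self.reforf_span
            if not (1 <= s <= e <= len(self.sequence)):
                raise ValueError(f"{self.transcript_id}: refORF span {s}-{e} outside transcript")
            if (e - s + 1) % 3:
                raise ValueError(f"{self.transcript_id}: refORF span length not divisible by 3")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """One stop-free reading-frame region (refORF or altORF)."""

    transcript_id: str
    frame: str                  # "1F", "2F" or "3F"
    start_nt: int               # 1-based, inclusive
    end_nt: int
    aa_seq: str
    orf_class: str = "altORF"   # or "refORF"

    def __post_init__(self) -> None:
        if self.frame not in FRAME_LABELS:
            raise ValueError(f"bad frame label {self.frame!r}")
        if self.end_nt - self.start_nt + 1 != 3 * len(self.aa_seq):
            raise ValueError("ORF span is not three nucleotides per residue")
        if frame_of_position(self.start_nt) != self.frame_number:
            raise ValueError(f"start {self.start_nt} is not in frame {self.frame}")
        if "*" in self.aa_seq:
            raise ValueError("ORF translation contains a stop symbol")
        if self.orf_class not in ("refORF", "altORF"):
            raise ValueError(f"bad orf_class {self.orf_class!r}")

    @property
    def frame_number(self) -> int:
        return int(self.frame[0])

    @property
    def length_nt(self) -> int:
        return self.end_nt - self.start_nt + 1

    @property
    def identifier(self) -> str:
        return make_identifier(self)


@dataclass(frozen=True)
class ExtractionParams:
    """Scan settings.

    ``min_len_nt`` is applied to the codon-complete nucleotide length, so
    the default of 60 nt corresponds to translations of 20 aa or longer.
    """

    min_len_nt: int = 60
    ambiguous_codon_policy: str = "X-nonstop"

    def __post_init__(self) -> None:
        if self.effective_min_len_nt < 3:
            raise ValueError("min_len_nt must cover at least one codon")
        if self.ambiguous_codon_policy not in ("X-nonstop", "break"):
            raise ValueError(f"bad ambiguous_codon_policy {self.ambiguous_codon_policy!r}")

    @property
    def effective_min_len_nt(self) -> int:
        return self.min_len_nt - self.min_len_nt % 3


def scan_altorfs(transcript: TranscriptRecord,
                 params: ExtractionParams = ExtractionParams()) -> list[OrfRecord]:
    """Maximal stop-free complete-codon runs in the three forward frames.

    Trailing incomplete codons are ignored; each reported region is maximal
    (extending by one codon in either direction leaves the transcript or
    meets a stop codon) and at least ``params.min_len_nt`` long.
    """
    seq = transcript.sequence
    min_nt = params.effective_min_len_nt
    out: list[OrfRecord] = []
    for off in range(3):
        n_codons = (len(seq) - off) // 3
        run_start: Optional[int] = None  # codon index of current run
        aa: list[str] = []

        def flush(end_codon: int) -> None:
            nonlocal run_start, aa
            if run_start is not None and 3 * len(aa) >= min_nt:
                start_nt = off + 3 * run_start + 1
                out.append(OrfRecord(
                    transcript_id=transcript.transcript_id,
                    frame=FRAME_LABELS[off],
                    start_nt=start_nt,
                    end_nt=start_nt + 3 * len(aa) - 1,
                    aa_seq="".join(aa)))
            run_start, aa = None, []

        for ci in range(n_codons):
            p = off + 3 * ci
            sym = translate_codon(seq[p:p + 3], params.ambiguous_codon_policy)
            if sym == "*" or sym is None:
                flush(ci)
            else:
                if run_start is None:
                    run_start = ci
                aa.append(sym)
        flush(n_codons)
    out.sort(key=lambda o: (o.frame, o.start_nt))
    return out


def reforf_record(transcript: TranscriptRecord) -> OrfRecord:
    """The refORF of an mRNA as an :class:`OrfRecord`.

    A span whose final codon is a stop is trimmed by one codon; internal
    stops are rejected.
    """
    if transcript.reforf_span is None:
        raise ValueError(f"{transcript.transcript_id}: no refORF span annotated")
    s, e = transcript.reforf_span
    aa = translate_region(transcript.sequence, s, e)
    if aa.endswith("*"):
        aa, e = aa[:-1], e - 3
    if "*" in aa:
        raise ValueError(f"{transcript.transcript_id}: refORF span contains an internal stop")
    return OrfRecord(transcript.transcript_id, FRAME_LABELS[(s - 1) % 3], s, e, aa,
                     orf_class="refORF")


def make_identifier(orf: OrfRecord) -> str:
    """``locus|frame|start|end|length`` identifier for an extracted region."""
    return f"{orf.transcript_id}|{orf.frame}|{orf.start_nt}|{orf.end_nt}|{orf.length_nt}"


def parse_identifier(text: str) -> tuple[str, str, int, int, int]:
    """Invert :func:`make_identifier` (locus ids may themselves contain '|')."""
    locus, frame, start, end, length = text.rsplit("|", 4)
    return locus, frame, int(start), int(end), int(length)


def drop_refprot_identical(altprots: Iterable[OrfRecord],
                           refprots: Iterable[str]) -> list[OrfRecord]:
    """Remove altProts whose full translation equals a reference protein.

    Equality is exact and case-insensitive over the whole sequence; proper
    substrings of refProts are retained (peptide-level ambiguity is resolved
    later by attribution).
    """
    ref = {p.upper() for p in refprots}
    return [o for o in altprots if o.aa_seq.upper() not in ref]


def extract_transcriptome(transcripts: Sequence[TranscriptRecord],
                          params: ExtractionParams = ExtractionParams(),
                          refprots: Optional[Iterable[str]] = None,
                          ) -> tuple[list[OrfRecord], list[OrfRecord], dict[str, int]]:
    """Scan a transcript set; returns (altORFs, refORFs, counts).

    ``counts`` reports the altORF total both before and after removal of
    translations identical to reference proteins.
    """
    alt: list[OrfRecord] = []
    ref: list[OrfRecord] = []
    for tr in transcripts:
        alt.extend(scan_altorfs(tr, params))
        if tr.reforf_span is not None:
            ref.append(reforf_record(tr))
    counts = {"altorfs_total": len(alt)}
    if refprots is not None:
        alt = drop_refprot_identical(alt, refprots)
    counts["altorfs_nonidentical"] = len(alt)
    return alt, ref, counts
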