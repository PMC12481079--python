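"""Mosaic-protein candidate detection.

A mosaic protein is the product of two or more PRF events on one transcript.
The tractable category is the *short round trip*: a pair of shifts whose
values sum to 0 mod 3, leaving the donor frame and returning to it a short
distance downstream, so that total protein length is conserved for net-zero
value pairs.  Compatibility of an ordered event pair is assessed from frame
geometry (a second event cannot continue a first one if both start from the
same frame), from stop codons in the bridging frame between the sites, and
from the inter-site distance.  Compatible pairs anchored on an annotated
refORF are assembled into a full-length mosaic protein and compared with the
conventional translation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .chimeras import PrfEvent
from .orfs import OrfRecord, STOP_CODONS, translate_region


class AssemblyError(ValueError):
    """Raised when mosaic assembly runs through a stop codon."""


@dataclass(frozen=True)
class Compatibility:
    round_trip: bool
    same_start_frame_conflict: bool
    bridge_stop_count: int
    inter_site_nt: int


@dataclass(frozen=True)
class MosaicAssembly:
    mosaic_aa: str
    annotated_aa: str
    diff_start_aa: Optional[int]    # 1-based on the mosaic, None if identical
    diff_len_aa: int


def group_multi_prf(peptide_events: Mapping[str, Iterable[PrfEvent]],
                    ) -> dict[str, list[PrfEvent]]:
    """Transcripts carrying >=2 distinct validated PRF sites.

    ``peptide_events`` maps each chimeric-specific peptide to the events its
    matching models describe.  Sites supported by the same peptide cannot be
    told apart and are merged into one site cluster; a transcript qualifies
    when it retains at least two clusters.  Returns one representative event
    per distinct site, ordered by site, for each qualifying transcript.
    """
    by_transcript: dict[str, dict[int, PrfEvent]] = {}
    site_peptides: dict[str, dict[int, set[str]]] = {}
    for pep, events in peptide_events.items():
        for ev in events:
            by_transcript.setdefault(ev.transcript_id, {}).setdefault(ev.site_nt, ev)
            site_peptides.setdefault(ev.transcript_id, {}).setdefault(
                ev.site_nt, set()).add(pep)

    out: dict[str, list[PrfEvent]] = {}
    for tid, sites in by_transcript.items():
        ordered = sorted(sites)
        # union-find over sites linked by a shared supporting peptide
        parent = {s: s for s in ordered}

        def find(s: int) -> int:
            while parent[s] != s:
                parent[s] = parent[parent[s]]
                s = parent[s]
            return s

        for i, s1 in enumerate(ordered):
            for s2 in ordered[i + 1:]:
                if site_peptides[tid][s1] & site_peptides[tid][s2]:
                    parent[find(s2)] = find(s1)
        clusters = {find(s) for s in ordered}
        if len(clusters) >= 2:
            out[tid] = [sites[s] for s in ordered]
    return out


def assess_compatibility(sequence: str, first: PrfEvent, second: PrfEvent,
                         ) -> Compatibility:
    """Compatibility of an ordered event pair on one transcript.

    The pair is a round trip iff the second event mirrors the first (donor
    frame of one equals acceptor frame of the other).  ``bridge_stop_count``
    counts stop codons in the bridging frame (the first event's acceptor
    frame) over complete codons lying between the two sites; each such stop
    would interrupt the mosaic bridge.
    """
    if first.transcript_id != second.transcript_id:
        raise ValueError("events on different transcripts")
    if second.site_nt <= first.site_nt:
        raise ValueError("events must be ordered by strictly increasing site")

    bridge_off = first.acceptor_frame - 1
    # first bridging-frame codon start at or after site 1
    p = first.site_nt + (bridge_off - (first.site_nt - 1)) % 3
    stops = 0
    while p + 2 <= second.site_nt - 1:
        if sequence[p - 1:p + 2] in STOP_CODONS:
            stops += 1
        p += 3

    return Compatibility(
        round_trip=(first.donor_frame == second.acceptor_frame
                    and first.acceptor_frame == second.donor_frame),
        same_start_frame_conflict=first.donor_frame == second.donor_frame,
        bridge_stop_count=stops,
        inter_site_nt=second.site_nt - first.site_nt)


def _translate_or_fail(sequence: str, start: int, end: int, what: str) -> str:
    aa = translate_region(sequence, start, end)
    if "*" in aa:
        pos = start + 3 * aa.index("*")
        raise AssemblyError(f"stop codon at nt {pos} while translating the {what} segment")
    return aa


def diff_segment(mosaic_aa: str, annotated_aa: str) -> tuple[Optional[int], int]:
    """Maximal contiguous differing segment of the mosaic vs the annotated
    protein: 1-based start position on the mosaic and length in aa
    (``(None, 0)`` for identical sequences).  Shared prefix and suffix are
    stripped; everything between them counts as differing."""
    if mosaic_aa == annotated_aa:
        return None, 0
    p = 0
    while p < min(len(mosaic_aa), len(annotated_aa)) and mosaic_aa[p] == annotated_aa[p]:
        p += 1
    s = 0
    while (s < min(len(mosaic_aa), len(annotated_aa)) - p
           and mosaic_aa[-1 - s] == annotated_aa[-1 - s]):
        s += 1
    return p + 1, len(mosaic_aa) - p - s


def assemble_mosaic(sequence: str, reforf: OrfRecord,
                    first: PrfEvent, second: PrfEvent) -> MosaicAssembly:
    """Assemble the mosaic protein of a round-trip pair anchored on a refORF.

    Translation runs in the refORF frame from its start to the first shift,
    continues in the bridging (acceptor) frame up to the second shift, and
    returns to the refORF frame from the second site to the refORF end.  A
    stop codon anywhere along this path aborts assembly with its position.
    Net-zero value pairs conserve the annotated protein length.
    """
    if first.donor_frame != reforf.frame_number:
        raise ValueError("first event must shift out of the refORF frame")
    if second.acceptor_frame != reforf.frame_number:
        raise ValueError("second event must return to the refORF frame")
    b1 = first.donor_boundary_nt
    b2 = second.donor_boundary_nt
    if not (reforf.start_nt <= b1 < second.site_nt <= reforf.end_nt - 2):
        raise ValueError("shift sites do not lie within the refORF")

    seg1 = _translate_or_fail(sequence, reforf.start_nt, b1, "upstream refORF")
    seg2 = _translate_or_fail(sequence, first.site_nt, b2, "bridging-frame")
    seg3 = _translate_or_fail(sequence, second.site_nt, reforf.end_nt, "downstream refORF")
    mosaic = seg1 + seg2 + seg3

    annotated = reforf.aa_seq
    start, length = diff_segment(mosaic, annotated)
    return MosaicAssembly(mosaic, annotated, start, length)


def coverage_gap(peptide_spans: Sequence[tuple[int, int]],
                 protein_len: Optional[int] = None) -> int:
    """Residues between peptide footprints covered by no peptide.

    ``peptide_spans`` are 1-based inclusive (start, end) positions of the
    supporting (junction-spanning) peptides on the mosaic protein.  The gap
    is counted between the outermost footprint bounds; overlapping or
    adjacent peptides give 0.
    """
    if len(peptide_spans) < 2:
        raise ValueError("need at least two peptide footprints")
    lo = min(s for s, _ in peptide_spans)
    hi = max(e for _, e in peptide_spans)
    if protein_len is not None and hi > protein_len:
        raise ValueError("peptide footprint extends beyond the protein")
    covered = set()
    for s, e in peptide_spans:
        covered.update(range(s, e + 1))
    return sum(1 for pos in range(lo, hi + 1) if pos not in covered)
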