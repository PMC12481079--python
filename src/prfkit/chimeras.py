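"""Enumeration of programmed ribosomal frameshift (PRF) events and
junction-spanning chimeric protein models.

A PRF event moves the ribosome by ``value`` nucleotides (negative =
backward slippage re-reading ``|value|`` nt, positive = forward slippage
skipping ``value`` nt) from a donor ORF into an acceptor ORF in another
frame.  ``site_nt`` is the first nucleotide of the first post-shift codon,
so the last donor codon ends at ``site_nt - 1 - value``.  Within overlapping
ORFs only values in {-2, -1, +1, +2} are considered; adjacent ORFs separated
by a 1-10 nt gap can additionally be bridged by a forward shift equal to the
gap length.

The chimeric model of an event is the translation window around the
junction: up to ``window_up_aa`` donor residues before the shift joined to
up to ``window_down_aa`` acceptor residues from ``site_nt``, capped by the
ORF boundaries (40 aa total at the defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .orfs import OrfRecord, STOP_CODONS, translate_codon

OVERLAP_VALUES = (-2, -1, 1, 2)

PairRelation = str  # "overlap" or "gap:<g>"


def shifted_frame(frame: int, value: int) -> int:
    """Frame reached from ``frame`` by a shift of ``value`` nucleotides."""
    return (frame - 1 + value) % 3 + 1


@dataclass(frozen=True)
class PrfEvent:
    """One frameshift between a donor and an acceptor ORF."""

    transcript_id: str
    donor: OrfRecord
    acceptor: OrfRecord
    site_nt: int
    value: int

    def __post_init__(self) -> None:
        if self.donor.transcript_id != self.transcript_id or \
           self.acceptor.transcript_id != self.transcript_id:
            raise ValueError("donor/acceptor ORFs are not on the event transcript")
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor ORFs are identical")
        if shifted_frame(self.donor_frame, self.value) != self.acceptor_frame:
            raise ValueError(
                f"value {self.value:+d} does not map frame {self.donor_frame} "
                f"to frame {self.acceptor_frame}")
        if not (self.acceptor.start_nt <= self.site_nt <= self.acceptor.end_nt - 2):
            raise ValueError(f"site {self.site_nt} outside acceptor codon range")
        b = self.donor_boundary_nt
        if (b - self.donor.start_nt + 1) % 3:
            raise ValueError("pre-shift boundary is not a donor codon boundary")
        if not (self.donor.start_nt + 2 <= b <= self.donor.end_nt):
            raise ValueError("donor has no complete codon before the shift")

    @property
    def donor_frame(self) -> int:
        return self.donor.frame_number

    @property
    def acceptor_frame(self) -> int:
        return self.acceptor.frame_number

    @property
    def donor_boundary_nt(self) -> int:
        """Last nucleotide of the last codon translated before the shift."""
        return self.site_nt - 1 - self.value

    @property
    def prf_type(self) -> str:
        return f"{self.donor_frame}->{self.acceptor_frame}"

    @property
    def prf_subtype(self) -> str:
        return classify_prf(self)[2]

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.transcript_id, self.site_nt, self.value)


def classify_prf(event: PrfEvent) -> tuple[int, str, str]:
    """(value, type, subtype) of an event.

    Subtypes: ``r->a`` (refORF donates), ``a->r`` (refORF accepts),
    ``a1->a2`` / ``a2->a1`` between two altORFs, where altORF1 is the one
    starting further upstream on the transcript.
    """
    d, a = event.donor, event.acceptor
    if d.orf_class == "refORF" and a.orf_class == "refORF":
        raise ValueError("a transcript has a single refORF; refORF->refORF is invalid")
    if d.orf_class == "refORF":
        subtype = "r->a"
    elif a.orf_class == "refORF":
        subtype = "a->r"
    else:
        subtype = "a1->a2" if d.start_nt <= a.start_nt else "a2->a1"
    return event.value, event.prf_type, subtype


def find_orf_pairs(orfs: Sequence[OrfRecord], max_gap_nt: int = 10,
                   ) -> list[tuple[OrfRecord, OrfRecord, PairRelation]]:
    """Donor/acceptor candidate pairs among ORFs; never across transcripts.

    Different-frame ORFs overlapping by >=3 nt yield an ``overlap`` pair in
    both orders (either ORF may donate); ORFs separated by a gap of
    1..``max_gap_nt`` nt yield a ``gap:<g>`` pair with the upstream ORF as
    donor, in any frame combination.
    """
    pairs = []
    for d in orfs:
        for a in orfs:
            if d == a or d.transcript_id != a.transcript_id:
                continue
            overlap = min(d.end_nt, a.end_nt) - max(d.start_nt, a.start_nt) + 1
            if overlap >= 3 and d.frame != a.frame:
                pairs.append((d, a, "overlap"))
            else:
                gap = a.start_nt - d.end_nt - 1
                if 1 <= gap <= max_gap_nt:
                    pairs.append((d, a, f"gap:{gap}"))
    return pairs


def enumerate_prf_events(donor: OrfRecord, acceptor: OrfRecord,
                         relation: PairRelation,
                         values: Sequence[int] = OVERLAP_VALUES) -> list[PrfEvent]:
    """All PRF events admitted by one ORF pair.

    Overlap pairs: for each value consistent with the frame change (exactly
    one negative and one positive of ``values`` at the defaults), an event at
    every donor codon boundary leaving >=1 complete donor codon before the
    shift and >=1 complete acceptor codon at/after the site.  Gap pairs:
    a single forward event of value ``g`` at the donor's final boundary.
    """
    tid = donor.transcript_id
    events: list[PrfEvent] = []
    if relation == "overlap":
        admissible = [v for v in values
                      if shifted_frame(donor.frame_number, v) == acceptor.frame_number]
        n_codons = len(donor.aa_seq)
        for v in admissible:
            for k in range(1, n_codons + 1):
                site = donor.start_nt + 3 * k + v
                if acceptor.start_nt <= site <= acceptor.end_nt - 2:
                    events.append(PrfEvent(tid, donor, acceptor, site, v))
    elif relation.startswith("gap:"):
        g = int(relation.split(":", 1)[1])
        site = donor.end_nt + 1 + g
        if site == acceptor.start_nt and site <= acceptor.end_nt - 2:
            events.append(PrfEvent(tid, donor, acceptor, site, g))
    else:
        raise ValueError(f"unknown pair relation {relation!r}")
    return events


@dataclass(frozen=True)
class ModelingParams:
    window_up_aa: int = 20
    window_down_aa: int = 20
    min_model_aa: int = 8
    max_gap_nt: int = 10
    stop_policy: str = "trim"   # or "drop"

    def __post_init__(self) -> None:
        if self.window_up_aa < 1 or self.window_down_aa < 1:
            raise ValueError("translation windows must be at least one codon")
        if self.min_model_aa < 2:
            raise ValueError("a model needs at least one residue per side")
        if self.stop_policy not in ("trim", "drop"):
            raise ValueError(f"bad stop_policy {self.stop_policy!r}")


@dataclass(frozen=True)
class ChimericModel:
    """Junction-spanning translation product of one PRF event."""

    event: PrfEvent
    up_aa: str
    down_aa: str
    provenances: frozenset[str] = frozenset()

    @property
    def aa_seq(self) -> str:
        return self.up_aa + self.down_aa

    @property
    def junction_index(self) -> int:
        """Number of residues translated before the shift."""
        return len(self.up_aa)

    @property
    def model_id(self) -> str:
        e = self.event
        return f"{e.transcript_id}|{e.site_nt}|{e.value:+d}|{e.prf_type}"


def build_chimeric_model(event: PrfEvent, params: ModelingParams = ModelingParams(),
                         sequence: Optional[str] = None,
                         provenances: Iterable[str] = (),
                         ) -> Optional[ChimericModel]:
    """Translate the junction window of an event, or return ``None``.

    ``up_aa`` is the last ``window_up_aa`` (or fewer) donor codons before the
    shift; ``down_aa`` the next ``window_down_aa`` acceptor codons from
    ``site_nt``, truncated at the acceptor end.  A downstream stop codon
    (possible only when translating from raw ``sequence`` past designed ORF
    content) trims the model under ``stop_policy='trim'`` or discards it
    under ``'drop'``.  Models shorter than ``min_model_aa`` or lacking a
    residue on either side are discarded.
    """
    d, a = event.donor, event.acceptor
    k = (event.donor_boundary_nt - d.start_nt + 1) // 3
    up = d.aa_seq[max(0, k - params.window_up_aa):k]

    n_down = min(params.window_down_aa, (a.end_nt - event.site_nt + 1) // 3)
    if sequence is None:
        j0 = (event.site_nt - a.start_nt) // 3
        down = a.aa_seq[j0:j0 + n_down]
    else:
        out = []
        for p in range(event.site_nt - 1, event.site_nt - 1 + 3 * n_down, 3):
            sym = translate_codon(sequence[p:p + 3])
            if sym == "*":
                if params.stop_policy == "drop":
                    return None
                break
            out.append(sym)
        down = "".join(out)

    if not up or not down or len(up) + len(down) < params.min_model_aa:
        return None
    return ChimericModel(event, up, down, frozenset(provenances))


@dataclass
class DedupResult:
    """Non-redundant chimeric models plus identical-sequence grouping."""

    models: list[ChimericModel]
    sequence_groups: dict[str, list[str]]   # aa_seq -> sorted model_ids


def deduplicate_models(models: Iterable[ChimericModel]) -> DedupResult:
    """Collapse redundant chimeric models.

    Models describing the same event (same transcript, site and value) are
    kept once with their provenance flags merged; when an event was modeled
    both with its refORF and with the enclosing same-frame altORF as donor,
    the refORF-involving model is preferred.  Models with identical amino
    acid sequences are additionally grouped, retaining all source events.
    """
    by_key: dict[tuple, ChimericModel] = {}
    for m in models:
        key = m.event.key
        old = by_key.get(key)
        if old is None:
            by_key[key] = m
            continue
        prov = old.provenances | m.provenances
        keep = old
        old_ref = "refORF" in (old.event.donor.orf_class, old.event.acceptor.orf_class)
        new_ref = "refORF" in (m.event.donor.orf_class, m.event.acceptor.orf_class)
        if new_ref and not old_ref:
            keep = m
        by_key[key] = replace(keep, provenances=prov)

    unique = [by_key[k] for k in sorted(by_key)]
    groups: dict[str, list[str]] = {}
    for m in unique:
        groups.setdefault(m.aa_seq, []).append(m.model_id)
    for ids in groups.values():
        ids.sort()
    return DedupResult(unique, groups)


def model_transcript(orfs: Sequence[OrfRecord],
                     params: ModelingParams = ModelingParams(),
                     sequence: Optional[str] = None,
                     basis_ids: Optional[set[str]] = None,
                     provenance_of: Optional[dict[str, frozenset[str]]] = None,
                     ) -> list[ChimericModel]:
    """Enumerate and build all chimeric models for one transcript's ORFs.

    When ``basis_ids`` is given, only pairs in which at least one altORF
    belongs to the basis (conserved and/or MS-validated altProts) are
    modeled, mirroring how modeling is restricted to avoid an astronomic
    search space; the refORF itself needs no basis membership.
    """
    out: list[ChimericModel] = []
    for d, a, rel in find_orf_pairs(orfs, params.max_gap_nt):
        if basis_ids is not None:
            members = [o for o in (d, a) if o.orf_class == "altORF"]
            if not members or not any(o.identifier in basis_ids for o in members):
                continue
        for ev in enumerate_prf_events(d, a, rel):
            prov: frozenset[str] = frozenset()
            if provenance_of is not None:
                for o in (d, a):
                    prov |= provenance_of.get(o.identifier, frozenset())
            m = build_chimeric_model(ev, params, sequence, prov)
            if m is not None:
                out.append(m)
    return out
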