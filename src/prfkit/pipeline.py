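"""End-to-end discovery: extraction -> modeling -> attribution -> mosaics.

Given transcripts, a reference proteome, contaminants, a conservation hit
table and identified-peptide lists, the pipeline extracts altORFs, selects
the modeling basis (conserved and/or MS-validated altProts), enumerates
frameshift events and chimeric models over the basis, attributes peptides
against the full class-labelled database, groups validated sites into
multi-PRF transcripts, assembles round-trip mosaic candidates, and derives
the PRF-value category statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .attribution import AttributionResult, attribute_peptides, build_search_database
from .chimeras import (ChimericModel, DedupResult, ModelingParams, PrfEvent,
                       deduplicate_models, model_transcript)
from .conservation import HitRecord, classify_conserved, conserved_ids
from .mosaic import (assemble_mosaic, assess_compatibility, coverage_gap,
                     group_multi_prf)
from .orfs import ExtractionParams, OrfRecord, TranscriptRecord, extract_transcriptome
from .stats import TestResult, expected_from_models, gof_test


def is_gap_event(event: PrfEvent) -> bool:
    """True for events bridging non-overlapping (adjacent) ORFs."""
    return event.donor.end_nt < event.acceptor.start_nt


@dataclass
class MosaicCandidate:
    transcript_id: str
    sites: tuple[int, int]
    values: tuple[int, int]
    round_trip: bool
    same_start_frame_conflict: bool
    bridge_stop_count: int
    inter_site_nt: int
    mosaic_aa: Optional[str] = None
    annotated_aa: Optional[str] = None
    diff_start_aa: Optional[int] = None
    diff_len_aa: int = 0
    coverage_gap_aa: Optional[int] = None


@dataclass
class DiscoveryResult:
    counts: dict
    altorfs: list[OrfRecord]
    reforfs: list[OrfRecord]
    conserved: set[str]
    ms_validated: set[str]
    models: DedupResult
    attributions: dict[str, AttributionResult]
    peptide_events: dict[str, list[PrfEvent]]
    multi_prf: dict[str, list[PrfEvent]]
    mosaic_candidates: list[MosaicCandidate]
    observed_values: dict[str, int]
    model_value_counts: dict[str, int]
    value_gof: Optional[TestResult]
    recovery: Optional[dict] = None


def _ms_validate_altprots(peptides: Sequence[str], altorfs: Sequence[OrfRecord],
                          refprots: Iterable[str], contaminants: Iterable[str],
                          ) -> set[str]:
    """First-pass altProt validation: altProts containing an identified
    peptide that no reference or contaminant protein explains."""
    ref_space = [s.upper() for s in refprots] + [s.upper() for s in contaminants]
    validated: set[str] = set()
    for pep in set(peptides):
        if any(pep in s for s in ref_space):
            continue
        for o in altorfs:
            if pep in o.aa_seq:
                validated.add(o.identifier)
    return validated


def run_discovery(transcripts: Sequence[TranscriptRecord],
                  refprots: dict[str, str],
                  contaminants: dict[str, str],
                  peptides: pd.DataFrame,
                  hits: Sequence[HitRecord] | pd.DataFrame,
                  ground_truth: Optional[dict] = None,
                  extraction: ExtractionParams = ExtractionParams(),
                  modeling: ModelingParams = ModelingParams(),
                  require_junction_flank: int = 1,
                  seed: int = 0) -> DiscoveryResult:
    """Run the whole discovery pipeline on in-memory inputs.

    ``hits`` may be HitRecord rows or a DataFrame in the package's hit-table
    layout.  With ``ground_truth`` (from the synthetic generator) the result
    additionally reports planted-event recovery and the false
    chimeric-specific call rate.
    """
    if isinstance(hits, pd.DataFrame):
        hits = [HitRecord(**{**row, "align_len": int(row["align_len"])})
                for row in hits.to_dict("records")]

    seqs = {t.transcript_id: t.sequence for t in transcripts}
    altorfs, reforfs, counts = extract_transcriptome(
        transcripts, extraction, refprots.values())

    alt_ids = {o.identifier for o in altorfs}
    conserved = conserved_ids(classify_conserved(hits)) & alt_ids
    peptide_list = sorted(set(peptides["peptide"]))
    ms_validated = _ms_validate_altprots(
        peptide_list, altorfs, refprots.values(), contaminants.values())
    basis = conserved | ms_validated
    provenance_of = {i: frozenset(
        (["conserved"] if i in conserved else []) +
        (["ms"] if i in ms_validated else [])) for i in basis}

    reforf_by_tid = {o.transcript_id: o for o in reforfs}
    raw_models: list[ChimericModel] = []
    for tid in sorted(seqs):
        orfs = [o for o in altorfs if o.transcript_id == tid]
        if tid in reforf_by_tid:
            orfs.append(reforf_by_tid[tid])
        if len(orfs) > 1:
            raw_models.extend(model_transcript(
                orfs, modeling, seqs[tid], basis, provenance_of))
    dedup = deduplicate_models(raw_models)
    counts["chimeric_models_raw"] = len(raw_models)
    counts["chimeric_models_nonredundant"] = len(dedup.models)
    counts["conserved_altprots"] = len(conserved)
    counts["ms_validated_altprots"] = len(ms_validated)

    alt_by_id = {o.identifier: o for o in altorfs}
    db = build_search_database(
        dedup.models,
        altprots={i: alt_by_id[i].aa_seq for i in sorted(basis) if i in alt_by_id},
        refprots=refprots, contaminants=contaminants)
    attributions = attribute_peptides(peptide_list, db, require_junction_flank)

    model_by_id = {m.model_id: m for m in dedup.models}
    peptide_events: dict[str, list[PrfEvent]] = {}
    for pep, res in attributions.items():
        if res.verdict != "chimeric_specific":
            continue
        events = [model_by_id[m.entry_id].event
                  for m in res.matches["chimeric"] if m.junction_spanning]
        peptide_events[pep] = events
    counts["chimeric_specific_peptides"] = len(peptide_events)

    multi = group_multi_prf(peptide_events)
    mosaic_candidates: list[MosaicCandidate] = []
    for tid in sorted(multi):
        events = multi[tid]
        seq = seqs[tid]
        for i in range(len(events)):
            for jj in range(i + 1, len(events)):
                e1, e2 = events[i], events[jj]
                comp = assess_compatibility(seq, e1, e2)
                cand = MosaicCandidate(
                    tid, (e1.site_nt, e2.site_nt), (e1.value, e2.value),
                    comp.round_trip, comp.same_start_frame_conflict,
                    comp.bridge_stop_count, comp.inter_site_nt)
                reforf = reforf_by_tid.get(tid)
                if (comp.round_trip and comp.bridge_stop_count == 0
                        and reforf is not None
                        and e1.donor_frame == reforf.frame_number):
                    asm = assemble_mosaic(seq, reforf, e1, e2)
                    cand.mosaic_aa = asm.mosaic_aa
                    cand.annotated_aa = asm.annotated_aa
                    cand.diff_start_aa = asm.diff_start_aa
                    cand.diff_len_aa = asm.diff_len_aa
                    spans = []
                    for pep, evs in peptide_events.items():
                        if any(ev.key in (e1.key, e2.key) for ev in evs):
                            off = asm.mosaic_aa.find(pep)
                            if off != -1:
                                spans.append((off + 1, off + len(pep)))
                    if len(spans) >= 2:
                        cand.coverage_gap_aa = coverage_gap(spans)
                mosaic_candidates.append(cand)
    counts["multi_prf_transcripts"] = len(multi)
    counts["round_trip_candidates"] = sum(
        1 for c in mosaic_candidates if c.mosaic_aa is not None)

    # ---- PRF value statistics against the model distribution --------------
    validated_events = {ev.key: ev for evs in peptide_events.values() for ev in evs}
    # one count per peptide and PRF value (a peptide may support several
    # neighbouring models of the same value; that is still one observation)
    observed: dict[str, int] = {}
    for evs in peptide_events.values():
        cats = {"other" if is_gap_event(ev) else f"{ev.value:+d}" for ev in evs}
        for cat in cats:
            observed[cat] = observed.get(cat, 0) + 1
    model_counts: dict[str, int] = {}
    for m in dedup.models:
        cat = "other" if is_gap_event(m.event) else f"{m.event.value:+d}"
        model_counts[cat] = model_counts.get(cat, 0) + 1

    value_gof = None
    cats = sorted(set(observed) - {"other"})
    if len(cats) >= 2 and all(model_counts.get(c, 0) > 0 for c in cats):
        expected = expected_from_models(
            {c: model_counts[c] for c in cats},
            sum(observed[c] for c in cats))
        value_gof = gof_test([observed[c] for c in cats],
                             [expected[c] for c in cats], seed=seed)

    recovery = None
    if ground_truth is not None:
        planted = {(e["transcript_id"], e["site_nt"], e["value"])
                   for e in ground_truth.get("events", [])}
        gt_peptides = {p for e in ground_truth.get("events", [])
                       for p in e["peptides"]}
        recovered = planted & set(validated_events)
        false_peps = set(peptide_events) - gt_peptides
        recovery = {
            "planted_events": len(planted),
            "recovered_events": len(recovered),
            "recovery_fraction": len(recovered) / len(planted) if planted else 1.0,
            "false_chimeric_peptides": len(false_peps),
            "false_call_fraction": (len(false_peps) / len(peptide_events)
                                    if peptide_events else 0.0),
        }

    return DiscoveryResult(counts, altorfs, reforfs, conserved, ms_validated,
                           dedup, attributions, peptide_events, multi,
                           mosaic_candidates, observed, model_counts,
                           value_gof, recovery)
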