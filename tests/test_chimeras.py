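"""PRF event enumeration, chimeric model building, classification, dedup."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from prfkit import (ExtractionParams, ModelingParams, OrfRecord,
                    TranscriptRecord, build_chimeric_model, classify_prf,
                    deduplicate_models, enumerate_prf_events, find_orf_pairs,
                    scan_altorfs, shifted_frame)
from prfkit.chimeras import OVERLAP_VALUES, PrfEvent

from conftest import TOY_SEQ


def lattice_orfs(n_codons=40, tid="t"):
    """Three full-length overlapping ORFs on a GCA lattice (stop-free in
    every frame: GCA/CAG/AGC)."""
    seq = "GCA" * n_codons
    tr = TranscriptRecord(tid, "ncRNA", "Chr0", seq)
    orfs = scan_altorfs(tr, ExtractionParams(min_len_nt=9))
    return seq, {o.frame_number: o for o in orfs}


def test_overlap_pairs_both_orders_and_gap_pairs():
    _, by_frame = lattice_orfs()
    pairs = find_orf_pairs(list(by_frame.values()))
    rel = {(d.frame_number, a.frame_number, r) for d, a, r in pairs}
    assert rel == {(f, g, "overlap") for f in (1, 2, 3) for g in (1, 2, 3) if f != g}

    # two same-frame ORFs separated by one stop codon -> gap of 3 nt
    seq = "GCA" * 10 + "TAA" + "GCA" * 10
    tr = TranscriptRecord("t", "ncRNA", "Chr0", seq)
    orfs = [o for o in scan_altorfs(tr, ExtractionParams(9)) if o.frame == "1F"]
    pairs = find_orf_pairs(orfs)
    assert [(d.start_nt, a.start_nt, r) for d, a, r in pairs] == [(1, 34, "gap:3")]


def test_orfs_on_different_transcripts_never_pair():
    _, a = lattice_orfs(tid="t1")
    _, b = lattice_orfs(tid="t2")
    assert find_orf_pairs([a[1], b[2]]) == []


def test_each_frame_pair_admits_one_negative_and_one_positive_value():
    """Exhaustive over ordered frame pairs: the admissible overlap values are
    exactly {v, v-3} or {v, v+3} intersected with [-2, 2]."""
    for f, g in itertools.permutations((1, 2, 3), 2):
        admissible = sorted(v for v in OVERLAP_VALUES if shifted_frame(f, v) == g)
        assert len(admissible) == 2
        neg, pos = admissible
        assert neg < 0 < pos and pos - neg == 3
    # spot checks: 1->2 admits {+1, -2}; 2 with value -2 lands in 3
    assert sorted(v for v in OVERLAP_VALUES if shifted_frame(1, v) == 2) == [-2, 1]
    assert shifted_frame(2, -2) == 3


def test_toy_event_enumeration_contains_site_11():
    tr = TranscriptRecord("T1", "mRNA", "Chr1", TOY_SEQ, (1, 21))
    orfs = scan_altorfs(tr, ExtractionParams(min_len_nt=9))
    f1 = next(o for o in orfs if o.frame == "1F")
    f2 = next(o for o in orfs if o.frame == "2F")
    events = enumerate_prf_events(f1, f2, "overlap")
    assert {(e.site_nt, e.value) for e in events if e.value == 1} \
        == {(5, 1), (8, 1), (11, 1), (14, 1), (17, 1), (20, 1)}
    e = next(e for e in events if (e.site_nt, e.value) == (11, 1))
    assert (e.donor_boundary_nt, e.prf_type) == (9, "1->2")
    # every emitted event satisfies the frame congruence by construction
    for e in events:
        assert shifted_frame(e.donor_frame, e.value) == e.acceptor_frame


def test_gap_event_lands_on_acceptor_start():
    seq = "GCA" * 10 + "TAA" + "GCA" * 10
    tr = TranscriptRecord("t", "ncRNA", "Chr0", seq)
    orfs = [o for o in scan_altorfs(tr, ExtractionParams(9)) if o.frame == "1F"]
    (d, a, rel), = find_orf_pairs(orfs)
    (ev,), = [enumerate_prf_events(d, a, rel)]
    assert (ev.site_nt, ev.value, ev.prf_type) == (34, 3, "1->1")


def test_toy_model_and_length_cap():
    tr = TranscriptRecord("T1", "mRNA", "Chr1", TOY_SEQ, (1, 21))
    orfs = scan_altorfs(tr, ExtractionParams(min_len_nt=9))
    f1 = next(o for o in orfs if o.frame == "1F")
    f2 = next(o for o in orfs if o.frame == "2F")
    ev = PrfEvent("T1", f1, f2, 11, 1)
    m = build_chimeric_model(ev, ModelingParams(min_model_aa=4), TOY_SEQ)
    assert (m.up_aa, m.down_aa, m.aa_seq, m.junction_index) == \
        ("MAA", "RERG", "MAARERG", 3)
    # the default windows cap every model at 40 aa
    seq, by_frame = lattice_orfs(60)
    for d, a, rel in find_orf_pairs(list(by_frame.values())):
        for ev in enumerate_prf_events(d, a, rel):
            m = build_chimeric_model(ev, ModelingParams(), seq)
            if m is not None:
                assert len(m.aa_seq) <= 40 and "*" not in m.aa_seq
                assert m.up_aa and m.down_aa


def test_short_model_is_discarded():
    tr = TranscriptRecord("T1", "mRNA", "Chr1", TOY_SEQ, (1, 21))
    orfs = scan_altorfs(tr, ExtractionParams(min_len_nt=9))
    f1 = next(o for o in orfs if o.frame == "1F")
    f2 = next(o for o in orfs if o.frame == "2F")
    ev = PrfEvent("T1", f1, f2, 11, 1)   # 3 + 4 = 7 aa total
    assert build_chimeric_model(ev, ModelingParams(min_model_aa=8), TOY_SEQ) is None


def test_downstream_stop_policy_trim_vs_drop():
    # acceptor record declared over a designed span whose raw sequence holds
    # a stop two codons after the site: trim shortens, drop discards
    seq = "GCA" * 4 + "GCATAAGCA" + "GCA" * 4
    donor = OrfRecord("t", "2F", 2, 13, "AAAA")
    acceptor = OrfRecord("t", "1F", 1, 27, "A" * 9)   # declared span crosses the stop
    ev = PrfEvent("t", donor, acceptor, 13, -1)
    trimmed = build_chimeric_model(
        ev, ModelingParams(min_model_aa=2, stop_policy="trim"), seq)
    assert trimmed is not None and trimmed.down_aa == "A"   # cut before the stop
    dropped = build_chimeric_model(
        ev, ModelingParams(min_model_aa=2, stop_policy="drop"), seq)
    assert dropped is None


def test_classification_subtypes_and_errors(toy_events):
    ref, f2, e1, e2, _ = toy_events
    assert classify_prf(e1) == (1, "1->2", "r->a")
    assert classify_prf(e2) == (-1, "2->1", "a->r")
    seq, by_frame = lattice_orfs()
    a12 = PrfEvent("t", by_frame[1], by_frame[2], 8, 1)
    assert classify_prf(a12)[2] == "a1->a2"      # frame-1 ORF starts upstream
    a21 = PrfEvent("t", by_frame[2], by_frame[1], 10, -1)
    assert classify_prf(a21)[2] == "a2->a1"
    with pytest.raises(ValueError):
        PrfEvent("t", by_frame[1], by_frame[1], 8, 0)


def test_dedup_merges_provenance_and_groups_identical_sequences():
    seq, by_frame = lattice_orfs()
    ev = PrfEvent("t", by_frame[1], by_frame[2], 8, 1)
    m_cons = build_chimeric_model(ev, ModelingParams(min_model_aa=4), seq,
                                  provenances=("conserved",))
    m_ms = build_chimeric_model(ev, ModelingParams(min_model_aa=4), seq,
                                provenances=("ms",))
    out = deduplicate_models([m_cons, m_ms])
    assert len(out.models) == 1
    assert out.models[0].provenances == {"conserved", "ms"}

    # identical sequences on two transcripts collapse into one group
    seq2, by2 = lattice_orfs(tid="t2")
    ev2 = PrfEvent("t2", by2[1], by2[2], 8, 1)
    m2 = build_chimeric_model(ev2, ModelingParams(min_model_aa=4), seq2)
    out = deduplicate_models([m_cons, m2])
    assert len(out.models) == 2
    (members,) = [v for k, v in out.sequence_groups.items()]
    assert len(members) == 2


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=25, deadline=None)
def test_dedup_idempotent_under_duplication(seed):
    import random
    rng = random.Random(seed)
    seq, by_frame = lattice_orfs()
    models = []
    for _ in range(rng.randint(1, 12)):
        f = rng.choice([1, 2, 3])
        g = rng.choice([x for x in (1, 2, 3) if x != f])
        v = rng.choice([v for v in OVERLAP_VALUES if shifted_frame(f, v) == g])
        events = enumerate_prf_events(by_frame[f], by_frame[g], "overlap", (v,))
        if events:
            ev = rng.choice(events)
            m = build_chimeric_model(ev, ModelingParams(min_model_aa=4), seq)
            if m:
                models.append(m)
    once = deduplicate_models(models)
    twice = deduplicate_models(models + models)
    assert len(once.models) == len(twice.models)
    assert once.sequence_groups == twice.sequence_groups
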