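"""Six-frame index and alternative-source scanning vs a brute-force oracle."""

import random

import pytest

from prfkit import (find_chimeric_sources, find_nonchimeric_sources,
                    sixframe_translate)
from prfkit.chimeras import OVERLAP_VALUES

from conftest import TOY_SEQ, oracle_translate_frame


def revcomp(seq):
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def oracle_nonchimeric(peptide, db, forward_only=False):
    """Every (locus, strand, frame, offset) producing the whole peptide."""
    out = set()
    for locus, seq in db.items():
        strands = [("+", seq)] + ([] if forward_only else [("-", revcomp(seq))])
        for strand, s in strands:
            for off in range(3):
                aa = oracle_translate_frame(s, off)
                for i in range(len(aa) - len(peptide) + 1):
                    if aa[i:i + len(peptide)] == peptide:
                        out.add((locus, strand, off, i))
    return out


def oracle_chimeric(peptide, db, min_flank=2, forward_only=False):
    """Every (locus, strand, split, shift, prefix-frame offset, prefix aa
    offset) tuple admitting prefix-then-shift-then-suffix."""
    out = set()
    for locus, seq in db.items():
        strands = [("+", seq)] + ([] if forward_only else [("-", revcomp(seq))])
        for strand, s in strands:
            frames = {off: oracle_translate_frame(s, off) for off in range(3)}
            for split in range(min_flank, len(peptide) - min_flank + 1):
                pre, suf = peptide[:split], peptide[split:]
                for off in range(3):
                    aa = frames[off]
                    for i in range(len(aa) - split + 1):
                        if aa[i:i + split] != pre:
                            continue
                        end = off + 3 * (i + split)       # 1-based prefix end
                        for v in OVERLAP_VALUES:
                            site = end + 1 + v
                            if site < 1:
                                continue
                            off2 = (site - 1) % 3
                            j, rem = divmod(site - 1 - off2, 3)
                            assert rem == 0
                            aa2 = frames[off2]
                            if aa2[j:j + len(suf)] == suf:
                                out.add((locus, strand, split, v, off, i))
    return out


def hits_as_tuples(hits):
    return {(h.locus_id, h.strand, h.split_index, h.shift_value) for h in hits}


def test_sixframe_toy_translations():
    idx = sixframe_translate({"T1": TOY_SEQ})
    fwd = {f.frame_label: f.aa_seq for f in idx if f.strand == "+"}
    assert fwd == {"1F": "MAATRTW*", "2F": "WQQRERG", "3F": "GSNANVV"}
    assert [len(f.aa_seq) for f in idx] == [8, 7, 7, 8, 7, 7]


def test_coordinate_map_round_trips_on_both_strands():
    rng = random.Random(2)
    seq = "".join(rng.choice("ACGT") for _ in range(120))
    for ft in sixframe_translate({"x": seq}):
        for i in range(0, len(ft.aa_seq) - 3, 5):
            s, e = ft.nt_span(i, 3)
            window = seq[s - 1:e]
            if ft.strand == "-":
                window = revcomp(window)
            assert oracle_translate_frame(window, 0) == ft.aa_seq[i:i + 3]


def test_empty_database_gives_empty_index():
    assert sixframe_translate({}) == []


def test_self_consistency_and_frame_spanning_peptide():
    idx = sixframe_translate({"T1": TOY_SEQ})
    hits = find_nonchimeric_sources("QQRER", idx)
    assert [(h.locus_id, h.frames, h.coords) for h in hits] \
        == [("T1", ("2F",), ((5, 19),))]
    # the junction peptide spans frames: no single-frame source
    assert find_nonchimeric_sources("MAARERG", idx) == []
    chim = find_chimeric_sources("MAARERG", idx, min_flank_aa=2)
    assert ("T1", "+", 3, 1) in hits_as_tuples(chim)
    split = next(h for h in chim if h.split_index == 3 and h.shift_value == 1)
    assert split.coords == ((1, 9), (11, 22))     # suffix starts at site nt 11


def test_peptide_shorter_than_two_flanks_errors():
    idx = sixframe_translate({"T1": TOY_SEQ})
    with pytest.raises(ValueError, match="flank"):
        find_chimeric_sources("MAA", idx, min_flank_aa=2)


def test_reverse_strand_sources_controlled_by_flag():
    idx_fwd = sixframe_translate({"x": revcomp(TOY_SEQ)}, forward_only=True)
    idx_all = sixframe_translate({"x": revcomp(TOY_SEQ)}, forward_only=False)
    pep = "QQRER"      # encoded on the reverse complement only
    assert find_nonchimeric_sources(pep, idx_fwd) == []
    hits = find_nonchimeric_sources(pep, idx_all)
    assert [(h.locus_id, h.strand) for h in hits] == [("x", "-")]


def test_scanner_matches_exhaustive_oracle_on_random_db():
    rng = random.Random(31)
    db = {f"L{i}": "".join(rng.choice("ACGT") for _ in range(rng.randint(60, 400)))
          for i in range(8)}
    idx = sixframe_translate(db)
    # peptides: random draws from real frames plus engineered split peptides
    peptides = []
    for _ in range(6):
        locus = rng.choice(sorted(db))
        off = rng.randrange(3)
        aa = oracle_translate_frame(db[locus], off).replace("*", "A")
        i = rng.randrange(max(1, len(aa) - 8))
        peptides.append(aa[i:i + 6])
    peptides += ["MAARERG", "AAAA"]
    for pep in peptides:
        if len(pep) < 4 or "*" in pep:
            continue
        got = {(h.locus_id, h.strand) for h in find_nonchimeric_sources(pep, idx)}
        want = {(l, s) for l, s, *_ in oracle_nonchimeric(pep, db)}
        assert got == want
        got_c = hits_as_tuples(find_chimeric_sources(pep, idx, 2))
        want_c = {(l, s, sp, v) for l, s, sp, v, *_ in oracle_chimeric(pep, db, 2)}
        assert got_c == want_c


def test_shuffled_decoy_database_yields_no_hits_for_long_peptides():
    rng = random.Random(7)
    db = {f"D{i}": "".join(rng.choice("ACGT") for _ in range(2000))
          for i in range(5)}
    idx = sixframe_translate(db)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(10):
        pep = "".join(rng.choice(aas) for _ in range(12))
        assert find_nonchimeric_sources(pep, idx) == []
        assert find_chimeric_sources(pep, idx, 2) == []


def test_every_planted_model_is_rediscovered_on_its_own_transcript():
    from prfkit import SimulationConfig, simulate
    cfg = SimulationConfig(
        n_transcripts={"mRNA": 3, "ncRNA": 1, "rRNA": 1, "tRNA": 1},
        length_bounds={"mRNA": (450, 700), "ncRNA": (150, 300),
                       "rRNA": (90, 140), "tRNA": (60, 90)},
        n_planted_single_prf=2, n_planted_round_trips=1)
    res = simulate(cfg, seed=3)
    idx = sixframe_translate({t.transcript_id: t.sequence
                              for t in res.transcripts}, forward_only=True)
    for e in res.ground_truth["events"]:
        j = e["junction_index"]
        hits = find_chimeric_sources(e["model_aa"], idx, min_flank_aa=1)
        assert any(h.locus_id == e["transcript_id"] and h.split_index == j
                   and h.shift_value == e["value"] for h in hits)
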