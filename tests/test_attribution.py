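"""Tryptic digestion, search databases, two-step plan, peptide verdicts."""

import itertools

import pytest

from prfkit import (SimulationConfig, attribute_peptide, build_search_database,
                    second_step_db, simulate, tryptic_peptides, two_step_plan)
from prfkit import io as pio


def oracle_tryptic(seq, max_missed, min_len, max_len):
    """Brute force over all cleavage-site subsets."""
    sites = [i + 1 for i in range(len(seq) - 1)
             if seq[i] in "KR" and seq[i + 1] != "P"]
    bounds = [0] + sites + [len(seq)]
    out = set()
    for i, j in itertools.combinations(range(len(bounds)), 2):
        if j - i - 1 <= max_missed:
            pep = seq[bounds[i]:bounds[j]]
            if min_len <= len(pep) <= max_len:
                out.add(pep)
    return out


@pytest.mark.parametrize("seq,expected", [
    ("MKRV", {"MK", "R", "V", "MKR", "RV", "MKRV"}),
    ("AKPA", {"AKPA"}),                       # K before P does not cleave
    ("MAATW", {"MAATW"}),                     # no K/R at all
])
def test_tryptic_examples(seq, expected):
    assert tryptic_peptides(seq, max_missed=2, min_len=1, max_len=30) == expected


def test_tryptic_matches_bruteforce_oracle():
    import random
    rng = random.Random(17)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(40):
        seq = "".join(rng.choice(aas) for _ in range(rng.randint(5, 60)))
        mm = rng.randint(0, 2)
        lo, hi = sorted((rng.randint(1, 10), rng.randint(5, 40)))
        assert tryptic_peptides(seq, mm, lo, hi) == oracle_tryptic(seq, mm, lo, hi)


def test_database_counts_decoys_and_duplicates(toy_events):
    *_, model = toy_events
    db = build_search_database([model], {"a1": "MWAAK"},
                               {"r1": "MAAR"}, {"c1": "CCCC"})
    assert len(db.targets) == 4 and len(db.decoys) == 4
    decoy = next(d for d in db.decoys if d.entry_id == "rev_r1")
    assert decoy.aa_seq == "RAAM"
    with pytest.raises(ValueError, match="duplicate"):
        build_search_database([], {"x": "AA"}, {"x": "AA"}, {})


def test_database_fasta_round_trip(tmp_path, toy_events):
    *_, model = toy_events
    db = build_search_database([model], {"a1": "MWAAK"}, {"r1": "MAAR"}, {})
    path = tmp_path / "db.fasta"
    pio.write_fasta(path, {e.entry_id: e.aa_seq for e in db.targets})
    assert pio.read_fasta(path) == {e.entry_id: e.aa_seq for e in db.targets}


def test_two_step_plan_partition_and_sizes():
    ids = [f"id{i}" for i in range(103)]
    chunks = two_step_plan(ids, n_chunks=10, seed=42)
    sizes = sorted(len(c) for c in chunks)
    assert sizes == [10] * 7 + [11] * 3
    flat = [i for c in chunks for i in c]
    assert sorted(flat) == sorted(ids)                    # a true partition
    assert two_step_plan(ids, 10, seed=42) == chunks      # deterministic
    assert two_step_plan(ids, 10, seed=43) != chunks
    assert [len(c) for c in two_step_plan(ids[:10], 10, seed=0)] == [1] * 10


def test_second_step_db_contains_exactly_survivors(toy_events):
    *_, model = toy_events
    db = build_search_database([model], {"a1": "MWAAK", "a2": "MWAAR"},
                               {"r1": "MAAR"}, {})
    survivors = {"a2", "r1"}
    db2 = second_step_db(db, survivors)
    assert {e.entry_id for e in db2.targets} == survivors
    assert len(db2.decoys) == 2


def test_verdict_precedence_and_junction_rule(toy_events):
    *_, model = toy_events            # MAARERG, junction 3
    db = build_search_database([model], {}, {"T1|refProt": "MAATRTW"}, {})
    assert attribute_peptide("MAAR", db).verdict == "chimeric_specific"
    res = attribute_peptide("MAAR", db)
    m = res.matches["chimeric"][0]
    assert (m.offset, m.junction_spanning) == (0, True)
    # a refProt tryptic peptide is vetoed even though inside a chimeric model
    db2 = build_search_database([model], {}, {"r": "XXMAARERGXX"}, {})
    assert attribute_peptide("MAAR", db2).verdict == "refProt"
    # contaminants outrank refProts
    db3 = build_search_database([model], {}, {"r": "MAARX"}, {"c": "MAARY"})
    assert attribute_peptide("MAAR", db3).verdict == "contaminant"
    # chimeric match that does not span the junction is ambiguous
    assert attribute_peptide("RERG", db).verdict == "ambiguous"
    assert attribute_peptide("WWWWW", db).verdict == "unmatched"


def test_junction_flank_requirement(toy_events):
    *_, model = toy_events
    db = build_search_database([model], {}, {}, {})
    # AARE covers 2 aa on each side; ARER only 1 upstream of the junction
    assert attribute_peptide("AARE", db, require_junction_flank=2).verdict \
        == "chimeric_specific"
    assert attribute_peptide("MAAR", db, require_junction_flank=2).verdict \
        == "ambiguous"


def test_isoleucine_leucine_equivalence(toy_events):
    db = build_search_database([], {}, {"r": "MALLIR"}, {})
    assert attribute_peptide("MAILLR", db).verdict == "unmatched"
    assert attribute_peptide("MAILLR", db, il_equivalent=True).verdict == "refProt"


def test_attribution_is_order_independent(toy_events):
    from prfkit.attribution import SearchDatabase, _reverse_decoys
    *_, model = toy_events
    db = build_search_database([model], {"a": "QQMAARQQ"}, {"r": "MAATRTW"}, {})
    rev = SearchDatabase(tuple(reversed(db.targets)),
                         _reverse_decoys(tuple(reversed(db.targets))))
    for pep in ("MAAR", "MAATR", "RERG", "AATRTW"):
        assert attribute_peptide(pep, db).verdict == attribute_peptide(pep, rev).verdict


def test_noise_free_synthetic_recovery_has_no_false_chimeric_calls():
    cfg = SimulationConfig(
        n_transcripts={"mRNA": 4, "ncRNA": 2, "rRNA": 1, "tRNA": 1},
        length_bounds={"mRNA": (450, 700), "ncRNA": (150, 300),
                       "rRNA": (90, 140), "tRNA": (60, 90)},
        n_planted_single_prf=2, n_planted_round_trips=1,
        n_random_peptides=0, n_altprot_peptides=0, fdr_like_fraction=0.0)
    from prfkit import run_discovery
    res = simulate(cfg, seed=5)
    out = run_discovery(res.transcripts, res.refprots, res.contaminants,
                        res.peptides, res.hits, res.ground_truth, seed=5)
    gt_peps = {p for e in res.ground_truth["events"] for p in e["peptides"]}
    for pep, r in out.attributions.items():
        if pep in gt_peps:
            assert r.verdict == "chimeric_specific"
        else:
            assert r.verdict != "chimeric_specific"
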