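"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own translation and
scanning code: translation uses a literal codon table, ORF discovery
enumerates every (frame, start-codon, end-codon) window, and the
alternative-source oracle tests every (locus, strand, frame, offset,
split, shift) tuple directly.
"""

from __future__ import annotations

import random

import pytest

from prfkit import (ExtractionParams, ModelingParams, TranscriptRecord,
                    build_chimeric_model, reforf_record, scan_altorfs)
from prfkit.chimeras import PrfEvent

# Standard genetic code, written out independently of Bio.Data.
ORACLE_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
ORACLE_STOPS = {c for c, a in ORACLE_CODON_TABLE.items() if a == "*"}

TOY_SEQ = "ATGGCAGCAACGCGAACGTGGTAA"


def oracle_translate_codon(codon: str) -> str:
    """X for any codon outside the unambiguous table (e.g. containing N)."""
    return ORACLE_CODON_TABLE.get(codon, "X")


def oracle_translate_frame(seq: str, offset: int) -> str:
    n = (len(seq) - offset) // 3
    return "".join(oracle_translate_codon(seq[offset + 3 * i:offset + 3 * i + 3])
                   for i in range(n))


def oracle_orf_regions(seq: str, min_len_nt: int) -> set[tuple[str, int, int, str]]:
    """Brute force over all (frame, start-codon, end-codon) windows, filtered
    for stop-freedom, maximality and length.

    Returns {(frame_label, start_nt, end_nt, aa_seq)} with 1-based inclusive
    coordinates, matching the scanner's contract.
    """
    out = set()
    min_codons = max(1, min_len_nt // 3)
    for off in range(3):
        aa = oracle_translate_frame(seq, off)
        n = len(aa)
        is_stop = [a == "*" for a in aa]
        for i in range(n):
            for j in range(i, n):
                if any(is_stop[i:j + 1]):
                    continue
                left_max = i == 0 or is_stop[i - 1]
                right_max = j == n - 1 or is_stop[j + 1]
                if not (left_max and right_max):
                    continue
                if j - i + 1 < min_codons:
                    continue
                start_nt = off + 3 * i + 1
                out.add((f"{off + 1}F", start_nt, start_nt + 3 * (j - i + 1) - 1,
                         aa[i:j + 1]))
    return out


def random_transcript_seq(rng: random.Random, max_len: int = 300,
                          with_n: bool = True) -> str:
    n = rng.randint(10, max_len)
    alphabet = "ACGT" + ("N" if with_n and rng.random() < 0.3 else "")
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture
def toy_transcript() -> TranscriptRecord:
    """24-nt transcript whose refORF translates to MAATRTW."""
    return TranscriptRecord("T1", "mRNA", "Chr1", TOY_SEQ, (1, 21))


@pytest.fixture
def toy_events(toy_transcript):
    """The toy +1@11 / -1@19 round-trip event pair and its first model."""
    ref = reforf_record(toy_transcript)
    orfs = scan_altorfs(toy_transcript, ExtractionParams(min_len_nt=9))
    f2 = next(o for o in orfs if o.frame == "2F")
    e1 = PrfEvent("T1", ref, f2, 11, 1)
    e2 = PrfEvent("T1", f2, ref, 19, -1)
    model = build_chimeric_model(e1, ModelingParams(min_model_aa=4), TOY_SEQ)
    return ref, f2, e1, e2, model
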