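"""Target/decoy search databases and peptide attribution.

Proteins are digested in silico with trypsin (cleavage C-terminal to K/R
except before P, up to two missed cleavages).  Identified peptides are
matched by exact substring against a class-labelled database of reference
proteins, alternative proteins, chimeric models and contaminants, with
reversed-sequence decoys alongside.  A peptide is specific evidence for a
chimeric model only if it spans the model's frameshift junction and matches
nothing in the refProt/altProt/contaminant classes: any such match vetoes
chimeric candidacy, because a peptide differing from a conventional protein
by nothing (or by residues MS cannot resolve) must not be counted as
frameshift evidence.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from pyteomics import parser as _pparser

from .chimeras import ChimericModel

TRYPSIN_RULE = r"[KR](?!P)"

SEQ_CLASSES = ("contaminant", "refProt", "altProt", "chimeric")
#: veto precedence: a match in an earlier class decides the verdict
VETO_ORDER = ("contaminant", "refProt", "altProt")


def tryptic_peptides(aa_seq: str, max_missed: int = 2,
                     min_len: int = 8, max_len: int = 30) -> set[str]:
    """Tryptic products of one protein within the length window."""
    if not aa_seq:
        raise ValueError("empty protein sequence")
    return set(_pparser.cleave(aa_seq, TRYPSIN_RULE,
                               missed_cleavages=max_missed,
                               min_length=min_len, max_length=max_len))


@dataclass(frozen=True)
class DbEntry:
    entry_id: str
    seq_class: str
    aa_seq: str
    junction_index: Optional[int] = None    # chimeric entries only

    def __post_init__(self) -> None:
        if self.seq_class not in SEQ_CLASSES:
            raise ValueError(f"unknown sequence class {self.seq_class!r}")
        if self.seq_class == "chimeric" and self.junction_index is None:
            raise ValueError(f"{self.entry_id}: chimeric entry lacks junction index")


@dataclass(frozen=True)
class SearchDatabase:
    targets: tuple[DbEntry, ...]
    decoys: tuple[DbEntry, ...]

    def __post_init__(self) -> None:
        if len(self.targets) != len(self.decoys):
            raise ValueError("decoy count must equal target count")

    def subset(self, keep_ids: set[str]) -> "SearchDatabase":
        targets = tuple(e for e in self.targets if e.entry_id in keep_ids)
        return SearchDatabase(targets, _reverse_decoys(targets))


def _reverse_decoys(targets: Sequence[DbEntry]) -> tuple[DbEntry, ...]:
    return tuple(DbEntry(f"rev_{e.entry_id}", e.seq_class, e.aa_seq[::-1],
                         junction_index=(len(e.aa_seq) - e.junction_index
                                         if e.junction_index is not None else None))
                 for e in targets)


def build_search_database(models: Iterable[ChimericModel] = (),
                          altprots: Mapping[str, str] | Iterable[tuple[str, str]] = (),
                          refprots: Mapping[str, str] | Iterable[tuple[str, str]] = (),
                          contaminants: Mapping[str, str] | Iterable[tuple[str, str]] = (),
                          ) -> SearchDatabase:
    """Class-labelled targets plus one reversed decoy per target.

    The altProts used for chimeric modeling belong in the database next to
    the refProt and contaminant collections so that peptides identical to a
    conventional protein are vetoed rather than mistaken for chimeric ones.
    Duplicate entry ids raise.
    """
    def items(x):
        return x.items() if isinstance(x, Mapping) else x

    entries: list[DbEntry] = []
    for eid, seq in items(contaminants):
        entries.append(DbEntry(eid, "contaminant", seq.upper()))
    for eid, seq in items(refprots):
        entries.append(DbEntry(eid, "refProt", seq.upper()))
    for eid, seq in items(altprots):
        entries.append(DbEntry(eid, "altProt", seq.upper()))
    for m in models:
        entries.append(DbEntry(m.model_id, "chimeric", m.aa_seq.upper(),
                               junction_index=m.junction_index))
    seen: set[str] = set()
    for e in entries:
        if e.entry_id in seen:
            raise ValueError(f"duplicate database id {e.entry_id!r}")
        seen.add(e.entry_id)
    targets = tuple(entries)
    return SearchDatabase(targets, _reverse_decoys(targets))


@dataclass(frozen=True)
class PeptideMatch:
    entry_id: str
    offset: int                      # 0-based position of the peptide
    junction_spanning: Optional[bool] = None   # chimeric entries only


@dataclass(frozen=True)
class AttributionResult:
    peptide: str
    matches: Mapping[str, tuple[PeptideMatch, ...]]   # class -> matches
    verdict: str    # refProt | altProt | contaminant | chimeric_specific | ambiguous | unmatched


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def _spans_junction(offset: int, pep_len: int, junction: int, flank: int) -> bool:
    left = junction - offset
    right = offset + pep_len - junction
    return left >= flank and right >= flank


def attribute_peptide(peptide: str, db: SearchDatabase,
                      require_junction_flank: int = 1,
                      il_equivalent: bool = False) -> AttributionResult:
    """Classify one identified peptide against the search database.

    Verdict precedence: any contaminant, refProt or altProt containment
    decides the verdict in that order (vetoing chimeric candidacy); else a
    junction-spanning chimeric match (>= ``require_junction_flank`` residues
    on each side of the junction) gives ``chimeric_specific``; a chimeric
    match that does not span the junction gives ``ambiguous``; otherwise
    ``unmatched``.  With ``il_equivalent`` isoleucine and leucine are folded
    together before matching, mirroring their identical mass.
    """
    def norm(s: str) -> str:
        s = s.upper()
        return s.replace("L", "I") if il_equivalent else s

    pep = norm(peptide)
    matches: dict[str, list[PeptideMatch]] = {c: [] for c in SEQ_CLASSES}
    for entry in db.targets:
        for off in _find_all(norm(entry.aa_seq), pep):
            span = None
            if entry.seq_class == "chimeric":
                span = _spans_junction(off, len(pep), entry.junction_index,
                                       require_junction_flank)
            matches[entry.seq_class].append(PeptideMatch(entry.entry_id, off, span))

    verdict = "unmatched"
    for cls in VETO_ORDER:
        if matches[cls]:
            verdict = cls
            break
    else:
        chim = matches["chimeric"]
        if any(m.junction_spanning for m in chim):
            verdict = "chimeric_specific"
        elif chim:
            verdict = "ambiguous"
    frozen = {c: tuple(sorted(v, key=lambda m: (m.entry_id, m.offset)))
              for c, v in matches.items()}
    return AttributionResult(peptide, frozen, verdict)


def attribute_peptides(peptides: Iterable[str], db: SearchDatabase,
                       require_junction_flank: int = 1,
                       il_equivalent: bool = False) -> dict[str, AttributionResult]:
    uniq = sorted(set(peptides))
    return {p: attribute_peptide(p, db, require_junction_flank, il_equivalent)
            for p in uniq}


def two_step_plan(entry_ids: Iterable[str], n_chunks: int = 10,
                  seed: int = 0) -> list[list[str]]:
    """Seeded shuffle-and-split of database ids into near-equal chunks.

    Used to control search-database inflation: each chunk is searched
    separately in a first pass and only first-pass survivors enter the
    second-pass database.  Chunk sizes differ by at most one; the partition
    is deterministic under ``seed``.  Peptide lists from different source
    studies are searched independently, so callers plan per study.
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    ids = sorted(set(entry_ids))
    random.Random(seed).shuffle(ids)
    base, rem = divmod(len(ids), n_chunks)
    chunks, pos = [], 0
    for i in range(n_chunks):
        size = base + (1 if i < rem else 0)
        chunks.append(ids[pos:pos + size])
        pos += size
    return chunks


def second_step_db(db: SearchDatabase, survivor_ids: Iterable[str]) -> SearchDatabase:
    """Database for the second search pass: exactly the first-pass survivors."""
    return db.subset(set(survivor_ids))
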