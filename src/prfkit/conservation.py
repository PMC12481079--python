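"""Conservation filter over protein-alignment hit tables.

The pipeline never runs an aligner itself: it parses BLASTP/DIAMOND-style
tabular output and flags an altProt as *conserved* when at least one of its
hits simultaneously reaches 70% amino acid identity and an e-value of at
most 1e-3 (both thresholds inclusive and configurable).  Per-RNA-type
summaries mirror the usual per-type statistics table: transcript and altORF
counts, medians of altProt length, alignment length, percent identity and
query coverage, and counts of long altORFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .orfs import OrfRecord, parse_identifier

#: column order of the hit tables this package reads/writes
HIT_COLUMNS = ("qseqid", "stitle", "align_len", "pident", "ppos",
               "qcovhsp", "evalue", "taxon")


@dataclass(frozen=True)
class HitRecord:
    qseqid: str
    stitle: str
    align_len: int
    pident: float
    ppos: float
    qcovhsp: float
    evalue: float
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("pident", "ppos", "qcovhsp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")


@dataclass(frozen=True)
class ConservationSummary:
    qseqid: str
    n_hits: int
    top_pident: float
    conserved: bool


def read_hit_table(path, column_map: Optional[Mapping[str, str]] = None) -> list[HitRecord]:
    """Parse a tab-separated hit table into :class:`HitRecord` rows.

    The default layout is the package's own eight-column dialect
    (:data:`HIT_COLUMNS`); ``column_map`` renames caller columns onto it,
    so any outfmt-6-style table can be ingested by mapping its header.
    Malformed rows raise with their line number.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=list(HIT_COLUMNS),
                     dtype=str, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(HitRecord(
                qseqid=row.qseqid, stitle=row.stitle,
                align_len=int(row.align_len), pident=float(row.pident),
                ppos=float(row.ppos), qcovhsp=float(row.qcovhsp),
                evalue=float(row.evalue),
                taxon=None if pd.isna(row.taxon) else row.taxon))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed hit-table row at line {i}: {exc}") from exc
    return records


def classify_conserved(hits: Iterable[HitRecord],
                       min_pident: float = 70.0,
                       max_evalue: float = 1e-3) -> list[ConservationSummary]:
    """One summary per query with >=1 hit; queries without hits are absent.

    A query is conserved iff some single hit satisfies *both* thresholds
    (pident >= ``min_pident`` and evalue <= ``max_evalue``, inclusive).
    """
    if min_pident <= 0 or max_evalue <= 0:
        raise ValueError("thresholds must be positive")
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.qseqid, []).append(h)
    out = []
    for q in sorted(by_query):
        hs = by_query[q]
        out.append(ConservationSummary(
            qseqid=q,
            n_hits=len(hs),
            top_pident=max(h.pident for h in hs),
            conserved=any(h.pident >= min_pident and h.evalue <= max_evalue
                          for h in hs)))
    return out


def conserved_ids(summaries: Iterable[ConservationSummary]) -> set[str]:
    return {s.qseqid for s in summaries if s.conserved}


def summarize_by_rna_type(summaries: Sequence[ConservationSummary],
                          hits: Sequence[HitRecord],
                          orfs: Sequence[OrfRecord],
                          rna_type_of_transcript: Mapping[str, str],
                          n_transcripts_per_type: Optional[Mapping[str, int]] = None,
                          ) -> pd.DataFrame:
    """Per-RNA-type statistics over the conserved (surviving) altORFs.

    For each RNA type: the number of transcripts with >=1 surviving altORF,
    the surviving altORF total, altORFs per transcript (against the full
    transcript count of that type when supplied), medians of altProt length
    (aa), alignment length, percent identity and query coverage over the
    surviving queries' hits, and counts of surviving altORFs longer than
    300 and 600 nt.  Empty input yields an empty table.
    """
    keep = conserved_ids(summaries)
    orf_by_id = {o.identifier: o for o in orfs}
    rows = []
    for q in sorted(keep):
        orf = orf_by_id.get(q)
        if orf is None:
            tid = parse_identifier(q)[0]
            length_nt = None
        else:
            tid, length_nt = orf.transcript_id, orf.length_nt
        rtype = rna_type_of_transcript[tid]
        for h in hits:
            if h.qseqid == q:
                rows.append({"qseqid": q, "transcript_id": tid, "rna_type": rtype,
                             "length_nt": length_nt, "align_len": h.align_len,
                             "pident": h.pident, "qcovhsp": h.qcovhsp})
    if not rows:
        return pd.DataFrame(columns=[
            "rna_type", "n_transcripts", "n_altorfs", "altorfs_per_transcript",
            "median_altprot_aa", "median_align_len", "median_pident",
            "median_qcovhsp", "n_gt_300nt", "n_gt_600nt"])
    df = pd.DataFrame(rows)
    out = []
    for rtype, g in df.groupby("rna_type", sort=True):
        per_query = g.drop_duplicates("qseqid")
        n_alt = len(per_query)
        denom = (n_transcripts_per_type or {}).get(
            rtype, per_query["transcript_id"].nunique())
        out.append({
            "rna_type": rtype,
            "n_transcripts": per_query["transcript_id"].nunique(),
            "n_altorfs": n_alt,
            "altorfs_per_transcript": n_alt / denom if denom else float("nan"),
            "median_altprot_aa": (per_query["length_nt"] / 3).median(),
            "median_align_len": g["align_len"].median(),
            "median_pident": g["pident"].median(),
            "median_qcovhsp": g["qcovhsp"].median(),
            "n_gt_300nt": int((per_query["length_nt"] > 300).sum()),
            "n_gt_600nt": int((per_query["length_nt"] > 600).sum()),
        })
    return pd.DataFrame(out)
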