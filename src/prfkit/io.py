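"""File interfaces: FASTA, GFF3-like annotations, TSV tables.

Transcript annotations travel either as a GFF3 companion (a ``transcript``
feature carrying ``rna_type``/``location`` attributes plus a ``CDS``
feature for the refORF of an mRNA) or as a TSV sidecar with columns
``transcript_id, rna_type, location, reforf_start, reforf_end``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .chimeras import ChimericModel
from .orfs import OrfRecord, TranscriptRecord


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid in seqs:
            fh.write(f">{sid}\n")
            s = seqs[sid]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def write_annotations(path, transcripts: Sequence[TranscriptRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            attrs = f"ID={t.transcript_id};rna_type={t.rna_type};location={t.location}"
            fh.write(f"{t.transcript_id}\tprfkit\ttranscript\t1\t{len(t)}\t.\t+\t.\t{attrs}\n")
            if t.reforf_span is not None:
                s, e = t.reforf_span
                fh.write(f"{t.transcript_id}\tprfkit\tCDS\t{s}\t{e}\t.\t+\t0\t"
                         f"Parent={t.transcript_id}\n")


def read_annotations(path) -> pd.DataFrame:
    """GFF3 companion file -> one row per transcript."""
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    rows = []
    for feat in db.features_of_type("transcript"):
        rows.append({
            "transcript_id": feat.id,
            "rna_type": feat.attributes.get("rna_type", ["mRNA"])[0],
            "location": feat.attributes.get("location", ["Chr0"])[0],
            "reforf_start": pd.NA, "reforf_end": pd.NA})
    by_id = {r["transcript_id"]: r for r in rows}
    for feat in db.features_of_type("CDS"):
        parent = feat.attributes.get("Parent", [feat.seqid])[0]
        if parent in by_id:
            by_id[parent]["reforf_start"] = feat.start
            by_id[parent]["reforf_end"] = feat.end
    return pd.DataFrame(rows)


def read_transcripts(fasta_path, annotations_path=None,
                     sidecar_tsv=None) -> list[TranscriptRecord]:
    seqs = read_fasta(fasta_path)
    if annotations_path is not None:
        ann = read_annotations(annotations_path)
    elif sidecar_tsv is not None:
        ann = pd.read_csv(sidecar_tsv, sep="\t")
    else:
        raise ValueError("need a GFF3 annotation file or a TSV sidecar")
    out = []
    for row in ann.itertuples(index=False):
        tid = row.transcript_id
        if tid not in seqs:
            raise ValueError(f"annotated transcript {tid} missing from FASTA")
        span = None
        if not pd.isna(row.reforf_start):
            span = (int(row.reforf_start), int(row.reforf_end))
        out.append(TranscriptRecord(tid, row.rna_type, row.location,
                                    seqs[tid], span))
    return out


def orfs_to_fasta(path, orfs: Iterable[OrfRecord]) -> None:
    write_fasta(path, {o.identifier: o.aa_seq for o in orfs})


def orfs_to_bed(path, orfs: Iterable[OrfRecord]) -> None:
    """BED-like TSV of ORF coordinates (0-based half-open starts)."""
    rows = [(o.transcript_id, o.start_nt - 1, o.end_nt, o.identifier,
             o.frame, o.orf_class) for o in orfs]
    pd.DataFrame(rows, columns=["transcript_id", "start", "end",
                                "identifier", "frame", "orf_class"]
                 ).to_csv(path, sep="\t", index=False)


def models_to_tsv(path, models: Iterable[ChimericModel]) -> None:
    rows = []
    for m in models:
        e = m.event
        rows.append((m.model_id, e.transcript_id, e.site_nt, e.value,
                     e.prf_type, e.prf_subtype, e.donor.identifier,
                     e.acceptor.identifier, m.junction_index, m.aa_seq,
                     ",".join(sorted(m.provenances))))
    pd.DataFrame(rows, columns=[
        "model_id", "transcript_id", "site_nt", "value", "prf_type",
        "prf_subtype", "donor_id", "acceptor_id", "junction_index",
        "aa_seq", "provenances"]).to_csv(path, sep="\t", index=False)


def models_to_fasta(path, models: Iterable[ChimericModel]) -> None:
    write_fasta(path, {m.model_id: m.aa_seq for m in models})


def read_peptides(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"peptide", "sample", "source_study"} - set(df.columns)
    if missing:
        raise ValueError(f"peptide table lacks columns: {sorted(missing)}")
    return df
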