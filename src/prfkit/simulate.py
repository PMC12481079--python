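"""Synthetic transcriptomes with planted frameshift ground truth.

The generator emulates the statistical structure of the discovery inputs:
transcripts of four RNA types (one annotated refORF per mRNA, stop-free
altORFs arising naturally in the other frames), planted single PRF events
with values in {-2, -1, +1, +2}, planted "short round trip" event pairs
whose values sum to zero, and identified-peptide lists built by tryptic
digestion of the simulated proteins, with optional random and decoy-derived
noise peptides.  A synthetic conservation hit table marks the planted
altProts (and a background fraction) as conserved so the modeling basis of
the real pipeline finds them.

Planted events are constructed by back-translating a designed amino acid
segment into the shifted frame inside the refORF while keeping the refORF
frame stop-free across the overlap (rejection sampling over synonymous
codons with a bounded retry budget), and are then *verified through the
package's own extraction/modeling/digestion code* before being accepted, so
every ground-truth entry is re-derivable from the emitted transcript.

All outputs are deterministic under the configuration seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .attribution import tryptic_peptides
from .chimeras import (ChimericModel, ModelingParams, PrfEvent,
                       build_chimeric_model, shifted_frame)
from .conservation import HIT_COLUMNS
from .mosaic import assemble_mosaic, assess_compatibility
from .orfs import (CODON_TO_AA, ExtractionParams, OrfRecord, STOP_CODONS,
                   TranscriptRecord, reforf_record, scan_altorfs,
                   translate_region)

SENSE_CODONS = tuple(sorted(CODON_TO_AA))
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_c], ())
AA_TO_CODONS = {aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
                for aa in AA_TO_CODONS}
AA_ALPHABET = tuple(sorted(AA_TO_CODONS))
_NO_KRP = tuple(a for a in AA_ALPHABET if a not in "KRP")

DEFAULT_VALUES = (-2, -1, 1, 2)


class SimulationError(ValueError):
    """Raised when a configuration cannot be realised."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Transcript counts are desk-scale; per-type length bounds bracket the
    median transcript lengths reported for the four RNA types of a plant
    transcriptome (mRNA ~1.3 kb, ncRNA ~0.4 kb, rRNA ~120 nt, tRNA ~75 nt).
    The planted value mix leans toward negative and two-nucleotide shifts,
    matching the observed overrepresentation of backward and "long" events.
    ``fdr_like_fraction`` adds decoy-derived noise peptides at the rate of
    the conventional 1% peptide-level FDR.
    """

    seed: int = 0
    n_transcripts: dict[str, int] = field(default_factory=lambda: {
        "mRNA": 12, "ncRNA": 6, "rRNA": 4, "tRNA": 4})
    length_bounds: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "mRNA": (900, 1500), "ncRNA": (250, 600),
        "rRNA": (90, 160), "tRNA": (60, 90)})
    gc_fraction: float = 0.42
    n_planted_single_prf: int = 6
    n_planted_round_trips: int = 2
    value_mix: dict[int, float] = field(default_factory=lambda: {
        -2: 0.30, -1: 0.28, 1: 0.14, 2: 0.28})
    overlap_bounds_nt: tuple[int, int] = (60, 120)
    n_random_peptides: int = 5
    n_altprot_peptides: int = 4
    fdr_like_fraction: float = 0.01
    max_missed_cleavages: int = 2
    peptide_len_bounds: tuple[int, int] = (8, 30)
    refprot_peptides_per_sample: int = 2
    background_conserved_rate: float = 0.10
    n_contaminants: int = 5
    samples: tuple[tuple[str, str], ...] = (
        ("root", "D1"), ("nodule", "D1"), ("seed", "D2"))
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.overlap_bounds_nt[0] < 9:
            raise SimulationError("overlap bounds must be at least 9 nt")
        if self.n_planted_single_prf < 0 or self.n_planted_round_trips < 0:
            raise SimulationError("planted counts must be non-negative")
        n_planted = self.n_planted_single_prf + self.n_planted_round_trips
        if n_planted > self.n_transcripts.get("mRNA", 0):
            raise SimulationError("more planted events than mRNA transcripts")
        lo, hi = self.length_bounds.get("mRNA", (0, 0))
        if n_planted and lo < 3 * (self.overlap_bounds_nt[1] // 3 + 30):
            raise SimulationError("mRNA length bounds too small for the overlap bounds")
        if not 0 <= self.fdr_like_fraction < 1:
            raise SimulationError("fdr_like_fraction must be in [0, 1)")


@dataclass
class SimulationResult:
    config: SimulationConfig
    seed: int
    transcripts: list[TranscriptRecord]
    refprots: dict[str, str]
    contaminants: dict[str, str]
    peptides: pd.DataFrame            # peptide, sample, source_study
    hits: pd.DataFrame                # HIT_COLUMNS
    ground_truth: dict

    def transcript(self, tid: str) -> TranscriptRecord:
        return next(t for t in self.transcripts if t.transcript_id == tid)

    def write(self, outdir) -> dict[str, Path]:
        from . import io as _io
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "transcripts": outdir / "transcripts.fasta",
            "annotations": outdir / "annotations.gff3",
            "refprots": outdir / "refprots.fasta",
            "contaminants": outdir / "contaminants.fasta",
            "peptides": outdir / "peptides.tsv",
            "hits": outdir / "hits.tsv",
            "ground_truth": outdir / "ground_truth.json",
        }
        _io.write_fasta(paths["transcripts"],
                        {t.transcript_id: t.sequence for t in self.transcripts})
        _io.write_annotations(paths["annotations"], self.transcripts)
        _io.write_fasta(paths["refprots"], self.refprots)
        _io.write_fasta(paths["contaminants"], self.contaminants)
        self.peptides.to_csv(paths["peptides"], sep="\t", index=False)
        self.hits.to_csv(paths["hits"], sep="\t", index=False, header=False)
        paths["ground_truth"].write_text(
            json.dumps(self.ground_truth, indent=2, sort_keys=True) + "\n")
        return paths


# ---------------------------------------------------------------- helpers

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=p))


def _random_sense_codon(rng: np.random.Generator) -> str:
    return str(rng.choice(np.array(SENSE_CODONS)))


def _back_translate(rng: np.random.Generator, aa: str) -> str:
    return "".join(str(rng.choice(np.array(AA_TO_CODONS[a]))) for a in aa)


def _designed_alt_aa(rng: np.random.Generator, m: int, round_trip: bool) -> str:
    """Shifted-frame segment skeleton: tryptic sites placed so that each
    planted junction yields a digestible junction-spanning peptide.  Proline
    is avoided so cleavage sites stay predictable."""
    out = [str(rng.choice(np.array(_NO_KRP))) for _ in range(m)]
    out[3] = "R"
    if round_trip:
        out[m - 5] = str(rng.choice(np.array(["K", "R"])))
    return "".join(out)


def _junction_peptides(model: ChimericModel, cfg: SimulationConfig,
                       flank: int = 1) -> list[str]:
    """Tryptic peptides of a model that span its junction."""
    peps = tryptic_peptides(model.aa_seq, cfg.max_missed_cleavages,
                            *cfg.peptide_len_bounds)
    j = model.junction_index
    out = []
    for p in sorted(peps):
        i = model.aa_seq.find(p)
        while i != -1:
            if j - i >= flank and i + len(p) - j >= flank:
                out.append(p)
                break
            i = model.aa_seq.find(p, i + 1)
    return out


def _frame_translations(seq: str) -> list[str]:
    return [translate_region(seq, off + 1, off + 1 + 3 * ((len(seq) - off) // 3) - 1)
            for off in range(3) if (len(seq) - off) // 3 > 0]


def _collides(pep: str, spaces: Iterable[str]) -> bool:
    return any(pep in s for s in spaces)


# ---------------------------------------------------------------- planting

def _try_make_mrna(rng: np.random.Generator, cfg: SimulationConfig, tid: str,
                   location: str, plant: Optional[str], values: tuple[int, ...],
                   foreign_space: list[str]) -> Optional[tuple[TranscriptRecord, list[dict]]]:
    lo, hi = cfg.length_bounds["mRNA"]
    length = int(rng.integers(lo, hi + 1))
    utr5 = int(rng.integers(12, 41))
    utr3 = int(rng.integers(12, 41))
    ncod = (length - utr5 - utr3 - 3) // 3
    if ncod < 40:
        return None
    start = utr5 + 1
    end = start + 3 * ncod - 1
    codons = ["ATG"] + [_random_sense_codon(rng) for _ in range(ncod - 1)]
    stop = str(rng.choice(np.array(sorted(STOP_CODONS))))
    tail = length - (utr5 + 3 * ncod + 3)
    seq = (_random_seq(rng, utr5, cfg.gc_fraction) + "".join(codons) + stop
           + _random_seq(rng, tail, cfg.gc_fraction))

    gt_events: list[dict] = []
    if plant is not None:
        v1 = values[0]
        m = max(20, int(rng.integers(*cfg.overlap_bounds_nt)) // 3)
        k_min = 9
        k_max = (end - 9 - 3 * m - v1 - start) // 3
        if k_max < k_min:
            return None
        k = int(rng.integers(k_min, k_max + 1))
        site = start + 3 * k + v1
        designed = _designed_alt_aa(rng, m, round_trip=(plant == "round_trip"))
        for _ in range(60):
            window = _back_translate(rng, designed)
            cand = seq[:site - 1] + window + seq[site - 1 + 3 * m:]
            if "*" not in translate_region(cand, start, end):
                seq = cand
                break
        else:
            return None

        tr = TranscriptRecord(tid, "mRNA", location, seq, (start, end))
        ref = reforf_record(tr)
        alts = scan_altorfs(tr, ExtractionParams())
        f_a = shifted_frame(ref.frame_number, v1)
        acceptor = next(
            (o for o in alts if o.frame_number == f_a
             and o.start_nt <= site and o.end_nt >= site + 3 * m - 1), None)
        if acceptor is None:
            return None

        local_space = _frame_translations(seq)
        mp = ModelingParams()

        def plant_event(ev: PrfEvent) -> Optional[dict]:
            model = build_chimeric_model(ev, mp, seq)
            if model is None:
                return None
            cands = [p for p in _junction_peptides(model, cfg)
                     if not _collides(p, local_space)
                     and not _collides(p, foreign_space)]
            if not cands:
                return None
            pep = str(rng.choice(np.array(cands)))
            return {"transcript_id": tid, "site_nt": ev.site_nt,
                    "value": ev.value, "prf_type": ev.prf_type,
                    "prf_subtype": ev.prf_subtype,
                    "donor_id": ev.donor.identifier,
                    "acceptor_id": ev.acceptor.identifier,
                    "model_aa": model.aa_seq,
                    "junction_index": model.junction_index,
                    "peptides": [pep]}

        e1 = PrfEvent(tid, ref, acceptor, site, v1)
        g1 = plant_event(e1)
        if g1 is None:
            return None
        g1["kind"] = "single" if plant == "single" else "round_trip"
        gt_events.append(g1)

        if plant == "round_trip":
            v2 = -v1
            site2 = site + 3 * m + v2
            if site2 > end - 2:
                return None
            e2 = PrfEvent(tid, acceptor, ref, site2, v2)
            g2 = plant_event(e2)
            if g2 is None or g2["peptides"] == g1["peptides"]:
                return None
            g2["kind"] = "round_trip"
            gt_events.append(g2)
            comp = assess_compatibility(seq, e1, e2)
            if not comp.round_trip or comp.bridge_stop_count:
                return None
            asm = assemble_mosaic(seq, ref, e1, e2)
            if len(asm.mosaic_aa) != len(ref.aa_seq):
                return None
            g1["mosaic"] = g2["mosaic"] = {
                "sites": [site, site2], "values": [v1, v2],
                "inter_site_nt": comp.inter_site_nt,
                "mosaic_aa": asm.mosaic_aa, "annotated_aa": asm.annotated_aa,
                "diff_start_aa": asm.diff_start_aa,
                "diff_len_aa": asm.diff_len_aa}
    else:
        tr = TranscriptRecord(tid, "mRNA", location, seq, (start, end))

    return TranscriptRecord(tid, "mRNA", location, seq, (start, end)), gt_events


def _make_mrna(rng, cfg, tid, location, plant, values, foreign_space):
    for _ in range(cfg.max_retries):
        made = _try_make_mrna(rng, cfg, tid, location, plant, values, foreign_space)
        if made is not None:
            return made
    raise SimulationError(
        f"could not realise {plant or 'background'} mRNA {tid} within the retry budget; "
        "the configuration is likely infeasible (overlap bounds vs transcript length)")


# ---------------------------------------------------------------- simulate

def simulate(config: SimulationConfig = SimulationConfig(),
             seed: Optional[int] = None) -> SimulationResult:
    """Generate one synthetic study; deterministic under the seed."""
    used_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    locations = [f"Chr{i}" for i in range(9)] + ["chloroplast", "mitochondrion"]

    vals = np.array(sorted(config.value_mix))
    probs = np.array([config.value_mix[int(v)] for v in vals], dtype=float)
    probs = probs / probs.sum()

    transcripts: list[TranscriptRecord] = []
    gt_events: list[dict] = []
    refprots: dict[str, str] = {}
    foreign_space: list[str] = []

    contaminants = {
        f"CONTAM_{i + 1}": "".join(
            str(rng.choice(np.array(AA_ALPHABET)))
            for _ in range(int(rng.integers(100, 301))))
        for i in range(config.n_contaminants)}
    foreign_space.extend(contaminants.values())

    n_mrna = config.n_transcripts.get("mRNA", 0)
    plant_plan: list[Optional[str]] = (
        ["round_trip"] * config.n_planted_round_trips
        + ["single"] * config.n_planted_single_prf
        + [None] * (n_mrna - config.n_planted_round_trips - config.n_planted_single_prf))

    for i, plant in enumerate(plant_plan):
        tid = f"T{i + 1:03d}"
        loc = str(rng.choice(np.array(locations)))
        v1 = int(rng.choice(vals, p=probs))
        tr, events = _make_mrna(rng, config, tid, loc, plant, (v1,), foreign_space)
        transcripts.append(tr)
        gt_events.extend(events)
        aa = reforf_record(tr).aa_seq
        refprots[f"{tr.transcript_id}|refProt"] = aa
        foreign_space.extend(_frame_translations(tr.sequence))

    idx = n_mrna
    for rtype in ("ncRNA", "rRNA", "tRNA"):
        lo, hi = config.length_bounds.get(rtype, (60, 120))
        for _ in range(config.n_transcripts.get(rtype, 0)):
            idx += 1
            tid = f"T{idx:03d}"
            loc = str(rng.choice(np.array(locations)))
            transcripts.append(TranscriptRecord(
                tid, rtype, loc, _random_seq(rng, int(rng.integers(lo, hi + 1)),
                                             config.gc_fraction)))

    # ---- synthetic conservation hit table ---------------------------------
    planted_alt_ids = {e["acceptor_id"] for e in gt_events} | {
        e["donor_id"] for e in gt_events if not e["donor_id"].endswith("refORF")}
    planted_alt_ids = {i for i in planted_alt_ids}
    all_altorfs: list[OrfRecord] = []
    for tr in transcripts:
        all_altorfs.extend(scan_altorfs(tr, ExtractionParams()))
    alt_ids = {o.identifier for o in all_altorfs}
    planted_alt_ids &= alt_ids

    hit_rows = []
    for o in all_altorfs:
        oid = o.identifier
        if oid in planted_alt_ids or rng.random() < config.background_conserved_rate:
            hit_rows.append((oid, "hypothetical conserved protein", len(o.aa_seq),
                             round(float(rng.uniform(70, 100)), 1),
                             round(float(rng.uniform(80, 100)), 1),
                             round(float(rng.uniform(60, 100)), 1),
                             float(10.0 ** rng.uniform(-12, -3.2)), "Fabaceae"))
        elif rng.random() < 0.2:
            hit_rows.append((oid, "weak hit", len(o.aa_seq),
                             round(float(rng.uniform(20, 69.8)), 1),
                             round(float(rng.uniform(30, 80)), 1),
                             round(float(rng.uniform(20, 90)), 1),
                             float(10.0 ** rng.uniform(-2.9, 0.9)), None))
    hits = pd.DataFrame(hit_rows, columns=list(HIT_COLUMNS))

    # ---- identified-peptide lists ----------------------------------------
    samples = list(config.samples)
    rows: list[tuple[str, str, str]] = []
    for e in gt_events:
        sample, study = samples[int(rng.integers(len(samples)))]
        for pep in e["peptides"]:
            rows.append((pep, sample, study))
    for rid in sorted(refprots):
        pool = sorted(tryptic_peptides(refprots[rid], config.max_missed_cleavages,
                                       *config.peptide_len_bounds))
        if not pool:
            continue
        for sample, study in samples:
            take = min(config.refprot_peptides_per_sample, len(pool))
            for j in rng.choice(len(pool), size=take, replace=False):
                rows.append((pool[int(j)], sample, study))

    ref_space = list(refprots.values()) + list(contaminants.values())
    unplanted = [o for o in all_altorfs if o.identifier not in planted_alt_ids]
    if config.n_altprot_peptides and unplanted:
        for j in rng.choice(len(unplanted),
                            size=min(config.n_altprot_peptides, len(unplanted)),
                            replace=False):
            o = unplanted[int(j)]
            pool = sorted(p for p in tryptic_peptides(
                o.aa_seq, config.max_missed_cleavages, *config.peptide_len_bounds)
                if not _collides(p, ref_space))
            if pool:
                sample, study = samples[int(rng.integers(len(samples)))]
                rows.append((pool[int(rng.integers(len(pool)))], sample, study))

    n_true = len(rows)
    for _ in range(config.n_random_peptides):
        pep = "".join(str(rng.choice(np.array(AA_ALPHABET)))
                      for _ in range(int(rng.integers(8, 21))))
        sample, study = samples[int(rng.integers(len(samples)))]
        rows.append((pep, sample, study))
    n_decoy = int(round(config.fdr_like_fraction * n_true))
    if n_decoy:
        decoy_pool = sorted({
            p for aa in refprots.values()
            for p in tryptic_peptides(aa[::-1], config.max_missed_cleavages,
                                      *config.peptide_len_bounds)
            if not _collides(p, foreign_space)})
        for j in rng.choice(len(decoy_pool), size=min(n_decoy, len(decoy_pool)),
                            replace=False):
            sample, study = samples[int(rng.integers(len(samples)))]
            rows.append((decoy_pool[int(j)], sample, study))

    peptides = pd.DataFrame(sorted(set(rows)),
                            columns=["peptide", "sample", "source_study"])

    mosaics = []
    seen = set()
    for e in gt_events:
        mos = e.get("mosaic")
        if mos and e["transcript_id"] not in seen:
            seen.add(e["transcript_id"])
            mosaics.append({"transcript_id": e["transcript_id"], **mos,
                            "junction_peptides": [
                                g["peptides"] for g in gt_events
                                if g["transcript_id"] == e["transcript_id"]]})
    gt = {
        "seed": used_seed,
        "events": [{k: v for k, v in e.items() if k != "mosaic"} for e in gt_events],
        "mosaics": mosaics,
    }
    return SimulationResult(config, used_seed, transcripts, refprots,
                            contaminants, peptides, hits, gt)


# ---------------------------------------------------------------- verification

@dataclass
class VerificationReport:
    failures: list[str]

    @property
    def passed(self) -> bool:
        return not self.failures


def verify_ground_truth(result: SimulationResult, strict: bool = False,
                        ground_truth: Optional[dict] = None) -> VerificationReport:
    """Independently re-derive every ground-truth entry from the emitted
    transcripts (direct coordinate arithmetic plus Biopython translation)
    and report any mismatch.  With ``strict`` a failure raises."""
    gt = result.ground_truth if ground_truth is None else ground_truth
    by_id = {t.transcript_id: t for t in result.transcripts}
    peptide_set = set(result.peptides["peptide"])
    failures: list[str] = []

    def translate(seq: str, start: int, end: int) -> str:
        return str(Seq(seq[start - 1:end]).translate())

    for e in gt.get("events", []):
        name = f"event {e['transcript_id']}@{e['site_nt']}{e['value']:+d}"
        tr = by_id.get(e["transcript_id"])
        if tr is None:
            failures.append(f"{name}: unknown transcript")
            continue
        seq = tr.sequence
        _, df, ds, de, _ = _parse_id(e["donor_id"])
        _, af, as_, ae, _ = _parse_id(e["acceptor_id"])
        v, site = e["value"], e["site_nt"]
        if (df - 1 + v) % 3 + 1 != af:
            failures.append(f"{name}: frame congruence violated ({df}->{af}, v={v:+d})")
            continue
        b = site - 1 - v
        if (b - ds + 1) % 3 or not (ds + 2 <= b <= de):
            failures.append(f"{name}: pre-shift boundary not on a donor codon")
            continue
        if not (as_ <= site <= ae - 2) or (site - as_) % 3:
            failures.append(f"{name}: site not on an acceptor codon")
            continue
        j = e["junction_index"]
        model = e["model_aa"]
        up = translate(seq, b - 3 * j + 1, b)
        down = translate(seq, site, site + 3 * (len(model) - j) - 1)
        if up + down != model:
            failures.append(f"{name}: model sequence does not re-derive "
                            f"({up}+{down} != {model})")
        if "*" in model or "*" in translate(seq, as_, ae):
            failures.append(f"{name}: stop codon inside a planted region")
        for pep in e["peptides"]:
            i = model.find(pep)
            ok = False
            while i != -1:
                if i < j < i + len(pep):
                    ok = True
                    break
                i = model.find(pep, i + 1)
            if not ok:
                failures.append(f"{name}: peptide {pep} does not span the junction")
            if pep not in peptide_set:
                failures.append(f"{name}: peptide {pep} missing from the emitted list")

    for mos in gt.get("mosaics", []):
        tid = mos["transcript_id"]
        tr = by_id.get(tid)
        if tr is None or tr.reforf_span is None:
            failures.append(f"mosaic {tid}: transcript or refORF missing")
            continue
        s, eref = tr.reforf_span
        (s1, s2), (v1, v2) = mos["sites"], mos["values"]
        seq = tr.sequence
        rebuilt = (translate(seq, s, s1 - 1 - v1)
                   + translate(seq, s1, s2 - 1 - v2)
                   + translate(seq, s2, eref))
        if rebuilt != mos["mosaic_aa"] or "*" in rebuilt:
            failures.append(f"mosaic {tid}: assembled sequence does not re-derive")
        if (v1 + v2) % 3 == 0 and len(rebuilt) != len(mos["annotated_aa"]):
            failures.append(f"mosaic {tid}: net-zero pair does not conserve length")

    report = VerificationReport(failures)
    if strict and failures:
        raise SimulationError("ground truth verification failed:\n  "
                              + "\n  ".join(failures))
    return report


def _parse_id(identifier: str) -> tuple[str, int, int, int, int]:
    if identifier.endswith("|refProt"):
        raise ValueError("expected an ORF identifier")
    locus, frame, start, end, length = identifier.rsplit("|", 4)
    return locus, int(frame[0]), int(start), int(end), int(length)
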