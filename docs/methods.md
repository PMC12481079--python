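# Methods

## Model and coordinate conventions

All coordinates are 1-based and inclusive in transcript space. The three
forward frames are labelled `1F`–`3F`; frame `f` of a position `p` is
`((p − 1) mod 3) + 1`. Only forward frames are scanned for ORFs (reverse
frames are irrelevant for translation of a transcript, though the
alternative-source scanner does search reverse-complement frames of a
sequence database, where repeat elements can act through either strand).

An **altORF** is a maximal run of consecutive non-stop complete codons of
at least `min_len_nt` nucleotides (default 60, i.e. ≥ 20 aa, the shortest
length at which protein-level alignment statistics remain usable). No start
codon is required: translated ORFs without any ATG are documented, so an
altProt may begin with any residue. Codons containing `N` translate to `X`
and are treated as non-stop under the default policy (`break` terminates
the region instead); reference assemblies contain rare `N`s and silently
splitting regions there would be a larger distortion than an `X` residue.

The **refORF** of an mRNA is taken from the annotation. Its span covers
the coding codons only; the stop codon immediately follows it. Spans that
include the trailing stop are trimmed by one codon; internal stops are
rejected.

A **PRF event** with value `v` (negative = backward slippage re-reading
`|v|` nt, positive = forward slippage skipping `v` nt) satisfies the frame
congruence `f′ = ((f − 1 + v) mod 3) + 1`. `site_nt` is the first
nucleotide of the first post-shift codon, so the last donor codon ends at
`site_nt − 1 − v`; the inter-site distance of an event pair is
`site₂ − site₁`. This convention makes net-zero round trips conserve
protein length exactly, which is the property the mosaic analysis relies
on. Events are enumerated at every admissible donor codon boundary that
leaves at least one complete codon on each side, so enumeration density is
bounded by the overlap length in codons. Within overlaps only
`v ∈ {−2, −1, +1, +2}` is considered; for each ordered frame pair exactly
one negative and one positive value are admissible. ORFs separated by a
1–10 nt gap are additionally bridged by a single forward event of value
equal to the gap, attached at the donor's final codon boundary — the only
coherent position for a hop across a gap.

A **chimeric model** translates 20 donor codons before the shift and 20
acceptor codons from the site (both configurable, truncated at the ORF
boundaries), capping models at 40 aa. A stop in the downstream window
trims the model (`stop_policy="trim"`) or discards it (`"drop"`); models
shorter than `min_model_aa` (default 8, the shortest confidently
identifiable tryptic peptide) are discarded. Models of the same event
(transcript, site, value) are kept once with provenance flags merged —
preferring the refORF-involving description when an event was also modeled
through the enclosing same-frame altORF — and identical sequences are
grouped while retaining all source events.

**Round-trip compatibility** of an ordered event pair requires mirrored
frames (donor of one = acceptor of the other). The frame arithmetic admits
a return to the original frame exactly when `(v₁ + v₂) mod 3 = 0`; the
net-zero subset (`v₂ = −v₁`) additionally conserves length. Bridge-frame
stop codons are counted over complete codons of the first event's acceptor
frame with start ≥ site₁ and end ≤ site₂ − 1 (the region the mosaic bridge
would translate). Assembly is anchored on the annotated refORF start;
transcripts without a refORF receive compatibility assessment only. The
reported differing segment strips the common prefix and suffix of mosaic
and annotated protein and reports the remainder's 1-based start and length
on the mosaic; the coverage gap counts mosaic residues between the
outermost supporting-peptide footprints covered by neither peptide.

## Attribution semantics

Trypsin cleaves C-terminal to K/R except before P; up to two missed
cleavages and an 8–30 aa length window are the defaults. The search
database labels every entry refProt / altProt / chimeric / contaminant and
pairs it with a reversed decoy. A peptide's verdict follows a strict veto
order: any contaminant, refProt or altProt containment decides the verdict
(in that order) because a peptide explainable by a conventional protein —
possibly differing only in residues MS cannot resolve — must not count as
frameshift evidence. Only a match spanning a model's junction with at
least one residue on each side (configurable flank) is
`chimeric_specific`; a non-spanning chimeric match is `ambiguous`.
Isoleucine/leucine are distinct by default with an equivalence switch,
since MS cannot separate them but sequence databases can. Spectral
searching itself (search engines, FDR estimation from spectra) is outside
this package: identified-peptide lists are inputs, and the decoy machinery
exists so synthetic lists can carry decoy-derived noise at a chosen rate.
The shuffle-and-chunk two-step plan (ten near-equal chunks, seeded,
studies never pooled) is provided for database-inflation control and is
exercised by tests, while the desk-scale pipeline searches in one step.

For category statistics, observations are counted per peptide and PRF
value: a peptide supporting several neighbouring models of the same value
is one observation. Expected counts are proportional to non-redundant
model counts per category after dropping the "other" (gap-bridging)
group, which never receives junction-spanning support. Chi-square is used
when all expected cells are ≥ 5; otherwise the exact binomial (1×2), exact
multinomial (1×k; enumerated when the outcome space is ≤ 2·10⁵, else
seeded Monte-Carlo), or Fisher's exact test (r×c; scipy for 2×2, margin
enumeration when bounded, else a seeded simulated p-value) is applied. All
p-values are two-sided; exact tests use the minimum-likelihood rule with a
1 + 1e−9 relative tolerance, matching the conventional R implementations.

## The synthetic generator

The generator emulates the statistical structure of the real inputs, not
their biology: per-type transcript length bounds bracket the median
lengths of the four RNA types in a plant transcriptome (mRNA ~1.3 kb,
ncRNA ~0.4 kb, rRNA ~120 nt, tRNA ~75 nt) while transcript *counts* are
desk-scale (12/6/4/4 by default) so a full study simulates and analyses in
seconds. Each mRNA carries one stop-flanked refORF starting with ATG.
Planted events back-translate a designed amino acid segment into the
shifted frame inside the refORF, rejection-sampling synonymous codons
until the refORF frame stays stop-free across the overlap; tryptic sites
are placed in the designed segment (an R four residues after the junction,
and for round trips a K/R five residues before the second shift) so each
junction yields a digestible junction-spanning peptide. Every planted
event is then verified through the package's own extraction, modeling and
digestion code, and its junction peptide is checked against all
single-frame translations so the attribution veto cannot remove it; a
transcript that fails any check is regenerated within a bounded retry
budget. The planted value mix (−2: 0.30, −1: 0.28, +1: 0.14, +2: 0.28)
reflects the observed overrepresentation of backward and two-nucleotide
shifts. Identified-peptide lists combine the planted junction peptides,
per-sample draws from each refProt's tryptic peptides, optional
altProt-specific peptides, random-sequence noise, and decoy-derived noise
at `fdr_like_fraction` (default 0.01, the conventional peptide-level FDR).
A synthetic hit table marks planted altProts (plus a 10 % background) as
conserved so the modeling basis finds them. All outputs are byte-identical
under a fixed seed.

What passing tests on this generator do **not** show: realistic spectral
noise, retention behaviour, peptide detectability biases, shared-peptide
protein inference, splice/edit/polymorphism confounders, or genome-scale
search-space inflation. The generator's decoy noise probes only the
attribution veto logic, not FDR control in a spectral search.

`verify_ground_truth` re-derives every planted entry with independent
coordinate arithmetic and Biopython translation, and fails loudly (naming
the event) on any tampering — site shifts, stop injections, or missing
peptides.

## Numerical and design choices

- Identifier format `locus|frame|start|end|length` round-trips exactly
  even when locus ids contain `|` (parsed from the right).
- Conservation thresholds are inclusive (pident ≥ 70, e-value ≤ 1e−3) and
  configurable; no coverage threshold is applied.
- The refProt-identity filter removes exact full-length matches only;
  substring containment is left to the attribution veto, which handles it
  at peptide resolution.
- Chains of ≥ 3 events are assessed pairwise only; chained assembly is out
  of scope (multi-event mosaics beyond a pair are reported as their
  compatible pairs).
- Problem sizes in tests: the oracle-equivalence suite uses 500 random
  transcripts ≤ 300 nt; the end-to-end suite runs 200 seeds of a reduced
  configuration (4 mRNA of 450–700 nt, 2 planted events, every fourth seed
  with random/decoy noise) — sizes chosen to keep each property suite in
  the tens of seconds while leaving planted-event recovery exact.
- Known limitations: attribution is exact-substring (no mass-tolerant or
  modified matching); gap-bridging events beyond +10 nt and overlap values
  beyond ±2 are excluded by design; expression-based ranking of
  alternative sources is not modeled.
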