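# Methods

## The problem

A pair of SpCas9 nickases (D10A or H840A) directed to opposite strands of
a locus converts two single-strand nicks into a double-strand break (DSB)
whose end structure depends entirely on cut-site geometry.  DSBs with
complementary 5′ overhangs are repaired mutagenically with good
efficiency; 3′-overhanging ends are not, unless a 3′→5′ exonuclease such
as TREX2 (free, or fused to the nickase) removes the protruding strands.
`nickpair` implements the desk side of this system: target discovery, the
overhang geometry of any nick pair, a rule-based model of whether the
*second* nick of an overlapping pair can still be induced, indel calling
from amplicon reads, and nick-anchored deletion-spectrum analysis, plus a
seeded simulator that generates data with the structure those analyses
assume.

## Cut-site geometry

Coordinates are 0-based, half-open, on the plus strand; a nick junction
`j` lies between reference indices `j−1` and `j`.  A target is a 20-nt
protospacer followed by an NGG PAM (23-bp footprint; only canonical NGG is
accepted).  Both nickase variants cut at the canonical blunt junction
3 bp 5′ of the PAM, i.e. between spacer positions 17 and 18 (the RuvC
nick is modelled blunt-equivalent; no staggered RuvC cutting).  D10A nicks
the target strand (the strand base-paired with the sgRNA), H840A the
nontarget, PAM-bearing strand.  For two nicks on opposite strands,
polarity follows from junction order: plus-strand junction left of the
minus-strand junction ⇒ 5′ overhangs; right of it ⇒ 3′ overhangs; equal ⇒
blunt; overhang length = inter-nick distance.  Two same-strand nicks make
no DSB and are reported as `same_strand`.

Sliding two 23-bp targets through every 1-bp offset gives the closed
forms the engine is tested against: for D10A on overlapping PAM-facing
targets, overhang = 12 − overlap (blunt exactly at 12-bp overlap, 3′
overhangs up to 11 nt); for H840A the two branches give
overhang = overlap − 12 (overlap 12–23) and 34 − overlap (overlap 1–23),
with a 33-nt maximum and a 23-bp maximum overlap at full coincidence.

One geometric fact worth knowing: in the D10A PAM-facing series, overlaps
of 1–3 bp require one reference base to satisfy both a plus-strand `GG`
and a minus-strand `CC` simultaneously.  These placements exist as
coordinate geometry (and the sliding-series identities above include
them) but cannot be realised by any real sequence; `make_reference`
raises `GeometryError` for them.

An H840A nick frees the PAM-distal portion of the nontarget strand that
the bound Cas9 has unwound: 20 − 3 = 17 nt for a 20-nt spacer.  A D10A
nick frees nothing (its cut strand is the target strand).

## Sequential-nicking viability

Overlapping targets cannot be bound simultaneously, so nicking must be
sequential, and the first nick can defeat the second binding/cleavage
event.  All distances below are nt along the relevant strand between the
first nick junction and the proximal edge of the second PAM; positive
means the nick lies inside the region the second complex must unwind.
Rules are applied in order:

| rule | condition | outcome |
|---|---|---|
| R1 | nick at/inside the second 3-bp PAM (distance −3…0) | nonviable |
| R2 | D10A pair, nick on second's nontarget strand ≤ 17 nt from PAM | nonviable |
| R3 | H840A pair, nick on second's target strand ≤ 17 nt from PAM | nonviable |
| R4 | H840A first nick with TREX2: resection of the released 17-nt 3′ segment extends the gap toward the second PAM; intact pairing = distance − depth; < 18 nt ⇒ nonviable |

Defaults: pairing threshold 18 nt (of the 20-nt spacer), released segment
17 nt, free-TREX2 resection 5–8 nt (worst case 8, the 5-nt minimum
selectable via `use_free_min_as_worst_case`), fused-TREX2 resection
modelled as exactly 9 nt (its lower bound — the least assumption that
reproduces the fused-mode failures).  R4 only applies to H840A first
nicks: a D10A nick creates no released 3′ substrate.  Distances beyond
the PAM's far side (< −3) do not interact.  These constants yield the
model's worked identities: minimum viable distance 18 + 8 = 26 nt under
free TREX2; 22 nt fails (22 − 5 = 17 < 18) while 26 nt passes
(26 − 8 = 18); a fused nuclease kills the 26-nt case (26 − 9 = 17).

Both nicking orders are evaluated and a pair counts viable if either
order is; the model is categorical (no binding-order kinetics, no
modelling of Cas9 shielding the released strand from TREX2).

A pair is predicted *stimulable* by TREX2 iff it is viable, leaves 3′
overhangs, and its inter-nick distance falls in the empirically robust
13–96 bp window; narrower per-locus sub-windows (14–81, 29–86, 13–43,
34–96 bp) are attached as annotations, not filters.

## Indel calling

Reads are globally aligned (end-anchored) to the amplicon with affine
gaps: match +2, mismatch −3, gap open −6, gap extend −1 (a gap of length
L costs 6 + (L−1)); these are conventional amplicon settings and are
configurable.  Alignment uses Bio.Align.PairwiseAligner; the test suite
checks it against an independent Gotoh dynamic programme with traceback
on randomized instances.  Gaps map to deletion intervals and insertion
events; every indel is left-aligned (deletions shifted to the lowest
coordinate, insertions rotated through flanking repeats) so that all
shift-equivalent placements in a repeat collapse to one representative —
canonicalization is idempotent.  Classes: `unedited` (substitutions
only), `deletion`, `insertion`, `deletion_plus_insertion` (one insertion
plus deletions), `complex` (two or more insertions), `low_quality`
(mean Phred < 20 at Phred+33, or length < 30 nt).  The
deletion-plus-insertion/complex split is this package's taxonomy.

Equal-length reads with ≤ 2 mismatches skip the dynamic programme: under
the default scoring an alignment containing an insertion–deletion pair
loses ≥ 14 relative to the diagonal while ≤ 2 mismatches cost ≤ 10, so
the shortcut is provably score-identical, not a heuristic.

A read counts as *edited* iff it carries an indel of ≥ `min_indel_nt`
(default 1) intersecting the analysis window (CLI default: nicks ± 20 bp).
Indel frequency = (edited/total)/transfection_efficiency, capped at 1.

## Junction spectra

Given nick junctions NickA < NickB, each deletion-bearing read is
anchored at the nick nearest one of its deletion boundaries (within
`boundary_tol_nt`, default 1); the signed length is the extent of the
other boundary toward (+) or away (−) from the second nick.  Reads whose
boundaries sit on both nicks anchor to NickA (junction plots
conventionally show both anchorings; single assignment needs a
deterministic tie-break).  Reads
with no boundary near either nick are `unassigned` and binned at 0.
Spectrum frequencies support both denominators (total or edited reads);
with the edited denominator, spectrum mass plus the non-deletion edited
classes sums to 1.

Summary metrics over edited reads: full-removal % (deletion union covers
the whole inter-nick span; the near-full variant tolerates
`near_full_tolerance_nt`, default 3 nt, and is monotone in it), precise
deletion fraction (exactly nick-to-nick, no insertion — always a subset
of full removals), and median deletion length (total deleted nt per
read; by default over deletion-bearing reads, switchable to all edited
reads since the convention is ambiguous).  Multi-deletion reads
contribute the sum of their deleted nt.  With zero edited reads all
summary fields are `None`, never fabricated zeros.

Fold change between conditions is a plain ratio of indel frequencies
(undefined, not infinite, at zero control).  The stimulation-vs-overhang
regression is ordinary least squares with Pearson R and its exact
two-sided p from the t transform with n−2 df (scipy.stats.linregress).

## The simulator

`make_reference` plants two targets with an exactly requested geometry
(non-overlapping PAM-in/PAM-out at a given inter-nick distance, or
overlapping at a given overlap/overhang) into a random background, then
scrubs incidental GG/CC dinucleotides so the planted pair are the only
NGG hits — discovery and windowed calling are then deterministic in the
requested geometry.  Planted sites are re-validated through the geometry
engine before use.

`simulate_reads` draws each read independently: unedited with probability
1 − edit_rate; otherwise one mixture component — `nick_local` (deletion
starting at a uniformly chosen nick, Geometric(p=0.2) length ≥ 1,
toward/away 50/50), `full_span` (deletion covering the inter-nick
interval, overshooting each side by Geometric(p=0.5) − 1 nt), or
`insertion` (1–6 random nt at a nick) — then uniform per-base
substitution error (10⁻³) on the full-amplicon read with constant Q30
qualities.  Geometric laws are the minimal, testable choice; the true
overshoot law of resection tails is not identified by the data the
analyses consume.  Deletions are clamped to keep ≥ 1 anchoring base at
each read end.  One `default_rng` stream per run; same seed ⇒
byte-identical FASTQ.

Presets (fixed study conditions, not fits): `EV_like` edit_rate 0.03 with
weights nick_local/full_span/insertion = 0.75/0.10/0.15; `TREX2_like`
0.30 with 0.25/0.65/0.10; `fused_like` 0.35 with 0.15/0.75/0.10.  They
emulate the qualitative contrast between control spectra (nucleotide loss
around single nicks) and exonuclease-driven spectra (full or near-full
inter-nick removal).  The simulator omits PCR duplicates, chimeras,
quality-dependent errors and paired-end structure, so passing recovery
tests demonstrate correctness of the analysis chain under the stated
error model, not robustness to every real-data artefact.

## Verification choices and problem sizes

* Geometry and scanning are property-tested against exhaustive
  brute-force oracles (regex-style scans, per-base nick enumeration, a
  strand-separation simulation, exhaustive pair double-loops) on
  randomized references (100 seeds at 500 bp).
* The caller is compared to the Gotoh oracle on 1,000 randomized ≤120-bp
  instances with planted single indels; zero mismatches after
  canonicalization are required.  For planted single indels the optimal
  alignment is unique up to shift-equivalence under this scoring, so
  exact recovery is the correct expectation, not an approximation.
* Pipeline parameter recovery runs every preset at n = 10,000 reads for
  20 fixed seeds over a 200-bp amplicon with 40 bp between nicks, and
  requires the edit rate, near-full-removal fraction and median deletion
  length to land inside central 99% sampling bands in ≥ 19/20 runs.  The
  99% level is chosen so the 19/20 rule has ~98% power per metric: with
  95% bands a correct pipeline misses ~1 run in 20 by construction and
  the check would reject correct code about a quarter of the time.  The
  median band maps the binomial order-statistic interval through the
  exact mixture pmf of deleted lengths.
* With substitution error set to zero, calls must equal ground truth
  exactly (canonical placement), read by read.

## Known limitations

* Only canonical NGG PAMs and single-variant pairs; mixed D10A+H840A
  pairs are rejected, and no other nucleases are modelled.
* Viability is categorical; it does not model nick religation, binding
  kinetics, or R-loop shielding of the released strand.
* The caller is single-amplicon and single-end: no genome mapping,
  paired-end merging, UMIs, or quality recalibration.
* Empirical editing efficiencies and fold stimulations measured in cells
  depend on cell biology and are outside what this package computes.
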