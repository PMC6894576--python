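# Methods

This note documents the models and procedures implemented in
`codonpause`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the package's known
limitations.

## Codon usage and classification

RSCU is computed per synonymous family: observed count divided by the
count expected under equal synonym usage, so family values always
average to 1. Two estimator details matter:

- **Empty families are undefined, not zero.** A family with no
  observations yields `None` for every member rather than a silent 0/0
  → NaN. An additive pseudocount (default 0) is available for small
  gene sets; with it, every family is defined.
- **Terminal stop codons** are counted under their stop triplet but can
  never enter a family total, since stop codons have no synonymous
  family. Internal stops are a validation error, reported with the
  codon index.

Classification against a HEG-derived RSCU table: non-optimal ⇔
RSCU_HEG < 1; rare ⇔ RSCU_HEG ≤ 0.5 (the default threshold is chosen to
cover codons commonly described as "very rarely used", e.g. values near
0.5 and below, and is configurable); optimal = the unique family member
with RSCU_HEG > 1 of maximal value — on a tie, the family has no optimal
codon. Single-codon families (Met/ATG, Trp/TGG) are excluded from all
three classes: with one synonym, RSCU is 1 by definition and carries no
usage information. The statistical over-representation tests sometimes
used to define optimal-codon sets from expression data are out of scope;
when such a set exists for the organism, its RSCU table can be supplied
directly and the classification rule reduces to reading it.

## Alignment and back-translation

Coordinates are 1-based residue/codon positions with closed intervals
throughout. Back-translation follows tranalign semantics: every aligned
residue is replaced by the codon that encodes it in that species' CDS
(checked by re-translation; the first mismatching residue is reported),
residue gaps become `---`, and terminal stop codons are stripped first —
a protein alignment never encodes the stop.

External protein alignments (FASTA or Clustal) are the primary input.
The built-in aligner exists so fixture-scale pipelines need no external
tool: global pairwise Needleman–Wunsch with affine gaps (Gotoh's three
matrices), BLOSUM62, gap open 10, gap extend 1, where a gap of length k
costs `open + (k−1)·extend`. Pairwise alignments to a centre sequence
(the longest input; first on ties) are merged star-wise with the
once-a-gap-always-a-gap rule; insertions relative to the centre are
left-aligned within their slot. Traceback prefers diagonal over up over
left, making output deterministic. This is not a progressive aligner
and does not try to reproduce any particular MSA tool's output; for the
screen's purposes only the reference species' self-coordinates matter,
which any sensible alignment preserves.

## Topology

TMS prediction is a hydropathy stand-in for dedicated HMM predictors,
suitable for single-pass sanity checks and for synthetic data; external
predictions can be loaded from TSV and used identically downstream.

Defaults: Kyte–Doolittle scale, window 19 (the classic choice for
membrane-spanning helices), threshold 1.6, minimum segment length 15,
merge gap 3. Segment calling proceeds in four steps: (1) maximal runs
of residues whose windowed mean ≥ threshold; (2) each run extended
outward while the **raw** per-residue value stays ≥ threshold; (3) runs
separated by ≤ merge-gap residues merged; (4) merged runs shorter than
the minimum discarded. The extension step is load-bearing: a centred
mean erodes a hydrophobic block by up to half a window at each end (a
21-residue block between strongly hydrophilic flanks yields an
above-threshold run of only ~13 residues), which would both misplace
boundaries and fail the length filter. Extension by the raw value
restores the physical block boundaries; because the raw-value criterion
uses the same threshold, raising the threshold still never increases
total predicted length (monotonicity).

Offsets to the first TMS are signed residue differences
(`position − first_TMS_start`): negative = N-terminal of the TMS, 0 =
its first residue.

## Conserved-site detection

Per alignment column, the profile records each species' codon and its
RSCU_HEG, plus the cross-species mean and **population** SD (divide by
n; stated in output headers). A conserved non-optimal site is a column
where every species' codon has RSCU_HEG < 1; the default policy demands
a gap-free column, since an indel region makes "the same position"
ill-defined. Both knobs relax: `min_fraction` below 1.0 allows a
fraction of species to deviate, `require_gap_free=False` evaluates
non-gap species only, and `require_rare` additionally demands
RSCU_HEG ≤ the rare threshold in every species. Adjacent sites are
grouped into maximal runs. The batch scanner keeps sites whose TMS
offset lies in a window of [−10, +5] by default — wide enough to cover
sites at the N-terminus/TMS boundary (offsets around −2…0) reported for
urea, glucose and nitrate transporter genes — and skips families with
no detectable first TMS, recording the reason.

Under a null model where each species independently uses a non-optimal
codon with probability p, the expected number of conserved sites in L
gap-free columns is `L·p^N`; the acceptance suite verifies the detector
against this closed form (N=8, p=0.3, L=500, 200 simulations, 3
standard errors).

## Codon-pair screen

`codon_pair_gg_junction` flags pairs matching `nnGGnn` — the first
codon ends with G and the second starts with G — a junction class that
is genome-wide under-represented. This is the screen's rationale for
why an upstream Gln position retains CAA rather than the optimal CAG
when followed by a glycine GGN codon.

## mRNA window structure screen

The window spans 100 nt upstream of the ATG through 250 nt downstream
(truncation at sequence ends is flagged). Folding is a Nussinov-style
weighted maximum-pairing DP: allowed pairs GC (weight 3), AU (2), GU
(1), minimum hairpin loop 3. The score is a heuristic proxy for
structure content — **not** a free energy; temperature-dependent
nearest-neighbour thermodynamics are deliberately out of scope. The
screen's deliverable is differential: for a wild-type/synonymous-variant
pair it reports Δscore and the base-pair distance between the two
predicted structures, which is the decision such predictions are used
for (did the synonymous change plausibly rearrange structure near the
start codon?). Traceback is deterministic: the 5′ base of a subproblem
is paired with its smallest admissible partner achieving the optimum,
else left unpaired.

## Synthetic data

The generator emulates the study design: N orthologous CDS (default 8)
encoding one shared 120-residue protein whose residues are strongly
hydrophobic (F/I/L/V) inside a single TM block (default [26, 46]) and
strongly hydrophilic (D/E/K/N/Q/R) elsewhere, with an ATG initiator.
The two pools are chosen so the topology defaults always recover the
planted block: inside KD ≥ 2.8, outside ≤ −3.5.

Codon choice follows a two-regime usage model. Per multi-codon family
one codon is "elevated"; the HEG regime gives it weight
`bias + (1−bias)/k` (default bias 0.8), the background regime half the
bias (`bias/2`). The half-strength background reflects that ordinary
genes in translationally selected genomes still favour optimal codons,
only less sharply than HEGs — a pure-uniform background would make
three quarters of all drawn codons non-optimal and the conserved-site
signature meaningless at N=8. The canonical model pins Gln→CAG and
Gly→GGT as elevated, matching the known optima of the *Aspergillus*
organisms the screen models, so the canonical planted codons CAA and
GGG are rare under the HEG regime; other families are seed-random.

Planted sites carry fixed codons in every species (positions 24–25 with
CAA/GGG in the default fixture, i.e. offsets −2/−1 to the TMS start) and
can be eroded with a per-species `divergence` probability, re-drawing
from the background or substituting the optimal synonym. An indel
option deletes residues per non-reference species outside the TM and
planted neighbourhoods, to exercise gap handling; the reference species
is never gapped, so alignment columns equal reference codon positions.
All draws come from one seeded generator in a documented order (protein,
then per-species codons, then indels), so artifacts are byte-identical
across runs.

What the generator does **not** emulate: phylogenetic structure (species
are i.i.d. given the shared protein — no tree, no substitution model),
amino-acid divergence, multiple TM segments, introns/UTR structure, and
genome-scale covariates of codon bias (GC content, expression
gradients). Passing the planted-recovery tests therefore demonstrates
the pipeline's correctness and calibration under its own assumptions,
not performance on real genomes, where alignment error, paralogy and
non-equilibrium usage add noise the model does not contain.

## Problem sizes and numerics

Test and acceptance runs use deliberately compact problem sizes chosen
to exercise every code path: synthetic HEG sets of 200–300 genes
(~90k codons, enough for the RSCU estimator to sit within ~0.06 of the
model's implied values), 1,000 random families for back-translation
round trips, exhaustive-enumeration oracles for both DPs (all short
sequences, plus seeded random mid-length samples), and 200 simulations
for false-positive calibration. Floating-point comparisons in DP
tracebacks use a 1e−9 tolerance; RSCU values are exact rationals in
floating point. Ties are broken deterministically everywhere (documented
per algorithm above), and every stochastic artifact is a pure function
of its seed.

## Known limitations

- The hydropathy TMS caller has no inside/outside orientation, no
  signal-peptide discrimination, and will fuse closely spaced helices;
  supply external topology for serious use.
- The fold score ranks structure content; it cannot compare across
  sequences of different composition and says nothing about kinetics or
  temperature.
- The optimal/non-optimal rule is a threshold on RSCU_HEG; organisms
  with weak translational selection need an externally validated
  optimal-codon set instead.
- The star aligner is fixture-grade; real orthologue sets should be
  aligned with a dedicated MSA tool and imported.
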