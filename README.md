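# codonpause

Comparative codon-usage screening for **conserved non-optimal codon sites
in membrane-protein genes** — candidate mRNA-encoded translational
pauses near the first transmembrane segment (TMS).

## The problem

Synonymous codons are used unevenly. Codons over-represented in highly
expressed genes (HEGs) are translated fast and accurately ("optimal"
codons); under-represented synonyms are "non-optimal" and slow. In
polytopic membrane proteins, clusters of non-optimal codons have been
proposed to program local slowdowns of the ribosome that give the signal
recognition particle and the membrane-targeting machinery time to engage
the nascent chain. A tell-tale signature is a codon-alignment column
where *every* orthologue keeps a non-optimal codon — synonymous
conservation that amino-acid conservation cannot explain — sitting just
upstream of the first TMS.

`codonpause` implements that screen end to end:

1. **RSCU** — relative synonymous codon usage. For codon $c$ in a
   synonymous family $F$:

   $$\mathrm{RSCU}(c) = \frac{n_c}{\tfrac{1}{|F|}\sum_{c' \in F} n_{c'}}$$

   RSCU measured on a HEG set classifies codons: $\mathrm{RSCU}_{HEG} > 1$
   → optimal, $< 1$ → non-optimal, $\le 0.5$ → rare (configurable).
2. **Codon alignment** — a protein MSA (external, FASTA/Clustal, or the
   built-in Needleman–Wunsch star aligner) back-translated to the known
   coding sequences, one codon per aligned residue (tranalign
   semantics).
3. **Conserved-site detection** — columns where 100% of species use a
   non-optimal codon (fraction and rarity configurable), grouped into
   runs of adjacent columns.
4. **Topology** — first-TMS prediction from a Kyte–Doolittle hydropathy
   window (or externally supplied segments), and signed residue offsets
   of each site to the first TMS start.
5. **Codon-pair screen** — flags junctions matching the avoided
   `nnGGnn` pattern (first codon ends in G, second starts with G).
6. **mRNA structure screen** — folds the window 100 nt upstream to
   250 nt downstream of the ATG for wild type vs a synonymous variant
   with a weighted maximum-pairing dynamic programme (a heuristic
   structure score, not a free energy) and reports the score change and
   base-pair distance.
7. **Synthetic data** — orthologue families with a biased codon-usage
   model, one hydrophobic segment and planted conserved rare codons at
   known positions, so the whole pipeline is testable without any
   downloads.

## Worked example

Generate the canonical synthetic family — 8 species, a 120-residue
protein with a TMS at residues 26–46, and the rare codons CAA/GGG
planted at positions 24–25 — then scan it:

```sh
codonpause simulate --seed 7 --out-dir demo
codonpause scan --cds-dir demo/cds --msa demo/protein_msa.fasta \
    --heg-fasta demo/heg.fasta --reference-species sp01 \
    --out-prefix demo/ureA_like
# 2 conserved non-optimal sites in 1 runs
```

`demo/ureA_like.sites.tsv` (per-species codon columns omitted):

```text
column  reference_position  tms_offset  all_rare  mean_rscu  sd_rscu
24      24                  -2          True      0.2158     0.0000
25      25                  -1          True      0.1989     0.0000
```

Read: the two planted columns — and nothing else — are recovered as
100%-conserved rare-codon sites. Both lie in the N-terminal boundary
region immediately upstream of the predicted first TMS (offsets −2 and
−1 relative to the TMS start at residue 26), the geometry the screen is
designed to find. `demo/ureA_like.runs.tsv` groups them into one run of
length 2, and `demo/ureA_like.profile.png` shows the per-column RSCU
profile with the cross-species mean ± SD, the TMS box and the
highlighted sites.

The same `scan` command accepts real data: a directory of per-species
CDS FASTA, a Clustal/FASTA protein alignment, an RSCU table
(`--rscu codon<TAB>rscu`) or a HEG CDS set, and optionally external TMS
coordinates (`--topology` TSV) in place of the hydropathy prediction.
`codonpause fold-screen` runs the mRNA window comparison, and
`codonpause rscu` / `codonpause backtranslate` expose the individual
stages.

## Layout

```
src/codonpause/
  genetic_code.py       standard code, codon families, normalization
  codon_stats.py        counting, RSCU, classification, substitutions
  codon_alignment.py    CDS validation, back-translation, NW star aligner
  topology.py           hydropathy profiles, TMS calling, topology IO
  conservation_scan.py  profiles, conserved-site detection, batch scan
  rna_fold.py           window extraction, max-pairing fold, comparisons
  synthetic_data.py     usage models, planted families, HEG sets
  pipeline.py           orchestration, TSV/JSON artifacts, profile plot
  cli.py                rscu / backtranslate / scan / fold-screen / simulate
docs/methods.md         model, parameters, numerical choices, limitations
```
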