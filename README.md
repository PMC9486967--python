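# srnaforge

A toolkit for **"plug and play" engineering of synthetic bacterial small
RNAs (sRNAs)**: design antisense seed regions against an annotated target
mRNA, fuse them to sRNA scaffolds with structural sanity checks, simulate
the type IIS (Golden Gate) cloning that builds the expression plasmids, and
analyze the phenotypic screen that benchmarks the resulting regulators.

It is written for microbiologists and synthetic biologists who want to
knock down a bacterial gene post-transcriptionally — e.g. silencing *acrA*
(AcrAB–TolC efflux pump) in *E. coli* to sensitize cells to the β-lactam
oxacillin — and need the full desk workflow from seed design to screen
statistics.

## The model

A prototype sRNA has two modules. The **seed region** (here 16 nt, like
RybB's) is the regulatory module: it is designed fully complementary to a
chosen window of the target mRNA. The **scaffold** (RybB: 63 nt) is the
structural module: an Hfq-binding element plus the intrinsic terminator
hairpin. A seed fused to the RybB scaffold gives a 79-nt sRNA whose
terminator occupies nucleotides 34–79; a fused seed must not disturb those
base pairs, and must itself stay single-stranded to be able to pair with
the target.

The design panel tiles the target's regulatory landmarks (display
coordinates: +1 = A of the start codon, no position 0):

* 4 nonoverlapping 16-mers over the 5′ UTR, from the TSS down into the
  Shine–Dalgarno (SD) sequence;
* 25 staggered 16-mers whose 3′ ends walk display positions −8…+17 in
  1-nt steps, classified by 3′ end into TIR (≤ −1; 8 seeds), start codon
  (+1…+10; 10 seeds) and "five codon window" (+11…+17; 7 seeds);
* 8 nonoverlapping 16-mers over the coding region anchored at codon 9
  (the last spans display +137…+152);
* 1 non-targeting wild-type control seed — 38 seeds in total.

Hybridization strength is scored as a nearest-neighbor ΔG°37 (Turner 2004
parameters) for a single contiguous helix, with an adapter to the external
IntaRNA predictor (mode H, model X) for accessibility-aware energies.
Cloning is simulated as complete type IIS digestion (BbsI: GAAGAC(2/6),
4-nt 5′ overhangs; SapI: GCTCTTC(1/4), 3-nt) followed by exhaustive
ligation-cycle enumeration; correct products lose every recognition site
and drop the mCherry/ccdB counter-selection cassette. Screen growth is
summarized by the empirical trapezoid AUC of the OD600 curve and the
effect statistic log2(AUC₊ₐᵣₐ/AUC₋ₐᵣₐ); MIC follows broth microdilution
(2.5-fold series).

## Worked example

```sh
srnaforge fixtures --out demo --seed 42
srnaforge design   --mrna demo/target.fa --ann demo/ann.yaml --out demo/panel.tsv
srnaforge score    --panel demo/panel.tsv --mrna demo/target.fa --out demo/scores.tsv
srnaforge oligos   --panel demo/panel.tsv --out demo/oligos.tsv
srnaforge assemble --acceptor demo/acceptor.gbk --oligos demo/oligos.tsv \
                   --pair s8 --out demo/product.gbk
srnaforge assay    --growth demo/plate.csv --map demo/map.csv --out demo/screen.tsv
```

prints

```
fixtures written to demo
panel of 38 seeds written to demo/panel.tsv
38 seeds scored (internal)
76 oligos written to demo/oligos.tsv
assembled product (624 bp) written to demo/product.gbk
screen summary for 4 strain/condition groups written to demo/screen.tsv
```

`panel.tsv` holds the 38 seeds with transcript/display windows and the
fused sRNA sequences; `scores.tsv` ranks them by internal duplex energy
(most negative = strongest predicted pairing; the non-targeting control
ranks last). The 624-bp `product.gbk` is the one-pot assembly product:
backbone plus the s8 seed insert, with zero remaining BbsI sites and the
counter-selection cassette dropped out. `screen.tsv` gives per-strain
mean AUCs and log2 fold-changes — in the synthetic screen the effective
sRNA strain scores log2FC < 0 under oxacillin while the control stays
positive, the signature of successful *acrA* knock-down:

```
strain   oxacillin_ug_ml  auc_plus  auc_minus  log2fc   n_replicates
control  100.0            16.069    14.805      0.118   3
sRNA-s8  100.0             5.907    14.810     -1.326   3
```

## Layout

| module | what it does |
|---|---|
| `srnaforge.seqio` | FASTA/GenBank I/O, circular records, strand arithmetic |
| `srnaforge.seed_design` | target annotation, region tiling, panel builder, scaffold registry |
| `srnaforge.hybridization` | nearest-neighbor duplex scorer, IntaRNA adapter, MFE folding, seed occlusion / terminator checks |
| `srnaforge.goldengate` | type IIS site scanning, digestion, ligation enumeration, one-pot simulation, oligo/primer design |
| `srnaforge.assay` | growth AUC, log2FC, MIC caller, fluorescence normalization, statistics |
| `srnaforge.fixtures` | deterministic synthetic targets, acceptors, growth curves |
| `srnaforge.cli` | `srnaforge` command-line workflow |
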