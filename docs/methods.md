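# Methods

## Scope and model

srnaforge implements the desk half of a synthetic-sRNA engineering
workflow for bacteria: panel design against one annotated target mRNA,
structural vetting of the seed–scaffold fusion, hybridization scoring,
in-silico type IIS (Golden Gate) cloning, and analysis of a plate-reader
benchmarking screen. Wet-lab procedures (recombineering, transformation,
blotting, proteomics) and genome-wide off-target scanning are out of
scope.

## Coordinates

Storage and arithmetic use 1-based inclusive transcript coordinates with
the transcriptional start site at 1, the GenBank convention. Presentation
uses display coordinates relative to the start codon: +1 is the A of the
ATG, upstream positions are negative, and 0 does not exist. Circular
plasmids are stored linearized with an explicit flag; site scanning,
feature extraction and fragment slicing all handle the origin seam, and
assembled circles are compared by lexicographically minimal rotation over
both strands.

## Panel design

`derive_regions` splits the transcript into 5′ UTR (1…sd_start−1), TIR
(SD through the nucleotide before the ATG), start codon, "five codon
window" (codons 2–6 by default; whether the window is codons 1–5 or 2–6
is a config choice, `five_codon_first/last`) and remaining CDS.

`build_panel` assembles, in order:

1. **UTR tiles** — nonoverlapping 16-mers anchored at the TSS over
   [1, sd_end] (`utr_tile_span_end`). Tiling through the SD rather than
   stopping just before it lets the tiles cover essentially the whole
   UTR; on the default fixture (70-nt UTR, SD at 62–65) this yields 4
   tiles ending at nt 64, the last reaching 3 nt into the SD.
2. **Staggered tiles** — one 16-mer per 3′-end display position from −8
   to +17 (25 windows at 1-nt shift), classified by 3′ end: ≤ −1 → TIR
   (8), +1…+10 → start codon (10), +11…+17 → five-codon window (7). The
   span and the two cutoffs are config keys; the defaults reproduce the
   canonical 8/10/7 split. A `None` span disables the block.
3. **CDS tiles** — nonoverlapping 16-mers anchored at codon 9 (display
   +25), 8 tiles by default (`cds_tile_count`, clipped by the available
   CDS length), so the last tile spans display +137…+152. The count is
   a config key because tiling to the end of an arbitrary CDS would
   produce however many windows fit, not a fixed screening panel.
4. One **wild-type control seed** from the registry (non-targeting).

Seed sequences are the reverse complement of the sense-strand window;
seed length defaults to 16 but is configurable (`seed_len`), since longer
seeds trade stronger pairing against a higher risk of intramolecular
structure. sids run s2… in 5′→3′ order *within* each tiling group (UTR,
staggered, CDS), mirroring conventional panel numbering; on the default
fixture the fourth UTR tile (start 49) and the first staggered window
(start 48) interleave by one nucleotide, so a single global positional
sort would break the grouped numbering. Duplicate seed sequences across
groups are kept and logged.

## Scaffolds

The registry ships **synthetic stand-in scaffolds** (RybB 63 nt, MicA
72, MicF 93, OmrB 82): an A/C-only single-stranded linker standing in
for the Hfq-binding element, a 16-bp G/C-rich terminator stem with a
6-nt loop, and a U-rich tail. The RybB-style geometry places the
terminator at scaffold nucleotides 18–63, i.e. nucleotides 34–79 of the
79-nt seed+scaffold molecule. They are labelled synthetic because the
natural scaffold sequences live in deposited plasmid records that are
not bundled here; every structural check works identically on
user-supplied natural scaffolds. The A/C linker cannot base-pair with
itself (no G/U partners), which makes the stand-ins clean test beds for
the occlusion logic; natural scaffolds have richer 5′ structure, so
passing tests on the stand-ins demonstrates the logic, not the folding
behavior of real RybB.

## Hybridization scoring

Two routes, deliberately kept apart:

* **Internal scorer** (`duplex_energy`): the best single contiguous
  antiparallel helix of ≥ 2 Watson–Crick/GU pairs between the two RNAs,
  scored as duplex initiation (+4.10 kcal/mol) + Turner 2004
  nearest-neighbor stack terms + 0.50 kcal/mol per AU/GU helix end, at
  37 °C (fixed). Sub-runs of a maximal complementary run are also
  scored, because GU-rich stacks can be destabilizing. No bulges,
  interior loops or accessibility — it is a fast screening score whose
  correctness is established by exhaustive equivalence with a
  brute-force enumeration oracle, and it is *not* expected to match
  IntaRNA's values. The parameter table is versioned in-code
  (`PARAMETER_VERSION = "turner-2004"`); on perfect complements the
  scorer agrees with ViennaRNA's `duplexfold` to within ~0.1 kcal/mol
  (end-treatment differences).
* **External adapter** (`predict_interaction`): invokes the IntaRNA
  CLI with the pinned settings (mode H, model X, lonely base pairs and
  GU helix ends allowed, 37 °C) and parses its CSV output. By default
  the full mRNA is submitted; a `window` option restricts it, since
  which window is appropriate depends on the experiment. If the
  executable is absent the adapter either raises a named error or, when
  `allow_internal_fallback` is set (default), logs a warning and
  returns the internal score marked `source="internal"`.

`rank_seeds` orders a panel by ascending energy with ties broken by 5′
target position; the non-targeting control is expected to rank last.

## Structural checks

`fold_mfe` delegates MFE folding to the ViennaRNA engine.
`occlusion_report` folds the full sRNA and reports (i) the fraction of
seed positions that are base-paired and (ii) terminator integrity: the
set of base pairs with both ends inside the scaffold's terminator region
must be identical between the full-sRNA fold and the scaffold-only fold.
A seed that sequesters itself in a 5′ stem-loop (the known failure mode
of some seed–scaffold combinations) shows a high paired fraction.

## Golden Gate simulation

Enzyme geometry: BbsI GAAGAC(2/6) — 2-nt spacer, 4-nt 5′ overhang; SapI
GCTCTTC(1/4) — 1-nt spacer, 3-nt overhang. Scanning covers both strands
and the circular seam. Fragments carry their sense-strand span including
both overhang regions, so ligation compatibility is simple string
equality of facing overhangs and total length is conserved exactly
(Σ(len − overhang) = plasmid length).

`enumerate_products` builds the directed overhang-compatibility graph
over both orientations of every fragment and enumerates simple cycles
(each fragment used at most once; concatemers from repeated compatible
overhangs surface as collision diagnostics rather than being
enumerated), up to configurable limits with a truncation diagnostic.
`simulate_one_pot` applies the fixed point of the cycled reaction:
digest the acceptor, ligate everything, and discard any circle that
still contains a recognition site (it would be re-digested) — the
religated acceptor with its counter-selection cassette falls out here.
`intended_ok` requires exactly one terminal product that lacks the
mCherry/ccdB cassette and contains every insert exactly once. Complete
digestion is assumed; ligation-fidelity thermodynamics and hierarchical
multi-level assembly are not modeled.

Oligo design produces a 4-nt-overhang annealed duplex (20-nt forward and
reverse oligos for a 16-nt seed), refuses seeds containing a recognition
site on either strand, and marks one oligo phosphorylated (required for
ligation of annealed pairs). Part primers are pad + recognition + spacer
fill + fusion site + 18-nt annealing region; in-silico PCR + digestion
round-trips to the requested overhangs. The default fusion-site set is a
placeholder passing `check_overhang_scheme` (no duplicates, palindromes,
or reverse-complement collisions); real projects supply their own scheme,
and multi-TU assemblies require one (the toolkit does not guess slot
sites).

## Assay analysis

Growth is summarized by the **empirical trapezoid AUC** of the raw OD600
series — deliberately no parametric growth-model fit, because β-lactam
filamentation produces irregular curves that defeat r/K/lag estimation.
The effect statistic is log2(AUC₊/AUC₋) of induced vs. uninduced arms.
MIC calling uses a growth threshold of 10 % of the no-drug control
endpoint (`threshold_frac`, a config key since assay setups differ),
endpoint at the final time point (24 h); a non-monotone series is
flagged and the topmost contiguous no-growth run decides. Fluorescence
is (F − F_blank)/(OD − OD_blank). Statistics are thin contracts over
scipy: Student's t-test (unpaired, equal variance) for two groups,
one-way ANOVA with Tukey HSD post-hoc for more, and Pearson's r for the
energy–phenotype correlation.

## Synthetic data generator

`fixtures` generates every input deterministically from a seeded RNG:

* **Target mRNA** — 70-nt 5′ UTR with "GAGG" SD at 62–65, ATG at 71,
  180-nt CDS ending in a stop codon (long enough to host the +137…+152
  tile), rejection-sampled free of enzyme recognition sites (capped at
  10,000 attempts). These lengths make the generated target reproduce
  the canonical 38-seed panel arithmetic without any downloads.
* **Acceptor plasmids** — 600-bp backbone (ori/marker placeholder
  features) plus a 300-bp cassette carrying mCherry/ccdB placeholder
  *labels* (not real ORFs; the simulation checks feature presence, not
  function) flanked by inward-pointing BbsI sites whose cuts expose the
  scheme's terminal fusion sites.
* **Growth curves** — logistic K/(1+((K−N0)/N0)e^(−rt)) with K = 1.0
  OD600, r = 0.5 h⁻¹, N0 = 0.01, Gaussian noise σ = 0.01, 97 samples
  over 24 h; suppressor mode adds a delayed (12 h) second logistic so
  the endpoint looks healthy while early-time AUC stays low — the
  failure mode that motivates AUC over endpoint reading. Real screens
  add well effects, drift and filamentation artifacts the generator
  does not emulate, so passing tests validate the analysis arithmetic,
  not robustness to such artifacts.

## Numerical choices and limitations

* Energies are plain float sums of table values rounded to 0.01;
  equal-energy seeds tie-break by upstream target position.
* Folding is single-sequence MFE only — no suboptimal ensembles or
  partition-function accessibility.
* `duplex_energy` returns +inf when no 2-pair helix exists; callers
  treating the sentinel as "no interaction" map it to 0 for ranking.
* The one-pot enumerator is exponential in fragment count; the default
  limits (8 fragments, 64 products) cover the intended low/medium/high
  complexity plans and the six-fragment dual-TU case.
* The panel builder assumes a single target; multi-target or
  concatenated multi-seed sRNAs are not built.
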