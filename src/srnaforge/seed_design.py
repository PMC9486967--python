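"""Seed-region panel design for synthetic small RNAs.

A synthetic sRNA is a 5' antisense *seed region* (default 16 nt, fully
complementary to a window of the target mRNA) fused to a 3' structural
*scaffold* (Hfq-binding element plus intrinsic terminator hairpin).  The
panel builder tiles the regulatory landmarks of an annotated target
mRNA the way an sRNA engineer would screen it:

* nonoverlapping windows over the 5' UTR, from the transcriptional
  start site down to the Shine–Dalgarno (SD) sequence;
* a staggered 1-nt ladder of windows whose 3' ends walk across the
  translation initiation region (TIR), the start codon, and the early
  "five codon window" of the coding sequence;
* nonoverlapping windows over the downstream coding region; and
* one non-targeting wild-type control seed.

Display coordinates follow the biology convention: position +1 is the
A of the start codon, positions upstream are negative, and 0 does not
exist.  Internal arithmetic is plain 1-based transcript coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import DesignError
from .seqio import SeqRecordX, revcomp

log = logging.getLogger(__name__)

UTR5 = "UTR5"
TIR = "TIR"
START = "START"
FIVE_CODON = "FIVE_CODON"
CDS = "CDS"
CONTROL = "CONTROL"
UNCLASSIFIED = "UNCLASSIFIED"


# ---------------------------------------------------------------------------
# annotation and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetAnnotation:
    """A sense-strand mRNA with regulatory landmarks.

    Transcript coordinates are 1-based with the transcriptional start
    site at position 1.  ``start_codon`` is the first nucleotide of the
    ATG; ``cds_end`` the last nucleotide of the coding sequence.
    """

    mrna: SeqRecordX
    sd_start: int
    sd_end: int
    start_codon: int
    cds_end: int

    def __post_init__(self) -> None:
        n = len(self.mrna)
        if self.mrna.circular:
            raise DesignError("target mRNA must be a linear record")
        if not (1 <= self.sd_start < self.sd_end < self.start_codon <= self.cds_end <= n):
            raise DesignError(
                "annotation must satisfy 1 <= sd_start < sd_end < start_codon "
                f"<= cds_end <= {n}; got SD {self.sd_start}-{self.sd_end}, "
                f"ATG {self.start_codon}, CDS end {self.cds_end}"
            )
        codon = self.mrna.subseq(self.start_codon, self.start_codon + 2)
        if codon != "ATG":
            raise DesignError(f"start codon at {self.start_codon} is {codon!r}, not ATG")
        if (self.cds_end - self.start_codon + 1) % 3:
            raise DesignError("CDS length is not divisible by 3")

    def to_display(self, pos: int) -> int:
        """Transcript position → display coordinate (+1 = A of ATG, no 0)."""
        d = pos - self.start_codon
        return d + 1 if d >= 0 else d

    def from_display(self, disp: int) -> int:
        """Display coordinate → transcript position."""
        if disp == 0:
            raise DesignError("display coordinate 0 does not exist")
        return self.start_codon + (disp - 1 if disp > 0 else disp)


@dataclass(frozen=True)
class RegionConfig:
    """Boundary rules of the default panel.

    The defaults reproduce the reference panel layout: 4 nonoverlapping
    5' UTR tiles, 25 staggered windows (3' display ends -8..+17, shift
    1) classified 8 TIR / 10 start codon / 7 five-codon, and 8
    nonoverlapping CDS tiles anchored at codon 9.
    """

    seed_len: int = 16
    # nonoverlapping UTR tiling runs from the TSS through the SD ("sd_end")
    # or only to the nucleotide before it ("sd_start").
    utr_tile_span_end: str = "sd_end"
    stagger_first_end: int | None = -8   # display coordinate of first 3' end
    stagger_last_end: int | None = 17    # None/None disables the staggered block
    stagger_shift: int = 1
    tir_max_end: int = -1          # 3' end <= this -> TIR
    start_max_end: int = 10        # -1 < 3' end <= this -> START
    five_codon_max_end: int = 17   # start_max_end < 3' end <= this -> FIVE_CODON
    cds_anchor_codon: int = 9      # CDS tiling starts at codon 9 (display +25)
    cds_tile_count: int = 8
    five_codon_first: int = 2      # "five codon window" = codons 2..6
    five_codon_last: int = 6
    strict: bool = True


DEFAULT_CONFIG = RegionConfig()


@dataclass(frozen=True)
class DesignRegions:
    """The five target regions, in transcript coordinates."""

    utr: tuple[int, int]
    tir: tuple[int, int]
    start_codon: tuple[int, int]
    five_codon_window: tuple[int, int]
    cds: tuple[int, int]


def derive_regions(ann: TargetAnnotation, cfg: RegionConfig = DEFAULT_CONFIG) -> DesignRegions:
    """Partition the transcript into the five canonical design regions."""
    utr = (1, ann.sd_start - 1)
    if cfg.strict and utr[1] - utr[0] + 1 < cfg.seed_len:
        raise DesignError(
            f"5' UTR upstream of the SD ({utr[1]} nt) is shorter than one "
            f"{cfg.seed_len}-nt window"
        )
    tir = (ann.sd_start, ann.start_codon - 1)
    start = (ann.start_codon, ann.start_codon + 2)
    fcw = (
        ann.start_codon + 3 * (cfg.five_codon_first - 1),
        ann.start_codon + 3 * cfg.five_codon_last - 1,
    )
    cds = (fcw[1] + 1, ann.cds_end)
    return DesignRegions(utr=utr, tir=tir, start_codon=start, five_codon_window=fcw, cds=cds)


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def tile_nonoverlapping(region: tuple[int, int], k: int = 16) -> list[tuple[int, int]]:
    """Nonoverlapping k-mers anchored at the region start; floor(len/k) windows."""
    if k < 1:
        raise DesignError("window length must be >= 1")
    a, b = region
    n = b - a + 1
    return [(a + i * k, a + i * k + k - 1) for i in range(max(n, 0) // k)]


def tile_staggered(
    ann: TargetAnnotation,
    first_end: int,
    last_end: int,
    k: int = 16,
    shift: int = 1,
) -> list[tuple[int, int]]:
    """Windows whose 3' ends walk display positions first_end..last_end.

    One window per visited 3'-end display position (0 is skipped);
    consecutive windows are shifted by ``shift`` nt.
    """
    if shift < 1:
        raise DesignError("shift must be >= 1")
    t_first = ann.from_display(first_end)
    t_last = ann.from_display(last_end)
    if t_first > t_last:
        raise DesignError("first_end must precede last_end in display order")
    ends = list(range(t_first, t_last + 1))[::shift]
    bad = [ann.to_display(e) for e in ends if e - k + 1 < 1]
    if bad:
        raise DesignError(
            f"windows ending at display positions {bad} would extend before the transcript start"
        )
    return [(e - k + 1, e) for e in ends]


def classify_window(
    w: tuple[int, int],
    ann: TargetAnnotation,
    cfg: RegionConfig = DEFAULT_CONFIG,
) -> str:
    """Region label from the window's 3'-end display position."""
    e = ann.to_display(w[1])
    if e <= cfg.tir_max_end:
        return TIR
    if 1 <= e <= cfg.start_max_end:
        return START
    if cfg.start_max_end < e <= cfg.five_codon_max_end:
        return FIVE_CODON
    return UNCLASSIFIED


# ---------------------------------------------------------------------------
# seeds, scaffolds, sRNAs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedRegion:
    """A 16-nt antisense module against one target window.

    ``seq`` is the antisense DNA string: revcomp of the sense-strand
    target window.  The control seed carries no target window.
    """

    sid: str
    seq: str
    region_label: str
    target_window: tuple[int, int] | None = None
    display_window: tuple[int, int] | None = None


@dataclass(frozen=True)
class Scaffold:
    """3' structural module: Hfq-binding element + terminator hairpin.

    ``terminator_region`` is an interval in scaffold coordinates
    (1-based).  For a RybB-style 63-nt scaffold carrying a 16-nt seed
    it corresponds to nucleotides 34-79 of the assembled sRNA.
    """

    name: str
    seq: str
    terminator_region: tuple[int, int]
    hfq_note: str = ""

    def __post_init__(self) -> None:
        a, b = self.terminator_region
        if not (1 <= a <= b <= len(self.seq)):
            raise DesignError(
                f"scaffold {self.name}: terminator region ({a},{b}) outside bounds"
            )


@dataclass(frozen=True)
class SyntheticSRNA:
    """seed + scaffold fusion; seed may be None for a Δseed variant."""

    seed: SeedRegion | None
    scaffold: Scaffold

    @property
    def seq(self) -> str:
        head = self.seed.seq if self.seed is not None else ""
        return head + self.scaffold.seq

    @property
    def name(self) -> str:
        tag = self.seed.sid if self.seed is not None else "dseed"
        return f"{self.scaffold.name}-{tag}"


def make_seed(
    w: tuple[int, int],
    ann: TargetAnnotation,
    sid: str,
    region_label: str | None = None,
    cfg: RegionConfig = DEFAULT_CONFIG,
) -> SeedRegion:
    """Antisense seed for the sense-strand window ``w``."""
    a, b = w
    if not (1 <= a <= b <= len(ann.mrna)):
        raise DesignError(f"window ({a},{b}) outside the transcript")
    sense = ann.mrna.subseq(a, b)
    label = region_label if region_label is not None else classify_window(w, ann, cfg)
    return SeedRegion(
        sid=sid,
        seq=revcomp(sense),
        region_label=label,
        target_window=(a, b),
        display_window=(ann.to_display(a), ann.to_display(b)),
    )


def attach_scaffold(seed: SeedRegion | None, scaffold: Scaffold) -> SyntheticSRNA:
    return SyntheticSRNA(seed=seed, scaffold=scaffold)


def build_panel(
    ann: TargetAnnotation,
    cfg: RegionConfig = DEFAULT_CONFIG,
    control_seed: str | None = None,
) -> list[SeedRegion]:
    """The full screening panel: UTR + staggered + CDS tiles + control.

    sids run s2, s3, ... in 5'→3' order of the target window within
    each tiling group (UTR, then staggered, then CDS), mirroring the
    conventional numbering; the non-targeting control is last.
    """
    regions = derive_regions(ann, cfg)
    k = cfg.seed_len

    utr_end = ann.sd_end if cfg.utr_tile_span_end == "sd_end" else ann.sd_start - 1
    utr_windows = tile_nonoverlapping((1, utr_end), k)

    if cfg.stagger_first_end is None or cfg.stagger_last_end is None:
        stag_windows: list[tuple[int, int]] = []
    else:
        stag_windows = tile_staggered(
            ann, cfg.stagger_first_end, cfg.stagger_last_end, k, cfg.stagger_shift
        )

    anchor = ann.start_codon + 3 * (cfg.cds_anchor_codon - 1)
    room = (ann.cds_end - anchor + 1) // k
    n_cds = min(cfg.cds_tile_count, max(room, 0))
    cds_windows = [(anchor + i * k, anchor + i * k + k - 1) for i in range(n_cds)]

    panel: list[SeedRegion] = []
    num = 2
    for w in sorted(utr_windows):
        panel.append(make_seed(w, ann, f"s{num}", UTR5, cfg))
        num += 1
    for w in stag_windows:
        panel.append(make_seed(w, ann, f"s{num}", None, cfg))
        num += 1
    for w in cds_windows:
        panel.append(make_seed(w, ann, f"s{num}", CDS, cfg))
        num += 1

    seen: dict[str, str] = {}
    for seed in panel:
        if seed.seq in seen:
            log.warning("duplicate seed sequence: %s == %s (kept)", seed.sid, seen[seed.seq])
        seen[seed.seq] = seed.sid

    wt = control_seed if control_seed is not None else WT_CONTROL_SEED
    panel.append(SeedRegion(sid="wt", seq=wt, region_label=CONTROL))
    return panel


# ---------------------------------------------------------------------------
# scaffold registry (synthetic stand-ins)
# ---------------------------------------------------------------------------

# Synthetic stand-in for the multi-targeting wild-type seed: registry
# data, not computed from any target.
WT_CONTROL_SEED = "ACTGGCTTACCGATGT"


def _hairpin_scaffold(name: str, linker: str, stem: str, loop: str, tail: str,
                      hfq_note: str = "") -> Scaffold:
    """Synthetic scaffold: unstructured linker + terminator stem-loop + U-rich tail.

    The terminator region is the hairpin plus tail.  These are
    deterministic synthetic stand-ins with realistic lengths, not the
    natural scaffold sequences.
    """
    seq = linker + stem + loop + revcomp(stem) + tail
    term = (len(linker) + 1, len(seq))
    return Scaffold(name=name, seq=seq, terminator_region=term, hfq_note=hfq_note)


def scaffold_registry() -> dict[str, Scaffold]:
    """Built-in scaffolds (synthetic stand-ins; lengths match the models).

    RybB-style: 63 nt, so a 16-nt seed yields a 79-nt sRNA whose
    terminator occupies nucleotides 34-79.
    """
    return {
        "RybB": _hairpin_scaffold(
            "RybB",
            linker="ACAACACACAACAACCA",            # 17 nt, A/C only: cannot self-pair
            stem="GGCAGCACCGGCAGGC",               # 16 bp terminator stem
            loop="GCAAAC",
            tail="TTCTTCTT",                       # U-rich tail, no poly-U run
            hfq_note="AU/AC-rich single-stranded linker stands in for the Hfq site",
        ),
        "MicA": _hairpin_scaffold(
            "MicA",
            linker="CACAACAACACAACAACACAACACCA",   # 26 nt
            stem="GGCAGCACCGGCAGGC",
            loop="GCAAAC",
            tail="TTCTTCTT",
        ),
        "MicF": _hairpin_scaffold(
            "MicF",
            linker="ACACAACAACAAACAACACACAACAACACAACAACACAACAACCACA",  # 47 nt
            stem="GGCAGCACCGGCAGGC",
            loop="GCAAAC",
            tail="TTCTTCTT",
        ),
        "OmrB": _hairpin_scaffold(
            "OmrB",
            linker="CACAACAACACAACAACACAACACAACAACACACCA",  # 36 nt
            stem="GGCAGCACCGGCAGGC",
            loop="GCAAAC",
            tail="TTCTTCTT",
        ),
    }
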