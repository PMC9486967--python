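"""Seed-target hybridization scoring and structural sanity checks.

Two scoring routes exist and are deliberately distinct:

* ``duplex_energy`` — a fast in-package nearest-neighbor scorer that
  models a single contiguous antiparallel helix of Watson-Crick/GU
  pairs (Turner 2004 parameters, 37 °C).  No bulges, interior loops or
  accessibility: it is a desk-testable screening score, not a
  replacement for a full interaction predictor.
* ``predict_interaction`` — an adapter around the external IntaRNA
  command-line predictor (heuristic mode H, seed-extension model X,
  lonely base pairs and GU helix ends allowed), which is the fidelity
  path when the executable is installed.

Secondary structure (``fold_mfe``) delegates to the ViennaRNA folding
engine; ``occlusion_report`` uses it to measure how much of a seed is
sequestered in the folded sRNA and whether the terminator hairpin is
unchanged by the fused seed.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
from dataclasses import dataclass, field

import RNA

from .errors import ParseError, PredictorUnavailableError
from .seed_design import SeedRegion, SyntheticSRNA
from .seqio import RNA_ALPHABET, transcribe

log = logging.getLogger(__name__)

# --- Turner 2004 nearest-neighbor parameters (kcal/mol, 37 °C) -------------
# Version: turner-2004 as rounded to 0.1 kcal/mol in the standard tables.
# STACK[(p, q)] is the free-energy increment of stacking pair q on pair p:
#     5'-x1 x2-3'
#     3'-y1 y2-5'      p = x1·y1, q = x2·y2
PARAMETER_VERSION = "turner-2004"
DUPLEX_INIT = 4.10
TERMINAL_AU = 0.50  # applied per AU or GU helix end

_PAIRS = ("CG", "GC", "GU", "UG", "AU", "UA")
_STACK_ROWS = {
    #        CG     GC     GU     UG     AU     UA
    "CG": (-2.40, -3.30, -2.10, -1.40, -2.10, -2.10),
    "GC": (-3.30, -3.40, -2.50, -1.50, -2.20, -2.40),
    "GU": (-2.10, -2.50, +1.30, -0.50, -1.40, -1.30),
    "UG": (-1.40, -1.50, -0.50, +0.30, -0.60, -1.00),
    "AU": (-2.10, -2.20, -1.40, -0.60, -1.10, -0.90),
    "UA": (-2.10, -2.40, -1.30, -1.00, -0.90, -1.30),
}
# _STACK_ROWS is indexed [p][q'] in the ViennaRNA orientation where the
# second pair is read 3'->5'; flatten to the plain (p, q) orientation:
STACK: dict[tuple[str, str], float] = {
    (p, q[::-1]): _STACK_ROWS[p][j]
    for p in _PAIRS
    for j, q in enumerate(_PAIRS)
}

CANONICAL = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def _check_rna(seq: str, name: str) -> str:
    s = seq.upper()
    if not s or not set(s) <= RNA_ALPHABET:
        raise ParseError(f"{name}: not an RNA string over A/C/G/U/N: {seq!r}")
    return s


def _helix_energy(pairs: list[tuple[str, str]]) -> float:
    """ΔG°37 of one contiguous helix given its ordered base pairs."""
    e = DUPLEX_INIT
    for (x1, y1), (x2, y2) in zip(pairs, pairs[1:]):
        e += STACK[(x1 + y1, x2 + y2)]
    for end in (pairs[0], pairs[-1]):
        if "U" in end:
            e += TERMINAL_AU
    return round(e, 10)


def duplex_energy(a: str, b: str) -> float:
    """Best single-helix hybridization energy between two RNA strands.

    Scans every antiparallel register of ``a`` (5'->3') against ``b``
    and scores every contiguous run of >= 2 canonical (WC or GU) pairs;
    returns the minimum ΔG°37, or +inf if no such helix exists.
    """
    a = _check_rna(a, "a")
    b = _check_rna(b, "b")
    br = b[::-1]  # br[j] faces a[i] in an antiparallel duplex
    la, lb = len(a), len(br)
    best = math.inf
    for off in range(-(lb - 1), la):
        i = max(0, off)
        j = i - off
        run: list[tuple[str, str]] = []
        while i < la and j < lb:
            if (a[i], br[j]) in CANONICAL:
                run.append((a[i], br[j]))
            else:
                best = min(best, _best_subhelix(run))
                run = []
            i += 1
            j += 1
        best = min(best, _best_subhelix(run))
    return best


def _best_subhelix(run: list[tuple[str, str]]) -> float:
    """Minimum energy over all length >= 2 sub-runs of a paired run.

    Needed because GU-rich stacks can be destabilizing, so the full run
    is not always optimal.
    """
    n = len(run)
    if n < 2:
        return math.inf
    best = math.inf
    for s in range(n - 1):
        for e in range(s + 2, n + 1):
            best = min(best, _helix_energy(run[s:e]))
    return best


# ---------------------------------------------------------------------------
# external predictor adapter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionSettings:
    """Pinned IntaRNA invocation (heuristic mode, seed-extension model).

    The settings mirror the reference configuration: mode H, model X,
    lonely base pairs and GU pairs at helix ends allowed, 37 °C.
    ``window`` optionally restricts the mRNA to a subsequence interval
    before prediction (default: full mRNA).
    """

    executable: str = "IntaRNA"
    mode: str = "H"
    model: str = "X"
    allow_lonely_bp: bool = True
    allow_gu_ends: bool = True
    temperature: float = 37.0
    window: tuple[int, int] | None = None
    allow_internal_fallback: bool = True
    extra_args: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class InteractionResult:
    """Predicted sRNA-mRNA hybridization, energy in kcal/mol (ΔG°37)."""

    energy: float
    srna_interval: tuple[int, int]
    mrna_interval: tuple[int, int]
    source: str  # "internal" | "external"

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise ValueError("interaction energy must be finite")


def build_intarna_args(srna_rna: str, mrna_rna: str, settings: InteractionSettings) -> list[str]:
    args = [
        settings.executable,
        "-q", srna_rna,
        "-t", mrna_rna,
        "--mode", settings.mode,
        "--model", settings.model,
        "--temperature", str(settings.temperature),
        "--outMode", "C",
        "--outCsvCols", "E,start1,end1,start2,end2",
    ]
    if settings.allow_lonely_bp:
        args += ["--outNoLP", "0"]
    if settings.allow_gu_ends:
        args += ["--outNoGUend", "0"]
    args += list(settings.extra_args)
    return args


def _internal_interaction(srna_rna: str, mrna_rna: str) -> InteractionResult:
    energy = duplex_energy(srna_rna, mrna_rna)
    if not math.isfinite(energy):
        energy = 0.0
    # intervals: best effort, the internal scorer does not track them
    return InteractionResult(
        energy=energy,
        srna_interval=(1, len(srna_rna)),
        mrna_interval=(1, len(mrna_rna)),
        source="internal",
    )


def predict_interaction(srna, mrna, settings: InteractionSettings | None = None) -> InteractionResult:
    """sRNA-mRNA interaction via the external predictor.

    ``srna``/``mrna`` may be DNA or RNA strings, or objects with a
    ``seq``/``sequence`` attribute.  If the predictor executable is not
    on PATH, the internal single-helix scorer is used with a logged
    warning when ``allow_internal_fallback`` is set, otherwise a
    :class:`PredictorUnavailableError` is raised.
    """
    settings = settings or InteractionSettings()
    srna_rna = transcribe(_seq_of(srna))
    mrna_rna = transcribe(_seq_of(mrna))
    if settings.window is not None:
        a, b = settings.window
        mrna_rna = mrna_rna[a - 1 : b]

    if shutil.which(settings.executable) is None:
        if settings.allow_internal_fallback:
            log.warning(
                "external predictor %r not found; falling back to the internal "
                "single-helix scorer (energies are NOT comparable to IntaRNA)",
                settings.executable,
            )
            return _internal_interaction(srna_rna, mrna_rna)
        raise PredictorUnavailableError(
            f"external predictor executable {settings.executable!r} (IntaRNA adapter) "
            "not found on PATH"
        )

    args = build_intarna_args(srna_rna, mrna_rna, settings)
    proc = subprocess.run(args, capture_output=True, text=True)
    if proc.returncode != 0:
        raise PredictorUnavailableError(
            f"{settings.executable} failed (exit {proc.returncode}): {proc.stderr.strip()}"
        )
    try:
        lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
        header = lines[0].split(";")
        row = dict(zip(header, lines[1].split(";")))
        return InteractionResult(
            energy=float(row["E"]),
            srna_interval=(int(row["start2"]), int(row["end2"])),
            mrna_interval=(int(row["start1"]), int(row["end1"])),
            source="external",
        )
    except (IndexError, KeyError, ValueError) as exc:
        raise PredictorUnavailableError(
            f"could not parse predictor output: {exc}\n--- captured stdout ---\n{proc.stdout}"
        ) from exc


def _seq_of(obj) -> str:
    if isinstance(obj, str):
        return obj
    for attr in ("seq", "sequence"):
        if hasattr(obj, attr):
            return getattr(obj, attr)
    raise TypeError(f"cannot extract a sequence from {type(obj).__name__}")


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SecondaryStructure:
    """MFE structure in dot-bracket notation plus its free energy."""

    dotbracket: str
    mfe: float

    def pairs(self) -> set[tuple[int, int]]:
        """Base pairs as 1-based (i, j) tuples with i < j."""
        stack: list[int] = []
        out: set[tuple[int, int]] = set()
        for pos, ch in enumerate(self.dotbracket, start=1):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                out.add((stack.pop(), pos))
        return out

    def paired_positions(self) -> set[int]:
        return {p for ij in self.pairs() for p in ij}


def fold_mfe(seq: str) -> SecondaryStructure:
    """MFE fold of a (DNA or RNA) sequence via the ViennaRNA engine."""
    rna = transcribe(_seq_of(seq))
    _check_rna(rna, "seq")
    db, mfe = RNA.fold(rna)
    return SecondaryStructure(dotbracket=db, mfe=round(float(mfe), 2))


@dataclass(frozen=True)
class OcclusionReport:
    """Seed accessibility and terminator integrity of a folded sRNA."""

    seed_paired_fraction: float
    terminator_intact: bool


def occlusion_report(srna: SyntheticSRNA) -> OcclusionReport:
    """Fold the full sRNA; measure seed pairing and terminator integrity.

    The terminator is intact iff the set of base pairs lying entirely
    inside the scaffold's terminator region is identical between the
    fold of the full sRNA and the fold of the scaffold alone.
    """
    if srna.seed is None:
        raise ValueError("occlusion is undefined for a Δseed sRNA")
    seed_len = len(srna.seed.seq)
    full = fold_mfe(srna.seq)
    paired = full.paired_positions()
    frac = sum(1 for p in range(1, seed_len + 1) if p in paired) / seed_len

    t1, t2 = srna.scaffold.terminator_region
    lo, hi = t1 + seed_len, t2 + seed_len
    full_term = {
        (i - seed_len, j - seed_len)
        for (i, j) in full.pairs()
        if lo <= i <= hi and lo <= j <= hi
    }
    alone = fold_mfe(srna.scaffold.seq)
    alone_term = {(i, j) for (i, j) in alone.pairs() if t1 <= i <= t2 and t1 <= j <= t2}
    return OcclusionReport(
        seed_paired_fraction=frac,
        terminator_intact=full_term == alone_term,
    )


# ---------------------------------------------------------------------------
# panel ranking
# ---------------------------------------------------------------------------

def rank_seeds(
    panel: list[SeedRegion],
    mrna,
    scaffold=None,
    settings: InteractionSettings | None = None,
    method: str = "internal",
) -> list[tuple[SeedRegion, InteractionResult]]:
    """Panel ordered by ascending interaction energy (strongest first).

    Ties are broken by 5' target position; seeds without a target
    window (the control) sort after positioned ties.  With
    ``method="external"`` each sRNA (or bare seed if no scaffold is
    given) is scored by the external predictor.
    """
    if not panel:
        raise ValueError("panel is empty")
    mrna_rna = transcribe(_seq_of(mrna))
    scored: list[tuple[SeedRegion, InteractionResult]] = []
    for seed in panel:
        query = seed.seq if scaffold is None else seed.seq + scaffold.seq
        if method == "external":
            res = predict_interaction(query, mrna_rna, settings)
        else:
            res = _internal_interaction(transcribe(query), mrna_rna)
        scored.append((seed, res))
    scored.sort(
        key=lambda it: (
            it[1].energy,
            it[0].target_window[0] if it[0].target_window else math.inf,
        )
    )
    return scored
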