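"""Type IIS (Golden Gate) part design and one-pot assembly simulation.

Type IIS enzymes (BbsI, SapI) have directional recognition sites and
cut a fixed distance outside them, leaving programmable 5' overhangs
("fusion sites").  In a one-pot cycled digestion-ligation, correct
products lose every recognition site and therefore stop being re-cut,
while religated input plasmids keep their sites and are recycled; a
counter-selection cassette (mCherry + ccdB placeholders here) marks
the drop-out fragment that must be absent from the intended product.

Fragment model: a double-stranded piece is stored as its sense-strand
span including both overhang regions.  ``seq[:lov]`` is the 5'
extension of the top strand at the left end; ``seq[-rov:]`` is, in
sense orientation, the 5' extension of the *bottom* strand at the
right end.  Two fragments ligate when the right overhang of one equals
the left overhang of the next (sense-strand identity implies
Watson-Crick complementarity of the single-stranded extensions), and
the joined sequence merges the shared overhang once.  Complete
digestion is assumed; ligation-fidelity thermodynamics are not
modeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .errors import AssemblyError, DesignError
from .seed_design import SeedRegion
from .seqio import SeqRecordX, revcomp

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# enzymes and site scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TypeIISEnzyme:
    name: str
    recognition: str  # top-strand recognition sequence, 5'->3'
    spacer: int       # nt between recognition 3' end and the top-strand cut
    overhang_len: int

    def __post_init__(self) -> None:
        if self.recognition == revcomp(self.recognition):
            raise DesignError(f"{self.name}: recognition site must be directional")


BBSI = TypeIISEnzyme("BbsI", "GAAGAC", spacer=2, overhang_len=4)
SAPI = TypeIISEnzyme("SapI", "GCTCTTC", spacer=1, overhang_len=3)

ENZYMES = {e.name: e for e in (BBSI, SAPI)}


@dataclass(frozen=True)
class TypeIISSite:
    """A recognition site and the double-strand cut it directs.

    ``cut_after`` is the 1-based top-strand position after which the
    top strand is cut; the bottom strand is cut ``overhang_len``
    further downstream, producing the 4 nt (BbsI) / 3 nt (SapI) 5'
    overhang at ``overhang_interval``.  ``cut_after == 0`` means the
    cut falls before position 1.  Sites whose cut would run off a
    linear record have ``cut_after = None``.
    """

    position: int  # 1-based start of the recognition sequence on the top strand
    strand: int    # +1 top, -1 bottom
    cut_after: int | None
    overhang_interval: tuple[int, int] | None


def scan_type_iis(rec: SeqRecordX, enz: TypeIISEnzyme) -> list[TypeIISSite]:
    """All recognition sites on both strands; circular seams included."""
    seq = rec.sequence
    n = len(seq)
    rlen = len(enz.recognition)
    hay = seq + (seq[: rlen + enz.spacer + enz.overhang_len] if rec.circular else "")
    sites: list[TypeIISSite] = []

    def add(pos0: int, strand: int) -> None:
        pos = pos0 % n + 1  # 1-based start on the stored strand
        if strand == +1:
            cut = pos0 + rlen + enz.spacer  # top cut after this 0-based count
        else:
            cut = pos0 - enz.spacer - enz.overhang_len
        if rec.circular:
            cut %= n
        elif not (0 <= cut and cut + enz.overhang_len <= n):
            sites.append(TypeIISSite(pos, strand, None, None))
            return
        ov_start = cut % n + 1 if rec.circular else cut + 1
        ov_end = (cut + enz.overhang_len - 1) % n + 1 if rec.circular else cut + enz.overhang_len
        sites.append(TypeIISSite(pos, strand, cut, (ov_start, ov_end)))

    rc_rec = revcomp(enz.recognition)
    limit = n if rec.circular else len(hay) - rlen + 1
    for i in range(max(limit, 0)):
        if hay[i : i + rlen] == enz.recognition:
            add(i, +1)
        if hay[i : i + rlen] == rc_rec:
            add(i, -1)
    sites.sort(key=lambda s: (s.position, -s.strand))
    return sites


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TypeIISFragment:
    """Sticky-ended dsDNA: sense-strand span including both overhangs."""

    seq: str
    lov: int  # left overhang length (5' extension, top strand)
    rov: int  # right overhang length (5' extension, bottom strand)
    name: str = "fragment"
    source: str = ""
    labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.seq) - self.lov - self.rov < 1:
            raise AssemblyError(f"{self.name}: duplex core must be >= 1 bp")

    @property
    def left_overhang(self) -> str:
        return self.seq[: self.lov]

    @property
    def right_overhang(self) -> str:
        return self.seq[len(self.seq) - self.rov :] if self.rov else ""

    @property
    def duplex_len(self) -> int:
        return len(self.seq) - self.lov - self.rov

    def rc(self) -> "TypeIISFragment":
        return replace(
            self, seq=revcomp(self.seq), lov=self.rov, rov=self.lov,
            name=self.name + "(rc)" if not self.name.endswith("(rc)") else self.name[:-4],
        )


def digest(rec: SeqRecordX, enz: TypeIISEnzyme) -> list[TypeIISFragment]:
    """Cut at every site; fragments in plasmid order.

    Circular records yield one fragment per cut; linear records yield
    cuts+1 fragments whose outermost ends are blunt (zero-length
    overhangs).  Features fully contained in a fragment's span are
    carried along as labels.
    """
    sites = [s for s in scan_type_iis(rec, enz) if s.cut_after is not None]
    if not sites:
        raise AssemblyError(f"nothing to digest: no {enz.name} cut in record {rec.id!r}")
    n = len(rec.sequence)
    ov = enz.overhang_len
    cuts = sorted({s.cut_after for s in sites})
    frags: list[TypeIISFragment] = []

    if rec.circular:
        m = len(cuts)
        for idx, c in enumerate(cuts):
            nxt = cuts[(idx + 1) % m]
            span = (nxt - c) % n or n  # single-cut record: whole circle
            start = c  # 0-based
            seq = _circular_slice(rec.sequence, start, span + ov)
            frags.append(
                TypeIISFragment(
                    seq=seq, lov=ov, rov=ov,
                    name=f"{rec.id}[{idx}]", source=rec.id,
                    labels=_labels_in(rec, start + 1, (start + span + ov - 1) % n + 1),
                )
            )
    else:
        bounds = [0] + cuts + [n]
        for idx in range(len(bounds) - 1):
            a, b = bounds[idx], bounds[idx + 1]
            right_ext = ov if idx < len(bounds) - 2 else 0
            seq = rec.sequence[a : b + right_ext]
            frags.append(
                TypeIISFragment(
                    seq=seq,
                    lov=ov if idx > 0 else 0,
                    rov=right_ext,
                    name=f"{rec.id}[{idx}]", source=rec.id,
                    labels=_labels_in(rec, a + 1, b + right_ext),
                )
            )
    return frags


def _circular_slice(seq: str, start0: int, length: int) -> str:
    n = len(seq)
    doubled = seq + seq
    start0 %= n
    return doubled[start0 : start0 + length]


def _labels_in(rec: SeqRecordX, start: int, end: int) -> frozenset[str]:
    """Labels of features fully inside [start, end] (modular on circles)."""
    n = len(rec.sequence)

    def within(fs: int, fe: int) -> bool:
        if not rec.circular:
            return start <= fs and fe <= end
        span = (end - start) % n + 1
        off_s = (fs - start) % n
        off_e = (fe - start) % n
        return off_s <= off_e < span

    return frozenset(lab for lab, fs, fe, _ in rec.features if within(fs, fe))


# ---------------------------------------------------------------------------
# ligation product enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssemblyLimits:
    max_fragments: int = 8
    max_products: int = 64


@dataclass
class Product:
    record: SeqRecordX
    fragments: list[TypeIISFragment]

    @property
    def fragment_names(self) -> list[str]:
        return [f.name for f in self.fragments]


def _canonical_circle(seq: str) -> str:
    def min_rot(s: str) -> str:
        d = s + s
        return min(d[i : i + len(s)] for i in range(len(s)))

    return min(min_rot(seq), min_rot(revcomp(seq)))


def enumerate_products(
    frags: list[TypeIISFragment],
    limits: AssemblyLimits | None = None,
) -> tuple[list[Product], list[str]]:
    """All circular ligation products, with diagnostics.

    Builds the directed compatibility graph over both orientations of
    every fragment (edge A→B iff right overhang of A equals left
    overhang of B) and enumerates simple cycles up to
    ``limits.max_fragments`` fragments, each fragment used at most
    once per product.  Products are deduplicated by canonical rotation.
    """
    limits = limits or AssemblyLimits()
    diagnostics: list[str] = []

    ends: dict[str, list[str]] = {}
    for f in frags:
        for ov in (f.left_overhang, f.right_overhang):
            if ov:
                ends.setdefault(ov, []).append(f.name)
    for ov, names in sorted(ends.items()):
        if len(names) > 2:
            diagnostics.append(
                f"overhang collision: {ov} appears on {len(names)} fragment ends ({', '.join(names)})"
            )

    oriented = []
    for idx, f in enumerate(frags):
        oriented.append((idx, f))
        if f.seq != revcomp(f.seq):
            oriented.append((idx, f.rc()))

    products: dict[str, Product] = {}
    truncated = False

    def dfs(path: list[tuple[int, TypeIISFragment]], used: set[int]) -> None:
        nonlocal truncated
        if len(products) >= limits.max_products:
            truncated = True
            return
        head_idx, head = path[0]
        tail = path[-1][1]
        if tail.right_overhang and tail.right_overhang == head.left_overhang:
            _emit(path)
        if len(path) >= limits.max_fragments:
            truncated = True
            return
        for idx, cand in oriented:
            if idx in used or idx < head_idx:  # head is the least index: kills rotations
                continue
            if tail.right_overhang and tail.right_overhang == cand.left_overhang:
                dfs(path + [(idx, cand)], used | {idx})

    def _emit(path: list[tuple[int, TypeIISFragment]]) -> None:
        pieces = [f for _, f in path]
        if any(f.lov == 0 or f.rov == 0 for f in pieces):
            return  # blunt ends cannot close a sticky circle
        seq = "".join(f.seq[: len(f.seq) - f.rov] for f in pieces)
        key = _canonical_circle(seq)
        if key in products:
            return
        rec = SeqRecordX(id=f"assembly_{len(products) + 1}", sequence=seq, circular=True)
        products[key] = Product(record=rec, fragments=pieces)

    for start_idx, start in oriented:
        # explore each fragment once as cycle head in its stored orientation
        if start.name.endswith("(rc)"):
            continue
        dfs([(start_idx, start)], {start_idx})

    if truncated:
        diagnostics.append("enumeration truncated by limits (max_fragments/max_products)")
    out = list(products.values())
    if len(out) > 1:
        diagnostics.append(f"{len(out)} distinct circular products (expected 1)")
    return out, diagnostics


# ---------------------------------------------------------------------------
# one-pot simulation
# ---------------------------------------------------------------------------

CASSETTE_LABELS = frozenset({"mCherry", "ccdB"})


@dataclass
class AssemblyResult:
    products: list[SeqRecordX]
    intended_ok: bool
    diagnostics: list[str]
    product_fragments: list[list[str]] = field(default_factory=list)


def simulate_one_pot(
    acceptor: SeqRecordX,
    inserts: list[TypeIISFragment],
    enz: TypeIISEnzyme = BBSI,
    limits: AssemblyLimits | None = None,
) -> AssemblyResult:
    """Cycled digestion-ligation of acceptor + inserts.

    The acceptor is digested; its fragments plus the inserts are
    ligated in all compatible circles; any circle that still contains a
    recognition site (e.g. the religated acceptor with its cassette) is
    re-digestible and therefore not terminal.  ``intended_ok`` holds
    iff exactly one terminal product exists, it carries no
    counter-selection cassette (mCherry/ccdB), and it contains every
    insert exactly once.
    """
    if not acceptor.circular:
        raise AssemblyError("acceptor must be circular")
    pool = digest(acceptor, enz) + list(inserts)
    candidates, diagnostics = enumerate_products(pool, limits)

    terminal: list[Product] = []
    for prod in candidates:
        if scan_type_iis(prod.record, enz):
            diagnostics.append(
                f"{prod.record.id} retains {enz.name} sites: re-digested, not terminal"
            )
        else:
            terminal.append(prod)

    ok = len(terminal) == 1
    if ok:
        prod = terminal[0]
        cassette = CASSETTE_LABELS & set().union(*(f.labels for f in prod.fragments))
        if cassette:
            diagnostics.append(f"cassette retention: {sorted(cassette)} in terminal product")
            ok = False
        counts = {ins.name: 0 for ins in inserts}
        for f in prod.fragments:
            base = f.name[:-4] if f.name.endswith("(rc)") else f.name
            if base in counts:
                counts[base] += 1
        missing = [n for n, c in counts.items() if c != 1]
        if missing:
            diagnostics.append(f"inserts not present exactly once: {missing}")
            ok = False

    return AssemblyResult(
        products=[p.record for p in terminal],
        intended_ok=ok,
        diagnostics=diagnostics,
        product_fragments=[p.fragment_names for p in terminal],
    )


# ---------------------------------------------------------------------------
# part design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverhangScheme:
    """Ordered fusion-site sequences around the insert slots.

    ``junctions[i]``/``junctions[i+1]`` are the left/right fusion
    sites of slot i; the digested backbone presents ``junctions[-1]``
    on its left end and ``junctions[0]`` on its right end.  These
    default sites are toolkit placeholders, not the deposited plasmid
    sequences.
    """

    junctions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.junctions) < 2:
            raise DesignError("a scheme needs at least two fusion sites")

    @property
    def n_slots(self) -> int:
        return len(self.junctions) - 1


DEFAULT_JUNCTIONS = ("AGGT", "CGCT", "TGGA", "ACTC", "GCAA", "TTAC", "CAGA")


def default_scheme(n_slots: int = 1) -> OverhangScheme:
    if n_slots + 1 > len(DEFAULT_JUNCTIONS):
        raise DesignError(f"no default scheme with {n_slots} slots")
    return OverhangScheme(junctions=DEFAULT_JUNCTIONS[: n_slots + 1])


@dataclass(frozen=True)
class OligoPair:
    """Annealed forward/reverse oligos yielding one sticky fragment."""

    fwd: str
    rev: str
    phosphorylated: bool
    fragment: TypeIISFragment


def anneal(fwd: str, rev: str, ov: int, name: str = "anneal") -> TypeIISFragment:
    """Reconstruct the sticky fragment an oligo pair forms on annealing."""
    top = fwd.upper()
    bottom_as_sense = revcomp(rev.upper())
    if top[ov:] != bottom_as_sense[:-ov]:
        raise DesignError(f"{name}: oligos do not anneal into a clean duplex")
    return TypeIISFragment(seq=top + bottom_as_sense[-ov:], lov=ov, rov=ov, name=name)


def design_seed_oligos(
    seed: SeedRegion,
    scheme: OverhangScheme,
    enz: TypeIISEnzyme = BBSI,
    slot: int = 0,
) -> OligoPair:
    """Forward/reverse oligos whose annealed duplex fills a seed slot."""
    for strand_seq in (seed.seq, revcomp(seed.seq)):
        if enz.recognition in strand_seq:
            raise DesignError(
                f"seed {seed.sid} contains a {enz.name} recognition site: "
                "the assembled plasmid would self-cut"
            )
    left = scheme.junctions[slot]
    right = scheme.junctions[slot + 1]
    ov = enz.overhang_len
    if len(left) != ov or len(right) != ov:
        raise DesignError(f"scheme fusion sites must be {ov} nt for {enz.name}")
    frag_seq = left + seed.seq + right
    if enz.recognition in frag_seq or revcomp(enz.recognition) in frag_seq:
        log.warning("seed %s: fusion-site junction creates a %s site", seed.sid, enz.name)
    fragment = TypeIISFragment(seq=frag_seq, lov=ov, rov=ov, name=f"seed_{seed.sid}")
    fwd = frag_seq[: len(frag_seq) - ov]
    rev = revcomp(frag_seq[ov:])
    return OligoPair(fwd=fwd, rev=rev, phosphorylated=True, fragment=fragment)


def design_part_primers(
    part_seq: str,
    enz: TypeIISEnzyme,
    left_site: str,
    right_site: str,
    pad: str = "TT",
    anneal_len: int = 18,
) -> tuple[str, str]:
    """PCR primers adding recognition tails and fusion sites to a part.

    Each primer is 5' pad + recognition + spacer fill + fusion site +
    annealing region.  In-silico PCR followed by digestion yields the
    part flanked by the requested overhangs.
    """
    part = part_seq.upper()
    if len(part) < 2 * anneal_len:
        raise DesignError(f"part too short for {anneal_len}-nt unique primer ends")
    if enz.recognition in part or revcomp(enz.recognition) in part:
        raise DesignError(
            f"part contains an internal {enz.name} site; consider gene synthesis "
            "with the site removed (domestication)"
        )
    fill = "A" * enz.spacer
    fwd = pad + enz.recognition + fill + left_site + part[:anneal_len]
    rev = pad + enz.recognition + fill + revcomp(right_site) + revcomp(part[-anneal_len:])
    return fwd, rev


def simulate_pcr(part_seq: str, fwd: str, rev: str) -> SeqRecordX:
    """Amplicon of a part with tailed primers (exact-end annealing)."""
    part = part_seq.upper()
    fwd = fwd.upper()
    rev = rev.upper()
    rev_rc = revcomp(rev)
    f_tail, r_tail = None, None
    for k in range(len(fwd), 0, -1):
        if part.startswith(fwd[-k:]):
            f_tail = fwd[:-k]
            break
    for k in range(len(rev_rc), 0, -1):
        if part.endswith(rev_rc[:k]):
            r_tail = rev_rc[k:]
            break
    if f_tail is None or r_tail is None:
        raise DesignError("primers do not anneal to the part ends")
    return SeqRecordX(id="amplicon", sequence=f_tail + part + r_tail, circular=False)


def check_overhang_scheme(scheme: OverhangScheme) -> list[str]:
    """Fusion-site QC: duplicates, palindromes, revcomp collisions, distances."""
    diags: list[str] = []
    sites = scheme.junctions
    seen: dict[str, int] = {}
    for i, s in enumerate(sites):
        if s in seen:
            diags.append(f"duplicate fusion site {s} (junctions {seen[s]} and {i})")
        seen.setdefault(s, i)
        if s == revcomp(s):
            diags.append(f"palindromic fusion site {s} (junction {i}): self-ligates")
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            if sites[i] == revcomp(sites[j]):
                diags.append(
                    f"reverse-complement collision: {sites[i]} (junction {i}) vs "
                    f"{sites[j]} (junction {j})"
                )
            hd = sum(a != b for a, b in zip(sites[i], sites[j]))
            diags.append(f"hamming({sites[i]},{sites[j]}) = {hd}")
    return diags
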