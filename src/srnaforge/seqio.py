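"""Sequence records and standard-format I/O.

All coordinates are 1-based inclusive, the GenBank convention. Circular
records are stored linearized at an arbitrary origin with an explicit
``circular`` flag; interval extraction handles the wrap-around seam.
DNA is the internal alphabet; RNA is produced on demand (T→U) for
folding and hybridization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import ParseError

log = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")
RNA_ALPHABET = set("ACGUN")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


@dataclass
class SeqRecordX:
    """A sequence record with optional circular topology and features.

    Features are ``(label, start, end, strand)`` tuples with 1-based
    inclusive coordinates on the stored (sense) strand; on circular
    records an interval with ``start > end`` crosses the origin.
    """

    id: str
    sequence: str
    circular: bool = False
    features: list[tuple[str, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        alphabet = set(seq)
        if "U" in alphabet and "T" in alphabet:
            raise ParseError(f"record {self.id!r}: mixed T/U alphabet")
        if not alphabet <= (DNA_ALPHABET | RNA_ALPHABET):
            bad = sorted(alphabet - (DNA_ALPHABET | RNA_ALPHABET))
            raise ParseError(f"record {self.id!r}: invalid characters {bad}")
        self.sequence = seq
        n = len(seq)
        for label, start, end, strand in self.features:
            if strand not in (1, -1):
                raise ParseError(f"feature {label!r}: strand must be +1/-1")
            if not (1 <= start <= n and 1 <= end <= n):
                raise ParseError(
                    f"feature {label!r}: interval ({start},{end}) outside [1,{n}]"
                )
            if not self.circular and start > end:
                raise ParseError(
                    f"feature {label!r}: start > end on a linear record"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_rna(self) -> bool:
        return "U" in self.sequence

    def subseq(self, start: int, end: int) -> str:
        """Extract [start, end] (1-based inclusive); wraps on circular records."""
        n = len(self.sequence)
        if not (1 <= start <= n and 1 <= end <= n):
            raise ValueError(f"interval ({start},{end}) outside [1,{n}]")
        if start <= end:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise ValueError("wrap-around interval on a linear record")
        return self.sequence[start - 1 :] + self.sequence[:end]

    def rotate(self, k: int) -> "SeqRecordX":
        """Move the origin of a circular record k nucleotides downstream."""
        if not self.circular:
            raise ValueError("cannot rotate a linear record")
        n = len(self.sequence)
        k %= n
        seq = self.sequence[k:] + self.sequence[:k]

        def shift(p: int) -> int:
            return (p - 1 - k) % n + 1

        feats = [(lab, shift(s), shift(e), st) for lab, s, e, st in self.features]
        return replace(self, sequence=seq, features=feats)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (alphabet ACGTN)."""
    s = seq.upper()
    if "U" in s:
        raise ValueError("U in input: use revcomp_rna for RNA sequences")
    if not set(s) <= DNA_ALPHABET:
        raise ValueError(f"non-DNA characters in input: {sorted(set(s) - DNA_ALPHABET)}")
    return s.translate(_DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string (alphabet ACGUN)."""
    s = seq.upper()
    if not set(s) <= RNA_ALPHABET:
        raise ValueError(f"non-RNA characters in input: {sorted(set(s) - RNA_ALPHABET)}")
    return s.translate(_RNA_COMPLEMENT)[::-1]


def transcribe(seq: str) -> str:
    """DNA → RNA of the same (sense) strand: T→U."""
    return seq.upper().replace("T", "U")


def _label_of(feat: SeqFeature) -> str:
    for key in ("label", "gene", "product", "locus_tag", "note"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return feat.type


def _from_biopython(rec: SeqRecord) -> SeqRecordX:
    topology = str(rec.annotations.get("topology", "linear")).lower()
    features = []
    for feat in rec.features:
        if feat.type == "source":
            continue
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        strand = feat.location.strand or 1
        features.append((_label_of(feat), start, end, strand))
    return SeqRecordX(
        id=rec.id,
        sequence=str(rec.seq),
        circular=topology == "circular",
        features=features,
    )


def _to_biopython(rec: SeqRecordX) -> SeqRecord:
    out = SeqRecord(
        Seq(rec.sequence),
        id=rec.id,
        name=rec.id[:16],
        description="",
        annotations={
            "molecule_type": "RNA" if rec.is_rna else "DNA",
            "topology": "circular" if rec.circular else "linear",
        },
    )
    for label, start, end, strand in rec.features:
        out.features.append(
            SeqFeature(
                FeatureLocation(start - 1, end, strand=strand),
                type="misc_feature",
                qualifiers={"label": [label]},
            )
        )
    return out


def read_genbank(path) -> list[SeqRecordX]:
    """Read GenBank flat files; topology taken from the LOCUS line."""
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise ParseError(f"malformed GenBank file {path}: {exc}") from exc
    if not records:
        raise ParseError(f"no records in GenBank file {path}")
    return [_from_biopython(r) for r in records]


def write_genbank(records, path) -> None:
    SeqIO.write([_to_biopython(r) for r in records], str(path), "genbank")


def read_fasta(path) -> list[SeqRecordX]:
    """Read FASTA; lowercase letters are normalized to uppercase (logged)."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:
        raise ParseError(f"malformed FASTA file {path}: {exc}") from exc
    if not records:
        raise ParseError(f"no records in FASTA file {path}")
    out = []
    for r in records:
        seq = str(r.seq)
        if seq != seq.upper():
            log.warning("record %s: lowercase letters normalized to uppercase", r.id)
        out.append(SeqRecordX(id=r.id, sequence=seq.upper()))
    return out


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")
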