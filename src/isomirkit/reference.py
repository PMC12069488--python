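"""miRNA hairpin reference: sequences, mature-arm annotations, seed extraction.

Every isomiR classification the package makes is expressed in *hairpin
space*: a mature miRNA is an annotated interval on its precursor hairpin,
and a read's 5'/3' offsets are measured against that interval. This module
loads the hairpin FASTA plus mature annotations (miRBase-dialect GFF3 with
hairpin-relative 1-based coordinates, or a plain TSV with 0-based half-open
coordinates), validates them, and builds a k-mer anchor index used for read
placement.

Coordinates are stored 0-based half-open internally. Input sequences are
normalized to the RNA alphabet (uppercase, T->U).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_rna(sequence: str) -> str:
    """Uppercase, convert DNA T to U, and validate the RNA alphabet."""
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if not seq:
        raise ValueError("empty sequence")
    if bad:
        raise ValueError(f"non-ACGU characters in sequence: {sorted(bad)}")
    return seq


def reverse_complement(sequence: str) -> str:
    """Reverse complement in the RNA alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HairpinRecord:
    """A precursor (pre-miRNA) hairpin sequence."""

    hairpin_id: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA as an interval [start, end) on its hairpin."""

    mature_name: str
    hairpin_id: str
    start: int
    end: int
    arm: Literal["5p", "3p"]

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"mature {self.mature_name!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"mature {self.mature_name!r}: arm must be 5p or 3p")


def extract_seed(sequence: str, start_pos: int = 2, length: int = 6) -> str:
    """Return the seed subsequence at 1-based positions start_pos..start_pos+length-1.

    The default (positions 2-7) is the 6-mer seed that dominates target
    recognition; length 7 (positions 2-8) gives the display seed used in
    figures. Raises ValueError if the sequence is too short.
    """
    if start_pos < 1 or length < 1:
        raise ValueError("start_pos and length must be >= 1")
    if len(sequence) < start_pos - 1 + length:
        raise ValueError(
            f"sequence of length {len(sequence)} too short for seed at "
            f"positions {start_pos}..{start_pos + length - 1}"
        )
    return sequence[start_pos - 1 : start_pos - 1 + length]


@dataclass
class ReferenceIndex:
    """Hairpins + matures with a k-mer anchor table for read placement.

    The anchor table maps every k-mer of every hairpin to its (hairpin_id,
    offset) occurrences; the caller uses it to propose candidate placements
    and falls back to an exhaustive scan when no anchor fires (e.g. a
    substitution in the middle of a short read).
    """

    hairpins: dict[str, HairpinRecord] = field(default_factory=dict)
    matures: dict[str, MatureAnnotation] = field(default_factory=dict)
    anchor_k: int = 12
    _anchors: dict[str, list[tuple[str, int]]] = field(default_factory=dict, repr=False)
    _matures_by_hairpin: dict[str, list[MatureAnnotation]] = field(
        default_factory=dict, repr=False
    )

    def add_hairpin(self, record: HairpinRecord) -> None:
        if record.hairpin_id in self.hairpins:
            raise ValueError(f"duplicate hairpin id {record.hairpin_id!r}")
        self.hairpins[record.hairpin_id] = record
        seq = record.sequence
        k = self.anchor_k
        for i in range(0, max(0, len(seq) - k + 1)):
            self._anchors.setdefault(seq[i : i + k], []).append((record.hairpin_id, i))

    def add_mature(self, annotation: MatureAnnotation) -> None:
        if annotation.mature_name in self.matures:
            raise ValueError(f"duplicate mature name {annotation.mature_name!r}")
        hairpin = self.hairpins.get(annotation.hairpin_id)
        if hairpin is None:
            raise ValueError(
                f"mature {annotation.mature_name!r} references unknown hairpin "
                f"{annotation.hairpin_id!r}"
            )
        if annotation.end > len(hairpin.sequence):
            raise ValueError(
                f"mature {annotation.mature_name!r}: end {annotation.end} exceeds "
                f"hairpin {annotation.hairpin_id!r} length {len(hairpin.sequence)}"
            )
        self.matures[annotation.mature_name] = annotation
        self._matures_by_hairpin.setdefault(annotation.hairpin_id, []).append(annotation)

    def mature_sequence(self, mature_name: str) -> str:
        """Canonical mature sequence: the annotated hairpin substring."""
        m = self.matures[mature_name]
        return self.hairpins[m.hairpin_id].sequence[m.start : m.end]

    def matures_of_hairpin(self, hairpin_id: str) -> list[MatureAnnotation]:
        return list(self._matures_by_hairpin.get(hairpin_id, []))

    def anchor_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._anchors.get(kmer, [])

    def __len__(self) -> int:
        return len(self.matures)

    def summary(self) -> dict:
        return {
            "n_hairpins": len(self.hairpins),
            "n_matures": len(self.matures),
            "anchor_k": self.anchor_k,
            "matures": {
                name: {
                    "hairpin_id": m.hairpin_id,
                    "start": m.start,
                    "end": m.end,
                    "arm": m.arm,
                    "sequence": self.mature_sequence(name),
                }
                for name, m in sorted(self.matures.items())
            },
        }


def _infer_arm(name: str, start: int, hairpin_len: int) -> Literal["5p", "3p"]:
    if name.endswith("-5p"):
        return "5p"
    if name.endswith("-3p"):
        return "3p"
    return "5p" if start < hairpin_len / 2 else "3p"


def _parse_gff3_attributes(field9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in field9.strip().split(";"):
        if "=" in item:
            key, value = item.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def _read_annotations_gff3(path: Path, hairpins: dict[str, HairpinRecord]) -> list[MatureAnnotation]:
    annotations = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line (expected 9 columns): {line!r}")
            seqid, _source, ftype, start, end, _score, _strand, _phase, attr = cols
            if ftype != "miRNA":
                continue
            attrs = _parse_gff3_attributes(attr)
            name = attrs.get("Name") or attrs.get("ID")
            if name is None:
                raise ValueError(f"miRNA feature without Name/ID attribute: {line!r}")
            hairpin_id = attrs.get("Derives_from", seqid)
            hp = hairpins.get(hairpin_id)
            hairpin_len = len(hp.sequence) if hp else 0
            # GFF3 is 1-based inclusive; convert to 0-based half-open.
            start0, end0 = int(start) - 1, int(end)
            annotations.append(
                MatureAnnotation(
                    mature_name=name,
                    hairpin_id=hairpin_id,
                    start=start0,
                    end=end0,
                    arm=_infer_arm(name, start0, hairpin_len),
                )
            )
    return annotations


def _read_annotations_tsv(path: Path, hairpins: dict[str, HairpinRecord]) -> list[MatureAnnotation]:
    annotations = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "mature_name":  # header
                continue
            if len(cols) < 4:
                raise ValueError(f"malformed annotation line: {line!r}")
            name, hairpin_id, start, end = cols[:4]
            start0, end0 = int(start), int(end)
            hp = hairpins.get(hairpin_id)
            hairpin_len = len(hp.sequence) if hp else 0
            arm = cols[4] if len(cols) > 4 and cols[4] in ("5p", "3p") else _infer_arm(
                name, start0, hairpin_len
            )
            annotations.append(
                MatureAnnotation(
                    mature_name=name, hairpin_id=hairpin_id, start=start0, end=end0, arm=arm
                )
            )
    return annotations


def _looks_like_gff3(path: Path) -> bool:
    with open(path) as handle:
        for line in handle:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("##gff-version"):
                return True
            if stripped.startswith("#"):
                continue
            return len(stripped.split("\t")) == 9
    return False


def load_reference(
    hairpin_fasta: str | Path,
    annotation: str | Path,
    anchor_k: int = 12,
) -> ReferenceIndex:
    """Load hairpin FASTA + mature annotations into a ReferenceIndex.

    The annotation file may be miRBase-dialect GFF3 (hairpin-relative,
    1-based inclusive) or a TSV with columns
    ``mature_name  hairpin_id  start  end  arm`` (0-based half-open).
    Rejects out-of-bounds coordinates and duplicate mature names, naming
    the offending record.
    """
    index = ReferenceIndex(anchor_k=anchor_k)
    for record in SeqIO.parse(str(hairpin_fasta), "fasta"):
        index.add_hairpin(
            HairpinRecord(hairpin_id=record.id, name=record.id, sequence=str(record.seq))
        )
    if not index.hairpins:
        raise ValueError(f"no hairpin records parsed from {hairpin_fasta}")
    annotation = Path(annotation)
    if _looks_like_gff3(annotation):
        annotations = _read_annotations_gff3(annotation, index.hairpins)
    else:
        annotations = _read_annotations_tsv(annotation, index.hairpins)
    for ann in annotations:
        index.add_mature(ann)
    return index


def write_reference(index: ReferenceIndex, hairpin_fasta: str | Path, annotation_tsv: str | Path) -> None:
    """Write the reference back to FASTA + TSV (round-trip safe)."""
    with open(hairpin_fasta, "w") as handle:
        for hid in sorted(index.hairpins):
            handle.write(f">{hid}\n{index.hairpins[hid].sequence}\n")
    with open(annotation_tsv, "w") as handle:
        handle.write("# coordinates are 0-based half-open, hairpin-relative\n")
        handle.write("mature_name\thairpin_id\tstart\tend\tarm\n")
        for name in sorted(index.matures):
            m = index.matures[name]
            handle.write(f"{m.mature_name}\t{m.hairpin_id}\t{m.start}\t{m.end}\t{m.arm}\n")


def write_summary_json(index: ReferenceIndex, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(index.summary(), handle, indent=2)


def build_index(
    hairpins: Iterable[HairpinRecord],
    matures: Iterable[MatureAnnotation],
    anchor_k: int = 12,
) -> ReferenceIndex:
    """Assemble a ReferenceIndex from in-memory records."""
    index = ReferenceIndex(anchor_k=anchor_k)
    for hp in hairpins:
        index.add_hairpin(hp)
    for m in matures:
        index.add_mature(m)
    return index
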