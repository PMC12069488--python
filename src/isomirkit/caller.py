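"""Read placement in hairpin space and isomiR classification.

A read is assigned to the mature miRNA whose hairpin-space alignment
minimizes (mismatches, |5' offset|, |3' offset| + tail length)
lexicographically, then classified into one of eight variant classes by
comparing its ends and bases to the canonical mature sequence:

=============  =====================================================
Canonical      identical to the annotated mature sequence
Trim5p/Ext5p   5' end trimmed / templated-extended (seed-shifting)
Trim3p/Ext3p   3' end trimmed / templated-extended
NTA            non-templated 3' addition (tail absent from precursor)
NucVar         internal single-nucleotide substitution
MultiVariant   5'+3' combination, or substitution + length change
=============  =====================================================

Sign conventions: ``d5`` is the read 5' start minus the mature 5' start
(negative = extension); ``d3`` is the read's *templated* 3' end minus the
mature 3' end (positive = templated extension). A non-templated tail is
carried separately in ``nta_tail``.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from isomirkit.reference import ReferenceIndex, extract_seed, normalize_rna


class VariantClass(str, Enum):
    Canonical = "Canonical"
    Trim3p = "Trim3p"
    Ext3p = "Ext3p"
    Trim5p = "Trim5p"
    Ext5p = "Ext5p"
    NTA = "NTA"
    NucVar = "NucVar"
    MultiVariant = "MultiVariant"

    def __str__(self) -> str:  # keeps TSV output clean
        return self.value


#: Tie-break precedence for dominant-class assignment (composition module).
CLASS_PRECEDENCE = [
    VariantClass.Canonical,
    VariantClass.Trim3p,
    VariantClass.Ext3p,
    VariantClass.NTA,
    VariantClass.Trim5p,
    VariantClass.Ext5p,
    VariantClass.NucVar,
    VariantClass.MultiVariant,
]


@dataclass(frozen=True)
class AssignmentPolicy:
    """Placement windows and filters for read assignment.

    max_5p_offset / max_3p_offset bound |d5| and |d3| + tail length;
    max_mismatches caps internal substitutions (reads above the cap are
    unassigned rather than called as multi-substitution variants);
    multimap governs reads tying across distinct matures.
    """

    max_5p_offset: int = 3
    max_3p_offset: int = 5
    max_mismatches: int = 1
    min_read_length: int = 16
    max_read_length: int = 30
    seed_start: int = 2
    seed_length: int = 6
    min_body_overlap: int = 8
    multimap: str = "drop"  # "drop" (ambiguous) or "fractional"


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct read sequence with per-sample counts."""

    sequence: str
    counts: tuple[int, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.sample_ids):
            raise ValueError("counts and sample_ids must have equal length")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class IsomirCall:
    """One read sequence's assignment to a mature miRNA."""

    sequence: str
    mature_name: str
    variant_class: VariantClass
    d5: int
    d3: int
    nta_tail: str
    substitutions: tuple[tuple[int, str, str], ...]  # (1-based read pos, ref, alt)
    seed: str
    seed_conserved: bool
    display_name: str
    fraction: float = 1.0  # < 1 only under fractional multimap assignment


@dataclass(frozen=True)
class Unassigned:
    """A read that could not be placed; reason in {no_hit, ambiguous, length}."""

    sequence: str
    reason: str


@dataclass(frozen=True)
class _Placement:
    mature_name: str
    d5: int
    d3: int
    nta_tail: str
    substitutions: tuple[tuple[int, str, str], ...]

    @property
    def key(self) -> tuple[int, int, int]:
        return (len(self.substitutions), abs(self.d5), abs(self.d3) + len(self.nta_tail))


def split_templated_tail(read_3prime_overhang: str, hairpin_context: str) -> tuple[int, str]:
    """Split a 3' overhang into (templated length, non-templated tail).

    The templated part is the longest prefix of the overhang matching the
    hairpin sequence downstream of the mature 3' end, base by base; any
    remainder (including everything past the hairpin end) is non-templated.
    """
    templated = 0
    for read_base, ref_base in zip(read_3prime_overhang, hairpin_context):
        if read_base != ref_base:
            break
        templated += 1
    return templated, read_3prime_overhang[templated:]


def classify(
    d5: int,
    d3: int,
    nta_tail: str,
    substitutions: Sequence[tuple[int, str, str]],
) -> VariantClass:
    """Classify a placement into a variant class.

    Decision order: Canonical; substitution + any length change ->
    MultiVariant; substitution only -> NucVar; 5' + 3' change ->
    MultiVariant; 5' only -> Trim5p/Ext5p; any non-templated tail -> NTA
    (the tail dominates the 3' call even alongside templated trimming or
    extension); 3' trim -> Trim3p; 3' extension -> Ext3p.
    """
    has_5p = d5 != 0
    has_3p = d3 != 0 or bool(nta_tail)
    if not has_5p and not has_3p and not substitutions:
        return VariantClass.Canonical
    if substitutions:
        return VariantClass.MultiVariant if (has_5p or has_3p) else VariantClass.NucVar
    if has_5p and has_3p:
        return VariantClass.MultiVariant
    if has_5p:
        return VariantClass.Trim5p if d5 > 0 else VariantClass.Ext5p
    if nta_tail:
        return VariantClass.NTA
    if d3 < 0:
        return VariantClass.Trim3p
    if d3 > 0:
        return VariantClass.Ext3p
    raise RuntimeError("unreachable classification state")  # pragma: no cover


_CORE_RE = re.compile(r"^(?:[A-Za-z0-9]+-)?(?:miR|mir|let)-(.+)$")


def _name_core(mature_name: str) -> str:
    match = _CORE_RE.match(mature_name)
    return match.group(1) if match else mature_name


def _name_components(
    d5: int, d3: int, nta_tail: str, substitutions: Sequence[tuple[int, str, str]]
) -> list[str]:
    parts: list[str] = []
    if d5 < 0:
        parts.append(f"Ext5p(+{-d5})")
    elif d5 > 0:
        parts.append(f"Trim5p(-{d5})")
    for pos, ref, alt in substitutions:
        parts.append(f"NucVar({pos}{ref}>{alt})")
    if d3 < 0:
        parts.append(f"Trim3p(-{-d3})")
    elif d3 > 0:
        parts.append(f"Ext3p(+{d3})")
    if nta_tail:
        parts.append(f"NTA(+{len(nta_tail)})")
    return parts


def build_display_name(call: IsomirCall) -> str:
    """Systematic isomiR name: originating miRNA, class, offset in brackets.

    Canonical sequences keep the mature name. Variants are named
    ``isomiR-<core>-<components 5'->3'>`` where the species/"miR" prefix is
    stripped from the core (hsa-miR-411-5p -> 411-5p); extensions print
    "+n", trims "-n", substitutions "NucVar(<pos><ref>><alt>)".
    """
    if call.variant_class is VariantClass.Canonical:
        return call.mature_name
    components = _name_components(call.d5, call.d3, call.nta_tail, call.substitutions)
    return f"isomiR-{_name_core(call.mature_name)}-" + "-".join(components)


_COMPONENT_RE = re.compile(
    r"(Ext5p|Trim5p|Ext3p|Trim3p|NTA)\(([+-]\d+)\)|NucVar\((\d+)([ACGU])>([ACGU])\)"
)


def parse_display_name(name: str) -> dict:
    """Parse a systematic isomiR name back into offsets and class.

    Returns a dict with keys core, d5, d3, nta_len, substitutions,
    variant_class. Canonical names (no "isomiR-" prefix) parse with all
    offsets zero.
    """
    if not name.startswith("isomiR-"):
        return {
            "core": _name_core(name),
            "d5": 0,
            "d3": 0,
            "nta_len": 0,
            "substitutions": (),
            "variant_class": VariantClass.Canonical,
        }
    body = name[len("isomiR-") :]
    d5 = d3 = nta_len = 0
    substitutions: list[tuple[int, str, str]] = []
    first = None
    for match in _COMPONENT_RE.finditer(body):
        if first is None:
            first = match.start()
        if match.group(1):
            kind, value = match.group(1), int(match.group(2))
            if kind == "Ext5p":
                d5 = -value
            elif kind == "Trim5p":
                d5 = -value  # component prints "-n", d5 is +n
            elif kind == "Ext3p":
                d3 = value
            elif kind == "Trim3p":
                d3 = value  # value is negative, e.g. Trim3p(-2)
            elif kind == "NTA":
                nta_len = value
        else:
            substitutions.append((int(match.group(3)), match.group(4), match.group(5)))
    if first is None:
        raise ValueError(f"unparseable isomiR name: {name!r}")
    core = body[:first].rstrip("-")
    variant_class = classify(d5, d3, "N" * nta_len, substitutions)
    return {
        "core": core,
        "d5": d5,
        "d3": d3,
        "nta_len": nta_len,
        "substitutions": tuple(substitutions),
        "variant_class": variant_class,
    }


def _evaluate_placement(
    read_seq: str, ref: ReferenceIndex, mature_name: str, d5: int, policy: AssignmentPolicy
) -> _Placement | None:
    mature = ref.matures[mature_name]
    hairpin_seq = ref.hairpins[mature.hairpin_id].sequence
    start = mature.start + d5
    if start < 0:  # 5' extension beyond the hairpin cannot be templated
        return None
    read_len = len(read_seq)
    body_len = min(read_len, mature.end - start)
    if body_len < policy.min_body_overlap:
        return None
    substitutions = []
    for i in range(body_len):
        if read_seq[i] != hairpin_seq[start + i]:
            substitutions.append((i + 1, hairpin_seq[start + i], read_seq[i]))
            if len(substitutions) > policy.max_mismatches:
                return None
    if read_len <= mature.end - start:
        d3 = (start + read_len) - mature.end
        nta_tail = ""
    else:
        overhang = read_seq[mature.end - start :]
        context = hairpin_seq[mature.end :]
        templated, nta_tail = split_templated_tail(overhang, context)
        d3 = templated
    if abs(d3) + len(nta_tail) > policy.max_3p_offset:
        return None
    return _Placement(
        mature_name=mature_name,
        d5=d5,
        d3=d3,
        nta_tail=nta_tail,
        substitutions=tuple(substitutions),
    )


def _candidate_offsets(read_seq: str, ref: ReferenceIndex, policy: AssignmentPolicy) -> set[tuple[str, int]]:
    """Propose (mature, d5) candidates from k-mer anchors; empty set = no anchor."""
    k = ref.anchor_k
    candidates: set[tuple[str, int]] = set()
    if len(read_seq) >= k:
        for i in range(0, len(read_seq) - k + 1):
            for hairpin_id, pos in ref.anchor_hits(read_seq[i : i + k]):
                implied_start = pos - i
                for mature in ref.matures_of_hairpin(hairpin_id):
                    d5 = implied_start - mature.start
                    if abs(d5) <= policy.max_5p_offset:
                        candidates.add((mature.mature_name, d5))
    return candidates


def _call_from_placement(
    read_seq: str, ref: ReferenceIndex, placement: _Placement, policy: AssignmentPolicy, fraction: float = 1.0
) -> IsomirCall:
    mature_seq = ref.mature_sequence(placement.mature_name)
    seed = extract_seed(read_seq, policy.seed_start, policy.seed_length)
    canonical_seed = extract_seed(mature_seq, policy.seed_start, policy.seed_length)
    variant_class = classify(
        placement.d5, placement.d3, placement.nta_tail, placement.substitutions
    )
    call = IsomirCall(
        sequence=read_seq,
        mature_name=placement.mature_name,
        variant_class=variant_class,
        d5=placement.d5,
        d3=placement.d3,
        nta_tail=placement.nta_tail,
        substitutions=placement.substitutions,
        seed=seed,
        seed_conserved=(seed == canonical_seed),
        display_name="",
        fraction=fraction,
    )
    return dataclasses.replace(call, display_name=build_display_name(call))


def assign_read(
    read: CollapsedRead | str,
    ref: ReferenceIndex,
    policy: AssignmentPolicy = AssignmentPolicy(),
) -> IsomirCall | list[IsomirCall] | Unassigned:
    """Place one read sequence against the reference and classify it.

    The best placement minimizes (mismatches, |d5|, |d3| + tail length)
    lexicographically. Ties across distinct matures yield
    Unassigned("ambiguous") under the default policy, or a list of
    fractional calls when policy.multimap == "fractional". Non-placeable
    reads return Unassigned("no_hit"); out-of-bounds lengths return
    Unassigned("length").
    """
    if not ref.matures:
        raise ValueError("reference index has no mature annotations")
    read_seq = read if isinstance(read, str) else read.sequence
    read_seq = normalize_rna(read_seq)
    if not (policy.min_read_length <= len(read_seq) <= policy.max_read_length):
        return Unassigned(read_seq, "length")

    candidates = _candidate_offsets(read_seq, ref, policy)
    if not candidates:  # anchor miss (e.g. central substitution): exhaustive scan
        candidates = {
            (name, d5)
            for name in ref.matures
            for d5 in range(-policy.max_5p_offset, policy.max_5p_offset + 1)
        }
    placements = []
    for name, d5 in sorted(candidates):
        placement = _evaluate_placement(read_seq, ref, name, d5, policy)
        if placement is not None:
            placements.append(placement)
    if not placements:
        return Unassigned(read_seq, "no_hit")
    best_key = min(p.key for p in placements)
    best = [p for p in placements if p.key == best_key]
    matures_hit = sorted({p.mature_name for p in best})
    if len(matures_hit) > 1:
        if policy.multimap == "fractional":
            per_mature = []
            for name in matures_hit:
                p = min(
                    (q for q in best if q.mature_name == name),
                    key=lambda q: (q.d5, q.d3),
                )
                per_mature.append(
                    _call_from_placement(read_seq, ref, p, policy, fraction=1.0 / len(matures_hit))
                )
            return per_mature
        return Unassigned(read_seq, "ambiguous")
    chosen = min(best, key=lambda p: (p.d5, p.d3))
    return _call_from_placement(read_seq, ref, chosen, policy)


def classify_reads(
    reads: Iterable[CollapsedRead],
    ref: ReferenceIndex,
    policy: AssignmentPolicy = AssignmentPolicy(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify a collapsed read set into a call table.

    Returns (calls, unassigned). The call table has one row per
    (sequence, mature) with classification columns followed by per-sample
    counts; the unassigned table records sequences, reasons and counts.
    Count conservation holds per sample: assigned + unassigned = input.
    Rows are sorted by (mature, display_name, sequence) so the result is
    independent of read order.
    """
    reads = list(reads)
    sample_ids: tuple[str, ...] = reads[0].sample_ids if reads else ()
    for read in reads:
        if read.sample_ids != sample_ids:
            raise ValueError("all reads must share the same sample_id ordering")
    call_rows: list[dict] = []
    unassigned_rows: list[dict] = []
    for read in reads:
        result = assign_read(read, ref, policy)
        if isinstance(result, Unassigned):
            unassigned_rows.append(
                {"sequence": result.sequence, "reason": result.reason}
                | dict(zip(sample_ids, read.counts))
            )
            continue
        calls = result if isinstance(result, list) else [result]
        for call in calls:
            counts = [c * call.fraction for c in read.counts]
            call_rows.append(
                {
                    "display_name": call.display_name,
                    "sequence": call.sequence,
                    "mature_name": call.mature_name,
                    "variant_class": str(call.variant_class),
                    "d5": call.d5,
                    "d3": call.d3,
                    "nta_tail": call.nta_tail,
                    "substitutions": ";".join(
                        f"{pos}{ref_b}>{alt}" for pos, ref_b, alt in call.substitutions
                    ),
                    "seed": call.seed,
                    "seed_conserved": call.seed_conserved,
                }
                | dict(zip(sample_ids, counts))
            )
    call_columns = [
        "display_name",
        "sequence",
        "mature_name",
        "variant_class",
        "d5",
        "d3",
        "nta_tail",
        "substitutions",
        "seed",
        "seed_conserved",
        *sample_ids,
    ]
    calls = pd.DataFrame(call_rows, columns=call_columns)
    calls = calls.sort_values(["mature_name", "display_name", "sequence"]).reset_index(drop=True)
    unassigned = pd.DataFrame(
        unassigned_rows, columns=["sequence", "reason", *sample_ids]
    ).sort_values("sequence").reset_index(drop=True)
    return calls, unassigned


def collapse_tsv(path: str | Path) -> list[CollapsedRead]:
    """Load collapsed reads from a TSV with columns sequence, sample, count."""
    table = pd.read_csv(path, sep="\t")
    required = {"sequence", "sample", "count"}
    if not required.issubset(table.columns):
        raise ValueError(f"collapsed TSV must have columns {sorted(required)}")
    wide = (
        table.pivot_table(index="sequence", columns="sample", values="count", aggfunc="sum")
        .fillna(0)
        .astype(int)
    )
    sample_ids = tuple(str(s) for s in wide.columns)
    return [
        CollapsedRead(sequence=normalize_rna(seq), counts=tuple(int(c) for c in row), sample_ids=sample_ids)
        for seq, row in wide.iterrows()
    ]


def collapse_fastq(
    sample_paths: dict[str, str | Path],
    min_quality: int | None = 30,
) -> list[CollapsedRead]:
    """Collapse per-sample FASTQ files into distinct sequences with counts.

    Reads containing any base below min_quality are dropped (set
    min_quality=None to keep everything); sequences are normalized to the
    RNA alphabet.
    """
    sample_ids = tuple(sample_paths)
    counts: dict[str, dict[str, int]] = {}
    for sample, path in sample_paths.items():
        for record in SeqIO.parse(str(path), "fastq"):
            quals = record.letter_annotations["phred_quality"]
            if min_quality is not None and quals and min(quals) < min_quality:
                continue
            seq = normalize_rna(str(record.seq))
            counts.setdefault(seq, {}).setdefault(sample, 0)
            counts[seq][sample] += 1
    return [
        CollapsedRead(
            sequence=seq,
            counts=tuple(per_sample.get(s, 0) for s in sample_ids),
            sample_ids=sample_ids,
        )
        for seq, per_sample in sorted(counts.items())
    ]
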