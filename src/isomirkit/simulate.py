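"""Synthetic data generators with full ground truth.

Every input the pipeline consumes can be generated here: a hairpin
reference with annotated mature arms, multi-sample read sets drawn from a
configurable per-miRNA isomiR composition with per-base sequencing
error, donor cohorts with a planted linear isomiR-phenotype association
and age/sex/BMI covariate effects, differential-expression tables
realizing an exact Venn structure, and 3'UTR sequences with planted seed
sites. Each generator is a pure function of its spec and seed, and emits
a truth table sufficient to score the downstream module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from isomirkit.caller import CollapsedRead, VariantClass
from isomirkit.reference import (
    HairpinRecord,
    MatureAnnotation,
    ReferenceIndex,
    build_index,
    write_reference,
)
from isomirkit.targets import _normalize_utr, _revcomp

_BASES = np.array(list("ACGU"))


# ---------------------------------------------------------------------------
# reference


def generate_reference(
    n_hairpins: int,
    mature_length_range: tuple[int, int] = (20, 23),
    seed: int = 0,
    two_armed_fraction: float = 0.5,
    flank: int = 8,
    loop: int = 12,
    out_fasta: str | Path | None = None,
    out_tsv: str | Path | None = None,
) -> ReferenceIndex:
    """Random hairpin reference with one or two annotated matures each.

    Every mature has at least `flank` nt of hairpin context on both sides
    (so every templated extension class is realizable). Deterministic
    under the seed; optionally written to FASTA + TSV.
    """
    if n_hairpins < 1:
        raise ValueError("n_hairpins must be >= 1")
    if flank < 6:
        raise ValueError("flank must be >= 6 so extension variants are realizable")
    rng = np.random.default_rng(seed)
    hairpins, matures = [], []
    for i in range(1, n_hairpins + 1):
        hid = f"syn-mir-{i}"
        two_armed = rng.random() < two_armed_fraction
        len5 = int(rng.integers(mature_length_range[0], mature_length_range[1] + 1))
        pieces = [
            "".join(rng.choice(_BASES, size=flank)),
            "".join(rng.choice(_BASES, size=len5)),
        ]
        start5 = flank
        annotations = [(f"syn-miR-{i}-5p", start5, start5 + len5, "5p")]
        if two_armed:
            len3 = int(rng.integers(mature_length_range[0], mature_length_range[1] + 1))
            pieces.append("".join(rng.choice(_BASES, size=loop)))
            start3 = start5 + len5 + loop
            pieces.append("".join(rng.choice(_BASES, size=len3)))
            annotations.append((f"syn-miR-{i}-3p", start3, start3 + len3, "3p"))
        pieces.append("".join(rng.choice(_BASES, size=flank)))
        sequence = "".join(pieces)
        hairpins.append(HairpinRecord(hairpin_id=hid, name=hid, sequence=sequence))
        for name, start, end, arm in annotations:
            matures.append(
                MatureAnnotation(
                    mature_name=name, hairpin_id=hid, start=start, end=end, arm=arm
                )
            )
    index = build_index(hairpins, matures)
    if out_fasta and out_tsv:
        write_reference(index, out_fasta, out_tsv)
    return index


# ---------------------------------------------------------------------------
# reads


def _default_class_proportions() -> dict[str, float]:
    # Composition echoing the 3'-dominant profile typical of beta-cell
    # small RNA-seq: canonical ~half, Trim3p the largest isomiR class.
    return {
        "Canonical": 0.45,
        "Trim3p": 0.30,
        "Ext3p": 0.08,
        "NTA": 0.08,
        "Trim5p": 0.02,
        "Ext5p": 0.04,
        "NucVar": 0.02,
        "MultiVariant": 0.01,
    }


@dataclass
class CompositionSpec:
    """Planted per-miRNA isomiR composition and sequencing conditions."""

    class_proportions: dict[str, float] = field(default_factory=_default_class_proportions)
    trim3p_lengths: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.15, 4: 0.05}
    )
    ext3p_lengths: dict[int, float] = field(default_factory=lambda: {1: 0.7, 2: 0.3})
    trim5p_lengths: dict[int, float] = field(default_factory=lambda: {1: 0.8, 2: 0.2})
    ext5p_lengths: dict[int, float] = field(default_factory=lambda: {1: 0.8, 2: 0.2})
    nta_lengths: dict[int, float] = field(default_factory=lambda: {1: 0.7, 2: 0.3})
    nta_base_weights: dict[str, float] = field(
        default_factory=lambda: {"A": 0.45, "U": 0.45, "C": 0.05, "G": 0.05}
    )
    error_rate: float = 0.0
    library_size: int = 100_000
    n_samples: int = 3
    n_datasets: int = 1
    mirna_weights: dict[str, float] | None = None  # None: uniform
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.library_size <= 0 or self.n_samples <= 0 or self.n_datasets <= 0:
            raise ValueError("library_size, n_samples and n_datasets must be positive")


def _normalized(weights: dict) -> tuple[list, np.ndarray]:
    keys = list(weights)
    values = np.array([weights[k] for k in keys], dtype=float)
    return keys, values / values.sum()


def _build_variant(
    ref: ReferenceIndex,
    mature_name: str,
    variant_class: str,
    spec: CompositionSpec,
    rng: np.random.Generator,
) -> tuple[str, int, int, str]:
    """Construct one variant sequence; returns (sequence, d5, d3, nta_tail)."""
    mature = ref.matures[mature_name]
    hairpin = ref.hairpins[mature.hairpin_id].sequence
    seq = hairpin[mature.start : mature.end]
    upstream = hairpin[: mature.start]
    downstream = hairpin[mature.end :]

    min_len = 16  # caller's default lower read-length bound

    def draw(dist: dict[int, float], max_k: int | None = None) -> int:
        if max_k is not None:
            dist = {k: w for k, w in dist.items() if k <= max_k}
            if not dist:
                raise ValueError(
                    f"{mature_name}: no feasible offset length for {variant_class}"
                )
        keys, probs = _normalized(dist)
        return int(rng.choice(keys, p=probs))

    if variant_class == "Canonical":
        return seq, 0, 0, ""
    if variant_class == "Trim3p":
        k = draw(spec.trim3p_lengths, max_k=len(seq) - min_len)
        return seq[:-k], 0, -k, ""
    if variant_class == "Ext3p":
        k = draw(spec.ext3p_lengths)
        if len(downstream) < k:
            raise ValueError(f"{mature_name}: Ext3p({k}) exceeds hairpin context")
        return seq + downstream[:k], 0, k, ""
    if variant_class == "Trim5p":
        k = draw(spec.trim5p_lengths, max_k=len(seq) - min_len)
        return seq[k:], k, 0, ""
    if variant_class == "Ext5p":
        k = draw(spec.ext5p_lengths)
        if len(upstream) < k:
            raise ValueError(f"{mature_name}: Ext5p({k}) exceeds hairpin context")
        return upstream[-k:] + seq, -k, 0, ""
    if variant_class == "NTA":
        k = draw(spec.nta_lengths)
        bases, probs = _normalized(spec.nta_base_weights)
        tail = [str(rng.choice(bases, p=probs)) for _ in range(k)]
        if downstream:  # first tail base must be non-templated
            while tail[0] == downstream[0]:
                tail[0] = str(rng.choice(bases, p=probs))
        return seq + "".join(tail), 0, 0, "".join(tail)
    if variant_class == "NucVar":
        pos = int(rng.integers(2, len(seq)))  # 1-based interior position
        alternatives = [b for b in "ACGU" if b != seq[pos - 1]]
        alt = str(rng.choice(alternatives))
        return seq[: pos - 1] + alt + seq[pos:], 0, 0, ""
    if variant_class == "MultiVariant":
        d5 = int(rng.choice([-1, 1]))
        k = draw(spec.trim3p_lengths, max_k=len(seq) - min_len - 1)
        if d5 < 0:
            if not upstream:
                raise ValueError(f"{mature_name}: Ext5p beyond hairpin context")
            return upstream[-1] + seq[:-k], -1, -k, ""
        return seq[1:-k], 1, -k, ""
    raise ValueError(f"unknown variant class {variant_class!r}")


def build_variant_table(spec: CompositionSpec, ref: ReferenceIndex) -> pd.DataFrame:
    """Enumerate the planted variant universe with sampling probabilities.

    One row per (miRNA, variant sequence) with the pre-error truth
    (class, d5, d3, nta_tail) and the probability of drawing that
    sequence in one read. Duplicate sequences across entries would make
    the truth ambiguous and raise.
    """
    rng = np.random.default_rng(spec.seed)
    mature_names = sorted(ref.matures)
    if spec.mirna_weights is None:
        mirna_probs = {name: 1.0 / len(mature_names) for name in mature_names}
    else:
        names, probs = _normalized(spec.mirna_weights)
        mirna_probs = dict(zip(names, probs))
    rows = []
    for name in mature_names:
        weight = mirna_probs.get(name, 0.0)
        if weight == 0:
            continue
        for variant_class, proportion in spec.class_proportions.items():
            if proportion == 0:
                continue
            sequence, d5, d3, nta = _build_variant(ref, name, variant_class, spec, rng)
            rows.append(
                {
                    "sequence": sequence,
                    "mature_name": name,
                    "variant_class": variant_class,
                    "d5": d5,
                    "d3": d3,
                    "nta_tail": nta,
                    "probability": weight * proportion,
                }
            )
    table = pd.DataFrame(rows)
    if table["sequence"].duplicated().any():
        dupes = table.loc[table["sequence"].duplicated(), "sequence"].tolist()
        raise RuntimeError(
            f"variant collision (identical sequence for two planted variants): {dupes}"
        )
    return table


def _inject_errors(
    sequence: str, n_reads: int, error_rate: float, rng: np.random.Generator
) -> dict[str, int]:
    """Distribute n_reads copies of `sequence` over error-mutated variants."""
    if error_rate == 0 or n_reads == 0:
        return {sequence: n_reads} if n_reads else {}
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    length = len(arr)
    mask = rng.random((n_reads, length)) < error_rate
    errored = np.nonzero(mask.any(axis=1))[0]
    out: dict[str, int] = {}
    n_clean = n_reads - len(errored)
    if n_clean:
        out[sequence] = n_clean
    base_index = {b"A": 0, b"C": 1, b"G": 2, b"U": 3}
    raw = np.frombuffer(b"ACGU", dtype="S1")
    for row in errored:
        read = arr.copy()
        for pos in np.nonzero(mask[row])[0]:
            current = base_index[read[pos].tobytes()]
            read[pos] = raw[(current + rng.integers(1, 4)) % 4]
        mutated = read.tobytes().decode()
        out[mutated] = out.get(mutated, 0) + 1
    return out


def generate_reads(
    spec: CompositionSpec, ref: ReferenceIndex
) -> tuple[dict[str, list[CollapsedRead]], pd.DataFrame]:
    """Draw multi-sample read sets from the planted composition.

    Returns (reads_by_dataset, truth). Reads are drawn multinomially from
    the planted variant universe per sample, then per-base substitution
    errors are injected at spec.error_rate. The truth table records the
    pre-error identity of every planted variant together with its planted
    counts per (dataset, sample). Deterministic under spec.seed.
    """
    table = build_variant_table(spec, ref)
    rng = np.random.default_rng(spec.seed + 1)
    probabilities = table["probability"].to_numpy()
    probabilities = probabilities / probabilities.sum()
    reads_by_dataset: dict[str, list[CollapsedRead]] = {}
    truth = table.drop(columns="probability").copy()
    for d in range(1, spec.n_datasets + 1):
        dataset = f"ds{d}"
        sample_ids = tuple(f"{dataset}_s{j + 1}" for j in range(spec.n_samples))
        collapsed: dict[str, list[int]] = {}
        for j in range(spec.n_samples):
            planted = rng.multinomial(spec.library_size, probabilities)
            truth[f"planted.{dataset}_s{j + 1}"] = planted
            for sequence, count in zip(table["sequence"], planted):
                for observed, n in _inject_errors(
                    sequence, int(count), spec.error_rate, rng
                ).items():
                    collapsed.setdefault(observed, [0] * spec.n_samples)[j] += n
        reads_by_dataset[dataset] = [
            CollapsedRead(sequence=seq, counts=tuple(c), sample_ids=sample_ids)
            for seq, c in sorted(collapsed.items())
        ]
    return reads_by_dataset, truth


def write_fastq(reads: list[CollapsedRead], directory: str | Path, quality: int = 40) -> dict[str, Path]:
    """Expand collapsed reads to per-sample FASTQ files with uniform quality."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    qchar = chr(quality + 33)
    paths = {}
    sample_ids = reads[0].sample_ids if reads else ()
    for idx, sample in enumerate(sample_ids):
        path = directory / f"{sample}.fastq"
        with open(path, "w") as handle:
            serial = 0
            for read in reads:
                for _ in range(int(read.counts[idx])):
                    serial += 1
                    handle.write(
                        f"@{sample}.{serial}\n{read.sequence}\n+\n{qchar * len(read.sequence)}\n"
                    )
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """A donor cohort with a planted isomiR-phenotype association.

    The focal isomiR's log2 expression is baseline + beta * parameter +
    covariate effects + Gaussian noise; counts are the back-transformed
    values. Covariate distributions default to a realistic adult donor
    cohort (age ~ N(55, 10) years, BMI ~ N(26, 4) kg/m^2, sex ~
    Bernoulli(0.5)); the clinical parameter is standard normal.
    """

    n_donors: int = 16
    parameter_name: str = "basal_isr"
    beta: float = 0.0
    noise_sd: float = 0.5
    baseline_log2: float = 8.0
    age_mean: float = 55.0
    age_sd: float = 10.0
    bmi_mean: float = 26.0
    bmi_sd: float = 4.0
    age_effect: float = 0.0
    sex_effect: float = 0.0
    bmi_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 8:
            raise ValueError("n_donors must be >= 8")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def generate_cohort(
    spec: CohortSpec, focal_isomir: str = "isomiR-1-5p-Ext5p(+1)"
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Generate donor metadata and focal-isomiR counts with planted truth.

    Returns (metadata, counts, truth): metadata is indexed by donor with
    columns age, sex, bmi and the clinical parameter; counts are the
    focal isomiR's normalized counts per donor; truth echoes the planted
    beta and noise SD.
    """
    rng = np.random.default_rng(spec.seed)
    donors = [f"donor{j + 1:02d}" for j in range(spec.n_donors)]
    age = rng.normal(spec.age_mean, spec.age_sd, spec.n_donors)
    sex = rng.integers(0, 2, spec.n_donors)
    bmi = rng.normal(spec.bmi_mean, spec.bmi_sd, spec.n_donors)
    parameter = rng.normal(0.0, 1.0, spec.n_donors)
    noise = rng.normal(0.0, spec.noise_sd, spec.n_donors)
    log2_expr = (
        spec.baseline_log2
        + spec.beta * parameter
        + spec.age_effect * (age - spec.age_mean)
        + spec.sex_effect * sex
        + spec.bmi_effect * (bmi - spec.bmi_mean)
        + noise
    )
    counts = pd.Series(
        np.maximum(np.exp2(log2_expr) - 1.0, 0.0), index=donors, name=focal_isomir
    )
    metadata = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "bmi": bmi,
            spec.parameter_name: parameter,
        },
        index=pd.Index(donors, name="donor_id"),
    )
    truth = {
        "beta": spec.beta,
        "noise_sd": spec.noise_sd,
        "focal_isomir": focal_isomir,
        "parameter_name": spec.parameter_name,
    }
    return metadata, counts, truth


# ---------------------------------------------------------------------------
# DE tables


def generate_de_tables(
    n_genes: int,
    down_a: int,
    down_b: int,
    shared_down: int,
    up_a: int = 0,
    up_b: int = 0,
    shared_up: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two DE tables realizing an exact down/up Venn structure.

    Gene symbols are synthetic (G00001...). Significant genes get
    padj < 0.05 with a signed log2FC; the rest sit above the cutoff with
    small fold changes. Raises if the requested structure cannot fit in
    n_genes.
    """
    if shared_down > min(down_a, down_b) or shared_up > min(up_a, up_b):
        raise ValueError("shared set larger than one of its parents")
    n_down = down_a + down_b - shared_down
    n_up = up_a + up_b - shared_up
    if n_down + n_up > n_genes:
        raise ValueError(
            f"requested structure needs {n_down + n_up} genes, universe has {n_genes}"
        )
    rng = np.random.default_rng(seed)
    genes = [f"G{j + 1:05d}" for j in range(n_genes)]
    order = list(rng.permutation(genes))
    shared_down_genes = set(order[:shared_down])
    a_only_down = set(order[shared_down:down_a])
    b_only_down = set(order[down_a : down_a + down_b - shared_down])
    offset = n_down
    shared_up_genes = set(order[offset : offset + shared_up])
    a_only_up = set(order[offset + shared_up : offset + up_a])
    b_only_up = set(order[offset + up_a : offset + up_a + up_b - shared_up])

    def make_table(down: set[str], up: set[str], contrast: str) -> pd.DataFrame:
        rows = []
        for gene in genes:
            if gene in down:
                padj = float(rng.uniform(1e-6, 0.049))
                lfc = float(-rng.uniform(0.5, 3.0))
            elif gene in up:
                padj = float(rng.uniform(1e-6, 0.049))
                lfc = float(rng.uniform(0.5, 3.0))
            else:
                padj = float(rng.uniform(0.051, 0.999))
                lfc = float(rng.normal(0.0, 0.2))
            rows.append({"gene": gene, "log2FC": lfc, "padj": padj, "contrast": contrast})
        return pd.DataFrame(rows)

    table_a = make_table(a_only_down | shared_down_genes, a_only_up | shared_up_genes, "A")
    table_b = make_table(b_only_down | shared_down_genes, b_only_up | shared_up_genes, "B")
    truth = {
        "down_a_only": sorted(a_only_down),
        "down_shared": sorted(shared_down_genes),
        "down_b_only": sorted(b_only_down),
        "up_a_only": sorted(a_only_up),
        "up_shared": sorted(shared_up_genes),
        "up_b_only": sorted(b_only_up),
    }
    return table_a, table_b, truth


# ---------------------------------------------------------------------------
# UTRs


_SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def _site_string(seed7: str, site_class: str) -> tuple[str, bool, bool]:
    """Embedded site string plus whether flank guards are needed (up, down)."""
    site6 = _revcomp(seed7[:6])
    m8c = _revcomp(seed7[6])[0]
    if site_class == "8mer":
        return m8c + site6 + "A", False, False
    if site_class == "7mer-m8":
        return m8c + site6, False, True  # downstream must not be A
    if site_class == "7mer-A1":
        return site6 + "A", True, False  # upstream must not be the m8 complement
    if site_class == "6mer":
        return site6, True, True
    raise ValueError(f"unknown site class {site_class!r}")


def generate_utrs(
    plants: dict[str, list[tuple[str, str]]],
    utr_length: int = 120,
    seed: int = 0,
    max_attempts: int = 1000,
    max_retries: int = 50,
) -> tuple[dict[str, str], pd.DataFrame]:
    """3'UTRs with planted seed sites and site-free background.

    `plants` maps transcript id -> list of (seed, site_class) where seed
    is a 7-mer (mature positions 2-8; position 8 is needed to realize m8
    sites) and site_class is one of 8mer/7mer-m8/7mer-A1/6mer. Background
    sequence is rejection-sampled so it contains no accidental 6mer core
    for any planted seed, and flank guards prevent class upgrades at the
    planted site boundaries. Each transcript is verified by rescanning
    with every planted seed: the three flagging classes must match the
    plan exactly (extra 6mers can arise inside sites of overlapping
    seeds and are tolerated). Designs that are structurally unrealizable
    raise, e.g. an 8mer for one seed unavoidably flags a 1-nt-shifted
    seed because the two sites share their pairing region. Returns
    (utrs, truth table).
    """
    from isomirkit.targets import scan_seed_sites

    rng = np.random.default_rng(seed)
    all_seeds = {_normalize_utr(s) for sites in plants.values() for s, _ in sites}
    for s in all_seeds:
        if len(s) != 7:
            raise ValueError("planted seeds must be 7 nt (mature positions 2-8)")
    forbidden_cores = {_revcomp(s[:6]) for s in all_seeds}

    def clean_background(length: int) -> str:
        for _ in range(max_attempts):
            candidate = "".join(rng.choice(_BASES, size=length))
            if not any(core in candidate for core in forbidden_cores):
                return candidate
        raise RuntimeError("could not sample site-free background; shorten the UTRs")

    _CLASS_COLUMNS = {
        "8mer": "site_8mer",
        "7mer-m8": "site_7mer_m8",
        "7mer-A1": "site_7mer_a1",
        "6mer": "site_6mer",
    }

    def build_transcript(sites: list[tuple[str, str]]) -> str:
        n_sites = len(sites)
        segment = max(10, utr_length // (n_sites + 1)) if n_sites else utr_length
        parts = [clean_background(segment)]
        for seed_str, site_class in sites:
            seed7 = _normalize_utr(seed_str)
            site, guard_up, guard_down = _site_string(seed7, site_class)
            m8c = _revcomp(seed7[6])[0]
            before = parts[-1]
            if guard_up and before and before[-1] == m8c:
                replacement = str(rng.choice([b for b in "ACGU" if b != m8c]))
                parts[-1] = before[:-1] + replacement
            parts.append(site)
            after = clean_background(segment)
            if guard_down and after[0] == "A":
                after = str(rng.choice(["C", "G", "U"])) + after[1:]
            parts.append(after)
        return "".join(parts)

    def verify(full: str, sites: list[tuple[str, str]]) -> bool:
        planned: dict[str, dict[str, int]] = {}
        for seed_str, site_class in sites:
            seed7 = _normalize_utr(seed_str)
            planned.setdefault(seed7, {c: 0 for c in _SITE_CLASSES})
            planned[seed7][site_class] += 1
        for seed7 in all_seeds:
            report = scan_seed_sites({"t": full}, seed7).loc["t"]
            expected = planned.get(seed7, {c: 0 for c in _SITE_CLASSES})
            for site_class in ("8mer", "7mer-m8", "7mer-A1"):
                if int(report[_CLASS_COLUMNS[site_class]]) != expected[site_class]:
                    return False
            if int(report["site_6mer"]) < expected["6mer"]:
                return False
        return True

    utrs: dict[str, str] = {}
    truth_rows = []
    for transcript, sites in plants.items():
        for attempt in range(max_retries):
            full = build_transcript(sites)
            if verify(full, sites):
                break
        else:
            raise RuntimeError(
                f"transcript {transcript!r}: planted design not realizable "
                "(overlapping seeds can force extra flagging sites; use 7mer-m8 "
                "or 6mer plants for 1-nt-shifted seed pairs)"
            )
        utrs[transcript] = full
        for seed_str, site_class in sites:
            truth_rows.append(
                {
                    "transcript": transcript,
                    "seed": _normalize_utr(seed_str),
                    "site_class": site_class,
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["transcript", "seed", "site_class"])
    return utrs, truth


def write_utr_fasta(utrs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for transcript, sequence in utrs.items():
            handle.write(f">{transcript}\n{sequence}\n")
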