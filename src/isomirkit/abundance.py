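"""Relative-abundance filtering and count normalization for isomiR matrices.

Distinct sequences that amount to a tiny fraction of their parent miRNA's
reads are overwhelmingly sequencing-error artefacts: a per-base
substitution rate epsilon spreads roughly epsilon/3 of a miRNA's reads
onto each (position, alternative base) single-error sequence, so at
epsilon ~ 1e-3 (Q30) every error-born row sits far below 1% of its parent.
The 1% relative-abundance filter removes those rows; its behaviour can be
validated in silico with `validate_filter_by_simulation`.

Normalization follows the median-of-ratios scheme: a pseudo-reference
sample is the per-row geometric mean over samples (rows with any zero are
ignored), and each sample's size factor is the median of its count/
reference ratios.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from isomirkit.caller import AssignmentPolicy, CollapsedRead, classify_reads
from isomirkit.reference import ReferenceIndex

_META_COLUMNS = ["display_name", "sequence", "mature_name", "variant_class", "seed_conserved"]


@dataclass
class ExpressionMatrix:
    """Sequences x samples counts with raw/RPM/normalized layers.

    Rows are identified by ``display_name|sequence``; ``row_meta`` carries
    the sequence, parent mature, variant class and seed-conservation flag;
    ``sample_datasets`` maps each sample column to its dataset label.
    """

    counts: pd.DataFrame
    row_meta: pd.DataFrame
    sample_datasets: dict[str, str]
    layers: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.row_meta.index):
            raise ValueError("counts and row_meta must share the same row index")
        missing = set(self.counts.columns) - set(self.sample_datasets)
        if missing:
            raise ValueError(f"samples without dataset label: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.layers.setdefault("raw", self.counts)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def datasets(self) -> list[str]:
        seen: list[str] = []
        for sample in self.samples:
            ds = self.sample_datasets[sample]
            if ds not in seen:
                seen.append(ds)
        return seen

    def dataset_samples(self, dataset: str) -> list[str]:
        return [s for s in self.samples if self.sample_datasets[s] == dataset]

    def subset_rows(self, row_ids: pd.Index) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts.loc[row_ids].copy(),
            row_meta=self.row_meta.loc[row_ids].copy(),
            sample_datasets=dict(self.sample_datasets),
            layers={name: layer.loc[row_ids].copy() for name, layer in self.layers.items()},
        )

    @classmethod
    def from_call_table(
        cls,
        calls: pd.DataFrame,
        sample_datasets: dict[str, str],
    ) -> "ExpressionMatrix":
        """Build a matrix from `classify_reads` output.

        Sample columns are those named in sample_datasets; classification
        columns become row metadata.
        """
        samples = [s for s in calls.columns if s in sample_datasets]
        if not samples:
            raise ValueError("no sample columns of the call table match sample_datasets")
        table = calls.copy()
        table.index = pd.Index(
            table["display_name"] + "|" + table["sequence"], name="row_id"
        )
        counts = table[samples].astype(float)
        meta = table[[c for c in _META_COLUMNS if c in table.columns]]
        return cls(counts=counts, row_meta=meta, sample_datasets=dict(sample_datasets))

    def to_tsv(self, path: str | Path, layer: str = "raw") -> None:
        out = pd.concat([self.row_meta, self.layers[layer]], axis=1)
        out.to_csv(path, sep="\t", index_label="row_id")

    @classmethod
    def from_tsv(cls, path: str | Path, sample_datasets: dict[str, str]) -> "ExpressionMatrix":
        table = pd.read_csv(path, sep="\t", index_col="row_id")
        samples = [s for s in table.columns if s in sample_datasets]
        meta_cols = [c for c in _META_COLUMNS if c in table.columns]
        return cls(
            counts=table[samples].astype(float),
            row_meta=table[meta_cols],
            sample_datasets=dict(sample_datasets),
        )


@dataclass
class FilterReport:
    """Outcome of the relative-abundance filter."""

    threshold: float
    n_rows_before: int
    n_rows_removed: int
    rows_removed_per_parent: dict[str, int]
    counts_removed_per_sample: dict[str, float]
    removed_row_ids: list[str]

    @property
    def n_rows_retained(self) -> int:
        return self.n_rows_before - self.n_rows_removed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class NormalizationResult:
    """Median-of-ratios size factors and the geometric-mean pseudo-reference."""

    size_factors: pd.Series
    reference: pd.Series


def compute_rpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Add and return the reads-per-million layer.

    RPM[row, sample] = raw[row, sample] / column total * 1e6. Raises on an
    all-zero sample (no assigned reads), naming it.
    """
    totals = matrix.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero assigned reads: {list(zero.index)}")
    rpm = matrix.counts / totals * 1e6
    matrix.layers["rpm"] = rpm
    return rpm


def relative_abundance_filter(
    matrix: ExpressionMatrix, threshold: float = 0.01
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop rows contributing less than `threshold` of their parent miRNA.

    A row's share is its RPM divided by the summed RPM of all rows of the
    same parent miRNA, computed per sample and averaged over the samples
    of each dataset (samples where the parent has zero RPM are excluded
    from the mean). Removal uses strict inequality (share < threshold) and
    is decided per dataset independently; a row is dropped from the matrix
    only if it falls below the threshold in every dataset in which its
    parent is observed. Parents with zero RPM throughout are untouched.
    """
    if "rpm" not in matrix.layers:
        compute_rpm(matrix)
    rpm = matrix.layers["rpm"]
    parents = matrix.row_meta["mature_name"]
    parent_totals = rpm.groupby(parents).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = rpm / parent_totals  # NaN where parent total is 0
    keep = pd.Series(False, index=rpm.index)
    observed_any = pd.Series(False, index=rpm.index)
    for dataset in matrix.datasets:
        samples = matrix.dataset_samples(dataset)
        mean_share = shares[samples].mean(axis=1, skipna=True)  # NaN if parent silent
        observed = mean_share.notna()
        observed_any |= observed
        keep |= observed & (mean_share >= threshold)
    keep |= ~observed_any  # parent silent everywhere: leave rows untouched
    removed_ids = matrix.counts.index[~keep]
    report = FilterReport(
        threshold=threshold,
        n_rows_before=len(matrix.counts),
        n_rows_removed=len(removed_ids),
        rows_removed_per_parent=parents.loc[removed_ids].value_counts().to_dict(),
        counts_removed_per_sample=matrix.counts.loc[removed_ids].sum(axis=0).to_dict(),
        removed_row_ids=list(removed_ids),
    )
    return matrix.subset_rows(matrix.counts.index[keep]), report


def median_of_ratios_normalize(
    matrix: ExpressionMatrix, pseudo_reference: bool = False
) -> NormalizationResult:
    """Median-of-ratios size factors; adds the "normalized" layer.

    The pseudo-reference sample is the per-row geometric mean over
    samples; rows containing any zero are excluded. Each sample's size
    factor is the median over the remaining rows of count/reference, and
    normalized counts are raw counts divided by the size factor. With
    pseudo_reference=True the geometric mean and ratio median are taken
    over nonzero entries only (a fallback for sparse matrices with no
    all-positive row).
    """
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ValueError("median-of-ratios requires at least two samples")
    values = counts.to_numpy(dtype=float)
    if pseudo_reference:
        logs = np.full_like(values, np.nan)
        np.log(values, out=logs, where=values > 0)
        with np.errstate(invalid="ignore"):
            reference = np.exp(np.nanmean(logs, axis=1))
        usable = ~np.all(values == 0, axis=1)
    else:
        usable = (values > 0).all(axis=1)
        if not usable.any():
            raise ValueError(
                "no row with all-positive counts; rerun with pseudo_reference=True"
            )
        reference = np.full(len(values), np.nan)
        reference[usable] = np.exp(np.log(values[usable]).mean(axis=1))
    size_factors = []
    for j in range(values.shape[1]):
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = values[usable, j] / reference[usable]
        ratios = ratios[np.isfinite(ratios) & (ratios > 0)] if pseudo_reference else ratios
        if ratios.size == 0:
            raise ValueError(f"sample {counts.columns[j]!r} has no usable ratios")
        size_factors.append(float(np.median(ratios)))
    factors = pd.Series(size_factors, index=counts.columns, name="size_factor")
    matrix.layers["normalized"] = counts / factors
    return NormalizationResult(
        size_factors=factors,
        reference=pd.Series(reference, index=counts.index, name="reference"),
    )


def validate_filter_by_simulation(
    ref: ReferenceIndex,
    error_rate: float,
    library_size: int,
    thresholds: list[float],
    seed: int,
    n_samples: int = 3,
    policy: AssignmentPolicy = AssignmentPolicy(),
) -> pd.DataFrame:
    """Validate the relative-abundance filter against simulated error reads.

    Reads are drawn from canonical mature sequences only (uniform across
    matures), independent per-base substitution errors are injected at
    `error_rate`, the caller and filter are run, and for each threshold
    the table reports how many error-born rows survive and how much true
    canonical signal is lost. Deterministic under a fixed seed.
    """
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    mature_names = sorted(ref.matures)
    bases = np.frombuffer(b"ACGU", dtype="S1")
    base_index = {b"A": 0, b"C": 1, b"G": 2, b"U": 3}
    sample_ids = tuple(f"sim{i + 1}" for i in range(n_samples))
    collapsed: dict[str, list[int]] = {}
    canonical_seqs = {name: ref.mature_sequence(name) for name in mature_names}
    for s in range(n_samples):
        per_mature = rng.multinomial(library_size, np.full(len(mature_names), 1 / len(mature_names)))
        for name, n_reads in zip(mature_names, per_mature):
            seq = canonical_seqs[name]
            arr = np.frombuffer(seq.encode(), dtype="S1")
            length = len(arr)
            if error_rate > 0 and n_reads > 0:
                mask = rng.random((n_reads, length)) < error_rate
                errored = np.nonzero(mask.any(axis=1))[0]
                n_clean = n_reads - len(errored)
            else:
                errored = np.empty(0, dtype=int)
                n_clean = n_reads
            if n_clean:
                collapsed.setdefault(seq, [0] * n_samples)[s] += int(n_clean)
            for row in errored:
                read = arr.copy()
                for pos in np.nonzero(mask[row])[0]:
                    current = base_index[read[pos].tobytes()]
                    read[pos] = bases[(current + rng.integers(1, 4)) % 4]
                mutated = read.tobytes().decode()
                collapsed.setdefault(mutated, [0] * n_samples)[s] += 1
    reads = [
        CollapsedRead(sequence=seq, counts=tuple(c), sample_ids=sample_ids)
        for seq, c in sorted(collapsed.items())
    ]
    calls, _ = classify_reads(reads, ref, policy)
    matrix = ExpressionMatrix.from_call_table(
        calls, {s: "sim" for s in sample_ids}
    )
    compute_rpm(matrix)
    canonical_truth = set(canonical_seqs.values())
    is_error_row = ~matrix.row_meta["sequence"].isin(canonical_truth)
    total_canonical = float(matrix.counts.loc[~is_error_row].to_numpy().sum())
    rows = []
    for threshold in thresholds:
        filtered, _report = relative_abundance_filter(matrix, threshold=threshold)
        surviving_error = filtered.row_meta.index[
            ~filtered.row_meta["sequence"].isin(canonical_truth)
        ]
        surviving_canonical = float(
            filtered.counts.loc[filtered.row_meta["sequence"].isin(canonical_truth)]
            .to_numpy()
            .sum()
        )
        n_error_before = int(is_error_row.sum())
        rows.append(
            {
                "threshold": threshold,
                "n_rows_before": len(matrix.counts),
                "n_error_rows_before": n_error_before,
                "n_error_rows_surviving": len(surviving_error),
                "spurious_survival_fraction": (
                    len(surviving_error) / n_error_before if n_error_before else 0.0
                ),
                "error_fraction_of_survivors": (
                    len(surviving_error) / len(filtered.counts) if len(filtered.counts) else 0.0
                ),
                "canonical_loss_fraction": (
                    1.0 - surviving_canonical / total_canonical if total_canonical else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
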