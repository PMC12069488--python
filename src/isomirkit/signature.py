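"""Cross-dataset isomiR signature: three-step filter plus intersection.

Per dataset, sequences survive if they are (1) not the canonical mature
sequence, (2) expressed at a mean of at least ``min_mean`` normalized
counts, and (3) contribute at least ``min_contribution`` of their
corresponding canonical sequence's expression. The signature is the
intersection of survivors over all datasets; the per-step survivor counts
(the filtering funnel) are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from isomirkit.abundance import ExpressionMatrix
from isomirkit.caller import VariantClass


@dataclass
class SignatureEntry:
    """One signature sequence with its per-dataset support."""

    row_id: str
    display_name: str
    sequence: str
    mature_name: str
    variant_class: str
    seed_conserved: bool
    mean_normalized: dict[str, float]
    contribution: dict[str, float]


def _dataset_means(matrix: ExpressionMatrix, dataset: str, layer: str) -> pd.Series:
    samples = matrix.dataset_samples(dataset) or matrix.samples
    return matrix.layers[layer][samples].mean(axis=1)


def derive_signature(
    matrices: dict[str, ExpressionMatrix],
    min_mean: float = 20.0,
    min_contribution: float = 0.5,
    denominator: str = "canonical_sequence",
    layer: str = "normalized",
) -> tuple[list[SignatureEntry], dict]:
    """Derive the cross-dataset isomiR signature.

    Step 2 keeps sequences with mean normalized counts >= min_mean
    (exclusion below the threshold); step 3's contribution is the
    sequence's mean counts divided by the canonical sequence's mean
    counts for the same miRNA (denominator="canonical_sequence") or by
    the miRNA's total mean counts (denominator="mirna_total"). A miRNA
    expressed with no canonical sequence gives an infinite ratio, which
    passes. Returns (entries, funnel) where funnel maps each dataset to
    the survivor counts after steps 0-3 plus the final intersection size.
    """
    if denominator not in ("canonical_sequence", "mirna_total"):
        raise ValueError("denominator must be 'canonical_sequence' or 'mirna_total'")
    survivors: dict[str, pd.Index] = {}
    funnel: dict[str, object] = {}
    stats: dict[str, dict[str, pd.Series]] = {}
    for dataset, matrix in matrices.items():
        meta = matrix.row_meta
        for column in ("variant_class", "mature_name"):
            if column not in meta.columns:
                raise ValueError(f"dataset {dataset!r}: matrix lacks {column!r} metadata")
        if layer not in matrix.layers:
            raise ValueError(f"dataset {dataset!r}: layer {layer!r} not computed")
        means = _dataset_means(matrix, dataset, layer)
        is_canonical = meta["variant_class"] == str(VariantClass.Canonical)
        step1 = means.index[~is_canonical]
        step2 = step1[means.loc[step1] >= min_mean]
        canonical_means = (
            means[is_canonical].groupby(meta.loc[is_canonical, "mature_name"]).sum()
        )
        if denominator == "canonical_sequence":
            denom = meta["mature_name"].map(canonical_means)
        else:
            denom = meta["mature_name"].map(means.groupby(meta["mature_name"]).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            contribution = means / denom
        contribution = contribution.where(
            ~(denom.isna() | (denom == 0)), np.inf
        )  # no canonical expression: isomiR-only miRNA passes
        step3 = step2[contribution.loc[step2] >= min_contribution]
        survivors[dataset] = step3
        stats[dataset] = {"means": means, "contribution": contribution}
        funnel[dataset] = {
            "input": int(len(means)),
            "after_remove_canonical": int(len(step1)),
            "after_min_mean": int(len(step2)),
            "after_min_contribution": int(len(step3)),
        }
    shared: set[str] | None = None
    for index in survivors.values():
        shared = set(index) if shared is None else shared & set(index)
    shared = shared or set()
    funnel["intersection"] = len(shared)
    entries = []
    for row_id in sorted(shared):
        meta_row = None
        for matrix in matrices.values():
            if row_id in matrix.row_meta.index:
                meta_row = matrix.row_meta.loc[row_id]
                break
        assert meta_row is not None
        entries.append(
            SignatureEntry(
                row_id=row_id,
                display_name=str(meta_row.get("display_name", row_id.split("|")[0])),
                sequence=str(meta_row.get("sequence", row_id.split("|")[-1])),
                mature_name=str(meta_row["mature_name"]),
                variant_class=str(meta_row["variant_class"]),
                seed_conserved=bool(meta_row.get("seed_conserved", False)),
                mean_normalized={
                    ds: float(stats[ds]["means"].get(row_id, np.nan)) for ds in matrices
                },
                contribution={
                    ds: float(stats[ds]["contribution"].get(row_id, np.nan))
                    for ds in matrices
                },
            )
        )
    return entries, funnel


def partition_by_seed(
    entries: list[SignatureEntry],
) -> tuple[list[SignatureEntry], list[SignatureEntry]]:
    """Split signature entries into (seed-shifted, seed-conserved).

    5' length variants (Trim5p/Ext5p) must carry seed_conserved=False; an
    inconsistent flag indicates a caller bug and raises.
    """
    shifted, conserved = [], []
    five_prime = {str(VariantClass.Trim5p), str(VariantClass.Ext5p)}
    for entry in entries:
        if entry.variant_class in five_prime and entry.seed_conserved:
            raise ValueError(
                f"{entry.display_name}: 5' length variant flagged seed-conserved "
                "(inconsistent classification)"
            )
        (conserved if entry.seed_conserved else shifted).append(entry)
    return shifted, conserved


def signature_table(entries: list[SignatureEntry]) -> pd.DataFrame:
    """Flatten signature entries into a TSV-ready table."""
    rows = []
    for entry in entries:
        row = {
            "row_id": entry.row_id,
            "display_name": entry.display_name,
            "sequence": entry.sequence,
            "mature_name": entry.mature_name,
            "variant_class": entry.variant_class,
            "seed_conserved": entry.seed_conserved,
        }
        for ds, value in entry.mean_normalized.items():
            row[f"mean_normalized.{ds}"] = value
        for ds, value in entry.contribution.items():
            row[f"contribution.{ds}"] = value
        rows.append(row)
    return pd.DataFrame(rows)
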