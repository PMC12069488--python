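"""Per-miRNA isomiR class composition, dominant classes, and PCA embedding.

Composition is a within-miRNA proportion: for each miRNA and each variant
class, the mean (over a dataset's samples) of class counts divided by the
miRNA's total counts in that sample. Because the fractions are
within-miRNA, they are invariant to per-sample scaling and can be
compared across datasets and external cell-type panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from isomirkit.abundance import ExpressionMatrix
from isomirkit.caller import CLASS_PRECEDENCE

CLASS_NAMES = [str(c) for c in CLASS_PRECEDENCE]


@dataclass
class CompositionEmbedding:
    """PCA scores/loadings over composition feature vectors."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    imputed_features: list[str]


def class_fractions(
    matrix: ExpressionMatrix, dataset: str, layer: str = "normalized"
) -> pd.DataFrame:
    """Per-miRNA class-fraction profile for one dataset.

    Returns a DataFrame indexed by mature miRNA with one column per
    variant class (fractions summing to 1) plus ``total``, the summed
    normalized counts over the dataset's samples. Samples where the miRNA
    has zero counts are excluded from the mean; miRNAs absent from the
    dataset are omitted.
    """
    samples = matrix.dataset_samples(dataset)
    if not samples:
        raise ValueError(f"no samples labelled with dataset {dataset!r}")
    values = matrix.layers[layer][samples]
    grouped = values.groupby(
        [matrix.row_meta["mature_name"], matrix.row_meta["variant_class"]]
    ).sum()
    per_class = grouped.unstack(level=1).fillna(0.0)  # miRNA x (class, sample)
    profiles = {}
    for mirna in per_class.index:
        block = per_class.loc[mirna].unstack(level=1)  # sample x class
        block = block.reindex(columns=CLASS_NAMES, fill_value=0.0)
        totals = block.sum(axis=1)
        expressed = totals > 0
        if not expressed.any():
            continue
        fractions = block.loc[expressed].div(totals[expressed], axis=0).mean(axis=0)
        profiles[mirna] = fractions.to_dict() | {"total": float(totals.sum())}
    result = pd.DataFrame.from_dict(profiles, orient="index")
    if len(result):
        result = result[CLASS_NAMES + ["total"]]
        result.index.name = "mature_name"
    return result


def dominant_class(profile: pd.DataFrame) -> pd.DataFrame:
    """Assign each miRNA to the class contributing most to its expression.

    Ties are broken by the fixed precedence Canonical > Trim3p > Ext3p >
    NTA > Trim5p > Ext5p > NucVar > MultiVariant.
    """
    fractions = profile[CLASS_NAMES]
    rows = []
    for mirna, row in fractions.iterrows():
        best = max(CLASS_NAMES, key=lambda c: (row[c], -CLASS_NAMES.index(c)))
        rows.append({"mature_name": mirna, "class": best, "fraction": float(row[best])})
    return pd.DataFrame(rows).set_index("mature_name")


def select_consistent_mirnas(
    matrices: dict[str, ExpressionMatrix],
    min_mean: float = 20.0,
    layer: str = "normalized",
) -> set[str]:
    """miRNAs whose summed expression exceeds min_mean in every dataset.

    Expression is aggregated over all sequences of the miRNA, averaged
    over each dataset's samples; the comparison is strict (> min_mean).
    """
    if not matrices:
        raise ValueError("at least one dataset is required")
    selected: set[str] | None = None
    for dataset, matrix in matrices.items():
        samples = matrix.dataset_samples(dataset) or matrix.samples
        means = (
            matrix.layers[layer][samples]
            .groupby(matrix.row_meta["mature_name"])
            .sum()
            .mean(axis=1)
        )
        passing = set(means.index[means > min_mean])
        selected = passing if selected is None else selected & passing
    return selected or set()


def composition_pca(
    profiles: dict[str, pd.DataFrame],
    mirna_set: set[str] | list[str],
    n_components: int | None = None,
    scale: bool = False,
) -> CompositionEmbedding:
    """PCA of per-(miRNA, class) composition vectors across units.

    Each unit (a dataset or an external cell type) contributes one feature
    vector: the concatenated class fractions over the shared miRNA set.
    Features for miRNAs missing from a unit are imputed as 0 and reported
    in ``imputed_features``. Columns are centered; unit-variance scaling
    is off by default because features are same-unit fractions. The sign
    of each component is fixed so its largest-magnitude loading is
    positive.
    """
    if len(profiles) < 3:
        raise ValueError("composition PCA requires at least 3 units")
    mirnas = sorted(mirna_set)
    feature_names = [f"{m}:{c}" for m in mirnas for c in CLASS_NAMES]
    units = sorted(profiles)
    data = np.zeros((len(units), len(feature_names)))
    imputed: list[str] = []
    for i, unit in enumerate(units):
        profile = profiles[unit]
        for j, m in enumerate(mirnas):
            if m in profile.index:
                data[i, j * len(CLASS_NAMES) : (j + 1) * len(CLASS_NAMES)] = (
                    profile.loc[m, CLASS_NAMES].to_numpy()
                )
            else:
                imputed.append(f"{unit}:{m}")
    if scale:
        sd = data.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        data = data / sd
    max_components = min(len(units) - 1, data.shape[1])
    k = max_components if n_components is None else min(n_components, max_components)
    pca = PCA(n_components=k, svd_solver="full")
    with np.errstate(invalid="ignore"):
        scores = pca.fit_transform(data)
    loadings = pca.components_
    variance_ratio = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
    for comp in range(k):  # deterministic sign: largest-|loading| positive
        pivot = np.argmax(np.abs(loadings[comp]))
        if loadings[comp, pivot] < 0:
            loadings[comp] *= -1
            scores[:, comp] *= -1
    pc_names = [f"PC{i + 1}" for i in range(k)]
    return CompositionEmbedding(
        scores=pd.DataFrame(scores, index=units, columns=pc_names),
        loadings=pd.DataFrame(loadings, index=pc_names, columns=feature_names),
        explained_variance_ratio=variance_ratio,
        imputed_features=imputed,
    )
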