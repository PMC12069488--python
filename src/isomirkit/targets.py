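"""Regulated-gene set algebra, hypergeometric overlap, and seed-site scanning.

A 5'-shifted isomiR carries a different seed (mature positions 2-7) than
its canonical miRNA and therefore recognizes a largely different target
set. This module consumes externally produced differential-expression
tables, partitions regulated genes into exclusive and shared sets, tests
overlap sizes with the one-sided hypergeometric upper tail, and
demonstrates targetome divergence directly by scanning 3'UTR sequences
for the four canonical seed-site classes:

    6mer      perfect match to seed positions 2-7
    7mer-m8   6mer plus a match to mature position 8
    7mer-A1   6mer plus an A opposite mature position 1
    8mer      both the position-8 match and the A1

A transcript is a predicted target if it carries at least one 7mer-A1,
7mer-m8 or 8mer site (6mers are counted but do not flag).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def _normalize_utr(sequence: str) -> str:
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"unexpected characters in UTR sequence: {sorted(bad)}")
    return seq


def _revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def select_regulated(table: pd.DataFrame, direction: str, fdr: float = 0.05) -> set[str]:
    """Genes with adjusted p < fdr and fold change in the given direction."""
    required = {"gene", "log2FC", "padj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table lacks columns {sorted(missing)}")
    if direction == "down":
        mask = (table["padj"] < fdr) & (table["log2FC"] < 0)
    elif direction == "up":
        mask = (table["padj"] < fdr) & (table["log2FC"] > 0)
    else:
        raise ValueError("direction must be 'down' or 'up'")
    return set(table.loc[mask, "gene"])


def exclusive_and_shared(
    set_a: set[str], set_b: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Partition two gene sets into (A-only, shared, B-only)."""
    shared = set_a & set_b
    return set_a - shared, shared, set_b - shared


def hypergeometric_overlap(N: int, K: int, n: int, k: int) -> float:
    """One-sided enrichment p value P(X >= k), X ~ Hypergeometric(N, K, n).

    Computed by exact summation of the probability mass in log space.
    Raises on infeasible (N, K, n, k).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"infeasible set sizes: N={N}, K={K}, n={n}")
    upper = min(K, n)
    lower = max(0, K + n - N)
    if not (lower <= k <= upper):
        raise ValueError(f"infeasible overlap k={k} for N={N}, K={K}, n={n}")
    if k <= lower:
        return 1.0  # every draw has at least the forced overlap

    def log_choose(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    terms = [
        log_choose(K, i) + log_choose(N - K, n - i) - log_choose(N, n)
        for i in range(k, upper + 1)
    ]
    return float(min(1.0, np.exp(logsumexp(terms))))


def _split_seed(seed: str, pos8: str | None) -> tuple[str, str | None]:
    seed = _normalize_utr(seed)
    if len(seed) == 7:
        if pos8 is not None:
            raise ValueError("pass either a 7-mer seed or an explicit pos8, not both")
        return seed[:6], seed[6]
    if len(seed) != 6:
        raise ValueError("seed must be 6 nt (positions 2-7) or 7 nt (positions 2-8)")
    return seed, pos8


def scan_seed_sites(
    utrs: dict[str, str] | str | Path,
    seed: str,
    pos8: str | None = None,
) -> pd.DataFrame:
    """Count canonical seed sites per transcript for one miRNA seed.

    ``utrs`` is a mapping transcript id -> sequence, or a FASTA path.
    ``seed`` is mature positions 2-7 (6 nt) or 2-8 (7 nt, in which case
    the 7th base supplies position 8 for m8-site detection). A site is
    the reverse complement of the seed in the UTR; each occurrence is
    counted once in its most specific class (8mer > 7mer > 6mer).
    Positions containing N never match.
    """
    if not isinstance(utrs, dict):
        utrs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(utrs), "fasta")}
    seed6, pos8 = _split_seed(seed, pos8)
    site6 = _revcomp(seed6)
    m8_base = _revcomp(pos8)[0] if pos8 else None  # complement of mature position 8
    rows = []
    for transcript, raw in utrs.items():
        utr = _normalize_utr(raw)
        counts = {"8mer": 0, "7mer-m8": 0, "7mer-A1": 0, "6mer": 0}
        start = 0
        while True:
            i = utr.find(site6, start)
            if i < 0:
                break
            start = i + 1
            has_m8 = m8_base is not None and i > 0 and utr[i - 1] == m8_base
            has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
            if has_m8 and has_a1:
                counts["8mer"] += 1
            elif has_m8:
                counts["7mer-m8"] += 1
            elif has_a1:
                counts["7mer-A1"] += 1
            else:
                counts["6mer"] += 1
        rows.append(
            {
                "transcript": transcript,
                "site_8mer": counts["8mer"],
                "site_7mer_m8": counts["7mer-m8"],
                "site_7mer_a1": counts["7mer-A1"],
                "site_6mer": counts["6mer"],
                "predicted_target": (
                    counts["8mer"] + counts["7mer-m8"] + counts["7mer-A1"] > 0
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript",
            "site_8mer",
            "site_7mer_m8",
            "site_7mer_a1",
            "site_6mer",
            "predicted_target",
        ],
    ).set_index("transcript")


def compare_targetomes(
    seed_a: str,
    seed_b: str,
    utrs: dict[str, str] | str | Path,
    pos8_a: str | None = None,
    pos8_b: str | None = None,
) -> tuple[set[str], set[str], set[str]]:
    """Predicted-target partition (A-only, shared, B-only) for two seeds."""
    report_a = scan_seed_sites(utrs, seed_a, pos8_a)
    report_b = scan_seed_sites(utrs, seed_b, pos8_b)
    targets_a = set(report_a.index[report_a["predicted_target"]])
    targets_b = set(report_b.index[report_b["predicted_target"]])
    return exclusive_and_shared(targets_a, targets_b)


def load_de_table(path: str | Path, contrast: str | None = None) -> pd.DataFrame:
    """Load a differential-expression TSV (columns gene, log2FC, padj)."""
    table = pd.read_csv(path, sep="\t")
    if contrast is not None and "contrast" in table.columns:
        table = table[table["contrast"] == contrast]
    if table["gene"].duplicated().any():
        raise ValueError(f"duplicate gene symbols in DE table {path}")
    return table.reset_index(drop=True)
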