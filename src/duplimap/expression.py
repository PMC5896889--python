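"""Post-differential-expression summaries of genome-wide misexpression.

White hybrid seedlings are compared against each green class (the two
parental lines and green F2s) in three pairwise DE tests; a gene counts as
misexpressed only when significant in all three. The module intersects the
three comparisons, averages log2 fold-changes, Z-scores FPKM rows for
heatmap display, and tallies mis-regulation within chloroplast polymerase
classes (PEP, PEP-and-NEP, NEP) — PEP-transcribed photosynthesis genes are
expected down and NEP-transcribed rpo genes up when PEP function is lost.
A planted-truth simulator stands in for the upstream DE caller so the
stage is testable without RNA-seq data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEComparison",
    "intersect_significant",
    "row_zscore",
    "class_misexpression_report",
    "simulate_de_tables",
]


@dataclass
class DEComparison:
    """One white-vs-green pairwise comparison: per-gene log2FC + flag."""

    comparison_id: str
    table: pd.DataFrame  # columns: gene, log2fc, significant [, q_value]

    def __post_init__(self):
        need = {"gene", "log2fc", "significant"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"comparison table needs columns {sorted(need)}")
        if self.table["gene"].duplicated().any():
            raise ValueError("one record per gene required")


def intersect_significant(comparisons: Sequence[DEComparison]) -> pd.DataFrame:
    """Genes significant in every comparison, with mean log2FC and direction.

    All comparisons must share one gene universe. The returned frame has
    columns gene, mean_log2fc, direction ('up' = overexpressed in white),
    and sign_discordant (True when the three log2FCs disagree in sign —
    surfaced but not used to exclude genes).
    """
    if len(comparisons) < 2:
        raise ValueError("need at least two comparisons")
    universes = [frozenset(c.table["gene"]) for c in comparisons]
    if len(set(universes)) != 1:
        raise ValueError("comparisons have different gene universes")
    merged = None
    for i, c in enumerate(comparisons):
        t = c.table[["gene", "log2fc", "significant"]].rename(
            columns={"log2fc": f"log2fc_{i}", "significant": f"sig_{i}"}
        )
        merged = t if merged is None else merged.merge(t, on="gene")
    sig_cols = [f"sig_{i}" for i in range(len(comparisons))]
    fc_cols = [f"log2fc_{i}" for i in range(len(comparisons))]
    hit = merged[sig_cols].all(axis=1)
    out = merged.loc[hit, ["gene"]].copy()
    fcs = merged.loc[hit, fc_cols].to_numpy()
    out["mean_log2fc"] = fcs.mean(axis=1)
    out["direction"] = np.where(out["mean_log2fc"] >= 0, "up", "down")
    signs = np.sign(fcs)
    out["sign_discordant"] = [
        len({s for s in row if s != 0}) > 1 for row in signs
    ]
    return out.reset_index(drop=True)


def row_zscore(matrix: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Z-score each gene (row) across samples for heatmap display.

    Uses the population standard deviation (divisor n) by default; constant
    rows map to all zeros. Negative abundances are rejected — the input is
    an FPKM-scale matrix.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def class_misexpression_report(genes: pd.DataFrame,
                               class_map: Mapping[str, str]) -> pd.DataFrame:
    """Count up/down-misexpressed genes per polymerase class.

    ``genes`` is the output of :func:`intersect_significant`; ``class_map``
    maps gene ids to 'PEP', 'PEP_and_NEP' or 'NEP'. Genes absent from the
    map are tallied under 'unmapped'. Returns one row per (class,
    direction) with counts and the gene lists.
    """
    classes = ("PEP", "PEP_and_NEP", "NEP", "unmapped")
    bucket = {(c, d): [] for c in classes for d in ("up", "down")}
    for row in genes.itertuples():
        cls = class_map.get(row.gene, "unmapped")
        if cls not in classes:
            raise ValueError(f"unknown polymerase class {cls!r}")
        bucket[(cls, row.direction)].append(row.gene)
    rows = [
        {"class": c, "direction": d, "n_genes": len(bucket[(c, d)]),
         "genes": ",".join(bucket[(c, d)])}
        for c in classes for d in ("up", "down")
    ]
    return pd.DataFrame(rows)


def simulate_de_tables(n_genes: int, fraction_misexpressed: float,
                       effect_size: float = 2.0, fp_rate: float = 0.01,
                       seed=None, n_samples_per_class: int = 3):
    """Plant a ground-truth misexpression signal and emit three DE tables.

    Truly misexpressed genes get a log2FC of ±``effect_size`` (sign split
    evenly, consistent across the three comparisons, observed with N(0,0.25)
    noise) and are flagged in all three; null genes have N(0,0.25) log2FC
    and are flagged independently at ``fp_rate`` per comparison. Also
    returns a matching FPKM-scale matrix (classes: gutt, nas, green F2,
    white F2) and the planted truth table.
    """
    if not (0.0 <= fraction_misexpressed <= 1.0):
        raise ValueError("fraction_misexpressed must be in [0, 1]")
    if not (0.0 <= fp_rate < 1.0):
        raise ValueError("fp_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = np.array([f"gene{i:06d}" for i in range(n_genes)])
    n_true = int(round(n_genes * fraction_misexpressed))
    truth = np.zeros(n_genes, dtype=bool)
    idx = rng.choice(n_genes, size=n_true, replace=False)
    truth[idx] = True
    sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)

    comparisons = []
    for cid in ("white_vs_gutt", "white_vs_nas", "white_vs_greenF2"):
        noise = rng.normal(0.0, 0.5, size=n_genes)
        log2fc = np.where(truth, sign * effect_size, 0.0) + noise
        flagged = truth | (rng.random(n_genes) < fp_rate)
        comparisons.append(
            DEComparison(
                cid,
                pd.DataFrame(
                    {"gene": genes, "log2fc": log2fc, "significant": flagged}
                ),
            )
        )

    base = rng.lognormal(mean=2.0, sigma=1.0, size=n_genes)
    cols = {}
    for cls in ("gutt", "nas", "greenF2", "whiteF2"):
        mult = np.ones(n_genes)
        if cls == "whiteF2":
            mult = np.where(truth, 2.0 ** (sign * effect_size), 1.0)
        for rep in range(n_samples_per_class):
            noise = rng.lognormal(0.0, 0.1, size=n_genes)
            cols[f"{cls}_{rep + 1}"] = base * mult * noise
    matrix = pd.DataFrame(cols, index=genes)
    truth_table = pd.DataFrame(
        {"gene": genes, "misexpressed": truth,
         "planted_log2fc": np.where(truth, sign * effect_size, 0.0)}
    )
    return comparisons, matrix, truth_table
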