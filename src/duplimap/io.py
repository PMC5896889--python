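"""Plain-TSV readers and writers for the pipeline's tables.

All tables are tab-separated with a header row. Intervals use 0-based,
half-open coordinates (BED convention).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .finemap import RecombinantRecord
from .segregation import CrossCounts
from .sim import LinkageMap, SnpPanel


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cross_counts(path) -> list[CrossCounts]:
    """Read a cross-count table: cross_class, maternal, n_green, n_white."""
    df = pd.read_csv(path, sep="\t")
    return [
        CrossCounts(r.cross_class, str(r.maternal), int(r.n_green), int(r.n_white))
        for r in df.itertuples()
    ]


def write_cross_counts(counts: Iterable[CrossCounts], path) -> None:
    write_tsv(
        pd.DataFrame(
            [
                {"cross_class": c.cross_class, "maternal": c.maternal,
                 "n_green": c.n_green, "n_white": c.n_white}
                for c in counts
            ]
        ),
        path,
    )


def write_linkage_map(map: LinkageMap, path) -> None:
    write_tsv(map.to_frame(), path)


def read_linkage_map(path, chromosomes=None) -> LinkageMap:
    """Read a locus table; chromosome lengths default to the max locus cM."""
    df = pd.read_csv(path, sep="\t")
    if chromosomes is None:
        chromosomes = [
            (chrom, float(sub["pos_cm"].max()))
            for chrom, sub in df.groupby("chrom", sort=False)
        ]
    loci = [
        (r.locus_id, r.chrom, r.pos_cm,
         None if pd.isna(r.pos_bp) else r.pos_bp)
        for r in df.itertuples()
    ]
    return LinkageMap(chromosomes, loci)


def write_snp_panel(panel: SnpPanel, path) -> None:
    write_tsv(panel.table, path)


def read_snp_panel(path) -> SnpPanel:
    return SnpPanel(pd.read_csv(path, sep="\t"))


def read_pool_counts(path, pool_id=None) -> pd.DataFrame:
    """Read pool counts (chrom, pos, ref_depth, alt_depth [, pool_id])."""
    df = pd.read_csv(path, sep="\t")
    if pool_id is not None and "pool_id" in df.columns:
        df = df[df["pool_id"] == pool_id].drop(columns="pool_id")
    return df.reset_index(drop=True)


def write_pool_counts(counts: pd.DataFrame, path, pool_id=None) -> None:
    df = counts.copy()
    if pool_id is not None:
        df["pool_id"] = pool_id
    write_tsv(df, path)


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Write candidate regions as BED3+ (chrom, start, end, extra columns)."""
    cols = ["chrom", "start_bp", "end_bp"] + [
        c for c in regions.columns if c not in ("chrom", "start_bp", "end_bp")
    ]
    regions[cols].to_csv(path, sep="\t", index=False, header=False)


def read_recombinants(path, marker_ids: Sequence[str]) -> list[RecombinantRecord]:
    """Read a recombinant table: one row per individual.

    Expected columns: individual, phenotype, partner (optional), f3_green /
    f3_white (optional), then one column per marker in map order. Empty or
    '.' marker cells are missing calls.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for r in df.itertuples():
        genos = []
        for m in marker_ids:
            g = getattr(r, m, None)
            genos.append(None if g in (None, "", ".") or pd.isna(g) else g)
        f3 = None
        if "f3_green" in df.columns and not pd.isna(r.f3_green):
            f3 = (int(r.f3_green), int(getattr(r, "f3_white", 0) or 0))
        records.append(
            RecombinantRecord(
                r.individual, r.phenotype, genos,
                getattr(r, "partner", None), f3,
            )
        )
    return records
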