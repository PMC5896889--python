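"""Recombinant-driven fine mapping of the hybrid-lethality loci.

Green F2 recombinants are classified by progeny testing (a selfed family
segregating white seedlings 3:1 reveals a heterozygous parent; an all-green
family of decisive size reveals a compatible homozygote), each informative
recombinant's breakpoints constrain where the causal locus can sit, and the
intersection of those constraints across recombinants is the mapped
interval. A genotype-phenotype concordance table over the nine two-locus
marker classes summarizes how tightly flanking markers tag the causal loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "RecombinantRecord",
    "GenomicInterval",
    "InconsistencyError",
    "progeny_test",
    "minimal_decisive_family_size",
    "concordance",
    "ConcordanceResult",
    "infer_causal_genotype",
    "narrow_interval",
]

GENOTYPE_CODES = ("G", "H", "N")


@dataclass
class RecombinantRecord:
    """One phenotyped F2 with ordered marker genotypes on the target chromosome.

    ``marker_genotypes`` follow map order with codes G/H/N; ``None`` marks a
    missing call. ``f3_counts`` holds (n_green, n_white) from the selfed
    progeny test when the plant was green and grown to adulthood.
    """

    individual_id: str
    phenotype: str
    marker_genotypes: Sequence
    partner_genotype: str | None = None
    f3_counts: tuple | None = None

    def __post_init__(self):
        if self.phenotype not in ("green", "white"):
            raise ValueError("phenotype must be 'green' or 'white'")
        if len(self.marker_genotypes) < 2:
            raise ValueError("need at least two markers")
        for g in self.marker_genotypes:
            if g is not None and g not in GENOTYPE_CODES:
                raise ValueError(f"bad genotype code {g!r}")


@dataclass
class GenomicInterval:
    """Half-open, 0-based bp interval bounded by flanking markers."""

    chrom: str
    start_bp: int
    end_bp: int
    left_marker: str | None = None
    right_marker: str | None = None
    spans_assembly_gap: bool = False

    def __post_init__(self):
        if not self.start_bp < self.end_bp:
            raise ValueError("require start_bp < end_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def contains(self, bp: float) -> bool:
        return self.start_bp <= bp < self.end_bp


class InconsistencyError(ValueError):
    """No causal position satisfies every informative recombinant."""

    def __init__(self, conflicting_ids):
        self.conflicting_ids = list(conflicting_ids)
        super().__init__(
            "no marker interval is consistent with all informative records; "
            f"conflicts involve: {', '.join(self.conflicting_ids)}"
        )


# ---------------------------------------------------------------------------
# progeny tests


def progeny_test(n_green: int, n_white: int, alpha: float = 0.05) -> str:
    """Classify a selfed F3 family: segregating het vs compatible homozygote.

    Any white progeny prove the parent heterozygous (expected 3:1). An
    all-green family indicates a compatible homozygote only once it is large
    enough that observing zero whites from a true heterozygote
    (probability 0.75^n) falls below ``alpha``; smaller families are
    ambiguous.
    """
    if n_green < 0 or n_white < 0:
        raise ValueError("counts must be non-negative")
    n = n_green + n_white
    if n < 1:
        raise ValueError("empty family")
    if n_white > 0:
        return "segregating_het"
    return "homozygous_compatible" if 0.75 ** n < alpha else "ambiguous"


def minimal_decisive_family_size(alpha: float = 0.05) -> int:
    """Smallest all-green family classified homozygous_compatible (11 at 0.05)."""
    n = 1
    while 0.75 ** n >= alpha:
        n += 1
    return n


# ---------------------------------------------------------------------------
# two-locus concordance


@dataclass
class ConcordanceResult:
    table: pd.DataFrame  # counts per (hl13, hl14, phenotype)
    white_concordance: float  # NaN when no white individuals
    n_excluded: int


def concordance(genotypes: pd.DataFrame, hl13_col: str = "hl13",
                hl14_col: str = "hl14",
                phenotype_col: str = "phenotype") -> ConcordanceResult:
    """Tabulate two-locus marker genotypes against seedling phenotype.

    Returns the nine-class count table and the white-concordance fraction:
    the share of white seedlings carrying the lethal-predicted (G at the
    hl13 markers, N at the hl14 markers) class. Individuals missing either
    genotype are excluded and counted.
    """
    df = genotypes[[hl13_col, hl14_col, phenotype_col]].copy()
    complete = df[hl13_col].isin(GENOTYPE_CODES) & df[hl14_col].isin(GENOTYPE_CODES)
    n_excluded = int((~complete).sum())
    df = df[complete]
    table = (
        df.groupby([hl13_col, hl14_col, phenotype_col])
        .size()
        .rename("count")
        .reset_index()
    )
    white = df[df[phenotype_col] == "white"]
    if len(white) == 0:
        frac = float("nan")
    else:
        frac = float(
            ((white[hl13_col] == "G") & (white[hl14_col] == "N")).mean()
        )
    return ConcordanceResult(table, frac, n_excluded)


# ---------------------------------------------------------------------------
# interval narrowing


def infer_causal_genotype(record: RecombinantRecord,
                          incompatible_allele: str = "G",
                          alpha: float = 0.05) -> str:
    """Causal-locus genotype class implied by phenotype and progeny test.

    Returns 'incompatible_hom', 'het', 'compatible_hom' or 'unknown'.
    White seedlings must be homozygous for the incompatible allele at the
    target locus; green plants are resolved by their F3 segregation.
    """
    if incompatible_allele not in ("G", "N"):
        raise ValueError("incompatible_allele must be 'G' or 'N'")
    if record.phenotype == "white":
        return "incompatible_hom"
    if record.f3_counts is None:
        return "unknown"
    result = progeny_test(*record.f3_counts, alpha=alpha)
    return {
        "segregating_het": "het",
        "homozygous_compatible": "compatible_hom",
        "ambiguous": "unknown",
    }[result]


def _expected_code(cls: str, incompatible_allele: str) -> str:
    other = "N" if incompatible_allele == "G" else "G"
    return {
        "incompatible_hom": incompatible_allele,
        "het": "H",
        "compatible_hom": other,
    }[cls]


def narrow_interval(records: Sequence[RecombinantRecord],
                    markers: Sequence[tuple],
                    current: GenomicInterval,
                    incompatible_allele: str = "G",
                    alpha: float = 0.05) -> GenomicInterval:
    """Intersect recombinant constraints into the minimal marker-bounded interval.

    ``markers`` is the ordered list of ``(marker_id, bp)`` on the target
    chromosome (bp may be None across an assembly gap of unknown size).
    Every record's genotypes must parallel ``markers``. A candidate segment
    (the gap between two adjacent markers) is consistent with a record when
    the record's inferred causal genotype matches the call at either
    flanking marker (missing calls match anything — conservative, so
    intervals may be slightly wide but never wrongly narrow). The returned
    interval is the span of all segments consistent with every informative
    record, clipped to ``current``; an empty intersection raises
    :class:`InconsistencyError`.
    """
    markers = list(markers)
    if len(markers) < 2:
        raise ValueError("need at least two markers")
    ids = [m[0] for m in markers]
    bps = [m[1] for m in markers]

    # candidate gaps restricted to the current search interval
    known = [(i, bp) for i, bp in enumerate(bps) if bp is not None]
    if len(known) < 2:
        raise ValueError("need at least two markers with bp positions")

    def gap_bounds(i):
        """bp bounds of the gap between markers i and i+1 (None bp widens)."""
        left = next((bps[j] for j in range(i, -1, -1) if bps[j] is not None), None)
        right = next((bps[j] for j in range(i + 1, len(bps))
                      if bps[j] is not None), None)
        return left, right

    n_gaps = len(markers) - 1
    candidate = []
    for i in range(n_gaps):
        lo, hi = gap_bounds(i)
        if lo is None or hi is None:
            continue
        if hi > current.start_bp and lo < current.end_bp:
            candidate.append(i)
    if not candidate:
        raise ValueError("no marker gap overlaps the current interval")

    informative = []
    for rec in records:
        if len(rec.marker_genotypes) != len(markers):
            raise ValueError(
                f"record {rec.individual_id!r} has {len(rec.marker_genotypes)} "
                f"genotypes for {len(markers)} markers"
            )
        cls = infer_causal_genotype(rec, incompatible_allele, alpha)
        if cls != "unknown":
            informative.append((rec, cls))

    if not informative:
        return current

    consistent = {i: True for i in candidate}
    for rec, cls in informative:
        want = _expected_code(cls, incompatible_allele)
        for i in candidate:
            gl = rec.marker_genotypes[i]
            gr = rec.marker_genotypes[i + 1]
            ok = (gl is None or gl == want) or (gr is None or gr == want)
            consistent[i] = consistent[i] and ok

    keep = [i for i in candidate if consistent[i]]
    if not keep:
        raise InconsistencyError([r.individual_id for r, _ in informative])

    lo_bp, hi_bp = gap_bounds(keep[0])[0], gap_bounds(keep[-1])[1]
    spans_gap = any(
        bps[j] is None for j in range(keep[0], keep[-1] + 2) if j < len(bps)
    )
    return GenomicInterval(
        current.chrom,
        int(max(lo_bp, current.start_bp)),
        int(min(hi_bp, current.end_bp)),
        left_marker=ids[keep[0]],
        right_marker=ids[keep[-1] + 1],
        spans_assembly_gap=spans_gap,
    )
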