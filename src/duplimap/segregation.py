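"""Competing genetic models for hybrid lethality and the chi-squared screen.

Observed green/white seedling counts per cross class (parental selfs,
reciprocal F1s, F2s, F3s) are compared against the exact Mendelian
expectations of a catalog of incompatibility models. A model is rejected
when any cross class deviates significantly; the screen retains the models
the data cannot reject — for the real cross, only the two-locus
recessive-recessive model survives (expected F2 white fraction 1/16).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .sim import IncompatibilitySpec, MODEL_CATALOG

__all__ = [
    "CrossCounts",
    "ModelVerdict",
    "default_catalog",
    "expected_white_fraction",
    "expected_selfed_white_fraction",
    "chisq_gof",
    "reciprocal_homogeneity",
    "screen_models",
    "paper_cross_counts",
]

CROSS_CLASSES = ("parental_self", "F1", "F2", "F3")


@dataclass(frozen=True)
class CrossCounts:
    """Green/white seedling counts from one cross class."""

    cross_class: str
    maternal: str  # 'G' or 'N': maternal lineage (cytoplasm) of the cross
    n_green: int
    n_white: int

    def __post_init__(self):
        if self.cross_class not in CROSS_CLASSES:
            raise ValueError(f"unknown cross class {self.cross_class!r}")
        if self.n_green < 0 or self.n_white < 0:
            raise ValueError("counts must be non-negative")
        if self.n_green + self.n_white < 1:
            raise ValueError("at least one seedling required")

    @property
    def total(self) -> int:
        return self.n_green + self.n_white

    @property
    def white_fraction(self) -> float:
        return self.n_white / self.total


@dataclass
class ModelVerdict:
    """Outcome of testing one model against all supplied cross classes."""

    model: str
    expected_white_fraction: Fraction  # for the most discrepant cross class
    statistic: float
    df: int
    p_value: float
    verdict: str  # 'rejected' | 'not_rejected'
    details: pd.DataFrame = None


def default_catalog() -> dict:
    """The model families screened: one instantiated spec per family."""
    return {name: factory() for name, factory in MODEL_CATALOG.items()}


# ---------------------------------------------------------------------------
# exact expectations

_HALF = Fraction(1, 2)
_F2_LOCUS_DIST = {0: Fraction(1, 4), 1: _HALF, 2: Fraction(1, 4)}
_SELF_DIST = {
    0: {0: Fraction(1)},
    1: dict(_F2_LOCUS_DIST),
    2: {2: Fraction(1)},
}


def _genotype_distribution(spec: IncompatibilitySpec, cross_class: str,
                           maternal: str):
    """Joint distribution of N-allele counts at the causal loci.

    Yields ``(genotype_tuple, probability, cytoplasm)``; loci are unlinked.
    """
    loci = spec.loci
    k = len(loci)
    if cross_class == "F1":
        yield (1,) * k, Fraction(1), maternal
    elif cross_class == "F2":
        for combo in product(*([list(_F2_LOCUS_DIST)] * k)):
            p = Fraction(1)
            for c in combo:
                p *= _F2_LOCUS_DIST[c]
            yield combo, p, maternal
    elif cross_class == "F3":
        # parent: green F2 (lethal genotypes never reproduce), then selfed
        parents = []
        total = Fraction(0)
        for combo in product(*([list(_F2_LOCUS_DIST)] * k)):
            p = Fraction(1)
            for c in combo:
                p *= _F2_LOCUS_DIST[c]
            if not spec.is_lethal(dict(zip(loci, combo)), maternal):
                parents.append((combo, p))
                total += p
        for combo, p in parents:
            for child in product(*[list(_SELF_DIST[c]) for c in combo]):
                q = Fraction(1)
                for c, ch in zip(combo, child):
                    q *= _SELF_DIST[c][ch]
                yield child, p / total * q, maternal
    else:
        raise ValueError(f"unknown cross class {cross_class!r}")


def expected_white_fraction(spec: IncompatibilitySpec, cross_class: str,
                            maternal: str = "G") -> Fraction:
    """Exact expected white-seedling fraction under Mendelian segregation.

    ``maternal`` is the maternal lineage of the founding cross (it matters
    only for cyto-nuclear models). Causal loci are assumed unlinked.

    Parental selfs return 0 for every model: hybrid-incompatibility models
    describe alleles that are only exposed on a heterospecific background,
    and both parental lines are observed viable.
    """
    if isinstance(spec, str):
        try:
            spec = MODEL_CATALOG[spec]()
        except KeyError:
            raise ValueError(f"unknown model {spec!r}") from None
    if cross_class == "parental_self":
        return Fraction(0)
    total = Fraction(0)
    for genotype, p, cyto in _genotype_distribution(spec, cross_class, maternal):
        if spec.is_lethal(dict(zip(spec.loci, genotype)), cyto):
            total += p
    return total


# ---------------------------------------------------------------------------
# tests


def expected_selfed_white_fraction(spec: IncompatibilitySpec,
                                   parent_n_alt: Mapping[str, int],
                                   cytoplasm: str = "G") -> Fraction:
    """Exact white fraction among selfed progeny of a given parent.

    ``parent_n_alt`` maps each causal locus to the parent's N-allele count
    (0, 1 or 2). A green F2 heterozygous at one causal locus and fixed
    incompatible at the other segregates white 1/4 (green:white 3:1).
    """
    loci = spec.loci
    combos = [parent_n_alt[l] for l in loci]
    total = Fraction(0)
    for child in product(*[list(_SELF_DIST[c]) for c in combos]):
        p = Fraction(1)
        for c, ch in zip(combos, child):
            p *= _SELF_DIST[c][ch]
        if spec.is_lethal(dict(zip(loci, child)), cytoplasm):
            total += p
    return total


def chisq_gof(counts: CrossCounts, expected_white: float):
    """Pearson goodness-of-fit of {white, green} counts to an expected fraction.

    Two cells, df = 1, no continuity correction. Boundary expectations (0 or
    1) use the exact rule: any discordant observation rejects outright.
    """
    n = counts.total
    if n == 0:
        raise ValueError("zero total count")
    p0 = float(expected_white)
    if p0 <= 0.0 or p0 >= 1.0:
        discordant = counts.n_white > 0 if p0 <= 0.0 else counts.n_green > 0
        if discordant:
            return float("inf"), 1, 0.0
        return 0.0, 1, 1.0
    exp_white = n * p0
    exp_green = n * (1.0 - p0)
    stat = (counts.n_white - exp_white) ** 2 / exp_white
    stat += (counts.n_green - exp_green) ** 2 / exp_green
    return float(stat), 1, float(stats.chi2.sf(stat, 1))


@dataclass
class HomogeneityResult:
    statistic: float
    p_value: float
    homogeneous: bool
    pooled: CrossCounts | None
    cyto_nuclear_flag: bool


def reciprocal_homogeneity(counts_dir1: CrossCounts, counts_dir2: CrossCounts,
                           alpha: float = 0.05) -> HomogeneityResult:
    """Test whether reciprocal F2s segregate white at the same rate.

    A 2x2 Pearson chi-squared (no continuity correction) on direction x
    phenotype. Homogeneous reciprocals are pooled; a significant difference
    raises the cyto-nuclear flag instead.
    """
    for c in (counts_dir1, counts_dir2):
        if c.cross_class != "F2":
            raise ValueError("reciprocal test expects F2 counts")
        if c.total == 0:
            raise ValueError("zero total count")
    if counts_dir1.maternal == counts_dir2.maternal:
        raise ValueError("counts must come from opposite maternal parents")
    table = np.array(
        [
            [counts_dir1.n_white, counts_dir1.n_green],
            [counts_dir2.n_white, counts_dir2.n_green],
        ]
    )
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    homogeneous = p >= alpha
    pooled = None
    if homogeneous:
        pooled = CrossCounts(
            "F2", "pooled",
            counts_dir1.n_green + counts_dir2.n_green,
            counts_dir1.n_white + counts_dir2.n_white,
        )
    return HomogeneityResult(float(stat), float(p), homogeneous, pooled,
                             not homogeneous)


def screen_models(counts: Iterable[CrossCounts],
                  catalog: Mapping[str, IncompatibilitySpec] | None = None,
                  alpha: float = 0.05) -> list[ModelVerdict]:
    """Screen every model in the catalog against all observed cross counts.

    A model is rejected if any single cross class rejects it at ``alpha``
    (boundary expectations use the exact any-discordant rule). Returns one
    verdict per model; the headline statistic is the most significant class.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("empty count table")
    if not any(c.cross_class == "F2" for c in counts):
        raise ValueError("at least one F2 count is required")
    if catalog is None:
        catalog = default_catalog()

    verdicts = []
    for name, spec in catalog.items():
        rows = []
        for cc in counts:
            p0 = expected_white_fraction(spec, cc.cross_class, cc.maternal)
            stat, df, p = chisq_gof(cc, float(p0))
            rows.append(
                {
                    "cross_class": cc.cross_class,
                    "maternal": cc.maternal,
                    "n_green": cc.n_green,
                    "n_white": cc.n_white,
                    "expected_white": float(p0),
                    "statistic": stat,
                    "df": df,
                    "p_value": p,
                    "rejected": p < alpha,
                }
            )
        details = pd.DataFrame(rows)
        worst = details.loc[details["p_value"].idxmin()]
        rejected = bool(details["rejected"].any())
        verdicts.append(
            ModelVerdict(
                model=name,
                expected_white_fraction=expected_white_fraction(
                    spec, worst["cross_class"], worst["maternal"]
                ),
                statistic=float(worst["statistic"]),
                df=int(worst["df"]),
                p_value=float(worst["p_value"]),
                verdict="rejected" if rejected else "not_rejected",
                details=details,
            )
        )
    return verdicts


def paper_cross_counts() -> list[CrossCounts]:
    """Observed cross counts reconstructed from the printed (N, %) pairs.

    Reciprocal F2s of 516 (7.36% white, G maternal) and 661 (5.75% white,
    N maternal) seedlings; white counts are round(N * fraction). Parental
    selfs and F1s never produced white seedlings (totals not printed; a
    nominal 100 per class is used, which only matters for the exact
    boundary rule and not its outcome).
    """
    n1, f1 = 516, 0.0736
    n2, f2 = 661, 0.0575
    w1, w2 = round(n1 * f1), round(n2 * f2)
    return [
        CrossCounts("parental_self", "G", 100, 0),
        CrossCounts("parental_self", "N", 100, 0),
        CrossCounts("F1", "G", 100, 0),
        CrossCounts("F1", "N", 100, 0),
        CrossCounts("F2", "G", n1 - w1, w1),
        CrossCounts("F2", "N", n2 - w2, w2),
    ]
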