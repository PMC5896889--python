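"""Forward simulation of inbred lines, crosses, and pooled sequencing.

Models the breeding design used to map a two-locus recessive-recessive
hybrid-lethality incompatibility between *Mimulus guttatus* (G) and
*M. nasutus* (N): an outbred G founder inbred by serial selfing, a
naturally selfing N founder, reciprocal F1/F2/F3 hybrids, and bulked
segregant pools sequenced to finite depth.

Alleles are coded by parental origin: 0 = G, 1 = N. Genotypes at a locus
are reported with the field's G/H/N codes (homozygous G, heterozygous,
homozygous N). Recombination follows the Haldane map function (no
crossover interference): the recombinant fraction between loci d cM apart
is (1 - exp(-d/50))/2, and chromosomes assort independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ALLELE_G = 0
ALLELE_N = 1

#: genotype code by count of N alleles
GENO_CODES = np.array(["G", "H", "N"])

__all__ = [
    "ALLELE_G",
    "ALLELE_N",
    "GENO_CODES",
    "LinkageMap",
    "Diplotype",
    "Population",
    "IncompatibilitySpec",
    "SnpPanel",
    "expected_homozygosity",
    "default_map",
    "make_parental_lines",
    "meiosis",
    "gametes",
    "mate",
    "self_",
    "phenotype",
    "phenotypes",
    "simulate_f2_population",
    "simulate_f3_family",
    "random_panel",
    "pool_counts",
    "two_locus_recessive_recessive",
    "one_locus_recessive",
    "two_locus_dominant_recessive",
    "cyto_nuclear_recessive",
    "haldane_rf",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def haldane_rf(d_cm: float) -> float:
    """Recombinant fraction between loci ``d_cm`` centimorgans apart."""
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cm, dtype=float) / 50.0))


def expected_homozygosity(generations_selfed: int) -> float:
    """Expected genome-wide homozygosity after serial self-fertilization.

    A fully heterozygous founder loses half its heterozygosity each selfed
    generation, so after ``g`` generations homozygosity is ``1 - (1/2)^g``
    (0.875 for the three generations used to derive the G inbred line).
    """
    g = generations_selfed
    if not (isinstance(g, (int, np.integer)) and not isinstance(g, bool)):
        raise TypeError("generations_selfed must be an integer")
    if g < 0:
        raise ValueError("generations_selfed must be >= 0")
    return 1.0 - 0.5 ** int(g)


class LinkageMap:
    """Chromosome lengths in cM plus an ordered set of named loci.

    Parameters
    ----------
    chromosomes
        Sequence of ``(chrom_id, length_cm)`` pairs.
    loci
        Sequence of ``(locus_id, chrom_id, position_cm)`` or
        ``(locus_id, chrom_id, position_cm, position_bp)`` tuples. Loci are
        stored sorted by chromosome (map order) then cM position.
    """

    def __init__(self, chromosomes, loci):
        self.chromosomes = [(str(c), float(l)) for c, l in chromosomes]
        if len({c for c, _ in self.chromosomes}) != len(self.chromosomes):
            raise ValueError("duplicate chromosome ids")
        chrom_order = {c: i for i, (c, _) in enumerate(self.chromosomes)}
        lengths = dict(self.chromosomes)

        rows = []
        for entry in loci:
            if len(entry) == 3:
                lid, chrom, cm = entry
                bp = np.nan
            else:
                lid, chrom, cm, bp = entry
                bp = np.nan if bp is None else float(bp)
            if chrom not in chrom_order:
                raise ValueError(f"locus {lid!r} on unknown chromosome {chrom!r}")
            cm = float(cm)
            if not (0.0 <= cm <= lengths[chrom]):
                raise ValueError(
                    f"locus {lid!r} at {cm} cM outside chromosome {chrom!r} "
                    f"(length {lengths[chrom]} cM)"
                )
            rows.append((str(lid), str(chrom), cm, bp))
        rows.sort(key=lambda r: (chrom_order[r[1]], r[2], r[3]))

        self.locus_ids = [r[0] for r in rows]
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        self.locus_chrom = np.array([chrom_order[r[1]] for r in rows], dtype=int)
        self.locus_cm = np.array([r[2] for r in rows], dtype=float)
        self.locus_bp = np.array([r[3] for r in rows], dtype=float)
        self._index = {lid: i for i, lid in enumerate(self.locus_ids)}

        # bp positions, where present, must increase with cM within a chromosome
        for ci in range(len(self.chromosomes)):
            sel = self.locus_chrom == ci
            bps = self.locus_bp[sel]
            bps = bps[~np.isnan(bps)]
            if len(bps) > 1 and not np.all(np.diff(bps) > 0):
                raise ValueError(
                    f"bp positions not strictly increasing with cM on "
                    f"{self.chromosomes[ci][0]!r}"
                )

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def index(self, locus_id: str) -> int:
        try:
            return self._index[locus_id]
        except KeyError:
            raise KeyError(f"unknown locus {locus_id!r}") from None

    def chrom_slices(self):
        """Yield ``(chrom_index, locus_index_array)`` per chromosome with loci."""
        for ci in range(len(self.chromosomes)):
            idx = np.nonzero(self.locus_chrom == ci)[0]
            if len(idx):
                yield ci, idx

    def with_loci(self, extra_loci) -> "LinkageMap":
        """Return a new map containing this map's loci plus ``extra_loci``."""
        existing = [
            (lid, self.chromosomes[self.locus_chrom[i]][0], self.locus_cm[i],
             None if np.isnan(self.locus_bp[i]) else self.locus_bp[i])
            for i, lid in enumerate(self.locus_ids)
        ]
        return LinkageMap(self.chromosomes, existing + list(extra_loci))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_ids,
                "chrom": [self.chromosomes[c][0] for c in self.locus_chrom],
                "pos_cm": self.locus_cm,
                "pos_bp": self.locus_bp,
            }
        )


#: default physical scale used when a locus needs a bp coordinate
BP_PER_CM = 200_000


def default_map(n_chromosomes: int = 14, length_cm: float = 100.0,
                hl13=("chr13", 90.0), hl14=("chr14", 50.0),
                extra_loci: Sequence = ()) -> LinkageMap:
    """The 14-chromosome cross map with the two hybrid-lethality loci.

    hl13 sits near the distal end of chromosome 13 and hl14 mid-chromosome 14;
    bp coordinates use a uniform 200 kb/cM scale.
    """
    chroms = [(f"chr{i + 1:02d}", length_cm) for i in range(n_chromosomes)]
    loci = [
        ("hl13", hl13[0], hl13[1], hl13[1] * BP_PER_CM),
        ("hl14", hl14[0], hl14[1], hl14[1] * BP_PER_CM),
    ]
    return LinkageMap(chroms, loci + list(extra_loci))


@dataclass
class Diplotype:
    """One individual: two phased haplotypes over a map plus a cytoplasm label.

    ``haps`` has shape ``(2, n_loci)`` with entries 0 (G allele) or 1 (N
    allele); the cytoplasm label records the maternal lineage.
    """

    map: LinkageMap
    haps: np.ndarray
    cytoplasm: str = "G"

    def __post_init__(self):
        self.haps = np.asarray(self.haps, dtype=np.int8)
        if self.haps.shape != (2, self.map.n_loci):
            raise ValueError("haps must have shape (2, n_loci)")

    def genotype(self, locus_id: str) -> str:
        """G/H/N code at a locus."""
        return str(GENO_CODES[int(self.haps[:, self.map.index(locus_id)].sum())])

    def n_alt(self, locus_id: str) -> int:
        """Number of N-origin alleles (0, 1 or 2) at a locus."""
        return int(self.haps[:, self.map.index(locus_id)].sum())

    def heterozygosity(self, exclude: Sequence[str] = ()) -> float:
        """Fraction of loci (optionally excluding some ids) that are H."""
        mask = np.ones(self.map.n_loci, dtype=bool)
        for lid in exclude:
            mask[self.map.index(lid)] = False
        if not mask.any():
            return float("nan")
        het = self.haps[0] != self.haps[1]
        return float(het[mask].mean())


class Population:
    """A set of individuals sharing one map; array-backed for speed."""

    def __init__(self, map: LinkageMap, haps: np.ndarray, cytoplasm):
        self.map = map
        self.haps = np.asarray(haps, dtype=np.int8)  # (n, 2, L)
        if self.haps.ndim != 3 or self.haps.shape[1:] != (2, map.n_loci):
            raise ValueError("haps must have shape (n, 2, n_loci)")
        if isinstance(cytoplasm, str):
            cytoplasm = [cytoplasm] * len(self.haps)
        self.cytoplasm = list(cytoplasm)
        if len(self.cytoplasm) != len(self.haps):
            raise ValueError("cytoplasm labels must match population size")

    def __len__(self) -> int:
        return self.haps.shape[0]

    def __getitem__(self, i: int) -> Diplotype:
        return Diplotype(self.map, self.haps[i], self.cytoplasm[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def n_alt(self, locus_id: str) -> np.ndarray:
        """Per-individual count of N alleles at ``locus_id``."""
        return self.haps[:, :, self.map.index(locus_id)].sum(axis=1)

    def genotype_codes(self, locus_id: str) -> np.ndarray:
        return GENO_CODES[self.n_alt(locus_id)]

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the N allele at every locus, pooled over individuals."""
        if len(self) == 0:
            return np.full(self.map.n_loci, np.nan)
        return self.haps.mean(axis=(0, 1))

    def subset(self, idx) -> "Population":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return Population(
            self.map, self.haps[idx], [self.cytoplasm[i] for i in idx]
        )

    def genotype_frame(self, locus_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Individuals x loci table of G/H/N codes."""
        ids = list(locus_ids) if locus_ids is not None else self.map.locus_ids
        data = {lid: self.genotype_codes(lid) for lid in ids}
        df = pd.DataFrame(data)
        df.insert(0, "cytoplasm", self.cytoplasm)
        df.insert(0, "individual", [f"ind{i:05d}" for i in range(len(self))])
        return df


# ---------------------------------------------------------------------------
# meiosis and mating

_CHUNK = 50_000_000  # cap on the n * max_crossovers * n_loci broadcast


def gametes(parent: Diplotype, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` independent gametes from ``parent``; shape ``(n, n_loci)``.

    Crossovers per chromosome are Poisson with mean length/100 Morgans, placed
    uniformly (Haldane model); the starting strand is fair per chromosome.
    """
    rng = _as_rng(seed)
    L = parent.map.n_loci
    out = np.empty((n, L), dtype=np.int8)
    for ci, idx in parent.map.chrom_slices():
        length = parent.map.chromosomes[ci][1]
        pos = parent.map.locus_cm[idx]
        hap0 = parent.haps[0, idx]
        hap1 = parent.haps[1, idx]
        k = rng.poisson(length / 100.0, size=n)
        start = rng.integers(0, 2, size=n)
        m = int(k.max()) if n else 0
        if m == 0:
            which = start[:, None] % 2
        else:
            # chunk the (n, m, P) broadcast to bound memory
            which = np.empty((n, len(idx)), dtype=np.int64)
            step = max(1, _CHUNK // max(1, m * len(idx)))
            for lo in range(0, n, step):
                hi = min(n, lo + step)
                x = rng.uniform(0.0, length, size=(hi - lo, m))
                x[np.arange(m)[None, :] >= k[lo:hi, None]] = np.inf
                before = (x[:, :, None] < pos[None, None, :]).sum(axis=1)
                which[lo:hi] = (start[lo:hi, None] + before) % 2
        out[:, idx] = np.where(which == 0, hap0[None, :], hap1[None, :])
    return out


def meiosis(parent: Diplotype, map: LinkageMap | None = None, seed=None) -> np.ndarray:
    """One gamete from ``parent`` (``map`` is accepted for signature symmetry)."""
    if map is not None and map is not parent.map:
        raise ValueError("map does not match parent's map")
    return gametes(parent, 1, seed)[0]


def mate(parent_a: Diplotype, parent_b: Diplotype, n_offspring: int,
         seed=None) -> Population:
    """Cross two individuals; ``parent_a`` is the maternal (cytoplasm) parent."""
    if parent_a.map is not parent_b.map:
        # allow equal maps constructed separately
        if parent_a.map.locus_ids != parent_b.map.locus_ids or not np.array_equal(
            parent_a.map.locus_cm, parent_b.map.locus_cm
        ):
            raise ValueError("parents are on different maps")
    rng = _as_rng(seed)
    ga = gametes(parent_a, n_offspring, rng)
    gb = gametes(parent_b, n_offspring, rng)
    haps = np.stack([ga, gb], axis=1)
    return Population(parent_a.map, haps, parent_a.cytoplasm)


def self_(parent: Diplotype, n_offspring: int, seed=None) -> Population:
    """Self-fertilize ``parent``."""
    return mate(parent, parent, n_offspring, seed)


def make_parental_lines(map: LinkageMap, selfing_generations_G: int = 3,
                        seed=None, causal_loci: Sequence[str] = ("hl13", "hl14"),
                        fixed_difference_loci: Sequence[str] = ()):
    """Build the two founder inbred lines.

    The N founder (a natural selfer) is homozygous N everywhere. The G founder
    starts fully heterozygous and is selfed ``selfing_generations_G`` times,
    leaving residual heterozygosity ~(1/2)^g; both founders are forced
    homozygous for their own allele at the causal loci, mirroring the
    empirical verification that the real lines were fixed there.

    ``fixed_difference_loci`` lists additional loci (typically SNP-panel
    positions, which are ascertained as differences between the lineages)
    where the G founder is likewise forced homozygous G: its residual
    heterozygosity lives at sites the panel does not see.
    """
    rng = _as_rng(seed)
    L = map.n_loci
    founder_n = Diplotype(map, np.full((2, L), ALLELE_N, dtype=np.int8), "N")

    g = Diplotype(
        map,
        np.stack([np.full(L, ALLELE_G, np.int8), np.full(L, ALLELE_N, np.int8)]),
        "G",
    )
    for _ in range(int(selfing_generations_G)):
        g = self_(g, 1, rng)[0]
    haps = g.haps.copy()
    for lid in list(causal_loci) + list(fixed_difference_loci):
        if lid in map._index:
            haps[:, map.index(lid)] = ALLELE_G
    founder_g = Diplotype(map, haps, "G")
    return founder_g, founder_n


# ---------------------------------------------------------------------------
# incompatibility models and phenotypes


@dataclass(frozen=True)
class IncompatibilitySpec:
    """A deterministic lethality predicate over causal-locus genotypes.

    ``requires`` lists ``(locus_id, incompatible_allele)`` pairs; lethality
    needs every listed locus to carry its incompatible allele homozygously
    (or at all, where ``dominant`` is True), and, for cyto-nuclear models,
    the cytoplasm to match ``maternal``.
    """

    name: str
    requires: tuple
    dominant: tuple = None
    maternal: str | None = None

    def __post_init__(self):
        req = tuple((str(l), str(a)) for l, a in self.requires)
        if not 1 <= len(req) <= 2:
            raise ValueError("models must involve one or two nuclear loci")
        for _, a in req:
            if a not in ("G", "N"):
                raise ValueError("incompatible allele must be 'G' or 'N'")
        dom = self.dominant
        if dom is None:
            dom = (False,) * len(req)
        object.__setattr__(self, "requires", req)
        object.__setattr__(self, "dominant", tuple(bool(d) for d in dom))
        if len(self.dominant) != len(req):
            raise ValueError("dominant flags must parallel requires")

    @property
    def loci(self):
        return tuple(l for l, _ in self.requires)

    def is_lethal(self, n_alt: Mapping[str, int], cytoplasm: str | None = None) -> bool:
        """Lethality given per-locus N-allele counts and a cytoplasm label."""
        if self.maternal is not None and cytoplasm != self.maternal:
            return False
        for (locus, allele), dom in zip(self.requires, self.dominant):
            count = n_alt[locus] if allele == "N" else 2 - n_alt[locus]
            if count < (1 if dom else 2):
                return False
        return True


def two_locus_recessive_recessive(hl13: str = "hl13", hl14: str = "hl14"):
    """White iff homozygous G at hl13 AND homozygous N at hl14."""
    return IncompatibilitySpec(
        "two_locus_recessive_recessive", ((hl13, "G"), (hl14, "N"))
    )


def one_locus_recessive(locus: str = "hl14", allele: str = "N"):
    return IncompatibilitySpec("one_locus_recessive", ((locus, allele),))


def two_locus_dominant_recessive(hl13: str = "hl13", hl14: str = "hl14"):
    """White iff any G allele at hl13 AND homozygous N at hl14."""
    return IncompatibilitySpec(
        "two_locus_dominant_recessive", ((hl13, "G"), (hl14, "N")),
        dominant=(True, False),
    )


def cyto_nuclear_recessive(locus: str = "hl14", allele: str = "N",
                           maternal: str = "G"):
    """White iff homozygous at the nuclear locus AND cytoplasm from ``maternal``."""
    return IncompatibilitySpec(
        "cyto_nuclear_recessive", ((locus, allele),), maternal=maternal
    )


MODEL_CATALOG = {
    "two_locus_recessive_recessive": two_locus_recessive_recessive,
    "one_locus_recessive": one_locus_recessive,
    "two_locus_dominant_recessive": two_locus_dominant_recessive,
    "cyto_nuclear_recessive": cyto_nuclear_recessive,
}


def phenotype(individual: Diplotype, spec: IncompatibilitySpec) -> str:
    """'white' or 'green' for one individual."""
    for lid in spec.loci:
        if lid not in individual.map._index:
            raise KeyError(f"individual's map lacks causal locus {lid!r}")
    n_alt = {lid: individual.n_alt(lid) for lid in spec.loci}
    return "white" if spec.is_lethal(n_alt, individual.cytoplasm) else "green"


def phenotypes(pop: Population, spec: IncompatibilitySpec) -> np.ndarray:
    """Vectorized phenotype call; returns an array of 'green'/'white'."""
    for lid in spec.loci:
        if lid not in pop.map._index:
            raise KeyError(f"population's map lacks causal locus {lid!r}")
    lethal = np.ones(len(pop), dtype=bool)
    if spec.maternal is not None:
        lethal &= np.array([c == spec.maternal for c in pop.cytoplasm])
    for (locus, allele), dom in zip(spec.requires, spec.dominant):
        n_alt = pop.n_alt(locus)
        count = n_alt if allele == "N" else 2 - n_alt
        lethal &= count >= (1 if dom else 2)
    return np.where(lethal, "white", "green")


# ---------------------------------------------------------------------------
# crossing schemes


@dataclass
class CrossResult:
    population: Population
    phenotypes: np.ndarray
    founder_g: Diplotype = None
    founder_n: Diplotype = None
    f1: Diplotype = None

    @property
    def white_fraction(self) -> float:
        return float((self.phenotypes == "white").mean())


def simulate_f2_population(n: int, spec: IncompatibilitySpec | None = None,
                           seed=None, map: LinkageMap | None = None,
                           maternal: str = "G",
                           selfing_generations_G: int = 3,
                           fixed_difference_loci: Sequence[str] = ()) -> CrossResult:
    """Simulate an F2 population from the standard cross.

    ``maternal`` selects the cross direction ('G': G line is the F1's mother).
    Under the two-locus recessive-recessive model with unlinked causal loci
    the expected white fraction is 1/16. Mapping markers and panel SNPs,
    which are ascertained as parental differences, should be listed in
    ``fixed_difference_loci`` so the G founder is fixed G there.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    if map is None:
        map = default_map()
    if spec is None:
        spec = two_locus_recessive_recessive()
    fg, fn = make_parental_lines(map, selfing_generations_G, rng,
                                 fixed_difference_loci=fixed_difference_loci)
    mother, father = (fg, fn) if maternal == "G" else (fn, fg)
    f1 = mate(mother, father, 1, rng)[0]
    f2 = self_(f1, n, rng)
    return CrossResult(f2, phenotypes(f2, spec), fg, fn, f1)


def simulate_f3_family(f2_parent: Diplotype, n: int,
                       spec: IncompatibilitySpec | None = None,
                       seed=None) -> CrossResult:
    """Self one F2 parent and phenotype its F3 family."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec is None:
        spec = two_locus_recessive_recessive()
    fam = self_(f2_parent, n, seed)
    return CrossResult(fam, phenotypes(fam, spec))


# ---------------------------------------------------------------------------
# SNP panel and pooled sequencing


class SnpPanel:
    """Genome-wide SNPs that differentiate the parental lines.

    The alternate allele is the N-parent allele. A small configurable
    fraction of SNPs violate the shared-SNP assumption (the G founder also
    carries the alternate allele there), emulating panels called against a
    reference that is a different accession of the G species.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"snp_id", "chrom", "pos_bp", "pos_cm", "g_carries_alt"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        table = table.sort_values(["chrom", "pos_bp"], kind="mergesort")
        self.table = table.reset_index(drop=True)
        if self.table["snp_id"].duplicated().any():
            raise ValueError("duplicate snp ids")

    def __len__(self) -> int:
        return len(self.table)

    def as_loci(self):
        """Loci tuples suitable for :meth:`LinkageMap.with_loci`."""
        return [
            (r.snp_id, r.chrom, r.pos_cm, r.pos_bp)
            for r in self.table.itertuples()
        ]


def random_panel(map: LinkageMap, n_snps: int, seed=None,
                 bp_per_cm: float = BP_PER_CM,
                 violation_rate: float = 0.02) -> SnpPanel:
    """Scatter ``n_snps`` panel SNPs uniformly over the map's chromosomes."""
    rng = _as_rng(seed)
    lengths = np.array([l for _, l in map.chromosomes])
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(lengths), size=n_snps, p=probs)
    cm = rng.uniform(0, lengths[chrom_idx])
    violate = rng.random(n_snps) < violation_rate
    df = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(n_snps)],
            "chrom": [map.chromosomes[c][0] for c in chrom_idx],
            "pos_cm": cm,
            "pos_bp": np.round(cm * bp_per_cm).astype(int),
            "g_carries_alt": violate,
        }
    )
    # enforce strictly increasing bp within each chromosome
    df = df.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)
    for _, sub in df.groupby("chrom", sort=False):
        bp = sub["pos_bp"].to_numpy(dtype=np.int64)
        for i in range(1, len(bp)):
            if bp[i] <= bp[i - 1]:
                bp[i] = bp[i - 1] + 1
        df.loc[sub.index, "pos_bp"] = bp
    lengths_by_id = dict(map.chromosomes)
    df["pos_cm"] = np.minimum(
        df["pos_bp"] / bp_per_cm, df["chrom"].map(lengths_by_id)
    )
    return SnpPanel(df)


def pool_counts(members, panel: SnpPanel, mean_depth: float,
                error_rate: float = 0.005, seed=None) -> pd.DataFrame:
    """Sequence a DNA pool at panel SNPs to finite depth.

    Per SNP, total depth is Poisson(``mean_depth``); alternate-read counts
    are binomial with success probability equal to the pool's alternate
    allele frequency, pushed toward 0.5 by a symmetric per-read error flip.
    Zero-depth SNPs are emitted with both depths zero (missing).

    Returns a DataFrame with columns chrom, pos, ref_depth, alt_depth.
    """
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = _as_rng(seed)
    if isinstance(members, Population):
        pop = members
    else:
        members = list(members)
        if members:
            pop = Population(
                members[0].map,
                np.stack([m.haps for m in members]),
                [m.cytoplasm for m in members],
            )
        else:
            pop = None

    snp_ids = panel.table["snp_id"].tolist()
    s = len(panel)
    if pop is None or len(pop) == 0:
        depth = np.zeros(s, dtype=int)
        alt = np.zeros(s, dtype=int)
    else:
        idx = np.array([pop.map.index(sid) for sid in snp_ids])
        p_alt = pop.haps[:, :, idx].mean(axis=(0, 1)).astype(float)
        p_alt = np.where(panel.table["g_carries_alt"].to_numpy(), 1.0, p_alt)
        p_obs = p_alt * (1.0 - error_rate) + (1.0 - p_alt) * error_rate
        depth = rng.poisson(mean_depth, size=s)
        alt = rng.binomial(depth, p_obs)
    return pd.DataFrame(
        {
            "chrom": panel.table["chrom"].to_numpy(),
            "pos": panel.table["pos_bp"].to_numpy(),
            "ref_depth": depth - alt,
            "alt_depth": alt,
        }
    )
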