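"""End-to-end simulations of the study's mapping designs.

These functions wire the forward simulator into the exact experimental
designs the analysis stages consume: the F3 bulked-segregant pooling design
(one seedling per independent F2 family, so unlinked markers sit at ~50%
frequency in both pools) and the 96-individual two-locus genotype panel
used to place duplicate copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .sim import (
    Diplotype,
    IncompatibilitySpec,
    LinkageMap,
    Population,
    SnpPanel,
    _as_rng,
    default_map,
    make_parental_lines,
    mate,
    phenotypes,
    pool_counts,
    random_panel,
    two_locus_recessive_recessive,
)

__all__ = ["F3PoolingResult", "simulate_f3_bsa_pools", "simulate_copy_panel"]


@dataclass
class F3PoolingResult:
    """Pools and metadata from the second-round BSA design."""

    white_counts: pd.DataFrame
    green_counts: pd.DataFrame
    panel: SnpPanel
    map: LinkageMap
    causal_bp: dict
    white_members: Population
    green_members: Population


def _collect_f2_parents(f1: Diplotype, spec, n_segregating: int,
                        n_nonsegregating: int, rng,
                        batch: int = 128, max_batches: int = 400):
    """Draw distinct green F2s fixed N at hl14: het (segregating family
    founders) or NN (non-segregating) at hl13."""
    seg, nonseg = [], []
    for _ in range(max_batches):
        pop = mate(f1, f1, batch, rng)
        n13 = pop.n_alt("hl13")
        n14 = pop.n_alt("hl14")
        green = phenotypes(pop, spec) == "green"
        for i in np.nonzero(green & (n14 == 2))[0]:
            if n13[i] == 1 and len(seg) < n_segregating:
                seg.append(pop[int(i)])
            elif n13[i] == 2 and len(nonseg) < n_nonsegregating:
                nonseg.append(pop[int(i)])
        if len(seg) >= n_segregating and len(nonseg) >= n_nonsegregating:
            return seg, nonseg
    raise RuntimeError("failed to collect enough F2 family founders")


def simulate_f3_bsa_pools(n_white: int = 34, n_green: int = 26,
                          mean_depth: float = 30.0, error_rate: float = 0.005,
                          n_snps: int = 20_000, seed=None,
                          map: LinkageMap | None = None,
                          panel: SnpPanel | None = None,
                          spec: IncompatibilitySpec | None = None,
                          selfing_generations_G: int = 3) -> F3PoolingResult:
    """Simulate the round-2 BSA design and sequence both pools.

    60 F3 families are founded by green F2s homozygous N at hl14; families
    whose founder is heterozygous at hl13 segregate white 3:1 and
    contribute one white seedling each to the white pool (``n_white``
    families), while non-segregating families (founder NN at hl13)
    contribute one green seedling each to the green pool (``n_green``
    families). Every pooled seedling therefore comes from a distinct F2
    maternal parent. Pools are sequenced at ``mean_depth`` per SNP.
    """
    rng = _as_rng(seed)
    if map is None:
        map = default_map()
    if panel is None:
        panel = random_panel(map, n_snps, rng)
    full_map = map.with_loci(panel.as_loci())
    if spec is None:
        spec = two_locus_recessive_recessive()

    fg, fn = make_parental_lines(
        full_map, selfing_generations_G, rng,
        fixed_difference_loci=panel.table["snp_id"].tolist(),
    )
    f1 = mate(fg, fn, 1, rng)[0]
    seg_parents, nonseg_parents = _collect_f2_parents(
        f1, spec, n_white, n_green, rng
    )

    white_members = []
    for parent in seg_parents:
        for _ in range(100):
            fam = mate(parent, parent, 16, rng)
            ph = phenotypes(fam, spec)
            hits = np.nonzero(ph == "white")[0]
            if len(hits):
                white_members.append(fam[int(hits[0])])
                break
        else:
            raise RuntimeError("segregating family produced no white seedling")
    green_members = [mate(p, p, 1, rng)[0] for p in nonseg_parents]

    white_pop = Population(
        full_map, np.stack([m.haps for m in white_members]),
        [m.cytoplasm for m in white_members],
    )
    green_pop = Population(
        full_map, np.stack([m.haps for m in green_members]),
        [m.cytoplasm for m in green_members],
    )
    white_counts = pool_counts(white_pop, panel, mean_depth, error_rate, rng)
    green_counts = pool_counts(green_pop, panel, mean_depth, error_rate, rng)
    causal_bp = {
        lid: float(full_map.locus_bp[full_map.index(lid)])
        for lid in ("hl13", "hl14")
    }
    return F3PoolingResult(white_counts, green_counts, panel, full_map,
                           causal_bp, white_pop, green_pop)


def simulate_copy_panel(n_per_green: int = 10, n_white: int = 16,
                        placements: dict | None = None,
                        n_flips: int = 0, seed=None):
    """Simulate the 96-individual two-locus genotype panel with planted copies.

    All eight green two-locus genotype classes are replicated
    ``n_per_green`` times and the white (G at hl13, N at hl14) class
    ``n_white`` times. Copy presence follows the planted ``placements``
    (haplotype -> (locus, allele)) under dominant detection; ``n_flips``
    presence entries are inverted at random to model genotyping error.
    Returns ``(genotypes, presence, placements)``.
    """
    rng = _as_rng(seed)
    if placements is None:
        placements = {"G1": ("hl13", "G"), "G2": ("hl14", "G"),
                      "N1": ("hl13", "N")}
    classes = [
        (g13, g14) for g13, g14 in product("GHN", repeat=2)
    ]
    rows = []
    for g13, g14 in classes:
        n = n_white if (g13, g14) == ("G", "N") else n_per_green
        rows.extend({"hl13": g13, "hl14": g14} for _ in range(n))
    genotypes = pd.DataFrame(rows)
    genotypes.insert(0, "individual",
                     [f"F2_{i:03d}" for i in range(len(genotypes))])

    presence = {}
    for hap, (locus, allele) in placements.items():
        codes = genotypes[locus].to_numpy()
        presence[hap] = (codes == allele) | (codes == "H")
    presence = pd.DataFrame(presence, index=genotypes.index)

    if n_flips:
        flat = [(i, h) for i in presence.index for h in presence.columns]
        for k in rng.choice(len(flat), size=n_flips, replace=False):
            i, h = flat[int(k)]
            presence.loc[i, h] = not presence.loc[i, h]
    return genotypes, presence, placements
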