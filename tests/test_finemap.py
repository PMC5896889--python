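"""Progeny tests, concordance, and interval narrowing."""

import numpy as np
import pandas as pd
import pytest

from duplimap import finemap as fm
from duplimap import sim


class TestProgenyTest:
    @pytest.mark.parametrize(
        "green,white,expected",
        [
            (30, 10, "segregating_het"),
            (40, 0, "homozygous_compatible"),  # 0.75^40 ~ 1e-5
            (8, 0, "ambiguous"),  # 0.75^8 ~ 0.100
        ],
    )
    def test_classification(self, green, white, expected):
        assert fm.progeny_test(green, white) == expected

    def test_minimal_decisive_family_size_is_eleven(self):
        # exact binomial: 0.75^11 ~ 0.042 < 0.05 <= 0.75^10
        assert fm.minimal_decisive_family_size(0.05) == 11
        assert fm.progeny_test(11, 0) == "homozygous_compatible"
        assert fm.progeny_test(10, 0) == "ambiguous"

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            fm.progeny_test(0, 0)


class TestConcordance:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["hl13", "hl14", "phenotype"])

    def test_error_free_simulation_is_fully_concordant(self):
        # markers placed 0 cM from the causal loci: genotype == marker call
        res = sim.simulate_f2_population(3000, seed=50)
        pop = res.population
        df = pd.DataFrame(
            {
                "hl13": pop.genotype_codes("hl13"),
                "hl14": pop.genotype_codes("hl14"),
                "phenotype": res.phenotypes,
            }
        )
        out = fm.concordance(df)
        assert out.white_concordance == 1.0
        green_gn = df[(df.hl13 == "G") & (df.hl14 == "N")
                      & (df.phenotype == "green")]
        assert len(green_gn) == 0

    def test_offset_markers_match_closed_form(self):
        # markers 1 cM from each causal locus: a white F2 shows the G:N
        # marker class iff neither of its four relevant gametes recombined
        d = 1.0
        map_ = sim.default_map(extra_loci=[
            ("m13", "chr13", 89.0, 17_800_000),
            ("m14", "chr14", 49.0, 9_800_000),
        ])
        res = sim.simulate_f2_population(
            60_000, seed=51, map=map_, fixed_difference_loci=["m13", "m14"]
        )
        pop, ph = res.population, res.phenotypes
        white = pop.subset(ph == "white")
        r = float(sim.haldane_rf(d))
        expected = (1 - r) ** 4
        df = pd.DataFrame(
            {
                "hl13": white.genotype_codes("m13"),
                "hl14": white.genotype_codes("m14"),
                "phenotype": ["white"] * len(white),
            }
        )
        out = fm.concordance(df)
        se = np.sqrt(expected * (1 - expected) / len(white))
        assert out.white_concordance == pytest.approx(expected, abs=3 * se)
        assert out.white_concordance < 1.0

    def test_empty_white_class_reports_missing(self):
        out = fm.concordance(self._table([("H", "H", "green")]))
        assert np.isnan(out.white_concordance)

    def test_individuals_missing_calls_excluded_and_counted(self):
        out = fm.concordance(
            self._table([("G", "N", "white"), (None, "N", "white")])
        )
        assert out.n_excluded == 1
        assert out.white_concordance == 1.0


class TestInferCausalGenotype:
    def _rec(self, phenotype, f3=None):
        return fm.RecombinantRecord("r1", phenotype, ["G", "H"], "N", f3)

    def test_white_is_incompatible_homozygote(self):
        assert fm.infer_causal_genotype(self._rec("white")) == "incompatible_hom"

    def test_green_with_segregating_f3_is_het(self):
        assert fm.infer_causal_genotype(self._rec("green", (30, 10))) == "het"

    def test_green_decisive_all_green_family_is_compatible_hom(self):
        assert fm.infer_causal_genotype(
            self._rec("green", (40, 0))
        ) == "compatible_hom"

    def test_green_without_f3_is_unknown(self):
        assert fm.infer_causal_genotype(self._rec("green")) == "unknown"


def brute_force_interval(records, markers, current, incompatible_allele="G",
                         alpha=0.05):
    """Independent oracle: test every marker gap against every record."""
    consistent_gaps = []
    for i in range(len(markers) - 1):
        lo, hi = markers[i][1], markers[i + 1][1]
        if lo is None or hi is None:
            continue
        if hi <= current.start_bp or lo >= current.end_bp:
            continue
        ok = True
        for rec in records:
            cls = fm.infer_causal_genotype(rec, incompatible_allele, alpha)
            if cls == "unknown":
                continue
            want = {"incompatible_hom": incompatible_allele, "het": "H",
                    "compatible_hom": "N" if incompatible_allele == "G" else "G"}[cls]
            gl, gr = rec.marker_genotypes[i], rec.marker_genotypes[i + 1]
            if not ((gl is None or gl == want) or (gr is None or gr == want)):
                ok = False
                break
        if ok:
            consistent_gaps.append(i)
    return consistent_gaps


class TestNarrowInterval:
    MARKERS = [("m0", 0), ("m1", 100), ("m2", 200), ("m3", 300), ("m4", 400)]

    def test_hand_built_recombinants_isolate_one_gap(self):
        current = fm.GenomicInterval("chr13", 0, 400)
        records = [
            # whites must sit next to a G call: w1's G run ends at m2,
            # excluding the m3-m4 gap ...
            fm.RecombinantRecord("w1", "white", ["G", "G", "G", "H", "H"]),
            # ... and w2's only G call is m3, excluding gaps left of m2
            fm.RecombinantRecord("w2", "white", ["N", "N", "N", "G", "N"]),
        ]
        interval = fm.narrow_interval(records, self.MARKERS, current)
        gaps = brute_force_interval(records, self.MARKERS, current)
        assert gaps == [2]
        assert (interval.start_bp, interval.end_bp) == (200, 300)
        assert interval.left_marker == "m2" and interval.right_marker == "m3"

    def test_no_informative_records_returns_input(self):
        current = fm.GenomicInterval("chr13", 0, 400)
        records = [fm.RecombinantRecord("g1", "green", ["G"] * 5)]
        assert fm.narrow_interval(records, self.MARKERS, current) is current

    def test_disjoint_constraints_raise_inconsistency(self):
        current = fm.GenomicInterval("chr13", 0, 400)
        records = [
            fm.RecombinantRecord("w1", "white", ["G", "N", "N", "N", "N"]),
            fm.RecombinantRecord("w2", "white", ["N", "N", "N", "N", "G"]),
        ]
        with pytest.raises(fm.InconsistencyError):
            fm.narrow_interval(records, self.MARKERS, current)

    def test_missing_calls_are_wildcards(self):
        current = fm.GenomicInterval("chr13", 0, 400)
        records = [
            fm.RecombinantRecord("w1", "white", [None, None, "G", None, "H"]),
        ]
        interval = fm.narrow_interval(records, self.MARKERS, current)
        # G at m2 keeps every gap touching m2 or a wildcard consistent
        assert interval.start_bp == 0 and interval.end_bp == 400

    def test_assembly_gap_flag(self):
        markers = [("m0", 0), ("m1", 100), ("gapM", None), ("m3", 300)]
        current = fm.GenomicInterval("chr14", 0, 300)
        records = [
            fm.RecombinantRecord("w1", "white", ["N", "G", "G", "G"]),
        ]
        interval = fm.narrow_interval(records, markers, current,
                                      incompatible_allele="G")
        assert interval.spans_assembly_gap

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(52)
        n_checked = 0
        for _ in range(200):
            n_markers = int(rng.integers(3, 13))
            bps = np.sort(rng.choice(10_000, size=n_markers, replace=False))
            markers = [(f"m{i}", int(b)) for i, b in enumerate(bps)]
            current = fm.GenomicInterval("c", int(bps[0]), int(bps[-1]) + 1)
            records = []
            for r in range(int(rng.integers(1, 30))):
                phen = "white" if rng.random() < 0.5 else "green"
                genos = [
                    None if rng.random() < 0.1
                    else str(rng.choice(["G", "H", "N"]))
                    for _ in range(n_markers)
                ]
                f3 = None
                if phen == "green" and rng.random() < 0.7:
                    f3 = (int(rng.integers(0, 50)), int(rng.integers(0, 5)))
                    if sum(f3) == 0:
                        f3 = (1, 0)
                records.append(
                    fm.RecombinantRecord(f"r{r}", phen, genos, None, f3)
                )
            gaps = brute_force_interval(records, markers, current)
            informative = any(
                fm.infer_causal_genotype(r) != "unknown" for r in records
            )
            if not gaps:
                if informative:
                    with pytest.raises(fm.InconsistencyError):
                        fm.narrow_interval(records, markers, current)
                continue
            interval = fm.narrow_interval(records, markers, current)
            if not informative:
                assert interval is current
                continue
            assert interval.start_bp == markers[gaps[0]][1]
            assert interval.end_bp == markers[gaps[-1] + 1][1]
            n_checked += 1
        assert n_checked > 30

    def test_soundness_interval_contains_causal_bp(self):
        # error-free simulated recombinants never exclude the true position
        rng = np.random.default_rng(53)
        causal_cm, causal_bp = 90.0, 18_000_000
        # the bracket around the causal locus is tight (0.5 cM each side) so
        # double crossovers inside it — the one event that can mislead
        # marker-based mapping even without genotyping error — are negligible
        marker_cm = [70.0, 80.0, 85.0, 89.5, 90.5, 95.0]
        extra = [
            (f"m{i}", "chr13", cm, cm * sim.BP_PER_CM)
            for i, cm in enumerate(marker_cm)
        ]
        map_ = sim.default_map(extra_loci=extra)
        marker_ids = [f"m{i}" for i in range(len(marker_cm))]
        markers = [(mid, int(map_.locus_bp[map_.index(mid)]))
                   for mid in marker_ids]
        for rep in range(30):
            res = sim.simulate_f2_population(
                400, seed=500 + rep, map=map_,
                fixed_difference_loci=marker_ids,
            )
            pop, ph = res.population, res.phenotypes
            records = []
            for i in range(len(pop)):
                ind = pop[i]
                genos = [ind.genotype(mid) for mid in marker_ids]
                if ph[i] == "white":
                    records.append(
                        fm.RecombinantRecord(f"w{i}", "white", genos)
                    )
                else:
                    # perfect-knowledge progeny test: derive family from truth
                    n13 = ind.n_alt("hl13")
                    if ind.n_alt("hl14") != 2 or n13 == 0:
                        continue  # progeny test uninformative for hl13
                    f3 = (30, 10) if n13 == 1 else (40, 0)
                    records.append(
                        fm.RecombinantRecord(f"g{i}", "green", genos,
                                             None, f3)
                    )
            current = fm.GenomicInterval("chr13", 14_000_000, 19_000_000)
            interval = fm.narrow_interval(records, markers, current)
            assert interval.contains(causal_bp)

    def test_adding_records_never_widens(self):
        rng = np.random.default_rng(54)
        markers = self.MARKERS
        current = fm.GenomicInterval("chr13", 0, 400)
        base = [
            fm.RecombinantRecord("w1", "white", ["H", "H", "G", "G", "G"]),
        ]
        interval = fm.narrow_interval(base, markers, current)
        more = base + [
            fm.RecombinantRecord("w2", "white", ["H", "H", "H", "G", "G"]),
        ]
        narrowed = fm.narrow_interval(more, markers, current)
        assert narrowed.start_bp >= interval.start_bp
        assert narrowed.end_bp <= interval.end_bp
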