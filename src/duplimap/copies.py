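"""Placing duplicate gene copies onto loci and assessing their function.

PCR across a duplicated gene amplifies every copy an individual carries, so
the sequencing read-out at diagnostic SNP positions is a superposition of
haplotypes (here G1, G2 from the *M. guttatus* parent and N1 from
*M. nasutus*). Copies are placed onto loci by association: a haplotype that
is present exactly in the individuals whose genotype at a locus contains a
given parental allele maps to that (locus, allele) with zero mismatches.
Copy functionality is probed by frameshift / premature-stop detection
against an intact reference CDS, and by which haplotypes appear in
transcript (RNA-seq) evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

__all__ = [
    "HaplotypePanel",
    "HaplotypeCall",
    "CopyPlacement",
    "call_haplotypes",
    "infer_placement",
    "FrameshiftReport",
    "detect_frameshift",
    "expressed_copies",
    "NOT_EXPRESSED",
]

_NUCLEOTIDES = set("ACGT")


class HaplotypePanel:
    """Diagnostic SNP positions and each haplotype's allele state at them."""

    def __init__(self, positions: Sequence[int], states: Mapping[str, Sequence[str]]):
        self.positions = [int(p) for p in positions]
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("duplicate diagnostic positions")
        self.states = {}
        for hap, vec in states.items():
            vec = tuple(str(b).upper() for b in vec)
            if len(vec) != len(self.positions):
                raise ValueError(
                    f"haplotype {hap!r} has {len(vec)} states for "
                    f"{len(self.positions)} positions"
                )
            self.states[str(hap)] = vec
        vectors = list(self.states.values())
        if len(set(vectors)) != len(vectors):
            raise ValueError("haplotype state vectors must be pairwise distinct")
        # every position must distinguish at least one haplotype pair
        for j, pos in enumerate(self.positions):
            if len({v[j] for v in vectors}) < 2 and len(vectors) > 1:
                raise ValueError(f"position {pos} is uninformative")

    @property
    def haplotypes(self):
        return list(self.states)

    def __len__(self):
        return len(self.positions)


@dataclass(frozen=True)
class HaplotypeCall:
    """Haplotypes detected in one superposed observation."""

    present: frozenset
    ambiguous: frozenset

    def __contains__(self, hap):
        return hap in self.present


def call_haplotypes(observed: Mapping[int, object],
                    panel: HaplotypePanel) -> HaplotypeCall:
    """Which panel haplotypes are contained in a superposed observation.

    ``observed`` maps a diagnostic position to the set of bases seen there
    (a string of one or more bases also works). A haplotype is called
    present when its state at every observed position is among the observed
    bases. Haplotypes that are indistinguishable because their only
    diagnostic differences fall at unobserved positions, or whose observed
    states are wholly covered by the other called haplotypes, are flagged
    ambiguous. Observations at non-panel positions are rejected.
    """
    obs = {}
    for pos, bases in observed.items():
        pos = int(pos)
        if pos not in panel.positions:
            raise ValueError(f"position {pos} is not in the panel")
        obs[pos] = {str(b).upper() for b in bases}
    observed_idx = [j for j, p in enumerate(panel.positions) if p in obs]
    unobserved_idx = [j for j in range(len(panel)) if j not in observed_idx]

    present = set()
    for hap, vec in panel.states.items():
        if all(vec[j] in obs[panel.positions[j]] for j in observed_idx):
            present.add(hap)

    ambiguous = set()
    for hap in present:
        vec = panel.states[hap]
        # indistinguishable from another candidate at the observed positions
        for other in present:
            if other == hap:
                continue
            if all(panel.states[other][j] == vec[j] for j in observed_idx):
                ambiguous.add(hap)
                ambiguous.add(other)
        # adds no unique evidence beyond the other candidates combined
        others_union = [
            {panel.states[o][j] for o in present if o != hap}
            for j in range(len(panel))
        ]
        if present - {hap} and all(
            vec[j] in others_union[j] for j in observed_idx
        ):
            ambiguous.add(hap)
    return HaplotypeCall(frozenset(present), frozenset(ambiguous))


# ---------------------------------------------------------------------------
# locus placement


@dataclass
class CopyPlacement:
    """Assignment of each haplotype to a (locus, parental allele)."""

    assignments: dict  # hap -> (locus, allele) or None
    mismatches: dict  # hap -> mismatch count of its assignment (or best)
    table: pd.DataFrame  # all (hap, locus, allele) mismatch counts

    @property
    def perfect(self) -> bool:
        return all(
            a is not None and self.mismatches[h] == 0
            for h, a in self.assignments.items()
        )


def infer_placement(presence: pd.DataFrame,
                    genotypes: pd.DataFrame,
                    loci: Sequence[str] = ("hl13", "hl14")) -> CopyPlacement:
    """Place haplotypes onto loci from presence/absence across genotype classes.

    ``presence`` is individuals x haplotypes (bool); ``genotypes`` holds the
    same individuals' G/H/N codes in one column per locus. Presence is
    dominant — a copy amplifies from either homolog — so the predicted
    presence of a copy sitting at (locus, allele) is "genotype at locus
    contains that allele". Each haplotype is assigned its unique
    zero-mismatch candidate; otherwise it is left unplaced with its best
    candidates reported.
    """
    if len(presence) != len(genotypes):
        raise ValueError("presence and genotype tables differ in length")
    classes = genotypes[list(loci)].apply(tuple, axis=1).nunique()
    if classes < 2:
        raise ValueError(
            "placement is unidentifiable with fewer than two genotype classes"
        )
    rows = []
    assignments = {}
    mismatches = {}
    for hap in presence.columns:
        obs = presence[hap].to_numpy(dtype=bool)
        best = []
        for locus in loci:
            codes = genotypes[locus].to_numpy()
            for allele in ("G", "N"):
                predicted = (codes == allele) | (codes == "H")
                mm = int((obs != predicted).sum())
                rows.append(
                    {"haplotype": hap, "locus": locus, "allele": allele,
                     "mismatches": mm}
                )
                best.append((mm, locus, allele))
        best.sort()
        zero = [b for b in best if b[0] == 0]
        if len(zero) == 1:
            assignments[hap] = (zero[0][1], zero[0][2])
            mismatches[hap] = 0
        else:
            assignments[hap] = None
            mismatches[hap] = best[0][0]
    return CopyPlacement(assignments, mismatches, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# frameshift / premature stop detection


@dataclass
class FrameshiftReport:
    net_offset: int  # (len(query) - len(reference)) mod 3, in {0, 1, 2}
    frameshift: bool
    premature_stops: list  # codon indices (0-based) in the query translation
    truncated_protein_length: int | None  # aa before the first premature stop
    alignment_score: float


def _check_nucleotides(seq: str, name: str) -> str:
    s = str(seq).upper().replace("\n", "")
    bad = set(s) - _NUCLEOTIDES
    if bad:
        raise ValueError(f"{name} contains non-nucleotide symbols: {sorted(bad)}")
    return s


def detect_frameshift(query, reference, open_gap: float = 10.0,
                      extend_gap: float = 0.5, match: float = 1.0,
                      mismatch: float = -1.0) -> FrameshiftReport:
    """Detect frame-disrupting indels and the premature stops they cause.

    The query CDS is globally aligned to an intact reference CDS (affine
    gaps). A net indel offset that is not a multiple of three is a
    frameshift. The query is then translated from the position aligned to
    the reference start; every stop codon falling before the reference's
    terminal stop is reported as premature.
    """
    q = _check_nucleotides(query, "query")
    r = _check_nucleotides(reference, "reference")

    ref_prot = str(Seq(r[: len(r) - len(r) % 3]).translate())
    internal = ref_prot[:-1] if ref_prot else ""
    if "*" in internal:
        raise ValueError("reference CDS has internal stop codons")
    ref_terminal_idx = len(ref_prot) - 1 if ref_prot.endswith("*") else len(ref_prot)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(open_gap)
    aligner.extend_gap_score = -abs(extend_gap)
    aln = aligner.align(q, r)[0]

    net = len(q) - len(r)
    offset = net % 3
    frameshift = offset != 0

    q_blocks, r_blocks = aln.aligned

    def map_ref_to_query(p: int) -> int:
        """Project a reference coordinate onto the query through the alignment."""
        for (qs, qe), (rs, re) in zip(q_blocks, r_blocks):
            if p < rs:
                return int(qs)
            if rs <= p < re:
                return int(qs + (p - rs))
        return len(q)

    # translate the query from the position aligned to the reference start;
    # a stop is premature only if its codon ends before the query position
    # aligned to the reference's terminal stop codon
    q_start = map_ref_to_query(0)
    terminal_q = map_ref_to_query(ref_terminal_idx * 3)
    coding = q[q_start:]
    q_prot = str(Seq(coding[: len(coding) - len(coding) % 3]).translate())
    stops = [i for i, aa in enumerate(q_prot) if aa == "*"]
    premature = [i for i in stops if q_start + 3 * i + 3 <= terminal_q]
    truncated = premature[0] if premature else None
    return FrameshiftReport(offset, frameshift, premature, truncated,
                            float(aln.score))


# ---------------------------------------------------------------------------
# expressed copies from transcript evidence

NOT_EXPRESSED = "not_expressed"


def expressed_copies(observed: Mapping[int, object],
                     coverage: Mapping[int, int],
                     panel: HaplotypePanel,
                     min_coverage: int = 5):
    """Which copies a sample expresses, from transcript SNP states.

    Diagnostic positions with read coverage below ``min_coverage`` are
    masked. If every position is masked the sample is called
    ``'not_expressed'`` (the signature of white seedlings, whose transcript
    coverage collapses); otherwise the unmasked observations are resolved
    with :func:`call_haplotypes`.
    """
    kept = {}
    for pos in panel.positions:
        cov = int(coverage.get(pos, 0))
        if cov >= min_coverage and pos in observed:
            kept[pos] = observed[pos]
    if not kept:
        return NOT_EXPRESSED
    return call_haplotypes(kept, panel)
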