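"""Core-microbiome selection, keystone intersection and isolate matching.

The core rule is the prevalence-abundance OR criterion: a taxon is core if
it is present in at least 85% of all samples or has a mean relative
abundance of at least 0.1%.  Keystone sets from per-genotype networks are
intersected Venn-style, and cultured-isolate 16S sequences are matched to
ASV representatives by global (Needleman-Wunsch) alignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .io import FeatureTable, relative_abundance

__all__ = [
    "keystone_intersection",
    "prevalence_abundance_core",
    "match_isolate_to_asv",
    "AlignmentResult",
    "rank_core_candidates",
]

_IUPAC = set("ACGTUNRYSWKMBDHV")


def keystone_intersection(
    keystone_sets: dict[str, set[str]]
) -> tuple[dict[frozenset, set[str]], set[str]]:
    """Venn decomposition of per-group keystone sets.

    Returns ``(regions, shared)``: ``regions`` maps each non-empty group
    subset to the taxa belonging to exactly those groups (regions partition
    the union), and ``shared`` is the all-groups intersection.
    """
    if not keystone_sets:
        raise ValueError("no keystone sets given")
    groups = list(keystone_sets)
    regions: dict[frozenset, set[str]] = {}
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            inside = set.intersection(*(keystone_sets[g] for g in combo))
            outside = set.union(
                set(), *(keystone_sets[g] for g in groups if g not in combo)
            )
            exact = inside - outside
            if exact:
                regions[frozenset(combo)] = exact
    shared = set.intersection(*keystone_sets.values())
    return regions, shared


def prevalence_abundance_core(
    table: FeatureTable,
    prevalence_min: float = 0.85,
    abundance_min: float = 0.001,
) -> pd.DataFrame:
    """Per-taxon prevalence/abundance records with inclusive OR core flags.

    Prevalence is the fraction of all samples (pooled across groups) with a
    non-zero count; mean relative abundance averages per-sample proportions.
    A taxon is core if either statistic reaches its threshold ("at least").
    """
    for thr in (prevalence_min, abundance_min):
        if not (0 <= thr <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
    prevalence = (table.counts > 0).mean(axis=0)
    mean_rel = relative_abundance(table).mean(axis=0)
    out = pd.DataFrame(
        {
            "prevalence": prevalence,
            "mean_rel_abund": mean_rel,
            "core_by_prevalence": prevalence >= prevalence_min,
            "core_by_abundance": mean_rel >= abundance_min,
        }
    ).rename_axis("taxon_id")
    out["core"] = out["core_by_prevalence"] | out["core_by_abundance"]
    return out


@dataclass
class AlignmentResult:
    aligned_length: int
    matches: int
    mismatches: int
    gaps: int
    identity_pct: float  # matches / aligned columns * 100
    identity_ungapped_pct: float  # matches / (matches + mismatches) * 100
    orientation: str  # "forward" or "revcomp"
    score: float


def _validate_seq(seq: str, name: str) -> str:
    seq = seq.upper().replace("U", "T")
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"{name} has non-IUPAC characters: {sorted(bad)}")
    return seq


def _global_align(a: str, b: str, match, mismatch, gap_open, gap_extend):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return alignment.score, counts.identities, counts.mismatches, counts.gaps


def match_isolate_to_asv(
    isolate_seq: str,
    asv_seq: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -2.0,
    try_revcomp: bool = False,
) -> AlignmentResult:
    """Global pairwise alignment of an isolate 16S read against an ASV.

    Identity is reported two ways: over all aligned columns (gap columns in
    the denominator) and over substitution columns only, since a gapless
    comparison of near-identical 16S fragments makes the two coincide.
    With ``try_revcomp`` the reverse-complement orientation of the isolate
    is also scored and the better one reported.
    """
    a = _validate_seq(isolate_seq, "isolate")
    b = _validate_seq(asv_seq, "asv")
    score, ident, mism, gaps = _global_align(a, b, match, mismatch, gap_open, gap_extend)
    orientation = "forward"
    if try_revcomp:
        rc = str(Seq(a).reverse_complement())
        score_rc, ident_rc, mism_rc, gaps_rc = _global_align(
            rc, b, match, mismatch, gap_open, gap_extend
        )
        if score_rc > score:
            score, ident, mism, gaps = score_rc, ident_rc, mism_rc, gaps_rc
            orientation = "revcomp"
    aligned = ident + mism + gaps
    return AlignmentResult(
        aligned_length=int(aligned),
        matches=int(ident),
        mismatches=int(mism),
        gaps=int(gaps),
        identity_pct=100.0 * ident / aligned if aligned else 0.0,
        identity_ungapped_pct=100.0 * ident / (ident + mism) if ident + mism else 0.0,
        orientation=orientation,
        score=float(score),
    )


def rank_core_candidates(
    core_records: pd.DataFrame, keystone_shared: set[str]
) -> pd.DataFrame:
    """Core taxa that are also shared keystones, best candidates first.

    Ordered by prevalence, then mean relative abundance (both descending),
    ties broken by taxon id.
    """
    core_taxa = core_records[core_records["core"]]
    cand = core_taxa.loc[core_taxa.index.isin(keystone_shared)].reset_index()
    cand = cand.sort_values(
        by=["prevalence", "mean_rel_abund", "taxon_id"],
        ascending=[False, False, True],
    )
    return cand.set_index("taxon_id")
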