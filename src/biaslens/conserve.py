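"""Pairwise identity/similarity and per-column conservation profiling.

The focal pair (e.g., the two catalytically biased paralogs) is compared by
optimal global alignment; the "conserved region" is the catalytic-domain
block spanning the L1 motif through the end of the L3 motif of a chosen
reference sequence. Conservation profiling removes columns where the two
focal sequences agree and, for each remaining column, reports how often
homologs carry the focal-A residue, the focal-B residue, or anything else.

Defaults (substitution matrix BLOSUM62, gap open 10, gap extend 0.5) are
documented conventions, overridable at every entry point. A gap of length
L scores -(open) - (L-1)*(extend).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import GAP, Alignment, SequenceRecord
from .motifs import BUILTIN_MOTIFS, MotifDef, scan_motifs

__all__ = [
    "PairwiseResult",
    "PROFILE_COLUMNS",
    "global_align",
    "percent_identity",
    "percent_similarity",
    "conserved_region",
    "trim_to_region",
    "compare_pair",
    "conservation_profile",
]

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

#: Fixed column order of the conservation-profile table.
PROFILE_COLUMNS = ["column", "res_a", "res_b", "pct_a", "pct_b", "pct_other"]


@dataclass(frozen=True)
class PairwiseResult:
    identity_full: float  # % over the whole alignment, gaps in denominator
    identity_region: float  # % within the conserved region
    similarity_region: float  # % of positive-substitution-score positions
    region: tuple[int, int]  # closed 1-based column bounds
    score: float

    def __post_init__(self) -> None:
        lo, hi = self.region
        if not (0 <= self.identity_region <= self.similarity_region <= 100):
            raise ValueError("identity/similarity out of order")
        if lo > hi:
            raise ValueError("empty conserved region")


def _load_matrix(matrix: str | substitution_matrices.Array):
    if isinstance(matrix, str):
        return substitution_matrices.load(matrix)
    return matrix


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: str | substitution_matrices.Array = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[Alignment, float]:
    """Optimal global alignment under affine gaps; returns (pair, score)."""
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _load_matrix(matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    result = aligner.align(a.ungapped, b.ungapped)
    best = result[0]
    pair = Alignment(
        [
            SequenceRecord(a.id, str(best[0]), a.description),
            SequenceRecord(b.id, str(best[1]), b.description),
        ]
    )
    return pair, float(best.score)


def percent_identity(
    pair: Alignment, start: int | None = None, end: int | None = None
) -> float:
    """Exact matches over region length (gap columns count in denominator)."""
    start = 1 if start is None else start
    end = pair.n_columns if end is None else end
    row_a, row_b = (r.residues for r in pair.records[:2])
    matches = sum(
        1
        for c in range(start - 1, end)
        if row_a[c] == row_b[c] != GAP
    )
    return 100.0 * matches / (end - start + 1)


def percent_similarity(
    pair: Alignment,
    matrix: str | substitution_matrices.Array = DEFAULT_MATRIX,
    start: int | None = None,
    end: int | None = None,
) -> float:
    """Positions with a positive substitution score, over region length."""
    m = _load_matrix(matrix)
    start = 1 if start is None else start
    end = pair.n_columns if end is None else end
    row_a, row_b = (r.residues for r in pair.records[:2])
    positive = 0
    for c in range(start - 1, end):
        x, y = row_a[c], row_b[c]
        if GAP in (x, y):
            continue
        if m[x, y] > 0:
            positive += 1
    return 100.0 * positive / (end - start + 1)


def conserved_region(
    aln: Alignment,
    reference_id: str,
    l1: MotifDef | None = None,
    l3: MotifDef | None = None,
) -> tuple[int, int]:
    """Closed column bounds of the catalytic block: L1 start .. L3 end.

    Anchors are located on the ungapped reference sequence (first L1 hit,
    last L3 hit) and mapped to alignment columns.
    """
    l1 = l1 or BUILTIN_MOTIFS["L1"]
    l3 = l3 or BUILTIN_MOTIFS["L3"]
    ref = aln[reference_id]
    ungapped = SequenceRecord(ref.id, ref.ungapped, ref.description)
    l1_hits = scan_motifs(ungapped, [l1])
    l3_hits = scan_motifs(ungapped, [l3])
    if not l1_hits:
        raise ValueError(f"anchor motif {l1.name} not found in {reference_id!r}")
    if not l3_hits:
        raise ValueError(f"anchor motif {l3.name} not found in {reference_id!r}")
    start_res = l1_hits[0].start
    end_res = l3_hits[-1].start + len(l3.pattern) - 1
    return (
        aln.res_to_col(reference_id, start_res),
        aln.res_to_col(reference_id, end_res),
    )


def trim_to_region(aln: Alignment, reference_id: str, **kwargs) -> Alignment:
    """The alignment restricted to the conserved (catalytic-domain) block."""
    lo, hi = conserved_region(aln, reference_id, **kwargs)
    return aln.slice_columns(lo, hi)


def compare_pair(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: str | substitution_matrices.Array = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[Alignment, PairwiseResult]:
    """Align the focal pair and report full-length and region statistics."""
    pair, score = global_align(a, b, matrix, gap_open, gap_extend)
    lo, hi = conserved_region(pair, a.id)
    return pair, PairwiseResult(
        identity_full=percent_identity(pair),
        identity_region=percent_identity(pair, lo, hi),
        similarity_region=percent_similarity(pair, matrix, lo, hi),
        region=(lo, hi),
        score=score,
    )


def conservation_profile(
    msa: Alignment,
    focal_a: str,
    focal_b: str,
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-column conservation of the focal residues among homologs.

    Columns where the focal residues are identical (including both-gap) are
    dropped. Homolog residues equal to focal A count toward ``pct_a``, equal
    to focal B toward ``pct_b``; gaps and anything else count as
    ``pct_other``. The two focal rows are excluded from the denominator.
    ``region`` optionally restricts profiling to closed column bounds.
    """
    for fid in (focal_a, focal_b):
        if fid not in msa:
            raise ValueError(f"focal sequence {fid!r} not in alignment")
    homologs = [r for r in msa.records if r.id not in (focal_a, focal_b)]
    if not homologs:
        raise ValueError("need at least one homolog besides the focal pair")
    row_a = msa[focal_a].residues
    row_b = msa[focal_b].residues
    lo, hi = region if region is not None else (1, msa.n_columns)
    rows = []
    n = len(homologs)
    for col in range(lo, hi + 1):
        ca, cb = row_a[col - 1], row_b[col - 1]
        if ca == cb:
            continue
        count_a = count_b = 0
        for hom in homologs:
            ch = hom.residues[col - 1]
            if ch == GAP:
                continue
            if ch == ca and ca != GAP:
                count_a += 1
            elif ch == cb and cb != GAP:
                count_b += 1
        pct_a = 100.0 * count_a / n
        pct_b = 100.0 * count_b / n
        rows.append(
            {
                "column": col,
                "res_a": ca,
                "res_b": cb,
                "pct_a": pct_a,
                "pct_b": pct_b,
                "pct_other": 100.0 - pct_a - pct_b,
            }
        )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)
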