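"""Hydrogenase signature-motif scanning and group classification.

Motif patterns are strings over the amino-acid alphabet where lowercase
``x`` matches any residue. Matching is exact (wildcards only) unless a
mismatch budget is requested explicitly.

Group rules are a deliberate simplification of the published A1–A5/B1–B3
scheme: only the groups this pipeline needs (A2, A3, B2) are assigned, from
the catalytic-domain motifs plus the accessory-cluster cysteine inventory.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core_io import GAP, Alignment, SequenceRecord

logger = logging.getLogger(__name__)

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "MotifDef",
    "MotifHit",
    "HydrogenaseClassification",
    "BUILTIN_MOTIFS",
    "scan_motifs",
    "ligand_inventory",
    "classify",
    "read_motif_table",
    "read_reference_annotation",
]


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        bad = set(self.pattern) - set(AA_LETTERS) - {"x", "X"}
        # uppercase X is a residue wildcard in sequences, lowercase x is the
        # pattern wildcard; both are accepted in patterns and mean "any"
        if bad:
            raise ValueError(f"invalid characters in pattern {self.pattern!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, window: str, max_mismatch: int = 0) -> bool:
        if len(window) != len(self.pattern):
            return False
        mismatches = 0
        for p, c in zip(self.pattern, window):
            if p in "xX":
                continue
            if p != c:
                mismatches += 1
                if mismatches > max_mismatch:
                    return False
        return True


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int  # 1-based, inclusive
    matched: str


#: Catalytic-domain signatures: the three H-cluster motifs of
#: [FeFe]-hydrogenases, the B-group P1 variant carrying an extra cysteine,
#: and the [NiFe] terminal cysteine pair.
BUILTIN_MOTIFS: dict[str, MotifDef] = {
    "L1": MotifDef("L1", "TSCCPxW"),
    "L2": MotifDef("L2", "MPCxxKxxE"),
    "L3": MotifDef("L3", "ExMxCxxGCxxG"),
    "P1B": MotifDef("P1B", "TSCCCPxW"),
    "NIFE_CXXC": MotifDef("NIFE_CXXC", "CxxC"),
}


def scan_motifs(
    seq: SequenceRecord,
    motifs: Iterable[MotifDef],
    max_mismatch: int = 0,
) -> list[MotifHit]:
    """All (possibly overlapping) motif occurrences, sorted by start."""
    residues = seq.ungapped
    hits: list[MotifHit] = []
    for motif in motifs:
        m = len(motif.pattern)
        for start in range(len(residues) - m + 1):
            window = residues[start : start + m]
            if motif.matches(window, max_mismatch):
                hits.append(MotifHit(motif.name, start + 1, window))
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


def ligand_inventory(
    seq: SequenceRecord,
    reference: SequenceRecord,
    ref_positions: Mapping[str, Sequence[int]],
    pairwise_aln: Alignment,
) -> dict[str, int]:
    """Count conserved cysteines of `seq` at reference ligand positions.

    ``ref_positions`` maps an accessory-cluster label to the 1-based
    ungapped residue indices of its ligating cysteines in the reference.
    A position aligned to a gap in `seq` contributes 0.
    """
    if reference.id not in pairwise_aln or seq.id not in pairwise_aln:
        raise ValueError("pairwise alignment must contain both sequences")
    ref_ungapped = reference.ungapped
    seq_row = pairwise_aln[seq.id].residues
    counts: dict[str, int] = {}
    for cluster, positions in ref_positions.items():
        n = 0
        for pos in positions:
            if not 1 <= pos <= len(ref_ungapped):
                raise ValueError(
                    f"{cluster}: reference position {pos} out of range"
                )
            if ref_ungapped[pos - 1] != "C":
                raise ValueError(
                    f"{cluster}: reference residue {pos} is "
                    f"{ref_ungapped[pos - 1]!r}, expected cysteine "
                    "(corrupt annotation)"
                )
            col = pairwise_aln.res_to_col(reference.id, pos)
            if seq_row[col - 1] == "C":
                n += 1
        counts[cluster] = n
    return counts


@dataclass
class HydrogenaseClassification:
    seq_id: str
    type: str  # "[FeFe]" | "[NiFe]" | "none"
    hits: list[MotifHit]
    ligand_inventory: dict[str, int] | None
    group: str  # "A2" | "A3" | "B2" | "unclassified"
    reasons: list[str] = field(default_factory=list)


def _in_order(hits: list[MotifHit], names: Sequence[str]) -> bool:
    """True if one occurrence of each name exists with increasing starts."""
    last = 0
    for name in names:
        starts = [h.start for h in hits if h.motif == name and h.start > last]
        if not starts:
            return False
        last = min(starts)
    return True


NIFE_TERMINUS_WINDOW = 80  # "near each terminus", operationalized


def classify(
    seq: SequenceRecord,
    motifs: Mapping[str, MotifDef] | None = None,
    reference: SequenceRecord | None = None,
    ref_positions: Mapping[str, Sequence[int]] | None = None,
    pairwise_aln: Alignment | None = None,
    max_mismatch: int = 0,
) -> HydrogenaseClassification:
    """Assign hydrogenase type and group from motifs and ligand inventory.

    [FeFe] requires the three H-cluster motifs in order (the P1B variant
    satisfies the L1 requirement, since it is the same motif with an extra
    cysteine). Among [FeFe]: a P1B hit gives B2; a full accessory inventory
    gives A2; FS2 and FS4C empty with FS4A/FS4B full gives A3; anything else
    is unclassified with the reasons recorded.
    """
    motifs = dict(motifs or BUILTIN_MOTIFS)
    hits = scan_motifs(seq, motifs.values(), max_mismatch=max_mismatch)
    reasons: list[str] = []

    has = lambda name: any(h.motif == name for h in hits)  # noqa: E731
    fefe = (_in_order(hits, ["L1", "L2", "L3"]) if has("L1") else False) or (
        _in_order(hits, ["P1B", "L2", "L3"]) if has("P1B") else False
    )

    inventory: dict[str, int] | None = None
    if reference is not None and ref_positions is not None and pairwise_aln is not None:
        inventory = ligand_inventory(seq, reference, ref_positions, pairwise_aln)

    if fefe:
        if has("P1B"):
            return HydrogenaseClassification(seq.id, "[FeFe]", hits, inventory, "B2")
        if inventory is None:
            reasons.append("no reference annotation: accessory inventory unknown")
            return HydrogenaseClassification(
                seq.id, "[FeFe]", hits, None, "unclassified", reasons
            )
        full = {
            c: len(ref_positions[c]) for c in inventory  # type: ignore[index]
        }
        if all(inventory[c] == full[c] for c in inventory):
            return HydrogenaseClassification(seq.id, "[FeFe]", hits, inventory, "A2")
        absent = {c for c in inventory if inventory[c] == 0}
        complete = {c for c in inventory if inventory[c] == full[c]}
        if {"FS2", "FS4C"} <= absent and {"FS4A", "FS4B"} <= complete:
            return HydrogenaseClassification(seq.id, "[FeFe]", hits, inventory, "A3")
        reasons.append(
            f"accessory inventory {inventory} matches neither A2 nor A3 pattern"
        )
        return HydrogenaseClassification(
            seq.id, "[FeFe]", hits, inventory, "unclassified", reasons
        )

    # [NiFe]: CxxC within NIFE_TERMINUS_WINDOW residues of both termini
    n = seq.length
    cxxc = [h for h in hits if h.motif == "NIFE_CXXC"]
    near_n = any(h.start <= NIFE_TERMINUS_WINDOW for h in cxxc)
    near_c = any(h.start + len(h.matched) - 1 > n - NIFE_TERMINUS_WINDOW for h in cxxc)
    if near_n and near_c and n > 0:
        return HydrogenaseClassification(
            seq.id, "[NiFe]", hits, inventory, "unclassified",
            ["[NiFe] large-subunit cysteine pairs found near both termini"],
        )

    reasons.append("no hydrogenase signature motifs found in required arrangement")
    logger.info("classify(%s): %s", seq.id, "; ".join(reasons))
    return HydrogenaseClassification(seq.id, "none", hits, inventory, "unclassified", reasons)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def read_motif_table(path: str | Path) -> dict[str, MotifDef]:
    """TSV with columns ``name`` and ``pattern``."""
    motifs: dict[str, MotifDef] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            motifs[row["name"]] = MotifDef(row["name"], row["pattern"])
    if not motifs:
        warnings.warn(f"no motifs read from {path}")
    return motifs


def read_reference_annotation(path: str | Path) -> dict[str, list[int]]:
    """TSV with columns ``cluster`` and ``position`` (1-based residue)."""
    positions: dict[str, list[int]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            positions.setdefault(row["cluster"], []).append(int(row["position"]))
    return positions
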