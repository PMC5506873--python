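"""Seeded generators that give every pipeline stage inputs with known truth.

All randomness flows from a single integer seed. Each generator derives an
independent stream with :func:`stream_rng`, which mixes the seed with a
CRC32 of a stream name, so adding a generator never perturbs another's
draws.

Generators return the in-memory object plus a "truth" dict recording what
was planted (motif offsets, per-column residue frequencies, cluster
distances, expression ratios), so tests can assert exact recovery.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    Alignment,
    Atom,
    Residue,
    SequenceRecord,
    StructureModel,
    Tree,
    TreeNode,
)
from .motifs import AA_LETTERS, BUILTIN_MOTIFS, MotifDef
from .qpcr import CtTable

__all__ = [
    "stream_rng",
    "gen_tree",
    "gen_bm_trait",
    "gen_binary_trait",
    "gen_proteome",
    "gen_sequence_with_motifs",
    "MsaColumnSpec",
    "gen_msa",
    "gen_hydrogenase",
    "gen_structure",
    "gen_ct",
    "gen_bundle",
]


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for (seed, stream name)."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


# ---------------------------------------------------------------------------
# trees and traits
# ---------------------------------------------------------------------------


def gen_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Tree:
    """Yule (pure-birth) tree with `n_tips` extant tips, labeled t1..tn.

    Lineages split at rate ``birth_rate`` each; a final holding time is run
    after the last split so no terminal branch has zero length.
    """
    if n_tips < 4:
        raise ValueError("need at least 4 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = stream_rng(seed, "tree")
    active = [TreeNode(None, 0.0), TreeNode(None, 0.0)]
    root = TreeNode(None, None, list(active))
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.length += wait  # type: ignore[operator]
        parent = active.pop(int(rng.integers(len(active))))
        children = [TreeNode(None, 0.0), TreeNode(None, 0.0)]
        parent.children = children
        active.extend(children)
    wait = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length += wait  # type: ignore[operator]
    for i, node in enumerate(active, 1):
        node.label = f"t{i}"
    return Tree(root, rooted=True)


def gen_bm_trait(tree: Tree, sigma: float = 1.0, seed: int = 0) -> dict[str, float]:
    """Brownian-motion trait: tip covariance is sigma^2 times the tree's C."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = stream_rng(seed, "bm-trait")
    trait: dict[str, float] = {}

    def walk(node, value: float) -> None:
        if node.length is not None and node.length > 0:
            value = value + rng.normal(0.0, sigma * math.sqrt(node.length))
        if node.is_leaf:
            trait[node.label or ""] = value
        for child in node.children:
            walk(child, value)

    walk(tree.root, 0.0)
    return trait


def gen_binary_trait(
    tree: Tree,
    seed: int = 0,
    method: str = "threshold",
    rate: float = 1.0,
    sigma: float = 1.0,
) -> dict[str, float]:
    """Binary tip trait, by thresholding a BM draw at its median or by a
    symmetric two-state Markov (Mk) walk at the given rate."""
    if method == "threshold":
        values = gen_bm_trait(tree, sigma=sigma, seed=seed)
        cut = float(np.median(list(values.values())))
        return {k: 1.0 if v > cut else 0.0 for k, v in values.items()}
    if method != "mk":
        raise ValueError(f"unknown method {method!r}")
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = stream_rng(seed, "mk-trait")
    trait: dict[str, float] = {}

    def walk(node, state: float) -> None:
        if node.length:
            p_flip = 0.5 * (1.0 - math.exp(-2.0 * rate * node.length))
            if rng.random() < p_flip:
                state = 1.0 - state
        if node.is_leaf:
            trait[node.label or ""] = state
        for child in node.children:
            walk(child, state)

    walk(tree.root, float(rng.integers(2)))
    return trait


# ---------------------------------------------------------------------------
# sequences and alignments
# ---------------------------------------------------------------------------


def _random_residues(rng: np.random.Generator, length: int, alphabet: str = AA_LETTERS) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def gen_proteome(
    n: int, length_range: tuple[int, int] = (50, 400), seed: int = 0
) -> list[SequenceRecord]:
    rng = stream_rng(seed, "proteome")
    lo, hi = length_range
    return [
        SequenceRecord(f"prot{i+1:04d}", _random_residues(rng, int(rng.integers(lo, hi + 1))))
        for i in range(n)
    ]


def _concretize(pattern: str, filler: str = "A") -> str:
    """A concrete string matching the pattern (wildcards become `filler`)."""
    return "".join(filler if c in "xX" else c for c in pattern)


def gen_sequence_with_motifs(
    length: int,
    offsets: Mapping[str, int],
    seed: int = 0,
    motifs: Mapping[str, MotifDef] | None = None,
    seq_id: str = "synth",
) -> tuple[SequenceRecord, dict]:
    """Random sequence with motifs planted at 1-based offsets.

    Planted instances must not overlap; offsets are recorded in the truth
    dict (note the random background can contain additional chance hits —
    callers that need exact hit sets should scan with an oracle).
    """
    motifs = dict(motifs or BUILTIN_MOTIFS)
    rng = stream_rng(seed, "motif-seq")
    residues = list(_random_residues(rng, length))
    occupied: set[int] = set()
    for name, start in sorted(offsets.items(), key=lambda kv: kv[1]):
        pattern = motifs[name].pattern
        span = range(start - 1, start - 1 + len(pattern))
        if span.stop > length:
            raise ValueError(f"motif {name} at {start} exceeds sequence length")
        if occupied & set(span):
            raise ValueError(f"motif {name} at {start} overlaps a prior motif")
        occupied.update(span)
        concrete = _concretize(pattern)
        for i, c in zip(span, concrete):
            residues[i] = c
    return (
        SequenceRecord(seq_id, "".join(residues)),
        {"offsets": dict(offsets)},
    )


@dataclass(frozen=True)
class MsaColumnSpec:
    """A focal-pair-differing column with exact planted homolog frequencies."""

    res_a: str
    res_b: str
    freq_a: float
    freq_b: float

    def __post_init__(self) -> None:
        if self.res_a == self.res_b:
            raise ValueError("focal residues must differ on a planted column")
        if self.freq_a < 0 or self.freq_b < 0 or self.freq_a + self.freq_b > 1 + 1e-12:
            raise ValueError("frequencies must be nonnegative and sum to <= 1")

    @property
    def freq_other(self) -> float:
        return 1.0 - self.freq_a - self.freq_b


def gen_msa(
    n_homologs: int,
    length: int,
    diff_columns: Mapping[int, MsaColumnSpec],
    motif_offsets: Mapping[str, int] | None = None,
    seed: int = 0,
    focal_a: str = "focalA",
    focal_b: str = "focalB",
) -> tuple[Alignment, dict]:
    """Gapless MSA of a focal pair plus homologs with planted column truth.

    At each planted column the homologs carry exactly
    ``round(freq * n_homologs)`` copies of each focal residue (an error is
    raised if a frequency is not exactly representable); everywhere else
    every record agrees with the focal pair, so the conservation profile
    retains exactly the planted columns. Motifs (shared by both focal
    sequences, hence outside the profile) are planted at ``motif_offsets``.
    """
    rng = stream_rng(seed, "msa")
    motif_offsets = dict(motif_offsets or {})
    backbone = list(_random_residues(rng, length))
    occupied: set[int] = set()
    for name, start in motif_offsets.items():
        pattern = BUILTIN_MOTIFS[name].pattern
        span = range(start - 1, start - 1 + len(pattern))
        if span.stop > length or (occupied & set(span)):
            raise ValueError(f"motif {name} at {start} does not fit")
        occupied.update(span)
        for i, c in zip(span, _concretize(pattern)):
            backbone[i] = c

    counts: dict[int, tuple[int, int]] = {}
    for col, spec in diff_columns.items():
        if not 1 <= col <= length:
            raise ValueError(f"column {col} outside 1..{length}")
        if (col - 1) in occupied:
            raise ValueError(f"column {col} collides with a planted motif")
        na = spec.freq_a * n_homologs
        nb = spec.freq_b * n_homologs
        if abs(na - round(na)) > 1e-9 or abs(nb - round(nb)) > 1e-9:
            raise ValueError(
                f"column {col}: frequencies not exact for n={n_homologs}"
            )
        counts[col] = (round(na), round(nb))

    row_a = backbone.copy()
    row_b = backbone.copy()
    homologs = [backbone.copy() for _ in range(n_homologs)]
    for col, spec in diff_columns.items():
        row_a[col - 1] = spec.res_a
        row_b[col - 1] = spec.res_b
        na, nb = counts[col]
        other = next(
            c for c in AA_LETTERS if c not in (spec.res_a, spec.res_b)
        )
        fill = [spec.res_a] * na + [spec.res_b] * nb + [other] * (n_homologs - na - nb)
        rng.shuffle(fill)
        for hom, c in zip(homologs, fill):
            hom[col - 1] = c

    records = [
        SequenceRecord(focal_a, "".join(row_a)),
        SequenceRecord(focal_b, "".join(row_b)),
    ] + [
        SequenceRecord(f"hom{i+1:03d}", "".join(h)) for i, h in enumerate(homologs)
    ]
    truth = {
        "diff_columns": {
            col: {
                "res_a": spec.res_a,
                "res_b": spec.res_b,
                "pct_a": 100.0 * counts[col][0] / n_homologs,
                "pct_b": 100.0 * counts[col][1] / n_homologs,
            }
            for col, spec in diff_columns.items()
        },
        "motif_offsets": motif_offsets,
        "n_homologs": n_homologs,
    }
    return Alignment(records), truth


# default ligand architecture used by gen_hydrogenase
_LIGAND_LAYOUT: dict[str, list[int]] = {
    "FS2": [40, 45, 50, 55],
    "FS4C": [70, 75, 80, 85],
    "FS4B": [100, 105, 110, 115],
    "FS4A": [130, 135, 140, 145],
}
_MOTIF_LAYOUT = {"L1": 200, "L2": 250, "L3": 300}


def gen_hydrogenase(
    group: str, seed: int = 0, length: int = 400, seq_id: str | None = None
) -> tuple[SequenceRecord, SequenceRecord, dict[str, list[int]], Alignment, dict]:
    """Synthetic classified sequence plus reference and annotation.

    Returns (sequence, reference, ligand positions, pairwise alignment,
    truth). Groups: "A2" (full inventory), "A3" (FS2+FS4C ablated),
    "B2" (P1 motif with the extra cysteine).
    """
    if group not in {"A2", "A3", "B2"}:
        raise ValueError(f"unknown group {group!r}")
    rng = stream_rng(seed, f"hydrogenase-{group}")
    # cysteine-free background so planted C positions are the only ligands
    background = _random_residues(rng, length, AA_LETTERS.replace("C", ""))
    ref = list(background)
    for positions in _LIGAND_LAYOUT.values():
        for pos in positions:
            ref[pos - 1] = "C"
    for name, start in _MOTIF_LAYOUT.items():
        for i, c in zip(range(start - 1, start - 1 + len(BUILTIN_MOTIFS[name].pattern)),
                        _concretize(BUILTIN_MOTIFS[name].pattern)):
            ref[i] = c
    reference = SequenceRecord("reference", "".join(ref))

    seq = ref.copy()
    if group == "A3":
        for cluster in ("FS2", "FS4C"):
            for pos in _LIGAND_LAYOUT[cluster]:
                seq[pos - 1] = "A"
    if group == "B2":
        # replace the L1 block with the P1B variant (one residue longer);
        # overwrite in place over len(P1B) characters
        p1b = _concretize(BUILTIN_MOTIFS["P1B"].pattern)
        start = _MOTIF_LAYOUT["L1"] - 1
        seq[start : start + len(p1b)] = list(p1b)
        seq = seq[:length]
    record = SequenceRecord(seq_id or f"synth_{group}", "".join(seq))
    pair = Alignment(
        [
            SequenceRecord(reference.id, reference.residues),
            SequenceRecord(record.id, record.residues),
        ]
    )
    truth = {"group": group, "ligands": dict(_LIGAND_LAYOUT), "motifs": dict(_MOTIF_LAYOUT)}
    return record, reference, {k: list(v) for k, v in _LIGAND_LAYOUT.items()}, pair, truth


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedResidue:
    number: int
    name: str  # 3-letter residue name
    cluster: str  # target cluster label
    distance: float  # exact min heavy-atom distance to that cluster, Å


def gen_structure(
    residues: Sequence[PlantedResidue],
    cluster_sizes: Mapping[str, int],
    seed: int = 0,
    chain: str = "A",
) -> tuple[StructureModel, dict]:
    """Toy structure with residues at exact distances from planted clusters.

    Cluster groups are placed on widely separated centers (200 Å apart) so
    each residue's global minimum distance is to its own target cluster.
    Every planted residue is a single CA pseudo-atom positioned along +x
    from the +x-most atom of its cluster, making the planted distance the
    exact minimum. Coordinates are kept on a 0.001 Å grid so the PDB
    round-trip is lossless.
    """
    labels = sorted(cluster_sizes)
    if not labels:
        raise ValueError("need at least one cluster group")
    rng = stream_rng(seed, "structure")
    centers = {label: np.array([0.0, 0.0, 200.0 * i]) for i, label in enumerate(labels)}
    groups: dict[str, list[Atom]] = {}
    for label in labels:
        n_atoms = cluster_sizes[label]
        if n_atoms < 1:
            raise ValueError(f"cluster {label!r} must have at least one atom")
        atoms = []
        for j in range(n_atoms):
            # distinct x-offsets avoid argmax ties; all within 1 Å of center
            offset = np.round(
                np.array([0.2 * j, 0.3 * (j % 2), 0.1 * j]) - 0.1 * n_atoms, 3
            )
            x, y, z = centers[label] + offset
            atoms.append(Atom(f"FE{j+1}", "FE", float(x), float(y), float(z)))
        groups[label] = atoms

    placed: list[Residue] = []
    truth_rows = []
    for spec in residues:
        if spec.cluster not in groups:
            raise ValueError(f"unknown cluster {spec.cluster!r}")
        if spec.distance < 0:
            raise ValueError("distance must be nonnegative")
        anchor = max(groups[spec.cluster], key=lambda a: a.x)
        x = round(anchor.x + spec.distance, 3)
        if abs(x - (anchor.x + spec.distance)) > 5e-4:
            raise ValueError(
                f"distance {spec.distance} not representable on the 0.001 Å grid"
            )
        atom = Atom("CA", "C", x, anchor.y, anchor.z)
        placed.append(Residue(chain, spec.number, spec.name, [atom]))
        truth_rows.append(
            {"number": spec.number, "cluster": spec.cluster, "distance": spec.distance}
        )
    model = StructureModel(placed, groups)
    return model, {"residues": truth_rows, "clusters": {l: cluster_sizes[l] for l in labels}}


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def gen_ct(
    true_ratios: Mapping[str, float],
    efficiencies: Mapping[str, float],
    controls: Sequence[str] = ("ctrl",),
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    base_ct: float = 20.0,
    seed: int = 0,
) -> tuple[CtTable, dict]:
    """Ct table whose efficiency-corrected ratios equal `true_ratios`.

    Controls are constructed with zero condition shift; each target's
    condition shift is ln(ratio)/ln(1+E). Gaussian noise with `noise_sd`
    cycles is added per replicate.
    """
    rng = stream_rng(seed, "qpcr")
    rows = []
    genes = list(true_ratios) + [c for c in controls if c not in true_ratios]
    for gene in genes:
        eff = efficiencies.get(gene)
        if eff is None:
            raise ValueError(f"no efficiency for gene {gene!r}")
        ratio = true_ratios.get(gene, 1.0)
        delta = math.log(ratio) / math.log(1.0 + eff)
        for cond, ct in (("Nplus", base_ct + delta), ("Nminus", base_ct)):
            for rep in range(1, n_replicates + 1):
                noisy = ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append(
                    {"gene": gene, "condition": cond, "replicate": rep, "ct": noisy}
                )
    table = CtTable(pd.DataFrame(rows), dict(efficiencies))
    return table, {"true_ratios": dict(true_ratios), "controls": list(controls)}


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


def gen_bundle(seed: int = 0) -> dict:
    """One coherent synthetic data set exercising every pipeline stage."""
    diff_columns = {
        20: MsaColumnSpec("M", "T", 0.6, 0.3),
        35: MsaColumnSpec("A", "S", 0.5, 0.5),
        60: MsaColumnSpec("I", "T", 0.8, 0.1),
        90: MsaColumnSpec("K", "R", 0.2, 0.7),
        120: MsaColumnSpec("F", "Y", 0.4, 0.4),
        150: MsaColumnSpec("V", "L", 0.1, 0.1),
    }
    msa, msa_truth = gen_msa(
        n_homologs=10,
        length=200,
        diff_columns=diff_columns,
        motif_offsets={"L1": 5, "L2": 170, "L3": 185},
        seed=seed,
    )
    # structure: residue numbers equal alignment columns (gapless MSA)
    planted = [
        PlantedResidue(20, "MET", "H2Fe", 3.0),
        PlantedResidue(35, "ALA", "FS4A", 4.99),
        PlantedResidue(60, "ILE", "FS4B", 5.01),
        PlantedResidue(90, "LYS", "FS4B", 4.2),
        PlantedResidue(120, "PHE", "FS2", 12.0),
        PlantedResidue(150, "VAL", "H2Fe", 2.5),
    ]
    structure, struct_truth = gen_structure(
        planted, {"H2Fe": 2, "FS4A": 4, "FS4B": 4, "FS2": 4}, seed=seed
    )
    tree = gen_tree(10, seed=seed)
    for tip in tree.tips:  # tree tips are the homolog rows of the MSA
        tip.label = f"hom{int(tip.label[1:]):03d}"
    ct, ct_truth = gen_ct(
        {"geneX": 7.5, "geneY": 1 / 2.9},
        {"geneX": 0.92, "geneY": 0.97, "ctrl": 0.98},
        controls=("ctrl",),
        noise_sd=0.0,
        seed=seed,
    )
    return {
        "msa": msa,
        "msa_truth": msa_truth,
        "structure": structure,
        "structure_truth": struct_truth,
        "within_cutoff_truth": sorted(
            r["number"] for r in struct_truth["residues"] if r["distance"] <= 5.0
        ),
        "tree": tree,
        "ct": ct,
        "ct_truth": ct_truth,
        "seed": seed,
    }
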