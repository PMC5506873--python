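"""Readers and writers for the standard formats the pipeline touches.

Conventions enforced here and relied on everywhere else:

* alignment columns and structure residue numbers are 1-based, intervals
  closed;
* the gap character is ``'-'`` ('.' is normalized to '-' on read);
* newick branch lengths are mandatory (no silent defaults);
* only ``ATOM``/``HETATM``/``TER`` records of the PDB v3.3 fixed-width
  dialect are honored, and insertion codes are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

GAP = "-"

__all__ = [
    "GAP",
    "SequenceRecord",
    "Alignment",
    "Tree",
    "TreeNode",
    "Atom",
    "Residue",
    "StructureModel",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_newick",
    "write_newick",
    "read_structure",
    "write_structure",
]


# ---------------------------------------------------------------------------
# sequences and alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence (possibly gapped when part of an alignment)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.residues != self.residues.upper():
            raise ValueError(f"residues of {self.id!r} must be uppercase")

    @property
    def length(self) -> int:
        """Number of residue characters (gaps excluded)."""
        return len(self.residues) - self.residues.count(GAP)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """An ordered collection of equal-length gapped records.

    Maintains, per record, a bijective map between 1-based ungapped residue
    indices and 1-based non-gap column indices.
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise ValueError("alignment needs at least one record")
        n = len(records[0].residues)
        for rec in records:
            if len(rec.residues) != n:
                raise ValueError(
                    f"record {rec.id!r} has length {len(rec.residues)}, "
                    f"expected {n}: ragged alignment"
                )
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate record id {dup!r} in alignment")
        self.records = records
        self._index = {r.id: r for r in records}
        # residue index i (1-based) of record -> column (1-based)
        self._res_cols: dict[str, np.ndarray] = {}
        for rec in records:
            cols = np.flatnonzero(np.frombuffer(rec.residues.encode(), dtype="S1") != GAP.encode())
            self._res_cols[rec.id] = cols + 1

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        return self._index[rec_id]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def res_to_col(self, rec_id: str, residue_index: int) -> int:
        """Column (1-based) holding the given 1-based ungapped residue."""
        cols = self._res_cols[rec_id]
        if not 1 <= residue_index <= len(cols):
            raise IndexError(
                f"residue index {residue_index} out of range for {rec_id!r}"
            )
        return int(cols[residue_index - 1])

    def col_to_res(self, rec_id: str, column: int) -> int | None:
        """1-based ungapped residue index at a column, or None on a gap."""
        if not 1 <= column <= self.n_columns:
            raise IndexError(f"column {column} outside 1..{self.n_columns}")
        rec = self._index[rec_id]
        if rec.residues[column - 1] == GAP:
            return None
        return column - rec.residues[:column].count(GAP)

    def column(self, column: int) -> str:
        """The characters of one 1-based column, in record order."""
        if not 1 <= column <= self.n_columns:
            raise IndexError(f"column {column} outside 1..{self.n_columns}")
        return "".join(r.residues[column - 1] for r in self.records)

    def gap_only_columns(self) -> list[int]:
        return [
            c
            for c in range(1, self.n_columns + 1)
            if set(self.column(c)) == {GAP}
        ]

    def slice_columns(self, start: int, end: int) -> "Alignment":
        """Sub-alignment over closed 1-based column interval [start, end]."""
        if not (1 <= start <= end <= self.n_columns):
            raise ValueError(f"bad column interval [{start}, {end}]")
        return Alignment(
            [
                SequenceRecord(r.id, r.residues[start - 1 : end], r.description)
                for r in self.records
            ]
        )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records, uppercasing and normalizing gaps."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).replace(".", GAP)
        if seq != seq.upper():
            warnings.warn(f"sequence {rec.id!r}: lowercase residues uppercased")
            seq = seq.upper()
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(SequenceRecord(rec.id, seq, desc))
    if not records:
        warnings.warn(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


def read_alignment(path: str | Path) -> Alignment:
    records = read_fasta(path)
    aln = Alignment(records)
    if aln.gap_only_columns():
        warnings.warn(
            f"{path}: gap-only columns at {aln.gap_only_columns()[:10]}"
        )
    return aln


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    label: str | None
    length: float | None  # edge to parent; None only at the root
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class Tree:
    """A phylogenetic tree with mandatory finite nonnegative branch lengths."""

    def __init__(self, root: TreeNode, rooted: bool | None = None):
        self.root = root
        for node in root.preorder():
            if node is root:
                continue
            if node.length is None:
                raise ValueError(
                    f"edge above {node.label or 'internal node'} has no "
                    "branch length; lengths are required"
                )
            if not np.isfinite(node.length) or node.length < 0:
                raise ValueError(
                    f"edge above {node.label or 'internal node'} has invalid "
                    f"length {node.length}"
                )
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dup = next(l for l in labels if labels.count(l) > 1)
            raise ValueError(f"duplicate tip label {dup!r}")
        # a basal polytomy marks an unrooted tree unless stated otherwise
        self.rooted = rooted if rooted is not None else len(root.children) <= 2

    @property
    def tips(self) -> list[TreeNode]:
        return [n for n in self.root.preorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label or "" for n in self.tips]

    @property
    def n_edges(self) -> int:
        return sum(1 for n in self.root.preorder()) - 1

    def tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            acc += node.length or 0.0
            if node.is_leaf:
                depths[node.label or ""] = acc
            for child in node.children:
                walk(child, acc)

        walk(self.root, 0.0)
        return depths

    def prune_to(self, keep: Iterable[str]) -> "Tree":
        """Tree restricted to the tips in `keep`; unary nodes are collapsed."""
        keep = set(keep)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")

        def rebuild(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                return (
                    TreeNode(node.label, node.length) if node.label in keep else None
                )
            kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                merged = (node.length or 0.0) + (child.length or 0.0)
                return TreeNode(
                    child.label, merged if node.length is not None else child.length,
                    child.children,
                )
            return TreeNode(node.label, node.length, kids)

        new_root = rebuild(self.root)
        if new_root is None or new_root.is_leaf:
            raise ValueError("pruning left fewer than 2 tips")
        while len(new_root.children) == 1:
            only = new_root.children[0]
            new_root = TreeNode(only.label, None, only.children)
        return Tree(new_root, rooted=self.rooted)

    def to_newick(self, precision: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")" + (
                    node.label or ""
                )
            if node.length is not None:
                core += f":{node.length:.{precision}f}".rstrip("0").rstrip(".")
                if core.endswith(":"):
                    core += "0"
            return core

        return fmt(self.root) + ";"


def _from_dendropy(dtree: dendropy.Tree, rooted: bool | None = None) -> Tree:
    def convert(dnode: dendropy.Node) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon else (dnode.label or None)
        node = TreeNode(label, dnode.edge.length)
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    root.length = None  # root edge carries no information here
    return Tree(root, rooted=rooted)


def read_newick(path: str | Path, rooted: bool | None = None) -> Tree:
    return parse_newick(Path(path).read_text(), rooted=rooted)


def parse_newick(newick: str, rooted: bool | None = None) -> Tree:
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # normalize dendropy's parse errors
        if "Duplicate taxon labels" in str(exc):
            raise ValueError(f"duplicate tip labels in newick: {exc}") from exc
        raise ValueError(f"malformed newick: {exc}") from exc
    return _from_dendropy(dtree, rooted=rooted)


def write_newick(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

_TWO_LETTER_ELEMENTS = {"FE", "ZN", "MG", "MN", "NI", "CU", "CO", "MO", "SE", "NA", "CL", "CA"}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Residue:
    chain: str
    number: int  # 1-based per the source file
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.heavy_atoms], dtype=float)


@dataclass
class StructureModel:
    residues: list[Residue]
    cluster_groups: dict[str, list[Atom]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, atoms in self.cluster_groups.items():
            if not atoms:
                raise ValueError(f"cluster group {label!r} is empty")
        seen: set[tuple[str, int]] = set()
        for res in self.residues:
            key = (res.chain, res.number)
            if key in seen:
                raise ValueError(
                    f"duplicate residue number {res.number} in chain {res.chain!r}"
                )
            seen.add(key)
            for atom in res.atoms:
                if not np.all(np.isfinite(atom.coord)):
                    raise ValueError(
                        f"non-finite coordinates on atom {atom.name} of "
                        f"{res.chain}/{res.number}"
                    )

    def get_residue(self, chain: str, number: int) -> Residue:
        for res in self.residues:
            if res.chain == chain and res.number == number:
                return res
        raise KeyError(f"no residue {number} in chain {chain!r}")

    def find_residue(self, number: int) -> Residue | None:
        """First residue with this number in any chain, or None."""
        for res in self.residues:
            if res.number == number:
                return res
        return None


def _element_of(name_field: str, element_field: str) -> str:
    element = element_field.strip().upper()
    if element:
        return element
    stripped = "".join(c for c in name_field if c.isalpha()).upper()
    if stripped[:2] in _TWO_LETTER_ELEMENTS:
        return stripped[:2]
    return stripped[:1]


ClusterMap = Mapping[tuple[str, str, int], str]


def read_structure(
    path: str | Path, cluster_map: ClusterMap | None = None
) -> StructureModel:
    """Parse a PDB v3.3 subset (ATOM/HETATM/TER only).

    ``cluster_map`` assigns HETATM records, keyed by
    (residue name, chain, residue number), to named cluster groups;
    unmapped HETATMs are ignored with a warning.
    """
    cluster_map = dict(cluster_map or {})
    residues: dict[tuple[str, int], Residue] = {}
    groups: dict[str, list[Atom]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        record = line[:6].strip()
        if record not in {"ATOM", "HETATM"}:
            continue
        icode = line[26:27]
        if icode.strip():
            raise ValueError(
                f"{path}:{lineno}: insertion code {icode!r} not supported"
            )
        altloc = line[16:17]
        if altloc.strip() not in {"", "A"}:
            continue  # keep the first alternate location only
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        resseq = int(line[22:26])
        x, y, z = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        atom = Atom(name, _element_of(name, line[76:78] if len(line) >= 78 else ""), x, y, z)
        if record == "HETATM":
            key = (resname, chain, resseq)
            if key in cluster_map:
                groups.setdefault(cluster_map[key], []).append(atom)
            else:
                warnings.warn(
                    f"{path}:{lineno}: HETATM {resname} {chain}/{resseq} not in "
                    "cluster map; atom ignored"
                )
            continue
        residues.setdefault((chain, resseq), Residue(chain, resseq, resname)).atoms.append(atom)
    unhit = set(cluster_map.values()) - set(groups)
    if unhit:
        warnings.warn(f"{path}: cluster labels with no atoms: {sorted(unhit)}")
    return StructureModel(list(residues.values()), groups)


def write_structure(
    model: StructureModel,
    path: str | Path,
    cluster_residue_names: Mapping[str, str] | None = None,
) -> None:
    """Write a minimal PDB v3.3 file; cluster groups become HETATM records.

    ``cluster_residue_names`` maps a cluster label to the 3-character residue
    name used in its HETATM records (default: first 3 characters of label).
    """
    cluster_residue_names = dict(cluster_residue_names or {})
    lines: list[str] = []
    serial = 1
    for res in model.residues:
        for atom in res.atoms:
            lines.append(
                f"ATOM  {serial:>5} {atom.name:<4.4}{'':1}{res.name:<3.3} "
                f"{res.chain:1.1}{res.number:>4}    "
                f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {atom.element:>2.2}"
            )
            serial += 1
    hetseq = 900
    for label, atoms in model.cluster_groups.items():
        resname = cluster_residue_names.get(label, label[:3].upper())
        for atom in atoms:
            lines.append(
                f"HETATM{serial:>5} {atom.name:<4.4}{'':1}{resname:<3.3} "
                f"X{hetseq:>4}    "
                f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {atom.element:>2.2}"
            )
            serial += 1
        hetseq += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
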