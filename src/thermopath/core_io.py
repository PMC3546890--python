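"""Domain types and readers/writers shared by every analysis stage.

The unit of analysis is a gapped protein multiple sequence alignment of a
single-copy ortholog group, evaluated on a fixed rooted binary species tree
whose branches are labeled as thermophily-gain (``focal_gain``),
thermophily-loss (``focal_loss``) or mesophilic ``background``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"
MISSING = "X"
VALID_RESIDUES = frozenset(AMINO_ACIDS) | {GAP, MISSING}

BRANCH_LABELS = ("focal_gain", "focal_loss", "background")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class ResidueSet:
    """A non-empty subset of the 20-letter amino-acid alphabet."""

    members: frozenset[str]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError("ResidueSet must be non-empty")
        bad = set(self.members) - set(AMINO_ACIDS)
        if bad:
            raise DataError(f"ResidueSet contains non-amino-acid symbols: {sorted(bad)}")

    def __contains__(self, residue: str) -> bool:
        return residue in self.members

    def complement(self) -> "ResidueSet":
        return ResidueSet(frozenset(AMINO_ACIDS) - self.members, name=f"not-{self.name}")


#: Residue set whose summed frequency tracks optimal growth temperature in
#: prokaryotes: Ile, Val, Tyr, Trp, Arg, Glu, Leu.
IVYWREL = ResidueSet(frozenset("IVYWREL"), name="IVYWREL")


@dataclass
class OrthologAlignment:
    """A gapped protein MSA for one single-copy ortholog group.

    ``sequences`` maps species name -> aligned residue string; the single-copy
    assumption means at most one sequence per species.
    """

    group_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise DataError(f"{self.group_id}: alignment has no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            offender = next(
                name
                for name, s in self.sequences.items()
                if len(s) != len(next(iter(self.sequences.values())))
            )
            raise DataError(
                f"{self.group_id}: ragged alignment (record '{offender}' differs in length)"
            )
        (length,) = lengths
        if length < 1:
            raise DataError(f"{self.group_id}: zero-length alignment")
        for name, seq in self.sequences.items():
            for col, residue in enumerate(seq, start=1):
                if residue not in VALID_RESIDUES:
                    raise DataError(
                        f"{self.group_id}: invalid residue symbol {residue!r} "
                        f"in record '{name}' at column {col}"
                    )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    def column(self, index: int) -> dict[str, str]:
        """Residues of 0-based column ``index`` keyed by species."""
        return {sp: seq[index] for sp, seq in self.sequences.items()}


class TreeNode:
    """Node of a rooted binary tree; leaves carry species names."""

    __slots__ = ("name", "children", "parent", "length")

    def __init__(self, name: str, length: float = 0.0):
        self.name = name
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r})"


@dataclass
class SpeciesInfo:
    phenotype: str  # "thermophile" | "mesophile"
    ogt: float | None = None  # optimal growth temperature, degrees C


class AnnotatedTree:
    """Rooted binary species tree with per-branch lineage labels.

    Branches are identified by (parent_name, child_name); every branch carries
    exactly one label from ``BRANCH_LABELS``. Species metadata records the
    phenotype (thermophile/mesophile) and, when known, the optimal growth
    temperature in degrees Celsius.
    """

    def __init__(
        self,
        root: TreeNode,
        branch_labels: Mapping[tuple[str, str], str],
        species_meta: Mapping[str, SpeciesInfo],
    ):
        self.root = root
        self.nodes: dict[str, TreeNode] = {}
        for node in self.postorder():
            if node.name in self.nodes:
                raise DataError(f"duplicate node name '{node.name}' in tree")
            self.nodes[node.name] = node
        self._check_binary()
        self.branch_labels = dict(branch_labels)
        self.species_meta = dict(species_meta)
        for branch in self.branches():
            if branch not in self.branch_labels:
                logger.warning("branch %s -> %s unlabeled; defaulting to background", *branch)
                self.branch_labels[branch] = "background"
            elif self.branch_labels[branch] not in BRANCH_LABELS:
                raise DataError(
                    f"branch {branch}: unknown label {self.branch_labels[branch]!r}"
                )
        for leaf in self.leaf_names():
            if leaf not in self.species_meta:
                raise DataError(f"species '{leaf}' missing from lineage table")

    def _check_binary(self) -> None:
        for node in self.postorder():
            if node.children and len(node.children) != 2:
                raise DataError(
                    f"polytomy at node '{node.name}': trees must be strictly binary"
                )
        if len(self.root.children) != 2:
            raise DataError("root must have exactly two children")

    # -- traversal -----------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            yield node
            for child in node.children:
                yield from walk(child)

        return walk(self.root)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_names(self) -> list[str]:
        return [n.name for n in self.postorder() if not n.is_leaf]

    def branches(self) -> list[tuple[str, str]]:
        """All (parent, child) branches in preorder; 2n-2 for n leaves."""
        return [
            (node.name, child.name) for node in self.preorder() for child in node.children
        ]

    def branches_with_label(self, label: str) -> list[tuple[str, str]]:
        return [b for b in self.branches() if self.branch_labels[b] == label]

    def label_of(self, branch: tuple[str, str]) -> str:
        return self.branch_labels[branch]

    # -- serialization -------------------------------------------------
    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.name
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.name
            if node.parent is not None:
                return f"{core}:{node.length:.6f}"
            return core

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"AnnotatedTree({len(self.leaves())} leaves)"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> OrthologAlignment:
    """Read a protein FASTA alignment; headers are parsed as species names
    (first whitespace-delimited token)."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        species = record.id.split()[0]
        if species in sequences:
            raise DataError(f"{path.name}: duplicate species '{species}' (single-copy input)")
        sequences[species] = str(record.seq).upper()
    if len(sequences) < 2:
        raise DataError(f"{path.name}: FASTA alignment needs >= 2 records")
    return OrthologAlignment(group_id=path.stem, sequences=sequences)


def write_alignment(alignment: OrthologAlignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for species in alignment.sequences:
            fh.write(f">{species}\n{alignment.sequences[species]}\n")


def _convert_dendropy(tree: dendropy.Tree) -> TreeNode:
    counter = [0]

    def convert(dnode: dendropy.Node) -> TreeNode:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            if not name:
                raise DataError("tree contains an unnamed leaf")
        else:
            name = dnode.label
            if not name:
                counter[0] += 1
                name = f"N{counter[0]}"
        node = TreeNode(str(name), float(dnode.edge.length or 0.0))
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return convert(tree.seed_node)


def read_lineage_table(
    path: str | Path,
) -> tuple[dict[str, SpeciesInfo], dict[tuple[str, str], str]]:
    """Parse the typed-row lineage TSV.

    Rows are either ``species <name> <phenotype> <ogt|NA>`` or
    ``branch <parent_node> <child_node> <label>``.
    """
    species_meta: dict[str, SpeciesInfo] = {}
    branch_labels: dict[tuple[str, str], str] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise DataError(f"{path}: empty lineage table")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            kind = row[0]
            if kind == "species":
                _, name, phenotype, ogt = row[:4]
                if phenotype not in ("thermophile", "mesophile"):
                    raise DataError(f"{path}: unknown phenotype {phenotype!r} for {name}")
                value = None if ogt in ("", "NA", "na") else float(ogt)
                if value is not None and not math.isfinite(value):
                    raise DataError(f"{path}: non-finite OGT for {name}")
                species_meta[name] = SpeciesInfo(phenotype=phenotype, ogt=value)
            elif kind == "branch":
                _, parent, child, label = row[:4]
                branch_labels[(parent, child)] = label
            else:
                raise DataError(f"{path}: unknown record type {kind!r}")
    return species_meta, branch_labels


def read_tree(path: str | Path, lineage_table: str | Path) -> AnnotatedTree:
    """Read a rooted binary newick tree plus its lineage annotation TSV."""
    dtree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    root = _convert_dendropy(dtree)
    species_meta, branch_labels = read_lineage_table(lineage_table)
    return AnnotatedTree(root, branch_labels, species_meta)


def write_lineage_table(tree: AnnotatedTree, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("record_type\ta\tb\tc\n")
        for species in sorted(tree.species_meta):
            info = tree.species_meta[species]
            ogt = "NA" if info.ogt is None else f"{info.ogt:.1f}"
            fh.write(f"species\t{species}\t{info.phenotype}\t{ogt}\n")
        for parent, child in tree.branches():
            fh.write(f"branch\t{parent}\t{child}\t{tree.branch_labels[(parent, child)]}\n")


def write_report(records: Sequence, path: str | Path, row_type: type | None = None) -> None:
    """Write a list of dataclass result rows as a TSV with header.

    All rows must share one type; alignment columns are reported 1-based by
    the row types themselves. ``row_type`` lets an empty list still emit its
    schema header.
    """
    import dataclasses

    path = Path(path)
    if records:
        row_type = type(records[0])
        if not dataclasses.is_dataclass(records[0]):
            raise DataError("write_report expects dataclass rows")
        if any(type(r) is not row_type for r in records):
            raise DataError("write_report: mixed row types")
    if row_type is not None:
        fields = [f.name for f in dataclasses.fields(row_type)]
    else:
        fields = []
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(fields) + "\n")
        for record in records:
            values = []
            for name in fields:
                value = getattr(record, name)
                if isinstance(value, float):
                    values.append(repr(value))
                elif value is None:
                    values.append("NA")
                else:
                    values.append(str(value))
            fh.write("\t".join(values) + "\n")
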