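"""Generalized (Sankoff) parsimony on a fixed rooted binary species tree.

Ancestral states are reconstructed per alignment column by dynamic
programming under a step-cost matrix. For each internal node the exact MPR
set — the set of states the node takes across *all* minimum-cost labelings —
is computed with an up-pass/out-pass, and a substitution event X→Y on a
branch is extracted only when it is unambiguous: every minimum-cost labeling
changes state on that branch, always from X to Y. Two cost presets are
provided: unit steps and the genetic-code minimum-nucleotide-change cost
(one step per nucleotide difference between the closest codons).

Missing data ('-' and 'X') at a leaf is treated as the full state set;
columns where every leaf is missing are skipped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .core_io import AA_INDEX, AMINO_ACIDS, AnnotatedTree, DataError, OrthologAlignment

_BIG = 1.0e9
_TOL = 1e-6
N_AA = 20


@dataclass(frozen=True)
class CostMatrix:
    """20x20 non-negative step costs with zero diagonal."""

    name: str
    costs: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.costs, dtype=float)
        if c.shape != (N_AA, N_AA):
            raise DataError("CostMatrix must be 20x20")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise DataError("CostMatrix entries must be finite and non-negative")
        if np.any(np.diag(c) != 0):
            raise DataError("CostMatrix diagonal must be zero")
        object.__setattr__(self, "costs", c)


def unit_cost_matrix() -> CostMatrix:
    return CostMatrix("unit", np.ones((N_AA, N_AA)) - np.eye(N_AA))


@lru_cache(maxsize=1)
def _genetic_code_costs() -> np.ndarray:
    from Bio.Data.CodonTable import standard_dna_table

    codons_by_aa: dict[str, list[str]] = {a: [] for a in AMINO_ACIDS}
    for codon, aa in standard_dna_table.forward_table.items():
        if aa in codons_by_aa:
            codons_by_aa[aa].append(codon)
    cost = np.zeros((N_AA, N_AA))
    for x in AMINO_ACIDS:
        for y in AMINO_ACIDS:
            if x == y:
                continue
            best = min(
                sum(a != b for a, b in zip(cx, cy))
                for cx in codons_by_aa[x]
                for cy in codons_by_aa[y]
            )
            cost[AA_INDEX[x], AA_INDEX[y]] = best
    return cost


def genetic_code_cost_matrix() -> CostMatrix:
    """Minimum nucleotide changes between any codons of the two residues."""
    return CostMatrix("genetic_code", _genetic_code_costs())


COST_PRESETS = {"unit": unit_cost_matrix, "genetic_code": genetic_code_cost_matrix}


def get_cost_matrix(preset: str | CostMatrix) -> CostMatrix:
    if isinstance(preset, CostMatrix):
        return preset
    try:
        return COST_PRESETS[preset]()
    except KeyError:
        raise DataError(f"unknown cost-matrix preset {preset!r}") from None


@dataclass
class ColumnReconstruction:
    """Parsimony result for one alignment column (0-based ``column``)."""

    column: int
    parsimony_score: float
    node_state_sets: dict[str, frozenset[str]]
    skipped: bool = False


@dataclass(frozen=True)
class SubstitutionEvent:
    """An unambiguous state change on one branch at one column.

    ``column`` is 1-based, matching all external reports.
    """

    protein_id: str
    column: int
    parent_node: str
    child_node: str
    from_aa: str
    to_aa: str


@dataclass
class BranchCountMatrix:
    """20x20 aggregation of unambiguous events for one branch or label set."""

    key: str
    counts: np.ndarray = field(default_factory=lambda: np.zeros((N_AA, N_AA), dtype=np.int64))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_AA, N_AA):
            raise DataError("BranchCountMatrix must be 20x20")
        if np.any(np.diag(self.counts) != 0):
            raise DataError("BranchCountMatrix diagonal must be zero")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def get(self, from_aa: str, to_aa: str) -> int:
        return int(self.counts[AA_INDEX[from_aa], AA_INDEX[to_aa]])

    def __add__(self, other: "BranchCountMatrix") -> "BranchCountMatrix":
        return BranchCountMatrix(self.key, self.counts + other.counts)


# ---------------------------------------------------------------------------
# batched Sankoff engine
# ---------------------------------------------------------------------------

def _leaf_state_matrix(alignment: OrthologAlignment, tree: AnnotatedTree) -> np.ndarray:
    """(n_leaves, n_columns) int8 matrix; -1 encodes missing ('-' or 'X')."""
    leaves = tree.leaf_names()
    aln_species = set(alignment.species)
    if set(leaves) != aln_species:
        raise DataError(
            f"{alignment.group_id}: alignment species do not match tree leaves "
            f"(missing {sorted(set(leaves) - aln_species)}, "
            f"extra {sorted(aln_species - set(leaves))})"
        )
    lut = np.full(128, -1, dtype=np.int8)
    for aa, i in AA_INDEX.items():
        lut[ord(aa)] = i
    out = np.empty((len(leaves), alignment.length), dtype=np.int8)
    for row, sp in enumerate(leaves):
        out[row] = lut[np.frombuffer(alignment.sequences[sp].encode("ascii"), dtype=np.uint8)]
    return out


class _BatchReconstruction:
    """Vectorized Sankoff DP over all columns of one alignment at once."""

    def __init__(self, leaf_states: np.ndarray, tree: AnnotatedTree, costs: CostMatrix):
        self.tree = tree
        self.costs = costs.costs
        leaves = tree.leaf_names()
        n_cols = leaf_states.shape[1]
        self.n_cols = n_cols
        cost = self.costs

        # up-pass: D[node][c, s] = min cost of node's subtree given state s
        D: dict[str, np.ndarray] = {}
        M: dict[str, np.ndarray] = {}  # M[child][c, s_p] = min_t cost[s_p, t] + D[child][c, t]
        leaf_row = {name: i for i, name in enumerate(leaves)}
        for node in tree.postorder():
            if node.is_leaf:
                states = leaf_states[leaf_row[node.name]]
                d = np.full((n_cols, N_AA), _BIG)
                observed = states >= 0
                d[observed] = _BIG
                d[np.arange(n_cols)[observed], states[observed]] = 0.0
                d[~observed] = 0.0
            else:
                d = np.zeros((n_cols, N_AA))
                for child in node.children:
                    d += M[child.name]
            D[node.name] = d
            if node.parent is not None:
                M[node.name] = (d[:, None, :] + cost[None, :, :]).min(axis=2)

        self.scores = D[tree.root.name].min(axis=1)
        self.all_missing = (leaf_states < 0).all(axis=0)

        # out-pass: O[node][c, s] = min cost of everything outside node's
        # subtree (including the branch into node) given node state s
        O: dict[str, np.ndarray] = {tree.root.name: np.zeros((n_cols, N_AA))}
        for node in tree.preorder():
            for child in node.children:
                a = O[node.name].copy()
                for sibling in node.children:
                    if sibling is not child:
                        a += M[sibling.name]
                O[child.name] = (a[:, :, None] + cost[None, :, :]).min(axis=1)

        # MPR membership: state s in node's MPR set iff D+O hits the optimum
        self.mpr: dict[str, np.ndarray] = {}
        for name in D:
            total = D[name] + O[name]
            self.mpr[name] = total <= (self.scores[:, None] + _TOL)

    def column_reconstruction(self, col: int) -> ColumnReconstruction:
        if self.all_missing[col]:
            return ColumnReconstruction(col, 0.0, {}, skipped=True)
        sets = {
            name: frozenset(AMINO_ACIDS[i] for i in np.flatnonzero(self.mpr[name][col]))
            for name in self.tree.internal_names()
        }
        return ColumnReconstruction(col, float(self.scores[col]), sets)

    def events(self, protein_id: str) -> list[SubstitutionEvent]:
        """Unambiguous events: both branch endpoints have singleton MPR sets
        that differ. Columns with all leaves missing are skipped."""
        out: list[SubstitutionEvent] = []
        ok = ~self.all_missing
        single: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, mask in self.mpr.items():
            counts = mask.sum(axis=1)
            single[name] = (counts == 1, mask.argmax(axis=1))
        for parent, child in self.tree.branches():
            ps, pstate = single[parent]
            cs, cstate = single[child]
            hit = ok & ps & cs & (pstate != cstate)
            for col in np.flatnonzero(hit):
                out.append(
                    SubstitutionEvent(
                        protein_id,
                        int(col) + 1,
                        parent,
                        child,
                        AMINO_ACIDS[pstate[col]],
                        AMINO_ACIDS[cstate[col]],
                    )
                )
        return out

    def ancestral_sequences(self) -> dict[str, str]:
        """Per internal node, singleton-MPR states ('X' where ambiguous)."""
        out = {}
        for name in self.tree.internal_names():
            mask = self.mpr[name]
            counts = mask.sum(axis=1)
            arg = mask.argmax(axis=1)
            chars = np.where(
                counts == 1,
                np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)[arg],
                ord("X"),
            ).astype(np.uint8)
            chars[self.all_missing] = ord("X")
            out[name] = chars.tobytes().decode("ascii")
        return out


def reconstruct_alignment(
    alignment: OrthologAlignment,
    tree: AnnotatedTree,
    costs: str | CostMatrix = "unit",
) -> _BatchReconstruction:
    """Run the Sankoff DP on every column of an alignment at once."""
    return _BatchReconstruction(
        _leaf_state_matrix(alignment, tree), tree, get_cost_matrix(costs)
    )


def sankoff_reconstruct(
    leaf_states: dict[str, str],
    tree: AnnotatedTree,
    costs: str | CostMatrix = "unit",
) -> ColumnReconstruction:
    """Reconstruct a single column given per-species residues."""
    missing = {name for name, s in leaf_states.items() if s in ("-", "X")}
    mat = np.array(
        [
            [-1 if name in missing else AA_INDEX[leaf_states[name]]]
            for name in tree.leaf_names()
        ],
        dtype=np.int8,
    )
    return _BatchReconstruction(mat, tree, get_cost_matrix(costs)).column_reconstruction(0)


def unambiguous_events(
    alignment: OrthologAlignment,
    tree: AnnotatedTree,
    costs: str | CostMatrix = "unit",
) -> list[SubstitutionEvent]:
    """Extract every unambiguous per-branch substitution of an alignment."""
    return reconstruct_alignment(alignment, tree, costs).events(alignment.group_id)


def ancestral_sequences(
    alignment: OrthologAlignment,
    tree: AnnotatedTree,
    costs: str | CostMatrix = "unit",
) -> dict[str, str]:
    """Unambiguous ancestral residues per internal node ('X' elsewhere)."""
    return reconstruct_alignment(alignment, tree, costs).ancestral_sequences()


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_mp_labelings(
    leaf_states: dict[str, str],
    tree: AnnotatedTree,
    costs: str | CostMatrix = "unit",
    limit: int = 12,
) -> list[dict[str, str]]:
    """Exhaustively list every internal labeling achieving minimal cost.

    Branch-and-bound search over the full 20-state alphabet per internal
    node; independent of the DP above so it can serve as its oracle. Missing
    leaves contribute, per assignment of their parent, the cheapest state of
    their full state set. Limited to ``limit`` internal nodes.
    """
    costs = get_cost_matrix(costs)
    cost = costs.costs
    internal = [n for n in tree.postorder() if not n.is_leaf]
    if len(internal) > limit:
        raise DataError(
            f"{len(internal)} internal nodes exceed the enumeration limit {limit}; "
            "use sankoff_reconstruct for large trees"
        )
    missing = {name for name, s in leaf_states.items() if s in ("-", "X")}
    if all(leaf.name in missing for leaf in tree.leaves()):
        return []

    order = internal  # postorder: children decided before parents
    index = {node.name: i for i, node in enumerate(order)}

    def edge_cost(node_state: int, child, assignment: list[int]) -> float:
        if child.is_leaf:
            if child.name in missing:
                return 0.0  # full state set: the matching state is free
            return cost[node_state, AA_INDEX[leaf_states[child.name]]]
        return cost[node_state, assignment[index[child.name]]]

    best = [np.inf]
    solutions: list[list[int]] = []
    assignment = [-1] * len(order)

    def recurse(i: int, partial: float) -> None:
        if i == len(order):
            if partial < best[0] - _TOL:
                best[0] = partial
                solutions.clear()
            if partial <= best[0] + _TOL:
                solutions.append(assignment.copy())
            return
        node = order[i]
        increments = []
        for s in range(N_AA):
            inc = sum(edge_cost(s, child, assignment) for child in node.children)
            increments.append((inc, s))
        increments.sort()
        for inc, s in increments:
            if partial + inc > best[0] + _TOL:
                break
            assignment[i] = s
            recurse(i + 1, partial + inc)
        assignment[i] = -1

    recurse(0, 0.0)
    return [
        {order[i].name: AMINO_ACIDS[s] for i, s in enumerate(sol)} for sol in solutions
    ]


def labeling_cost(
    labeling: dict[str, str],
    leaf_states: dict[str, str],
    tree: AnnotatedTree,
    costs: str | CostMatrix = "unit",
) -> float:
    """Total step cost of one complete internal labeling (oracle helper)."""
    cost = get_cost_matrix(costs).costs
    total = 0.0
    for parent, child in tree.branches():
        p = AA_INDEX[labeling[parent]]
        child_node = tree.nodes[child]
        if child_node.is_leaf:
            s = leaf_states[child]
            if s in ("-", "X"):
                continue
            total += cost[p, AA_INDEX[s]]
        else:
            total += cost[p, AA_INDEX[labeling[child]]]
    return total


# ---------------------------------------------------------------------------
# event counting
# ---------------------------------------------------------------------------

def count_events(
    events: list[SubstitutionEvent],
    tree: AnnotatedTree,
    grouping: str = "branch",
) -> dict[str, BranchCountMatrix]:
    """Aggregate events into 20x20 matrices, per branch or per branch label.

    Keys are ``"parent->child"`` for per-branch grouping or the branch label
    for per-label grouping; all groups of the chosen universe are present
    even when empty, so totals always partition the event list.
    """
    if grouping == "branch":
        keys = {b: f"{b[0]}->{b[1]}" for b in tree.branches()}
    elif grouping == "label":
        keys = {b: tree.branch_labels[b] for b in tree.branches()}
    else:
        raise DataError(f"unknown grouping {grouping!r}")
    out = {k: BranchCountMatrix(k) for k in dict.fromkeys(keys.values())}
    for event in events:
        branch = (event.parent_node, event.child_node)
        if branch not in keys:
            raise DataError(f"event references unknown branch {branch}")
        out[keys[branch]].counts[AA_INDEX[event.from_aa], AA_INDEX[event.to_aa]] += 1
    return out
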