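"""Synthetic ortholog alignments evolving on an annotated species tree.

Each alignment column evolves independently as a continuous-time Markov
chain over the 20 amino acids. The baseline process is symmetric (uniform
exchangeability by default), so every directional excess in the output is
attributable to the planted biases: on branches matched by a
:class:`BiasSpec`, the instantaneous rate of one ordered change (e.g. K→R)
is multiplied on the designated "adaptive" columns (and, optionally, at a
weaker multiplier on all columns). Modified rows are renormalized to the
baseline leaving rate, so the bias redistributes substitution direction
without changing the overall rate.

Every realized substitution is logged; replaying the root sequence through
the event log reproduces each leaf exactly, which is the internal
consistency contract tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    AA_INDEX,
    AMINO_ACIDS,
    AnnotatedTree,
    DataError,
    OrthologAlignment,
    SpeciesInfo,
    TreeNode,
    write_alignment,
    write_lineage_table,
)
from .parsimony import BranchCountMatrix, N_AA


@dataclass(frozen=True)
class BiasSpec:
    """A planted directional bias: multiply the rate of ``from_aa``→``to_aa``
    on branches whose label is in ``applies_to``.

    ``multiplier`` acts on adaptive columns, ``background_multiplier`` on all
    other columns; a multiplier of 1 is the null (no planted bias).
    """

    from_aa: str
    to_aa: str
    multiplier: float
    applies_to: tuple[str, ...] = ("focal_gain",)
    background_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.from_aa == self.to_aa:
            raise DataError("BiasSpec requires from_aa != to_aa")
        if self.from_aa not in AA_INDEX or self.to_aa not in AA_INDEX:
            raise DataError("BiasSpec residues must be standard amino acids")
        if self.multiplier < 0 or self.background_multiplier < 0:
            raise DataError("BiasSpec multipliers must be >= 0")


@dataclass
class SimulationConfig:
    """Parameters of one simulation run.

    ``baseline_rate`` is the expected number of substitutions per site per
    unit branch length under the unbiased process.
    """

    tree: AnnotatedTree
    n_proteins: int = 10
    n_columns: int = 200
    baseline_rate: float = 1.0
    exchangeability: np.ndarray | None = None  # symmetric 20x20, zero diagonal
    stationary_frequencies: np.ndarray | None = None
    biases: tuple[BiasSpec, ...] = ()
    adaptive_fraction: float = 0.0
    gap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.adaptive_fraction <= 1.0:
            raise DataError("adaptive_fraction must be in [0, 1]")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise DataError("gap_fraction must be in [0, 1)")
        if self.n_proteins < 1 or self.n_columns < 1:
            raise DataError("n_proteins and n_columns must be >= 1")
        if self.stationary_frequencies is not None:
            pi = np.asarray(self.stationary_frequencies, dtype=float)
            if pi.shape != (N_AA,) or abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
                raise DataError("stationary frequencies must be a 20-vector summing to 1")

    @property
    def pi(self) -> np.ndarray:
        if self.stationary_frequencies is None:
            return np.full(N_AA, 1.0 / N_AA)
        return np.asarray(self.stationary_frequencies, dtype=float)


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the simulator: planted biases, per-column
    adaptive flags, per-node (pre-gap) states, and the complete event log."""

    tree: AnnotatedTree
    config: SimulationConfig
    protein_ids: list[str]
    adaptive: np.ndarray  # (n_proteins, n_columns) bool
    node_states: dict[str, np.ndarray]  # node name -> flat int8 states
    events: dict[tuple[str, str], dict[str, np.ndarray]]  # branch -> {col, from, to}

    @property
    def adaptive_flat(self) -> np.ndarray:
        return self.adaptive.reshape(-1)

    def n_events(self, branch: tuple[str, str] | None = None) -> int:
        if branch is not None:
            return len(self.events[branch]["col"])
        return sum(len(e["col"]) for e in self.events.values())

    def branch_counts(
        self,
        branch: tuple[str, str] | None = None,
        label: str | None = None,
        adaptive_only: bool | None = None,
    ) -> BranchCountMatrix:
        """Aggregate the logged events of one branch (or of all branches
        carrying ``label``) into a 20x20 count matrix."""
        if (branch is None) == (label is None):
            raise DataError("pass exactly one of branch= or label=")
        if branch is not None:
            branches = [branch]
            key = f"{branch[0]}->{branch[1]}"
        else:
            branches = self.tree.branches_with_label(label)
            key = label
        counts = np.zeros(N_AA * N_AA, dtype=np.int64)
        for b in branches:
            log = self.events[b]
            sel = slice(None)
            if adaptive_only is not None:
                mask = self.adaptive_flat[log["col"]] == adaptive_only
                sel = mask
            pair = log["from"][sel].astype(np.int64) * N_AA + log["to"][sel]
            counts += np.bincount(pair, minlength=N_AA * N_AA)
        return BranchCountMatrix(key, counts.reshape(N_AA, N_AA))

    def events_dataframe(self) -> pd.DataFrame:
        """Event log as a tidy table; columns are 1-based within protein."""
        n_cols = self.config.n_columns
        rows = []
        for (parent, child), log in self.events.items():
            if not len(log["col"]):
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "protein_id": [self.protein_ids[c // n_cols] for c in log["col"]],
                        "column": log["col"] % n_cols + 1,
                        "parent_node": parent,
                        "child_node": child,
                        "from_aa": [AMINO_ACIDS[i] for i in log["from"]],
                        "to_aa": [AMINO_ACIDS[i] for i in log["to"]],
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["protein_id", "column", "parent_node", "child_node", "from_aa", "to_aa"]
            )
        return pd.concat(rows, ignore_index=True)

    def substitution_events(self, labels: tuple[str, ...] | None = None):
        """Logged events as :class:`~thermopath.parsimony.SubstitutionEvent`
        objects, optionally restricted to branches with the given labels."""
        from .parsimony import SubstitutionEvent

        n_cols = self.config.n_columns
        out = []
        for (parent, child), log in self.events.items():
            if labels is not None and self.tree.branch_labels[(parent, child)] not in labels:
                continue
            for col, frm, to in zip(log["col"], log["from"], log["to"]):
                out.append(
                    SubstitutionEvent(
                        self.protein_ids[col // n_cols],
                        int(col % n_cols) + 1,
                        parent,
                        child,
                        AMINO_ACIDS[frm],
                        AMINO_ACIDS[to],
                    )
                )
        return out

    def replay_consistent(self) -> bool:
        """Replay the root states through the event log branch by branch and
        check that every node's stored states are reproduced."""
        for parent, child in self.tree.branches():
            states = self.node_states[parent].copy()
            log = self.events[(parent, child)]
            for col, frm, to in zip(log["col"], log["from"], log["to"]):
                if states[col] != frm:
                    return False
                states[col] = to
            if not np.array_equal(states, self.node_states[child]):
                return False
        return True


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def _random_topology(rng: np.random.Generator, leaf_names: list[str]) -> TreeNode:
    """Random rooted binary topology by sequential edge attachment."""
    root = TreeNode("")
    root.add_child(TreeNode(leaf_names[0]))
    root.add_child(TreeNode(leaf_names[1]))
    for name in leaf_names[2:]:
        edges = [
            (node, child)
            for node in _preorder(root)
            for child in node.children
        ]
        parent, child = edges[rng.integers(len(edges))]
        mid = TreeNode("")
        parent.children[parent.children.index(child)] = mid
        mid.parent = parent
        mid.add_child(child)
        mid.add_child(TreeNode(name))
    return root


def _preorder(node: TreeNode):
    yield node
    for child in node.children:
        yield from _preorder(child)


def simulate_tree(
    n_mesophiles: int,
    n_thermophiles: int,
    branch_scale: float,
    seed: int,
    include_loss: bool = False,
) -> AnnotatedTree:
    """Random annotated species tree with a monophyletic thermophile clade.

    Branches into and inside the thermophile clade are labeled
    ``focal_gain``; with ``include_loss`` one thermophile-clade leaf reverts
    to a mesophile phenotype and its pendant branch is labeled
    ``focal_loss``. Everything else is ``background``. Branch lengths are
    gamma-distributed (shape 4) with mean ``branch_scale`` — a resolved
    species tree without near-zero branches. Deterministic given ``seed``.
    """
    if n_mesophiles < 2 or n_thermophiles < 2:
        raise DataError("need at least 2 mesophiles and 2 thermophiles")
    rng = np.random.default_rng(seed)
    meso_names = [f"Meso{i + 1:02d}" for i in range(n_mesophiles)]
    thermo_names = [f"Thermo{i + 1:02d}" for i in range(n_thermophiles)]

    meso_root = _random_topology(rng, meso_names)
    thermo_root = _random_topology(rng, thermo_names)

    # graft the thermophile clade into a random mesophile edge
    edges = [(n, c) for n in _preorder(meso_root) for c in n.children]
    parent, child = edges[rng.integers(len(edges))]
    mid = TreeNode("")
    parent.children[parent.children.index(child)] = mid
    mid.parent = parent
    mid.add_child(child)
    mid.add_child(thermo_root)
    root = meso_root

    # name internal nodes and draw branch lengths in preorder
    counter = 0
    for node in _preorder(root):
        if not node.is_leaf:
            counter += 1
            node.name = f"N{counter}"
    for node in _preorder(root):
        if node.parent is not None:
            node.length = float(rng.gamma(4.0, branch_scale / 4.0))

    thermo_clade = {n.name for n in _preorder(thermo_root)}
    branch_labels: dict[tuple[str, str], str] = {}
    for node in _preorder(root):
        for c in node.children:
            if c.name in thermo_clade:
                branch_labels[(node.name, c.name)] = "focal_gain"
            else:
                branch_labels[(node.name, c.name)] = "background"

    species_meta = {
        name: SpeciesInfo("mesophile", float(rng.uniform(20.0, 35.0)))
        for name in meso_names
    }
    species_meta.update(
        {
            name: SpeciesInfo("thermophile", float(rng.uniform(50.0, 60.0)))
            for name in thermo_names
        }
    )

    if include_loss:
        loss_leaf = thermo_names[int(rng.integers(n_thermophiles))]
        leaf_node = next(n for n in _preorder(root) if n.name == loss_leaf)
        branch_labels[(leaf_node.parent.name, loss_leaf)] = "focal_loss"
        species_meta[loss_leaf] = SpeciesInfo("mesophile", float(rng.uniform(20.0, 35.0)))

    return AnnotatedTree(root, branch_labels, species_meta)


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def _baseline_rate_matrix(cfg: SimulationConfig) -> np.ndarray:
    pi = cfg.pi
    if cfg.exchangeability is None:
        ex = np.ones((N_AA, N_AA))
    else:
        ex = np.asarray(cfg.exchangeability, dtype=float)
        if ex.shape != (N_AA, N_AA) or not np.allclose(ex, ex.T):
            raise DataError("exchangeability must be a symmetric 20x20 matrix")
    q = ex * pi[None, :]
    np.fill_diagonal(q, 0.0)
    mean_rate = float((pi * q.sum(axis=1)).sum())
    if mean_rate <= 0:
        raise DataError("degenerate baseline rate matrix")
    return q * (cfg.baseline_rate / mean_rate)


def _branch_matrix(base: np.ndarray, label: str, biases, adaptive: bool) -> np.ndarray:
    q = base.copy()
    for spec in biases:
        if label not in spec.applies_to:
            continue
        mult = spec.multiplier if adaptive else spec.background_multiplier
        if mult == 1.0:
            continue
        row = AA_INDEX[spec.from_aa]
        col = AA_INDEX[spec.to_aa]
        orig = q[row].sum()
        q[row, col] *= mult
        new = q[row].sum()
        if not np.isfinite(new) or new <= 0:
            raise DataError(
                f"bias multiplier {mult} for {spec.from_aa}->{spec.to_aa} "
                "leaves the rate matrix row unnormalizable"
            )
        q[row] *= orig / new  # keep the total leaving rate at baseline
    return q


def _jump_chain(
    rng: np.random.Generator,
    states: np.ndarray,
    idx: np.ndarray,
    n_jumps: np.ndarray,
    cum_p: np.ndarray,
    log: list,
) -> None:
    """Advance columns ``idx`` through their Poisson numbers of jumps."""
    max_jumps = int(n_jumps.max()) if len(n_jumps) else 0
    for r in range(max_jumps):
        active = n_jumps > r
        if not active.any():
            break
        sub = idx[active]
        cur = states[sub]
        new = np.empty(len(sub), dtype=np.int8)
        for s in np.unique(cur):
            mask = cur == s
            u = rng.random(int(mask.sum()))
            new[mask] = np.searchsorted(cum_p[s], u, side="right").astype(np.int8)
        log.append((sub, cur.copy(), new))
        states[sub] = new


def _gillespie(
    rng: np.random.Generator,
    states: np.ndarray,
    idx: np.ndarray,
    q: np.ndarray,
    t: float,
    log: list,
) -> None:
    """Per-column exact simulation for rate matrices with unequal row sums."""
    rates = q.sum(axis=1)
    cum = np.cumsum(q, axis=1)
    cum /= rates[:, None]
    cum[:, -1] = 1.0
    for i in idx:
        s = int(states[i])
        elapsed = 0.0
        while True:
            elapsed += rng.exponential(1.0 / rates[s])
            if elapsed > t:
                break
            nxt = int(np.searchsorted(cum[s], rng.random(), side="right"))
            log.append((np.array([i]), np.array([s], dtype=np.int8), np.array([nxt], dtype=np.int8)))
            states[i] = nxt
            s = nxt
        states[i] = s


def simulate_alignments(
    cfg: SimulationConfig,
) -> tuple[list[OrthologAlignment], SyntheticTruth]:
    """Evolve ``n_proteins`` alignments of ``n_columns`` each on the tree.

    Returns the (possibly gap-injected) leaf alignments plus the full ground
    truth. Deterministic given ``cfg.seed``.
    """
    tree = cfg.tree
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_proteins * cfg.n_columns
    protein_ids = [f"OG{i + 1:04d}" for i in range(cfg.n_proteins)]

    # adaptive columns: a fixed fraction per protein
    adaptive = np.zeros((cfg.n_proteins, cfg.n_columns), dtype=bool)
    k = int(round(cfg.adaptive_fraction * cfg.n_columns))
    for p in range(cfg.n_proteins):
        if k:
            adaptive[p, rng.choice(cfg.n_columns, size=k, replace=False)] = True
    adaptive_flat = adaptive.reshape(-1)

    base = _baseline_rate_matrix(cfg)
    node_states: dict[str, np.ndarray] = {
        tree.root.name: rng.choice(N_AA, size=n_total, p=cfg.pi).astype(np.int8)
    }
    events: dict[tuple[str, str], dict[str, np.ndarray]] = {}

    for parent_node in tree.preorder():
        for child in parent_node.children:
            branch = (parent_node.name, child.name)
            label = tree.branch_labels[branch]
            t = child.length
            states = node_states[parent_node.name].copy()
            log: list = []
            for is_adaptive in (True, False):
                idx = np.flatnonzero(adaptive_flat == is_adaptive)
                if not len(idx):
                    continue
                q = _branch_matrix(base, label, cfg.biases, is_adaptive)
                rates = q.sum(axis=1)
                if np.allclose(rates, rates[0], rtol=1e-12, atol=1e-12):
                    lam = float(rates[0])
                    if lam > 0 and t > 0:
                        n_jumps = rng.poisson(lam * t, size=len(idx))
                        cum_p = np.cumsum(q / lam, axis=1)
                        cum_p[:, -1] = 1.0
                        _jump_chain(rng, states, idx, n_jumps, cum_p, log)
                elif t > 0:
                    _gillespie(rng, states, idx, q, t, log)
            if log:
                cols = np.concatenate([c for c, _, _ in log])
                frm = np.concatenate([f for _, f, _ in log])
                to = np.concatenate([n for _, _, n in log])
                # chronological within a column: stable sort by column keeps
                # the round order of the jump chain
                order = np.argsort(cols, kind="stable")
                events[branch] = {"col": cols[order], "from": frm[order], "to": to[order]}
            else:
                events[branch] = {
                    "col": np.empty(0, dtype=np.int64),
                    "from": np.empty(0, dtype=np.int8),
                    "to": np.empty(0, dtype=np.int8),
                }
            node_states[child.name] = states

    aa_bytes = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    leaf_names = tree.leaf_names()
    gap_mask = None
    if cfg.gap_fraction > 0:
        gap_mask = rng.random((len(leaf_names), n_total)) < cfg.gap_fraction

    alignments = []
    for p, pid in enumerate(protein_ids):
        lo, hi = p * cfg.n_columns, (p + 1) * cfg.n_columns
        sequences = {}
        for row, leaf in enumerate(leaf_names):
            chars = aa_bytes[node_states[leaf][lo:hi]].copy()
            if gap_mask is not None:
                chars[gap_mask[row, lo:hi]] = ord("-")
            sequences[leaf] = chars.tobytes().decode("ascii")
        alignments.append(OrthologAlignment(group_id=pid, sequences=sequences))

    truth = SyntheticTruth(
        tree=tree,
        config=cfg,
        protein_ids=protein_ids,
        adaptive=adaptive,
        node_states=node_states,
        events=events,
    )
    return alignments, truth


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def write_fixtures(
    alignments: list[OrthologAlignment],
    truth: SyntheticTruth,
    tree: AnnotatedTree,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the simulation as the exact on-disk formats the readers consume:
    one FASTA per protein, the newick tree, the lineage TSV, and two truth
    TSVs (adaptive positions and the branch event log)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aln_dir = out_dir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    for aln in alignments:
        path = aln_dir / f"{aln.group_id}.fasta"
        write_alignment(aln, path)
        paths[aln.group_id] = path

    tree_path = out_dir / "tree.nwk"
    tree_path.write_text(tree.newick() + "\n", encoding="utf-8")
    paths["tree"] = tree_path

    lineage_path = out_dir / "lineage.tsv"
    write_lineage_table(tree, lineage_path)
    paths["lineage"] = lineage_path

    pos_path = out_dir / "truth_positions.tsv"
    with open(pos_path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tcolumn\tadaptive_flag\n")
        for p, pid in enumerate(truth.protein_ids):
            for c in range(truth.config.n_columns):
                fh.write(f"{pid}\t{c + 1}\t{int(truth.adaptive[p, c])}\n")
    paths["truth_positions"] = pos_path

    events_path = out_dir / "truth_events.tsv"
    truth.events_dataframe().to_csv(events_path, sep="\t", index=False)
    paths["truth_events"] = events_path
    return paths
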