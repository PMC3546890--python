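"""Model/Results interface tying reconstruction, bias testing and scoring.

:class:`SubstitutionBiasModel` is built from data (ortholog alignments plus
an annotated species tree); ``fit()`` runs ancestral reconstruction, counts
unambiguous per-branch substitutions, tests all 190 amino-acid pairs on the
focal branches against background-calibrated ratios, scores the significant
directions, and applies the sign rule to every focal mutation. The returned
:class:`SubstitutionBiasResults` carries the tables, diagnostics, a
``summary()`` and evaluation/plotting helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import parsimony as pars
from . import scoring as scoring_mod
from .core_io import AMINO_ACIDS, AnnotatedTree, DataError, OrthologAlignment, read_alignment, read_tree
from .simulate import SimulationConfig, SyntheticTruth, simulate_alignments


@dataclass
class ModelOptions:
    cost_matrix: str = "unit"
    alpha: float = 0.05
    pseudocount: float = 1.0
    correction: str | None = None
    two_sided_method: str = "min-likelihood"
    score_tail: str = "upper"
    score_log_base: float = 10.0
    adaptive_threshold: float = 1.3
    loss_branch_mode: str = "reversed"
    gating_background: str = "background"  # label pool gating significance
    score_background: str = "whole_tree"  # ratio pool feeding the score S

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class SubstitutionBiasModel:
    """Branch-specific substitution-bias model over ortholog alignments.

    Parameters
    ----------
    alignments
        Single-copy ortholog alignments, one per protein, whose species set
        matches the tree's leaves.
    tree
        Rooted binary species tree with focal/background branch labels.
    options
        Keyword overrides of :class:`ModelOptions` defaults.
    """

    def __init__(
        self,
        alignments: list[OrthologAlignment],
        tree: AnnotatedTree,
        **options,
    ):
        if not alignments:
            raise DataError("model requires at least one alignment")
        self.alignments = alignments
        self.tree = tree
        self.options = ModelOptions(**options)
        self._precomputed_events: list[pars.SubstitutionEvent] | None = None

    @classmethod
    def from_files(
        cls,
        alignment_dir: str | Path,
        tree_path: str | Path,
        lineage_path: str | Path,
        **options,
    ) -> "SubstitutionBiasModel":
        """Build the model from a directory of FASTA alignments, a newick
        tree and a lineage annotation TSV."""
        alignment_dir = Path(alignment_dir)
        paths = sorted(
            p for p in alignment_dir.iterdir()
            if p.suffix in (".fasta", ".fa", ".faa") and p.is_file()
        )
        if not paths:
            raise DataError(f"no FASTA alignments found in {alignment_dir}")
        tree = read_tree(tree_path, lineage_path)
        return cls([read_alignment(p) for p in paths], tree, **options)

    @classmethod
    def from_simulation(
        cls, cfg: SimulationConfig, **options
    ) -> tuple["SubstitutionBiasModel", SyntheticTruth]:
        """Simulate alignments under ``cfg`` and wrap them in a model."""
        alignments, truth = simulate_alignments(cfg)
        return cls(alignments, cfg.tree, **options), truth

    @classmethod
    def from_event_log(
        cls, truth: SyntheticTruth, **options
    ) -> "SubstitutionBiasModel":
        """Build a model whose data is a simulation's logged event stream.

        Skips ancestral reconstruction and feeds the generator's exact
        events to the bias/scoring stages — the configuration used to study
        calibration and recovery of the statistical machinery under known
        ground truth, free of reconstruction loss.
        """
        model = cls.__new__(cls)
        model.alignments = []
        model.tree = truth.tree
        model.options = ModelOptions(**options)
        model._precomputed_events = truth.substitution_events()
        return model

    def fit(self) -> "SubstitutionBiasResults":
        opts = self.options
        n_skipped = 0
        if self._precomputed_events is not None:
            events = list(self._precomputed_events)
        else:
            events = []
            for aln in self.alignments:
                recon = pars.reconstruct_alignment(aln, self.tree, opts.cost_matrix)
                events.extend(recon.events(aln.group_id))
                n_skipped += int(recon.all_missing.sum())

        by_branch = pars.count_events(events, self.tree, grouping="branch")
        by_label = pars.count_events(events, self.tree, grouping="label")
        whole_tree = pars.BranchCountMatrix(
            "whole_tree", sum(m.counts for m in by_branch.values())
        )
        background = by_label.get(
            "background", pars.BranchCountMatrix("background")
        )
        gating_bg = whole_tree if opts.gating_background == "whole_tree" else background
        score_bg = whole_tree if opts.score_background == "whole_tree" else background

        scan_kwargs = dict(
            alpha=opts.alpha,
            pseudocount=opts.pseudocount,
            method=opts.two_sided_method,
            correction=opts.correction,
        )
        label_scans = {
            label: bias_mod.branch_bias_scan(by_label[label], gating_bg, **scan_kwargs)
            for label in ("focal_gain", "focal_loss")
            if label in by_label
        }
        focal_branches = self.tree.branches_with_label("focal_gain") + \
            self.tree.branches_with_label("focal_loss")
        branch_scans = {
            f"{p}->{c}": bias_mod.branch_bias_scan(
                by_branch[f"{p}->{c}"], gating_bg, **scan_kwargs
            )
            for p, c in focal_branches
        }

        gain_scan = label_scans.get("focal_gain", [])
        significant = bias_mod.significant_directions(gain_scan)
        focal_gain_counts = by_label.get("focal_gain", pars.BranchCountMatrix("focal_gain"))
        scores = scoring_mod.score_table(
            significant,
            focal_gain_counts,
            score_bg,
            pseudocount=opts.pseudocount,
            tail=opts.score_tail,
            log_base=opts.score_log_base,
        )

        focal_set = set(focal_branches)
        focal_events = [
            e for e in events if (e.parent_node, e.child_node) in focal_set
        ]
        calls = scoring_mod.score_mutations(
            focal_events,
            significant,
            scores,
            branch_labels=self.tree.branch_labels,
            loss_branch_mode=opts.loss_branch_mode,
        )
        predictions = scoring_mod.predict_adaptive_positions(
            calls, threshold=opts.adaptive_threshold
        )

        return SubstitutionBiasResults(
            model=self,
            events=events,
            n_skipped_columns=n_skipped,
            counts_by_branch=by_branch,
            counts_by_label=by_label,
            whole_tree_counts=whole_tree,
            label_scans=label_scans,
            branch_scans=branch_scans,
            significant=significant,
            pair_scores=scores,
            calls=calls,
            predictions=predictions,
        )


@dataclass
class SubstitutionBiasResults:
    """Fitted estimates: per-branch bias tests, pair scores, mutation calls."""

    model: SubstitutionBiasModel
    events: list[pars.SubstitutionEvent]
    n_skipped_columns: int
    counts_by_branch: dict[str, pars.BranchCountMatrix]
    counts_by_label: dict[str, pars.BranchCountMatrix]
    whole_tree_counts: pars.BranchCountMatrix
    label_scans: dict[str, list[bias_mod.BiasResult]]
    branch_scans: dict[str, list[bias_mod.BiasResult]]
    significant: set[tuple[str, str]]
    pair_scores: dict[tuple[str, str], scoring_mod.PairScore]
    calls: list[scoring_mod.AdaptiveMutationCall]
    predictions: pd.DataFrame

    # -- tables --------------------------------------------------------
    def bias_table(self, which: str = "focal_gain") -> pd.DataFrame:
        """Bias scan as a DataFrame; ``which`` is a label or 'parent->child'."""
        scan = self.label_scans.get(which) or self.branch_scans.get(which)
        if scan is None:
            raise DataError(f"no scan named {which!r}")
        return pd.DataFrame([r.__dict__ for r in scan])

    def pair_score_table(self) -> pd.DataFrame:
        rows = [ps.__dict__ for ps in self.pair_scores.values()]
        columns = ["from_aa", "to_aa", "s", "n_xy", "n_yx", "p_background"]
        if not rows:
            return pd.DataFrame(columns=columns)
        return pd.DataFrame(rows)[columns].sort_values(
            "s", ascending=False, kind="mergesort"
        ).reset_index(drop=True)

    def consistency(self) -> pd.DataFrame:
        rows = bias_mod.consistency_histogram(list(self.branch_scans.values()))
        return pd.DataFrame(
            [r.__dict__ for r in rows],
            columns=["from_aa", "to_aa", "n_branches_biased"],
        )

    def evaluate(self, truth: SyntheticTruth) -> dict[str, float]:
        """Score predictions against a simulation's planted ground truth."""
        return scoring_mod.evaluate_against_truth(self.predictions, truth)

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        opts = self.model.options
        tree = self.model.tree
        lines = [
            "Branch-specific substitution bias analysis",
            "=" * 58,
            f"alignments: {len(self.model.alignments)}    "
            f"species: {len(tree.leaves())}    "
            f"events: {len(self.events)}",
            f"focal branches: gain={len(tree.branches_with_label('focal_gain'))} "
            f"loss={len(tree.branches_with_label('focal_loss'))} "
            f"background={len(tree.branches_with_label('background'))}",
            f"cost matrix: {opts.cost_matrix}    alpha: {opts.alpha}    "
            f"correction: {opts.correction or 'none'}",
            f"two-sided method: {opts.two_sided_method}    "
            f"pseudocount: {opts.pseudocount}",
            "-" * 58,
        ]
        gain = self.label_scans.get("focal_gain", [])
        n_sig = sum(r.significant for r in gain)
        lines.append(
            f"significantly biased pairs on thermophily-gain branches: "
            f"{n_sig} / {len(gain)}"
        )
        table = self.pair_score_table()
        if len(table):
            lines.append("top scored directions (S = -log10 binomial tail p):")
            for row in table.head(8).itertuples(index=False):
                lines.append(
                    f"  {row.from_aa}->{row.to_aa}  S={row.s:6.2f}  "
                    f"n={row.n_xy}:{row.n_yx}  p_bg={row.p_background:.3f}"
                )
        n_adaptive = int((self.predictions["prediction"] == "adaptive").sum()) \
            if len(self.predictions) else 0
        lines.append(
            f"scored mutations: {sum(c.signed_score is not None for c in self.calls)}"
            f" / {len(self.calls)}    predicted adaptive (S >= "
            f"{opts.adaptive_threshold}): {n_adaptive}"
        )
        return "\n".join(lines)

    def plot_bias_matrix(self, which: str = "focal_gain", ax=None):
        """Heat map of directional excess (n_xy - n_yx) with significant
        pairs outlined."""
        import matplotlib.pyplot as plt

        counts = self.counts_by_label.get(which) or self.counts_by_branch.get(which)
        if counts is None:
            raise DataError(f"no counts named {which!r}")
        excess = counts.counts - counts.counts.T
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 6))
        limit = max(1, np.abs(excess).max())
        im = ax.imshow(excess, cmap="RdBu_r", vmin=-limit, vmax=limit)
        ax.set_xticks(range(20), list(AMINO_ACIDS))
        ax.set_yticks(range(20), list(AMINO_ACIDS))
        ax.set_xlabel("to")
        ax.set_ylabel("from")
        ax.set_title(f"directional excess of substitutions ({which})")
        plt.colorbar(im, ax=ax, shrink=0.8)
        return ax

    def plot_score_distribution(self, ax=None):
        """Histogram of signed scores of all scored mutations."""
        import matplotlib.pyplot as plt

        scores = [c.signed_score for c in self.calls if c.signed_score is not None]
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(scores, bins=30)
        ax.set_xlabel("signed score")
        ax.set_ylabel("mutations")
        return ax
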