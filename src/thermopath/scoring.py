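"""Scoring of individual substitutions for their contribution to thermophily.

For each ordered amino-acid pair X→Y with a significant directional bias on
the thermophily branches, a score

    S = -log10 P(K >= n_xy | n = n_xy + n_yx, p = p_background)

is computed from the focal event counts, where ``p_background`` is the
average X→Y share over the whole tree. A reconstructed mutation X→Y then
receives +S when the X→Y bias is significant, -S when the reverse bias Y→X
is significant, and is otherwise not scored. On the thermophily-loss branch
the rule is (by default) applied against the reversed bias directions, so
mutations undoing the adaptation are labeled destabilizing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DataError
from .parsimony import SubstitutionEvent
from .simulate import SyntheticTruth


@dataclass(frozen=True)
class PairScore:
    """Score S for one ordered pair, with the counts and background used."""

    from_aa: str
    to_aa: str
    s: float
    n_xy: int
    n_yx: int
    p_background: float


@dataclass
class AdaptiveMutationCall:
    """One reconstructed mutation with its signed score and call."""

    protein_id: str
    column: int  # 1-based
    branch: str  # "parent->child"
    from_aa: str
    to_aa: str
    signed_score: float | None
    call: str  # adaptive | destabilizing | neutral | unscored


def pair_score(
    n_xy: int,
    n_yx: int,
    p_background: float,
    tail: str = "upper",
    log_base: float = 10.0,
) -> PairScore:
    """Score S = -log of the binomial probability of the directional excess.

    ``tail="upper"`` (default) uses P(K >= n_xy); ``tail="pmf"`` uses the
    point probability. S is non-negative for the upper-tail convention.
    """
    if n_xy + n_yx < 1:
        raise DataError("pair_score requires at least one informative event")
    if not 0.0 < p_background < 1.0:
        raise DataError("p_background must be strictly inside (0, 1); use a "
                        "pseudocounted background ratio")
    n = n_xy + n_yx
    if tail == "upper":
        prob = float(stats.binom.sf(n_xy - 1, n, p_background))
    elif tail == "pmf":
        prob = float(stats.binom.pmf(n_xy, n, p_background))
    else:
        raise DataError(f"unknown tail convention {tail!r}")
    prob = min(prob, 1.0)
    s = -math.log(prob) / math.log(log_base) if prob > 0 else math.inf
    return PairScore("", "", max(0.0, s), n_xy, n_yx, p_background)


def score_table(
    directions: set[tuple[str, str]],
    focal_counts,
    whole_tree_counts,
    pseudocount: float = 1.0,
    tail: str = "upper",
    log_base: float = 10.0,
) -> dict[tuple[str, str], PairScore]:
    """Score every significant ordered direction from focal counts against
    the whole-tree background ratio."""
    from .bias import background_ratio

    out = {}
    for x, y in sorted(directions):
        p_bg = background_ratio(whole_tree_counts, (x, y), pseudocount)
        n_xy = focal_counts.get(x, y)
        n_yx = focal_counts.get(y, x)
        if p_bg is None or n_xy + n_yx == 0:
            continue
        ps = pair_score(n_xy, n_yx, p_bg, tail=tail, log_base=log_base)
        out[(x, y)] = PairScore(x, y, ps.s, n_xy, n_yx, p_bg)
    return out


def score_mutations(
    events: list[SubstitutionEvent],
    significant: set[tuple[str, str]],
    scores: dict[tuple[str, str], PairScore],
    branch_labels: dict[tuple[str, str], str] | None = None,
    loss_branch_mode: str = "reversed",
) -> list[AdaptiveMutationCall]:
    """Apply the sign rule to every event.

    An event X→Y gets +S(X→Y) when that direction is significantly biased,
    -S(Y→X) when the reverse is, otherwise it is unscored. On focal_loss
    branches with ``loss_branch_mode="reversed"``, an event running against
    a significant gain bias (i.e. in the loss direction) is labeled
    ``destabilizing``; with ``loss_branch_mode="same"`` loss branches are
    treated like gain branches.
    """
    if loss_branch_mode not in ("reversed", "same"):
        raise DataError(f"unknown loss_branch_mode {loss_branch_mode!r}")
    calls = []
    for e in events:
        branch = (e.parent_node, e.child_node)
        label = branch_labels.get(branch, "background") if branch_labels else "background"
        key = (e.from_aa, e.to_aa)
        rev = (e.to_aa, e.from_aa)
        if key in significant:
            missing = key not in scores
            signed = None if missing else scores[key].s
            call = "unscored" if missing else "adaptive"
        elif rev in significant:
            missing = rev not in scores
            signed = None if missing else -scores[rev].s
            call = "unscored" if missing else "neutral"
        else:
            signed, call = None, "unscored"
        if label == "focal_loss" and loss_branch_mode == "reversed" and call == "neutral":
            # the mutation undoes a gain-direction bias: responsible for loss
            call = "destabilizing"
        calls.append(
            AdaptiveMutationCall(
                e.protein_id, e.column, f"{e.parent_node}->{e.child_node}",
                e.from_aa, e.to_aa, signed, call,
            )
        )
    return calls


def predict_adaptive_positions(
    calls: list[AdaptiveMutationCall],
    threshold: float = 1.3,
) -> pd.DataFrame:
    """Rank scored positions per protein by signed score (descending).

    Positions at or above ``threshold`` are predicted adaptive; scored
    positions below it are candidate-neutral. The default threshold 1.3
    corresponds to p <= 0.05 on the -log10 scale. Ties break
    deterministically by (protein_id, column).
    """
    rows = [
        {
            "protein_id": c.protein_id,
            "column": c.column,
            "branch": c.branch,
            "from_aa": c.from_aa,
            "to_aa": c.to_aa,
            "signed_score": c.signed_score,
            "call": c.call,
        }
        for c in calls
        if c.signed_score is not None
    ]
    columns = ["protein_id", "column", "branch", "from_aa", "to_aa",
               "signed_score", "call", "prediction"]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    df["prediction"] = np.where(
        df["signed_score"] >= threshold, "adaptive", "candidate_neutral"
    )
    df = df.sort_values(
        by=["protein_id", "signed_score", "column"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df[columns]


def evaluate_against_truth(
    predictions: pd.DataFrame,
    truth: SyntheticTruth,
    planted_pairs: set[frozenset[str]] | None = None,
) -> dict[str, float]:
    """Confusion-matrix metrics of predicted-adaptive positions against the
    generator's planted adaptive flags, plus a Mann-Whitney comparison of
    the signed scores of planted vs non-planted scored positions.

    When ``planted_pairs`` is given (or derivable from the truth's planted
    biases), the planted group is restricted to positions whose scored
    change involves a planted pair — the positions the planted signal can
    actually reach; all non-planted scored positions form the comparison
    group regardless of pair.
    """
    if planted_pairs is None:
        planted_pairs = {
            frozenset((b.from_aa, b.to_aa))
            for b in truth.config.biases
            if b.multiplier != 1.0
        }
    known = set(truth.protein_ids)
    n_columns = truth.config.n_columns
    protein_index = {pid: i for i, pid in enumerate(truth.protein_ids)}

    planted_scores: list[float] = []
    other_scores: list[float] = []
    predicted_positions: set[tuple[str, int]] = set()
    seen_positions: set[tuple[str, int]] = set()
    for row in predictions.itertuples(index=False):
        if row.protein_id not in known or not 1 <= row.column <= n_columns:
            raise DataError(
                f"prediction references unknown position {row.protein_id}:{row.column}"
            )
        is_planted = bool(truth.adaptive[protein_index[row.protein_id], row.column - 1])
        if is_planted:
            if not planted_pairs or frozenset((row.from_aa, row.to_aa)) in planted_pairs:
                planted_scores.append(row.signed_score)
        else:
            other_scores.append(row.signed_score)
        position = (row.protein_id, row.column)
        seen_positions.add(position)
        if row.prediction == "adaptive":
            predicted_positions.add(position)

    planted_all = {
        (pid, c + 1)
        for pid in truth.protein_ids
        for c in np.flatnonzero(truth.adaptive[protein_index[pid]])
    }
    tp = len(predicted_positions & planted_all)
    fp = len(predicted_positions - planted_all)
    fn = len(planted_all - predicted_positions)
    metrics = {
        "n_predicted_adaptive": float(len(predicted_positions)),
        "n_planted": float(len(planted_all)),
        "precision": tp / (tp + fp) if tp + fp else math.nan,
        "recall": tp / (tp + fn) if tp + fn else math.nan,
    }
    if planted_scores and other_scores:
        u, p = stats.mannwhitneyu(planted_scores, other_scores, alternative="greater")
        metrics["rank_u"] = float(u)
        metrics["rank_p"] = float(p)
        metrics["median_score_planted"] = float(np.median(planted_scores))
        metrics["median_score_other"] = float(np.median(other_scores))
    else:
        metrics["rank_u"] = math.nan
        metrics["rank_p"] = math.nan
    return metrics
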