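"""Branch-specific directional substitution-bias tests.

For every unordered pair of distinct amino acids {X, Y} (C(20,2) = 190
pairs), the number of unambiguous X→Y vs Y→X events on a focal branch is
compared with an exact binomial test. In principle X→Y and Y→X are equally
likely; because whole-clade biases exist, the expected ratio is not fixed at
1:1 but calibrated on the event counts of the mesophilic background
branches (with a pseudocount so the expectation stays inside (0, 1)).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import AA_INDEX, AMINO_ACIDS, DataError
from .parsimony import BranchCountMatrix, SubstitutionEvent

#: All 190 unordered pairs of distinct amino acids, lexicographic.
ALL_PAIRS: tuple[tuple[str, str], ...] = tuple(itertools.combinations(AMINO_ACIDS, 2))


@dataclass
class BiasResult:
    """Binomial bias-test outcome for one pair on one focal branch/label."""

    branch: str
    aa_x: str
    aa_y: str
    n_xy: int
    n_yx: int
    p_expected: float
    p_value: float | None
    direction: str  # "X>Y", "Y>X" or "" when undefined
    significant: bool
    insufficient: bool = False


@dataclass
class ConsistencyRow:
    """How many focal branches show a significant bias in one direction."""

    from_aa: str
    to_aa: str
    n_branches_biased: int


def background_ratio(
    background_counts: BranchCountMatrix,
    pair: tuple[str, str],
    pseudocount: float = 1.0,
) -> float | None:
    """Expected probability of the X→Y direction from background branches.

    ``(n_xy + pc) / (n_xy + n_yx + 2 pc)``; None (undefined) when both
    counts and the pseudocount are zero.
    """
    if pseudocount < 0:
        raise DataError("pseudocount must be >= 0")
    x, y = pair
    n_xy = background_counts.get(x, y)
    n_yx = background_counts.get(y, x)
    denom = n_xy + n_yx + 2 * pseudocount
    if denom == 0:
        return None
    return (n_xy + pseudocount) / denom


def _min_likelihood_p(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p: sum pmf over outcomes no more likely than
    the observed one (small relative tolerance for pmf ties)."""
    pmf = stats.binom.pmf(np.arange(n + 1), n, p)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-8)].sum()))


def _doubled_one_sided_p(k: int, n: int, p: float) -> float:
    lower = stats.binom.cdf(k, n, p)
    upper = stats.binom.sf(k - 1, n, p)
    return float(min(1.0, 2 * min(lower, upper)))


def binomial_bias_test(
    n_xy: int,
    n_yx: int,
    p_expected: float,
    method: str = "min-likelihood",
) -> tuple[float | None, str]:
    """Exact two-sided binomial test of ``n_xy`` X→Y events among
    ``n_xy + n_yx`` informative events at expected direction probability
    ``p_expected``.

    Returns (p_value, direction); p_value is None and direction "" for the
    insufficient-data case n_xy + n_yx = 0.
    """
    if n_xy < 0 or n_yx < 0:
        raise DataError("counts must be non-negative")
    if not 0.0 < p_expected < 1.0:
        raise DataError("p_expected must lie strictly inside (0, 1)")
    n = n_xy + n_yx
    if n == 0:
        return None, ""
    if method == "min-likelihood":
        p = _min_likelihood_p(n_xy, n, p_expected)
    elif method == "doubled":
        p = _doubled_one_sided_p(n_xy, n, p_expected)
    else:
        raise DataError(f"unknown two-sided method {method!r}")
    if n_xy == n_yx:
        direction = ""
    else:
        direction = "X>Y" if n_xy > n_yx else "Y>X"
    return p, direction


def _adjust(p_values: list[float | None], correction: str | None) -> list[float | None]:
    if correction is None:
        return p_values
    valid = [(i, p) for i, p in enumerate(p_values) if p is not None]
    adjusted = list(p_values)
    m = len(valid)
    if correction == "bonferroni":
        for i, p in valid:
            adjusted[i] = min(1.0, p * m)
    elif correction == "bh":
        order = sorted(valid, key=lambda t: t[1])
        prev = 1.0
        for rank in range(m, 0, -1):
            i, p = order[rank - 1]
            prev = min(prev, p * m / rank)
            adjusted[i] = prev
    else:
        raise DataError(f"unknown correction {correction!r}")
    return adjusted


def branch_bias_scan(
    focal_counts: BranchCountMatrix,
    background_counts: BranchCountMatrix,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    method: str = "min-likelihood",
    correction: str | None = None,
) -> list[BiasResult]:
    """Test all 190 unordered pairs on one focal branch (or pooled label)
    against background-calibrated expected ratios."""
    results = []
    p_values: list[float | None] = []
    for x, y in ALL_PAIRS:
        n_xy = focal_counts.get(x, y)
        n_yx = focal_counts.get(y, x)
        p_exp = background_ratio(background_counts, (x, y), pseudocount)
        if p_exp is None or n_xy + n_yx == 0:
            results.append(
                BiasResult(focal_counts.key, x, y, n_xy, n_yx,
                           math.nan if p_exp is None else p_exp,
                           None, "", False, insufficient=True)
            )
            p_values.append(None)
            continue
        p, direction = binomial_bias_test(n_xy, n_yx, p_exp, method=method)
        results.append(
            BiasResult(focal_counts.key, x, y, n_xy, n_yx, p_exp, p, direction, False)
        )
        p_values.append(p)
    for result, p_adj in zip(results, _adjust(p_values, correction)):
        if p_adj is not None and result.direction:
            result.significant = p_adj <= alpha
    return results


def significant_directions(results: list[BiasResult]) -> set[tuple[str, str]]:
    """Ordered (from, to) pairs with a significant bias in that direction."""
    out = set()
    for r in results:
        if not r.significant:
            continue
        if r.direction == "X>Y":
            out.add((r.aa_x, r.aa_y))
        elif r.direction == "Y>X":
            out.add((r.aa_y, r.aa_x))
    return out


def consistency_histogram(
    scans: list[list[BiasResult]],
) -> list[ConsistencyRow]:
    """Across per-branch scans, count how many focal branches show each
    significant ordered direction."""
    if not scans:
        raise DataError("consistency histogram needs >= 1 scan")
    counter: dict[tuple[str, str], int] = {}
    for scan in scans:
        for direction in significant_directions(scan):
            counter[direction] = counter.get(direction, 0) + 1
    return [
        ConsistencyRow(f, t, n)
        for (f, t), n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def shared_position_overlap(
    event_lists: dict[str, list[SubstitutionEvent]],
) -> dict[tuple[str, str], tuple[int, int]]:
    """Per ordered pair X→Y: of the alignment positions changed X→Y in ANY
    lineage, how many are changed in ALL lineages.

    Positions are keyed (protein_id, column); all lineages must therefore
    come from the same ortholog alignments. Returns
    {(X, Y): (n_shared, n_total)} for pairs seen in at least one lineage.
    """
    if len(event_lists) < 2:
        raise DataError("overlap requires events from >= 2 lineages")
    universes = [
        {e.protein_id for e in events} for events in event_lists.values() if events
    ]
    if len(universes) >= 2 and not set.intersection(*universes):
        raise DataError(
            "lineage event lists share no protein ids: positions are not on a "
            "common alignment coordinate system"
        )
    per_lineage: list[dict[tuple[str, str], set[tuple[str, int]]]] = []
    for events in event_lists.values():
        positions: dict[tuple[str, str], set[tuple[str, int]]] = {}
        for e in events:
            positions.setdefault((e.from_aa, e.to_aa), set()).add((e.protein_id, e.column))
        per_lineage.append(positions)
    pairs = set().union(*(p.keys() for p in per_lineage))
    out = {}
    for pair in sorted(pairs):
        sets = [p.get(pair, set()) for p in per_lineage]
        union = set().union(*sets)
        shared = set.intersection(*sets) if all(sets) else set()
        out[pair] = (len(shared), len(union))
    return out
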