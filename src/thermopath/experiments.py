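"""Canned simulation experiments: calibration, power and recovery.

These functions define the package's canonical study conditions — a
Sordariomycetes-like tree of 15 mesophiles plus a 5-leaf thermophile clade
(nine focal branches), gamma branch lengths around 0.15 substitutions/site,
a uniform baseline process, and a planted 5x K→R bias on the thermophily
branches at 20% adaptive columns. They consume the generator's logged event
stream, so they measure the statistical machinery (calibration of the
binomial scan, detection power, position recovery) free of reconstruction
loss; ancestral reconstruction is validated separately against exhaustive
enumeration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bias import branch_bias_scan
from .composition import aa_frequencies, pool_profiles, z_test_species_vs_group
from .core_io import IVYWREL
from .model import SubstitutionBiasModel
from .simulate import BiasSpec, SimulationConfig, simulate_alignments, simulate_tree

#: canonical study-tree shape: the clade sizes of the Sordariomycetes data
#: regime the generator emulates (20 species, 9 thermophily branches)
N_MESOPHILES = 15
N_THERMOPHILES = 5
BRANCH_SCALE = 0.15


def null_type_one_error(
    base_seed: int,
    n_replicates: int = 100,
    n_columns: int = 4000,
    baseline_rate: float = 12.0,
    branch_scale: float = 0.25,
    min_events: int = 50,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of the per-branch bias scan under the null process.

    Simulates ``n_replicates`` unbiased runs on small high-rate trees (five
    focal branches each), pools the background event counts over replicates
    (one common null background, so the expected-ratio calibration is
    essentially noise-free), and scans every focal branch. Only pairs with
    at least ``min_events`` informative events enter the measured fraction.
    """
    replicates = []
    bg_total = None
    for i in range(n_replicates):
        seed = base_seed + i
        tree = simulate_tree(4, 3, branch_scale, seed=seed)
        cfg = SimulationConfig(
            tree=tree, n_proteins=1, n_columns=n_columns,
            baseline_rate=baseline_rate, seed=seed,
        )
        _, truth = simulate_alignments(cfg)
        bg = truth.branch_counts(label="background")
        bg_total = bg if bg_total is None else bg_total + bg
        replicates.append((tree, truth))

    n_sig = n_tests = n_scans = 0
    for tree, truth in replicates:
        for branch in tree.branches_with_label("focal_gain"):
            focal = truth.branch_counts(branch=branch)
            n_scans += 1
            for row in branch_bias_scan(focal, bg_total, alpha=alpha):
                if row.p_value is None or row.n_xy + row.n_yx < min_events:
                    continue
                n_tests += 1
                n_sig += row.significant
    return {
        "fraction_significant": n_sig / n_tests if n_tests else float("nan"),
        "n_tests": float(n_tests),
        "n_scans": float(n_scans),
    }


def planted_recovery_config(seed: int, multiplier: float = 5.0) -> SimulationConfig:
    """The canonical planted-bias run: K→R x``multiplier`` on thermophily
    branches, 20% adaptive columns, 200 proteins x 200 columns."""
    tree = simulate_tree(N_MESOPHILES, N_THERMOPHILES, BRANCH_SCALE, seed=seed)
    return SimulationConfig(
        tree=tree,
        n_proteins=200,
        n_columns=200,
        baseline_rate=1.0,
        biases=(BiasSpec("K", "R", multiplier),),
        adaptive_fraction=0.2,
        seed=seed,
    )


def planted_recovery_experiment(
    base_seed: int,
    n_seeds: int = 20,
    multiplier: float = 5.0,
) -> pd.DataFrame:
    """Detection power and position recovery over independent seeds.

    Per seed: simulate the planted-bias run, scan the logged focal events,
    and record whether {K, R} is significant with direction K→R, the score
    S(K→R), and the Mann-Whitney p comparing planted K/R positions with
    non-planted scored positions.
    """
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = planted_recovery_config(seed, multiplier=multiplier)
        _, truth = simulate_alignments(cfg)
        results = SubstitutionBiasModel.from_event_log(truth).fit()
        kr = next(
            r for r in results.label_scans["focal_gain"]
            if r.aa_x == "K" and r.aa_y == "R"
        )
        metrics = results.evaluate(truth)
        score = results.pair_scores.get(("K", "R"))
        rows.append(
            {
                "seed": seed,
                "n_kr": kr.n_xy,
                "n_rk": kr.n_yx,
                "p_value": kr.p_value,
                "detected": bool(kr.significant and kr.direction == "X>Y"),
                "score_kr": score.s if score is not None else np.nan,
                "rank_p": metrics["rank_p"],
                "precision": metrics["precision"],
                "recall": metrics["recall"],
            }
        )
    return pd.DataFrame(rows)


#: ordered pairs feeding IVYWREL members from non-members, used to plant a
#: proteome-wide composition shift on the thermophily branches
IVYWREL_BIAS_PAIRS = (
    ("K", "R"), ("D", "E"), ("A", "V"), ("T", "I"),
    ("S", "L"), ("G", "W"), ("F", "Y"),
)


def ivywrel_enrichment_power(
    base_seed: int,
    n_seeds: int = 50,
    n_proteins: int = 100,
    n_columns: int = 200,
    multiplier: float = 5.0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Power of the composition z-test to flag a simulated IVYWREL-enriched
    thermophile against the pooled mesophilic background (20,000 positions
    per run by default).

    The tested species is the thermophile with the longest path of
    enrichment branches — the clade's most extreme member, which is the
    species such a composition comparison targets.
    """

    def focal_path(tree, leaf: str) -> float:
        node, total = tree.nodes[leaf], 0.0
        while node.parent is not None and \
                tree.branch_labels[(node.parent.name, node.name)] == "focal_gain":
            total += node.length
            node = node.parent
        return total

    n_detected = 0
    for i in range(n_seeds):
        seed = base_seed + i
        tree = simulate_tree(N_MESOPHILES, N_THERMOPHILES, BRANCH_SCALE, seed=seed)
        biases = tuple(
            BiasSpec(x, y, multiplier) for x, y in IVYWREL_BIAS_PAIRS
        )
        cfg = SimulationConfig(
            tree=tree, n_proteins=n_proteins, n_columns=n_columns,
            baseline_rate=1.0, biases=biases, adaptive_fraction=1.0, seed=seed,
        )
        alignments, _ = simulate_alignments(cfg)
        mesophiles = [
            s for s, info in tree.species_meta.items() if info.phenotype == "mesophile"
        ]
        thermophiles = [
            s for s, info in tree.species_meta.items() if info.phenotype == "thermophile"
        ]
        focal_species = max(thermophiles, key=lambda s: focal_path(tree, s))
        profiles = aa_frequencies(alignments, [focal_species] + mesophiles)
        background = pool_profiles([profiles[s] for s in mesophiles])
        tests = z_test_species_vs_group(
            profiles[focal_species], background, residue_sets=[IVYWREL]
        )
        row = next(t for t in tests if t.residue == "IVYWREL")
        if row.p_value < alpha and row.direction > 0:
            n_detected += 1
    return {
        "power": n_detected / n_seeds,
        "n_seeds": float(n_seeds),
        "n_positions": float(n_proteins * n_columns),
    }
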