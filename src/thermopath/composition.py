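"""Amino-acid composition analyses.

Frequencies are counted over aligned positions that contain no gap in any
species; ancestral (reconstructed) entities contribute only columns where
their state is unambiguous. On top of the per-entity profiles sit the
comparisons used to characterize thermophilic proteomes: residue-set sums
(IVYWREL), two-proportion z-tests of one species against a pooled
background, Welch t-tests between groups of entities, correlations of
frequencies with optimal growth temperature, mean/sd-normalized profile
matrices, and GC content at third codon positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    AA_INDEX,
    AMINO_ACIDS,
    DataError,
    GAP,
    MISSING,
    OrthologAlignment,
    ResidueSet,
)

N_AA = 20


@dataclass
class FrequencyProfile:
    """Residue counts and frequencies for one species or ancestral node."""

    entity: str
    counts: np.ndarray  # 20-vector of residue counts

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_AA,):
            raise DataError("FrequencyProfile counts must be a 20-vector")

    @property
    def n_positions(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        n = self.n_positions
        if n == 0:
            return np.zeros(N_AA)
        return self.counts / n

    def frequency(self, residue: str) -> float:
        return float(self.frequencies[AA_INDEX[residue]])


@dataclass
class CompositionTest:
    """Outcome of one composition comparison for one residue or residue set."""

    residue: str  # one-letter code or residue-set name
    statistic: float
    p_value: float
    direction: int  # sign of focal minus background
    skipped: bool = False
    note: str = ""


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_AA_LUT = np.full(128, -1, dtype=np.int16)
for _aa, _i in AA_INDEX.items():
    _AA_LUT[ord(_aa)] = _i


def gap_free_columns(alignment: OrthologAlignment) -> list[int]:
    """0-based indices of columns where no sequence has '-' or 'X'."""
    mat = np.stack([_seq_array(s) for s in alignment.sequences.values()])
    bad = (mat == ord(GAP)) | (mat == ord(MISSING))
    return np.flatnonzero(~bad.any(axis=0)).tolist()


def aa_frequencies(
    alignments: list[OrthologAlignment],
    entities: list[str],
    ancestral: list[dict[str, str]] | None = None,
) -> dict[str, FrequencyProfile]:
    """Pool residue counts per entity over all alignments' gap-free columns.

    ``ancestral`` optionally supplies, per alignment, reconstructed internal
    sequences ('X' marks ambiguous states, which are skipped). Gap-free
    columns are determined from the species alignment alone.
    """
    if ancestral is not None and len(ancestral) != len(alignments):
        raise DataError("need one ancestral-sequence mapping per alignment")
    counts = {e: np.zeros(N_AA, dtype=np.int64) for e in entities}
    for i, aln in enumerate(alignments):
        cols = np.asarray(gap_free_columns(aln), dtype=np.int64)
        for entity in entities:
            if entity in aln.sequences:
                seq = aln.sequences[entity]
            elif ancestral is not None and entity in ancestral[i]:
                seq = ancestral[i][entity]
            else:
                raise DataError(f"entity '{entity}' absent from alignment {aln.group_id}")
            if not len(cols):
                continue
            codes = _AA_LUT[_seq_array(seq)[cols]]
            codes = codes[codes >= 0]  # ambiguous ancestral states skipped
            counts[entity] += np.bincount(codes, minlength=N_AA)
    return {e: FrequencyProfile(e, c) for e, c in counts.items()}


def pool_profiles(profiles: list[FrequencyProfile], name: str = "pooled") -> FrequencyProfile:
    """Sum counts over entities into one background profile."""
    if not profiles:
        raise DataError("cannot pool zero profiles")
    return FrequencyProfile(name, np.sum([p.counts for p in profiles], axis=0))


def residue_set_sum(profile: FrequencyProfile, residue_set: ResidueSet) -> float:
    """Summed frequency of the set's members; in [0, 1]."""
    return float(sum(profile.frequency(r) for r in residue_set.members))


def _two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float] | None:
    """Pooled-variance two-proportion z-test; None when variance is zero."""
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return None
    z = (p1 - p2) / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return z, p


def z_test_species_vs_group(
    focal: FrequencyProfile,
    background: FrequencyProfile,
    residue_sets: list[ResidueSet] = (),
) -> list[CompositionTest]:
    """Two-proportion z-test per residue (and per residue set) of one focal
    entity against a pooled background profile."""
    if focal.n_positions == 0 or background.n_positions == 0:
        raise DataError("z-test requires positive position counts on both sides")
    out = []
    n1, n2 = focal.n_positions, background.n_positions
    items: list[tuple[str, int, int]] = [
        (aa, int(focal.counts[i]), int(background.counts[i]))
        for i, aa in enumerate(AMINO_ACIDS)
    ]
    for rs in residue_sets:
        idx = [AA_INDEX[r] for r in rs.members]
        items.append((rs.name or "".join(sorted(rs.members)),
                      int(focal.counts[idx].sum()), int(background.counts[idx].sum())))
    for name, x1, x2 in items:
        result = _two_proportion_z(x1, n1, x2, n2)
        if result is None:
            out.append(CompositionTest(name, 0.0, 1.0, 0, skipped=True,
                                       note="zero pooled variance"))
            continue
        z, p = result
        out.append(CompositionTest(name, z, p, int(np.sign(x1 / n1 - x2 / n2))))
    return out


def t_test_groups(
    group_a: list[FrequencyProfile],
    group_b: list[FrequencyProfile],
) -> list[CompositionTest]:
    """Welch (unequal-variance) two-sample t-test per residue on per-entity
    frequencies; group A is the focal (e.g. thermophiles + their ancestors)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise DataError("each group needs >= 2 profiles for a t-test")
    fa = np.array([p.frequencies for p in group_a])
    fb = np.array([p.frequencies for p in group_b])
    out = []
    for i, aa in enumerate(AMINO_ACIDS):
        a, b = fa[:, i], fb[:, i]
        diff = float(a.mean() - b.mean())
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            if diff == 0:
                out.append(CompositionTest(aa, 0.0, 1.0, 0, note="zero variance, equal means"))
            else:
                out.append(CompositionTest(aa, math.inf * np.sign(diff), 0.0,
                                           int(np.sign(diff)), note="zero within-group variance"))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out.append(CompositionTest(aa, float(t), float(p), int(np.sign(diff))))
    return out


def ogt_correlation(
    profiles: dict[str, FrequencyProfile],
    ogt: dict[str, float],
    residue_sets: list[ResidueSet] = (),
    method: str = "pearson",
) -> list[CompositionTest]:
    """Correlation of per-species residue frequencies with optimal growth
    temperature (degrees C). ``method`` is ``pearson`` (default) or
    ``spearman``."""
    species = [s for s in profiles if s in ogt and ogt[s] is not None]
    if len(species) < 3:
        raise DataError("OGT correlation requires >= 3 species with OGT values")
    temps = np.array([ogt[s] for s in species], dtype=float)
    freq = np.array([profiles[s].frequencies for s in species])
    corr = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}.get(method)
    if corr is None:
        raise DataError(f"unknown correlation method {method!r}")
    if np.ptp(temps) == 0:
        return [CompositionTest(aa, math.nan, math.nan, 0, skipped=True,
                                note="constant OGT") for aa in AMINO_ACIDS]
    series: list[tuple[str, np.ndarray]] = [(aa, freq[:, i]) for i, aa in enumerate(AMINO_ACIDS)]
    for rs in residue_sets:
        idx = [AA_INDEX[r] for r in rs.members]
        series.append((rs.name or "".join(sorted(rs.members)), freq[:, idx].sum(axis=1)))
    out = []
    for name, values in series:
        if np.ptp(values) == 0:
            out.append(CompositionTest(name, math.nan, math.nan, 0, skipped=True,
                                       note="constant frequency"))
            continue
        r, p = corr(values, temps)
        out.append(CompositionTest(name, float(r), float(p), int(np.sign(r))))
    return out


def normalized_profile_matrix(
    profiles: list[FrequencyProfile],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-residue frequencies normalized to mean 0, sd 1 across entities
    (population sd). Zero-variance residues come back as all-zero columns
    and are listed in the returned flag list."""
    if len(profiles) < 2:
        raise DataError("normalization requires >= 2 entities")
    freq = np.array([p.frequencies for p in profiles])
    mean = freq.mean(axis=0)
    sd = freq.std(axis=0)  # population sd
    zero = sd <= 1e-12  # tolerate rounding fuzz of identical columns
    flagged = [AMINO_ACIDS[i] for i in np.flatnonzero(zero)]
    safe_sd = np.where(zero, 1.0, sd)
    z = (freq - mean) / safe_sd
    z[:, zero] = 0.0
    return (
        pd.DataFrame(z, index=[p.entity for p in profiles], columns=list(AMINO_ACIDS)),
        flagged,
    )


# ---------------------------------------------------------------------------
# GC3
# ---------------------------------------------------------------------------

def gc3_by_residue(
    cds: dict[str, list[tuple[str, str]]],
) -> pd.DataFrame:
    """GC fraction at third codon positions, overall and per encoded residue.

    ``cds`` maps species -> list of (in-frame CDS, protein sequence) pairs.
    Records with internal stop codons are skipped with a warning; codons
    whose translation disagrees with the protein are flagged and excluded.
    Rows: species; columns: ``overall`` plus each amino acid (NaN when the
    species has no codon for it).
    """
    import logging

    from Bio.Seq import Seq

    logger = logging.getLogger(__name__)
    rows = {}
    for species, records in cds.items():
        gc3 = {aa: [0, 0] for aa in AMINO_ACIDS}  # aa -> [gc count, total]
        overall = [0, 0]
        for cds_seq, protein in records:
            cds_seq = cds_seq.upper()
            if len(cds_seq) % 3 != 0:
                raise DataError(f"{species}: CDS length not divisible by 3")
            translated = str(Seq(cds_seq).translate())
            if "*" in translated.rstrip("*"):
                logger.warning("%s: internal stop codon, record skipped", species)
                continue
            translated = translated.rstrip("*")
            if len(translated) > len(protein.replace("-", "")):
                logger.warning("%s: translation longer than protein, record skipped", species)
                continue
            ungapped = protein.replace("-", "")
            for i, aa in enumerate(translated):
                codon = cds_seq[3 * i : 3 * i + 3]
                if i < len(ungapped) and ungapped[i] != aa:
                    continue  # translation mismatch at this codon, flagged out
                if aa not in AA_INDEX:
                    continue
                third = codon[2]
                is_gc = int(third in "GC")
                gc3[aa][0] += is_gc
                gc3[aa][1] += 1
                overall[0] += is_gc
                overall[1] += 1
        row = {"overall": overall[0] / overall[1] if overall[1] else math.nan}
        for aa in AMINO_ACIDS:
            got, tot = gc3[aa]
            row[aa] = got / tot if tot else math.nan
        rows[species] = row
    return pd.DataFrame.from_dict(rows, orient="index")
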