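"""Evidence suites for cDNA-mediated intron loss and for intron gain.

The cDNA-loss model predicts that lost introns were short, sat near the
3' ends of highly expressed genes, and vanished precisely, often in adjacent
runs.  Intron gains by double-strand-break repair predict short direct
repeats (microhomology) straddling the new intron's boundaries, canonical
GT..AG ends and a polypyrimidine tract.  This module computes the individual
statistics behind those contrasts: representative lengths via the closest
retaining relative, relative 3' distances, gene-class co-occurrence tests,
nonparametric group comparisons with Benjamini-Hochberg correction,
microhomology scans, and splice-signal checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .phylo import TreeIndex

PYRIMIDINES = frozenset("CT")
VALID_NT = frozenset("ACGTN")


def representative_length(
    lengths_by_species: Mapping[str, int | float | None],
    target_species: str,
    tree: TreeIndex,
) -> float | None:
    """Length of the orthologous intron in the closest retaining relative.

    ``lengths_by_species`` maps species to the intron length where the intron
    is present (None/missing where absent).  Relatives at exactly the minimal
    patristic distance are averaged; None when nobody retains the intron.
    """
    if target_species not in tree.index_of:
        raise ValueError(f"{target_species} is not in the tree")
    target = tree.index_of[target_species]
    candidates: list[tuple[float, float]] = []
    for sp, length in lengths_by_species.items():
        if length is None or sp == target_species:
            continue
        if sp not in tree.index_of:
            raise ValueError(f"{sp} is not in the tree")
        candidates.append((tree.patristic_distance(target, tree.index_of[sp]), float(length)))
    if not candidates:
        return None
    dmin = min(d for d, _ in candidates)
    closest = [length for d, length in candidates if abs(d - dmin) < 1e-9]
    return float(np.mean(closest))


def rel3_distance(intron_cds_offset: int, cds_length: int) -> float:
    """Relative distance of a junction to the CDS 3' end, in [0, 1]."""
    if not 0 < intron_cds_offset < cds_length:
        raise ValueError(
            f"offset {intron_cds_offset} outside CDS of length {cds_length}"
        )
    return (cds_length - intron_cds_offset) / cds_length


@dataclass(frozen=True)
class CooccurrenceResult:
    expected_both: float
    expected_fraction: float
    chi2: float
    p_value: float


def cooccurrence_test(
    n_total: int, n_lost: int, n_gained: int, n_both: int
) -> CooccurrenceResult:
    """Are loss and gain concentrated in the same genes?

    Under independence the both-classes count is expected at
    ``n_lost * n_gained / n_total``; the observed 2x2 gene classification is
    tested with Pearson's chi-square (df=1, no continuity correction).
    """
    if not 0 <= n_both <= min(n_lost, n_gained) <= n_total:
        raise ValueError("inconsistent gene counts")
    if n_lost + n_gained - n_both > n_total:
        raise ValueError("class sizes exceed the total")
    expected = n_lost * n_gained / n_total
    table = np.array(
        [
            [n_both, n_lost - n_both],
            [n_gained - n_both, n_total - n_lost - n_gained + n_both],
        ]
    )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return CooccurrenceResult(
        expected_both=expected,
        expected_fraction=expected / n_total,
        chi2=float(chi2),
        p_value=float(p),
    )


@dataclass(frozen=True)
class CompareResult:
    statistic: float
    p_value: float
    median_a: float
    median_b: float


def group_compare(
    values_a: Sequence[float], values_b: Sequence[float], paired: bool = False
) -> CompareResult:
    """Two-sided Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal lengths")
        if np.allclose(a, b):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return CompareResult(
        statistic=float(stat),
        p_value=float(p),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def microhomology_scan(
    five_prime_window: str,
    three_prime_window: str,
    k_range: Sequence[int] = range(3, 9),
) -> dict[int, bool]:
    """Exact direct repeats shared by the two boundary windows.

    Each window is the 10 bp straddling one exon-intron boundary (5 exonic +
    5 intronic nt).  For each repeat size k the scan slides every k-mer of
    the 5' window along the 3' window and demands an identical match.
    """
    up = five_prime_window.upper()
    down = three_prime_window.upper()
    out: dict[int, bool] = {}
    for k in k_range:
        found = False
        if up and down:
            for i in range(len(up) - k + 1):
                probe = up[i : i + k]
                for j in range(len(down) - k + 1):
                    if down[j : j + k] == probe:
                        found = True
                        break
                if found:
                    break
        out[k] = found
    return out


def boundary_windows(
    upstream_exon: str, intron: str, downstream_exon: str, exonic: int = 5, intronic: int = 5
) -> tuple[str, str]:
    """The two 10-bp windows symmetric across an intron's boundaries."""
    five = upstream_exon[-exonic:] + intron[:intronic]
    three = intron[-intronic:] + downstream_exon[:exonic]
    return five, three


@dataclass(frozen=True)
class IntronFeatures:
    gt_ag: bool
    ppt: bool
    gc_fraction: float
    length: int


def intron_features(
    sequence: str,
    ppt_search: int = 30,
    ppt_window: int = 10,
    ppt_min_pyrimidines: int = 8,
) -> IntronFeatures:
    """Splice-signal features of one intron sequence.

    The polypyrimidine-tract call is true when any ``ppt_window`` stretch in
    the last ``ppt_search`` nt upstream of the terminal AG contains at least
    ``ppt_min_pyrimidines`` pyrimidines.
    """
    seq = sequence.upper()
    if len(seq) < 4:
        raise ValueError("intron sequence must be at least 4 nt")
    if not set(seq) <= VALID_NT:
        raise ValueError(f"non-nucleotide characters in sequence: {set(seq) - VALID_NT}")
    gt_ag = seq.startswith("GT") and seq.endswith("AG")
    tail = seq[:-2][-ppt_search:]
    ppt = False
    for i in range(max(len(tail) - ppt_window, 0) + 1):
        chunk = tail[i : i + ppt_window]
        if len(chunk) == ppt_window and sum(c in PYRIMIDINES for c in chunk) >= ppt_min_pyrimidines:
            ppt = True
            break
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    return IntronFeatures(gt_ag=gt_ag, ppt=ppt, gc_fraction=gc, length=len(seq))


def length_correlation(
    lengths_a: Sequence[float], lengths_b: Sequence[float], min_pairs: int = 10
) -> tuple[float, float] | None:
    """Spearman correlation of intron lengths over shared conserved sites."""
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size != b.size:
        raise ValueError("length vectors must align site-by-site")
    if a.size < min_pairs:
        return None
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def confirm_gains(
    putative_gains: pd.DataFrame, junctions: pd.DataFrame
) -> pd.DataFrame:
    """Keep putative gained introns whose genomic interval has exact RNA support.

    Both frames carry 1-based inclusive intervals in columns
    (species, chrom, start, end); a gain is confirmed only by a junction with
    identical species, chromosome, start and end.
    """
    required = {"species", "chrom", "start", "end"}
    for name, df in (("putative_gains", putative_gains), ("junctions", junctions)):
        if not required <= set(df.columns):
            raise ValueError(f"{name} must have columns {sorted(required)}")
        if (df["end"] < df["start"]).any():
            raise ValueError(f"{name}: malformed interval (end < start)")
    key = ["species", "chrom", "start", "end"]
    observed = set(map(tuple, junctions[key].itertuples(index=False)))
    confirmed = putative_gains[
        [tuple(row) in observed for row in putative_gains[key].itertuples(index=False)]
    ]
    return confirmed.reset_index(drop=True)
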