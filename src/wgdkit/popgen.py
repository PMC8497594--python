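"""Sequence-diversity summaries (pi, Watterson's theta, Tajima's D) and the
gene presence/conservation filter.

Haplotypes are an (n, L) matrix of 0/1 alleles with -1 for missing data.
Nucleotide diversity uses pairwise deletion by default: each haplotype pair
contributes its per-pair difference fraction over the sites where both are
called.  Tajima's D is computed with the standard constants; it is undefined
(NaN, flagged) when there are no segregating sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

MISSING = -1


@dataclass(frozen=True)
class DiversityResult:
    n: int
    L: int
    S: int
    pi_per_site: float
    theta_w_per_site: float
    tajimas_d: float
    d_defined: bool


def _check(h: np.ndarray) -> np.ndarray:
    h = np.asarray(h)
    if h.ndim != 2 or h.shape[0] < 2:
        raise ValueError("need an (n >= 2, L) haplotype matrix")
    if not np.isin(h, (0, 1, MISSING)).all():
        raise ValueError("alleles must be 0, 1 or -1 (missing)")
    return h.astype(np.int8)


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def segregating_sites(h: np.ndarray) -> int:
    h = _check(h)
    masked = np.ma.masked_equal(h, MISSING)
    col_min = masked.min(axis=0)
    col_max = masked.max(axis=0)
    seg = (col_max - col_min).filled(0) > 0
    return int(seg.sum())


def _pairwise_fractions(h: np.ndarray, pairwise_deletion: bool) -> list[float]:
    """Per-pair difference fractions d_ij / L_ij."""
    n, L = h.shape
    fracs = []
    for i, j in combinations(range(n), 2):
        a, b = h[i], h[j]
        valid = (a != MISSING) & (b != MISSING)
        if not pairwise_deletion:
            valid = (h != MISSING).all(axis=0)
        lij = int(valid.sum())
        if lij == 0:
            raise ValueError(f"haplotypes {i},{j} share no called sites")
        fracs.append(float((a[valid] != b[valid]).sum()) / lij)
    return fracs


def nucleotide_diversity(h: np.ndarray, pairwise_deletion: bool = True) -> float:
    """pi per site: average pairwise difference fraction over all haplotype pairs."""
    h = _check(h)
    return float(np.mean(_pairwise_fractions(h, pairwise_deletion)))


def wattersons_theta(h: np.ndarray) -> float:
    """Watterson's theta per site: S / (a1 * L)."""
    h = _check(h)
    n, L = h.shape
    return segregating_sites(h) / (_harmonic(n) * L)


def tajimas_d(h: np.ndarray) -> tuple[float, bool]:
    """Tajima's D and a defined flag (False when S = 0).

    Uses the standard constants a1, a2, b1, b2, c1, c2, e1, e2 of the
    original statistic; pi_total is rescaled to full length per pair under
    pairwise deletion so D remains comparable across missingness patterns.
    """
    h = _check(h)
    n, L = h.shape
    S = segregating_sites(h)
    if S == 0:
        return float("nan"), False
    pi_total = float(np.mean(_pairwise_fractions(h, pairwise_deletion=True))) * L
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    denom = np.sqrt(e1 * S + e2 * S * (S - 1))
    if denom == 0:
        return float("nan"), False
    return float((pi_total - S / a1) / denom), True


def diversity_summary(h: np.ndarray) -> DiversityResult:
    h = _check(h)
    n, L = h.shape
    S = segregating_sites(h)
    d, defined = tajimas_d(h) if S > 0 else (float("nan"), False)
    return DiversityResult(
        n=n,
        L=L,
        S=S,
        pi_per_site=nucleotide_diversity(h),
        theta_w_per_site=wattersons_theta(h),
        tajimas_d=d,
        d_defined=defined,
    )


def gene_presence_filter(
    coverage: pd.DataFrame,
    max_ambiguous: float = 0.30,
) -> tuple[pd.DataFrame, set[str]]:
    """Presence matrix and conserved gene set from per-gene ambiguity fractions.

    ``coverage`` holds the fraction of each gene's positions that are
    ambiguous (missing or under the depth threshold, already applied
    upstream) per sample, genes as index.  A gene is present in a sample iff
    its ambiguous fraction is strictly below ``max_ambiguous``; it is
    conserved iff present in every sample.
    """
    vals = coverage.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("ambiguous fractions must lie in [0, 1]")
    presence = coverage < max_ambiguous
    conserved = set(presence.index[presence.all(axis=1)])
    return presence, conserved


def ambiguity_from_depth(covered_fraction: pd.DataFrame, callable_mask: pd.DataFrame | None = None) -> pd.DataFrame:
    """Ambiguous fractions from per-gene depth summaries.

    ``covered_fraction`` holds, per gene x sample, the fraction of the gene's
    positions whose depth meets the caller's threshold (e.g. 5x); the
    ambiguous fraction is its complement, optionally widened by a callable
    mask (fraction of non-missing positions).
    """
    amb = 1.0 - covered_fraction.clip(0, 1)
    if callable_mask is not None:
        amb = np.maximum(amb, 1.0 - callable_mask.clip(0, 1))
    return amb
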