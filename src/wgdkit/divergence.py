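"""NG86 Ka/Ks estimation, duplication-event deduplication and Ks-peak detection.

The synonymous/nonsynonymous machinery follows Nei & Gojobori (1986): sites
are counted per codon as the fraction of single-nucleotide changes that are
synonymous (changes creating stop codons count as nonsynonymous, so sites sum
to 3 per codon), differences are averaged with equal weight over all minimal
mutational paths between two codons that avoid stop codons, and the raw
proportions are corrected for multiple hits with the Jukes-Cantor formula
d = -(3/4) ln(1 - (4/3) p).  Pairs with pS or pN beyond the correction domain
are flagged saturated rather than raising.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from ._kde import kde_grid
from .codons import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, synonymous_site_fractions
from .seqalign import GAP3, CodonAlignment

SATURATION_P = 0.75


@dataclass(frozen=True)
class KsEstimate:
    """NG86 site/difference counts and JC-corrected rates for one gene pair."""

    id_a: str
    id_b: str
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    p_s: float
    p_n: float
    ks: float
    ka: float
    omega: float
    n_codons: int
    saturated: bool
    n_skipped_codons: int = 0


@dataclass(frozen=True)
class DuplicationEvent:
    family_id: int
    members: tuple[str, ...]
    ks: float


@dataclass(frozen=True)
class RateComparisonResult:
    statistic: float
    p_value: float
    p_adjusted: float
    n_a: int
    n_b: int
    alternative: str


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction; NaN when p >= 3/4 (saturated)."""
    if p < 0:
        raise ValueError("proportion of differences must be non-negative")
    if p >= SATURATION_P:
        return float("nan")
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


@lru_cache(maxsize=1)
def _site_table() -> dict[str, float]:
    return {c: synonymous_site_fractions(c) for c in SENSE_CODONS}


def _path_steps(c1: str, c2: str) -> tuple[float, float] | None:
    """Average (syn, nonsyn) step counts over all minimal stop-free paths.

    Returns None when every ordering of the differing positions passes
    through a stop codon (the codon pair is then skipped and flagged).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return (0.0, 0.0)
    syn_tot = nsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        syn = nsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nsyn_tot += nsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_tot / n_paths, nsyn_tot / n_paths


@lru_cache(maxsize=1)
def _diff_table() -> dict[tuple[str, str], tuple[float, float] | None]:
    """(codon, codon) -> averaged (Sd, Nd) contribution, for all sense pairs."""
    table: dict[tuple[str, str], tuple[float, float] | None] = {}
    for c1 in SENSE_CODONS:
        for c2 in SENSE_CODONS:
            table[(c1, c2)] = _path_steps(c1, c2)
    return table


def estimate_ka_ks(caln: CodonAlignment) -> KsEstimate:
    """NG86 Ka/Ks for a cleaned (gap-free) codon alignment."""
    sites = _site_table()
    diffs = _diff_table()
    s_sites = n_sites = sd = nd = 0.0
    n_codons = 0
    skipped = 0
    for ca, cb in zip(caln.columns_a, caln.columns_b):
        if ca == GAP3 or cb == GAP3:
            raise ValueError("estimate_ka_ks requires a gap-free (cleaned) alignment")
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon in alignment column ({ca}/{cb})")
        if ca not in sites or cb not in sites:
            raise ValueError(f"invalid codon in alignment column ({ca}/{cb})")
        step = diffs[(ca, cb)]
        if step is None:
            skipped += 1
            continue
        sa, sb = sites[ca], sites[cb]
        s_sites += 0.5 * (sa + sb)
        n_sites += 3.0 - 0.5 * (sa + sb)
        sd += step[0]
        nd += step[1]
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no usable codon columns")
    p_s = sd / s_sites if s_sites > 0 else float("nan")
    p_n = nd / n_sites if n_sites > 0 else float("nan")
    saturated = (not np.isfinite(p_s)) or (not np.isfinite(p_n)) or p_s >= SATURATION_P or p_n >= SATURATION_P
    ks = jc_correct(p_s) if np.isfinite(p_s) else float("nan")
    ka = jc_correct(p_n) if np.isfinite(p_n) else float("nan")
    omega = ka / ks if np.isfinite(ka) and np.isfinite(ks) and ks > 0 else float("nan")
    return KsEstimate(
        id_a=caln.id_a,
        id_b=caln.id_b,
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        p_s=p_s,
        p_n=p_n,
        ks=ks,
        ka=ka,
        omega=omega,
        n_codons=n_codons,
        saturated=bool(saturated),
        n_skipped_codons=skipped,
    )


def estimate_ka_ks_codons(codons_a: list[str], codons_b: list[str], id_a: str = "a", id_b: str = "b") -> KsEstimate:
    """Convenience wrapper for two equal-length, gap-free codon lists."""
    caln = CodonAlignment(
        tuple(codons_a),
        tuple(codons_b),
        id_a=id_a,
        id_b=id_b,
        source_len_a=len(codons_a),
        source_len_b=len(codons_b),
    )
    return estimate_ka_ks(caln)


def cluster_duplication_events(
    pairwise_ks: list[tuple[str, str, float]],
    max_ks: float = 5.0,
) -> list[DuplicationEvent]:
    """Deduplicate pairwise paralog Ks values into one value per duplication.

    Genes are joined into families as connected components over pairs with
    Ks <= max_ks; within each family, average-linkage hierarchical clustering
    on the Ks values emits one event per internal merge (n - 1 events for a
    family of n genes), at the merge height.  Within-family pairs that lack a
    Ks estimate are imputed at ``max_ks``.
    """
    import networkx as nx

    edges = [(a, b, ks) for a, b, ks in pairwise_ks if np.isfinite(ks) and 0 <= ks <= max_ks]
    g = nx.Graph()
    for a, b, ks in edges:
        if g.has_edge(a, b):
            g[a][b]["ks"] = min(g[a][b]["ks"], ks)
        else:
            g.add_edge(a, b, ks=ks)
    events: list[DuplicationEvent] = []
    for fam_id, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])):
        members = sorted(comp)
        if len(members) == 2:
            events.append(DuplicationEvent(fam_id, tuple(members), g[members[0]][members[1]]["ks"]))
            continue
        n = len(members)
        dm = np.full((n, n), float(max_ks))
        np.fill_diagonal(dm, 0.0)
        idx = {m: i for i, m in enumerate(members)}
        for a, b in itertools.combinations(members, 2):
            if g.has_edge(a, b):
                dm[idx[a], idx[b]] = dm[idx[b], idx[a]] = g[a][b]["ks"]
        link = _average_linkage(squareform(dm, checks=False))
        for height in link[:, 2]:
            events.append(DuplicationEvent(fam_id, tuple(members), float(height)))
    return events


def ks_distribution_mode(
    ks_values,
    grid_size: int = 512,
) -> tuple[float, np.ndarray, np.ndarray]:
    """KDE peak of a Ks distribution; grid spans [0, max + 3 bandwidths]."""
    x = np.asarray([v for v in np.asarray(ks_values, dtype=float) if np.isfinite(v)])
    if x.size < 2:
        raise ValueError("Ks mode requires at least 2 finite values")
    grid, dens = kde_grid(x, grid_size=grid_size, lo=0.0)
    mode = float(grid[int(np.argmax(dens))])
    return mode, grid, dens


def compare_rate_distributions(
    group_a,
    group_b,
    alternative: str = "less",
    m: int = 1,
) -> RateComparisonResult:
    """One-sided Mann-Whitney U comparison with Bonferroni adjustment.

    ``alternative="less"`` tests whether values in group A are stochastically
    smaller than in group B.  The exact null distribution is used when both
    groups have <= 10 observations and no ties cross the groups; otherwise
    the normal approximation with tie correction (scipy) is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    exact_ok = a.size <= 10 and b.size <= 10 and np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if exact_ok else "asymptotic"
    res = mannwhitneyu(a, b, alternative=alternative, method=method)
    p = float(res.pvalue)
    return RateComparisonResult(
        statistic=float(res.statistic),
        p_value=p,
        p_adjusted=min(1.0, m * p),
        n_a=int(a.size),
        n_b=int(b.size),
        alternative=alternative,
    )
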