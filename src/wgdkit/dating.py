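"""Consensus-age meta-analysis over per-family Bayesian dating traces.

MCMC sampling itself is out of scope: the inputs are per-family trace logs
(one column per node statistic, one row per sample).  The meta-analysis
discards a burn-in, screens families by effective sample size (ESS >= 200
for every statistic), represents each family by its per-node posterior
median, takes the mode of a Gaussian KDE over the family medians as the
consensus age, and attaches a ranked-bootstrap 95% CI (modes of the 26th and
974th of 1000 bootstrap density estimates, ranked by mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kde import kde_mode, kde_modes_batch


@dataclass
class AgeSampleSet:
    """Per-family median ages for one node, plus consensus mode and CI."""

    node: str
    medians: np.ndarray
    mode: float | None = None
    ci: tuple[float, float] | None = None

    def __post_init__(self):
        self.medians = np.asarray(self.medians, dtype=float)
        if self.ci is not None and self.mode is not None:
            lo, hi = self.ci
            if not (lo <= self.mode <= hi):
                raise ValueError("CI must bracket the consensus mode")


@dataclass(frozen=True)
class DatingFamily:
    """One dating gene family: the fixed 8-gene composition plus provenance."""

    family_id: str
    focal_dup1: str
    focal_dup2: str
    outgroup_a: str
    outgroup_b: str
    clade_x: tuple[str, str]
    clade_y: tuple[str, str]
    aln_len_aa: int


def effective_sample_size(trace) -> float:
    """ESS by the autocorrelation-sum (initial positive sequence) estimator.

    ACT = 1 + 2 * sum of autocorrelations up to (excluding) the first
    negative lag; ESS = N / ACT, capped at N.  A constant trace has no
    information and reports 0.
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples to estimate ESS")
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0.0:
        return 0.0
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / var
    act = 1.0
    for t in range(1, n):
        if rho[t] < 0:
            break
        act += 2.0 * rho[t]
    return float(min(n, n / act))


def summarize_family_trace(trace: pd.DataFrame, burn_in: int = 1000) -> pd.Series:
    """Per-node posterior medians after discarding the first ``burn_in`` samples."""
    if len(trace) <= burn_in:
        raise ValueError(f"trace has {len(trace)} samples, burn-in {burn_in} leaves nothing")
    post = trace.iloc[burn_in:]
    return post.median(axis=0)


def screen_and_summarize(
    traces: dict[str, pd.DataFrame],
    burn_in: int = 1000,
    min_ess: float = 200.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Apply burn-in + ESS screening; return per-family medians and exclusions.

    A family is retained only when every statistic column of its post-burn-in
    trace has ESS >= ``min_ess``.  Returns (medians DataFrame indexed by
    family, excluded family ids).
    """
    rows = {}
    excluded = []
    for fam_id in sorted(traces):
        trace = traces[fam_id]
        post = trace.iloc[burn_in:]
        if len(post) < 10:
            excluded.append(fam_id)
            continue
        ess_ok = all(effective_sample_size(post[c].to_numpy()) >= min_ess for c in post.columns)
        if not ess_ok:
            excluded.append(fam_id)
            continue
        rows[fam_id] = post.median(axis=0)
    medians = pd.DataFrame(rows).T
    medians.index.name = "family_id"
    return medians, excluded


def consensus_age(median_ages, grid_size: int = 512) -> float:
    """Mode of the Gaussian KDE over per-family median ages."""
    x = np.asarray(median_ages, dtype=float)
    if x.size < 2:
        raise ValueError("consensus age requires at least 2 family medians")
    return kde_mode(x, grid_size=grid_size)


def bootstrap_ci(
    median_ages,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    grid_size: int = 512,
) -> tuple[float, float]:
    """Ranked-bootstrap 95% CI of the consensus age.

    ``B`` bootstrap resamples (with replacement) of the family medians are
    drawn; the KDE mode of each resample is computed; modes are sorted
    ascending and the ranks ceil(0.025 B) + 1 and B - ceil(0.025 B) - 1
    (1-based; the 26th and 974th for B = 1000) are the CI bounds.
    """
    x = np.asarray(median_ages, dtype=float)
    if x.size < 2:
        raise ValueError("bootstrap CI requires at least 2 family medians")
    if rng is None:
        rng = np.random.default_rng()
    if np.ptp(x) == 0:
        return float(x[0]), float(x[0])
    idx = rng.integers(0, x.size, size=(B, x.size))
    modes = np.sort(kde_modes_batch(x[idx], grid_size=grid_size))
    k = math.ceil(0.025 * B)
    lo = modes[k]            # (k+1)-th in 1-based ranking
    hi = modes[B - k - 2]    # (B-k-1)-th in 1-based ranking
    return float(lo), float(hi)


def consensus_with_ci(
    ages: AgeSampleSet,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    grid_size: int = 512,
) -> AgeSampleSet:
    """Fill the consensus mode and bootstrap CI of an age sample set."""
    mode = consensus_age(ages.medians, grid_size=grid_size)
    lo, hi = bootstrap_ci(ages.medians, B=B, rng=rng, grid_size=grid_size)
    lo, hi = min(lo, mode), max(hi, mode)
    return AgeSampleSet(node=ages.node, medians=ages.medians, mode=mode, ci=(lo, hi))


def assemble_dating_families(
    duplicate_pairs: pd.DataFrame,
    outgroup_orthologs: pd.DataFrame,
    clade_orthologs: pd.DataFrame,
    outgroup_b: pd.DataFrame,
    aln_len_aa: dict[str, int] | None = None,
    dup_ks_window: tuple[float, float] = (0.2, 0.6),
    outgroup_ks_window: tuple[float, float] = (0.5, 1.2),
    clade_ks_window: tuple[float, float] = (0.05, 0.30),
    min_aln_len_aa: int = 100,
) -> tuple[list[DatingFamily], list[tuple[str, str]]]:
    """Build dating gene families under the Ks-window composition rules.

    Inputs (all pandas):
      duplicate_pairs    dup1, dup2, ks           focal-genome WGD pairs
      outgroup_orthologs focal_gene, ortholog, ks, ka
      clade_orthologs    focal_gene, ortholog, clade ("X"|"Y"), ks, ka
      outgroup_b         outgroup_a_gene, ortholog, ka

    A family is emitted only if: the duplicate pair's Ks lies in
    ``dup_ks_window``; an outgroup-A ortholog of either focal gene exists
    with Ks in ``outgroup_ks_window``; each focal gene has one clade-X and
    one clade-Y ortholog with Ks in ``clade_ks_window``; the outgroup-A gene
    has an outgroup-B partner; and the family's cleaned alignment length is
    at least ``min_aln_len_aa`` (families absent from ``aln_len_aa`` pass
    when it is None).  Candidate ties are broken by lowest Ka then
    lexicographic gene id.  Returns (families, dropped (family, reason)).
    """
    def _in(v, w):
        return w[0] <= v <= w[1]

    og_by_focal: dict[str, list] = {}
    for r in outgroup_orthologs.itertuples(index=False):
        if _in(r.ks, outgroup_ks_window):
            og_by_focal.setdefault(r.focal_gene, []).append(r)
    clade_by_focal: dict[tuple[str, str], list] = {}
    for r in clade_orthologs.itertuples(index=False):
        if _in(r.ks, clade_ks_window):
            clade_by_focal.setdefault((r.focal_gene, r.clade), []).append(r)
    ogb_by_a: dict[str, list] = {}
    for r in outgroup_b.itertuples(index=False):
        ogb_by_a.setdefault(r.outgroup_a_gene, []).append(r)

    def _pick(cands):
        return min(cands, key=lambda r: (r.ka, r.ortholog)) if cands else None

    families: list[DatingFamily] = []
    dropped: list[tuple[str, str]] = []
    for pr in duplicate_pairs.itertuples(index=False):
        fam_id = f"{pr.dup1}|{pr.dup2}"
        if not _in(pr.ks, dup_ks_window):
            dropped.append((fam_id, "duplicate_ks_outside_window"))
            continue
        og = _pick(og_by_focal.get(pr.dup1, []) + og_by_focal.get(pr.dup2, []))
        if og is None:
            dropped.append((fam_id, "no_outgroup_ortholog_in_window"))
            continue
        slots = {}
        ok = True
        for focal in (pr.dup1, pr.dup2):
            for clade in ("X", "Y"):
                cand = _pick(clade_by_focal.get((focal, clade), []))
                if cand is None:
                    ok = False
                    dropped.append((fam_id, f"no_clade_{clade}_ortholog_for_{focal}"))
                    break
                slots[(focal, clade)] = cand.ortholog
            if not ok:
                break
        if not ok:
            continue
        ogb = _pick(ogb_by_a.get(og.ortholog, []))
        if ogb is None:
            dropped.append((fam_id, "no_second_outgroup_ortholog"))
            continue
        length = (aln_len_aa or {}).get(fam_id, min_aln_len_aa)
        if length < min_aln_len_aa:
            dropped.append((fam_id, "alignment_below_min_length"))
            continue
        families.append(
            DatingFamily(
                family_id=fam_id,
                focal_dup1=pr.dup1,
                focal_dup2=pr.dup2,
                outgroup_a=og.ortholog,
                outgroup_b=ogb.ortholog,
                clade_x=(slots[(pr.dup1, "X")], slots[(pr.dup2, "X")]),
                clade_y=(slots[(pr.dup1, "Y")], slots[(pr.dup2, "Y")]),
                aln_len_aa=int(length),
            )
        )
    return families, dropped
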