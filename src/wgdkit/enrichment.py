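"""Exact 2x2 enrichment tests and GO term enrichment with elim decorrelation.

The retention-by-expression comparison builds one 2x2 table per
differential-expression direction (retained/non-retained x responsive/not),
tests enrichment with a one-sided Fisher exact test (hypergeometric upper
tail, computed with log-factorials) and Bonferroni-adjusts across the
directions tested.  One-sided enrichment is the default because it is the
alternative consistent with both printed adjusted p-values of the source
contingency data; a two-sided variant is available via ``alternative``.

GO enrichment supports the classic one-sided Fisher score and the "elim"
decorrelation: terms are processed children-before-parents, and the study
genes of a significant term are removed from its ancestors' annotation sets
before those are tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a retained & responsive, b retained & not, c non-retained &
    responsive, d non-retained & not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


def _log_choose(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def _hypergeom_logpmf(x: int, N: int, K: int, n: int) -> float:
    return _log_choose(K, x) + _log_choose(N - K, n - x) - _log_choose(N, n)


def fisher_exact_one_sided(t: ContingencyTable2x2, alternative: str = "greater") -> float:
    """Fisher exact test via the hypergeometric tail, in log space.

    ``greater`` (enrichment) returns P(X >= a) under the hypergeometric null
    with the table's margins; ``two-sided`` sums all tables with pmf <= that
    of the observed one.  Degenerate margins return p = 1.
    """
    if t.degenerate:
        return 1.0
    N, K, n = t.n, t.a + t.c, t.a + t.b
    lo, hi = max(0, n - (N - K)), min(K, n)
    logs = np.array([_hypergeom_logpmf(x, N, K, n) for x in range(lo, hi + 1)])
    mx = logs.max()
    probs = np.exp(logs - mx)
    obs = t.a - lo
    if alternative == "greater":
        p = probs[obs:].sum() / probs.sum()
    elif alternative == "less":
        p = probs[: obs + 1].sum() / probs.sum()
    elif alternative == "two-sided":
        cutoff = probs[obs] * (1 + 1e-7)
        p = probs[probs <= cutoff].sum() / probs.sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(1.0, p))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """min(1, m * p) for each p; m defaults to the number of tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    if m < len(p):
        raise ValueError("Bonferroni family size must cover all tests")
    return np.minimum(1.0, m * p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(1.0, adjusted)
    return out


@dataclass(frozen=True)
class DirectionResult:
    direction: str
    table: ContingencyTable2x2
    p_raw: float
    p_adjusted: float


def retention_enrichment_test(
    retention: pd.DataFrame,
    labels: pd.DataFrame,
    directions: tuple[str, ...] = ("up", "down"),
    alternative: str = "greater",
    m: int | None = None,
) -> list[DirectionResult]:
    """Retention x expression-response enrichment, one table per direction.

    ``retention`` needs gene_id/retained/non_retained columns; ``labels``
    needs gene_id/direction.  Genes without a retention call (neither flag,
    e.g. category B/C) are excluded.  Bonferroni family size defaults to the
    number of directions tested.
    """
    called = retention[retention["retained"] | retention["non_retained"]]
    lab = labels.set_index("gene_id")["direction"]
    unknown = set(lab.index) - set(retention["gene_id"])
    if unknown:
        raise ValueError(f"labels reference genes without retention rows, e.g. {sorted(unknown)[:5]}")
    gene_dir = called["gene_id"].map(lab).fillna("none")
    is_ret = called["retained"].to_numpy()
    results = []
    for d in directions:
        resp = (gene_dir == d).to_numpy()
        t = ContingencyTable2x2(
            a=int((is_ret & resp).sum()),
            b=int((is_ret & ~resp).sum()),
            c=int((~is_ret & resp).sum()),
            d=int((~is_ret & ~resp).sum()),
        )
        results.append((d, t, fisher_exact_one_sided(t, alternative=alternative)))
    fam = len(directions) if m is None else m
    adj = bonferroni([p for _, _, p in results], m=fam)
    return [DirectionResult(d, t, p, float(ap)) for (d, t, p), ap in zip(results, adj)]


def table2_style_report(tables: dict[str, tuple[int, int, int, int]], m: int | None = None) -> pd.DataFrame:
    """Adjusted p-values for externally supplied per-direction 2x2 counts."""
    rows = []
    raw = []
    for direction, (a, b, c, d) in tables.items():
        t = ContingencyTable2x2(a, b, c, d)
        raw.append(fisher_exact_one_sided(t))
        rows.append({"direction": direction, "a": a, "b": b, "c": c, "d": d})
    adj = bonferroni(raw, m=len(tables) if m is None else m)
    out = pd.DataFrame(rows)
    out["p_raw"] = raw
    out["p_adjusted"] = np.round(adj, 4)
    return out


class GoDag:
    """A gene-ontology-style DAG (is_a edges) with upward-propagated annotations."""

    def __init__(self, edges: list[tuple[str, str]], annotations: dict[str, set[str]]):
        """``edges`` are (child_term, parent_term); ``annotations`` map term ->
        directly annotated genes (propagated to all ancestors here)."""
        g = nx.DiGraph()
        g.add_edges_from(edges)  # child -> parent
        for term in annotations:
            g.add_node(term)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("GO term graph contains a cycle")
        self.graph = g
        self.annotations: dict[str, set[str]] = {t: set() for t in g.nodes}
        for term, genes in annotations.items():
            self.annotations[term] |= set(genes)
            for anc in nx.descendants(g, term):  # edges point child->parent
                self.annotations[anc] |= set(genes)

    def ancestors(self, term: str) -> set[str]:
        return set(nx.descendants(self.graph, term))

    def bottom_up_terms(self) -> list[str]:
        """Terms ordered children-before-parents, deepest first, stable."""
        depth = {}
        for t in nx.topological_sort(self.graph.reverse()):  # parents first
            preds = list(self.graph.reverse().predecessors(t))
            depth[t] = 0 if not preds else 1 + max(depth[p] for p in preds)
        # reverse-topological ensures children precede parents; within the
        # order, sort by decreasing depth then id for determinism
        return sorted(self.graph.nodes, key=lambda t: (-depth[t], t))


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    annotated: int
    study_count: int
    expected: float
    p_classic: float
    p_elim: float
    p_bh: float


def go_enrichment_elim(
    dag: GoDag,
    study: set[str],
    population: set[str],
    elim_threshold: float = 0.05,
    top_k: int = 40,
) -> list[EnrichmentRow]:
    """GO enrichment with the elim decorrelation plus classic Fisher + BH.

    Terms are tested bottom-up with a one-sided Fisher test on (annotated in
    study) vs (annotated in population); when a term's elim p-value falls
    below ``elim_threshold``, its annotated study genes are removed from all
    of its ancestors' annotation sets before those are tested.  Classic
    (non-eliminated) p-values and their BH adjustment are reported alongside.
    Rows are sorted by elim p-value; the ``top_k`` most significant are
    returned.
    """
    study = set(study)
    population = set(population)
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    n_pop, n_study = len(population), len(study)

    def _fisher(ann: set[str]) -> tuple[int, int, float]:
        k_ann = len(ann & population)
        k_study = len(ann & study)
        t = ContingencyTable2x2(
            a=k_study,
            b=k_ann - k_study,
            c=n_study - k_study,
            d=(n_pop - k_ann) - (n_study - k_study),
        )
        return k_ann, k_study, fisher_exact_one_sided(t)

    classic: dict[str, tuple[int, int, float]] = {}
    elim_p: dict[str, float] = {}
    working = {t: set(g) for t, g in dag.annotations.items()}
    for term in dag.bottom_up_terms():
        classic[term] = _fisher(dag.annotations[term])
        _, _, p_e = _fisher(working[term])
        elim_p[term] = p_e
        if p_e < elim_threshold:
            removed = dag.annotations[term] & study
            for anc in dag.ancestors(term):
                working[anc] -= removed

    terms = list(classic)
    bh = bh_fdr([classic[t][2] for t in terms])
    rows = []
    for t, p_bh in zip(terms, bh):
        k_ann, k_study, p_c = classic[t]
        rows.append(
            EnrichmentRow(
                term=t,
                annotated=k_ann,
                study_count=k_study,
                expected=k_ann * n_study / n_pop if n_pop else 0.0,
                p_classic=p_c,
                p_elim=elim_p[t],
                p_bh=float(p_bh),
            )
        )
    rows.sort(key=lambda r: (r.p_elim, r.term))
    return rows[:top_k]
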