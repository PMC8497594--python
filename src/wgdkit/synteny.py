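"""Collinear-block detection and 1:1 / 1:2 orthology classification.

Homologous gene pairs (anchors) that pass the e-value / best-hit filters are
chained into collinear blocks per scaffold pair and orientation with a
dynamic program over rank-sorted anchors (score = 20 * anchors - total rank
gap, i.e. anchors - 0.05 * gap in the conventional scaling, kept in integers
for exact tie handling).  An outgroup gene anchored in exactly two blocks on
distinct ingroup genes defines a 1:2 orthology group whose two ingroup genes
are the WGD-retained duplicates; a gene anchored in one block defines a 1:1
group (non-retained partner); genes hit by three or more blocks are excluded
and logged.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SCORE_PER_ANCHOR = 20  # = 1 anchor in units of 0.05 rank-gap penalty


@dataclass(frozen=True)
class Anchor:
    out_gene: str
    out_scaffold: str
    out_rank: int
    in_gene: str
    in_scaffold: str
    in_rank: int
    score: float


@dataclass(frozen=True)
class CollinearBlock:
    block_id: int
    out_scaffold: str
    in_scaffold: str
    orientation: str  # "same" | "inverted"
    anchors: tuple[Anchor, ...]

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class OrthologyGroup:
    out_gene: str
    in_genes: tuple[str, ...]

    @property
    def relation(self) -> str:
        return "one_to_one" if len(self.in_genes) == 1 else "one_to_two"


def find_homolog_anchors(
    hits: pd.DataFrame,
    outgroup_genes: pd.DataFrame,
    ingroup_genes: pd.DataFrame,
    evalue_cutoff: float = 1e-10,
    best_per_query: bool = True,
) -> list[Anchor]:
    """Filter a tabular homology hit list into positioned anchors.

    ``hits`` carries query (ingroup gene), subject (outgroup gene), bitscore,
    evalue.  Hits above the e-value cutoff are dropped; with
    ``best_per_query`` only the highest-bitscore hit per ingroup query is
    kept (ties: lowest e-value, then lexicographic subject).  Unknown gene
    ids raise.  Output order is deterministic.
    """
    out_pos = outgroup_genes.set_index("gene_id")[["scaffold", "rank"]]
    in_pos = ingroup_genes.set_index("gene_id")[["scaffold", "rank"]]
    unknown_q = set(hits["query"]) - set(in_pos.index)
    unknown_s = set(hits["subject"]) - set(out_pos.index)
    if unknown_q or unknown_s:
        missing = sorted(unknown_q | unknown_s)[:5]
        raise ValueError(f"hits reference unknown gene ids, e.g. {missing}")

    kept = hits[hits["evalue"] <= evalue_cutoff].copy()
    if best_per_query and not kept.empty:
        kept = kept.sort_values(
            ["query", "bitscore", "evalue", "subject"],
            ascending=[True, False, True, True],
        ).drop_duplicates("query", keep="first")

    anchors = []
    for row in kept.itertuples(index=False):
        op = out_pos.loc[row.subject]
        ip = in_pos.loc[row.query]
        anchors.append(
            Anchor(
                out_gene=row.subject,
                out_scaffold=str(op["scaffold"]),
                out_rank=int(op["rank"]),
                in_gene=row.query,
                in_scaffold=str(ip["scaffold"]),
                in_rank=int(ip["rank"]),
                score=float(row.bitscore),
            )
        )
    anchors.sort(key=lambda a: (a.out_scaffold, a.out_rank, a.in_scaffold, a.in_rank, a.in_gene))
    return anchors


def _chain_score(length: int, gap_total: int) -> int:
    return SCORE_PER_ANCHOR * length - gap_total


def _step_ok(prev: Anchor, nxt: Anchor, orientation: str, max_gap: int) -> bool:
    dout = nxt.out_rank - prev.out_rank
    din = nxt.in_rank - prev.in_rank
    if dout < 1 or dout - 1 > max_gap:
        return False
    if orientation == "same":
        return din >= 1 and din - 1 <= max_gap
    return din <= -1 and (-din) - 1 <= max_gap


def _step_gap(prev: Anchor, nxt: Anchor) -> int:
    return (nxt.out_rank - prev.out_rank - 1) + (abs(nxt.in_rank - prev.in_rank) - 1)


def _best_chain(anchors: list[Anchor], orientation: str, max_gap: int) -> tuple[int, list[int]]:
    """Maximum-scoring chain by DP; deterministic tie-breaking.

    Anchors must be sorted by (out_rank, in_rank).  Ties in score are broken
    by preferring the smaller anchor index at every choice (end anchor and
    predecessor alike), which selects the chain with the lexicographically
    smallest reversed index sequence.
    """
    n = len(anchors)
    best_score = [SCORE_PER_ANCHOR] * n
    pred = [-1] * n
    for j in range(n):
        for i in range(j):
            if not _step_ok(anchors[i], anchors[j], orientation, max_gap):
                continue
            cand = best_score[i] + SCORE_PER_ANCHOR - _step_gap(anchors[i], anchors[j])
            if cand > best_score[j]:
                best_score[j] = cand
                pred[j] = i
    end = max(range(n), key=lambda j: (best_score[j], -j))
    chain = []
    j = end
    while j != -1:
        chain.append(j)
        j = pred[j]
    chain.reverse()
    return best_score[end], chain


def chain_collinear_blocks(
    anchors: list[Anchor],
    min_block: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks per scaffold pair and orientation.

    Blocks are extracted greedily: within each scaffold pair, the
    maximum-scoring chain over the remaining anchors (either orientation) is
    emitted and its anchors removed, until the best chain falls below
    ``min_block`` anchors.  Outgroup ranks are strictly increasing within a
    chain; ingroup ranks strictly increase ("same") or decrease ("inverted");
    rank gaps on both genomes are at most ``max_gap``.
    """
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.out_scaffold, a.in_scaffold), []).append(a)

    blocks: list[CollinearBlock] = []
    bid = 0
    for (oscaf, iscaf) in sorted(by_pair):
        remaining = sorted(by_pair[(oscaf, iscaf)], key=lambda a: (a.out_rank, a.in_rank, a.in_gene))
        while len(remaining) >= min_block:
            best = None
            for orientation in ("same", "inverted"):
                score, chain = _best_chain(remaining, orientation, max_gap)
                if best is None or score > best[0]:
                    best = (score, chain, orientation)
            score, chain, orientation = best
            if len(chain) < min_block:
                break
            chosen = [remaining[i] for i in chain]
            blocks.append(CollinearBlock(bid, oscaf, iscaf, orientation, tuple(chosen)))
            bid += 1
            chain_set = set(chain)
            remaining = [a for i, a in enumerate(remaining) if i not in chain_set]
    return blocks


def classify_orthology(
    blocks: list[CollinearBlock],
    outgroup_genes: pd.DataFrame,
    ingroup_genes: pd.DataFrame,
    homolog_in_genes: set | None = None,
) -> tuple[list[OrthologyGroup], pd.DataFrame, list[str]]:
    """1:1 / 1:2 orthology groups and the per-ingroup-gene retention table.

    Returns (groups, retention table, excluded outgroup genes).  The
    retention table has one row per ingroup gene with ``retained`` /
    ``non_retained`` flags (mutually exclusive), a ``tandem`` placeholder
    (filled by :func:`detect_tandem_duplicates`) and a category: "A" for
    syntenic genes (anchored in a block), "B" for genes with homology only
    (present in ``homolog_in_genes``), "C" otherwise.
    """
    membership: dict[str, dict[int, set[str]]] = {}
    for b in blocks:
        for a in b.anchors:
            membership.setdefault(a.out_gene, {}).setdefault(b.block_id, set()).add(a.in_gene)

    groups: list[OrthologyGroup] = []
    excluded: list[str] = []
    claimed: set[str] = set()
    retained: set[str] = set()
    non_retained: set[str] = set()
    for out_gene in sorted(membership):
        by_block = membership[out_gene]
        in_genes = sorted({g for s in by_block.values() for g in s})
        in_genes = [g for g in in_genes if g not in claimed]
        n_blocks = len(by_block)
        if n_blocks == 1 and len(in_genes) == 1:
            groups.append(OrthologyGroup(out_gene, (in_genes[0],)))
            non_retained.add(in_genes[0])
            claimed.add(in_genes[0])
        elif n_blocks == 2 and len(in_genes) == 2:
            groups.append(OrthologyGroup(out_gene, tuple(in_genes)))
            retained.update(in_genes)
            claimed.update(in_genes)
        else:
            excluded.append(out_gene)

    syntenic = {a.in_gene for b in blocks for a in b.anchors}
    homolog_in_genes = homolog_in_genes or set()
    rows = []
    for gene in ingroup_genes["gene_id"]:
        if gene in syntenic:
            cat = "A"
        elif gene in homolog_in_genes:
            cat = "B"
        else:
            cat = "C"
        rows.append(
            {
                "gene_id": gene,
                "retained": gene in retained,
                "non_retained": gene in non_retained,
                "tandem": False,
                "category": cat,
            }
        )
    retention = pd.DataFrame(rows)
    return groups, retention, excluded


def detect_tandem_duplicates(
    ingroup_genes: pd.DataFrame,
    best_hits: dict[str, str],
    retention: pd.DataFrame,
) -> set[str]:
    """Adjacent same-scaffold genes sharing an outgroup best hit.

    A run of adjacent-rank genes whose best hit is the same outgroup gene is
    flagged tandem when at least one member is syntenic (retained or
    non-retained).  Returns the flagged gene set and marks the ``tandem``
    column of ``retention`` in place.
    """
    syntenic_status = retention.set_index("gene_id")[["retained", "non_retained"]]
    tandem: set[str] = set()
    for _, scaf_df in ingroup_genes.groupby("scaffold"):
        ordered = scaf_df.sort_values("rank")
        genes = ordered["gene_id"].tolist()
        run = [genes[0]]
        for g in genes[1:]:
            if best_hits.get(g) is not None and best_hits.get(g) == best_hits.get(run[-1]):
                run.append(g)
            else:
                if len(run) > 1 and _run_is_anchored(run, syntenic_status):
                    tandem.update(run)
                run = [g]
        if len(run) > 1 and _run_is_anchored(run, syntenic_status):
            tandem.update(run)
    retention["tandem"] = retention["gene_id"].isin(tandem)
    return tandem


def _run_is_anchored(run: list[str], status: pd.DataFrame) -> bool:
    for g in run:
        if g in status.index:
            row = status.loc[g]
            if bool(row["retained"]) or bool(row["non_retained"]):
                return True
    return False


def dotplot_table(blocks: list[CollinearBlock]) -> pd.DataFrame:
    """One row per anchor with its block id and orientation (dotplot export)."""
    rows = [
        {
            "block_id": b.block_id,
            "orientation": b.orientation,
            "out_scaffold": b.out_scaffold,
            "out_gene": a.out_gene,
            "out_rank": a.out_rank,
            "in_scaffold": b.in_scaffold,
            "in_gene": a.in_gene,
            "in_rank": a.in_rank,
        }
        for b in blocks
        for a in b.anchors
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "block_id",
            "orientation",
            "out_scaffold",
            "out_gene",
            "out_rank",
            "in_scaffold",
            "in_gene",
            "in_rank",
        ],
    )
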