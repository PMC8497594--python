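"""Anchor filtering, collinear chaining (vs brute force) and orthology calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wgdkit.synteny import (
    Anchor,
    SCORE_PER_ANCHOR,
    chain_collinear_blocks,
    classify_orthology,
    detect_tandem_duplicates,
    dotplot_table,
    find_homolog_anchors,
)


def _gene_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "genome", "scaffold", "rank", "strand"])


def _mk_anchor(orank, irank, oscaf="c1", iscaf="s1"):
    return Anchor(f"og{orank}_{irank}", oscaf, orank, f"ig{orank}_{irank}", iscaf, irank, 100.0)


class TestFindHomologAnchors:
    def setup_method(self):
        self.out = _gene_table([("O1", "out", "c1", 0, "+"), ("O2", "out", "c1", 1, "+")])
        self.ing = _gene_table([("I1", "in", "s1", 0, "+"), ("I2", "in", "s1", 1, "+")])

    def test_empty_hits(self):
        hits = pd.DataFrame(columns=["query", "subject", "bitscore", "evalue"])
        assert find_homolog_anchors(hits, self.out, self.ing) == []

    def test_evalue_cutoff_excludes_weak_hits(self):
        hits = pd.DataFrame(
            [("I1", "O1", 50.0, 1e-9), ("I2", "O2", 50.0, 1e-10)],
            columns=["query", "subject", "bitscore", "evalue"],
        )
        anchors = find_homolog_anchors(hits, self.out, self.ing)
        assert [a.in_gene for a in anchors] == ["I2"]

    def test_best_per_query_keeps_highest_bitscore(self):
        hits = pd.DataFrame(
            [("I1", "O1", 200.0, 1e-20), ("I1", "O2", 100.0, 1e-12)],
            columns=["query", "subject", "bitscore", "evalue"],
        )
        anchors = find_homolog_anchors(hits, self.out, self.ing)
        assert len(anchors) == 1 and anchors[0].out_gene == "O1"

    def test_unknown_gene_raises(self):
        hits = pd.DataFrame([("IX", "O1", 10.0, 1e-30)], columns=["query", "subject", "bitscore", "evalue"])
        with pytest.raises(ValueError, match="unknown"):
            find_homolog_anchors(hits, self.out, self.ing)


def oracle_chain_blocks(anchors, min_block, max_gap):
    """Brute-force reference: enumerate every valid chain, greedy extraction.

    A chain is any subsequence with strictly increasing outgroup ranks,
    strictly monotone ingroup ranks (increasing = same, decreasing =
    inverted) and rank gaps <= max_gap on both genomes; score = 20 * length -
    total gap; ties resolved by the lexicographically smallest reversed index
    tuple; the same orientation beats inverted at equal score.
    """
    def gaps(ch):
        return sum(
            (anchors[b].out_rank - anchors[a].out_rank - 1)
            + (abs(anchors[b].in_rank - anchors[a].in_rank) - 1)
            for a, b in zip(ch, ch[1:])
        )

    def step_ok(a, b, orientation):
        dout = anchors[b].out_rank - anchors[a].out_rank
        din = anchors[b].in_rank - anchors[a].in_rank
        if dout < 1 or dout - 1 > max_gap:
            return False
        if orientation == "same":
            return 1 <= din <= max_gap + 1
        return -max_gap - 1 <= din <= -1

    def all_chains(avail, orientation):
        chains = []

        def extend(chain):
            chains.append(tuple(chain))
            for j in avail:
                if j > chain[-1] and step_ok(chain[-1], j, orientation):
                    chain.append(j)
                    extend(chain)
                    chain.pop()

        for i in avail:
            extend([i])
        return chains

    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].out_rank, anchors[i].in_rank))
    pos = {idx: k for k, idx in enumerate(order)}  # tie-break on sorted position
    avail = set(range(len(anchors)))
    blocks = []
    while avail:
        per_orientation = {}
        for orientation in ("same", "inverted"):
            best = None
            for ch in all_chains(sorted(avail, key=lambda i: pos[i]), orientation):
                score = SCORE_PER_ANCHOR * len(ch) - gaps(ch)
                key = (-score, tuple(pos[i] for i in reversed(ch)))
                if best is None or key < best[0]:
                    best = (key, ch)
            per_orientation[orientation] = best
        # orientation tie: "same" wins unless "inverted" scores strictly higher
        chosen, orientation = per_orientation["same"], "same"
        inv = per_orientation["inverted"]
        if inv is not None and (chosen is None or -inv[0][0] > -chosen[0][0]):
            chosen, orientation = inv, "inverted"
        if chosen is None or len(chosen[1]) < min_block:
            break
        blocks.append((orientation, tuple(sorted(chosen[1]))))
        avail -= set(chosen[1])
    return blocks


class TestChainCollinearBlocks:
    def test_perfect_diagonal_one_block(self):
        anchors = [_mk_anchor(i, i) for i in range(6)]
        blocks = chain_collinear_blocks(anchors, min_block=5, max_gap=25)
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 6
        assert blocks[0].orientation == "same"

    def test_below_min_block_discarded(self):
        anchors = [_mk_anchor(i, i) for i in range(4)]
        assert chain_collinear_blocks(anchors, min_block=5) == []

    def test_inverted_diagonal_detected(self):
        anchors = [_mk_anchor(i, 10 - i) for i in range(6)]
        blocks = chain_collinear_blocks(anchors, min_block=5)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_gap_constraint_splits_chains(self):
        anchors = [_mk_anchor(i, i) for i in range(5)] + [_mk_anchor(i + 40, i + 40) for i in range(5)]
        blocks = chain_collinear_blocks(anchors, min_block=5, max_gap=25)
        assert len(blocks) == 2

    def test_blocks_never_share_anchors(self, small_dataset):
        d = small_dataset
        anchors = find_homolog_anchors(d.hits, d.outgroup_genes, d.ingroup_genes)
        blocks = chain_collinear_blocks(anchors)
        seen = set()
        for b in blocks:
            for a in b.anchors:
                key = (a.out_gene, a.in_gene)
                assert key not in seen
                seen.add(key)
            ranks_out = [a.out_rank for a in b.anchors]
            ranks_in = [a.in_rank for a in b.anchors]
            assert ranks_out == sorted(ranks_out)
            assert ranks_in == sorted(ranks_in) or ranks_in == sorted(ranks_in, reverse=True)

    def test_interleaved_diagonals_match_bruteforce(self):
        # two interleaved diagonals on one scaffold pair (12 anchors)
        anchors = [_mk_anchor(i, i) for i in range(0, 12, 2)] + [
            _mk_anchor(i, 20 + i) for i in range(1, 12, 2)
        ]
        got = chain_collinear_blocks(anchors, min_block=3, max_gap=25)
        idx = {(_a.out_rank, _a.in_rank): k for k, _a in enumerate(
            sorted(anchors, key=lambda a: (a.out_rank, a.in_rank, a.in_gene)))}
        got_sets = [
            (b.orientation, tuple(sorted(idx[(a.out_rank, a.in_rank)] for a in b.anchors)))
            for b in got
        ]
        expected = oracle_chain_blocks(
            sorted(anchors, key=lambda a: (a.out_rank, a.in_rank, a.in_gene)), 3, 25
        )
        assert got_sets == expected

    def test_random_instances_match_bruteforce(self):
        rng = np.random.default_rng(31)
        for trial in range(150):
            n = int(rng.integers(2, 11))
            coords = set()
            while len(coords) < n:
                coords.add((int(rng.integers(0, 12)), int(rng.integers(0, 12))))
            anchors = sorted(
                (_mk_anchor(o, i) for o, i in coords),
                key=lambda a: (a.out_rank, a.in_rank, a.in_gene),
            )
            min_block, max_gap = int(rng.integers(2, 4)), int(rng.integers(2, 8))
            got = chain_collinear_blocks(anchors, min_block=min_block, max_gap=max_gap)
            got_sets = [
                (b.orientation, tuple(sorted(anchors.index(a) for a in b.anchors))) for b in got
            ]
            expected = oracle_chain_blocks(anchors, min_block, max_gap)
            assert got_sets == expected, f"trial {trial}"


class TestClassifyOrthology:
    def test_full_retention_gives_all_one_to_two(self, full_retention_dataset):
        d = full_retention_dataset
        anchors = find_homolog_anchors(d.hits, d.outgroup_genes, d.ingroup_genes)
        blocks = chain_collinear_blocks(anchors)
        groups, retention, excluded = classify_orthology(blocks, d.outgroup_genes, d.ingroup_genes)
        assert excluded == []
        assert all(g.relation == "one_to_two" for g in groups)
        assert len(groups) == len(d.outgroup_genes)

    def test_two_to_one_dotplot_property(self, full_retention_dataset):
        d = full_retention_dataset
        anchors = find_homolog_anchors(d.hits, d.outgroup_genes, d.ingroup_genes)
        blocks = chain_collinear_blocks(anchors)
        per_gene_blocks = {}
        for b in blocks:
            for a in b.anchors:
                per_gene_blocks.setdefault(a.out_gene, set()).add(b.block_id)
        assert all(len(v) == 2 for v in per_gene_blocks.values())
        assert set(per_gene_blocks) == set(d.outgroup_genes["gene_id"])

    def test_retention_recovery_within_binomial_error(self, small_dataset):
        d = small_dataset
        anchors = find_homolog_anchors(d.hits, d.outgroup_genes, d.ingroup_genes)
        blocks = chain_collinear_blocks(anchors)
        groups, retention, _ = classify_orthology(blocks, d.outgroup_genes, d.ingroup_genes)
        frac_one_to_two = np.mean([g.relation == "one_to_two" for g in groups])
        true_frac = d.truth.genes["retained"].mean()
        se = np.sqrt(true_frac * (1 - true_frac) / len(groups))
        assert abs(frac_one_to_two - true_frac) < 4 * se

    def test_retained_and_non_retained_exclusive(self, small_dataset):
        d = small_dataset
        anchors = find_homolog_anchors(d.hits, d.outgroup_genes, d.ingroup_genes)
        blocks = chain_collinear_blocks(anchors)
        _, retention, _ = classify_orthology(blocks, d.outgroup_genes, d.ingroup_genes)
        assert not (retention["retained"] & retention["non_retained"]).any()
        assert set(retention["category"]) <= {"A", "B", "C"}


class TestTandemDetection:
    def _setup(self):
        ing = _gene_table(
            [
                ("I1", "in", "s1", 0, "+"),
                ("I2", "in", "s1", 1, "+"),
                ("I3", "in", "s1", 2, "+"),
            ]
        )
        retention = pd.DataFrame(
            {
                "gene_id": ["I1", "I2", "I3"],
                "retained": [True, False, False],
                "non_retained": [False, False, True],
                "tandem": False,
                "category": ["A", "B", "A"],
            }
        )
        return ing, retention

    def test_adjacent_shared_best_hit_flagged(self):
        ing, retention = self._setup()
        tandem = detect_tandem_duplicates(ing, {"I1": "OX", "I2": "OX", "I3": "OY"}, retention)
        assert tandem == {"I1", "I2"}
        assert retention.set_index("gene_id")["tandem"].tolist() == [True, True, False]

    def test_no_shared_hits_no_tandems(self):
        ing, retention = self._setup()
        assert detect_tandem_duplicates(ing, {"I1": "OA", "I2": "OB", "I3": "OC"}, retention) == set()

    def test_run_without_syntenic_member_not_flagged(self):
        ing, retention = self._setup()
        retention.loc[:, ["retained", "non_retained"]] = False
        assert detect_tandem_duplicates(ing, {"I1": "OX", "I2": "OX"}, retention) == set()


class TestDotplotTable:
    def test_empty_blocks_gives_header_only(self):
        df = dotplot_table([])
        assert len(df) == 0
        assert "block_id" in df.columns

    def test_one_row_per_anchor(self):
        anchors = [_mk_anchor(i, i) for i in range(6)]
        blocks = chain_collinear_blocks(anchors, min_block=5)
        df = dotplot_table(blocks)
        assert len(df) == 6
        assert set(df["orientation"]) == {"same"}

    def test_roundtrip_through_writer(self, tmp_path):
        from wgdkit import io as wio

        anchors = [_mk_anchor(i, i) for i in range(6)]
        df = dotplot_table(chain_collinear_blocks(anchors, min_block=5))
        path = tmp_path / "dot.tsv"
        wio.write_table(df, path, provenance={"seed": 1})
        back = wio.read_table(path)
        pd.testing.assert_frame_equal(df, back)
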