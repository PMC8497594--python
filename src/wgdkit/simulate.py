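"""Synthetic data with the statistical structure the WGD analysis assumes.

The generator emulates the comparative setting the pipeline is built for: a
diploid outgroup genome and a descendant genome that went through one
whole-genome duplication, with class-dependent retention of the duplicated
copies (a "drought_up" class retains both copies more often than the
"background" class), tandem duplicates, codon sequences diverged under a
chosen Ka/Ks, per-family node-age estimates scattered around a true WGD age,
neutral coalescent haplotypes, and per-gene coverage/ambiguity profiles with
differential-expression labels.

Every dataset is a deterministic function of one top-level seed; component
streams are spawned from a numpy SeedSequence so stages can be re-run in
isolation without perturbing each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import CODON_TO_AA, NUCLEOTIDES, SENSE_CODONS, STOP_CODONS, validate_cds

DEFAULT_CLASSES = {"drought_up": 0.10, "background": 0.90}
# pair-level retention; the implied gene-level retained fraction 2r/(1+r)
# is ~62% of syntenic genes, the regime this generator emulates
DEFAULT_RETENTION = {"drought_up": 0.70, "background": 0.42}
DEFAULT_OMEGA = {"drought_up": 0.15, "background": 0.25}
DEFAULT_DE_RATES = {"drought_up": 0.30, "background": 0.04}


@dataclass(frozen=True)
class CoverageModel:
    """Per-gene, per-sample ambiguity profile.

    ``mean_depth`` is carried as provenance (depth thresholds are applied
    upstream of the ambiguous fraction here); the ambiguous fraction of a
    present gene is Beta(ambiguity_alpha, ambiguity_beta), and with
    probability ``absent_rate`` a gene copy is effectively missing from a
    sample (ambiguous fraction drawn from U(0.5, 1)).
    """

    mean_depth: float = 16.0
    ambiguity_alpha: float = 0.5
    ambiguity_beta: float = 9.5
    absent_rate: float = 0.02


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_ancestral_genes: int = 2000
    n_chromosomes: int = 7
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASSES))
    retention_prob: dict = field(default_factory=lambda: dict(DEFAULT_RETENTION))
    wgd_ks: float = 0.3
    outgroup_ks: float = 1.0
    omega: dict = field(default_factory=lambda: dict(DEFAULT_OMEGA))
    tandem_rate: float = 0.02
    de_rates: dict = field(default_factory=lambda: dict(DEFAULT_DE_RATES))
    de_down_rate: float = 0.03
    wgd_age_ma: float = 66.0
    family_age_sd: float = 3.0
    n_families: int = 204
    coalescent: tuple = (20, 5.0, 2000)  # (n_haplotypes, theta per locus, locus length)
    coverage_model: CoverageModel = field(default_factory=CoverageModel)
    n_samples: int = 19
    mean_gene_len_codons: int = 300
    decoy_hit_rate: float = 0.01

    def __post_init__(self):
        if self.n_ancestral_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_ancestral_genes and n_chromosomes must be positive")
        props = self.class_proportions
        if "drought_up" not in props or "background" not in props:
            raise ValueError('class_proportions must include "drought_up" and "background"')
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        for name, d in (
            ("class_proportions", props),
            ("retention_prob", self.retention_prob),
            ("de_rates", self.de_rates),
        ):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{k}] = {v} outside [0, 1]")
        if set(self.retention_prob) != set(props) or set(self.omega) != set(props):
            raise ValueError("retention_prob and omega must cover exactly the class labels")
        if not 0.0 <= self.tandem_rate <= 1.0 or not 0.0 <= self.de_down_rate <= 1.0:
            raise ValueError("rates must be in [0, 1]")
        if not self.wgd_ks < self.outgroup_ks:
            raise ValueError("wgd_ks must be smaller than outgroup_ks")
        if self.wgd_ks < 0 or self.family_age_sd < 0 or self.wgd_age_ma <= 0:
            raise ValueError("invalid divergence/age parameters")
        n, theta, L = self.coalescent
        if n < 2 or theta <= 0 or L < 1:
            raise ValueError("coalescent parameters must satisfy n >= 2, theta > 0, L >= 1")


@dataclass
class TruthTables:
    """Ground truth for parameter-recovery tests."""

    genes: pd.DataFrame  # ancestral_id, class, retained, tandem, de_up, de_down
    pairs: pd.DataFrame  # dup1, dup2, true_ks
    ages: np.ndarray | None = None


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    outgroup_genes: pd.DataFrame  # gene_id, genome, scaffold, rank, strand
    ingroup_genes: pd.DataFrame
    outgroup_cds: dict
    ingroup_cds: dict
    hits: pd.DataFrame  # query (ingroup), subject (outgroup), bitscore, evalue
    truth: TruthTables


def _component_rngs(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random in-frame CDS of sense codons (no stops)."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def evolve_codon_sequence(cds: str, target_ks: float, omega: float, rng: np.random.Generator) -> str:
    """Evolve a CDS so its expected synonymous divergence from the input is ``target_ks``.

    Discrete-event nucleotide mutation with equal exchange rates: mutation
    proposals arrive as Poisson(target_ks * L) events, each picking a uniform
    site and a uniform alternative nucleotide.  Proposals creating a stop
    codon are rejected; synonymous proposals are always accepted;
    nonsynonymous proposals are accepted with probability ``omega``.  Because
    proposals per site equal ``target_ks`` and synonymous proposals are never
    rejected, the expected number of synonymous substitutions per synonymous
    site is ``target_ks``, matching what NG86 + Jukes-Cantor estimates in
    expectation.
    """
    if target_ks < 0:
        raise ValueError("target_ks must be non-negative")
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must be in [0, 1]")
    validate_cds(cds)
    cds = cds.upper()
    if cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    if target_ks == 0:
        return cds
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    L = len(cds)
    n_events = rng.poisson(target_ks * L)
    if n_events == 0:
        return cds
    positions = rng.integers(0, L, size=n_events)
    alt_choices = rng.integers(0, 3, size=n_events)
    accept_draws = rng.random(size=n_events)
    aa_of = CODON_TO_AA
    stops = STOP_CODONS
    for pos, alt_i, u in zip(positions, alt_choices, accept_draws):
        ci, off = divmod(int(pos), 3)
        cur = codons[ci]
        old_nt = cur[off]
        alts = [nt for nt in NUCLEOTIDES if nt != old_nt]
        new = cur[:off] + alts[alt_i] + cur[off + 1 :]
        if new in stops:
            continue
        if aa_of[new] == aa_of[cur] or u < omega:
            codons[ci] = new
    return "".join(codons)


def _draw_gene_lengths(n: int, mean_codons: int, rng: np.random.Generator) -> np.ndarray:
    """Right-skewed codon lengths (lognormal, clipped at 100 codons)."""
    sigma = 0.35
    mu = math.log(mean_codons) - sigma**2 / 2
    lens = np.round(rng.lognormal(mu, sigma, size=n)).astype(int)
    return np.clip(lens, 100, None)


def simulate_wgd_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full comparative dataset: two genomes, sequences, hits, truth.

    The ingroup genome consists of two subgenomes (scaffold ids ``<k>a`` and
    ``<k>b``), each inheriting the ancestral gene order; non-retained genes
    keep one copy on a randomly chosen subgenome, with ranks re-indexed after
    losses.  The outgroup keeps the ancestral order on ``n_chromosomes``
    scaffolds.  All true homolog pairs appear in the hits table, plus a small
    fraction of decoy hits with sub-best bitscores.
    """
    cfg = config
    rngs = _component_rngs(cfg.seed, ("layout", "classes", "seqs", "retention", "tandem", "hits", "labels"))

    n = cfg.n_ancestral_genes
    classes = list(cfg.class_proportions)
    probs = np.array([cfg.class_proportions[c] for c in classes])
    gene_class = rngs["classes"].choice(classes, size=n, p=probs)
    lengths = _draw_gene_lengths(n, cfg.mean_gene_len_codons, rngs["layout"])
    chrom = np.sort(rngs["layout"].integers(0, cfg.n_chromosomes, size=n))

    retained = np.array(
        [rngs["retention"].random() < cfg.retention_prob[c] for c in gene_class]
    )
    lost_copy_is_b = rngs["retention"].random(n) < 0.5
    tandem = rngs["tandem"].random(n) < cfg.tandem_rate

    seq_rng = rngs["seqs"]
    d_out = cfg.outgroup_ks - cfg.wgd_ks / 2.0
    d_dup = cfg.wgd_ks / 2.0

    out_rows, in_rows = [], []
    out_cds: dict[str, str] = {}
    in_cds: dict[str, str] = {}
    truth_rows, pair_rows = [], []
    hit_rows = []

    for i in range(n):
        anc_id = f"g{i:05d}"
        og_id = f"OG_{anc_id}"
        om = cfg.omega[gene_class[i]]
        anc = random_cds(int(lengths[i]), seq_rng)
        out_seq = evolve_codon_sequence(anc, d_out, om, seq_rng)
        out_cds[og_id] = out_seq
        out_rows.append((og_id, "outgroup", f"chr{chrom[i]}", 0, "+"))

        copies = []
        for sub in ("a", "b"):
            if not retained[i]:
                keep = "b" if lost_copy_is_b[i] else "a"
                if sub != keep:
                    continue
            gid = f"IN_{anc_id}_{sub}"
            seq = evolve_codon_sequence(anc, d_dup, om, seq_rng)
            in_cds[gid] = seq
            scaf = f"scaf{chrom[i]}{sub}"
            in_rows.append((gid, "ingroup", scaf, 0, "+"))
            copies.append(gid)
            bitscore = 400.0 + seq_rng.normal(0, 10)
            hit_rows.append((gid, og_id, round(bitscore, 1), 1e-80))
            if tandem[i] and sub == "a":
                tid = f"IN_{anc_id}_{sub}_t"
                in_cds[tid] = evolve_codon_sequence(seq, 0.05, om, seq_rng)
                in_rows.append((tid, "ingroup", scaf, 0, "+"))
                hit_rows.append((tid, og_id, round(bitscore - 20.0, 1), 1e-70))
        if retained[i]:
            pair_rows.append((copies[0], copies[1], cfg.wgd_ks))
        truth_rows.append(
            (
                anc_id,
                gene_class[i],
                bool(retained[i]),
                bool(tandem[i]),
            )
        )

    outgroup = pd.DataFrame(out_rows, columns=["gene_id", "genome", "scaffold", "rank", "strand"])
    ingroup = pd.DataFrame(in_rows, columns=["gene_id", "genome", "scaffold", "rank", "strand"])
    for df in (outgroup, ingroup):
        df["rank"] = df.groupby("scaffold").cumcount()

    hits = pd.DataFrame(hit_rows, columns=["query", "subject", "bitscore", "evalue"])
    if cfg.decoy_hit_rate > 0 and len(hits) > 1:
        n_decoys = int(round(cfg.decoy_hit_rate * len(hits)))
        drng = rngs["hits"]
        q = hits["query"].to_numpy()
        s = hits["subject"].to_numpy()
        decoys = []
        for _ in range(n_decoys):
            qi, si = drng.integers(0, len(q)), drng.integers(0, len(s))
            if s[si] == hits.loc[qi, "subject"]:
                continue
            decoys.append((q[qi], s[si], round(60.0 + drng.normal(0, 5), 1), 10.0 ** -drng.uniform(11, 20)))
        if decoys:
            hits = pd.concat([hits, pd.DataFrame(decoys, columns=hits.columns)], ignore_index=True)

    genes = pd.DataFrame(truth_rows, columns=["ancestral_id", "class", "retained", "tandem"])
    lrng = rngs["labels"]
    up_rate = genes["class"].map(cfg.de_rates).to_numpy(dtype=float)
    genes["de_up"] = lrng.random(n) < up_rate
    genes["de_down"] = (~genes["de_up"]) & (lrng.random(n) < cfg.de_down_rate)
    pairs = pd.DataFrame(pair_rows, columns=["dup1", "dup2", "true_ks"])
    truth = TruthTables(genes=genes, pairs=pairs)
    return SimulatedDataset(
        config=cfg,
        outgroup_genes=outgroup,
        ingroup_genes=ingroup,
        outgroup_cds=out_cds,
        ingroup_cds=in_cds,
        hits=hits,
        truth=truth,
    )


def simulate_family_ages(true_age: float, n_families: int, sd: float, rng: np.random.Generator):
    """Per-family median node ages scattered around the true WGD age.

    Normal(true_age, sd) truncated at zero by redraw; the per-family
    posterior-median scatter of the real meta-analysis is emulated by a
    single dispersion parameter.
    """
    from .dating import AgeSampleSet

    if n_families < 2:
        raise ValueError("need at least 2 families")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    ages = rng.normal(true_age, sd, size=n_families)
    while np.any(ages <= 0):
        bad = ages <= 0
        ages[bad] = rng.normal(true_age, sd, size=int(bad.sum()))
    return AgeSampleSet(node="wgd", medians=ages)


def simulate_coalescent_sample(n: int, theta: float, L: int, rng: np.random.Generator) -> np.ndarray:
    """Neutral coalescent haplotypes under the infinite-sites model.

    Standard n-coalescent: while k lineages remain, wait Exp(k(k-1)/2) and
    merge a uniform pair; mutations are Poisson(theta/2 * total branch
    length), each dropped on a branch with probability proportional to its
    length and assigned a distinct uniform column among the L sites.  Returns
    an (n, L) 0/1 matrix.
    """
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if theta <= 0 or L < 1:
        raise ValueError("theta must be > 0 and L >= 1")
    # active lineages: list of (node_id); descendants tracked as leaf sets
    desc: list[set[int]] = [{i} for i in range(n)]
    active = list(range(n))
    branch_len = {i: 0.0 for i in range(n)}  # length above each node
    next_node = n
    k = n
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        for node in active:
            branch_len[node] += t
        i, j = rng.choice(k, size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        a, b = active[i], active[j]
        desc.append(desc[a] | desc[b])
        branch_len[next_node] = 0.0
        active = [x for x in active if x not in (a, b)] + [next_node]
        next_node += 1
        k -= 1
    root = active[0]
    nodes = [x for x in branch_len if x != root]
    lens = np.array([branch_len[x] for x in nodes])
    total = float(lens.sum())
    S = int(rng.poisson(theta / 2.0 * total))
    S = min(S, L)
    mat = np.zeros((n, L), dtype=np.int8)
    if S > 0:
        cols = rng.choice(L, size=S, replace=False)
        branch_idx = rng.choice(len(nodes), size=S, p=lens / total)
        for col, bi in zip(cols, branch_idx):
            for leaf in desc[nodes[int(bi)]]:
                mat[leaf, int(col)] = 1
    return mat


def simulate_coverage_and_labels(
    genes: pd.DataFrame,
    n_samples: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene/sample ambiguous fractions and DE label table.

    ``genes`` must carry ``gene_id`` and ``class`` columns.  The label table
    assigns up-regulation per class with the configured true/false-positive
    rates and down-regulation at a class-independent base rate.
    """
    gm = config.coverage_model
    gene_ids = genes["gene_id"].tolist()
    n_g = len(gene_ids)
    absent = rng.random((n_g, n_samples)) < gm.absent_rate
    frac = rng.beta(gm.ambiguity_alpha, gm.ambiguity_beta, size=(n_g, n_samples))
    frac = np.where(absent, rng.uniform(0.5, 1.0, size=(n_g, n_samples)), frac)
    cov = pd.DataFrame(frac, index=gene_ids, columns=[f"sample{j:02d}" for j in range(n_samples)])
    cov.index.name = "gene_id"

    up_rate = genes["class"].map(config.de_rates).to_numpy(dtype=float)
    de_up = rng.random(n_g) < up_rate
    de_down = (~de_up) & (rng.random(n_g) < config.de_down_rate)
    direction = np.where(de_up, "up", np.where(de_down, "down", "none"))
    fdr = np.where(direction == "none", rng.uniform(0.05, 1.0, n_g), rng.uniform(0.0, 0.05, n_g))
    labels = pd.DataFrame({"gene_id": gene_ids, "direction": direction, "fdr": np.round(fdr, 5)})
    return cov, labels
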