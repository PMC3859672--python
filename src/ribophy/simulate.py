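"""Synthetic data generators emulating two-locus rRNA study designs.

The simulator evolves sites independently down a guide tree under a
GTR-style model whose stationary frequencies may differ per branch
("nonstationary" composition): a clade can be driven toward an AT-rich
equilibrium while the rest of the tree keeps a crown-like GC content.  That
is exactly the mechanism behind compositional attraction — unrelated
AT-shifted lineages come to resemble each other — so fixtures built here let
every downstream stage (QC, recoding, block filtering, NJ/bootstrap,
monophyly summaries, topology tests) be exercised without any database
download.

All generators are bit-reproducible given their profile and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import yaml
from scipy.linalg import expm

from .alignment import GroupMap, PartitionedAlignment, SeqRecord, write_fasta
from .likelihood import discrete_gamma_rates
from .trees import parse_newick, treeset_from_strings, write_newick, _below_sets

__all__ = [
    "CladeShift",
    "SimProfile",
    "freqs_from_gc",
    "simulate_alignment",
    "make_study_fixture",
    "make_treeset",
    "make_gc_pairs",
    "make_attraction_fixture",
    "attraction_experiment",
    "write_fixture",
]

_BASES = "ACGT"


def freqs_from_gc(gc: float) -> np.ndarray:
    """Symmetric ACGT frequencies with the requested GC fraction."""
    if not 0.0 < gc < 1.0:
        raise ValueError("GC fraction must lie strictly between 0 and 1")
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


@dataclass
class CladeShift:
    """Branch-local composition target applied to a whole subtree.

    Every branch whose descendant leaves all lie in ``taxa`` (stem included)
    evolves toward ``freqs`` and has its length multiplied by
    ``branch_scale``.
    """

    name: str
    taxa: frozenset[str]
    freqs: np.ndarray
    branch_scale: float = 1.0


@dataclass
class SimProfile:
    """Everything needed to simulate one partitioned alignment."""

    tree: str  # newick with branch lengths
    root_freqs: np.ndarray = field(default_factory=lambda: freqs_from_gc(0.54))
    exch: np.ndarray | None = None  # symmetric 4x4; None = equal rates
    gamma_alpha: float | None = 0.5
    ncat: int = 4
    partition_lengths: dict[str, int] = field(
        default_factory=lambda: {"ssu": 1400, "lsu": 2700}
    )
    shifts: list[CladeShift] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.root_freqs = np.asarray(self.root_freqs, dtype=float)
        if not np.isclose(self.root_freqs.sum(), 1.0) or np.any(self.root_freqs < 0):
            raise ValueError("root frequencies must be a simplex vector")
        for s in self.shifts:
            s.freqs = np.asarray(s.freqs, dtype=float)
            if not np.isclose(s.freqs.sum(), 1.0) or np.any(s.freqs < 0):
                raise ValueError(f"shift {s.name!r} frequencies must be a simplex vector")
        for L in self.partition_lengths.values():
            if L < 1:
                raise ValueError("partition lengths must be >= 1")


def _rate_matrix(exch: np.ndarray | None, freqs: np.ndarray) -> np.ndarray:
    k = freqs.size
    if exch is None:
        exch = np.ones((k, k)) - np.eye(k)
    q = exch * freqs[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(freqs * np.diag(q)).sum()
    return q / mu


def simulate_alignment(profile: SimProfile) -> PartitionedAlignment:
    """Simulate sequences down the guide tree, branch by branch.

    The root sequence is drawn from the root frequencies; along each branch
    sites evolve under P = exp(Q t) with Q built from the shared
    exchangeabilities and that branch's composition target, site rates drawn
    from a discrete Gamma.  Deterministic given (profile, seed).
    """
    rng = np.random.default_rng(profile.seed)
    tree = parse_newick(profile.tree)
    below = _below_sets(tree)

    def branch_model(node) -> tuple[np.ndarray, float]:
        for s in profile.shifts:
            if below[node] <= s.taxa:
                return s.freqs, s.branch_scale
        return profile.root_freqs, 1.0

    rates = (
        np.array([1.0])
        if profile.gamma_alpha is None
        else discrete_gamma_rates(profile.gamma_alpha, profile.ncat)
    )
    ncat = rates.size

    leaf_rows: dict[str, list[str]] = {
        leaf.taxon.label: [] for leaf in tree.leaf_node_iter()
    }
    partitions: dict[str, tuple[int, int]] = {}
    cursor = 0
    for part_name, length in profile.partition_lengths.items():
        partitions[part_name] = (cursor, cursor + length)
        cursor += length
        cats = rng.integers(0, ncat, size=length)
        states: dict[int, np.ndarray] = {
            id(tree.seed_node): rng.choice(4, size=length, p=profile.root_freqs)
        }
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            freqs, scale = branch_model(node)
            t = (node.edge.length or 0.0) * scale
            parent_states = states[id(node.parent_node)]
            child = parent_states.copy()
            if t > 0:
                q = _rate_matrix(profile.exch, freqs)
                for ci in range(ncat):
                    p = expm(q * t * rates[ci])
                    p = np.clip(p, 0.0, None)
                    p /= p.sum(axis=1, keepdims=True)
                    for s in range(4):
                        idx = np.flatnonzero((cats == ci) & (parent_states == s))
                        if idx.size:
                            child[idx] = rng.choice(4, size=idx.size, p=p[s])
            states[id(node)] = child
            if node.is_leaf():
                leaf_rows[node.taxon.label].append(
                    "".join(_BASES[s] for s in child)
                )
        # free internal states before the next partition
        states.clear()

    rows = {t: "".join(parts) for t, parts in leaf_rows.items()}
    return PartitionedAlignment(rows, "nt4", partitions)


# ---------------------------------------------------------------------------
# study-shaped fixtures


def _random_clade(labels: list[str], rng, blen_range=(0.02, 0.10)) -> str:
    """Random binary subtree over the labels, newick without the outer length."""
    nodes = [f"{lab}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(*blen_range, size=2)
        merged = f"({a}:{la:.4f},{b}:{lb:.4f})"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [merged]
    return nodes[0]


def make_study_fixture(
    n_crown: int = 8,
    n_rick: int = 6,
    n_mito: int = 4,
    n_outgroup: int = 3,
    seed: int = 0,
    stationary: bool = False,
    partition_lengths: dict[str, int] | None = None,
) -> tuple[list[SeqRecord], GroupMap, dendropy.Tree]:
    """Two-locus records over four clades with clade-specific GC content.

    The crown clade sits at ~54% rRNA GC, the Rickettsiales-like clade at
    ~50%, and the mitochondria-like clade at ~40% on branches three times
    longer; the outgroup subtends everything.  With ``stationary=True`` all
    clades share the root composition (for recovery experiments where the
    compositional confound must be off).  Sequence lengths default to
    1400 (SSU) and 2700 (LSU), passing the 1200/2000 length QC by design.
    """
    if min(n_crown, n_rick, n_mito, n_outgroup) < 1:
        raise ValueError("all clade sizes must be >= 1")
    rng = np.random.default_rng(seed)
    crown = [f"crown{i:02d}" for i in range(n_crown)]
    rick = [f"rick{i:02d}" for i in range(n_rick)]
    mito = [f"mito{i:02d}" for i in range(n_mito)]
    outg = [f"out{i:02d}" for i in range(n_outgroup)]

    newick = (
        "("
        + _random_clade(outg, rng) + ":0.30,"
        + "(" + _random_clade(crown, rng) + ":0.10,"
        + "(" + _random_clade(rick, rng) + ":0.08,"
        + _random_clade(mito, rng) + ":0.12):0.06):0.10);"
    )
    shifts = []
    if not stationary:
        shifts = [
            CladeShift("crown", frozenset(crown), freqs_from_gc(0.54)),
            CladeShift("rick", frozenset(rick), freqs_from_gc(0.50)),
            CladeShift("mito", frozenset(mito), freqs_from_gc(0.40), branch_scale=3.0),
        ]
    profile = SimProfile(
        tree=newick,
        root_freqs=freqs_from_gc(0.54),
        shifts=shifts,
        partition_lengths=partition_lengths or {"ssu": 1400, "lsu": 2700},
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    aln = simulate_alignment(profile)
    records: list[SeqRecord] = []
    for taxon in aln.taxa:
        for part in aln.partitions:
            start, stop = aln.partitions[part]
            records.append(
                SeqRecord(taxon, taxon, part, aln.rows[taxon][start:stop])
            )
    groups = GroupMap(
        groups={
            **{t: "crown" for t in crown},
            **{t: "rickettsiales_like" for t in rick},
            **{t: "mitochondria" for t in mito},
            **{t: "outgroup" for t in outg},
        },
        outgroup=set(outg),
        mitochondria=set(mito),
    )
    true_tree = parse_newick(newick)
    return records, groups, true_tree


def make_treeset(
    base: dendropy.Tree,
    group: set[str],
    target_freq: float,
    n: int,
    seed: int = 0,
) -> dendropy.TreeList:
    """Bootstrap-like tree set with a prescribed clade-monophyly frequency.

    Exactly ``round(target_freq * n)`` replicates keep the group intact; each
    of the rest relocates one group leaf onto an edge outside the group via a
    prune-and-regraft edit.  All replicates share the base leaf set.
    """
    leaves = {lf.taxon.label for lf in base.leaf_node_iter()}
    group = set(group)
    if not group <= leaves:
        raise ValueError(f"group members absent from base tree: {sorted(group - leaves)}")
    if not 0.0 <= target_freq <= 1.0:
        raise ValueError("target frequency must lie in [0, 1]")
    n_keep = int(round(target_freq * n))
    if n_keep < n and len(group) < 2:
        raise ValueError("cannot break monophyly of a single-member group")
    rng = np.random.default_rng(seed)
    base_newick = write_newick(base)
    texts: list[str] = []
    for rep in range(n):
        if rep < n_keep:
            texts.append(base_newick)
            continue
        tree = parse_newick(base_newick)
        below = _below_sets(tree)
        mover_label = sorted(group)[int(rng.integers(0, len(group)))]
        mover = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == mover_label
        )
        parent = mover.parent_node
        parent.remove_child(mover)
        tree.suppress_unifurcations()
        candidates = [
            nd
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None and not (below[nd] & group)
        ]
        dest = candidates[int(rng.integers(0, len(candidates)))]
        par = dest.parent_node
        graft = dendropy.Node()
        length = dest.edge.length
        par.remove_child(dest)
        par.add_child(graft)
        graft.add_child(dest)
        graft.add_child(mover)
        if length is not None:
            graft.edge.length = length / 2.0
            dest.edge.length = length / 2.0
        texts.append(write_newick(tree))
    return treeset_from_strings(texts)


def make_gc_pairs(
    n: int, slope: float, intercept: float, noise_sd: float, seed: int = 0
) -> np.ndarray:
    """(genomic GC, rRNA GC) pairs with a known linear relationship.

    Genomic GC is uniform on [0.3, 0.7]; rRNA GC adds Gaussian noise around
    the line and is clamped to the open unit interval.
    """
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.3, 0.7, size=n)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, size=n)
    eps = 1e-9
    y = np.clip(y, eps, 1.0 - eps)
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# compositional attraction experiment


def make_attraction_fixture(
    seed: int,
    n_sites: int = 600,
    base_gc: float = 0.55,
    shifted_gc: float = 0.15,
    stem: float = 0.5,
    internal: float = 0.03,
    tip: float = 0.05,
) -> tuple[PartitionedAlignment, dendropy.Tree, tuple[set[str], set[str]]]:
    """Eight taxa in four cherries; two non-sister cherries share a convergent
    AT-rich composition on stems of the same length as everyone else's.

    Because the four stems are equally long, any tendency of standard-coded
    inference to unite the two AT-rich cherries is compositional attraction,
    not long-branch attraction.  Returns the alignment, the true tree, and
    the artefactual split that unites the AT-rich cherries.
    """
    w, x, y, z = ["w1", "w2"], ["x1", "x2"], ["y1", "y2"], ["z1", "z2"]
    newick = (
        f"((w1:{tip},w2:{tip}):{stem},(x1:{tip},x2:{tip}):{stem},"
        f"((y1:{tip},y2:{tip}):{stem},(z1:{tip},z2:{tip}):{stem}):{internal});"
    )
    shifted = freqs_from_gc(shifted_gc)
    profile = SimProfile(
        tree=newick,
        root_freqs=freqs_from_gc(base_gc),
        gamma_alpha=None,
        partition_lengths={"all": n_sites},
        shifts=[
            CladeShift("w", frozenset(w), shifted),
            CladeShift("y", frozenset(y), shifted),
        ],
        seed=seed,
    )
    aln = simulate_alignment(profile)
    true_tree = parse_newick(newick)
    attract_split = (set(w + y), set(x + z))
    return aln, true_tree, attract_split


def attraction_experiment(
    n_seeds: int = 50,
    base_seed: int = 0,
    schemes: tuple[str, ...] = ("regular", "ry", "mk", "rymk"),
    **fixture_kwargs,
) -> dict[str, int]:
    """Count, per coding scheme, how many seeded fixtures make NJ unite the
    two convergently AT-rich cherries."""
    from .recoding import recode
    from .likelihood import nj_tree, pairwise_distance
    from .trees import bipartitions

    counts = {s: 0 for s in schemes}
    for i in range(n_seeds):
        aln, _, (side_a, _) = make_attraction_fixture(base_seed + i, **fixture_kwargs)
        leaves = frozenset(aln.taxa)
        anchor = min(leaves)
        canon = frozenset(side_a)
        if anchor in canon:
            canon = leaves - canon
        for scheme in schemes:
            coded = recode(aln, scheme)
            model = "jc4" if coded.alphabet == "nt4" else "cfn2"
            labels, dist = pairwise_distance(coded, model=model)
            tree = nj_tree(dist, labels)
            if canon in bipartitions(tree):
                counts[scheme] += 1
    return counts


def write_fixture(outdir, records, groups: GroupMap, true_tree, profile_info: dict) -> None:
    """Emit FASTA + taxon table + Newick truth + a provenance YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for locus in ("ssu", "lsu"):
        recs = [r for r in records if r.locus == locus]
        if recs:
            write_fasta(recs, outdir / f"{locus}.fasta")
    groups.to_tsv(outdir / "taxa.tsv")
    (outdir / "true_tree.nwk").write_text(write_newick(true_tree) + "\n")
    with open(outdir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(profile_info, fh, sort_keys=True)
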