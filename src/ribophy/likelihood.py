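"""k-state GTR+Gamma likelihood evaluation, NJ inference, bootstrap resampling,
and RELL-based KH/SH plus multiscale-bootstrap AU topology tests.

The engine evaluates per-site log-likelihoods by Felsenstein pruning under a
time-reversible model on 2 or 4 states with an optional discrete-Gamma rate
mixture.  Binary alphabets serve the RY/MK/RYMK recodings: an RYMK alignment
is scored as a two-state problem in which R and M map to one state and Y and
K to the other, so its log-likelihood decomposes exactly into the RY-half
plus the MK-half under a shared model.

Tree inference here is distance-based neighbor joining: it is the package's
desk-scale stand-in for heavy ML searches, which are delegated to an
external program through :func:`external_ml_adapter`.
"""

from __future__ import annotations

import shlex
import subprocess
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.special import gammainc, ndtr, ndtri
from scipy.stats import gamma as gamma_dist

from .alignment import PartitionedAlignment, write_phylip
from .trees import parse_newick, read_treeset

__all__ = [
    "GTRParams",
    "SiteLikelihoodMatrix",
    "TopologyTestResult",
    "discrete_gamma_rates",
    "site_log_likelihoods",
    "pairwise_distance",
    "nj_tree",
    "bootstrap_columns",
    "topology_tests",
    "ExternalMLConfig",
    "external_ml_adapter",
]

# residue -> state index per alignment alphabet; absent symbols are missing
CHAR_MAPS: dict[str, dict[str, int]] = {
    "nt4": {"A": 0, "C": 1, "G": 2, "T": 3},
    "ry2": {"R": 0, "Y": 1},
    "mk2": {"M": 0, "K": 1},
    "rymk2": {"R": 0, "Y": 1, "M": 0, "K": 1},
}


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability Gamma(alpha, 1/alpha) bins."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    edges = gamma_dist.ppf(np.linspace(0.0, 1.0, ncat + 1), a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, edges[1:] * alpha)
    lower = gammainc(alpha + 1.0, edges[:-1] * alpha)
    return (upper - lower) * ncat


@dataclass
class GTRParams:
    """Reversible k-state substitution model with optional Gamma rates.

    ``exch`` holds the symmetric exchangeabilities (diagonal ignored);
    ``freqs`` the stationary distribution.  The rate matrix is scaled to one
    expected substitution per unit branch length.
    """

    exch: np.ndarray
    freqs: np.ndarray
    gamma_alpha: float | None = None
    ncat: int = 4

    def __post_init__(self) -> None:
        self.exch = np.asarray(self.exch, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        k = self.freqs.size
        if self.exch.shape != (k, k):
            raise ValueError("exchangeability matrix shape must match frequency vector")
        if not np.allclose(self.exch, self.exch.T):
            raise ValueError("exchangeabilities must be symmetric")
        if np.any(self.freqs < 0) or not np.isclose(self.freqs.sum(), 1.0):
            raise ValueError("frequencies must be a simplex vector")
        off = self.exch[~np.eye(k, dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("exchangeabilities must be positive")
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma shape must be positive")

    @property
    def k(self) -> int:
        return self.freqs.size

    @classmethod
    def jc(cls, k: int = 4, gamma_alpha: float | None = None, ncat: int = 4) -> "GTRParams":
        """Equal-rates equal-frequencies model (Jukes-Cantor for k=4,
        Cavender-Farris-Neyman for k=2)."""
        exch = np.ones((k, k)) - np.eye(k)
        return cls(exch, np.full(k, 1.0 / k), gamma_alpha, ncat)

    def rate_matrix(self) -> np.ndarray:
        k = self.k
        q = self.exch * self.freqs[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.freqs * np.diag(q)).sum()
        return q / mu

    def _eig(self):
        # reversible Q symmetrised by sqrt(pi) similarity -> stable eigh
        d = np.sqrt(self.freqs)
        b = (d[:, None] * self.rate_matrix()) / d[None, :]
        w, u = np.linalg.eigh((b + b.T) / 2.0)
        v = u / d[:, None]
        vinv = u.T * d[None, :]
        return w, v, vinv

    def transition_matrix(self, t: float) -> np.ndarray:
        w, v, vinv = self._eig()
        return (v * np.exp(w * t)) @ vinv


@dataclass
class SiteLikelihoodMatrix:
    """Per-tree, per-site log-likelihoods (rows = candidate trees)."""

    tree_ids: list[str]
    values: np.ndarray  # (n_trees, n_sites)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.tree_ids):
            raise ValueError("matrix must be (n_trees, n_sites) with one id per row")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("site log-likelihoods must be finite")

    def totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for tid, row in zip(self.tree_ids, self.values):
                fh.write(tid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def _leaf_partials(aln: PartitionedAlignment, taxon: str, cmap: dict[str, int], k: int) -> np.ndarray:
    seq = aln.rows[taxon]
    out = np.ones((len(seq), k))
    for j, c in enumerate(seq):
        idx = cmap.get(c)
        if idx is not None:
            out[j, :] = 0.0
            out[j, idx] = 1.0
    return out


def site_log_likelihoods(
    tree: dendropy.Tree, aln: PartitionedAlignment, params: GTRParams
) -> np.ndarray:
    """Per-column log-likelihoods by Felsenstein pruning with per-node scaling.

    Gap ``-`` and missing ``?`` (and nucleotide ambiguity codes) contribute
    all-ones partials, so an all-missing column has likelihood 1.
    """
    cmap = CHAR_MAPS.get(aln.alphabet)
    if cmap is None:
        raise ValueError(f"no likelihood mapping for alphabet {aln.alphabet!r}")
    k_states = max(cmap.values()) + 1
    if k_states != params.k:
        raise ValueError(
            f"alphabet {aln.alphabet!r} needs a {k_states}-state model, got {params.k}-state"
        )
    leaf_names = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = leaf_names - set(aln.rows)
    if missing:
        raise ValueError(f"tree leaves absent from alignment: {sorted(missing)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")
    observed = np.zeros(params.k, dtype=bool)
    for name in leaf_names:
        for c in aln.rows[name]:
            idx = cmap.get(c)
            if idx is not None:
                observed[idx] = True
    if np.any(observed & (params.freqs == 0.0)):
        raise ValueError("stationary frequency of an observed state is zero")

    n_sites = aln.n_cols
    rates = (
        np.array([1.0])
        if params.gamma_alpha is None
        else discrete_gamma_rates(params.gamma_alpha, params.ncat)
    )
    w, v, vinv = params._eig()
    leaf_cache = {
        name: _leaf_partials(aln, name, cmap, params.k) for name in leaf_names
    }

    per_cat = np.empty((rates.size, n_sites))
    for ci, rate in enumerate(rates):
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros(n_sites)
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                partials[id(node)] = leaf_cache[node.taxon.label]
                continue
            acc = np.ones((n_sites, params.k))
            for child in node.child_nodes():
                t = (child.edge.length or 0.0) * rate
                p = (v * np.exp(w * t)) @ vinv
                acc *= partials.pop(id(child)) @ p.T
            mx = acc.max(axis=1)
            mx[mx == 0.0] = 1.0
            acc /= mx[:, None]
            logscale += np.log(mx)
            partials[id(node)] = acc
        root = partials[id(tree.seed_node)]
        site_l = root @ params.freqs
        per_cat[ci] = np.log(site_l) + logscale

    if rates.size == 1:
        return per_cat[0]
    m = per_cat.max(axis=0)
    return m + np.log(np.exp(per_cat - m).mean(axis=0))


# ---------------------------------------------------------------------------
# distances and neighbor joining

_DISTANCE_MODELS = ("p", "jc4", "cfn2")


def pairwise_distance(
    aln: PartitionedAlignment, model: str = "jc4", cap: float = 5.0
) -> tuple[list[str], np.ndarray]:
    """Pairwise distances; columns with a gap/missing symbol in either row of
    a pair are ignored for that pair.  Saturated distances beyond the model
    formula's domain are set to ``cap`` with a warning."""
    if model not in _DISTANCE_MODELS:
        raise ValueError(f"model must be one of {_DISTANCE_MODELS}")
    cmap = CHAR_MAPS.get(aln.alphabet)
    if cmap is None:
        raise ValueError(f"no distance mapping for alphabet {aln.alphabet!r}")
    k = max(cmap.values()) + 1
    if model == "cfn2" and k != 2:
        raise ValueError("cfn2 distances require a two-state alphabet")
    if model == "jc4" and k != 4:
        raise ValueError("jc4 distances require the nucleotide alphabet")
    taxa = aln.taxa
    enc = np.full((len(taxa), aln.n_cols), -1, dtype=np.int8)
    for i, t in enumerate(taxa):
        row = aln.rows[t]
        for j, c in enumerate(row):
            enc[i, j] = cmap.get(c, -1)
    n = len(taxa)
    dist = np.zeros((n, n))
    saturated = False
    for i in range(n):
        for j in range(i + 1, n):
            valid = (enc[i] >= 0) & (enc[j] >= 0)
            nv = int(valid.sum())
            if nv == 0:
                p = 0.0
            else:
                p = float(np.sum(enc[i, valid] != enc[j, valid])) / nv
            if model == "p":
                d = p
            elif model == "jc4":
                if p >= 0.75:
                    d, saturated = cap, True
                else:
                    d = -0.75 * np.log(1.0 - (4.0 / 3.0) * p)
            else:  # cfn2
                if p >= 0.5:
                    d, saturated = cap, True
                else:
                    d = -0.5 * np.log(1.0 - 2.0 * p)
            dist[i, j] = dist[j, i] = min(d, cap)
    if saturated:
        warnings.warn(f"saturated distances capped at {cap}", stacklevel=2)
    return taxa, dist


def nj_tree(dist: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; negative branch lengths are clamped to 0.

    Ties in the Q criterion break to the smallest (i, j) index pair so the
    result is deterministic.
    """
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix must be square and match the labels")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with a zero diagonal")
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes = [f"{lab}" for lab in labels]
    active = list(range(n))

    def _join(i: int, j: int, li: float, lj: float) -> str:
        return f"({nodes[i]}:{max(li, 0.0):.10g},{nodes[j]}:{max(lj, 0.0):.10g})"

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        new_label = _join(i, j, li, lj)
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_d])
        d = np.hstack([d, np.append(new_d, 0.0)[:, None]])
        nodes.append(new_label)
        active = [x for x in active if x not in (i, j)] + [d.shape[0] - 1]

    if len(active) == 2:
        i, j = active
        newick = f"({nodes[i]}:{d[i, j] / 2:.10g},{nodes[j]}:{d[i, j] / 2:.10g});"
    else:
        i, j, k = active
        li = max(0.5 * (d[i, j] + d[i, k] - d[j, k]), 0.0)
        lj = max(0.5 * (d[i, j] + d[j, k] - d[i, k]), 0.0)
        lk = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
        newick = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g},{nodes[k]}:{lk:.10g});"
    tree = parse_newick(newick)
    tree.is_rooted = False
    return tree


def bootstrap_columns(
    aln: PartitionedAlignment, n_reps: int, seed: int
) -> list[PartitionedAlignment]:
    """Seeded nonparametric bootstrap: each replicate draws n_cols columns
    with replacement from the whole alignment (no partition stratification)."""
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    n = aln.n_cols
    reps = []
    for _ in range(n_reps):
        idx = rng.integers(0, n, size=n)
        rows = {t: "".join(seq[j] for j in idx) for t, seq in aln.rows.items()}
        reps.append(PartitionedAlignment(rows, aln.alphabet, {"all": (0, n)}))
    return reps


# ---------------------------------------------------------------------------
# topology tests

DEFAULT_AU_SCALES = tuple(np.round(np.linspace(0.5, 1.4, 10), 3))


@dataclass
class TopologyTestResult:
    """Per-tree KH / SH / AU p-values with rejection flags at ``alpha``."""

    tree_ids: list[str]
    p_kh: dict[str, float] = field(default_factory=dict)
    p_sh: dict[str, float] = field(default_factory=dict)
    p_au: dict[str, float] = field(default_factory=dict)
    au_flags: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05

    def rejected(self, method: str) -> dict[str, bool]:
        table = {"kh": self.p_kh, "sh": self.p_sh, "au": self.p_au}[method]
        return {tid: p < self.alpha for tid, p in table.items()}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("tree\tp_kh\tp_sh\tp_au\tau_flag\n")
            for tid in self.tree_ids:
                fh.write(
                    f"{tid}\t{self.p_kh.get(tid, float('nan')):.6g}"
                    f"\t{self.p_sh.get(tid, float('nan')):.6g}"
                    f"\t{self.p_au.get(tid, float('nan')):.6g}"
                    f"\t{self.au_flags.get(tid, '')}\n"
                )


def _rell_sums(values: np.ndarray, n_draw: int, n_rell: int, rng) -> np.ndarray:
    """(n_trees, n_rell) resampled log-likelihood sums over n_draw sites.

    Sampling sites with replacement is realised as multinomial column
    weights, which turns each replicate into one matrix-vector product.
    """
    n_sites = values.shape[1]
    counts = rng.multinomial(n_draw, np.full(n_sites, 1.0 / n_sites), size=n_rell)
    return values @ counts.T.astype(float)


def _au_pvalue(
    values: np.ndarray, t: int, scales, n_rell: int, rng
) -> tuple[float, str]:
    """Multiscale-bootstrap AU p-value for tree ``t`` being the best tree."""
    n_sites = values.shape[1]
    rs, bps = [], []
    for r in scales:
        m = max(int(round(r * n_sites)), 1)
        sums = _rell_sums(values, m, n_rell, rng)
        best = sums.argmax(axis=0)
        bps.append(float(np.mean(best == t)))
        rs.append(m / n_sites)
    rs = np.asarray(rs)
    bps = np.asarray(bps)
    if np.all(bps <= 0.0):
        return 0.0, "degenerate_bp0"
    if np.all(bps >= 1.0):
        return 1.0, "degenerate_bp1"
    usable = (bps > 0.0) & (bps < 1.0)
    if usable.sum() < 3:
        return float("nan"), "too_few_scales"
    r_u, bp_u = rs[usable], bps[usable]
    z = ndtri(1.0 - bp_u)
    x = np.column_stack([np.sqrt(r_u), 1.0 / np.sqrt(r_u)])
    phi = np.exp(-0.5 * z**2) / np.sqrt(2.0 * np.pi)
    wts = n_rell * phi**2 / (bp_u * (1.0 - bp_u))
    sw = np.sqrt(wts)
    coef, *_ = np.linalg.lstsq(x * sw[:, None], z * sw, rcond=None)
    dd, cc = coef
    return float(np.clip(1.0 - ndtr(dd - cc), 0.0, 1.0)), "ok"


def topology_tests(
    matrix: SiteLikelihoodMatrix,
    methods: set[str] = frozenset({"kh", "sh", "au"}),
    n_rell: int = 1000,
    scales=DEFAULT_AU_SCALES,
    seed: int = 0,
    alpha: float = 0.05,
) -> TopologyTestResult:
    """KH and SH tests by RELL resampling plus the multiscale-bootstrap AU test.

    KH compares each tree against the maximum-likelihood tree with centered
    RELL replicates of the log-likelihood difference; SH compares against the
    per-replicate maximum of the centered sums, which guarantees the best
    tree is never rejected.  AU fits z(r) = d*sqrt(r) + c/sqrt(r) to probit
    bootstrap proportions across scales and reports p = 1 - Phi(d - c);
    when fewer than 3 scales are informative it falls back to the KH p-value
    with a flag.
    """
    values = matrix.values
    n_trees, n_sites = values.shape
    if n_trees < 2:
        raise ValueError("topology tests need at least two trees")
    if n_sites < 10:
        raise ValueError("topology tests need at least 10 sites")
    if n_rell < 100:
        warnings.warn("n_rell < 100 gives very coarse p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    result = TopologyTestResult(list(matrix.tree_ids), alpha=alpha)

    totals = values.sum(axis=1)
    best = int(totals.argmax())
    need_kh = "kh" in methods or "au" in methods  # AU may fall back to KH
    if need_kh or "sh" in methods:
        sums = _rell_sums(values, n_sites, n_rell, rng)
    if need_kh:
        for t, tid in enumerate(matrix.tree_ids):
            delta = totals[best] - totals[t]
            diffs = sums[best] - sums[t]
            centered = diffs - diffs.mean()
            result.p_kh[tid] = float(np.mean(centered >= delta))
    if "sh" in methods:
        centered = sums - sums.mean(axis=1, keepdims=True)
        maxima = centered.max(axis=0)
        for t, tid in enumerate(matrix.tree_ids):
            delta = totals[best] - totals[t]
            result.p_sh[tid] = float(np.mean(maxima - centered[t] >= delta))
    if "au" in methods:
        for t, tid in enumerate(matrix.tree_ids):
            p, flag = _au_pvalue(values, t, scales, n_rell, rng)
            if flag == "too_few_scales":
                p = result.p_kh[tid]
                flag = "kh_fallback"
            result.p_au[tid] = p
            result.au_flags[tid] = flag
    return result


# ---------------------------------------------------------------------------
# external maximum-likelihood adapter

@dataclass
class ExternalMLConfig:
    """Contract for delegating tree search to an external ML program.

    ``command`` is a shell-free template; the placeholders ``{phylip}``,
    ``{workdir}``, ``{model}``, ``{bootstraps}`` and ``{seed}`` are expanded
    before execution.  ``best_tree`` / ``bootstrap_trees`` name the Newick
    files the command is expected to produce inside ``workdir``.
    """

    command: str
    best_tree: str
    bootstrap_trees: str
    model: str = "GTRGAMMA"
    bootstraps: int = 1000
    seed: int = 12345


def external_ml_adapter(
    aln: PartitionedAlignment, config: ExternalMLConfig, workdir
) -> tuple[dendropy.Tree, dendropy.TreeList]:
    """Write the alignment in relaxed PHYLIP, invoke the external command,
    and parse the best tree plus bootstrap trees it produced."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    phylip = workdir / "alignment.phy"
    write_phylip(aln, phylip)
    argv = [
        a.format(
            phylip=str(phylip),
            workdir=str(workdir),
            model=config.model,
            bootstraps=config.bootstraps,
            seed=config.seed,
        )
        for a in shlex.split(config.command)
    ]
    try:
        proc = subprocess.run(argv, capture_output=True, text=True)
    except FileNotFoundError as exc:
        raise RuntimeError(
            f"external ML executable {argv[0]!r} not found on PATH; "
            "install it or point the command template at its location"
        ) from exc
    if proc.returncode != 0:
        raise RuntimeError(
            f"external ML command failed (exit {proc.returncode}): {proc.stderr.strip()}"
        )
    best_path = workdir / config.best_tree
    boots_path = workdir / config.bootstrap_trees
    if not best_path.exists() or not boots_path.exists():
        raise RuntimeError(
            f"external ML command produced no {config.best_tree!r} / "
            f"{config.bootstrap_trees!r} in {workdir}"
        )
    best = parse_newick(best_path.read_text())
    boots = read_treeset(boots_path)
    return best, boots
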