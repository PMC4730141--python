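"""Likelihood machinery on a fixed rooted tree.

GTR nucleotide substitution model with discrete-gamma rate variation and
an invariant-sites class, Felsenstein pruning log-likelihood, marginal
(maximum a posteriori) ancestral sequence reconstruction, maximum-
likelihood pairwise distances with neighbor joining, column-resampling
bootstrap support, and numerical model fitting.

The model is nucleotide-level; ancestral codon sequences are assembled
from per-site MAP bases afterwards, with a deterministic repair step for
the rare case where the three independently most probable bases spell a
stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from scipy import linalg, optimize, stats
from skbio import DistanceMatrix
from skbio.tree import nj

from .alignment import CodonAlignment
from .genetics import NUCLEOTIDES, GeneticCode, standard_code
from .phylo import label_internal_nodes, node_name, tree_from_newick

BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}
#: order of the six GTR exchangeabilities
EXCHANGEABILITY_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))


# ---------------------------------------------------------------------------
# substitution model


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR + discrete-gamma + invariant-sites nucleotide model.

    ``exchangeabilities`` follow the order AC, AG, AT, CG, CT, GT and are
    identifiable up to a constant (GT is conventionally fixed to 1 when
    fitting).  The rate matrix is scaled to one expected substitution
    per site per unit branch length; the discrete-gamma category rates
    (equal-probability bins, bin-mean rates) average to 1, and with an
    invariant class the variable-class rates are rescaled so the overall
    mean rate stays 1.
    """

    exchangeabilities: Tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_frequencies: Tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: Optional[float] = None
    n_rate_categories: int = 4
    p_invariant: float = 0.0

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6:
            raise ValueError("need 6 exchangeabilities (AC, AG, AT, CG, CT, GT)")
        if any(x < 0 for x in self.exchangeabilities):
            raise ValueError("exchangeabilities must be nonnegative")
        if len(self.base_frequencies) != 4:
            raise ValueError("need 4 base frequencies (A, C, G, T)")
        if abs(sum(self.base_frequencies) - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if not 0.0 <= self.p_invariant < 1.0:
            raise ValueError("p_invariant must be in [0, 1)")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    def rate_matrix(self) -> np.ndarray:
        """Scaled GTR generator Q with -sum(pi_i * Q_ii) = 1."""
        pi = np.asarray(self.base_frequencies)
        q = np.zeros((4, 4))
        for (a, b), s in zip(EXCHANGEABILITY_PAIRS, self.exchangeabilities):
            i, j = BASE_INDEX[a], BASE_INDEX[b]
            q[i, j] = s * pi[j]
            q[j, i] = s * pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        return q / mu

    def gamma_category_rates(self) -> np.ndarray:
        """Mean rates of the equal-probability discrete-gamma bins (mean 1)."""
        if self.gamma_shape is None:
            return np.array([1.0])
        a = self.gamma_shape
        k = self.n_rate_categories
        edges = stats.gamma.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        # E[X; X <= q] for Gamma(a, 1/a) is CDF of Gamma(a+1, 1/a)
        mass = stats.gamma.cdf(edges, a + 1, scale=1.0 / a)
        rates = k * np.diff(mass)
        return rates

    def rate_mixture(self) -> Tuple[np.ndarray, np.ndarray]:
        """(weights, rates) over the invariant class and gamma categories.

        The mixture mean rate is 1, so branch lengths remain expected
        substitutions per site.
        """
        gamma_rates = self.gamma_category_rates()
        p_inv = self.p_invariant
        if p_inv > 0:
            weights = np.concatenate([[p_inv], np.full(len(gamma_rates), (1 - p_inv) / len(gamma_rates))])
            rates = np.concatenate([[0.0], gamma_rates / (1 - p_inv)])
        else:
            weights = np.full(len(gamma_rates), 1.0 / len(gamma_rates))
            rates = gamma_rates
        return weights, rates

    def transition_matrices(self, t: float) -> List[np.ndarray]:
        """P(t * rate) for every mixture category (uses the GTR spectrum)."""
        evals, evecs, inv = _gtr_spectrum(self)
        _, rates = self.rate_mixture()
        out = []
        for r in rates:
            p = (evecs * np.exp(evals * t * r)) @ inv
            out.append(np.clip(p, 0.0, None))
        return out


def _gtr_spectrum(model: SubstitutionModel) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of Q via the pi-symmetrized form (real spectrum)."""
    q = model.rate_matrix()
    pi = np.asarray(model.base_frequencies)
    d = np.sqrt(pi)
    sym = (q * d[:, None]) / d[None, :]
    evals, u = np.linalg.eigh((sym + sym.T) / 2.0)
    evecs = u / d[:, None]
    inv = u.T * d[None, :]
    return evals, evecs, inv


# ---------------------------------------------------------------------------
# tree indexing and site patterns


class _TreeIndex:
    """Array view of a rooted dendropy tree in postorder."""

    def __init__(self, tree: dendropy.Tree):
        label_internal_nodes(tree)
        self.nodes: List[dendropy.Node] = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.names = [node_name(n) for n in self.nodes]
        self.parent = np.full(len(self.nodes), -1)
        self.lengths = np.zeros(len(self.nodes))
        self.children: List[List[int]] = [[] for _ in self.nodes]
        for i, n in enumerate(self.nodes):
            if n.parent_node is not None:
                p = self.index[id(n.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                bl = n.edge.length if n.edge.length is not None else 0.0
                if bl < 0:
                    raise ValueError(f"negative branch length {bl} above {self.names[i]!r}")
                self.lengths[i] = bl
        self.root = len(self.nodes) - 1
        self.is_leaf = np.array([n.is_leaf() for n in self.nodes])


def _site_matrix(alignment: CodonAlignment, leaf_names: Sequence[str]) -> np.ndarray:
    """Integer site matrix (leaves x nucleotide sites); -1 = ambiguous/gap."""
    rows = []
    for name in leaf_names:
        if name not in alignment.sequences:
            raise KeyError(f"tree leaf {name!r} has no row in the alignment")
        rows.append([BASE_INDEX.get(ch, -1) for ch in alignment.sequences[name]])
    return np.asarray(rows, dtype=np.int64)


def _compress_patterns(sites: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns, their counts, and pattern index per site."""
    patterns, inverse, counts = np.unique(sites, axis=1, return_inverse=True, return_counts=True)
    return patterns, counts, inverse


def _leaf_partials(pattern_col: np.ndarray) -> np.ndarray:
    """(4, n_patterns) indicator partials; ambiguity -> all ones."""
    n = len(pattern_col)
    part = np.zeros((4, n))
    known = pattern_col >= 0
    part[:, ~known] = 1.0
    part[pattern_col[known], np.nonzero(known)[0]] = 1.0
    return part


# ---------------------------------------------------------------------------
# pruning likelihood


def _category_partials(
    ti: _TreeIndex,
    patterns: np.ndarray,
    leaf_row: Dict[int, int],
    pmats: List[List[np.ndarray]],
    n_cats: int,
) -> Tuple[List[List[np.ndarray]], List[np.ndarray]]:
    """Postorder conditional likelihoods per category, with log scaling.

    Returns per-category per-node (4, n_patterns) partials and a
    per-category (n_nodes, n_patterns) log-scale array giving the scale
    accumulated within each node's subtree.
    """
    n_pat = patterns.shape[1]
    partials: List[List[Optional[np.ndarray]]] = [[None] * len(ti.nodes) for _ in range(n_cats)]
    scales = [np.zeros((len(ti.nodes), n_pat)) for _ in range(n_cats)]
    for c in range(n_cats):
        for i in range(len(ti.nodes)):
            if ti.is_leaf[i]:
                partials[c][i] = _leaf_partials(patterns[leaf_row[i]])
                continue
            acc = np.ones((4, n_pat))
            sc = np.zeros(n_pat)
            for ch in ti.children[i]:
                acc *= pmats[ch][c] @ partials[c][ch]
                sc += scales[c][ch]
            mx = acc.max(axis=0)
            mx = np.where(mx > 0, mx, 1.0)
            scales[c][i] = sc + np.log(mx)
            partials[c][i] = acc / mx
    return partials, scales  # type: ignore[return-value]


def _prepare(tree: dendropy.Tree, alignment: CodonAlignment, model: SubstitutionModel):
    ti = _TreeIndex(tree)
    leaf_names = [ti.names[i] for i in range(len(ti.nodes)) if ti.is_leaf[i]]
    sites = _site_matrix(alignment, leaf_names)
    patterns, counts, inverse = _compress_patterns(sites)
    leaf_row = {
        i: leaf_names.index(ti.names[i]) for i in range(len(ti.nodes)) if ti.is_leaf[i]
    }
    weights, _ = model.rate_mixture()
    pmats = [model.transition_matrices(ti.lengths[i]) for i in range(len(ti.nodes))]
    return ti, patterns, counts, inverse, leaf_row, weights, pmats


def log_likelihood(tree: dendropy.Tree, alignment: CodonAlignment, model: SubstitutionModel) -> float:
    """Felsenstein pruning log-likelihood (natural log) of the alignment."""
    ti, patterns, counts, _, leaf_row, weights, pmats = _prepare(tree, alignment, model)
    pi = np.asarray(model.base_frequencies)
    partials, scales = _category_partials(ti, patterns, leaf_row, pmats, len(weights))
    # log-likelihood per pattern: logsumexp over categories
    per_cat = np.stack(
        [
            np.log(np.maximum(pi @ partials[c][ti.root], 1e-300)) + scales[c][ti.root]
            for c in range(len(weights))
        ]
    )
    logw = np.log(weights)[:, None]
    site_ll = _logsumexp(per_cat + logw, axis=0)
    return float((site_ll * counts).sum())


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


# ---------------------------------------------------------------------------
# marginal ancestral state reconstruction


@dataclass
class AncestralStates:
    """Marginal posteriors and MAP sequences for internal nodes.

    ``posteriors[label]`` is an (n_sites, 4) array over A, C, G, T;
    ``map_sequences`` are nucleotide strings; ``codon_sequences`` are the
    MAP bases assembled into codons with stop codons repaired to the
    highest-posterior sense codon (deterministic search order).
    """

    node_labels: List[str]
    posteriors: Dict[str, np.ndarray]
    map_sequences: Dict[str, str]
    codon_sequences: Dict[str, str] = field(default_factory=dict)
    repaired_stops: Dict[str, List[int]] = field(default_factory=dict)


def marginal_asr(
    tree: dendropy.Tree,
    alignment: CodonAlignment,
    model: SubstitutionModel,
    code: Optional[GeneticCode] = None,
) -> AncestralStates:
    """Marginal (empirical Bayes) ancestral reconstruction at every internal node.

    Posterior at a node is proportional to the partial likelihood of the
    data below it times the partial likelihood of everything above it
    (computed by a preorder "outside" pass), mixture-weighted over rate
    categories.  MAP ties break by the fixed base order A < C < G < T.
    """
    if code is None:
        code = standard_code()
    ti, patterns, counts, inverse, leaf_row, weights, pmats = _prepare(tree, alignment, model)
    pi = np.asarray(model.base_frequencies)
    n_cats = len(weights)
    n_pat = patterns.shape[1]
    below, sub_scale = _category_partials(ti, patterns, leaf_row, pmats, n_cats)

    # outside pass: above[c][node] (4, n_pat) with its own log scale
    above: List[List[Optional[np.ndarray]]] = [[None] * len(ti.nodes) for _ in range(n_cats)]
    ascale = [np.zeros((len(ti.nodes), n_pat)) for _ in range(n_cats)]
    for c in range(n_cats):
        above[c][ti.root] = np.tile(pi[:, None], (1, n_pat))
    for i in reversed(range(len(ti.nodes))):  # preorder = reversed postorder
        for ch in ti.children[i]:
            for c in range(n_cats):
                msg = above[c][i].copy()
                sc = ascale[c][i].copy()
                for sib in ti.children[i]:
                    if sib == ch:
                        continue
                    msg = msg * (pmats[sib][c] @ below[c][sib])
                    sc = sc + sub_scale[c][sib]
                res = pmats[ch][c].T @ msg
                mx = res.max(axis=0)
                mx = np.where(mx > 0, mx, 1.0)
                above[c][ch] = res / mx
                ascale[c][ch] = sc + np.log(mx)

    node_labels: List[str] = []
    posteriors: Dict[str, np.ndarray] = {}
    map_sequences: Dict[str, str] = {}
    n_sites = len(inverse)
    for i in range(len(ti.nodes)):
        if ti.is_leaf[i]:
            continue
        logjoint = np.stack(
            [
                np.log(np.maximum(above[c][i] * below[c][i], 1e-300))
                + (ascale[c][i] + sub_scale[c][i])[None, :]
                + np.log(weights[c])
                for c in range(n_cats)
            ]
        )  # (cats, 4, n_pat)
        log_state = _logsumexp(logjoint, axis=0)  # (4, n_pat)
        log_state -= log_state.max(axis=0, keepdims=True)
        post = np.exp(log_state)
        post /= post.sum(axis=0, keepdims=True)
        per_site = post[:, inverse].T  # (n_sites, 4)
        label = ti.names[i]
        node_labels.append(label)
        posteriors[label] = per_site
        map_idx = per_site.argmax(axis=1)  # first max -> A<C<G<T tie-break
        map_sequences[label] = "".join(NUCLEOTIDES[j] for j in map_idx)

    states = AncestralStates(node_labels, posteriors, map_sequences)
    _assemble_codons(states, code)
    return states


def _assemble_codons(states: AncestralStates, code: GeneticCode) -> None:
    """MAP bases -> codon sequences; stop codons repaired deterministically.

    A stop codon in the assembled sequence is replaced by the sense codon
    with the highest product of per-base posteriors (ties broken by
    alphabetical codon order).
    """
    for label in states.node_labels:
        seq = states.map_sequences[label]
        post = states.posteriors[label]
        codons: List[str] = []
        repaired: List[int] = []
        for j in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[j : j + 3]
            if code.is_stop(codon):
                best = None
                best_score = -1.0
                for cand in code.sense_codons():
                    score = (
                        post[j, BASE_INDEX[cand[0]]]
                        * post[j + 1, BASE_INDEX[cand[1]]]
                        * post[j + 2, BASE_INDEX[cand[2]]]
                    )
                    if score > best_score + 1e-15:
                        best, best_score = cand, score
                codon = best or "AAA"
                repaired.append(j // 3 + 1)
            codons.append(codon)
        states.codon_sequences[label] = "".join(codons)
        if repaired:
            states.repaired_stops[label] = repaired


# ---------------------------------------------------------------------------
# pairwise ML distances, NJ, bootstrap


def _pair_distance(
    sx: np.ndarray, sy: np.ndarray, model: SubstitutionModel, t_max: float = 20.0
) -> float:
    """ML distance between two site vectors under the mixture model."""
    mask = (sx >= 0) & (sy >= 0)
    x, y = sx[mask], sy[mask]
    if len(x) == 0 or np.all(x == y):
        return 0.0
    pairs, counts = np.unique(np.stack([x, y]), axis=1, return_counts=True)
    pi = np.asarray(model.base_frequencies)
    weights, rates = model.rate_mixture()
    evals, evecs, inv = _gtr_spectrum(model)

    def neg_ll(t: float) -> float:
        lik = np.zeros(pairs.shape[1])
        for w, r in zip(weights, rates):
            p = (evecs * np.exp(evals * t * r)) @ inv
            lik += w * np.maximum(p[pairs[0], pairs[1]], 1e-300)
        return -float((counts * np.log(pi[pairs[0]] * lik)).sum())

    res = optimize.minimize_scalar(neg_ll, bounds=(1e-8, t_max), method="bounded")
    return float(res.x)


def ml_distance_matrix(alignment: CodonAlignment, model: SubstitutionModel) -> Tuple[np.ndarray, List[str]]:
    """Symmetric matrix of pairwise maximum-likelihood distances."""
    ids = alignment.ids()
    sites = _site_matrix(alignment, ids)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_distance(sites[i], sites[j], model)
    return d, ids


def build_nj_tree(alignment: CodonAlignment, model: SubstitutionModel) -> dendropy.Tree:
    """Neighbor-joining tree from pairwise ML distances, midpoint-rooted.

    Negative NJ branch lengths are clamped to zero.  With fewer than 3
    sequences no tree can be built.
    """
    if alignment.n_rows < 3:
        raise ValueError("need at least 3 sequences for a tree")
    d, ids = ml_distance_matrix(alignment, model)
    dm = DistanceMatrix(d, ids)
    sk_tree = nj(dm)
    tree = tree_from_newick(str(sk_tree))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    tree.reroot_at_midpoint(update_bipartitions=False)
    label_internal_nodes(tree, force=True)
    return tree


def tree_splits(tree: dendropy.Tree) -> Dict[frozenset, float]:
    """Non-trivial splits of the unrooted tree as canonical leaf-name sets."""
    leaves = frozenset(node_name(l) for l in tree.leaf_node_iter())
    ref = min(leaves)
    splits = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(node_name(l) for l in node.leaf_iter())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return {s: 0.0 for s in splits}


def bootstrap_support(
    alignment: CodonAlignment,
    model: SubstitutionModel,
    n_reps: int = 100,
    seed: Optional[int] = None,
) -> Dict[frozenset, float]:
    """Column-resampling bootstrap support (%) for the NJ point-estimate splits.

    Nucleotide columns are resampled with replacement; an NJ tree is
    rebuilt per replicate and each split of the point-estimate tree is
    scored by the percentage of replicate trees containing it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = build_nj_tree(alignment, model)
    supports = {s: 0 for s in tree_splits(point)}
    ids = alignment.ids()
    seq_len = len(alignment.sequences[ids[0]])
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = np.sort(rng.integers(0, seq_len, size=seq_len))
        rows = {rid: "".join(alignment.sequences[rid][c] for c in cols) for rid in ids}
        rep_tree = build_nj_tree(CodonAlignment(rows), model)
        rep_splits = tree_splits(rep_tree)
        for s in supports:
            if s in rep_splits:
                supports[s] += 1
    return {s: 100.0 * c / n_reps for s, c in supports.items()}


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class FitResult:
    model: SubstitutionModel
    log_likelihood: float
    converged: bool


def empirical_frequencies(alignment: CodonAlignment) -> Tuple[float, ...]:
    counts = np.zeros(4)
    for seq in alignment.sequences.values():
        for ch in seq:
            if ch in BASE_INDEX:
                counts[BASE_INDEX[ch]] += 1
    if counts.sum() == 0:
        raise ValueError("alignment contains no unambiguous bases")
    return tuple(counts / counts.sum())


def fit_model(
    alignment: CodonAlignment,
    tree: dendropy.Tree,
    gamma: bool = True,
    invariant: bool = True,
    n_rate_categories: int = 4,
    start: Optional[SubstitutionModel] = None,
) -> FitResult:
    """Fit GTR(+G+I) parameters by bounded quasi-Newton on the pruning likelihood.

    Base frequencies are taken as empirical; the five free
    exchangeabilities (GT fixed at 1), the gamma shape, and the invariant
    proportion are optimized on transformed (log / logit) scales.
    """
    freqs = empirical_frequencies(alignment)

    def unpack(x: np.ndarray) -> SubstitutionModel:
        ex = list(np.exp(x[:5])) + [1.0]
        shape = float(np.exp(x[5])) if gamma else None
        p_inv = float(1.0 / (1.0 + np.exp(-x[6]))) * 0.99 if invariant else 0.0
        return SubstitutionModel(
            exchangeabilities=tuple(ex),
            base_frequencies=freqs,
            gamma_shape=shape,
            n_rate_categories=n_rate_categories,
            p_invariant=p_inv,
        )

    def neg_ll(x: np.ndarray) -> float:
        try:
            return -log_likelihood(tree, alignment, unpack(x))
        except (ValueError, FloatingPointError):
            return 1e12

    if start is not None:
        ex = np.asarray(start.exchangeabilities, dtype=float)
        ex = ex / ex[5]
        x0 = np.concatenate(
            [
                np.log(np.maximum(ex[:5], 1e-6)),
                [np.log(start.gamma_shape or 1.0)],
                [np.log(max(start.p_invariant, 1e-3) / max(1 - start.p_invariant, 1e-3))],
            ]
        )
    else:
        x0 = np.zeros(7)
        x0[6] = -2.0
    bounds = [(-7, 7)] * 5 + [(np.log(0.05), np.log(20.0)), (-8, 4)]
    res = optimize.minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds)
    return FitResult(model=unpack(res.x), log_likelihood=-float(res.fun), converged=bool(res.success))
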