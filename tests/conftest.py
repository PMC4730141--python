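"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by brute force
(exhaustive enumeration, closed forms) so that the package's optimized
implementations are checked against independent computations.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest

from hyscav.genetics import NUCLEOTIDES, GeneticCode, standard_code


@pytest.fixture(scope="session")
def code() -> GeneticCode:
    return standard_code()


# ---------------------------------------------------------------------------
# NG86 pathway oracle: literal permutation enumerator


def ng_diff_oracle(codon_a: str, codon_b: str, code: GeneticCode):
    """Average (Sd, Nd) over all stop-free mutational pathways.

    Walks every permutation of the differing positions recursively and
    classifies each single-base step by translating the intermediate
    codons; returns (nan, nan, False) when every pathway hits a stop.
    """
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    totals: List[Tuple[int, int]] = []

    def walk(current: str, remaining: List[int], syn: int, nonsyn: int) -> None:
        if not remaining:
            totals.append((syn, nonsyn))
            return
        for pos in remaining:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                continue
            step_syn = code.translate_codon(nxt) == code.translate_codon(current)
            walk(
                nxt,
                [p for p in remaining if p != pos],
                syn + int(step_syn),
                nonsyn + int(not step_syn),
            )

    walk(codon_a, diffs, 0, 0)
    if not totals:
        return float("nan"), float("nan"), False
    s = sum(t[0] for t in totals) / len(totals)
    n = sum(t[1] for t in totals) / len(totals)
    return s, n, True


# ---------------------------------------------------------------------------
# pruning-likelihood oracle: exhaustive sum over ancestral assignments


def likelihood_enumeration_oracle(tree, alignment, model) -> float:
    """Total log-likelihood by brute-force summation over internal states.

    Enumerates every assignment of A/C/G/T to every internal node and
    sums the joint probabilities, mixed over the model's rate
    categories.  Only feasible for tiny trees; serves as the oracle for
    the pruning algorithm.
    """
    from hyscav.ancestral import BASE_INDEX, _gtr_spectrum, _TreeIndex

    ti = _TreeIndex(tree)
    pi = np.asarray(model.base_frequencies)
    weights, rates = model.rate_mixture()
    evals, evecs, inv = _gtr_spectrum(model)

    def pmat(t: float) -> np.ndarray:
        return (evecs * np.exp(evals * t)) @ inv

    internal = [i for i in range(len(ti.nodes)) if not ti.is_leaf[i]]
    leaves = [i for i in range(len(ti.nodes)) if ti.is_leaf[i]]
    seqs = {i: alignment.sequences[ti.names[i]] for i in leaves}
    n_sites = len(next(iter(seqs.values())))

    assignments = np.array(
        list(itertools.product(range(4), repeat=len(internal))), dtype=int
    )  # (n_assign, n_internal)
    pos_of = {node: k for k, node in enumerate(internal)}

    total = 0.0
    for site in range(n_sites):
        leaf_state = {i: BASE_INDEX.get(seqs[i][site], -1) for i in leaves}
        site_lik = 0.0
        for w, r in zip(weights, rates):
            mats = {i: pmat(ti.lengths[i] * r) for i in range(len(ti.nodes))}
            lik = pi[assignments[:, pos_of[ti.root]]].astype(float)
            for i in range(len(ti.nodes)):
                p = ti.parent[i]
                if p < 0:
                    continue
                sp = assignments[:, pos_of[p]]
                if ti.is_leaf[i]:
                    s = leaf_state[i]
                    if s < 0:  # ambiguous leaf: sums to 1 over states
                        continue
                    lik = lik * mats[i][sp, s]
                else:
                    lik = lik * mats[i][sp, assignments[:, pos_of[i]]]
            site_lik += w * lik.sum()
        total += np.log(site_lik)
    return float(total)


# ---------------------------------------------------------------------------
# hairpin oracle: plain enumeration of every geometry


def hairpin_oracle(window: str, min_stem: int, min_loop: int, max_loop: int):
    """Best hairpin by direct enumeration; same tie-break as the scanner:
    score desc, start asc, stem desc, loop asc."""
    from hyscav.readthrough import _PAIRS

    seq = window.upper().replace("U", "T")
    n = len(seq)
    best = None
    for start in range(n):
        for stem in range(min_stem, n // 2 + 1):
            for loop in range(min_loop, max_loop + 1):
                end = start + 2 * stem + loop
                if end > n:
                    continue
                if all(
                    (seq[start + i], seq[end - 1 - i]) in _PAIRS for i in range(stem)
                ):
                    key = (-stem, start + 1, -stem, loop)
                    if best is None or key < best[0]:
                        best = (key, start + 1, stem, loop)
    if best is None:
        return None
    return {"start": best[1], "stem": best[2], "loop": best[3], "score": best[2]}


def random_model(rng: np.random.Generator):
    """A random valid GTR(+G+I) model for property tests."""
    from hyscav.ancestral import SubstitutionModel

    freqs = rng.dirichlet([5, 5, 5, 5])
    freqs = tuple(float(f) for f in freqs / freqs.sum())
    ex = tuple(float(x) for x in rng.uniform(0.3, 3.0, 6))
    use_gamma = rng.random() < 0.5
    return SubstitutionModel(
        exchangeabilities=ex,
        base_frequencies=freqs,
        gamma_shape=float(rng.uniform(0.3, 3.0)) if use_gamma else None,
        n_rate_categories=3,
        p_invariant=float(rng.uniform(0, 0.4)) if rng.random() < 0.5 else 0.0,
    )


def random_small_instance(rng: np.random.Generator, max_leaves: int = 5):
    """Random tiny tree + alignment + model for likelihood cross-checks."""
    from hyscav.alignment import CodonAlignment
    from hyscav.synthetic import SimulationSpec, generate_tree

    n_leaves = int(rng.integers(3, max_leaves + 1))
    spec = SimulationSpec(
        n_leaves=n_leaves,
        tree_shape="yule",
        total_tree_length=float(rng.uniform(0.2, 2.0)),
        n_columns=3,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    tree = generate_tree(spec)
    n_sites = 9
    rows = {
        f"T{i+1}": "".join(rng.choice(list(NUCLEOTIDES), n_sites))
        for i in range(n_leaves)
    }
    return tree, CodonAlignment(rows), random_model(rng)
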