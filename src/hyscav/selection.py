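"""Nei–Gojobori (NG86) codon-based selection machinery.

Implements synonymous/nonsynonymous site counting with stop-exclusion
renormalization, pathway-averaged difference counting, Jukes–Cantor
corrected pairwise dN/dS with bootstrap variances, the codon-based
Z-test for positive selection, and the per-column selection profile
(deltaN, deltaS) aggregated over the branches of a rooted tree whose
internal nodes carry reconstructed ancestral sequences.

Conventions
-----------
Sites are fractional: at each codon position the synonymous fraction is
the share of single-nucleotide changes that preserve the amino acid,
taken over the changes that do not create a stop codon, so S + N = 3
for every sense codon.  Multi-nucleotide codon differences are averaged
with equal weight over all mutational pathways that avoid stop codons.
deltaN - deltaS > 0 at a column indicates positive selection pressure;
deltaN - deltaS < 0 indicates purifying selection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import CodonAlignment
from .genetics import NUCLEOTIDES, GeneticCode, iter_codons
from .phylo import iter_branches, node_name

__all__ = [
    "SiteCounts",
    "DiffCounts",
    "PairwiseNG",
    "ZTestResult",
    "SiteSelectionProfile",
    "count_sites",
    "count_differences",
    "pairwise_ng",
    "z_test",
    "site_profile",
    "summarize_positive_sites",
]


@dataclass(frozen=True)
class SiteCounts:
    """Fractional synonymous (S) and nonsynonymous (N) site counts."""

    S: float
    N: float


@dataclass(frozen=True)
class DiffCounts:
    """Pathway-averaged synonymous (Sd) / nonsynonymous (Nd) differences.

    ``admissible`` is False when every mutational pathway between the two
    codons passes through a stop codon; Sd/Nd are NaN in that case.
    """

    Sd: float
    Nd: float
    admissible: bool = True


def _is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in NUCLEOTIDES for b in codon)


@lru_cache(maxsize=None)
def _count_sites_cached(codon: str, code_name: str, stops: frozenset, aa_map: tuple) -> Tuple[float, float]:
    mapping = dict(aa_map)
    aa = mapping[codon]
    s_total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in stops:
                continue
            valid += 1
            if mapping[mutant] == aa:
                syn += 1
        if valid:
            s_total += syn / valid
    return s_total, 3.0 - s_total


def count_sites(codon: str, code: GeneticCode) -> SiteCounts:
    """NG86 synonymous/nonsynonymous site counts for one sense codon.

    At each of the three positions the synonymous fraction is computed
    over the single-nucleotide changes that do not create a stop codon
    (stop-excluded renormalization), so ``S + N == 3`` exactly.
    """
    codon = codon.upper()
    if not _is_valid_codon(codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site counts")
    s, n = _count_sites_cached(
        codon, code.name, code.stop_codons, tuple(sorted(code.codon_to_aa.items()))
    )
    return SiteCounts(S=s, N=n)


def count_differences(codon_a: str, codon_b: str, code: GeneticCode) -> DiffCounts:
    """Pathway-averaged synonymous/nonsynonymous differences between codons.

    All orderings of the differing positions are enumerated; pathways
    passing through a stop codon are discarded; each step is classified
    synonymous or nonsynonymous by the amino acids of its endpoint
    codons; step counts are averaged with equal weight over admissible
    pathways.  ``Sd + Nd`` equals the nucleotide Hamming distance.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if not _is_valid_codon(c):
            raise ValueError(f"not an unambiguous codon: {c!r}")
        if code.is_stop(c):
            raise ValueError(f"stop codon {c} not allowed in difference counting")
    diff_positions = [i for i in range(3) if a[i] != b[i]]
    if not diff_positions:
        return DiffCounts(0.0, 0.0)
    syn_sum = 0.0
    nonsyn_sum = 0.0
    n_admissible = 0
    for order in itertools.permutations(diff_positions):
        current = a
        syn = 0
        nonsyn = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if code.translate_codon(nxt) == code.translate_codon(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if ok:
            n_admissible += 1
            syn_sum += syn
            nonsyn_sum += nonsyn
    if n_admissible == 0:
        return DiffCounts(float("nan"), float("nan"), admissible=False)
    return DiffCounts(Sd=syn_sum / n_admissible, Nd=nonsyn_sum / n_admissible)


def _jukes_cantor(p: float) -> Tuple[float, bool]:
    """JC-corrected distance; returns (d, saturated)."""
    if p < 0.75:
        return -0.75 * np.log1p(-4.0 * p / 3.0), False
    return p, True


@dataclass(frozen=True)
class PairwiseNG:
    pS: float
    pN: float
    dS: float
    dN: float
    varS: float
    varN: float
    n_codons: int
    saturated_S: bool = False
    saturated_N: bool = False


def _column_ng_arrays(
    seq_a: str, seq_b: str, code: GeneticCode
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per usable codon column: (Sd, Nd, S_avg, N_avg)."""
    sd, nd, sbar, nbar = [], [], [], []
    for ca, cb in zip(iter_codons(seq_a), iter_codons(seq_b)):
        if not (_is_valid_codon(ca) and _is_valid_codon(cb)):
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            continue
        diff = count_differences(ca, cb, code)
        if not diff.admissible:
            continue
        sa, sb = count_sites(ca, code), count_sites(cb, code)
        sd.append(diff.Sd)
        nd.append(diff.Nd)
        sbar.append(0.5 * (sa.S + sb.S))
        nbar.append(0.5 * (sa.N + sb.N))
    return (np.asarray(sd), np.asarray(nd), np.asarray(sbar), np.asarray(nbar))


def pairwise_ng(
    seq_a: str,
    seq_b: str,
    code: GeneticCode,
    n_bootstrap: int = 1000,
    seed: Optional[int] = None,
) -> PairwiseNG:
    """NG86 pairwise pS/pN with Jukes–Cantor correction.

    Columns containing ambiguity characters, gaps, or stop codons in
    either sequence are skipped.  Variances of dS and dN come from a
    seeded bootstrap over codon columns.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be the same length")
    sd, nd, sbar, nbar = _column_ng_arrays(seq_a, seq_b, code)
    n_codons = len(sd)
    if n_codons == 0:
        raise ValueError("no usable codon columns")

    def stats_from(idx: np.ndarray) -> Tuple[float, float, bool, bool]:
        s_sites, n_sites = sbar[idx].sum(), nbar[idx].sum()
        ps = sd[idx].sum() / s_sites if s_sites > 0 else 0.0
        pn = nd[idx].sum() / n_sites if n_sites > 0 else 0.0
        ds, sat_s = _jukes_cantor(ps)
        dn, sat_n = _jukes_cantor(pn)
        return ds, dn, sat_s, sat_n

    all_idx = np.arange(n_codons)
    dS, dN, sat_s, sat_n = stats_from(all_idx)
    s_sites, n_sites = sbar.sum(), nbar.sum()
    pS = sd.sum() / s_sites if s_sites > 0 else 0.0
    pN = nd.sum() / n_sites if n_sites > 0 else 0.0

    rng = np.random.default_rng(seed)
    boot_ds = np.empty(n_bootstrap)
    boot_dn = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        idx = rng.integers(0, n_codons, size=n_codons)
        boot_ds[i], boot_dn[i], _, _ = stats_from(idx)
    return PairwiseNG(
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        varS=float(np.var(boot_ds, ddof=1)) if n_bootstrap > 1 else 0.0,
        varN=float(np.var(boot_dn, ddof=1)) if n_bootstrap > 1 else 0.0,
        n_codons=n_codons,
        saturated_S=sat_s,
        saturated_N=sat_n,
    )


@dataclass(frozen=True)
class ZTestResult:
    Z: float
    p_one_tailed: float
    infinite: bool = False


def z_test(dN: float, dS: float, varN: float, varS: float) -> ZTestResult:
    """Codon-based Z-test for positive selection (alternative dN > dS).

    Z = (dN - dS) / sqrt(varN + varS); one-tailed p from the upper tail
    of the standard normal.
    """
    if varN < 0 or varS < 0:
        raise ValueError("variances must be nonnegative")
    var = varN + varS
    if var == 0:
        if dN == dS:
            return ZTestResult(Z=0.0, p_one_tailed=0.5)
        z = np.inf if dN > dS else -np.inf
        return ZTestResult(Z=float(z), p_one_tailed=0.0 if dN > dS else 1.0, infinite=True)
    z = (dN - dS) / np.sqrt(var)
    return ZTestResult(Z=float(z), p_one_tailed=float(stats.norm.sf(z)))


@dataclass
class SiteSelectionProfile:
    """Per-codon-column selection profile over the branches of a tree.

    ``table`` is indexed by 1-based codon column with columns
    deltaN, deltaS, deltaN_minus_deltaS, n_branches_informative, Z,
    p_one_tailed.  Columns with no informative branch carry NaN values
    (flagged, never silently zero-filled).
    """

    table: pd.DataFrame

    @property
    def n_columns(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="column", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "SiteSelectionProfile":
        return cls(pd.read_csv(path, sep="\t", index_col="column"))


def site_profile(
    alignment: CodonAlignment,
    tree,
    ancestors: Dict[str, str],
    code: GeneticCode,
    n_bootstrap: int = 200,
    seed: Optional[int] = None,
    branches: str = "all",
) -> SiteSelectionProfile:
    """Per-column deltaN/deltaS profile aggregated over tree branches.

    For every branch (parent, child) and every codon column, pathway
    differences (Sd, Nd) and the branch-averaged site counts are
    accumulated; per column deltaS = sum(Sd)/sum(S_avg) and
    deltaN = sum(Nd)/sum(N_avg) over branches.  A per-column Z-test uses
    variances from a seeded bootstrap over branches.

    ``ancestors`` maps internal-node labels to codon sequences;
    ``branches`` is "all" (every tree branch) or "root_to_tip" (compare
    the root sequence directly against each extant leaf instead of
    walking individual branches).
    """
    if branches not in ("all", "root_to_tip"):
        raise ValueError(f"unknown branch mode {branches!r}")

    def sequence_of(node) -> str:
        name = node_name(node)
        if node.is_leaf():
            try:
                return alignment.sequences[name]
            except KeyError:
                raise KeyError(f"leaf {name!r} has no row in the alignment") from None
        try:
            return ancestors[name]
        except KeyError:
            raise KeyError(f"internal node {name!r} has no reconstructed sequence") from None

    n_cols = alignment.n_columns
    branch_pairs: List[Tuple[str, str]] = []
    # per-branch per-column arrays
    sd_rows, nd_rows, sbar_rows, nbar_rows, info_rows = [], [], [], [], []
    if branches == "all":
        node_pairs = list(iter_branches(tree))
    else:  # root against every extant leaf
        root = tree.seed_node
        node_pairs = [(root, leaf) for leaf in tree.leaf_node_iter()]
    for parent, child in node_pairs:
        seq_p, seq_c = sequence_of(parent), sequence_of(child)
        if len(seq_p) != 3 * n_cols or len(seq_c) != 3 * n_cols:
            raise ValueError("node sequence length does not match alignment")
        sd = np.zeros(n_cols)
        nd = np.zeros(n_cols)
        sbar = np.zeros(n_cols)
        nbar = np.zeros(n_cols)
        info = np.zeros(n_cols, dtype=bool)
        for j, (cp, cc) in enumerate(zip(iter_codons(seq_p), iter_codons(seq_c))):
            if not (_is_valid_codon(cp) and _is_valid_codon(cc)):
                continue
            if code.is_stop(cp) or code.is_stop(cc):
                continue
            diff = count_differences(cp, cc, code)
            if not diff.admissible:
                continue
            sp, sc = count_sites(cp, code), count_sites(cc, code)
            sd[j], nd[j] = diff.Sd, diff.Nd
            sbar[j] = 0.5 * (sp.S + sc.S)
            nbar[j] = 0.5 * (sp.N + sc.N)
            info[j] = True
        branch_pairs.append((node_name(parent), node_name(child)))
        sd_rows.append(sd)
        nd_rows.append(nd)
        sbar_rows.append(sbar)
        nbar_rows.append(nbar)
        info_rows.append(info)

    sd_m = np.array(sd_rows)  # branches x columns
    nd_m = np.array(nd_rows)
    sbar_m = np.array(sbar_rows)
    nbar_m = np.array(nbar_rows)
    info_m = np.array(info_rows)
    n_branches = sd_m.shape[0]

    def profile_from(idx: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        s_sites = sbar_m[idx].sum(axis=0)
        n_sites = nbar_m[idx].sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            d_s = np.where(s_sites > 0, sd_m[idx].sum(axis=0) / s_sites, np.nan)
            d_n = np.where(n_sites > 0, nd_m[idx].sum(axis=0) / n_sites, np.nan)
        return d_n, d_s

    all_idx = np.arange(n_branches)
    delta_n, delta_s = profile_from(all_idx)
    n_informative = info_m.sum(axis=0)

    rng = np.random.default_rng(seed)
    boot_n = np.empty((n_bootstrap, n_cols))
    boot_s = np.empty((n_bootstrap, n_cols))
    for i in range(n_bootstrap):
        idx = rng.integers(0, n_branches, size=n_branches)
        boot_n[i], boot_s[i] = profile_from(idx)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        # columns with no usable sites in some resamples produce all-NaN
        # slices; they are flagged below rather than scored
        _warnings.simplefilter("ignore", RuntimeWarning)
        var_n = np.nanvar(boot_n, axis=0, ddof=1)
        var_s = np.nanvar(boot_s, axis=0, ddof=1)

    z_vals = np.full(n_cols, np.nan)
    p_vals = np.full(n_cols, np.nan)
    for j in range(n_cols):
        if n_informative[j] == 0 or np.isnan(delta_n[j]) or np.isnan(delta_s[j]):
            continue
        res = z_test(delta_n[j], delta_s[j], max(var_n[j], 0.0), max(var_s[j], 0.0))
        z_vals[j], p_vals[j] = res.Z, res.p_one_tailed

    flagged_n = np.where(n_informative > 0, delta_n, np.nan)
    flagged_s = np.where(n_informative > 0, delta_s, np.nan)
    table = pd.DataFrame(
        {
            "deltaN": flagged_n,
            "deltaS": flagged_s,
            "deltaN_minus_deltaS": flagged_n - flagged_s,
            "n_branches_informative": n_informative,
            "Z": z_vals,
            "p_one_tailed": p_vals,
        },
        index=pd.RangeIndex(1, n_cols + 1, name="column"),
    )
    return SiteSelectionProfile(table)


def summarize_positive_sites(profile: SiteSelectionProfile) -> Dict[str, float]:
    """Count columns under positive selection pressure (deltaN - deltaS > 0)."""
    diff = profile.table["deltaN_minus_deltaS"]
    n_positive = int((diff > 0).sum())
    n_total = int(len(diff))
    return {
        "n_positive": n_positive,
        "n_total": n_total,
        "fraction": n_positive / n_total if n_total else 0.0,
    }
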