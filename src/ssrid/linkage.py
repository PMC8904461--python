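"""Pairwise linkage-disequilibrium testing and linkage-group construction.

The pair test is a genotypic log-likelihood-ratio (G) test on the two-locus
contingency table of individuals typed at both loci, with the null
distribution obtained by permuting one locus's genotype column.  Significant
pairs are merged into linkage groups (connected components by default), and
each group contributes a single representative locus — the member with the
lowest probability of identity — to the downstream forensic accumulation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping

import networkx as nx
import numpy as np

from .errors import UndefinedStatisticError, ValidationError
from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass
class LinkageStructure:
    """Linkage groups at a significance threshold.

    ``groups`` partitions the locus set (singletons included); every
    significant pair lies inside one group; ``representative_of`` maps each
    group (keyed by its sorted member tuple) to the member chosen for the
    forensic accumulation.
    """

    alpha: float
    significant_pairs: set[Pair]
    groups: list[list[str]]
    representative_of: dict[tuple[str, ...], str] = field(default_factory=dict)

    @property
    def representatives(self) -> list[str]:
        """All representative/singleton loci, one per group, in group order."""
        return [self.representative_of[tuple(g)] for g in self.groups]

    def group_of(self, locus: str) -> list[str]:
        for g in self.groups:
            if locus in g:
                return g
        raise KeyError(f"locus {locus!r} not in any group")


def _pair_key(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def _joint_codes(matrix: GenotypeMatrix, locus_a: str, locus_b: str) -> tuple[np.ndarray, np.ndarray]:
    ja, jb = matrix.locus_index(locus_a), matrix.locus_index(locus_b)
    ca, cb = matrix.calls[:, ja, :], matrix.calls[:, jb, :]
    ok = (ca[:, 0] != MISSING) & (cb[:, 0] != MISSING)
    ca, cb = ca[ok], cb[ok]

    def codes(cells: np.ndarray) -> np.ndarray:
        # unordered genotype -> dense integer code
        pairs = [tuple(map(int, c)) for c in cells]
        uniq = {g: k for k, g in enumerate(sorted(set(pairs)))}
        return np.asarray([uniq[g] for g in pairs], dtype=np.intp)

    return codes(ca), codes(cb)


def _g_statistic(table: np.ndarray) -> float:
    n = table.sum()
    if n == 0:
        return 0.0
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row * col / n
        ratio = np.where(table > 0, table / expected, 1.0)
        return float(2.0 * np.sum(table * np.log(ratio)))


def ld_test_pair(
    matrix: GenotypeMatrix,
    locus_a: str,
    locus_b: str,
    reps: int = 10_000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for genotypic association between two loci.

    Only individuals typed at both loci enter the contingency table.  The
    observed G statistic is compared against ``reps`` column permutations;
    p = (1 + #{G_perm >= G_obs}) / (1 + reps).
    """
    if seed is None:
        raise ValueError("ld_test_pair requires an explicit seed")
    a, b = _joint_codes(matrix, locus_a, locus_b)
    n = len(a)
    if n < 2:
        raise UndefinedStatisticError(
            f"loci {locus_a!r}/{locus_b!r} share fewer than 2 typed individuals"
        )
    ka, kb = int(a.max()) + 1, int(b.max()) + 1
    obs_table = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(obs_table, (a, b), 1)
    if (obs_table > 0).sum() <= 1:
        return 1.0  # degenerate single-cell table, G = 0 under any shuffle
    g_obs = _g_statistic(obs_table)
    rng = np.random.default_rng(seed)
    # margins are permutation-invariant, so the expected table is fixed;
    # G = 2 * sum over individuals of (log c_cell - log E_cell)
    row = obs_table.sum(axis=1).astype(float)
    col = obs_table.sum(axis=0).astype(float)
    log_e = np.log(np.outer(row, col).ravel() / n)
    hits = 0
    chunk = max(1, min(reps, 8_000_000 // (ka * kb)))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        perms = np.argsort(rng.random((m, n)), axis=1)
        joint = a[None, :] * kb + b[perms]
        offset = joint + (np.arange(m)[:, None] * ka * kb)
        counts = np.bincount(offset.ravel(), minlength=m * ka * kb)
        c = counts[offset]
        g = 2.0 * (np.log(c).sum(axis=1) - log_e[joint].sum(axis=1))
        hits += int(np.sum(g >= g_obs - 1e-9))
        done += m
    return (1 + hits) / (1 + reps)


def pairwise_ld(
    matrix: GenotypeMatrix,
    reps: int = 10_000,
    seed: int | None = None,
) -> dict[Pair, float]:
    """LD p-values for all testable locus pairs.

    Pairs untestable for data sparsity are skipped (treated downstream as
    non-significant) and logged.  Each pair gets an independent child seed so
    results do not depend on iteration order.
    """
    if seed is None:
        raise ValueError("pairwise_ld requires an explicit seed")
    root = np.random.SeedSequence(seed)
    pairs = list(itertools.combinations(matrix.locus_ids, 2))
    out: dict[Pair, float] = {}
    for (la, lb), child in zip(pairs, root.spawn(len(pairs))):
        try:
            out[_pair_key(la, lb)] = ld_test_pair(
                matrix, la, lb, reps=reps, seed=int(child.generate_state(1)[0])
            )
        except UndefinedStatisticError:
            logger.info("pair (%s, %s) untestable; treated as non-significant", la, lb)
    return out


def linkage_groups(
    p_values: Mapping[Pair, float],
    loci: list[str],
    alpha: float = 0.001,
    method: Literal["components", "cliques"] = "components",
) -> LinkageStructure:
    """Partition loci into linkage groups from pairwise p-values.

    ``components`` (default) merges loci connected through any chain of
    significant pairs; ``cliques`` only groups loci that are pairwise
    significant (maximal cliques, greedily made disjoint by clique size then
    lexicographic order).
    """
    graph = nx.Graph()
    graph.add_nodes_from(loci)
    significant: set[Pair] = set()
    for (la, lb), p in p_values.items():
        if la not in graph or lb not in graph:
            raise ValidationError(f"pair ({la}, {lb}) references an unknown locus")
        if p < alpha:
            key = _pair_key(la, lb)
            significant.add(key)
            graph.add_edge(*key)
    if method == "components":
        groups = [sorted(c) for c in nx.connected_components(graph)]
    elif method == "cliques":
        groups = _disjoint_cliques(graph)
    else:
        raise ValueError(f"unknown grouping method {method!r}")
    groups.sort(key=lambda g: g[0])
    return LinkageStructure(alpha=alpha, significant_pairs=significant, groups=groups)


def _disjoint_cliques(graph: nx.Graph) -> list[list[str]]:
    cliques = sorted((sorted(c) for c in nx.find_cliques(graph)), key=lambda c: (-len(c), c))
    taken: set[str] = set()
    groups: list[list[str]] = []
    for clique in cliques:
        free = [n for n in clique if n not in taken]
        if free:
            groups.append(free)
            taken.update(free)
    return groups


def select_representatives(
    structure: LinkageStructure, pi_of: Mapping[str, float]
) -> LinkageStructure:
    """Choose each group's representative: the member with minimal PI.

    Ties break to the lexicographically smallest locus id.  Singleton groups
    represent themselves.
    """
    reps: dict[tuple[str, ...], str] = {}
    for group in structure.groups:
        missing = [l for l in group if l not in pi_of and len(group) > 1]
        if missing:
            raise ValidationError(f"PI undefined for grouped locus/loci {missing}")
        if len(group) == 1:
            reps[tuple(group)] = group[0]
        else:
            reps[tuple(group)] = min(group, key=lambda l: (pi_of[l], l))
    return LinkageStructure(
        alpha=structure.alpha,
        significant_pairs=set(structure.significant_pairs),
        groups=[list(g) for g in structure.groups],
        representative_of=reps,
    )
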