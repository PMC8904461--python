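"""Per-locus diversity and forensic statistics.

For every locus: allele count A, observed/expected heterozygosity (Ho, He,
unbiased uHe), polymorphism information content (PIC, Botstein form), power
of discrimination PD = 1 - sum(genotype freq^2) over observed genotypes,
probability of identity PI = 1 - PD, and a Hardy-Weinberg test (chi-square
over all genotype classes, or a seeded Monte-Carlo exact test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import UndefinedStatisticError, ValidationError
from .genotype_io import MISSING, AlleleFrequencyTable, GenotypeMatrix, allele_frequencies

Subset = str | Iterable[str] | None


@dataclass
class LocusSummary:
    """Per-locus statistics row (one line of the locus summary table)."""

    locus_id: str
    A: int
    Ho: float
    He: float
    uHe: float
    PIC: float
    PD: float
    PI: float
    hwe_p: float | None  # None for monomorphic loci (test not applicable)
    n_typed: int


def _typed_calls(matrix: GenotypeMatrix, locus: str, subset: Subset) -> np.ndarray:
    rows = matrix.subset_indices(subset)
    j = matrix.locus_index(locus)
    cells = matrix.calls[rows, j, :]
    return cells[cells[:, 0] != MISSING]


def observed_heterozygosity(matrix: GenotypeMatrix, locus: str, subset: Subset = None) -> float:
    """Fraction of typed individuals carrying two distinct alleles."""
    typed = _typed_calls(matrix, locus, subset)
    if len(typed) == 0:
        raise UndefinedStatisticError(f"no typed individuals at locus {locus!r}")
    return float(np.mean(typed[:, 0] != typed[:, 1]))


def expected_heterozygosity(freqs: Mapping[int, float], n_typed: int) -> tuple[float, float]:
    """Return ``(He, uHe)`` from an allele-frequency vector.

    He = 1 - sum(p_i^2); uHe applies the small-sample factor 2n/(2n - 1).
    """
    if n_typed < 1:
        raise UndefinedStatisticError("He undefined with zero typed individuals")
    p = np.asarray(list(freqs.values()), dtype=float)
    _check_freqs(p)
    he = float(1.0 - np.sum(p**2))
    uhe = he * (2 * n_typed) / (2 * n_typed - 1)
    return he, uhe


def pic(freqs: Mapping[int, float]) -> float:
    """Polymorphism information content (Botstein et al. form).

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.
    """
    p = np.asarray(list(freqs.values()), dtype=float)
    _check_freqs(p)
    sq = p**2
    cross = (np.sum(sq) ** 2 - np.sum(sq**2)) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - np.sum(sq) - 2.0 * cross)


def _check_freqs(p: np.ndarray) -> None:
    if p.size == 0 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("invalid allele-frequency vector")


def genotype_counts(matrix: GenotypeMatrix, locus: str, subset: Subset = None) -> dict[tuple[int, int], int]:
    """Observed unordered-genotype counts among typed individuals."""
    typed = _typed_calls(matrix, locus, subset)
    out: dict[tuple[int, int], int] = {}
    for a, b in typed:
        key = (int(a), int(b))
        out[key] = out.get(key, 0) + 1
    return out


def power_of_discrimination(
    matrix: GenotypeMatrix,
    locus: str,
    subset: Subset = None,
    mode: Literal["observed", "expected"] = "observed",
) -> float:
    """PD = 1 - sum of squared genotype frequencies at a locus.

    ``mode="observed"`` (default) uses observed unordered-genotype relative
    frequencies; ``mode="expected"`` uses Hardy-Weinberg expected genotype
    frequencies from the allele-frequency vector (sensitivity option).
    """
    typed = _typed_calls(matrix, locus, subset)
    n = len(typed)
    if n == 0:
        raise UndefinedStatisticError(f"no typed individuals at locus {locus!r}")
    if mode == "observed":
        counts = np.asarray(list(genotype_counts(matrix, locus, subset).values()), dtype=float)
        return float(1.0 - np.sum((counts / n) ** 2))
    if mode == "expected":
        labels, copies = np.unique(typed.ravel(), return_counts=True)
        p = copies / copies.sum()
        hom = p**2
        het = 2.0 * np.outer(p, p)[np.triu_indices(len(p), k=1)]
        return float(1.0 - np.sum(hom**2) - np.sum(het**2))
    raise ValueError(f"unknown PD mode {mode!r}")


def probability_of_identity(pd_value: float) -> float:
    """PI = 1 - PD."""
    if not 0.0 <= pd_value <= 1.0:
        raise ValidationError(f"PD must lie in [0, 1], got {pd_value}")
    return 1.0 - pd_value


# ---------------------------------------------------------------------------
# Hardy-Weinberg testing
# ---------------------------------------------------------------------------

def hwe_test(
    matrix: GenotypeMatrix,
    locus: str,
    subset: Subset = None,
    method: Literal["chi2", "exact_mc"] = "chi2",
    mc_reps: int = 10_000,
    seed: int | None = None,
) -> float:
    """Hardy-Weinberg equilibrium p-value for one locus.

    ``chi2``: Pearson statistic over all A(A+1)/2 genotype classes with
    expected counts from the observed allele frequencies, df = A(A-1)/2.
    ``exact_mc``: Monte-Carlo exact test that permutes the 2n allele copies
    into random diploid pairings; the p-value is the fraction of shuffles
    whose conditional table probability does not exceed the observed one,
    with the +1 correction.  Requires a seed for reproducibility.
    """
    typed = _typed_calls(matrix, locus, subset)
    n = len(typed)
    if n == 0:
        raise UndefinedStatisticError(f"no typed individuals at locus {locus!r}")
    labels = np.unique(typed.ravel())
    a = len(labels)
    if a < 2:
        raise UndefinedStatisticError(f"locus {locus!r} is monomorphic; HWE test not applicable")
    if method == "chi2":
        return _hwe_chi2(typed, labels)
    if method == "exact_mc":
        if seed is None:
            raise ValueError("exact_mc requires an explicit seed")
        return _hwe_exact_mc(typed, labels, mc_reps, seed)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_chi2(typed: np.ndarray, labels: np.ndarray) -> float:
    a = len(labels)
    n = len(typed)
    idx = {int(l): k for k, l in enumerate(labels)}
    obs = np.zeros((a, a))
    for x, y in typed:
        i, j = sorted((idx[int(x)], idx[int(y)]))
        obs[i, j] += 1
    p = np.zeros(a)
    for (i, j), c in np.ndenumerate(obs):
        p[i] += c
        p[j] += c
    p /= 2 * n
    stat = 0.0
    for i in range(a):
        for j in range(i, a):
            exp = n * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
            if exp > 0:
                stat += (obs[i, j] - exp) ** 2 / exp
            elif obs[i, j] > 0:  # impossible: allele absent yet genotype seen
                stat += math.inf
    df = a * (a - 1) // 2
    return float(stats.chi2.sf(stat, df))


def _log_table_weight(pair_codes: np.ndarray, n_labels: int) -> float:
    """log of the permutation-invariant part of the conditional table probability.

    For fixed allele counts, P(table) is proportional to 2^h / prod(n_g!),
    with h the heterozygote count; the constant factor cancels in comparisons.
    """
    het = pair_codes[:, 0] != pair_codes[:, 1]
    flat = pair_codes[:, 0] * n_labels + pair_codes[:, 1]
    _, counts = np.unique(flat, return_counts=True)
    return float(het.sum() * math.log(2.0) - gammaln(counts + 1.0).sum())


def _hwe_exact_mc(typed: np.ndarray, labels: np.ndarray, reps: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    idx = {int(l): k for k, l in enumerate(labels)}
    a = len(labels)
    codes = np.vectorize(idx.__getitem__)(typed.astype(int))
    codes = np.sort(codes, axis=1)
    obs_w = _log_table_weight(codes, a)
    pool = codes.ravel().copy()
    hits = 0
    for _ in range(reps):
        rng.shuffle(pool)
        pairs = np.sort(pool.reshape(-1, 2), axis=1)
        if _log_table_weight(pairs, a) <= obs_w + 1e-12:
            hits += 1
    return (1 + hits) / (1 + reps)


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def summarize_loci(
    matrix: GenotypeMatrix,
    subset: Subset = None,
    hwe_method: Literal["chi2", "exact_mc"] = "chi2",
    mc_reps: int = 10_000,
    seed: int | None = None,
    pd_mode: Literal["observed", "expected"] = "observed",
) -> list[LocusSummary]:
    """One :class:`LocusSummary` per locus, in ``matrix.locus_ids`` order."""
    table = allele_frequencies(matrix, subset)
    out: list[LocusSummary] = []
    for locus in matrix.locus_ids:
        n = table.n_typed[locus]
        if n == 0:
            out.append(
                LocusSummary(locus, 0, math.nan, math.nan, math.nan, math.nan,
                             math.nan, math.nan, None, 0)
            )
            continue
        freqs = table.freqs[locus]
        a = len(freqs)
        ho = observed_heterozygosity(matrix, locus, subset)
        he, uhe = expected_heterozygosity(freqs, n)
        pic_v = pic(freqs)
        pd_v = power_of_discrimination(matrix, locus, subset, mode=pd_mode)
        pi_v = probability_of_identity(pd_v)
        if a < 2:
            hwe_p = None
        else:
            hwe_p = hwe_test(matrix, locus, subset, method=hwe_method, mc_reps=mc_reps, seed=seed)
        out.append(LocusSummary(locus, a, ho, he, uhe, pic_v, pd_v, pi_v, hwe_p, n))
    return out


def summaries_to_frame(summaries: list[LocusSummary], with_means: bool = True) -> pd.DataFrame:
    """Tabulate summaries; optionally append a footer row of column means.

    Means are taken over loci where the statistic is defined (unrounded
    values, NaN-aware)."""
    df = pd.DataFrame(
        [
            {
                "locus": s.locus_id,
                "A": s.A,
                "Ho": s.Ho,
                "He": s.He,
                "uHe": s.uHe,
                "PIC": s.PIC,
                "PD": s.PD,
                "PI": s.PI,
                "HWE_p": s.hwe_p if s.hwe_p is not None else math.nan,
                "n_typed": s.n_typed,
            }
            for s in summaries
        ]
    )
    if with_means and len(df):
        means = df.drop(columns=["locus"]).mean(numeric_only=True)
        footer = {"locus": "mean", **{c: means.get(c, math.nan) for c in df.columns if c != "locus"}}
        df = pd.concat([df, pd.DataFrame([footer])], ignore_index=True)
    return df
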