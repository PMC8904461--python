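"""Population-level diversity, differentiation, gene flow and cluster-number
selection.

Per-population summaries report locus-averaged A/Ho/He and the inbreeding
coefficient Fis = 1 - mean(Ho)/mean(He).  Pairwise differentiation uses the
Nei-style frequency estimator Fst = (Ht - Hs)/Ht by default (the estimator
behind the reference tables), with Weir-Cockerham theta available for
parameter-recovery work; gene flow is the island-model Nm = (1 - Fst)/(4 Fst).
`delta_k` post-processes a table of clustering-run log-likelihoods into the
Evanno second-difference statistic.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .genotype_io import MISSING, GenotypeMatrix, allele_frequencies
from .locus_stats import observed_heterozygosity

logger = logging.getLogger(__name__)


@dataclass
class PopulationSummary:
    """Per-population diversity row: N, locus-mean A/Ho/He, and Fis."""

    population: str
    n_individuals: int
    mean_A: float
    mean_Ho: float
    mean_He: float
    fis: float  # NaN when He is undefined or zero


@dataclass
class PopDiffMatrix:
    """Pairwise Fst (symmetric, zero diagonal) and derived Nm."""

    populations: list[str]
    fst: np.ndarray
    nm: np.ndarray

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = self.populations
        return (
            pd.DataFrame(self.fst, index=idx, columns=idx),
            pd.DataFrame(self.nm, index=idx, columns=idx),
        )


def population_summaries(matrix: GenotypeMatrix) -> list[PopulationSummary]:
    """A/Ho/He averaged over loci within each population, plus Fis.

    Statistics are computed per locus on that population's typed individuals
    and averaged over loci where they are defined; Fis uses the unrounded
    locus means.
    """
    out: list[PopulationSummary] = []
    for pop in matrix.population_labels:
        table = allele_frequencies(matrix, pop)
        a_vals, ho_vals, he_vals = [], [], []
        for locus in matrix.locus_ids:
            if table.n_typed[locus] == 0:
                continue
            freqs = table.freqs[locus]
            a_vals.append(len(freqs))
            ho_vals.append(observed_heterozygosity(matrix, locus, pop))
            he_vals.append(1.0 - sum(p * p for p in freqs.values()))
        n_ind = len(matrix.individuals_in(pop))
        if not he_vals:
            out.append(PopulationSummary(pop, n_ind, math.nan, math.nan, math.nan, math.nan))
            continue
        mean_ho, mean_he = float(np.mean(ho_vals)), float(np.mean(he_vals))
        fis = 1.0 - mean_ho / mean_he if mean_he > 0 else math.nan
        out.append(PopulationSummary(pop, n_ind, float(np.mean(a_vals)), mean_ho, mean_he, fis))
    return out


def population_summaries_frame(matrix: GenotypeMatrix) -> pd.DataFrame:
    rows = [
        {"population": s.population, "N": s.n_individuals, "A": s.mean_A,
         "Ho": s.mean_Ho, "He": s.mean_He, "Fis": s.fis}
        for s in population_summaries(matrix)
    ]
    df = pd.DataFrame(rows)
    mean_row = {"population": "mean", **df.drop(columns="population").mean().to_dict()}
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def pairwise_fst(
    matrix: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    method: Literal["nei", "wc"] = "nei",
) -> float:
    """Multi-locus Fst between two populations.

    ``nei``: per locus Hs = mean of the two within-population expected
    heterozygosities and Ht = expected heterozygosity of the mean allele
    frequency vector; locus values combine by summing Ht and Hs over loci
    before taking (sum Ht - sum Hs)/sum Ht.  ``wc`` is the Weir-Cockerham
    theta estimator (variance components, alleles weighted by sample size),
    which targets the model Fst parameter with no two-population bias.
    """
    if method == "wc":
        return _weir_cockerham_theta(matrix, [pop_a, pop_b])
    ta = allele_frequencies(matrix, pop_a)
    tb = allele_frequencies(matrix, pop_b)
    sum_ht = sum_hs = 0.0
    for locus in matrix.locus_ids:
        if ta.n_typed[locus] == 0 or tb.n_typed[locus] == 0:
            continue
        fa, fb = ta.freqs[locus], tb.freqs[locus]
        hs = 0.5 * ((1 - sum(p * p for p in fa.values())) + (1 - sum(p * p for p in fb.values())))
        alleles = set(fa) | set(fb)
        ht = 1.0 - sum(((fa.get(al, 0.0) + fb.get(al, 0.0)) / 2.0) ** 2 for al in alleles)
        sum_ht += ht
        sum_hs += hs
    if sum_ht == 0.0:
        logger.info("Ht = 0 at all shared loci for (%s, %s); Fst = 0 by convention", pop_a, pop_b)
        return 0.0
    return (sum_ht - sum_hs) / sum_ht


def _weir_cockerham_theta(matrix: GenotypeMatrix, pops: list[str]) -> float:
    """Weir & Cockerham (1984) theta summed over loci and alleles."""
    r = len(pops)
    sum_a = sum_abc = 0.0
    for locus in matrix.locus_ids:
        j = matrix.locus_index(locus)
        samples = []  # per pop: (n_i, freq map, het rate)
        for pop in pops:
            rows = matrix.subset_indices(pop)
            cells = matrix.calls[rows, j, :]
            typed = cells[cells[:, 0] != MISSING]
            if len(typed) < 2:
                samples = []
                break
            labels, counts = np.unique(typed.ravel(), return_counts=True)
            freqs = dict(zip(labels.astype(int), counts / counts.sum()))
            het = float(np.mean(typed[:, 0] != typed[:, 1]))
            samples.append((len(typed), freqs, het, typed))
        if not samples:
            continue
        ns = np.array([s[0] for s in samples], dtype=float)
        n_bar = ns.mean()
        nc = (ns.sum() - (ns**2).sum() / ns.sum()) / (r - 1)
        alleles = sorted(set().union(*[s[1].keys() for s in samples]))
        for al in alleles:
            p = np.array([s[1].get(al, 0.0) for s in samples])
            # heterozygosity involving this allele, per pop
            h = np.array(
                [
                    float(np.mean((t[:, 0] != t[:, 1]) & ((t[:, 0] == al) | (t[:, 1] == al))))
                    for (_, _, _, t) in samples
                ]
            )
            p_bar = float((ns * p).sum() / ns.sum())
            s2 = float((ns * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar))
            h_bar = float((ns * h).sum() / ns.sum())
            a = (n_bar / nc) * (
                s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2
            sum_a += a
            sum_abc += a + b + c
    if sum_abc == 0.0:
        return 0.0
    return sum_a / sum_abc


def nm_from_fst(fst: float) -> float:
    """Island-model gene flow Nm = 0.25 (1 - Fst)/Fst; infinite at Fst = 0."""
    if not 0.0 <= fst <= 1.0:
        raise ValidationError(f"Fst must lie in [0, 1], got {fst}")
    if fst == 0.0:
        return math.inf
    return 0.25 * (1.0 - fst) / fst


def fst_matrix(matrix: GenotypeMatrix, method: Literal["nei", "wc"] = "nei") -> PopDiffMatrix:
    """All pairwise Fst values plus the derived Nm matrix."""
    pops = matrix.population_labels
    k = len(pops)
    fst = np.zeros((k, k))
    nm = np.full((k, k), math.inf)
    for ia, ib in itertools.combinations(range(k), 2):
        value = pairwise_fst(matrix, pops[ia], pops[ib], method=method)
        fst[ia, ib] = fst[ib, ia] = value
        nm[ia, ib] = nm[ib, ia] = nm_from_fst(max(value, 0.0))
    return PopDiffMatrix(populations=pops, fst=fst, nm=nm)


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def delta_k(k_table: pd.DataFrame) -> pd.DataFrame:
    """Evanno second-difference statistic from clustering-run likelihoods.

    ``k_table`` needs columns ``K``, ``run``, ``lnP``.  Per K the run mean
    and sd of lnP are taken; L'(K) = L(K) - L(K-1); |L''(K)| =
    |L'(K+1) - L'(K)|; deltaK = |L''(K)| / sd(K), defined only for interior K
    with >= 2 runs and sd > 0 (NaN otherwise, flagged in the log).
    """
    required = {"K", "run", "lnP"}
    if not required.issubset(k_table.columns):
        raise ValidationError(f"K table needs columns {sorted(required)}")
    grouped = k_table.groupby("K")["lnP"]
    stats = pd.DataFrame({"mean_lnP": grouped.mean(), "sd_lnP": grouped.std(ddof=1),
                          "n_runs": grouped.size()}).sort_index()
    ks = stats.index.to_numpy()
    if len(ks) < 3 or np.any(np.diff(ks) != 1):
        raise ValidationError("delta-K needs >= 3 consecutive K values")
    mean = stats["mean_lnP"].to_numpy()
    lprime = np.full(len(ks), math.nan)
    lprime[1:] = np.diff(mean)
    lpp = np.full(len(ks), math.nan)
    lpp[1:-1] = np.abs(lprime[2:] - lprime[1:-1])
    dk = np.full(len(ks), math.nan)
    for i in range(1, len(ks) - 1):
        sd = stats["sd_lnP"].iloc[i]
        if stats["n_runs"].iloc[i] < 2 or not sd > 0:
            logger.info("deltaK undefined at K=%d (runs=%d, sd=%s)",
                        ks[i], stats["n_runs"].iloc[i], sd)
            continue
        dk[i] = lpp[i] / sd
    out = stats.reset_index()
    out["Lprime"] = lprime
    out["abs_Lpp"] = lpp
    out["deltaK"] = dk
    return out


def best_k(k_table: pd.DataFrame) -> int:
    """The K maximizing Evanno deltaK."""
    table = delta_k(k_table)
    if table["deltaK"].isna().all():
        raise UndefinedStatisticError("deltaK undefined at every interior K")
    return int(table.loc[table["deltaK"].idxmax(), "K"])
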