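"""Provenance assignment by genotype likelihood (frequency method).

Each individual is scored against every candidate population's allele
frequencies: log-likelihood = sum over non-missing loci of log P(genotype),
with P = p_a^2 for homozygotes and 2 p_a p_b for heterozygotes.  Alleles
absent from a reference population take a small substitute frequency
(``zero_freq``).  With leave-one-out the individual's own alleles are removed
from its own population's reference counts before scoring, giving an honest
self-assignment accuracy (per-population and overall percent correct).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class AssignmentResult:
    """Per-individual assignments and the derived accuracy table."""

    individuals: pd.DataFrame  # individual, population, assigned, correct, logL per pop
    per_population: pd.DataFrame  # population, N, n_correct, pct_correct
    overall_pct_correct: float
    excluded: list[str]  # individuals that could not be scored


def genotype_log_likelihood(
    calls: np.ndarray,
    locus_ids: list[str],
    freqs: Mapping[str, Mapping[int, float]],
    zero_freq: float = 0.01,
) -> float:
    """Log-likelihood of one individual's multilocus genotype.

    ``calls`` has shape (n_loci, 2); missing loci contribute 0.  Any allele
    absent from the reference frequency map enters with ``zero_freq``.
    """
    if not 0.0 < zero_freq <= 0.1:
        raise ValidationError(f"zero_freq must lie in (0, 0.1], got {zero_freq}")
    total = 0.0
    scored = 0
    for j, locus in enumerate(locus_ids):
        a, b = int(calls[j, 0]), int(calls[j, 1])
        if a == MISSING:
            continue
        f = freqs.get(locus, {})
        pa = f.get(a, 0.0) or zero_freq
        pb = f.get(b, 0.0) or zero_freq
        total += math.log(pa * pa) if a == b else math.log(2.0 * pa * pb)
        scored += 1
    if scored == 0:
        raise UndefinedStatisticError("individual is missing at every locus")
    return total


def _allele_counts(matrix: GenotypeMatrix) -> dict[str, dict[str, dict[int, int]]]:
    """population -> locus -> allele -> copy count."""
    out: dict[str, dict[str, dict[int, int]]] = {
        p: {l: {} for l in matrix.locus_ids} for p in matrix.population_labels
    }
    for i, pop in enumerate(matrix.populations):
        for j, locus in enumerate(matrix.locus_ids):
            a, b = matrix.calls[i, j]
            if a == MISSING:
                continue
            bucket = out[pop][locus]
            bucket[int(a)] = bucket.get(int(a), 0) + 1
            bucket[int(b)] = bucket.get(int(b), 0) + 1
    return out


def _freqs_from_counts(counts: Mapping[str, Mapping[int, int]]) -> dict[str, dict[int, float]]:
    freqs: dict[str, dict[int, float]] = {}
    for locus, bucket in counts.items():
        total = sum(bucket.values())
        freqs[locus] = {a: c / total for a, c in bucket.items() if c > 0} if total else {}
    return freqs


def assign_all(
    matrix: GenotypeMatrix,
    zero_freq: float = 0.01,
    leave_one_out: bool = True,
) -> AssignmentResult:
    """Assign every individual to the population maximizing its likelihood.

    Ties are scored conservatively: if the top likelihood is shared and the
    individual's own population is among the tied candidates, a tied foreign
    population is chosen instead (so ties count as misassignment); remaining
    ties break lexicographically.  Individuals that cannot be scored (missing
    everywhere, or sole member of their population under leave-one-out) are
    excluded from the accuracy with a warning.
    """
    pops = matrix.population_labels
    if len(pops) < 2 and leave_one_out:
        logger.warning("single population: every individual trivially self-assigns")
    counts = _allele_counts(matrix)
    base_freqs = {p: _freqs_from_counts(counts[p]) for p in pops}
    pop_sizes = {p: len(matrix.individuals_in(p)) for p in pops}

    rows = []
    excluded: list[str] = []
    for i, ind in enumerate(matrix.individual_ids):
        own = matrix.populations[i]
        calls = matrix.calls[i]
        if leave_one_out and pop_sizes[own] == 1:
            logger.warning("individual %r is the only member of %r; excluded from accuracy",
                           ind, own)
            excluded.append(ind)
            continue
        scores: dict[str, float] = {}
        try:
            for pop in pops:
                if leave_one_out and pop == own:
                    loo_counts = {l: dict(counts[pop][l]) for l in matrix.locus_ids}
                    for j, locus in enumerate(matrix.locus_ids):
                        a, b = calls[j]
                        if a == MISSING:
                            continue
                        loo_counts[locus][int(a)] -= 1
                        loo_counts[locus][int(b)] -= 1
                    freqs = _freqs_from_counts(loo_counts)
                else:
                    freqs = base_freqs[pop]
                scores[pop] = genotype_log_likelihood(calls, matrix.locus_ids, freqs, zero_freq)
        except UndefinedStatisticError:
            logger.warning("individual %r unscorable; excluded from accuracy", ind)
            excluded.append(ind)
            continue
        top = max(scores.values())
        tied = sorted(p for p, s in scores.items() if s >= top - 1e-9)
        if len(tied) > 1 and own in tied:
            assigned = min(p for p in tied if p != own)
        else:
            assigned = tied[0]
        rows.append(
            {"individual": ind, "population": own, "assigned": assigned,
             "correct": assigned == own,
             **{f"logL_{p}": scores[p] for p in pops}}
        )
    individuals = pd.DataFrame(rows)
    per_pop_rows = []
    for pop in pops:
        sub = individuals[individuals["population"] == pop] if len(individuals) else individuals
        n = len(sub)
        n_correct = int(sub["correct"].sum()) if n else 0
        per_pop_rows.append(
            {"population": pop, "N": n, "n_correct": n_correct,
             "pct_correct": 100.0 * n_correct / n if n else math.nan}
        )
    per_population = pd.DataFrame(per_pop_rows)
    total = len(individuals)
    overall = 100.0 * individuals["correct"].sum() / total if total else math.nan
    return AssignmentResult(
        individuals=individuals,
        per_population=per_population,
        overall_pct_correct=float(overall),
        excluded=excluded,
    )
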