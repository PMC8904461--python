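"""Cumulative forensic discrimination: CPI/CPD accumulation and capacity.

Loci (linkage representatives plus singletons) are sorted by ascending
probability of identity and multiplied, in log space, into the cumulative
probability of identity CPI_k; CPD_k = 1 - CPI_k.  The confidence level for
a registry of N individuals is CL = (1 - CPI)^N, and the capacity at a
target confidence CL* is the largest N with (1 - CPI)^N >= CL*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError

#: Returned by :func:`max_identifiable` when CPI = 0 (unlimited capacity).
UNLIMITED = math.inf


@dataclass
class ForensicStep:
    """One accumulation step: the k-th locus added and the cumulative state."""

    k: int
    locus: str
    pi: float
    cpi: float
    cpd: float
    n_max: dict[float, float]  # confidence level -> capacity


@dataclass
class ForensicProfile:
    """PI-sorted accumulation table (one :class:`ForensicStep` per locus)."""

    steps: list[ForensicStep]
    confidence_levels: tuple[float, ...]

    @property
    def loci(self) -> list[str]:
        return [s.locus for s in self.steps]

    @property
    def final_cpi(self) -> float:
        return self.steps[-1].cpi

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            row = {"k": s.k, "locus": s.locus, "PI": s.pi, "CPI": s.cpi, "CPD": s.cpd}
            for cl in self.confidence_levels:
                row[f"N_max@{cl:g}"] = s.n_max[cl]
            rows.append(row)
        return pd.DataFrame(rows)


def confidence_level(cpi: float, n: int) -> float:
    """CL = (1 - CPI)^N, evaluated as exp(N * log1p(-CPI)) for stability."""
    if not 0.0 <= cpi <= 1.0:
        raise ValidationError(f"CPI must lie in [0, 1], got {cpi}")
    if n < 0 or n != int(n):
        raise ValidationError(f"N must be a non-negative integer, got {n}")
    if cpi == 1.0:
        return 1.0 if n == 0 else 0.0
    return math.exp(n * math.log1p(-cpi))


def max_identifiable(cpi: float, cl_target: float) -> float:
    """Largest integer N with (1 - CPI)^N >= CL*.

    Closed form floor(ln CL* / ln(1 - CPI)) with a float-safety adjustment so
    the defining inequality holds exactly at the returned N and fails at
    N + 1.  CPI = 0 yields :data:`UNLIMITED`.
    """
    if not 0.0 <= cpi < 1.0:
        raise ValidationError(f"CPI must lie in [0, 1), got {cpi}")
    if not 0.0 < cl_target < 1.0:
        raise ValidationError(f"confidence level must lie in (0, 1), got {cl_target}")
    if cpi == 0.0:
        return UNLIMITED
    n = math.floor(math.log(cl_target) / math.log1p(-cpi))
    # bounded guard against floating-point boundary error in the division;
    # for very small CPI the step response of CL is below float resolution,
    # so only a few correction steps are ever meaningful
    for _ in range(64):
        if n > 0 and confidence_level(cpi, n) < cl_target:
            n -= 1
        elif confidence_level(cpi, n + 1) >= cl_target and confidence_level(
            cpi, n + 1
        ) < confidence_level(cpi, n):
            n += 1
        else:
            break
    return float(n)


def cumulative_profile(
    pi_of: Mapping[str, float],
    confidence_levels: Sequence[float] = (0.95, 0.99, 0.9999),
) -> ForensicProfile:
    """Accumulate loci by ascending PI into a cumulative CPI/CPD table.

    ``pi_of`` maps each usable locus (linkage representative or singleton)
    to its probability of identity; ties in PI order break by locus id.
    """
    if not pi_of:
        raise ValidationError("at least one usable locus is required")
    for locus, pi in pi_of.items():
        if not 0.0 < pi <= 1.0:
            raise ValidationError(f"PI of locus {locus!r} must lie in (0, 1], got {pi}")
    for cl in confidence_levels:
        if not 0.0 < cl < 1.0:
            raise ValidationError(f"confidence level must lie in (0, 1), got {cl}")
    ordered = sorted(pi_of.items(), key=lambda kv: (kv[1], kv[0]))
    steps: list[ForensicStep] = []
    log_cpi = 0.0
    for k, (locus, pi) in enumerate(ordered, start=1):
        log_cpi += math.log(pi)
        cpi = math.exp(log_cpi)
        n_max = {cl: max_identifiable(cpi, cl) if cpi < 1.0 else 0.0 for cl in confidence_levels}
        steps.append(ForensicStep(k=k, locus=locus, pi=pi, cpi=cpi, cpd=1.0 - cpi, n_max=n_max))
    return ForensicProfile(steps=steps, confidence_levels=tuple(confidence_levels))
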