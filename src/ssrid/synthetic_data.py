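"""Synthetic diploid SSR genotype generator.

Population allele frequencies follow the Balding-Nichols construction:
ancestral frequencies are drawn from a symmetric Dirichlet, then each
population draws its own frequencies from Dirichlet(p_anc * (1 - Fst)/Fst).
Genotypes are sampled with an inbreeding coefficient Fis (homozygote excess),
optional perfectly linked locus groups (copied genotypes with re-mapped
allele labels), hidden null alleles (null/null -> missing, null/visible ->
apparent homozygote), and a random missing-data mask.  Every draw flows from
the config seed, so a config reproduces its matrix byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np

from .errors import ConfigError
from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class SimConfig:
    """Full parameterization of one simulated dataset."""

    n_pops: int = 2
    pop_sizes: Sequence[int] = (50, 50)
    n_loci: int = 10
    alleles_min: int = 2
    alleles_max: int = 8
    dirichlet_alpha: float = 1.0
    fst: float = 0.05
    fis: float = 0.0
    linked_groups: list[list[int]] = field(default_factory=list)  # locus indices; first = head
    null_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    pop_names: Sequence[str] | None = None

    def validate(self) -> None:
        if self.n_pops < 1 or len(self.pop_sizes) != self.n_pops:
            raise ConfigError("pop_sizes must list one size per population")
        if any(s < 1 for s in self.pop_sizes):
            raise ConfigError("population sizes must be >= 1")
        if not 2 <= self.alleles_min <= self.alleles_max:
            raise ConfigError("allele count range must satisfy 2 <= min <= max")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigError(f"fst must lie in [0, 1), got {self.fst}")
        if not -1.0 < self.fis <= 1.0:  # fis = 1 allowed as the no-heterozygote limit
            raise ConfigError(f"fis must lie in (-1, 1], got {self.fis}")
        for rate, name in ((self.null_rate, "null_rate"), (self.missing_rate, "missing_rate")):
            if not 0.0 <= rate < 1.0:
                raise ConfigError(f"{name} must lie in [0, 1), got {rate}")
        seen: set[int] = set()
        for group in self.linked_groups:
            if len(group) < 2:
                raise ConfigError("linked groups need >= 2 loci")
            for j in group:
                if not 0 <= j < self.n_loci:
                    raise ConfigError(f"linked locus index {j} out of range")
                if j in seen:
                    raise ConfigError(f"locus index {j} appears in two linked groups")
                seen.add(j)
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.pop_names is not None and len(self.pop_names) != self.n_pops:
            raise ConfigError("pop_names must list one name per population")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["pop_sizes"] = list(self.pop_sizes)
        if self.pop_names is not None:
            d["pop_names"] = list(self.pop_names)
        return d


def canonical_config(seed: int = 20220308) -> SimConfig:
    """Canonical desk-scale fixture: 4 populations (20/25/23/24 individuals),
    36 loci with 2-27 alleles, moderate differentiation and inbreeding, two
    perfectly linked groups, low null-allele and missing rates."""
    return SimConfig(
        n_pops=4,
        pop_sizes=(20, 25, 23, 24),
        pop_names=("MM", "HV", "GW", "SY"),
        n_loci=36,
        alleles_min=2,
        alleles_max=27,
        dirichlet_alpha=0.15,  # skewed ancestral frequencies -> mean He near 0.55
        fst=0.06,
        fis=0.2,
        linked_groups=[[0, 1, 2], [10, 11, 12, 13]],
        null_rate=0.02,
        missing_rate=0.01,
        seed=seed,
    )


def _genotype_probs(freqs: np.ndarray, fis: float, locus: str) -> tuple[np.ndarray, np.ndarray]:
    """Flattened unordered-genotype probabilities (index pairs, probs)."""
    k = len(freqs)
    pairs = []
    probs = []
    for i in range(k):
        for j in range(i, k):
            if i == j:
                pr = freqs[i] ** 2 + fis * freqs[i] * (1.0 - freqs[i])
            else:
                pr = 2.0 * freqs[i] * freqs[j] * (1.0 - fis)
            if pr < -1e-12:
                raise ConfigError(
                    f"fis={fis} yields a negative genotype probability at locus {locus}"
                )
            pairs.append((i, j))
            probs.append(max(pr, 0.0))
    probs_arr = np.asarray(probs)
    return np.asarray(pairs, dtype=np.int64), probs_arr / probs_arr.sum()


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, dict[str, Any]]:
    """Draw one genotype matrix plus a truth record of all hidden parameters."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pops = list(config.pop_names) if config.pop_names else [f"P{i + 1}" for i in range(config.n_pops)]
    locus_ids = [f"L{j + 1:03d}" for j in range(config.n_loci)]
    n_total = int(sum(config.pop_sizes))
    individual_ids = []
    populations = []
    for pop, size in zip(pops, config.pop_sizes):
        for k in range(size):
            individual_ids.append(f"{pop}-{k + 1:03d}")
            populations.append(pop)

    head_of = {}  # member locus index -> (head index, is_head)
    for group in config.linked_groups:
        for j in group:
            head_of[j] = group[0]

    # per-locus allele machinery: labels are even bp-like sizes in 100-400
    n_alleles = rng.integers(config.alleles_min, config.alleles_max + 1, size=config.n_loci)
    ancestral: list[np.ndarray] = []
    pop_freqs: list[np.ndarray] = []  # per locus: (n_pops, k[+null])
    labels: list[np.ndarray] = []
    null_index: list[int | None] = []
    for j in range(config.n_loci):
        k = int(n_alleles[j])
        start = int(rng.integers(50, 200 - k))
        labels.append(np.arange(start, start + k) * 2)  # distinct even labels
        p_anc = rng.dirichlet(np.full(k, config.dirichlet_alpha))
        p_anc = np.clip(p_anc, 1e-6, None)
        p_anc /= p_anc.sum()
        if config.null_rate > 0:
            p_anc = np.append(p_anc * (1.0 - config.null_rate), config.null_rate)
            null_index.append(k)  # last index is the hidden null allele
        else:
            null_index.append(None)
        ancestral.append(p_anc)
        if config.fst == 0.0:
            pf = np.tile(p_anc, (config.n_pops, 1))
        else:
            scale = (1.0 - config.fst) / config.fst
            pf = np.vstack(
                [rng.dirichlet(np.clip(p_anc * scale, 1e-9, None)) for _ in range(config.n_pops)]
            )
        pop_freqs.append(pf)

    # genotype sampling in allele-index space (null included as an index)
    index_calls = np.zeros((n_total, config.n_loci, 2), dtype=np.int64)
    pop_offset = np.cumsum([0, *config.pop_sizes])
    for j in range(config.n_loci):
        if head_of.get(j, j) != j:
            continue  # linked member: copied from head below
        for pi in range(config.n_pops):
            lo, hi = pop_offset[pi], pop_offset[pi + 1]
            pairs, probs = _genotype_probs(pop_freqs[j][pi], config.fis, locus_ids[j])
            draw = rng.choice(len(probs), size=hi - lo, p=probs)
            index_calls[lo:hi, j, :] = pairs[draw]
    for group in config.linked_groups:
        head = group[0]
        for j in group[1:]:
            # same genotype pattern, locus-specific labels (perfect linkage)
            index_calls[:, j, :] = index_calls[:, head, :]

    # map indices to labels, collapsing null alleles
    calls = np.zeros_like(index_calls)
    for j in range(config.n_loci):
        src = head_of.get(j, j)  # linked members inherit the head's index space
        ni = null_index[src]
        k_eff = len(ancestral[src]) - (1 if ni is not None else 0)
        lab = labels[j]
        if len(lab) < k_eff:  # member locus needs at least the head's allele count
            lab = np.arange(lab[0] // 2, lab[0] // 2 + k_eff) * 2
            labels[j] = lab
        for i in range(n_total):
            a, b = index_calls[i, j]
            if ni is not None and a == ni and b == ni:
                calls[i, j] = (MISSING, MISSING)
            elif ni is not None and (a == ni or b == ni):
                visible = b if a == ni else a
                calls[i, j] = (lab[visible], lab[visible])  # apparent homozygote
            else:
                calls[i, j] = (lab[a], lab[b])

    if config.missing_rate > 0:
        mask = rng.random((n_total, config.n_loci)) < config.missing_rate
        calls[mask] = (MISSING, MISSING)

    matrix = GenotypeMatrix(individual_ids, locus_ids, populations, calls)
    truth = {
        "config": config.to_dict(),
        "populations": pops,
        "locus_ids": locus_ids,
        "n_alleles": [int(x) for x in n_alleles],
        "ancestral_freqs": {locus_ids[j]: ancestral[j].tolist() for j in range(config.n_loci)},
        "population_freqs": {locus_ids[j]: pop_freqs[j].tolist() for j in range(config.n_loci)},
        "allele_labels": {locus_ids[j]: labels[j].tolist() for j in range(config.n_loci)},
        "null_allele_index": {locus_ids[j]: null_index[j] for j in range(config.n_loci)},
        "linked_groups": [[locus_ids[j] for j in g] for g in config.linked_groups],
    }
    return matrix, truth
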