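"""Diploid SSR genotype matrices and text-format readers/writers.

The central data structure is :class:`GenotypeMatrix`: individuals x loci,
each cell an unordered pair of positive integer allele labels (fragment
sizes in bp) or missing.  Three community text formats are supported:

* GenAlEx codominant CSV (missing code ``0``),
* Genepop with 2- or 3-digit allele coding (missing ``00``/``000``),
* STRUCTURE two-row-per-individual layout (missing ``-9``).

Internally a single sentinel :data:`MISSING` (= -1) marks missing calls and
allele pairs are stored sorted, so ``(a, b)`` and ``(b, a)`` compare equal.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import FormatError, ValidationError

#: Sentinel allele value marking a missing call. Any real allele label is > 0.
MISSING: int = -1


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

class GenotypeMatrix:
    """Diploid genotype calls for a set of individuals at a set of loci.

    Parameters
    ----------
    individual_ids
        Unique individual identifiers, in file/sample order.
    locus_ids
        Unique locus identifiers.
    populations
        Population label per individual (parallel to ``individual_ids``).
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``.  A missing
        call is ``(MISSING, MISSING)``; otherwise both entries are positive
        allele labels.  Pairs are normalised to sorted order on construction.
    """

    def __init__(
        self,
        individual_ids: Sequence[str],
        locus_ids: Sequence[str],
        populations: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        self.individual_ids = [str(i) for i in individual_ids]
        self.locus_ids = [str(l) for l in locus_ids]
        self.populations = [str(p) for p in populations]
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(self.individual_ids), len(self.locus_ids), 2):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        # normalise unordered pairs; missing stored as (MISSING, MISSING)
        self.calls = np.sort(calls, axis=2)
        self._validate()

    def _validate(self) -> None:
        if len(set(self.individual_ids)) != len(self.individual_ids):
            dupes = {i for i in self.individual_ids if self.individual_ids.count(i) > 1}
            raise ValidationError(f"duplicate individual id(s): {sorted(dupes)}")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            dupes = {l for l in self.locus_ids if self.locus_ids.count(l) > 1}
            raise ValidationError(f"duplicate locus id(s): {sorted(dupes)}")
        if len(self.populations) != len(self.individual_ids):
            raise ValidationError("one population label required per individual")
        half_missing = (self.calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValidationError("half-missing calls are not representable")
        bad = (self.calls != MISSING) & (self.calls <= 0)
        if bad.any():
            raise ValidationError("allele labels must be positive integers")

    # -- basic introspection ------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def population_of(self) -> dict[str, str]:
        return dict(zip(self.individual_ids, self.populations))

    @property
    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (individual, locus) array, True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_ids.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def individuals_in(self, population: str) -> list[str]:
        if population not in self.populations:
            raise KeyError(f"unknown population label {population!r}")
        return [i for i, p in zip(self.individual_ids, self.populations) if p == population]

    def subset_indices(self, subset: str | Iterable[str] | None) -> np.ndarray:
        """Row indices selected by *subset*.

        ``subset`` may be ``None`` (all individuals), a population label, or
        an iterable of individual ids.
        """
        if subset is None:
            return np.arange(self.n_individuals)
        if isinstance(subset, str):
            if subset not in self.populations:
                raise KeyError(f"unknown population label {subset!r}")
            return np.flatnonzero(np.asarray(self.populations) == subset)
        wanted = list(subset)
        index = {ind: k for k, ind in enumerate(self.individual_ids)}
        missing = [i for i in wanted if i not in index]
        if missing:
            raise KeyError(f"unknown individual id(s): {missing}")
        return np.asarray([index[i] for i in wanted], dtype=np.intp)

    def drop_population(self, population: str) -> "GenotypeMatrix":
        keep = [k for k, p in enumerate(self.populations) if p != population]
        if len(keep) == len(self.populations):
            raise KeyError(f"unknown population label {population!r}")
        return GenotypeMatrix(
            [self.individual_ids[k] for k in keep],
            list(self.locus_ids),
            [self.populations[k] for k in keep],
            self.calls[keep],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locus_ids == other.locus_ids
            and self.populations == other.populations
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_individuals} individuals, {self.n_loci} loci, "
            f"{len(self.population_labels)} populations)"
        )


@dataclass
class AlleleFrequencyTable:
    """Relative allele frequencies per locus plus typed-sample counts.

    ``freqs[locus]`` maps allele label to relative frequency (sums to 1 for
    any locus with at least one typed individual); ``n_typed[locus]`` is the
    number of non-missing diploid individuals counted; loci where nobody was
    typed are listed in ``untyped_loci`` with an empty frequency map.
    """

    freqs: dict[str, dict[int, float]]
    n_typed: dict[str, int]
    untyped_loci: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for locus, f in self.freqs.items():
            if not f:
                continue
            total = sum(f.values())
            if any(v < 0 for v in f.values()) or abs(total - 1.0) > 1e-12:
                raise ValidationError(f"frequencies at locus {locus!r} do not sum to 1")


def allele_frequencies(
    matrix: GenotypeMatrix, subset: str | Iterable[str] | None = None
) -> AlleleFrequencyTable:
    """Count allele frequencies per locus over a subset of individuals.

    Each non-missing individual contributes its two allele copies
    (complete-case per locus).  Loci with zero typed individuals are flagged
    in ``untyped_loci`` rather than dropped.
    """
    rows = matrix.subset_indices(subset)
    if rows.size == 0:
        raise ValidationError("subset selects no individuals")
    freqs: dict[str, dict[int, float]] = {}
    n_typed: dict[str, int] = {}
    untyped: set[str] = set()
    for j, locus in enumerate(matrix.locus_ids):
        cells = matrix.calls[rows, j, :]
        typed = cells[cells[:, 0] != MISSING]
        n_typed[locus] = len(typed)
        if len(typed) == 0:
            freqs[locus] = {}
            untyped.add(locus)
            continue
        labels, counts = np.unique(typed.ravel(), return_counts=True)
        total = counts.sum()
        freqs[locus] = {int(a): float(c) / total for a, c in zip(labels, counts)}
    return AlleleFrequencyTable(freqs=freqs, n_typed=n_typed, untyped_loci=untyped)


# ---------------------------------------------------------------------------
# GenAlEx codominant CSV
# ---------------------------------------------------------------------------

def read_genalex(path: str | Path) -> GenotypeMatrix:
    """Read a GenAlEx codominant CSV file.

    Layout: row 1 holds ``n_loci, n_individuals, n_pops, size_1, ..., size_k``;
    row 2 a free title with population names after the third column; row 3 the
    column header (sample, population, then two columns per locus where the
    locus name sits over the first of the two).  The missing allele code is 0.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if len(rows) < 4:
        raise FormatError(f"{path}: fewer than 4 rows, not a GenAlEx codominant file")
    try:
        n_loci, n_ind, n_pops = (int(rows[0][k]) for k in range(3))
        pop_sizes = [int(x) for x in rows[0][3 : 3 + n_pops]]
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed GenAlEx header row 1: {exc}") from None
    if sum(pop_sizes) != n_ind:
        raise FormatError(
            f"{path}: header population sizes {pop_sizes} sum to {sum(pop_sizes)}, "
            f"expected {n_ind} individuals (row 1)"
        )
    header = rows[2]
    locus_ids = [header[2 + 2 * j].strip() for j in range(n_loci)]
    if any(not l for l in locus_ids):
        raise FormatError(f"{path}: empty locus name in header row 3")
    body = rows[3:]
    if len(body) != n_ind:
        raise FormatError(
            f"{path}: header declares {n_ind} individuals but body has {len(body)} "
            f"data rows (first body line is file line 4)"
        )
    individual_ids, populations = [], []
    calls = np.full((n_ind, n_loci, 2), MISSING, dtype=np.int64)
    for i, row in enumerate(body):
        if len(row) < 2 + 2 * n_loci:
            raise FormatError(f"{path}: data row {i + 4} has too few columns")
        individual_ids.append(row[0].strip())
        populations.append(row[1].strip())
        for j in range(n_loci):
            a, b = row[2 + 2 * j].strip(), row[3 + 2 * j].strip()
            calls[i, j] = _decode_pair(a, b, missing_code="0", where=f"{path} row {i + 4}")
    return GenotypeMatrix(individual_ids, locus_ids, populations, calls)


def _decode_pair(a: str, b: str, missing_code: str, where: str) -> tuple[int, int]:
    a = a or missing_code
    b = b or missing_code
    try:
        ai, bi = int(a), int(b)
    except ValueError:
        raise FormatError(f"{where}: non-integer allele call {a!r}/{b!r}") from None
    if ai == int(missing_code) or bi == int(missing_code):
        return (MISSING, MISSING)
    if ai <= 0 or bi <= 0:
        raise FormatError(f"{where}: allele labels must be positive, got {ai}/{bi}")
    return (ai, bi)


def write_genalex(matrix: GenotypeMatrix, path: str | Path, title: str = "ssrid export") -> None:
    """Write *matrix* as a GenAlEx codominant CSV (missing code 0)."""
    path = Path(path)
    pops = matrix.population_labels
    sizes = [matrix.populations.count(p) for p in pops]
    order = [i for p in pops for i, q in zip(range(matrix.n_individuals), matrix.populations) if q == p]
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([matrix.n_loci, matrix.n_individuals, len(pops), *sizes])
        w.writerow([title, "", "", *pops])
        header: list[str] = ["Sample", "Pop"]
        for locus in matrix.locus_ids:
            header += [locus, ""]
        w.writerow(header)
        for i in order:
            row: list[object] = [matrix.individual_ids[i], matrix.populations[i]]
            for j in range(matrix.n_loci):
                a, b = matrix.calls[i, j]
                row += ["0", "0"] if a == MISSING else [int(a), int(b)]
            w.writerow(row)


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Read a Genepop file with 2- or 3-digit allele coding.

    ``Pop`` lines separate populations.  Individual names written by this
    package carry the population label as ``pop:individual``; otherwise the
    population is named after its first individual (standard Genepop
    convention).  ``00``/``000`` encodes a missing allele.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: too short for a Genepop file")
    # locus names: either one per line, or a single comma-separated line
    locus_ids: list[str] = []
    k = 1
    while k < len(lines) and not _POP_RE.match(lines[k]):
        part = [t.strip() for t in lines[k].split(",") if t.strip()]
        locus_ids.extend(part)
        k += 1
    if k == len(lines):
        raise FormatError(f"{path}: no 'Pop' separator found")
    n_loci = len(locus_ids)
    individual_ids: list[str] = []
    populations: list[str] = []
    call_rows: list[list[tuple[int, int]]] = []
    digits_per_locus: list[int | None] = [None] * n_loci
    pop_ordinal = 0
    cur_pop: str | None = None
    while k < len(lines):
        if _POP_RE.match(lines[k]):
            pop_ordinal += 1
            cur_pop = None
            k += 1
            continue
        line = lines[k]
        if "," not in line:
            raise FormatError(f"{path} line {k + 1}: expected '<name> , <genotypes>'")
        name, geno = line.split(",", 1)
        name = name.strip()
        if ":" in name:
            pop_label, ind_id = name.split(":", 1)
        else:
            pop_label, ind_id = None, name
        if cur_pop is None:
            cur_pop = pop_label if pop_label is not None else f"Pop{pop_ordinal}"
        populations.append(pop_label if pop_label is not None else cur_pop)
        individual_ids.append(ind_id)
        tokens = geno.split()
        if len(tokens) != n_loci:
            raise FormatError(
                f"{path} line {k + 1}: {len(tokens)} genotype fields, expected {n_loci}"
            )
        row: list[tuple[int, int]] = []
        for j, tok in enumerate(tokens):
            if len(tok) == 4:
                d = 2
            elif len(tok) == 6:
                d = 3
            else:
                raise FormatError(
                    f"{path} line {k + 1}: genotype {tok!r} at locus {locus_ids[j]} is "
                    "neither 4 nor 6 characters"
                )
            if digits_per_locus[j] is None:
                digits_per_locus[j] = d
            elif digits_per_locus[j] != d:
                raise FormatError(
                    f"{path} line {k + 1}: mixed {digits_per_locus[j]}- and {d}-digit "
                    f"coding at locus {locus_ids[j]}"
                )
            try:
                a, b = int(tok[:d]), int(tok[d:])
            except ValueError:
                raise FormatError(f"{path} line {k + 1}: non-numeric genotype {tok!r}") from None
            row.append((MISSING, MISSING) if a == 0 or b == 0 else (a, b))
        call_rows.append(row)
        k += 1
    calls = np.asarray(call_rows, dtype=np.int64).reshape(len(individual_ids), n_loci, 2)
    return GenotypeMatrix(individual_ids, locus_ids, populations, calls)


def write_genepop(matrix: GenotypeMatrix, path: str | Path, title: str = "ssrid export") -> None:
    """Write *matrix* in Genepop format.

    Uses 3-digit coding (2-digit when every allele label at every locus is
    < 100) and names each individual ``pop:individual`` so population labels
    survive a round-trip.
    """
    path = Path(path)
    present = matrix.calls[matrix.calls != MISSING]
    digits = 2 if present.size and present.max() < 100 else 3
    if present.size and present.max() >= 10**digits:
        raise ValidationError(
            f"allele label {int(present.max())} does not fit {digits}-digit Genepop coding"
        )
    buf = io.StringIO()
    buf.write(title + "\n")
    for locus in matrix.locus_ids:
        buf.write(locus + "\n")
    for pop in matrix.population_labels:
        buf.write("Pop\n")
        for i in (k for k, p in enumerate(matrix.populations) if p == pop):
            fields = []
            for j in range(matrix.n_loci):
                a, b = matrix.calls[i, j]
                if a == MISSING:
                    fields.append("0" * (2 * digits))
                else:
                    fields.append(f"{int(a):0{digits}d}{int(b):0{digits}d}")
            buf.write(f"{pop}:{matrix.individual_ids[i]} ,  " + " ".join(fields) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# STRUCTURE (two-row)
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> GenotypeMatrix:
    """Read a two-row-per-individual STRUCTURE file.

    First line: whitespace-separated locus names.  Each individual occupies
    two consecutive rows of ``<id> <pop> <allele per locus ...>``; the two
    rows carry the two allele copies.  ``-9`` is the missing code.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: too short for a STRUCTURE file")
    locus_ids = lines[0].split()
    n_loci = len(locus_ids)
    body = lines[1:]
    if len(body) % 2:
        raise FormatError(
            f"{path}: {len(body)} genotype rows — two-row layout requires an even count"
        )
    individual_ids, populations = [], []
    n_ind = len(body) // 2
    calls = np.full((n_ind, n_loci, 2), MISSING, dtype=np.int64)
    for i in range(n_ind):
        r1, r2 = body[2 * i].split(), body[2 * i + 1].split()
        if len(r1) != 2 + n_loci or len(r2) != 2 + n_loci:
            raise FormatError(f"{path}: individual block {i + 1} has a wrong column count")
        if r1[0] != r2[0] or r1[1] != r2[1]:
            raise FormatError(
                f"{path}: the two rows of individual {r1[0]!r} disagree on id/population"
            )
        individual_ids.append(r1[0])
        populations.append(r1[1])
        for j in range(n_loci):
            try:
                a, b = int(r1[2 + j]), int(r2[2 + j])
            except ValueError:
                raise FormatError(f"{path}: non-integer allele for individual {r1[0]!r}") from None
            if a == -9 or b == -9:
                calls[i, j] = (MISSING, MISSING)
            else:
                calls[i, j] = (a, b)
    return GenotypeMatrix(individual_ids, locus_ids, populations, calls)


def write_structure(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write *matrix* in the two-row STRUCTURE layout (missing code -9)."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(" ".join(matrix.locus_ids) + "\n")
    for i in range(matrix.n_individuals):
        for slot in (0, 1):
            fields = [matrix.individual_ids[i], matrix.populations[i]]
            for j in range(matrix.n_loci):
                a = matrix.calls[i, j, slot]
                fields.append("-9" if a == MISSING else str(int(a)))
            buf.write(" ".join(fields) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


FORMAT_READERS = {
    "genalex": read_genalex,
    "genepop": read_genepop,
    "structure": read_structure,
}

FORMAT_WRITERS = {
    "genalex": write_genalex,
    "genepop": write_genepop,
    "structure": write_structure,
}


def read_any(path: str | Path, fmt: str) -> GenotypeMatrix:
    try:
        return FORMAT_READERS[fmt](path)
    except KeyError:
        raise ValueError(f"unknown format {fmt!r}; choose from {sorted(FORMAT_READERS)}") from None


def write_any(matrix: GenotypeMatrix, path: str | Path, fmt: str) -> None:
    try:
        FORMAT_WRITERS[fmt](matrix, path)
    except KeyError:
        raise ValueError(f"unknown format {fmt!r}; choose from {sorted(FORMAT_WRITERS)}") from None
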