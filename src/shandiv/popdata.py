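"""Genotype data model, GENEPOP I/O and without-replacement subsampling.

Diploid multilocus genotypes are held as an integer array of allele-state
labels; allele identity carries no repeat-length semantics here, so all
downstream statistics depend only on per-locus allele *counts*.  Missing
gene copies (GENEPOP code ``00``/``000``) are stored as ``-1`` and simply
reduce the number of gene copies counted at that locus.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "LocusSpec",
    "AlleleCounts",
    "PopulationSample",
    "MultiLocusDataset",
    "GenepopParseError",
    "allele_counts",
    "subsample",
    "read_genepop",
    "write_genepop",
    "write_records",
]


class GenepopParseError(ValueError):
    """Malformed GENEPOP input; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class LocusSpec:
    """A microsatellite locus: mutation rate and allelic-state cap.

    Parameters
    ----------
    name
        Text label, e.g. ``"L01"``.
    mu
        Mutation rate per gene copy per generation.
    k_max
        Maximum number of allelic states; states are labelled
        ``0 .. k_max - 1``.
    """

    name: str
    mu: float
    k_max: int

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError(f"mutation rate must be positive, got {self.mu}")
        if self.k_max < 2:
            raise ValueError(f"k_max must be >= 2, got {self.k_max}")


@dataclass(frozen=True)
class AlleleCounts:
    """Observed allele counts at one locus in one sample.

    ``counts`` stores one strictly positive integer per *observed* allele;
    unobserved alleles are never represented as zeros.  The allele labels
    themselves are discarded at tally time.
    """

    locus: str
    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("counts must be a non-empty 1-d vector")
        if np.any(arr < 1):
            raise ValueError("all allele counts must be >= 1 (drop zeros)")
        object.__setattr__(self, "counts", arr)

    @property
    def n(self) -> int:
        """Total number of gene copies."""
        return int(self.counts.sum())

    @property
    def k_obs(self) -> int:
        """Number of distinct alleles observed."""
        return int(self.counts.size)

    @property
    def f1(self) -> int:
        """Number of singleton alleles (observed exactly once)."""
        return int(np.count_nonzero(self.counts == 1))

    @property
    def f2(self) -> int:
        """Number of doubleton alleles (observed exactly twice)."""
        return int(np.count_nonzero(self.counts == 2))


@dataclass
class PopulationSample:
    """Diploid genotypes of one population at many loci.

    ``genotypes`` has shape ``(n_individuals, n_loci, 2)``; each cell pair is
    an unordered pair of integer allele states (no phase), with ``-1`` for a
    missing gene copy.
    """

    population: str
    genotypes: np.ndarray
    loci: list[str]

    def __post_init__(self):
        g = np.asarray(self.genotypes)
        if g.ndim != 3 or g.shape[2] != 2:
            raise ValueError("genotypes must have shape (individuals, loci, 2)")
        if g.shape[1] != len(self.loci):
            raise ValueError("loci list does not match genotype array width")
        self.genotypes = g.astype(np.int32, copy=False)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None


@dataclass
class MultiLocusDataset:
    """Several populations sharing one ordered locus list."""

    samples: list[PopulationSample] = field(default_factory=list)

    def __post_init__(self):
        names = [s.population for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("population labels must be unique")
        if self.samples:
            ref = self.samples[0].loci
            for s in self.samples[1:]:
                if s.loci != ref:
                    raise ValueError("all populations must share the locus list")

    @property
    def loci(self) -> list[str]:
        return self.samples[0].loci if self.samples else []

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, population: str) -> PopulationSample:
        for s in self.samples:
            if s.population == population:
                return s
        raise KeyError(f"unknown population {population!r}")


def allele_counts(sample: PopulationSample, locus: str) -> AlleleCounts:
    """Tally allele counts for one locus, both gene copies per individual.

    Missing copies (``-1``) are excluded, so ``n`` equals twice the number of
    individuals only when no data are missing at the locus.
    """
    if sample.n_individuals == 0:
        raise ValueError("cannot tally alleles from an empty sample")
    j = sample.locus_index(locus)
    copies = sample.genotypes[:, j, :].ravel()
    copies = copies[copies != MISSING]
    if copies.size == 0:
        raise ValueError(f"no genotyped copies at locus {locus!r}")
    counts = np.bincount(copies)
    return AlleleCounts(locus=locus, counts=counts[counts > 0])


def subsample(
    sample: PopulationSample, ns: int, rng: np.random.Generator
) -> PopulationSample:
    """Draw ``ns`` whole individuals uniformly without replacement.

    Both gene copies of an individual stay together; the source sample is
    untouched.
    """
    if not 1 <= ns <= sample.n_individuals:
        raise ValueError(
            f"ns must be in [1, {sample.n_individuals}], got {ns}"
        )
    idx = rng.choice(sample.n_individuals, size=ns, replace=False)
    return PopulationSample(
        population=sample.population,
        genotypes=sample.genotypes[idx].copy(),
        loci=list(sample.loci),
    )


# -- GENEPOP I/O -------------------------------------------------------------
#
# Reading goes through Bio.PopGen.GenePop (the reference parser for the
# dialect); its exceptions are re-raised as GenepopParseError with a line
# number recovered from the raw text where possible.


def read_genepop(path) -> MultiLocusDataset:
    """Read a GENEPOP file (2- or 3-digit allele codes) into a dataset.

    One :class:`PopulationSample` is produced per ``Pop`` block, labelled
    ``pop1``, ``pop2``, ...  The allele code ``00``/``000`` marks a missing
    gene copy and is stored as ``-1``.
    """
    from Bio.PopGen import GenePop

    with open(path) as fh:
        text = fh.read()
    try:
        record = GenePop.read(io.StringIO(text))
    except (ValueError, IndexError, StopIteration) as exc:
        # Biopython's parser raises bare IndexError on ragged genotype rows
        message = str(exc) or "malformed GENEPOP record"
        raise GenepopParseError(message, line=_guess_bad_line(text)) from exc

    loci = list(record.loci_list)
    samples = []
    for p, pop in enumerate(record.populations, start=1):
        rows = []
        for name, genotype in pop:
            if len(genotype) != len(loci):
                raise GenepopParseError(
                    f"individual {name.strip()!r} has {len(genotype)} genotypes "
                    f"for {len(loci)} loci"
                )
            row = [
                [MISSING if a in (None, 0) else int(a) for a in pair]
                for pair in genotype
            ]
            rows.append(row)
        samples.append(
            PopulationSample(
                population=f"pop{p}",
                genotypes=np.asarray(rows, dtype=np.int32),
                loci=loci,
            )
        )
    return MultiLocusDataset(samples=samples)


def _guess_bad_line(text: str) -> int | None:
    """Best-effort line number for a parse failure: first genotype row whose
    token count disagrees with the locus count, else None."""
    lines = text.splitlines()
    n_loci = 0
    for i, line in enumerate(lines[1:], start=2):
        if line.strip().lower() == "pop":
            break
        n_loci += len([t for t in line.replace(",", " ").split() if t])
    else:
        return None
    for j, line in enumerate(lines[i:], start=i + 1):
        if line.strip().lower() == "pop" or not line.strip():
            continue
        if "," not in line:
            return j
        geno = line.split(",", 1)[1].split()
        if len(geno) != n_loci:
            return j
    return None


def write_genepop(dataset: MultiLocusDataset, path, title: str = "shandiv export"):
    """Write a dataset as a GENEPOP file with 3-digit allele codes."""
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in dataset.loci:
            fh.write(locus + "\n")
        for sample in dataset:
            fh.write("Pop\n")
            for i in range(sample.n_individuals):
                cells = []
                for j in range(len(sample.loci)):
                    a, b = sample.genotypes[i, j]
                    cells.append(
                        f"{_code(a)}{_code(b)}"
                    )
                fh.write(f"{sample.population}_{i + 1} , " + " ".join(cells) + "\n")


def _code(allele: int) -> str:
    # state s is written as code s+1 so that 000 stays reserved for missing
    return "000" if allele == MISSING else f"{allele + 1:03d}"


def write_records(records, path, columns: Sequence[str] | None = None) -> None:
    """Write records to CSV: UTF-8, header row, empty cells for missing.

    ``records`` may be a DataFrame or a sequence of dataclasses/mappings
    sharing one schema.  Floats are written shortest-round-trip (lossless,
    always more than 6 significant digits when needed).  ``columns`` fixes
    the header order (and makes an empty sequence produce a header-only
    file).
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        rows = []
        for r in records:
            if isinstance(r, Mapping):
                rows.append(dict(r))
            elif hasattr(r, "__dataclass_fields__"):
                rows.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            else:
                raise TypeError(f"cannot serialise record of type {type(r)!r}")
        cols = list(columns) if columns is not None else (list(rows[0]) if rows else None)
        frame = pd.DataFrame(rows, columns=cols)
    try:
        frame.to_csv(path, index=False, na_rep="")
    except OSError as exc:
        raise OSError(f"cannot write records to {path}: {exc}") from exc
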