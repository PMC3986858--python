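"""Core in-memory containers shared across the package.

The analysis operates on three kinds of objects: diploid microsatellite
genotype tables (allele sizes in base pairs), per-locus allele frequency
spectra for a population or species pool, and symmetric distance matrices
(genetic or geographic).  All three are thin dataclasses around numpy
arrays / plain dicts so they serialize cleanly to the text formats in
:mod:`eelclines.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = 0
"""Sentinel allele size for a missing gene copy (Genepop's ``000``)."""


@dataclass
class GenotypeTable:
    """Diploid genotypes (allele sizes, bp) for individuals at named loci.

    Parameters
    ----------
    individuals
        Ordered individual IDs (unique).
    populations
        Population label per individual (same order).
    loci
        Ordered locus names.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``.  A call is
        missing iff both entries equal :data:`MISSING`; a half-missing call
        is invalid.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, m = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {m}, 2)"
            )
        if len(self.populations) != n:
            raise ValueError("populations length must match individuals")
        if any(not p for p in self.populations):
            raise ValueError("population labels must be non-empty")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing call for {self.individuals[i]} at {self.loci[j]}"
            )
        if (self.calls < 0).any():
            raise ValueError("allele sizes must be positive (0 = missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_individuals, n_loci)`` mask, True where missing."""
        return (self.calls == MISSING).all(axis=2)

    def subset(self, indices: Sequence[int], populations: Sequence[str] | None = None) -> "GenotypeTable":
        idx = list(indices)
        pops = list(populations) if populations is not None else [self.populations[i] for i in idx]
        return GenotypeTable(
            individuals=[self.individuals[i] for i in idx],
            populations=pops,
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
        )

    def population_groups(self) -> dict[str, list[int]]:
        """Indices of individuals per population, in first-seen order."""
        groups: dict[str, list[int]] = {}
        for i, p in enumerate(self.populations):
            groups.setdefault(p, []).append(i)
        return groups

    @staticmethod
    def concat(tables: Iterable["GenotypeTable"]) -> "GenotypeTable":
        tables = list(tables)
        loci = tables[0].loci
        for t in tables[1:]:
            if t.loci != loci:
                raise ValueError("cannot concatenate tables with different loci")
        return GenotypeTable(
            individuals=[i for t in tables for i in t.individuals],
            populations=[p for t in tables for p in t.populations],
            loci=list(loci),
            calls=np.concatenate([t.calls for t in tables], axis=0),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class AlleleFrequencySpectrum:
    """Per-locus allele counts and frequencies for one group of gene copies.

    ``counts[locus][allele]`` is the number of observed gene copies
    carrying ``allele`` (an allele size in bp); missing calls are never
    counted.  Frequencies are derived, so the spectrum stays usable for
    count-based smoothing (ancestry likelihoods) and for rarefaction.
    """

    loci: list[str]
    counts: dict[str, dict[int, int]]

    def n_copies(self, locus: str) -> int:
        return sum(self.counts[locus].values())

    def frequencies(self, locus: str) -> dict[int, float]:
        c = self.counts[locus]
        n = sum(c.values())
        if n == 0:
            return {}
        return {a: k / n for a, k in c.items()}

    def alleles(self, locus: str) -> list[int]:
        return sorted(self.counts[locus])

    @classmethod
    def from_table(cls, table: GenotypeTable, indices: Sequence[int] | None = None) -> "AlleleFrequencySpectrum":
        if indices is None:
            indices = range(table.n_individuals)
        counts: dict[str, dict[int, int]] = {l: {} for l in table.loci}
        for j, locus in enumerate(table.loci):
            d = counts[locus]
            for i in indices:
                a, b = table.calls[i, j]
                if a == MISSING:
                    continue
                d[int(a)] = d.get(int(a), 0) + 1
                d[int(b)] = d.get(int(b), 0) + 1
        return cls(loci=list(table.loci), counts=counts)

    @classmethod
    def from_frequencies(
        cls, freqs: Mapping[str, Mapping[int, float]], n_copies: int = 1_000_000
    ) -> "AlleleFrequencySpectrum":
        """Build a spectrum from exact frequencies via large pseudo-counts."""
        counts = {
            l: {int(a): int(round(p * n_copies)) for a, p in d.items()}
            for l, d in freqs.items()
        }
        return cls(loci=list(freqs), counts=counts)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with a zero diagonal and labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix is not symmetric within 1e-9")
        if np.abs(np.diag(self.values)).max(initial=0.0) != 0.0:
            raise ValueError("diagonal must be exactly zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")
        # enforce exact symmetry after the tolerance check
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries (row-major, i > j) as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class HaplotypeAlignment:
    """Equal-length uppercase DNA sequences over {A, C, G, T, N}."""

    ids: list[str]
    sequences: list[str]
    species: list[str] | None = None

    _ALPHABET = frozenset("ACGTN")

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must have equal length")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            bad = [
                i for i, s in zip(self.ids, self.sequences)
                if len(s) != len(self.sequences[0])
            ]
            raise ValueError(f"unequal sequence lengths for: {', '.join(bad)}")
        for i, s in zip(self.ids, self.sequences):
            if not set(s) <= self._ALPHABET:
                raise ValueError(f"non-ACGTN character in sequence {i}")
        if self.species is not None and len(self.species) != len(self.ids):
            raise ValueError("species tags must match sequence count")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)
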