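"""Generative hybridization-cline experiments.

Two ways of building 12 virtual populations whose hybrid content rises
linearly along a transect (population 1 = southern-most, purest;
population 12 = northern-most, most admixed):

* **F1 parent mode** — each population is bred from 50 random parental
  pairs drawn with replacement from the pure European pool; moving north,
  a growing percentage of parent slots is replaced by American parents
  (one extra American parent per population under the 1% increment).
* **Admixed-fraction mode** — each population contains a growing
  fraction of admixed genotypes whose ancestry proportion Q is drawn
  from a binned Q distribution; for each locus the number of
  European-origin gene copies is Binomial(2, Q), and each copy's allele
  is a multinomial draw from the corresponding species spectrum.

Both modes record realized (not nominal) hybrid fractions, which the
downstream gene-flow regressions consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .admixture import QDistribution
from .random_utils import rng_for
from .types import MISSING, AlleleFrequencySpectrum, GenotypeTable

F1_PARENTS = "f1_parents"
ADMIXED_FRACTION = "admixed_fraction"


@dataclass
class ClineScenario:
    increment_pct: float = 1.0
    n_populations: int = 12
    n_pairs: int = 50
    offspring_per_population: int = 100
    mode: str = F1_PARENTS
    strict_f1: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (F1_PARENTS, ADMIXED_FRACTION):
            raise ValueError(f"unknown mode '{self.mode}'")
        if self.increment_pct < 0:
            raise ValueError("increment must be non-negative")
        if self.increment_pct * (self.n_populations - 1) > 100:
            raise ValueError("cline would exceed 100% hybrids")
        if min(self.n_populations, self.n_pairs, self.offspring_per_population) < 1:
            raise ValueError("counts must be positive")


@dataclass
class ClineDataset:
    populations: list[GenotypeTable]
    realized_fractions: list[float]
    scenario: ClineScenario
    seed: int

    def __post_init__(self) -> None:
        fr = self.realized_fractions
        if any(b < a for a, b in zip(fr, fr[1:])):
            raise ValueError("realized hybrid fractions must be non-decreasing")

    def combined_table(self) -> GenotypeTable:
        return GenotypeTable.concat(self.populations)

    def labels(self) -> list[str]:
        return [t.populations[0] for t in self.populations]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# F1 parent mode


def make_f1_population(
    pool_european: GenotypeTable,
    pool_american: GenotypeTable,
    n_pairs: int,
    n_american_parents: int,
    offspring_per_population: int,
    rng: np.random.Generator,
    pop_label: str = "virt",
    strict_f1: bool = False,
) -> GenotypeTable:
    """Breed one virtual population from a partly American parent set.

    ``2 * n_pairs`` parent slots are filled with replacement from the
    European pool; ``n_american_parents`` uniformly chosen slots are
    replaced by American draws; slots are paired at random and each pair
    contributes an equal share of the offspring (Mendelian: one uniform
    allele per locus from each parent).  With ``strict_f1`` the American
    parents are placed so that no pair is American x American.
    """
    if pool_european.n_individuals == 0 or pool_american.n_individuals == 0:
        raise ValueError("parent pools must be non-empty")
    n_slots = 2 * n_pairs
    if not (0 <= n_american_parents <= n_slots):
        raise ValueError("n_american_parents out of range")
    if strict_f1 and n_american_parents > n_pairs:
        raise ValueError("strict_f1 needs at most one American parent per pair")

    # rng consumption is independent of n_american_parents so that runs
    # sharing a seed differ only in how many slots are American (common
    # random numbers across gene-flow levels)
    eur_idx = rng.integers(0, pool_european.n_individuals, size=n_slots)
    parents = pool_european.calls[eur_idx].copy()
    slot_order = rng.permutation(n_slots)
    am_idx_all = rng.integers(0, pool_american.n_individuals, size=n_slots)
    is_american = np.zeros(n_slots, dtype=bool)
    if n_american_parents > 0:
        slots = slot_order[:n_american_parents]
        parents[slots] = pool_american.calls[am_idx_all[:n_american_parents]]
        is_american[slots] = True

    order = rng.permutation(n_slots)
    if strict_f1:
        am = [s for s in order if is_american[s]]
        eu = [s for s in order if not is_american[s]]
        order = np.array(
            [x for pair in zip(am, eu) for x in pair] + eu[len(am):], dtype=int
        )
    pairs = order.reshape(n_pairs, 2)

    per_pair = offspring_per_population // n_pairs
    extra = offspring_per_population - per_pair * n_pairs
    n_loci = pool_european.n_loci
    calls = np.zeros((offspring_per_population, n_loci, 2), dtype=np.int64)
    k = 0
    for pi, (s1, s2) in enumerate(pairs):
        n_off = per_pair + (1 if pi < extra else 0)
        for _ in range(n_off):
            pick = rng.integers(0, 2, size=(n_loci, 2))
            child = np.stack(
                [
                    parents[s1][np.arange(n_loci), pick[:, 0]],
                    parents[s2][np.arange(n_loci), pick[:, 1]],
                ],
                axis=1,
            )
            # a missing parental call makes the whole offspring call missing
            miss = (parents[s1, :, 0] == MISSING) | (parents[s2, :, 0] == MISSING)
            child[miss] = MISSING
            calls[k] = child
            k += 1
    return GenotypeTable(
        individuals=[f"{pop_label}_i{j + 1:03d}" for j in range(offspring_per_population)],
        populations=[pop_label] * offspring_per_population,
        loci=list(pool_european.loci),
        calls=calls,
    )


def build_f1_cline(
    scenario: ClineScenario,
    pool_european: GenotypeTable,
    pool_american: GenotypeTable,
) -> ClineDataset:
    """12-population F1 cline: population k replaces ``(k-1) * increment``
    percent of its parent slots with American parents (population 1 is
    pure European)."""
    if scenario.mode != F1_PARENTS:
        raise ValueError("scenario mode must be f1_parents")
    tables, fractions = [], []
    n_slots = 2 * scenario.n_pairs
    for k in range(1, scenario.n_populations + 1):
        n_am = _round_half_up((k - 1) * scenario.increment_pct / 100.0 * n_slots)
        rng = rng_for(scenario.seed, "f1_cline", k)
        label = f"pop{k:02d}"
        tables.append(
            make_f1_population(
                pool_european, pool_american,
                scenario.n_pairs, n_am, scenario.offspring_per_population,
                rng, pop_label=label, strict_f1=scenario.strict_f1,
            )
        )
        fractions.append(n_am / n_slots)
    return ClineDataset(tables, fractions, scenario, scenario.seed)


# ---------------------------------------------------------------------------
# Admixed-fraction mode


def sample_admixed_genotype(
    q: float,
    afs_american: AlleleFrequencySpectrum,
    afs_european: AlleleFrequencySpectrum,
    rng: np.random.Generator,
) -> np.ndarray:
    """One diploid genotype at ancestry proportion ``q``.

    Per locus the number of European-origin copies is Binomial(2, q);
    each copy's allele is drawn from its pool's frequency spectrum.
    """
    loci = afs_european.loci
    out = np.zeros((len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        n_eur = rng.binomial(2, q)
        copies = []
        for src, n in ((afs_european, n_eur), (afs_american, 2 - n_eur)):
            if n == 0:
                continue
            freqs = src.frequencies(locus)
            alleles = np.array(list(freqs))
            p = np.array(list(freqs.values()))
            copies.extend(rng.choice(alleles, size=n, p=p / p.sum()))
        out[j] = copies
    return out


def _sample_admixed_block(
    q_vec: np.ndarray,
    afs_american: AlleleFrequencySpectrum,
    afs_european: AlleleFrequencySpectrum,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized equivalent of :func:`sample_admixed_genotype` for a
    whole population: Binomial(2, q) European copies per locus is two
    independent Bernoulli(q) copy origins."""
    n = len(q_vec)
    loci = afs_european.loci
    calls = np.zeros((n, len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        draws = {}
        for key, src in (("E", afs_european), ("A", afs_american)):
            freqs = src.frequencies(locus)
            alleles = np.array(list(freqs))
            p = np.array(list(freqs.values()))
            draws[key] = rng.choice(alleles, size=(n, 2), p=p / p.sum())
        from_eur = rng.random((n, 2)) < q_vec[:, None]
        calls[:, j, :] = np.where(from_eur, draws["E"], draws["A"])
    return calls


def build_admixed_cline(
    scenario: ClineScenario,
    afs_american: AlleleFrequencySpectrum,
    afs_european: AlleleFrequencySpectrum,
    q_distribution: QDistribution,
) -> ClineDataset:
    """12-population admixed cline: population k contains
    ``(k-1) * increment`` percent admixed genotypes (Q from the binned
    distribution) and pure European genotypes (Q = 1) otherwise."""
    if scenario.mode != ADMIXED_FRACTION:
        raise ValueError("scenario mode must be admixed_fraction")
    tables, fractions = [], []
    n_ind = scenario.offspring_per_population
    for k in range(1, scenario.n_populations + 1):
        n_adm = _round_half_up((k - 1) * scenario.increment_pct / 100.0 * n_ind)
        rng = rng_for(scenario.seed, "admixed_cline", k)
        label = f"pop{k:02d}"
        # always draw a full Q vector so rng consumption does not depend
        # on the admixed count (common random numbers across levels)
        q_all = q_distribution.sample(n_ind, rng)
        q_vec = np.ones(n_ind)
        q_vec[:n_adm] = q_all[:n_adm]
        calls = _sample_admixed_block(q_vec, afs_american, afs_european, rng)
        tables.append(
            GenotypeTable(
                individuals=[f"{label}_i{j + 1:03d}" for j in range(n_ind)],
                populations=[label] * n_ind,
                loci=list(afs_european.loci),
                calls=calls,
            )
        )
        fractions.append(n_adm / n_ind)
    return ClineDataset(tables, fractions, scenario, scenario.seed)


def build_cline(
    scenario: ClineScenario,
    pool_european: GenotypeTable | None = None,
    pool_american: GenotypeTable | None = None,
    afs_american: AlleleFrequencySpectrum | None = None,
    afs_european: AlleleFrequencySpectrum | None = None,
    q_distribution: QDistribution | None = None,
) -> ClineDataset:
    """Dispatch on scenario mode."""
    if scenario.mode == F1_PARENTS:
        if pool_european is None or pool_american is None:
            raise ValueError("f1_parents mode needs both parent pools")
        return build_f1_cline(scenario, pool_european, pool_american)
    if afs_american is None or afs_european is None or q_distribution is None:
        raise ValueError("admixed_fraction mode needs spectra and a Q distribution")
    return build_admixed_cline(scenario, afs_american, afs_european, q_distribution)


# ---------------------------------------------------------------------------
# Serialization


def write_cline_manifest(dataset: ClineDataset, path: str | Path) -> None:
    sc = dataset.scenario
    manifest = {
        "mode": sc.mode,
        "increment_pct": sc.increment_pct,
        "n_populations": sc.n_populations,
        "n_pairs": sc.n_pairs,
        "offspring_per_population": sc.offspring_per_population,
        "strict_f1": sc.strict_f1,
        "seed": dataset.seed,
        "realized_fractions": dataset.realized_fractions,
        "population_labels": dataset.labels(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
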