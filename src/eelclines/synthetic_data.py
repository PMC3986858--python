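"""Synthetic inputs with the statistical structure the analysis assumes.

The real genotypes behind the study are not redistributable, so this
module generates stand-ins that reproduce the features the pipeline
relies on:

* two species gene pools at 9 microsatellite loci, highly heterozygous
  (10-18 alleles per locus on a 2-bp size lattice), whose realized
  multi-locus Weir-Cockerham FST is calibrated to a target (default
  0.0146, the inter-species differentiation the markers show);
* two cleanly separated cytochrome-b haplotype clusters where only the
  American cluster carries a HinfI recognition site;
* a coastline-like 1-D transect distance matrix for 12 sites.

The divergence model is Balding-Nichols-style: each locus has an
ancestral spectrum drawn from a symmetric Dirichlet, and each species'
spectrum is drawn from ``Dirichlet(p_anc * (1 - F) / F)``; a single F is
calibrated by bisection so the realized FST between the sampled pools
hits the target.  No mutation process is simulated — allele labels live
on a size lattice only so that RST is computable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .admixture import QDistribution, Q_BIN_EDGES
from .popgen_stats import fst_weir_cockerham
from .random_utils import rng_for
from .species_id import find_hinfi_sites
from .types import (
    AlleleFrequencySpectrum,
    DistanceMatrix,
    GenotypeTable,
    HaplotypeAlignment,
)


# ---------------------------------------------------------------------------
# Species pools


@dataclass
class SpeciesPoolConfig:
    n_loci: int = 9
    alleles_per_locus_range: tuple[int, int] = (10, 18)
    repeat_motif_length: int = 2
    target_fst: float = 0.0146
    fst_tolerance: float = 0.005
    pool_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.alleles_per_locus_range
        if not (2 <= lo <= hi <= 50):
            raise ValueError("alleles_per_locus_range must lie within [2, 50]")
        if not (0 < self.target_fst < 0.2):
            raise ValueError("target_fst must be in (0, 0.2)")
        if self.pool_size < 10:
            raise ValueError("pool_size must be at least 10")


class CalibrationError(RuntimeError):
    pass


def _draw_ancestral_spectra(cfg: SpeciesPoolConfig, rng: np.random.Generator):
    """Per-locus allele size arrays and ancestral frequency vectors."""
    lo, hi = cfg.alleles_per_locus_range
    loci, sizes, p_anc = [], [], []
    for j in range(cfg.n_loci):
        k = int(rng.integers(lo, hi + 1))
        base = 100 + 30 * j  # loci occupy distinct size ranges
        sizes.append(base + cfg.repeat_motif_length * np.arange(k))
        p_anc.append(rng.dirichlet(np.ones(k)))
        loci.append(f"Loc{j + 1:03d}")
    return loci, sizes, p_anc


def _species_spectra(p_anc, f: float, rng: np.random.Generator):
    """Two species spectra per locus under the Balding-Nichols model."""
    spectra = ([], [])
    for p in p_anc:
        alpha = np.maximum(p * (1.0 - f) / f, 1e-9)
        for s in spectra:
            s.append(rng.dirichlet(alpha))
    return spectra


def _sample_pool(loci, sizes, spectra, n: int, prefix: str, rng: np.random.Generator) -> GenotypeTable:
    calls = np.zeros((n, len(loci), 2), dtype=np.int64)
    for j, (sz, p) in enumerate(zip(sizes, spectra)):
        idx = rng.choice(len(sz), size=(n, 2), p=p)
        calls[:, j, :] = sz[idx]
    return GenotypeTable(
        individuals=[f"{prefix}{i + 1:03d}" for i in range(n)],
        populations=[prefix] * n,
        loci=list(loci),
        calls=calls,
    )


def gen_species_pools(
    config: SpeciesPoolConfig, max_iter: int = 40
) -> tuple[GenotypeTable, GenotypeTable, AlleleFrequencySpectrum, AlleleFrequencySpectrum]:
    """Two diverged species pools with realized FST near the target.

    Returns (European table, American table, European spectrum, American
    spectrum); the spectra are empirical counts from the emitted tables,
    which is what downstream ancestry estimation consumes.  F is found by
    bisection on realized multi-locus Weir-Cockerham theta; each
    candidate F regenerates pools from a seed derived from ``config.seed``
    alone, so output is bit-identical for equal configs.
    """
    base_rng = rng_for(config.seed, "species_pools", "spectra")
    loci, sizes, p_anc = _draw_ancestral_spectra(config, base_rng)

    def realized(f: float, stream: int = 0) -> tuple[float, GenotypeTable, GenotypeTable]:
        if stream == 0:
            rng = rng_for(config.seed, "species_pools", "draw")
        else:
            rng = rng_for(config.seed, "species_pools", "draw", stream)
        spec_e, spec_a = _species_spectra(p_anc, f, rng)
        t_e = _sample_pool(loci, sizes, spec_e, config.pool_size, "EUR", rng)
        t_a = _sample_pool(loci, sizes, spec_a, config.pool_size, "AME", rng)
        both = GenotypeTable.concat([t_e, t_a])
        theta = fst_weir_cockerham(both).value
        return theta, t_e, t_a

    lo, hi = 1e-5, 0.4
    best = None
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        theta, t_e, t_a = realized(mid)
        if best is None or abs(theta - config.target_fst) < abs(best[0] - config.target_fst):
            best = (theta, t_e, t_a)
        if abs(theta - config.target_fst) <= config.fst_tolerance:
            best = (theta, t_e, t_a)
            break
        if theta > config.target_fst:
            hi = mid
        else:
            lo = mid
    if abs(best[0] - config.target_fst) > config.fst_tolerance:
        # with very few loci/alleles realized theta is a jumpy function of
        # F and bisection can straddle the target; fall back to a grid scan
        # over F and, if needed, over alternative deterministic draw streams
        for stream in range(3):
            for f in np.geomspace(1e-4, 0.45, max_iter * 2):
                theta, t_e, t_a = realized(float(f), stream)
                if abs(theta - config.target_fst) < abs(best[0] - config.target_fst):
                    best = (theta, t_e, t_a)
                if abs(theta - config.target_fst) <= config.fst_tolerance:
                    break
            if abs(best[0] - config.target_fst) <= config.fst_tolerance:
                break
    theta, t_e, t_a = best
    if abs(theta - config.target_fst) > config.fst_tolerance:
        raise CalibrationError(
            f"FST calibration search exhausted: "
            f"achieved {theta:.4f}, target {config.target_fst:.4f} "
            f"(tolerance {config.fst_tolerance})"
        )
    afs_e = AlleleFrequencySpectrum.from_table(t_e)
    afs_a = AlleleFrequencySpectrum.from_table(t_a)
    return t_e, t_a, afs_e, afs_a


# ---------------------------------------------------------------------------
# cytb haplotypes


@dataclass
class CytbConfig:
    amplicon_length: int = 362
    network_alignment_length: int = 276
    diagnostic_site_position: int = 120
    n_american_haplotypes: int = 15
    n_european_haplotypes: int = 34
    within_cluster_max_diffs: int = 2
    between_cluster_diffs: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diagnostic_site_position + 5 > self.amplicon_length:
            raise ValueError("diagnostic site does not fit in the amplicon")
        if self.amplicon_length < 30:
            raise ValueError("amplicon too short")
        if self.n_american_haplotypes < 1 or self.n_european_haplotypes < 1:
            raise ValueError("need at least one haplotype per cluster")
        if self.between_cluster_diffs <= 2 * self.within_cluster_max_diffs:
            raise ValueError(
                "between-cluster divergence must exceed twice the "
                "within-cluster radius for clusters to be separable"
            )


_B = np.array(list("ACGT"))


def _strip_hinfi(seq: list[str], rng: np.random.Generator, keep: set[int]) -> None:
    """Mutate the G of any HinfI site not starting in ``keep`` until none remain."""
    while True:
        bad = [p for p in find_hinfi_sites("".join(seq)) if p not in keep]
        if not bad:
            return
        for p in bad:
            seq[p] = str(rng.choice([b for b in "ACT"]))


def gen_cytb_haplotypes(config: CytbConfig) -> HaplotypeAlignment:
    """Two mtDNA haplotype clusters; only the American one carries GANTC.

    The European consensus is a random sequence scrubbed of HinfI motifs;
    the American consensus differs at ``between_cluster_diffs`` positions
    and carries GACTC at the diagnostic offset.  Haplotypes mutate the
    consensus at up to ``within_cluster_max_diffs`` positions, never
    creating a motif in the European cluster nor destroying the
    diagnostic one in the American cluster.
    """
    rng = rng_for(config.seed, "cytb")
    L = config.amplicon_length
    pos = config.diagnostic_site_position
    eur = list(rng.choice(_B, size=L))
    _strip_hinfi(eur, rng, keep=set())

    protected = set(range(pos, pos + 5))
    amer = list(eur)
    amer[pos : pos + 5] = list("GACTC")
    free = [i for i in range(L) if i not in protected]
    div_sites = rng.choice(free, size=config.between_cluster_diffs, replace=False)
    for i in div_sites:
        amer[i] = str(rng.choice([b for b in "ACGT" if b != amer[i]]))
    _strip_hinfi(amer, rng, keep={pos})
    # divergence may have been partly undone by motif scrubbing; re-check
    protected_a = protected | set(div_sites)

    def mutate(consensus: list[str], n_hap: int, fixed: set[int],
               want_motif_at: int | None) -> list[str]:
        seen = {"".join(consensus)}
        out = ["".join(consensus)]
        attempts = 0
        while len(out) < n_hap:
            attempts += 1
            if attempts > 1000 * n_hap:
                raise RuntimeError("could not generate enough distinct haplotypes")
            k = int(rng.integers(1, config.within_cluster_max_diffs + 1))
            cand = list(consensus)
            sites = rng.choice(
                [i for i in range(L) if i not in fixed], size=k, replace=False
            )
            for i in sites:
                cand[i] = str(rng.choice([b for b in "ACGT" if b != cand[i]]))
            s = "".join(cand)
            sites_found = find_hinfi_sites(s)
            if want_motif_at is None:
                if sites_found:
                    continue
            else:
                if sites_found != [want_motif_at]:
                    continue
            if s in seen:
                continue
            seen.add(s)
            out.append(s)
        return out

    eur_haps = mutate(eur, config.n_european_haplotypes, set(div_sites) | protected, None)
    amer_haps = mutate(amer, config.n_american_haplotypes, protected_a, pos)
    if set(eur_haps) & set(amer_haps):
        raise RuntimeError("clusters share a haplotype; raise between_cluster_diffs")
    ids = [f"EUR_h{k + 1}" for k in range(len(eur_haps))] + [
        f"AME_h{k + 1}" for k in range(len(amer_haps))
    ]
    species = ["European"] * len(eur_haps) + ["American"] * len(amer_haps)
    return HaplotypeAlignment(ids=ids, sequences=eur_haps + amer_haps, species=species)


# ---------------------------------------------------------------------------
# Geography


@dataclass
class GeographyConfig:
    n_sites: int = 12
    spacing_km: float = 500.0
    irregular: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("need at least 3 sites")
        if self.spacing_km <= 0:
            raise ValueError("spacing must be positive")


def gen_geography(config: GeographyConfig) -> DistanceMatrix:
    """Pairwise distances along a 1-D coastline transect.

    Site 1 is the southern-most (purest) locality.  With ``irregular``
    the segment lengths are log-normal with median ``spacing_km``,
    otherwise all segments equal ``spacing_km``; either way the matrix is
    metric and collinear: d(i, k) = d(i, j) + d(j, k) for i < j < k.
    """
    if config.irregular:
        rng = rng_for(config.seed, "geography")
        segments = config.spacing_km * np.exp(
            rng.normal(0.0, 0.5, size=config.n_sites - 1)
        )
    else:
        segments = np.full(config.n_sites - 1, config.spacing_km)
    pos = np.concatenate([[0.0], np.cumsum(segments)])
    values = np.abs(pos[:, None] - pos[None, :])
    labels = [f"site{k + 1:02d}" for k in range(config.n_sites)]
    return DistanceMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# Q distributions


def gen_q_distribution(mix: list[tuple[float, float]]) -> QDistribution:
    """Build a Q-bin distribution from (bin left edge, probability) pairs.

    Bins are the fixed 0.05-wide lattice over [0.10, 0.90); probabilities
    must sum to 1 within 1e-9.
    """
    if not mix:
        raise ValueError("mix must contain at least one bin")
    probs = np.zeros(len(Q_BIN_EDGES) - 1)
    for left, p in mix:
        diffs = np.abs(Q_BIN_EDGES[:-1] - left)
        i = int(np.argmin(diffs))
        if diffs[i] > 1e-6:
            raise ValueError(f"{left} is not a bin edge on the 0.05 lattice")
        probs[i] += p
    return QDistribution(probs)


def default_admixed_q_distribution() -> QDistribution:
    """Triangular Q-bin weights peaking near 0.55.

    Emulates the empirical distribution of intermediate ancestry values
    in the real data, whose mean sits near Q = 0.55 (slightly above the
    F1 expectation of 0.5 because the European pool is focal).
    """
    mids = (Q_BIN_EDGES[:-1] + Q_BIN_EDGES[1:]) / 2.0
    w = np.maximum(0.0, 1.0 - np.abs(mids - 0.55) / 0.45)
    return QDistribution(w / w.sum())
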