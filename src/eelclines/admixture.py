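"""Supervised two-pool ancestry estimation and the cline group tests.

Each individual's ancestry proportion Q toward the European pool is the
maximizer of the log-likelihood

    sum over non-missing allele copies of log(q * p_E(a) + (1-q) * p_A(a))

with pool frequencies smoothed so that no copy has zero likelihood in
either pool (alleles private to one species are exactly the informative
signal and must not blow up the likelihood).  The objective is concave in
q, so Brent's bounded scalar optimizer converges to the global optimum.

Also implements the purity classification at Q = 0.9 / Q = 0.1, the
urn-model permutation test used to show that Icelandic eels with American
mitochondria are genetically intermediate, the Q-histogram over
[0.10, 0.90) bins of width 0.05, the geographic-group comparisons
(Box-Cox + Shapiro-Wilk + pairwise Wilcoxon rank-sum), and the
rank-order probability for observing a prescribed latitudinal ordering.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .types import MISSING, AlleleFrequencySpectrum, GenotypeTable

PURE_EUROPEAN = "pure_European"
PURE_AMERICAN = "pure_American"
ADMIXED = "admixed"

Q_THRESHOLD = 0.9
SMOOTHING = 0.5

Q_BIN_EDGES = np.round(np.arange(0.10, 0.9001, 0.05), 10)  # 16 bins over [0.10, 0.90]


@dataclass
class AdmixtureResult:
    individual: str
    q: float
    log_likelihood: float
    purity: str


def classify_purity(q: float) -> str:
    """Pure European iff Q > 0.9, pure American iff Q < 0.1, else admixed."""
    if q > Q_THRESHOLD:
        return PURE_EUROPEAN
    if q < 1.0 - Q_THRESHOLD:
        return PURE_AMERICAN
    return ADMIXED


def _smoothed_pool_frequencies(
    afs_american: AlleleFrequencySpectrum,
    afs_european: AlleleFrequencySpectrum,
) -> dict[str, tuple[dict[int, float], dict[int, float], float, float]]:
    """Per locus: smoothed (p_A, p_E) maps plus each pool's floor frequency.

    Counts get +0.5 per allele in the union of alleles observed in either
    pool, plus one shared pseudo-allele per locus that absorbs any allele
    seen in neither pool; its smoothed frequency is the floor.
    """
    if afs_american.loci != afs_european.loci:
        raise ValueError("pool spectra must cover the same loci")
    out = {}
    for locus in afs_american.loci:
        ca = afs_american.counts[locus]
        ce = afs_european.counts[locus]
        union = sorted(set(ca) | set(ce))
        k = len(union) + 1  # + shared pseudo-allele
        na = sum(ca.values()) + SMOOTHING * k
        ne = sum(ce.values()) + SMOOTHING * k
        pa = {a: (ca.get(a, 0) + SMOOTHING) / na for a in union}
        pe = {a: (ce.get(a, 0) + SMOOTHING) / ne for a in union}
        out[locus] = (pa, pe, SMOOTHING / na, SMOOTHING / ne)
    return out


def _copy_likelihood_terms(
    genotype: np.ndarray,
    loci: list[str],
    smoothed: dict[str, tuple[dict[int, float], dict[int, float], float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """(p_A, p_E) per non-missing allele copy of one individual."""
    pa_list, pe_list = [], []
    for j, locus in enumerate(loci):
        a, b = genotype[j]
        if a == MISSING:
            continue
        pa, pe, floor_a, floor_e = smoothed[locus]
        for allele in (int(a), int(b)):
            pa_list.append(pa.get(allele, floor_a))
            pe_list.append(pe.get(allele, floor_e))
    return np.asarray(pa_list), np.asarray(pe_list)


def estimate_q(
    genotype: np.ndarray,
    afs_american: AlleleFrequencySpectrum,
    afs_european: AlleleFrequencySpectrum,
    individual: str = "",
    _smoothed=None,
) -> AdmixtureResult:
    """Maximum-likelihood ancestry proportion toward the European pool.

    ``genotype`` is an ``(n_loci, 2)`` slice of a GenotypeTable; loci
    missing in the genotype are skipped.
    """
    smoothed = _smoothed if _smoothed is not None else _smoothed_pool_frequencies(
        afs_american, afs_european
    )
    p_a, p_e = _copy_likelihood_terms(genotype, afs_american.loci, smoothed)
    if p_a.size == 0:
        raise ValueError(f"genotype {individual or '?'} is missing at all loci")

    def neg_ll(q: float) -> float:
        return -float(np.sum(np.log(q * p_e + (1.0 - q) * p_a)))

    res = minimize_scalar(neg_ll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-7})
    q_hat = float(np.clip(res.x, 0.0, 1.0))
    # the optimum may sit at a boundary; check both ends explicitly
    for cand in (0.0, 1.0):
        if neg_ll(cand) < neg_ll(q_hat):
            q_hat = cand
    return AdmixtureResult(
        individual=individual,
        q=q_hat,
        log_likelihood=-neg_ll(q_hat),
        purity=classify_purity(q_hat),
    )


def estimate_q_table(
    table: GenotypeTable,
    afs_american: AlleleFrequencySpectrum,
    afs_european: AlleleFrequencySpectrum,
) -> list[AdmixtureResult]:
    """Q for every individual in a table (pool smoothing computed once)."""
    smoothed = _smoothed_pool_frequencies(afs_american, afs_european)
    return [
        estimate_q(table.calls[i], afs_american, afs_european,
                   individual=table.individuals[i], _smoothed=smoothed)
        for i in range(table.n_individuals)
    ]


# ---------------------------------------------------------------------------
# Urn permutation test


@dataclass
class UrnTestResult:
    observed_mean_q: float
    group_size: int
    n_draws: int
    null_means_american: np.ndarray
    null_means_european: np.ndarray
    p_vs_american: float
    p_vs_european: float


def urn_test(
    q_american: Sequence[float],
    q_european: Sequence[float],
    observed_mean: float,
    group_size: int = 16,
    n_draws: int = 1000,
    seed: int | None = None,
) -> UrnTestResult:
    """Urn-model intermediacy test for a group mean ancestry proportion.

    Groups of ``group_size`` Q values are drawn without replacement
    (within a draw; with replacement across draws) from each species
    pool; the p-value against each pool is the one-tailed probability of
    a null mean at least as extreme as the observation, toward the
    opposing pool.
    """
    qa = np.asarray(q_american, dtype=float)
    qe = np.asarray(q_european, dtype=float)
    for pool, name in ((qa, "American"), (qe, "European")):
        if len(pool) < group_size:
            raise ValueError(f"{name} pool smaller than group_size={group_size}")
    rng = np.random.default_rng(seed)
    means_a = np.array([
        rng.choice(qa, size=group_size, replace=False).mean() for _ in range(n_draws)
    ])
    means_e = np.array([
        rng.choice(qe, size=group_size, replace=False).mean() for _ in range(n_draws)
    ])
    # American pool sits at low Q: extreme toward the European pool = higher mean
    p_a = (1 + int(np.sum(means_a >= observed_mean))) / (n_draws + 1)
    p_e = (1 + int(np.sum(means_e <= observed_mean))) / (n_draws + 1)
    return UrnTestResult(
        observed_mean_q=float(observed_mean),
        group_size=group_size,
        n_draws=n_draws,
        null_means_american=means_a,
        null_means_european=means_e,
        p_vs_american=p_a,
        p_vs_european=p_e,
    )


# ---------------------------------------------------------------------------
# Q-bin distribution


@dataclass
class QDistribution:
    """Histogram over 16 bins of width 0.05 spanning [0.10, 0.90)."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (len(Q_BIN_EDGES) - 1,):
            raise ValueError(f"need {len(Q_BIN_EDGES) - 1} bin probabilities")
        if (self.probabilities < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")

    @property
    def midpoints(self) -> np.ndarray:
        return (Q_BIN_EDGES[:-1] + Q_BIN_EDGES[1:]) / 2.0

    @property
    def mean(self) -> float:
        return float(np.dot(self.probabilities, self.midpoints))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Multinomial bin draws; each sample returns the bin midpoint."""
        idx = rng.choice(len(self.probabilities), size=n, p=self.probabilities)
        return self.midpoints[idx]


def fit_q_distribution(q_values: Sequence[float]) -> QDistribution:
    """Empirical Q histogram; values outside [0.10, 0.90) are excluded
    (those individuals are 'pure' under the threshold rule)."""
    q = np.asarray(q_values, dtype=float)
    q = q[(q >= Q_BIN_EDGES[0]) & (q < Q_BIN_EDGES[-1])]
    if q.size == 0:
        raise ValueError("no admixed Q values in [0.10, 0.90)")
    hist, _ = np.histogram(q, bins=Q_BIN_EDGES)
    return QDistribution(hist / hist.sum())


# ---------------------------------------------------------------------------
# Geographic group comparisons


@dataclass
class GroupClineTest:
    shapiro_p: dict[str, float]
    boxcox_lambda: dict[str, float]
    pairwise_p_raw: dict[tuple[str, str], float]
    pairwise_p_boxcox: dict[tuple[str, str], float]


def group_cline_test(groups: dict[str, Sequence[float]]) -> GroupClineTest:
    """Compare ancestry proportions among geographic groups.

    Per group: Box-Cox transform (MLE lambda on that group's values, all
    strictly positive) followed by a Shapiro-Wilk normality test.  Per
    pair: two-sided Wilcoxon rank-sum p on the raw and on the
    per-group-transformed values.
    """
    for g, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group '{g}' has fewer than 3 values")
        if np.min(vals) <= 0:
            raise ValueError(f"group '{g}' has non-positive Q values")
    transformed: dict[str, np.ndarray] = {}
    lambdas: dict[str, float] = {}
    shapiro_p: dict[str, float] = {}
    for g, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if np.ptp(arr) == 0:
            transformed[g] = arr
            lambdas[g] = 1.0
            shapiro_p[g] = np.nan
            continue
        t, lam = stats.boxcox(arr)
        transformed[g] = t
        lambdas[g] = float(lam)
        shapiro_p[g] = float(stats.shapiro(t).pvalue)
    names = list(groups)
    p_raw, p_bc = {}, {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            p_raw[(a, b)] = float(
                stats.ranksums(groups[a], groups[b]).pvalue
            )
            p_bc[(a, b)] = float(
                stats.ranksums(transformed[a], transformed[b]).pvalue
            )
    return GroupClineTest(shapiro_p, lambdas, p_raw, p_bc)


def rank_order_probability(group_counts: Sequence[int]) -> float:
    """Chance that independent random orderings all match a prescribed one.

    For k samples there are k! orderings, so observing one particular
    latitudinal rank order in each of several independent groups has
    probability ``prod_i 1/k_i!`` (e.g. [3, 4] -> 1/144).
    """
    if not group_counts:
        raise ValueError("need at least one group")
    p = 1.0
    for k in group_counts:
        if k < 1:
            raise ValueError("group counts must be positive")
        p /= math.factorial(k)
    return p


# ---------------------------------------------------------------------------
# Serialization


def write_admixture_csv(results: list[AdmixtureResult], populations: list[str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual", "population", "Q", "purity"])
        for r, pop in zip(results, populations):
            w.writerow([r.individual, pop, f"{r.q:.6f}", r.purity])


def write_urn_csv(result: UrnTestResult, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["draw", "null_mean_american", "null_mean_european"])
        for k, (a, e) in enumerate(
            zip(result.null_means_american, result.null_means_european)
        ):
            w.writerow([k, f"{a:.6f}", f"{e:.6f}"])
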