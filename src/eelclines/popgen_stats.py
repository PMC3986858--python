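"""Summary and differentiation statistics for microsatellite genotypes.

Implements the descriptive layer of the analysis: observed/expected
heterozygosity, Weir-Cockerham theta (FST) and the Slatkin allele-size
analogue (RST), Hardy-Weinberg tests by Monte-Carlo permutation of gene
copies, rarefied allelic and private-allele richness, and the
Cavalli-Sforza & Edwards chord distance between allele frequency spectra.

Conventions fixed here (they vary across classic programs):

* Multi-locus FST and RST are ratios of summed variance components across
  loci, never means of per-locus ratios.  Negative per-locus components
  are retained.
* The chord distance is ``D_CE = sqrt(mean_l(1 - sum_a sqrt(p1 * p2)))``,
  i.e. without the 2/pi angular factor some programs apply.  Every
  downstream use (Mantel correlations) is invariant to that global scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import MISSING, AlleleFrequencySpectrum, GenotypeTable


# ---------------------------------------------------------------------------
# Allele frequencies and heterozygosity


def allele_frequencies(
    table: GenotypeTable, grouping: dict[str, Sequence[int]] | None = None
) -> dict[str, AlleleFrequencySpectrum]:
    """Per-group allele frequency spectra (missing calls excluded).

    ``grouping`` maps group name to individual indices; default is the
    table's own population labels.  Loci with no data in a group keep an
    empty count dict and are flagged via :func:`empty_loci`.
    """
    if grouping is None:
        grouping = table.population_groups()
    return {
        g: AlleleFrequencySpectrum.from_table(table, idx)
        for g, idx in grouping.items()
    }


def empty_loci(afs: AlleleFrequencySpectrum) -> list[str]:
    """Loci with no observed gene copies in this spectrum."""
    return [l for l in afs.loci if afs.n_copies(l) == 0]


@dataclass
class SummaryStats:
    """Per-locus and mean Ho/He, F_IS, and optional rarefied richness."""

    group: str
    n: int
    ho: pd.Series
    he: pd.Series
    mean_ho: float
    mean_he: float
    f_is: float
    a_r: pd.Series | None = None


def heterozygosities(table: GenotypeTable, indices: Sequence[int], group: str = "") -> SummaryStats:
    """Observed and unbiased expected heterozygosity per locus.

    He uses Nei's small-sample correction ``(2n/(2n-1)) * (1 - sum p^2)``
    with n the number of genotyped individuals at the locus.  F_IS is the
    multi-locus ``1 - mean(Ho)/mean(He)``.
    """
    idx = list(indices)
    ho, he = {}, {}
    for j, locus in enumerate(table.loci):
        calls = table.calls[idx, j]
        ok = calls[:, 0] != MISSING
        calls = calls[ok]
        n = len(calls)
        if n == 0:
            ho[locus] = np.nan
            he[locus] = np.nan
            continue
        ho[locus] = float(np.mean(calls[:, 0] != calls[:, 1]))
        vals, counts = np.unique(calls.ravel(), return_counts=True)
        p = counts / counts.sum()
        raw = 1.0 - float(np.sum(p**2))
        he[locus] = (2 * n / (2 * n - 1)) * raw if n > 1 else raw
    ho_s, he_s = pd.Series(ho), pd.Series(he)
    mean_ho = float(ho_s.mean())
    mean_he = float(he_s.mean())
    f_is = 1.0 - mean_ho / mean_he if mean_he > 0 else 0.0
    return SummaryStats(
        group=group, n=len(idx), ho=ho_s, he=he_s,
        mean_ho=mean_ho, mean_he=mean_he, f_is=f_is,
    )


def summary_table(table: GenotypeTable, rarefy_to: int | None = None) -> pd.DataFrame:
    """Per-population stats CSV rows: n, Ho, He, A_R, F_IS."""
    groups = table.population_groups()
    specs = allele_frequencies(table)
    if rarefy_to is None:
        sizes = [
            min(specs[g].n_copies(l) for l in table.loci)
            for g in groups
        ]
        rarefy_to = max(2, min(s for s in sizes if s > 0))
    rows = []
    for g, idx in groups.items():
        s = heterozygosities(table, idx, group=g)
        ar = np.mean([
            allelic_richness_rarefied(specs[g].counts[l], rarefy_to)
            for l in table.loci
            if specs[g].n_copies(l) >= rarefy_to
        ])
        rows.append({
            "population": g, "n": s.n, "Ho": s.mean_ho, "He": s.mean_he,
            "A_R": float(ar), "F_IS": s.f_is,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST


@dataclass
class DifferentiationStats:
    """Multi-locus and per-locus differentiation with optional permutation p."""

    statistic: str
    value: float
    per_locus: pd.Series
    p_value: float | None = None
    n_permutations: int | None = None


def _wc_components(table: GenotypeTable, groups: dict[str, Sequence[int]], locus_j: int):
    """Weir-Cockerham (1984) variance components a, b, c summed over alleles."""
    per_pop = []
    for idx in groups.values():
        calls = table.calls[list(idx), locus_j]
        calls = calls[calls[:, 0] != MISSING]
        if len(calls) > 0:
            per_pop.append(calls)
    r = len(per_pop)
    if r < 2:
        return 0.0, 0.0, 0.0
    n_i = np.array([len(c) for c in per_pop], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([c.ravel() for c in per_pop]))
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array([np.mean(c.ravel() == allele) for c in per_pop])
        h_i = np.array([
            np.mean((c[:, 0] == allele) != (c[:, 1] == allele)) for c in per_pop
        ])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        if nbar <= 1:
            continue
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def fst_weir_cockerham(
    table: GenotypeTable,
    groups: dict[str, Sequence[int]] | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> DifferentiationStats:
    """Weir-Cockerham theta across two or more groups.

    Multi-locus value is the ratio of summed variance components.  If
    ``n_perm`` > 0, a one-tailed permutation p-value is computed by
    shuffling individuals across groups.
    """
    if groups is None:
        groups = table.population_groups()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"group '{g}' has fewer than 2 individuals")

    def theta(gmap):
        num = den = 0.0
        per_locus = {}
        for j, locus in enumerate(table.loci):
            a, b, c = _wc_components(table, gmap, j)
            tot = a + b + c
            per_locus[locus] = a / tot if tot != 0 else np.nan
            num += a
            den += tot
        return (num / den if den != 0 else np.nan), pd.Series(per_locus)

    obs, per_locus = theta(groups)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        all_idx = np.concatenate([np.asarray(list(v)) for v in groups.values()])
        sizes = [len(v) for v in groups.values()]
        names = list(groups)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(all_idx)
            gmap, start = {}, 0
            for name, s in zip(names, sizes):
                gmap[name] = perm[start : start + s]
                start += s
            t, _ = theta(gmap)
            if t >= obs:
                count += 1
        p = (1 + count) / (n_perm + 1)
    return DifferentiationStats("fst", float(obs), per_locus, p, n_perm or None)


# ---------------------------------------------------------------------------
# Slatkin RST


def rst_slatkin(
    table: GenotypeTable, groups: dict[str, Sequence[int]] | None = None
) -> DifferentiationStats:
    """Slatkin's RST from allele-size variance components.

    Per locus, ``S_bar`` is the average squared size difference between
    all pairs of pooled gene copies and ``S_W`` the weighted
    within-group analogue; ``RST = (S_bar - S_W) / S_bar``.  Multi-locus
    by ratio of summed components.
    """
    if groups is None:
        groups = table.population_groups()
    num = den = 0.0
    per_locus = {}
    for j, locus in enumerate(table.loci):
        pooled = []
        within = []
        weights = []
        for idx in groups.values():
            calls = table.calls[list(idx), j]
            sizes = calls[calls[:, 0] != MISSING].ravel().astype(float)
            if len(sizes) < 2:
                continue
            pooled.append(sizes)
            # mean squared pairwise difference within this group = 2 * var
            within.append(2.0 * sizes.var(ddof=1))
            weights.append(len(sizes))
        if len(pooled) < 2:
            per_locus[locus] = np.nan
            continue
        allsz = np.concatenate(pooled)
        s_bar = 2.0 * allsz.var(ddof=1)
        w = np.asarray(weights, dtype=float)
        s_w = float(np.average(within, weights=w))
        per_locus[locus] = (s_bar - s_w) / s_bar if s_bar > 0 else np.nan
        num += s_bar - s_w
        den += s_bar
    value = num / den if den > 0 else np.nan
    return DifferentiationStats("rst", float(value), pd.Series(per_locus))


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def hwe_test(
    table: GenotypeTable,
    indices: Sequence[int],
    locus: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo heterozygote-deficit test at one locus in one group.

    Gene copies are shuffled among individuals; the statistic is the
    heterozygote count, and the p-value is the permutation probability of
    a count at most as large as observed (deficit being the deviation the
    data show between species pools).
    """
    j = table.loci.index(locus)
    calls = table.calls[list(indices), j]
    calls = calls[calls[:, 0] != MISSING]
    n = len(calls)
    if n < 2:
        raise ValueError("need at least 2 genotyped individuals")
    obs_het = int(np.sum(calls[:, 0] != calls[:, 1]))
    copies = calls.ravel().copy()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        rng.shuffle(copies)
        pairs = copies.reshape(n, 2)
        het = int(np.sum(pairs[:, 0] != pairs[:, 1]))
        if het <= obs_het:
            count += 1
    return (1 + count) / (n_perm + 1)


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Reject H0 for each p iff ``p < alpha / m`` with m = len(p_values)."""
    m = len(p_values)
    if m == 0:
        return []
    return [p < alpha / m for p in p_values]


# ---------------------------------------------------------------------------
# Rarefaction


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _prob_absent(n_total: int, n_allele: int, g: int) -> float:
    """P(allele with n_allele of n_total copies absent from a g-subsample)."""
    if n_total - n_allele < g:
        return 0.0
    return float(np.exp(_log_comb(n_total - n_allele, g) - _log_comb(n_total, g)))


def allelic_richness_rarefied(counts: dict[int, int], g: int) -> float:
    """Expected number of distinct alleles in a subsample of g gene copies.

    Hypergeometric rarefaction: ``A_R(g) = sum_a [1 - C(N-N_a, g)/C(N, g)]``.
    """
    n_total = sum(counts.values())
    if g < 1 or g > n_total:
        raise ValueError(f"g must be in [1, {n_total}]")
    return float(sum(1.0 - _prob_absent(n_total, na, g) for na in counts.values()))


def private_allelic_richness_rarefied(
    group_counts: Sequence[dict[int, int]], g: int
) -> list[float]:
    """Expected private-allele count per group in g-copy subsamples.

    For group j, an allele contributes the probability that it appears in
    a size-g subsample of group j and in none of the other groups' size-g
    subsamples (subsamples drawn independently).
    """
    totals = [sum(c.values()) for c in group_counts]
    for t in totals:
        if g < 1 or g > t:
            raise ValueError("g exceeds a group's gene-copy total")
    alleles = sorted({a for c in group_counts for a in c})
    out = []
    for j, counts in enumerate(group_counts):
        s = 0.0
        for a in alleles:
            p_in_j = 1.0 - _prob_absent(totals[j], counts.get(a, 0), g)
            if p_in_j == 0.0:
                continue
            p_absent_rest = 1.0
            for k, other in enumerate(group_counts):
                if k == j:
                    continue
                p_absent_rest *= _prob_absent(totals[k], other.get(a, 0), g)
            s += p_in_j * p_absent_rest
        out.append(float(s))
    return out


# ---------------------------------------------------------------------------
# Chord distance


def cavalli_sforza_chord(
    afs1: AlleleFrequencySpectrum, afs2: AlleleFrequencySpectrum
) -> float:
    """Cavalli-Sforza & Edwards chord distance between two spectra.

    ``D_CE = sqrt(mean over loci of (1 - sum_a sqrt(p1a * p2a)))``; an
    allele absent from one spectrum contributes 0 to the inner sum, so
    completely disjoint spectra give exactly 1.
    """
    if afs1.loci != afs2.loci:
        raise ValueError("spectra must cover the same loci in the same order")
    terms = []
    for locus in afs1.loci:
        f1 = afs1.frequencies(locus)
        f2 = afs2.frequencies(locus)
        if not f1 or not f2:
            continue
        inner = sum(np.sqrt(f1[a] * f2[a]) for a in f1 if a in f2)
        terms.append(1.0 - min(inner, 1.0))
    if not terms:
        raise ValueError("no locus with data in both spectra")
    return float(np.sqrt(np.mean(terms)))
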