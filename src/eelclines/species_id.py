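"""Mitochondrial species diagnosis and haplotype network construction.

The American mtDNA lineage carries a HinfI restriction site (recognition
motif ``G^ANTC``) in the cytochrome-b amplicon that the European lineage
lacks, so an in-silico digest classifies every sequence.  Haplotype
relationships are summarized as a minimum spanning tree over Hamming
distances, the graph-native form of a minimum-spanning haplotype network.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .types import HaplotypeAlignment

AMERICAN = "American"
EUROPEAN = "European"

_BASES = frozenset("ACGT")


@dataclass
class RflpCall:
    """HinfI digest result for one sequence."""

    individual: str
    species: str
    n_cut_sites: int
    cut_positions: list[int]


@dataclass
class HaplotypeNetwork:
    """Haplotype MST: nodes carry multiplicity and species tags."""

    haplotypes: list[str]
    counts: list[int]
    species: list[str | None]
    member_ids: list[list[str]]
    edges: list[tuple[int, int, int]]  # (node_i, node_j, hamming distance)


def find_hinfi_sites(seq: str) -> list[int]:
    """0-based start offsets of every GANTC match (overlaps included).

    The wildcard position accepts any of A/C/G/T; an ``N`` in the input
    matches nothing, so ambiguous sequence never creates a cut site.
    """
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - 4):
        if (
            seq[i] == "G"
            and seq[i + 1] == "A"
            and seq[i + 2] in _BASES
            and seq[i + 3] == "T"
            and seq[i + 4] == "C"
        ):
            hits.append(i)
    return hits


def classify_species(seq: str, individual: str = "") -> RflpCall:
    """American iff the sequence contains at least one HinfI site."""
    sites = find_hinfi_sites(seq)
    species = AMERICAN if sites else EUROPEAN
    return RflpCall(
        individual=individual,
        species=species,
        n_cut_sites=len(sites),
        cut_positions=sites,
    )


@dataclass
class HaplotypeFrequencyReport:
    """Frequency of American haplotypes in a sample of N sequences."""

    h: float
    n: int
    n_american: int


def haplotype_frequency(calls: list[RflpCall]) -> HaplotypeFrequencyReport:
    n = len(calls)
    if n == 0:
        raise ValueError("no RFLP calls supplied")
    n_am = sum(1 for c in calls if c.species == AMERICAN)
    return HaplotypeFrequencyReport(h=n_am / n, n=n, n_american=n_am)


def hamming(a: str, b: str) -> int:
    """Pairwise differences; positions with N in either sequence skipped."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    return sum(1 for x, y in zip(a, b) if x != y and x != "N" and y != "N")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> bool:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return False
        self.parent[ry] = rx
        return True


def build_msn(alignment: HaplotypeAlignment) -> HaplotypeNetwork:
    """Collapse identical sequences and build a minimum spanning tree.

    Kruskal's algorithm with edges sorted by (weight, lexicographic pair
    of first-member IDs) so ties resolve deterministically.
    """
    seen: dict[str, int] = {}
    haplotypes: list[str] = []
    counts: list[int] = []
    species: list[str | None] = []
    member_ids: list[list[str]] = []
    for k, seq in enumerate(alignment.sequences):
        tag = alignment.species[k] if alignment.species else None
        if seq in seen:
            i = seen[seq]
            counts[i] += 1
            member_ids[i].append(alignment.ids[k])
            if species[i] is None:
                species[i] = tag
        else:
            seen[seq] = len(haplotypes)
            haplotypes.append(seq)
            counts.append(1)
            species.append(tag)
            member_ids.append([alignment.ids[k]])
    m = len(haplotypes)
    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            w = hamming(haplotypes[i], haplotypes[j])
            key = tuple(sorted((member_ids[i][0], member_ids[j][0])))
            candidates.append((w, key, i, j))
    candidates.sort()
    uf = _UnionFind(m)
    edges = []
    for w, _, i, j in candidates:
        if uf.union(i, j):
            edges.append((i, j, w))
            if len(edges) == m - 1:
                break
    return HaplotypeNetwork(
        haplotypes=haplotypes,
        counts=counts,
        species=species,
        member_ids=member_ids,
        edges=edges,
    )


# ---------------------------------------------------------------------------
# Serialization


def write_rflp_calls(calls: list[RflpCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual", "species", "n_cut_sites", "cut_positions"])
        for c in calls:
            w.writerow([
                c.individual, c.species, c.n_cut_sites,
                ";".join(map(str, c.cut_positions)),
            ])


def write_network(net: HaplotypeNetwork, edge_path: str | Path, node_path: str | Path) -> None:
    with open(edge_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["node1", "node2", "weight"])
        for i, j, wgt in net.edges:
            w.writerow([f"H{i + 1}", f"H{j + 1}", wgt])
    with open(node_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["node", "haplotype", "count", "species"])
        for i, (h, c, s) in enumerate(zip(net.haplotypes, net.counts, net.species)):
            w.writerow([f"H{i + 1}", h, c, s or ""])
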