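"""Readers and writers for the external text formats the pipeline touches.

Genotype tables travel as Genepop (3-digit allele dialect by default,
2-digit accepted on read) or as a long-format CSV; haplotype alignments as
FASTA; distance matrices as PHYLIP-style square text or labeled CSV; run
configuration as YAML/JSON.

Genepop has no field for population labels, so the writer emits individual
names as ``<population>:<individual>`` and the reader recovers the label
from that prefix (falling back to ``pop1``, ``pop2``, ... for plain
files).  Allele sizes above 999 are shifted by an offset recorded on the
title line so that round-trips are exact for any size.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import MISSING, DistanceMatrix, GenotypeTable, HaplotypeAlignment


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# Genepop

_OFFSET_RE = re.compile(r"allele_offset=(-?\d+)")


def write_genepop(table: GenotypeTable, path: str | Path, digits: int = 3) -> None:
    """Write ``table`` as a Genepop file with ``digits``-digit alleles."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    limit = 10**digits - 1
    present = table.calls[table.calls != MISSING]
    offset = 0
    if present.size and present.max() > limit:
        offset = int(present.min()) - 1
        if present.max() - offset > limit:
            raise ValueError("allele size range too wide for the encoding")
    lines = [f"eelclines genepop; allele_offset={offset}"]
    lines.extend(table.loci)
    last_pop = None
    for i, (ind, pop) in enumerate(zip(table.individuals, table.populations)):
        if pop != last_pop:
            lines.append("Pop")
            last_pop = pop
        codes = []
        for j in range(table.n_loci):
            a, b = table.calls[i, j]
            if a == MISSING:
                codes.append("0" * (2 * digits))
            else:
                codes.append(f"{a - offset:0{digits}d}{b - offset:0{digits}d}")
        lines.append(f"{pop}:{ind} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path) -> GenotypeTable:
    """Parse a Genepop file, auto-detecting 2- vs 3-digit allele coding."""
    raw = Path(path).read_text().splitlines()
    if not raw:
        raise ParseError("empty Genepop file")
    m = _OFFSET_RE.search(raw[0])
    offset = int(m.group(1)) if m else 0

    loci: list[str] = []
    i = 1
    while i < len(raw) and raw[i].strip().lower() != "pop":
        line = raw[i].strip()
        if line:
            loci.extend(x.strip() for x in line.split(",") if x.strip())
        i += 1
    if i == len(raw):
        raise ParseError("no 'Pop' line found")

    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_index = 0
    digits: int | None = None
    while i < len(raw):
        line = raw[i].strip()
        if line.lower() == "pop":
            pop_index += 1
            i += 1
            continue
        if not line:
            i += 1
            continue
        if "," not in line:
            raise ParseError(f"line {i + 1}: expected '<name> , <genotypes>'")
        name, _, geno = line.partition(",")
        name = name.strip()
        if ":" in name:
            pop_label, _, ind = name.partition(":")
        else:
            pop_label, ind = f"pop{pop_index}", name
        codes = geno.split()
        if len(codes) != len(loci):
            raise ParseError(
                f"line {i + 1}: {len(codes)} genotypes for {len(loci)} loci"
            )
        calls = []
        for code in codes:
            if len(code) == 4:
                d = 2
            elif len(code) == 6:
                d = 3
            else:
                raise ParseError(f"line {i + 1}: bad genotype code '{code}'")
            if digits is None:
                digits = d
            elif digits != d:
                raise ParseError(f"line {i + 1}: mixed 2- and 3-digit encodings")
            a, b = int(code[:d]), int(code[d:])
            if (a == 0) != (b == 0):
                raise ParseError(f"line {i + 1}: half-missing genotype '{code}'")
            if a == 0:
                calls.append((MISSING, MISSING))
            else:
                calls.append((a + offset, b + offset))
        individuals.append(ind)
        populations.append(pop_label)
        rows.append(calls)
        i += 1
    return GenotypeTable(
        individuals=individuals,
        populations=populations,
        loci=loci,
        calls=np.array(rows, dtype=np.int64).reshape(len(rows), len(loci), 2),
    )


# ---------------------------------------------------------------------------
# Genotype CSV (long format: individual, population, locus, allele1, allele2)


def write_genotype_csv(table: GenotypeTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual", "population", "locus", "allele1", "allele2"])
        for i, (ind, pop) in enumerate(zip(table.individuals, table.populations)):
            for j, locus in enumerate(table.loci):
                a, b = table.calls[i, j]
                w.writerow([ind, pop, locus, int(a), int(b)])


def read_genotype_csv(path: str | Path) -> GenotypeTable:
    inds: list[str] = []
    pops: dict[str, str] = {}
    loci: list[str] = []
    data: dict[tuple[str, str], tuple[int, int]] = {}
    with open(path, newline="") as fh:
        for k, row in enumerate(csv.DictReader(fh)):
            ind, pop, locus = row["individual"], row["population"], row["locus"]
            if ind not in pops:
                inds.append(ind)
                pops[ind] = pop
            if locus not in loci:
                loci.append(locus)
            data[(ind, locus)] = (int(row["allele1"]), int(row["allele2"]))
    calls = np.zeros((len(inds), len(loci), 2), dtype=np.int64)
    for i, ind in enumerate(inds):
        for j, locus in enumerate(loci):
            calls[i, j] = data.get((ind, locus), (MISSING, MISSING))
    return GenotypeTable(inds, [pops[i] for i in inds], loci, calls)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(alignment: HaplotypeAlignment, path: str | Path, wrap: int = 70) -> None:
    records = []
    for k, (hid, seq) in enumerate(zip(alignment.ids, alignment.sequences)):
        desc = alignment.species[k] if alignment.species else ""
        records.append(SeqRecord(Seq(seq), id=hid, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_fasta(path: str | Path) -> HaplotypeAlignment:
    ids, seqs, species = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
        tag = rec.description[len(rec.id):].strip()
        species.append(tag)
    if not ids:
        raise ParseError(f"no FASTA records in {path}")
    tags = species if any(species) else None
    return HaplotypeAlignment(ids=ids, sequences=seqs, species=tags)


# ---------------------------------------------------------------------------
# Distance matrices


def write_distance_matrix(dm: DistanceMatrix, path: str | Path, fmt: str = "phylip") -> None:
    """Write a square matrix as PHYLIP-style text or labeled CSV."""
    path = Path(path)
    if fmt == "phylip":
        lines = [f"{dm.n}"]
        for lab, row in zip(dm.labels, dm.values):
            lines.append(lab + "  " + " ".join(f"{v:.10g}" for v in row))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([""] + dm.labels)
            for lab, row in zip(dm.labels, dm.values):
                w.writerow([lab] + [f"{v:.10g}" for v in row])
    else:
        raise ValueError(f"unknown format '{fmt}'")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a PHYLIP-style square matrix or a labeled CSV matrix."""
    text = Path(path).read_text()
    first = text.lstrip().splitlines()[0]
    if "," in first:
        rows = list(csv.reader(text.splitlines()))
        labels = rows[0][1:]
        values = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
    else:
        lines = [l for l in text.splitlines() if l.strip()]
        n = int(lines[0].split()[0])
        labels, mat = [], []
        for line in lines[1 : n + 1]:
            parts = line.split()
            labels.append(parts[0])
            mat.append([float(x) for x in parts[1:]])
        values = np.array(mat)
    if values.shape[0] != values.shape[1]:
        raise ParseError("distance matrix is not square")
    if not np.allclose(values, values.T, atol=1e-6):
        raise ParseError("distance matrix asymmetric beyond 1e-6")
    return DistanceMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# Config


def read_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
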