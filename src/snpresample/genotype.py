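"""Diploid biallelic genotype matrices and their on-disk formats.

The central container is :class:`GenotypeMatrix`: an individuals × loci
table of alt-allele dosages (0, 1, 2) with an explicit missing sentinel,
partitioned into populations.  For biallelic SNPs the dosage encoding is
lossless and every downstream statistic (heterozygosity, effective allele
number, Fst) depends on the data only through it.

Two formats are supported: VCF (GT field only, biallelic SNP records) and a
GenAlEx-dialect codominant CSV with two allele columns per locus (allele
codes 1/2, 0 = missing), chosen for interoperability with spreadsheet-based
population-genetics workflows.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "DataError",
    "EmptyInputError",
    "GenotypeMatrix",
    "read_vcf",
    "read_genalex",
    "write_genalex",
]

#: Sentinel for a missing call. Distinct from dosage 0 (homozygous reference):
#: the per-locus typed count N drives the unbiased-heterozygosity correction.
MISSING: int = -1

log = logging.getLogger(__name__)


class DataError(ValueError):
    """Malformed or inconsistent genotype input."""


class EmptyInputError(DataError):
    """An input that yielded no usable biallelic SNP records."""


@dataclass
class GenotypeMatrix:
    """Individuals × loci diploid biallelic genotypes as alt-allele dosage.

    Parameters
    ----------
    sample_ids
        Unique identifier per individual (row order of ``calls``).
    pop_labels
        Population label per individual, aligned with ``sample_ids``.
    locus_ids
        Unique identifier per locus (column order of ``calls``).
    calls
        ``(n_samples, n_loci)`` int8 array with values in {0, 1, 2, MISSING}.
    """

    sample_ids: list[str]
    pop_labels: list[str]
    locus_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.pop_labels = list(self.pop_labels)
        self.locus_ids = list(self.locus_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise DataError("calls must be a 2-D samples × loci array")
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.locus_ids)} loci"
            )
        if len(self.pop_labels) != len(self.sample_ids):
            raise DataError("pop_labels and sample_ids must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("sample_ids must be unique")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise DataError("locus_ids must be unique")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError(
                f"{int(bad.sum())} calls outside {{0, 1, 2, MISSING}}"
            )

    # -- basic geometry ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p, None)
        return list(seen)

    def partition(self) -> dict[str, np.ndarray]:
        """Population label → ordered array of sample indices.

        The index sets are disjoint and their union covers all samples by
        construction.
        """
        out: dict[str, list[int]] = {p: [] for p in self.populations}
        for i, p in enumerate(self.pop_labels):
            out[p].append(i)
        return {p: np.asarray(ix, dtype=np.intp) for p, ix in out.items()}

    # -- subsetting --------------------------------------------------------

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        """New matrix keeping the given sample rows (loci unchanged)."""
        ix = np.asarray(indices, dtype=np.intp)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in ix],
            [self.pop_labels[i] for i in ix],
            self.locus_ids,
            self.calls[ix, :],
        )

    def subset_loci(self, loci: Sequence[int] | Sequence[str]) -> "GenotypeMatrix":
        """New matrix keeping the given loci, by index or by locus id."""
        loci = list(loci)
        if loci and isinstance(loci[0], str):
            pos = {lid: j for j, lid in enumerate(self.locus_ids)}
            unknown = [l for l in loci if l not in pos]
            if unknown:
                raise DataError(f"unknown locus ids: {unknown[:5]}")
            ix = np.asarray([pos[l] for l in loci], dtype=np.intp)
        else:
            ix = np.asarray(loci, dtype=np.intp)
        return GenotypeMatrix(
            self.sample_ids,
            self.pop_labels,
            [self.locus_ids[j] for j in ix],
            self.calls[:, ix],
        )

    def restrict_populations(self, labels: Iterable[str]) -> "GenotypeMatrix":
        """Keep only samples from the given populations (loci unchanged)."""
        labels = list(labels)
        unknown = set(labels) - set(self.populations)
        if unknown:
            raise DataError(f"unknown populations: {sorted(unknown)}")
        part = self.partition()
        ix = np.concatenate([part[p] for p in labels])
        return self.subset_samples(ix)

    def pop_calls(self, label: str) -> np.ndarray:
        """Calls array restricted to one population's samples."""
        return self.calls[self.partition()[label], :]

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.pop_labels == other.pop_labels
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_BASES = {"A", "C", "G", "T"}


def read_vcf(path: str | Path, pop_map: Mapping[str, str]) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Only the GT subfield is used.  Locus ids are ``CHROM:POS`` (1-based, per
    the VCF standard).  Multiallelic or non-SNP records are skipped with a
    logged count; half-calls (one missing allele) become MISSING.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped).
    pop_map
        sample id → population label.  Samples absent from the map are
        dropped with a warning; map entries absent from the VCF raise.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    unknown = sorted(set(pop_map) - set(vcf_samples))
    if unknown:
        raise DataError(f"pop_map references samples absent from VCF: {unknown}")
    keep = [i for i, s in enumerate(vcf_samples) if s in pop_map]
    dropped = [s for s in vcf_samples if s not in pop_map]
    if dropped:
        log.warning("dropping %d VCF samples absent from pop_map: %s",
                    len(dropped), dropped[:5])
    if not keep:
        raise DataError("pop_map matches no sample in the VCF")

    locus_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    n_half = 0
    for v in vcf:
        if (
            len(v.ALT) != 1
            or len(v.REF) != 1
            or len(v.ALT[0]) != 1
            or v.REF.upper() not in _BASES
            or v.ALT[0].upper() not in _BASES
        ):
            n_skipped += 1
            continue
        dos = np.full(len(keep), MISSING, dtype=np.int8)
        gts = v.genotypes  # [[a0, a1, phased], ...]
        for out_i, vcf_i in enumerate(keep):
            a = gts[vcf_i]
            a0, a1 = a[0], a[1]
            if a0 < 0 and a1 < 0:
                continue  # fully missing
            if a0 < 0 or a1 < 0:
                n_half += 1
                continue  # half-call treated as missing
            dos[out_i] = a0 + a1
        locus_ids.append(f"{v.CHROM}:{v.POS}")
        rows.append(dos)
    if n_skipped:
        log.info("skipped %d non-biallelic-SNP records", n_skipped)
    if n_half:
        log.info("treated %d half-calls as missing", n_half)
    if not rows:
        raise EmptyInputError(f"no biallelic SNP records in {path}")
    sample_ids = [vcf_samples[i] for i in keep]
    g = GenotypeMatrix(
        sample_ids,
        [pop_map[s] for s in sample_ids],
        locus_ids,
        np.vstack(rows).T,
    )
    g.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return g


# ---------------------------------------------------------------------------
# GenAlEx-dialect codominant CSV
# ---------------------------------------------------------------------------
#
# Layout (bit-exact):
#   row 1: n_loci, n_samples, n_pops, size_pop1, size_pop2, ...
#   row 2: title, blank, blank, pop1_name, pop2_name, ...
#   row 3: "Sample", "Pop", then each locus name spanning two columns
#   data : sample_id, pop_label, two integer allele codes per locus
# Allele codes: 1 = reference, 2 = alternate, 0 = missing.  Dosage mapping:
# (1,1)->0, (1,2)|(2,1)->1, (2,2)->2, any 0 in the pair -> MISSING.

_D2A = {0: ("1", "1"), 1: ("1", "2"), 2: ("2", "2"), MISSING: ("0", "0")}


def write_genalex(g: GenotypeMatrix, path: str | Path, title: str = "snpresample") -> None:
    """Write a :class:`GenotypeMatrix` as a GenAlEx-dialect codominant CSV.

    The output round-trips through :func:`read_genalex` to an identical
    matrix (calls, ids and labels all preserved).
    """
    if g.n_samples == 0 or g.n_loci == 0:
        raise DataError("refusing to write an empty genotype matrix")
    path = Path(path)
    pops = g.populations
    sizes = {p: 0 for p in pops}
    for lbl in g.pop_labels:
        sizes[lbl] += 1
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([g.n_loci, g.n_samples, len(pops)] + [sizes[p] for p in pops])
        w.writerow([title, "", ""] + pops)
        hdr = ["Sample", "Pop"]
        for lid in g.locus_ids:
            hdr += [lid, ""]
        w.writerow(hdr)
        for i, sid in enumerate(g.sample_ids):
            row = [sid, g.pop_labels[i]]
            for d in g.calls[i, :]:
                row += _D2A[int(d)]
            w.writerow(row)


def read_genalex(path: str | Path) -> GenotypeMatrix:
    """Read a GenAlEx-dialect codominant CSV (see :func:`write_genalex`).

    Declared counts in the header (loci, samples, per-population sizes) must
    match the parsed content; a mismatch raises :class:`DataError` naming the
    first offending row.  Unlike canonical GenAlEx, samples need not be
    grouped by population — the per-row population column is authoritative
    and the declared sizes are validated against it.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise DataError(f"{path}: fewer than 4 rows; not a GenAlEx table")
    try:
        hdr = [int(x) for x in rows[0] if x != ""]
    except ValueError as e:
        raise DataError(f"{path}: row 1 must be integer counts") from e
    if len(hdr) < 4:
        raise DataError(f"{path}: row 1 needs n_loci, n_samples, n_pops, sizes")
    n_loci, n_samples, n_pops, *sizes = hdr
    if len(sizes) != n_pops:
        raise DataError(f"{path}: row 1 declares {n_pops} pops but {len(sizes)} sizes")
    if sum(sizes) != n_samples:
        raise DataError(f"{path}: row 1 population sizes sum to {sum(sizes)}, "
                        f"not n_samples={n_samples}")
    pop_names = [c for c in rows[1][3:3 + n_pops]]
    if len(pop_names) != n_pops or any(p == "" for p in pop_names):
        raise DataError(f"{path}: row 2 must name {n_pops} populations")
    locus_ids = rows[2][2::2][:n_loci]
    if len(locus_ids) != n_loci or any(l == "" for l in locus_ids):
        raise DataError(f"{path}: row 3 must carry {n_loci} locus names "
                        "spanning two columns each")

    data = rows[3:3 + n_samples]
    if len(data) < n_samples:
        raise DataError(f"{path}: header declares {n_samples} samples, "
                        f"found {len(data)} data rows")
    sample_ids: list[str] = []
    pop_labels: list[str] = []
    calls = np.full((n_samples, n_loci), MISSING, dtype=np.int8)
    for r, row in enumerate(data, start=4):
        if len(row) < 2 + 2 * n_loci:
            raise DataError(f"{path}: row {r} has {len(row)} fields, "
                            f"expected {2 + 2 * n_loci}")
        sample_ids.append(row[0])
        pop_labels.append(row[1])
        for j in range(n_loci):
            a_raw, b_raw = row[2 + 2 * j], row[3 + 2 * j]
            try:
                a, b = int(a_raw), int(b_raw)
            except ValueError as e:
                raise DataError(f"{path}: row {r}, locus {locus_ids[j]}: "
                                f"non-integer allele code") from e
            if a not in (0, 1, 2) or b not in (0, 1, 2):
                raise DataError(f"{path}: row {r}, locus {locus_ids[j]}: "
                                f"allele code outside {{0,1,2}}")
            if a == 0 or b == 0:
                continue  # MISSING already in place
            calls[r - 4, j] = (a - 1) + (b - 1)
    observed_sizes = {p: pop_labels.count(p) for p in pop_names}
    for p, declared in zip(pop_names, sizes):
        if observed_sizes.get(p, 0) != declared:
            raise DataError(f"{path}: population {p!r} declares {declared} "
                            f"samples, found {observed_sizes.get(p, 0)}")
    extra = set(pop_labels) - set(pop_names)
    if extra:
        raise DataError(f"{path}: data rows use undeclared populations {sorted(extra)}")
    return GenotypeMatrix(sample_ids, pop_labels, locus_ids, calls)
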