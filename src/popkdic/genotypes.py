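"""Genotype tables in STRUCTURE text format.

Diploid genotypes are held as an ``N x L x 2`` integer array of per-locus
allele codes ``0..J_l - 1``, with ``-1`` marking a missing allele copy.
Raw allele labels from the input file (e.g. microsatellite repeat lengths)
are preserved per locus so a table can be written back verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1  #: internal missing-allele code
DEFAULT_SENTINEL = -9  #: STRUCTURE convention for missing data on disk


class StructureParseError(ValueError):
    """Raised when a STRUCTURE-format file cannot be parsed."""


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes for ``n_individuals`` at ``n_loci`` loci.

    Attributes
    ----------
    alleles
        ``N x L x 2`` int array, codes ``0..J_l-1`` or ``MISSING`` (-1).
        Allele copy order carries no meaning (unphased).
    locus_allele_counts
        Number of distinct observed alleles ``J_l`` per locus.
    allele_labels
        Per locus, the raw integer labels in code order (code ``j`` of locus
        ``l`` corresponds to raw label ``allele_labels[l][j]``).
    population_labels
        Optional per-individual population-of-origin labels (strings).
    """

    alleles: np.ndarray
    locus_allele_counts: np.ndarray
    individual_labels: list[str]
    allele_labels: list[np.ndarray] = field(default_factory=list)
    population_labels: list[str] | None = None
    locus_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (N, L, 2)")
        n, l, _ = self.alleles.shape
        if n < 1 or l < 1:
            raise ValueError("need N > 0 and L > 0")
        self.locus_allele_counts = np.asarray(self.locus_allele_counts, dtype=np.int64)
        if self.locus_allele_counts.shape != (l,):
            raise ValueError("locus_allele_counts must have length L")
        if (self.locus_allele_counts < 1).any():
            raise ValueError("every locus must have J_l >= 1")
        valid = (self.alleles == MISSING) | (
            (self.alleles >= 0) & (self.alleles < self.locus_allele_counts[None, :, None])
        )
        if not valid.all():
            i, j, c = np.argwhere(~valid)[0]
            raise ValueError(
                f"allele code {self.alleles[i, j, c]} out of range at individual "
                f"{i}, locus {j} (J={self.locus_allele_counts[j]})"
            )
        if not self.allele_labels:
            self.allele_labels = [
                np.arange(jl, dtype=np.int64) for jl in self.locus_allele_counts
            ]
        if len(self.individual_labels) != n:
            raise ValueError("individual_labels must have length N")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def max_alleles(self) -> int:
        return int(self.locus_allele_counts.max())

    def monomorphic_loci(self) -> np.ndarray:
        """Indices of loci with a single observed allele (J_l == 1)."""
        return np.flatnonzero(self.locus_allele_counts == 1)

    def dosage_matrix(self, allele: int = 1) -> np.ndarray:
        """``N x L`` count of copies of ``allele`` (NaN where both copies missing).

        Intended for diallelic data; a copy-level missing call contributes
        NaN as well, so downstream column statistics use complete calls only.
        """
        a = self.alleles
        miss = (a == MISSING).any(axis=2)
        d = (a == allele).sum(axis=2).astype(float)
        d[miss] = np.nan
        return d

    def __eq__(self, other: object) -> bool:  # content equality
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.locus_allele_counts, other.locus_allele_counts)
            and self.individual_labels == other.individual_labels
            and all(
                np.array_equal(a, b)
                for a, b in zip(self.allele_labels, other.allele_labels)
            )
            and (self.population_labels or None) == (other.population_labels or None)
        )


def recode_and_validate(
    raw_alleles: np.ndarray,
    individual_labels: list[str] | None = None,
    population_labels: list[str] | None = None,
    locus_names: list[str] | None = None,
    missing: int = DEFAULT_SENTINEL,
) -> GenotypeTable:
    """Map raw integer allele labels to dense codes ``0..J_l-1`` per locus.

    Distinct non-missing labels at each locus are assigned codes in ascending
    numeric order of the raw labels, which makes the coding deterministic and
    independent of individual ordering. The label-to-code mapping is retained
    on the table for writing.

    Raises
    ------
    ValueError
        If a locus has zero non-missing calls.
    """
    raw = np.asarray(raw_alleles, dtype=np.int64)
    if raw.ndim != 3 or raw.shape[2] != 2:
        raise ValueError("raw_alleles must have shape (N, L, 2)")
    n, l, _ = raw.shape
    codes = np.full(raw.shape, MISSING, dtype=np.int32)
    counts = np.zeros(l, dtype=np.int64)
    labels_per_locus: list[np.ndarray] = []
    for j in range(l):
        col = raw[:, j, :]
        obs = np.unique(col[col != missing])
        if obs.size == 0:
            raise ValueError(f"locus {j} has no non-missing calls")
        counts[j] = obs.size
        labels_per_locus.append(obs)
        present = col != missing
        codes[:, j, :][present] = np.searchsorted(obs, col[present])
    if individual_labels is None:
        individual_labels = [f"ind_{i + 1}" for i in range(n)]
    return GenotypeTable(
        alleles=codes,
        locus_allele_counts=counts,
        individual_labels=list(individual_labels),
        allele_labels=labels_per_locus,
        population_labels=population_labels,
        locus_names=locus_names,
    )


def _parse_rows(lines: list[tuple[int, list[str]]], path: str) -> list[list[int]]:
    rows = []
    for lineno, fields in lines:
        try:
            rows.append([int(x) for x in fields])
        except ValueError as exc:
            raise StructureParseError(f"{path}:{lineno}: non-integer field: {exc}")
    return rows


def read_structure(
    path,
    dialect: str = "onerow",
    missing: int = DEFAULT_SENTINEL,
    label_cols: int = 1,
    pop_col: bool = False,
    header: bool | None = None,
) -> GenotypeTable:
    """Read a STRUCTURE-format genotype file.

    Parameters
    ----------
    dialect
        ``"onerow"``: one row per individual, two adjacent columns per locus.
        ``"tworow"``: two consecutive rows per individual, one column per
        locus per row.
    label_cols
        Number of leading non-genotype columns; the first is the individual
        label. ``pop_col=True`` treats the second as a population label.
    header
        Whether the first line is a locus-name header. ``None`` auto-detects:
        a first line whose fields are all non-integer is taken as a header.
    """
    with open(path) as fh:
        raw_lines = [
            (i + 1, ln.split()) for i, ln in enumerate(fh) if ln.strip()
        ]
    if not raw_lines:
        raise StructureParseError(f"{path}: empty file")

    locus_names = None
    first = raw_lines[0][1]

    def _is_int(s: str) -> bool:
        try:
            int(s)
            return True
        except ValueError:
            return False

    if header is None:
        header = not any(_is_int(x) for x in first)
    if header:
        locus_names = list(first)
        raw_lines = raw_lines[1:]
        if not raw_lines:
            raise StructureParseError(f"{path}: header but no data rows")

    widths = {len(f) for _, f in raw_lines}
    if len(widths) != 1:
        bad = next(ln for ln, f in raw_lines if len(f) != len(raw_lines[0][1]))
        raise StructureParseError(
            f"{path}:{bad}: ragged row (inconsistent column count)"
        )
    ncol = widths.pop()
    n_geno_cols = ncol - label_cols - (1 if pop_col else 0)
    if n_geno_cols < 1:
        raise StructureParseError(f"{path}: no genotype columns")

    def split_row(fields):
        lab = fields[0]
        pop = fields[label_cols] if pop_col else None
        geno = fields[label_cols + (1 if pop_col else 0):]
        return lab, pop, geno

    if dialect == "onerow":
        if n_geno_cols % 2 != 0:
            raise StructureParseError(
                f"{path}: odd genotype column count {n_geno_cols} for onerow dialect"
            )
        n_loci = n_geno_cols // 2
        inds, pops, raw = [], [], []
        for lineno, fields in raw_lines:
            lab, pop, geno = split_row(fields)
            vals = _parse_rows([(lineno, geno)], str(path))[0]
            inds.append(lab)
            pops.append(pop)
            raw.append(np.asarray(vals).reshape(n_loci, 2))
    elif dialect == "tworow":
        if len(raw_lines) % 2 != 0:
            raise StructureParseError(
                f"{path}: odd number of data rows for tworow dialect"
            )
        n_loci = n_geno_cols
        inds, pops, raw = [], [], []
        for (ln1, f1), (ln2, f2) in zip(raw_lines[::2], raw_lines[1::2]):
            lab1, pop1, g1 = split_row(f1)
            lab2, _, g2 = split_row(f2)
            if lab1 != lab2:
                raise StructureParseError(
                    f"{path}:{ln2}: row pair labels differ ({lab1!r} vs {lab2!r})"
                )
            v1 = _parse_rows([(ln1, g1)], str(path))[0]
            v2 = _parse_rows([(ln2, g2)], str(path))[0]
            inds.append(lab1)
            pops.append(pop1)
            raw.append(np.stack([v1, v2], axis=1))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    raw_arr = np.stack(raw, axis=0)
    if locus_names is not None and len(locus_names) not in (n_loci,):
        locus_names = None  # header was not a locus-name line of matching width
    return recode_and_validate(
        raw_arr,
        individual_labels=inds,
        population_labels=pops if pop_col else None,
        locus_names=locus_names,
        missing=missing,
    )


def write_structure(
    table: GenotypeTable,
    path,
    dialect: str = "onerow",
    missing: int = DEFAULT_SENTINEL,
    write_pop: bool | None = None,
    write_header: bool = False,
) -> None:
    """Write a table in STRUCTURE format, inverting the allele recoding."""
    n, l = table.n_individuals, table.n_loci
    if write_pop is None:
        write_pop = table.population_labels is not None
    labels = table.individual_labels or [f"ind_{i + 1}" for i in range(n)]
    labels = [lab if lab else f"ind_{i + 1}" for i, lab in enumerate(labels)]

    raw = np.full((n, l, 2), missing, dtype=np.int64)
    for j in range(l):
        col = table.alleles[:, j, :]
        present = col != MISSING
        raw[:, j, :][present] = table.allele_labels[j][col[present]]

    with open(path, "w") as fh:
        if write_header and table.locus_names:
            fh.write(" ".join(table.locus_names) + "\n")
        for i in range(n):
            lead = [labels[i]]
            if write_pop:
                pop = table.population_labels[i] if table.population_labels else "1"
                lead.append(str(pop))
            if dialect == "onerow":
                geno = raw[i].reshape(-1)
                fh.write(" ".join(lead + [str(x) for x in geno]) + "\n")
            elif dialect == "tworow":
                for c in range(2):
                    fh.write(" ".join(lead + [str(x) for x in raw[i, :, c]]) + "\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
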