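"""Genetic map, genotype, phenotype and gene-catalog containers with TSV I/O.

All on-disk formats are UTF-8 tab-separated files with a header row;
lines starting with ``#`` are ignored.  Genotype codes are the three
symbols ``A`` (one parental homozygote), ``H`` (heterozygote) and ``B``
(the other homozygote).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Integer storage for genotype codes.
CODE_A, CODE_H, CODE_B = 0, 1, 2
_CODE_FROM_CHAR = {"A": CODE_A, "H": CODE_H, "B": CODE_B}
_CHAR_FROM_CODE = np.array(["A", "H", "B"])


class DataError(ValueError):
    """Raised on malformed or inconsistent input data."""


@dataclass(frozen=True)
class BinEntry:
    bin_id: str
    chromosome: str
    pos_cM: float
    bp_start: Optional[int] = None
    bp_end: Optional[int] = None


@dataclass
class BinMap:
    """Ordered genome coordinate system of marker bins.

    Entries are sorted by (chromosome, pos_cM); bin ids are unique.
    """

    entries: list[BinEntry]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [e.bin_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate bin_id(s): {dup[:5]}")
        order = sorted(range(len(ids)),
                       key=lambda t: (self.entries[t].chromosome,
                                      self.entries[t].pos_cM))
        if order != list(range(len(ids))):
            logger.warning("bin map rows were not sorted; re-sorting by "
                           "(chromosome, pos_cM)")
            self.entries = [self.entries[t] for t in order]
        self._index = {e.bin_id: t for t, e in enumerate(self.entries)}

    @property
    def m(self) -> int:
        return len(self.entries)

    @property
    def bin_ids(self) -> list[str]:
        return [e.bin_id for e in self.entries]

    def index_of(self, bin_id: str) -> int:
        try:
            return self._index[bin_id]
        except KeyError:
            raise DataError(f"unknown bin_id {bin_id!r}") from None

    def entry(self, bin_id: str) -> BinEntry:
        return self.entries[self.index_of(bin_id)]

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.chromosome, None)
        return list(seen)


def cm_distance(bin_map: BinMap, bin_a: str, bin_b: str) -> float:
    """Map distance in cM between two bins.

    Returns ``math.inf`` when the bins lie on different chromosomes:
    cross-chromosome map distances are incomparable and such bins are
    never grouped nor gene-associated.
    """
    ea = bin_map.entry(bin_a)
    eb = bin_map.entry(bin_b)
    if ea.chromosome != eb.chromosome:
        return math.inf
    return abs(ea.pos_cM - eb.pos_cM)


@dataclass
class GenotypeMatrix:
    """n individuals x m bins of genotype codes, stored as int8.

    Use :func:`genotypes_from_strings` to build from letter codes.
    No missing values are allowed.  Columns where neither homozygote
    is observed (all-H) are flagged via :attr:`monomorphic_h_bins`.
    """

    codes: np.ndarray  # int8, shape (n, m), values in {0, 1, 2}
    individual_ids: list[str]
    bin_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise DataError("codes must be a 2-D array")
        n, m = self.codes.shape
        if len(self.individual_ids) != n or len(self.bin_ids) != m:
            raise DataError("id lists do not match codes shape")
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=0) > 2:
            raise DataError("genotype codes must be in {A, H, B}")
        mono_h = np.flatnonzero((self.codes == CODE_H).all(axis=0))
        if mono_h.size:
            logger.warning("%d bin(s) are monomorphic-H: %s", mono_h.size,
                           [self.bin_ids[t] for t in mono_h[:5]])

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    @property
    def monomorphic_h_bins(self) -> list[str]:
        mask = (self.codes == CODE_H).all(axis=0)
        return [b for b, f in zip(self.bin_ids, mask) if f]

    def letters(self) -> np.ndarray:
        """Return the matrix as single-character strings."""
        return _CHAR_FROM_CODE[self.codes]

    def subset_rows(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(self.codes[rows],
                              [self.individual_ids[int(r)] for r in rows],
                              list(self.bin_ids))


def genotypes_from_strings(rows: Iterable[Sequence[str]],
                           individual_ids: Sequence[str],
                           bin_ids: Sequence[str]) -> GenotypeMatrix:
    n_rows = []
    for r_i, row in enumerate(rows):
        out = np.empty(len(row), dtype=np.int8)
        for c_i, cell in enumerate(row):
            try:
                out[c_i] = _CODE_FROM_CHAR[cell]
            except KeyError:
                raise DataError(
                    f"invalid genotype code {cell!r} at individual "
                    f"{individual_ids[r_i]!r}, bin {bin_ids[c_i]!r}"
                ) from None
        n_rows.append(out)
    return GenotypeMatrix(np.vstack(n_rows) if n_rows else
                          np.empty((0, len(bin_ids)), dtype=np.int8),
                          list(individual_ids), list(bin_ids))


@dataclass
class PhenotypeVector:
    trait_name: str
    values: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("phenotype values must be 1-D")
        if len(self.individual_ids) != self.values.size:
            raise DataError("individual_ids length mismatch")
        if not np.isfinite(self.values).all():
            raise DataError(f"non-finite phenotype values for trait "
                            f"{self.trait_name!r}")

    @property
    def n(self) -> int:
        return self.values.size

    def subset(self, rows: Sequence[int]) -> "PhenotypeVector":
        rows = np.asarray(rows)
        return PhenotypeVector(self.trait_name, self.values[rows],
                               [self.individual_ids[int(r)] for r in rows])


@dataclass
class GeneCatalog:
    """Known genes with genetic-map positions, for proximity annotation."""

    records: list[tuple[str, str, float]]  # (gene_name, chromosome, pos_cM)

    def validate_against(self, bin_map: BinMap) -> None:
        chroms = set(bin_map.chromosomes())
        bad = sorted({c for _, c, _ in self.records if c not in chroms})
        if bad:
            raise DataError(f"gene catalog chromosomes absent from map: {bad}")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False)


def read_bin_map(path) -> BinMap:
    """Parse a bin map TSV (``bin_id  chrom  pos_cM [bp_start bp_end]``)."""
    df = _read_tsv(path)
    required = {"bin_id", "chrom", "pos_cM"}
    if not required.issubset(df.columns):
        raise DataError(f"bin map must have columns {sorted(required)}, "
                        f"got {list(df.columns)}")
    entries = []
    for _, row in df.iterrows():
        try:
            pos = float(row["pos_cM"])
        except ValueError:
            raise DataError(f"non-numeric pos_cM {row['pos_cM']!r} for bin "
                            f"{row['bin_id']!r}") from None
        bp_s = int(row["bp_start"]) if "bp_start" in df.columns and row["bp_start"] != "" else None
        bp_e = int(row["bp_end"]) if "bp_end" in df.columns and row["bp_end"] != "" else None
        entries.append(BinEntry(row["bin_id"], row["chrom"], pos, bp_s, bp_e))
    return BinMap(entries)


def write_bin_map(bin_map: BinMap, path) -> None:
    has_bp = any(e.bp_start is not None for e in bin_map.entries)
    cols = ["bin_id", "chrom", "pos_cM"] + (["bp_start", "bp_end"] if has_bp else [])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in bin_map.entries:
            row = [e.bin_id, e.chromosome, repr(e.pos_cM)]
            if has_bp:
                row += ["" if e.bp_start is None else str(e.bp_start),
                        "" if e.bp_end is None else str(e.bp_end)]
            fh.write("\t".join(row) + "\n")


def read_genotypes(path, bin_map: BinMap) -> GenotypeMatrix:
    """Parse a genotype TSV (rows = individuals, columns = bin ids).

    Columns are re-ordered to match ``bin_map``; every map bin must be
    present.
    """
    df = _read_tsv(path)
    if df.columns[0] != "individual_id":
        raise DataError("first genotype column must be 'individual_id'")
    have = set(df.columns[1:])
    missing = [b for b in bin_map.bin_ids if b not in have]
    if missing:
        raise DataError(f"genotype file missing {len(missing)} map bin(s), "
                        f"e.g. {missing[:5]}")
    ids = df["individual_id"].tolist()
    ordered = df[bin_map.bin_ids]
    return genotypes_from_strings(ordered.to_numpy().tolist(), ids,
                                  bin_map.bin_ids)


def write_genotypes(G: GenotypeMatrix, path) -> None:
    letters = G.letters()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("individual_id\t" + "\t".join(G.bin_ids) + "\n")
        for i, ind in enumerate(G.individual_ids):
            fh.write(ind + "\t" + "\t".join(letters[i]) + "\n")


def read_phenotypes(path) -> dict[str, PhenotypeVector]:
    """Parse a phenotype TSV (``individual_id`` + one column per trait)."""
    df = _read_tsv(path)
    if df.columns[0] != "individual_id":
        raise DataError("first phenotype column must be 'individual_id'")
    ids = df["individual_id"].tolist()
    out = {}
    for trait in df.columns[1:]:
        try:
            vals = df[trait].astype(float).to_numpy()
        except ValueError:
            raise DataError(f"non-numeric phenotype in trait {trait!r}") from None
        out[trait] = PhenotypeVector(trait, vals, ids)
    return out


def write_phenotypes(phenos: dict[str, PhenotypeVector], path) -> None:
    traits = list(phenos)
    ids = phenos[traits[0]].individual_ids
    for t in traits:
        if phenos[t].individual_ids != ids:
            raise DataError("phenotype vectors have inconsistent individuals")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("individual_id\t" + "\t".join(traits) + "\n")
        for i, ind in enumerate(ids):
            fh.write(ind + "\t" +
                     "\t".join(repr(float(phenos[t].values[i])) for t in traits)
                     + "\n")


def read_gene_catalog(path, bin_map: Optional[BinMap] = None) -> GeneCatalog:
    df = _read_tsv(path)
    required = {"gene_name", "chrom", "pos_cM"}
    if not required.issubset(df.columns):
        raise DataError(f"gene catalog must have columns {sorted(required)}")
    records = [(r["gene_name"], r["chrom"], float(r["pos_cM"]))
               for _, r in df.iterrows()]
    cat = GeneCatalog(records)
    if bin_map is not None:
        cat.validate_against(bin_map)
    return cat


def write_gene_catalog(catalog: GeneCatalog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_name\tchrom\tpos_cM\n")
        for name, chrom, pos in catalog.records:
            fh.write(f"{name}\t{chrom}\t{pos!r}\n")


def align_phenotype(pheno: PhenotypeVector, G: GenotypeMatrix) -> PhenotypeVector:
    """Reorder a phenotype vector to the genotype matrix's individuals."""
    if pheno.individual_ids == G.individual_ids:
        return pheno
    pos = {ind: i for i, ind in enumerate(pheno.individual_ids)}
    try:
        rows = [pos[ind] for ind in G.individual_ids]
    except KeyError as exc:
        raise DataError(f"phenotype missing individual {exc.args[0]!r}") from None
    return pheno.subset(rows)
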