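"""Numeric genotype coding and the six-block effect design space.

The candidate effect space for ``m`` markers is laid out as six
contiguous blocks of linear column indices::

    [ A main (m) | D main (m) | AA (q) | AD (q) | DA (q) | DD (q) ]

with ``q = m(m-1)/2`` unordered marker pairs enumerated
lexicographically by (i, j), i < j.  Additive coding is +1/0/-1 for
A/H/B; dominance coding is 0/+1/0.  Interaction columns are
element-wise products of the two main-effect codings.  The full design
matrix is never stored; columns are materialized on demand in blocks.

Bin indices in :class:`EffectDescriptor` are 1-based, matching the
``Bin757``-style labels used in output tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .maps import CODE_H, GenotypeMatrix

logger = logging.getLogger(__name__)

MAIN_FAMILIES = ("A", "D")
INTERACTION_FAMILIES = ("AA", "AD", "DA", "DD")
FAMILIES = MAIN_FAMILIES + INTERACTION_FAMILIES


@dataclass(frozen=True, order=True)
class EffectDescriptor:
    """One candidate effect: a family and 1-based bin index pair.

    Main families (A, D) have i == j; interaction families have i < j.
    """

    family: str
    i: int
    j: int

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in MAIN_FAMILIES:
            if self.i != self.j:
                raise ValueError("main-effect descriptor requires i == j")
        else:
            if not self.i < self.j:
                raise ValueError("interaction descriptor requires i < j")
        if self.i < 1:
            raise ValueError("bin indices are 1-based")

    @property
    def is_main(self) -> bool:
        return self.family in MAIN_FAMILIES

    def label(self) -> str:
        fam_i = "add" if self.family[0] == "A" else "dom"
        if self.is_main:
            return f"Bin{self.i}_{fam_i}"
        fam_j = "add" if self.family[1] == "A" else "dom"
        return f"Bin{self.i}_{fam_i}:Bin{self.j}_{fam_j}"


def pair_count(m: int) -> int:
    """Number of unordered marker pairs, q = m(m-1)/2."""
    return m * (m - 1) // 2


def num_variables(m: int, include_interactions: bool = True) -> int:
    """Total candidate columns: 2m + 4q for the full model, 2m otherwise."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if include_interactions:
        return 2 * m + 4 * pair_count(m)
    return 2 * m


def code_additive(code: str) -> int:
    """A -> +1, H -> 0, B -> -1."""
    return {"A": 1, "H": 0, "B": -1}[code]


def code_dominance(code: str) -> int:
    """A -> 0, H -> +1, B -> 0."""
    return {"A": 0, "H": 1, "B": 0}[code]


def additive_matrix(G: GenotypeMatrix) -> np.ndarray:
    """n x m additive coding (+1/0/-1) as float64."""
    return (1 - G.codes).astype(np.float64)


def dominance_matrix(G: GenotypeMatrix) -> np.ndarray:
    """n x m dominance coding (0/+1/0) as float64."""
    return (G.codes == CODE_H).astype(np.float64)


# --- linear index <-> descriptor bijection ---------------------------------

def _row_start(i: int, m: int) -> int:
    """Number of (i', j') pairs with i' < i; rows are 0-based."""
    return i * m - i * (i + 1) // 2


def _pair_from_linear(p: int, m: int) -> tuple[int, int]:
    # approximate row from the quadratic formula, then correct exactly
    i = int((2 * m - 1 - np.sqrt((2 * m - 1) ** 2 - 8 * p)) / 2)
    i = min(max(i, 0), m - 2)
    while i > 0 and _row_start(i, m) > p:
        i -= 1
    while i < m - 2 and _row_start(i + 1, m) <= p:
        i += 1
    j = p - _row_start(i, m) + i + 1
    return i, j


def _pair_to_linear(i: int, j: int, m: int) -> int:
    return _row_start(i, m) + (j - i - 1)


def index_to_descriptor(idx: int, m: int,
                        include_interactions: bool = True) -> EffectDescriptor:
    """Map a linear column index in [0, k) to its effect descriptor."""
    k = num_variables(m, include_interactions)
    if not 0 <= idx < k:
        raise IndexError(f"column index {idx} out of range [0, {k})")
    if idx < m:
        return EffectDescriptor("A", idx + 1, idx + 1)
    if idx < 2 * m:
        return EffectDescriptor("D", idx - m + 1, idx - m + 1)
    q = pair_count(m)
    fam = INTERACTION_FAMILIES[(idx - 2 * m) // q]
    i, j = _pair_from_linear((idx - 2 * m) % q, m)
    return EffectDescriptor(fam, i + 1, j + 1)


def descriptor_to_index(desc: EffectDescriptor, m: int,
                        include_interactions: bool = True) -> int:
    """Inverse of :func:`index_to_descriptor`."""
    if desc.j > m:
        raise IndexError(f"descriptor {desc} exceeds m={m}")
    if desc.family == "A":
        return desc.i - 1
    if desc.family == "D":
        return m + desc.i - 1
    if not include_interactions:
        raise IndexError("interaction descriptor in a main-effects-only space")
    q = pair_count(m)
    fam_off = INTERACTION_FAMILIES.index(desc.family)
    return 2 * m + fam_off * q + _pair_to_linear(desc.i - 1, desc.j - 1, m)


def effect_column(desc: EffectDescriptor, G: GenotypeMatrix) -> np.ndarray:
    """Materialize one design column for all n individuals."""
    if desc.j > G.m:
        raise IndexError(f"descriptor {desc} exceeds m={G.m}")
    XA = additive_matrix(G)
    XD = dominance_matrix(G)
    i, j = desc.i - 1, desc.j - 1
    if desc.family == "A":
        return XA[:, i]
    if desc.family == "D":
        return XD[:, i]
    left = XA if desc.family[0] == "A" else XD
    right = XA if desc.family[1] == "A" else XD
    return left[:, i] * right[:, j]


@dataclass
class DesignSpec:
    """Dimensions and exclusion set of the candidate column space."""

    m: int
    include_interactions: bool
    excluded_columns: frozenset[int] = field(default_factory=frozenset)

    @property
    def k(self) -> int:
        return num_variables(self.m, self.include_interactions)

    @property
    def n_candidates(self) -> int:
        return self.k - len(self.excluded_columns)


class ColumnMaterializer:
    """Vectorized on-demand materialization of design columns.

    Holds only the two n x m coding matrices; any set of linear column
    indices is produced with a handful of gathers and one element-wise
    product, so memory stays O(n * block).
    """

    def __init__(self, G: GenotypeMatrix, include_interactions: bool = True):
        self.m = G.m
        self.n = G.n
        self.include_interactions = include_interactions
        self.XA = additive_matrix(G)
        self.XD = dominance_matrix(G)
        self.k = num_variables(self.m, include_interactions)
        self._q = pair_count(self.m)
        # pairs-before-row offsets for vectorized pair decoding
        rows = np.arange(self.m, dtype=np.int64)
        self._row_start = rows * self.m - rows * (rows + 1) // 2

    def _decode_pairs(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        i = np.searchsorted(self._row_start, p, side="right") - 1
        j = p - self._row_start[i] + i + 1
        return i, j

    def columns(self, idx: np.ndarray) -> np.ndarray:
        """Return the n x len(idx) sub-matrix of design columns."""
        idx = np.asarray(idx, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= self.k):
            raise IndexError("column index out of range")
        m, q = self.m, self._q
        out = np.empty((self.n, idx.size), dtype=np.float64)
        sel_a = idx < m
        if sel_a.any():
            out[:, sel_a] = self.XA[:, idx[sel_a]]
        sel_d = (idx >= m) & (idx < 2 * m)
        if sel_d.any():
            out[:, sel_d] = self.XD[:, idx[sel_d] - m]
        for f, fam in enumerate(INTERACTION_FAMILIES):
            lo = 2 * m + f * q
            sel = (idx >= lo) & (idx < lo + q)
            if not sel.any():
                continue
            i, j = self._decode_pairs(idx[sel] - lo)
            left = self.XA if fam[0] == "A" else self.XD
            right = self.XA if fam[1] == "A" else self.XD
            out[:, sel] = left[:, i] * right[:, j]
        return out

    def column(self, idx: int) -> np.ndarray:
        return self.columns(np.array([idx]))[:, 0]


def find_excluded_columns(G: GenotypeMatrix, include_interactions: bool = True,
                          block_size: int = 8192) -> frozenset[int]:
    """Linear indices of zero-sample-variance (constant) columns.

    Constant predictors have undefined shrinkage updates and are removed
    from the candidate set before fitting.
    """
    mat = ColumnMaterializer(G, include_interactions)
    excluded: list[int] = []
    for lo in range(0, mat.k, block_size):
        idx = np.arange(lo, min(lo + block_size, mat.k))
        X = mat.columns(idx)
        const = (X == X[0]).all(axis=0) if X.shape[0] else np.ones(idx.size, bool)
        excluded.extend(idx[const].tolist())
    if excluded:
        logger.info("excluding %d constant design column(s) of %d",
                    len(excluded), mat.k)
    return frozenset(excluded)


def build_design_spec(G: GenotypeMatrix,
                      include_interactions: bool = True) -> DesignSpec:
    """Design spec for a genotype matrix, with constant columns excluded."""
    excl = find_excluded_columns(G, include_interactions)
    return DesignSpec(G.m, include_interactions, excl)


def column_blocks(G: GenotypeMatrix, spec: DesignSpec,
                  block_size: int) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (linear indices, n x block matrix) over all candidate columns.

    Excluded columns never appear; ordering is the fixed block layout.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    mat = ColumnMaterializer(G, spec.include_interactions)
    if spec.excluded_columns:
        keep = np.setdiff1d(np.arange(spec.k),
                            np.fromiter(spec.excluded_columns, dtype=np.int64))
    else:
        keep = np.arange(spec.k)
    for lo in range(0, keep.size, block_size):
        idx = keep[lo:lo + block_size]
        yield idx, mat.columns(idx)


def dense_design(G: GenotypeMatrix, include_interactions: bool = True,
                 apply_exclusions: bool = False,
                 spec: Optional[DesignSpec] = None) -> np.ndarray:
    """Full dense design matrix; testing aid for small m only."""
    k = num_variables(G.m, include_interactions)
    if k > 50_000:
        raise ValueError("dense_design is a small-m testing aid")
    mat = ColumnMaterializer(G, include_interactions)
    idx = np.arange(k)
    if apply_exclusions:
        if spec is None:
            spec = build_design_spec(G, include_interactions)
        idx = np.setdiff1d(idx, np.fromiter(spec.excluded_columns, dtype=np.int64)
                           if spec.excluded_columns else np.array([], dtype=np.int64))
    return mat.columns(idx)


def write_dense_design(G: GenotypeMatrix, path,
                       include_interactions: bool = True) -> None:
    """TSV export of the dense design matrix (m <= 100 testing aid)."""
    if G.m > 100:
        raise ValueError("dense export supported only for m <= 100")
    X = dense_design(G, include_interactions)
    headers = [index_to_descriptor(t, G.m, include_interactions).label()
               for t in range(X.shape[1])]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("individual_id\t" + "\t".join(headers) + "\n")
        for i, ind in enumerate(G.individual_ids):
            fh.write(ind + "\t" + "\t".join("%g" % v for v in X[i]) + "\n")
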