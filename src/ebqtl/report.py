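"""Significance testing, variance decomposition, QTL grouping and outputs.

Each active effect gets a t-statistic ``beta_hat / sqrt(Sigma_jj)`` with
``n - M - 1`` degrees of freedom (M active effects plus the intercept)
and a per-effect phenotypic-variance-explained share
``var(x_j) * beta_hat_j^2 / var(y)``.  The total variance explained by
the significant set comes from an ordinary-least-squares refit.
Significant QTLs within 20 cM on the same chromosome are single-linkage
grouped, and genes from a user catalog are associated within 20 cM
(highlighted within 2 cM, boundaries inclusive).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .design import ColumnMaterializer, EffectDescriptor
from .eblasso import EBlassoFit
from .maps import BinMap, GeneCatalog, GenotypeMatrix, cm_distance

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
DEFAULT_RADIUS_CM = 20.0
DEFAULT_HIGHLIGHT_CM = 2.0


@dataclass
class EffectReport:
    desc: EffectDescriptor
    beta_hat: float
    sd: float
    t: float
    p_value: float
    h2: float
    significant: bool


def significance_test(fit: EBlassoFit, n: int,
                      alpha: float = DEFAULT_ALPHA,
                      use_normal: bool = False,
                      bonferroni: bool = False) -> list[EffectReport]:
    """t-tests of the active effects from the posterior covariance diagonal.

    ``use_normal`` switches the reference distribution to the standard
    normal (the degrees-of-freedom convention is not uniquely pinned
    down; the default is Student t with df = n - M - 1).  ``bonferroni``
    divides alpha by the number of tested effects; off by default,
    matching the raw p <= alpha selection rule.
    """
    M = fit.n_active
    if bonferroni and M:
        alpha = alpha / M
    df = n - M - 1
    if not use_normal and df <= 0:
        raise ValueError(f"non-positive degrees of freedom (n={n}, M={M}); "
                         "the model is too large for a t-test")
    reports = []
    for pos, (desc, _sigma2) in enumerate(fit.active):
        beta = float(fit.beta_hat[pos])
        sd = math.sqrt(float(fit.Sigma[pos, pos]))
        if beta == 0.0:
            t, p = 0.0, 1.0
        else:
            t = beta / sd
            if use_normal:
                p = 2.0 * float(stats.norm.sf(abs(t)))
            else:
                p = 2.0 * float(stats.t.sf(abs(t), df))
            p = min(p, 1.0)
        reports.append(EffectReport(desc, beta, sd, t, p, h2=0.0,
                                    significant=p <= alpha))
    return reports


def per_effect_pve(beta_hat: float, x: np.ndarray, y: np.ndarray) -> float:
    """h2_j = var(x_j) * beta_hat^2 / var(y) (sample variances)."""
    y = np.asarray(y, dtype=float)
    var_y = float(np.var(y, ddof=1))
    if var_y <= 0:
        raise ValueError("phenotype variance must be positive")
    var_x = float(np.var(np.asarray(x, dtype=float), ddof=1))
    if var_x == 0.0:
        logger.warning("zero-variance design column in PVE computation")
        return 0.0
    return var_x * beta_hat * beta_hat / var_y


def attach_pve(reports: list[EffectReport], fit: EBlassoFit,
               G: GenotypeMatrix, y: np.ndarray) -> list[EffectReport]:
    """Fill the per-effect variance-explained field of the reports."""
    if not reports:
        return reports
    mat = ColumnMaterializer(G, fit.spec.include_interactions)
    X = mat.columns(fit.active_idx)
    for pos, rep in enumerate(reports):
        rep.h2 = per_effect_pve(rep.beta_hat, X[:, pos], y)
    return reports


def total_pve_refit(y: np.ndarray, X_sig: np.ndarray,
                    significance_order: Optional[Sequence[int]] = None
                    ) -> tuple[float, np.ndarray, list[int]]:
    """OLS refit on the significant columns; returns (PVE, coefs, kept).

    PVE is 1 - RSS/TSS of the intercept-included refit.  Rank-deficient
    columns are dropped greedily, least significant first
    (``significance_order`` lists column positions from most to least
    significant; default is the given order).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X_sig.shape[1] == 0:
        return 0.0, np.empty(0), []
    order = (list(significance_order) if significance_order is not None
             else list(range(X_sig.shape[1])))
    kept: list[int] = []
    for pos in order:
        trial = kept + [pos]
        A = np.column_stack([np.ones(n), X_sig[:, trial]])
        if np.linalg.matrix_rank(A) == len(trial) + 1:
            kept.append(pos)
        else:
            logger.warning("dropping rank-deficient refit column %d", pos)
    kept.sort()
    A = np.column_stack([np.ones(n), X_sig[:, kept]])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(resid @ resid)
    pve = 1.0 - rss / tss if tss > 0 else 0.0
    return pve, coef, kept


def group_qtls(bins: Sequence[str], bin_map: BinMap,
               radius: float = DEFAULT_RADIUS_CM) -> list[list[str]]:
    """Single-linkage grouping of QTL bins within ``radius`` cM.

    Two QTLs share a group when a chain of member-to-member distances
    each <= radius connects them; groups never span chromosomes.
    Output order and within-group order follow the map; input order is
    irrelevant (set semantics).
    """
    uniq = sorted(set(bins), key=bin_map.index_of)
    groups: list[list[str]] = []
    for b in uniq:
        if groups and cm_distance(bin_map, groups[-1][-1], b) <= radius:
            groups[-1].append(b)
        else:
            groups.append([b])
    return groups


@dataclass
class GeneAssociation:
    bin_id: str
    gene_name: str
    distance_cM: float
    highlighted: bool


def associate_genes(bins: Sequence[str], catalog: GeneCatalog,
                    bin_map: BinMap,
                    radius: float = DEFAULT_RADIUS_CM,
                    highlight: float = DEFAULT_HIGHLIGHT_CM
                    ) -> list[GeneAssociation]:
    """Genes within ``radius`` cM of each QTL bin (same chromosome only).

    Distances are inclusive at both thresholds; associations within
    ``highlight`` cM are flagged.
    """
    catalog.validate_against(bin_map)
    out: list[GeneAssociation] = []
    for b in sorted(set(bins), key=bin_map.index_of):
        e = bin_map.entry(b)
        for gene, chrom, pos in catalog.records:
            if chrom != e.chromosome:
                continue
            d = abs(pos - e.pos_cM)
            if d <= radius:
                out.append(GeneAssociation(b, gene, d, d <= highlight))
    return out


def qtl_bins(reports: Sequence[EffectReport],
             significant_only: bool = True) -> list[int]:
    """Distinct 1-based bin indices involved in the (significant) effects."""
    bins: set[int] = set()
    for r in reports:
        if significant_only and not r.significant:
            continue
        bins.add(r.desc.i)
        if not r.desc.is_main:
            bins.add(r.desc.j)
    return sorted(bins)


# ---------------------------------------------------------------------------
# Table output
# ---------------------------------------------------------------------------

_EFFECT_COLUMNS = ["locus_i", "family_i", "locus_j", "family_j", "beta", "sd",
                   "t", "p_value", "h2", "sigma2_j", "significant"]


def _fam_letters(desc: EffectDescriptor) -> tuple[str, str]:
    if desc.is_main:
        return desc.family, desc.family
    return desc.family[0], desc.family[1]


def write_effect_table(reports: Sequence[EffectReport], path,
                       meta: Optional[dict] = None,
                       fit: Optional[EBlassoFit] = None) -> None:
    """Write the per-effect TSV plus one ``#meta`` metadata line.

    Column order is fixed: locus_i, family_i, locus_j, family_j, beta,
    sd, t, p_value, h2, sigma2_j, significant.
    """
    meta = dict(meta or {})
    sigma2 = {}
    if fit is not None:
        sigma2 = {desc: v for desc, v in fit.active}
        meta.setdefault("a", fit.prior.a)
        meta.setdefault("b", fit.prior.b)
        meta.setdefault("mu", fit.mu)
        meta.setdefault("sigma2_e", fit.sigma2_e)
        meta.setdefault("lambda", fit.lam)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#meta " + json.dumps(meta, sort_keys=True) + "\n")
        fh.write("\t".join(_EFFECT_COLUMNS) + "\n")
        for r in reports:
            fi, fj = _fam_letters(r.desc)
            row = [str(r.desc.i), fi, str(r.desc.j), fj, repr(r.beta_hat),
                   repr(r.sd), repr(r.t), repr(r.p_value), repr(r.h2),
                   repr(float(sigma2.get(r.desc, float("nan")))),
                   "1" if r.significant else "0"]
            fh.write("\t".join(row) + "\n")


def read_effect_table(path) -> tuple[list[EffectReport], dict]:
    """Inverse of :func:`write_effect_table` (sigma2_j is not restored)."""
    meta: dict = {}
    reports: list[EffectReport] = []
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#meta "):
                meta = json.loads(line[len("#meta "):])
                continue
            if line.startswith("#") or not line:
                continue
            if not header_seen:
                if line.split("\t") != _EFFECT_COLUMNS:
                    raise ValueError("unexpected effect-table header")
                header_seen = True
                continue
            (li, fi, lj, fj, beta, sd, t, p, h2, _s2, sig) = line.split("\t")
            i, j = int(li), int(lj)
            family = fi if i == j else fi + fj
            reports.append(EffectReport(EffectDescriptor(family, i, j),
                                        float(beta), float(sd), float(t),
                                        float(p), float(h2), sig == "1"))
    return reports, meta


def write_groups_table(groups: Sequence[Sequence[str]], bin_map: BinMap,
                       path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group_id\tchromosome\tmember_bins\tspan_cM\n")
        for g_id, members in enumerate(groups, start=1):
            chrom = bin_map.entry(members[0]).chromosome
            pos = [bin_map.entry(b).pos_cM for b in members]
            fh.write(f"{g_id}\t{chrom}\t{','.join(members)}\t"
                     f"{max(pos) - min(pos)!r}\n")


def write_gene_assoc_table(assoc: Sequence[GeneAssociation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("bin_id\tgene_name\tdistance_cM\thighlighted\n")
        for a in assoc:
            fh.write(f"{a.bin_id}\t{a.gene_name}\t{a.distance_cM!r}\t"
                     f"{'1' if a.highlighted else '0'}\n")


def write_edges_table(reports: Sequence[EffectReport], bin_map: BinMap,
                      path, significant_only: bool = True) -> None:
    """Plain edge list (self loops for main effects) for network drawing."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source_bin\ttarget_bin\tfamily\tabs_beta\n")
        for r in reports:
            if significant_only and not r.significant:
                continue
            src = bin_map.bin_ids[r.desc.i - 1]
            dst = bin_map.bin_ids[r.desc.j - 1]
            fh.write(f"{src}\t{dst}\t{r.desc.family}\t{abs(r.beta_hat)!r}\n")
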