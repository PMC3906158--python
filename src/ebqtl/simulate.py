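"""Synthetic RIL / immortalized-F2 genotypes and planted-effect phenotypes.

RIL genotypes are simulated at the fully-inbred limit as two-state
Markov chains along each chromosome with switch probability
``R = 2r/(1+2r)`` (map expansion under repeated selfing), where ``r`` is
the Haldane recombination fraction of the adjacent-bin interval.
Crosses between distinct RIL pairs yield the three-genotype population;
phenotypes follow the generative linear model with planted sparse
main/epistatic effects plus Gaussian noise.  Recovery of the planted
truth by the fitted model is scored as power and false discovery rate
at a map-distance tolerance.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .design import EffectDescriptor, effect_column
from .maps import (CODE_A, CODE_B, CODE_H, BinEntry, BinMap, GenotypeMatrix,
                   PhenotypeVector, cm_distance)
from .report import EffectReport

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    n_chrom: int = 12
    bins_per_chrom: int = 135
    cm_per_bin: float = 1.0
    n_ril: int = 240
    n_cross: int = 278
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chrom, self.bins_per_chrom, self.n_ril,
               self.n_cross) < 1 or self.cm_per_bin < 0:
            raise ValueError("invalid simulation configuration")

    @property
    def m(self) -> int:
        return self.n_chrom * self.bins_per_chrom


@dataclass
class SimTruth:
    """Planted generative truth for recovery scoring."""

    effects: list[tuple[EffectDescriptor, float]]
    mu: float
    sigma2_e: float

    def to_json(self) -> str:
        return json.dumps({
            "mu": self.mu,
            "sigma2_e": self.sigma2_e,
            "effects": [{"family": d.family, "i": d.i, "j": d.j, "beta": b}
                        for d, b in self.effects],
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        obj = json.loads(text)
        effects = [(EffectDescriptor(e["family"], e["i"], e["j"]), e["beta"])
                   for e in obj["effects"]]
        return cls(effects, obj["mu"], obj["sigma2_e"])


def haldane_r(d_cM: float) -> float:
    """Haldane map function: r = (1 - exp(-2 d/100)) / 2."""
    if d_cM < 0:
        raise ValueError("map distance must be >= 0")
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))


def ril_switch_prob(r: float) -> float:
    """Selfing map expansion for fully inbred lines: R = 2r/(1+2r)."""
    if not 0.0 <= r <= 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5]")
    return 2.0 * r / (1.0 + 2.0 * r)


def make_map(cfg: SimConfig) -> BinMap:
    """Evenly spaced bin map: Bin1..Binm across cfg.n_chrom chromosomes."""
    entries = []
    b = 1
    width = len(str(cfg.n_chrom))  # zero-pad so text sort = numeric sort
    for c in range(1, cfg.n_chrom + 1):
        for t in range(cfg.bins_per_chrom):
            entries.append(BinEntry(f"Bin{b}", f"{c:0{width}d}",
                                    t * cfg.cm_per_bin))
            b += 1
    return BinMap(entries)


def simulate_rils(cfg: SimConfig, bin_map: Optional[BinMap] = None,
                  rng: Optional[np.random.Generator] = None) -> GenotypeMatrix:
    """Fully homozygous RIL genotypes over {A, B} along the map."""
    if bin_map is None:
        bin_map = make_map(cfg)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chroms = [e.chromosome for e in bin_map.entries]
    pos = np.array([e.pos_cM for e in bin_map.entries])
    m = bin_map.m
    n = cfg.n_ril
    # per-interval switch probabilities; chromosome starts get R = 1/2
    R = np.empty(m)
    R[0] = 0.5
    for t in range(1, m):
        if chroms[t] != chroms[t - 1]:
            R[t] = 0.5
        else:
            R[t] = ril_switch_prob(haldane_r(pos[t] - pos[t - 1]))
    switches = rng.random((n, m)) < R[None, :]
    # cumulative XOR of switches gives the parental state (0 = A, 1 = B)
    state = np.logical_xor.accumulate(switches, axis=1)
    codes = np.where(state, CODE_B, CODE_A).astype(np.int8)
    ids = [f"RIL{t+1}" for t in range(n)]
    return GenotypeMatrix(codes, ids, bin_map.bin_ids)


def derive_imf2(rils: GenotypeMatrix, n_cross: int,
                seed: Optional[int] = None,
                rng: Optional[np.random.Generator] = None) -> GenotypeMatrix:
    """Cross genotypes from distinct unordered RIL pairs.

    Pairs are sampled without replacement; matching parental homozygotes
    pass through, mismatches become H.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if np.any(rils.codes == CODE_H):
        raise ValueError("RIL parents must be fully homozygous")
    n_ril = rils.n
    n_pairs = n_ril * (n_ril - 1) // 2
    if n_cross > n_pairs:
        raise ValueError(f"requested {n_cross} crosses but only {n_pairs} "
                         "distinct RIL pairs exist")
    chosen = rng.choice(n_pairs, size=n_cross, replace=False)
    # decode unordered pair index
    i = (np.ceil((np.sqrt(8 * (chosen + 1) + 1) - 1) / 2)).astype(np.int64)
    j = chosen - i * (i - 1) // 2
    # exact correction of float slop in the triangular decode
    bad = (j < 0) | (j >= i)
    while np.any(bad):
        i = np.where(j < 0, i - 1, np.where(j >= i, i + 1, i))
        j = chosen - i * (i - 1) // 2
        bad = (j < 0) | (j >= i)
    a, b = rils.codes[j], rils.codes[i]
    codes = np.where(a == b, a, CODE_H).astype(np.int8)
    ids = [f"IMF2_{t+1}" for t in range(n_cross)]
    return GenotypeMatrix(codes, ids, list(rils.bin_ids))


def simulate_phenotype(G: GenotypeMatrix, truth: SimTruth,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None,
                       trait_name: str = "trait") -> PhenotypeVector:
    """y = mu + sum_j beta_j x_j + N(0, sigma2_e) noise."""
    if rng is None:
        rng = np.random.default_rng(seed)
    y = np.full(G.n, truth.mu, dtype=float)
    for desc, beta in truth.effects:
        y += beta * effect_column(desc, G)
    if truth.sigma2_e > 0:
        y += rng.normal(0.0, math.sqrt(truth.sigma2_e), size=G.n)
    return PhenotypeVector(trait_name, y, list(G.individual_ids))


def genetic_values(G: GenotypeMatrix, truth: SimTruth) -> np.ndarray:
    g = np.zeros(G.n)
    for desc, beta in truth.effects:
        g += beta * effect_column(desc, G)
    return g


def default_truth(bin_map: BinMap, G: GenotypeMatrix,
                  rng: np.random.Generator,
                  n_main: int = 2, n_epistatic: int = 4,
                  h2: float = 0.6, min_sep_cM: float = 10.0) -> SimTruth:
    """Plant sparse main + digenic effects totalling heritability ~h2.

    Effect bins are kept at least ``min_sep_cM`` apart (or on different
    chromosomes) so recovery scoring is unambiguous.  Main effects are
    additive; the digenic effects cycle through the AA, AD, DA and DD
    families.  Magnitudes are chosen so each planted |beta| clears half
    the phenotypic standard deviation.
    """
    m = bin_map.m
    used: list[int] = []
    sep = [min_sep_cM]  # relaxed when the map is too small to honor it

    def pick_bin() -> int:
        while True:
            for _ in range(2_000):
                c = int(rng.integers(1, m + 1))
                ok = all(
                    cm_distance(bin_map, bin_map.bin_ids[c - 1],
                                bin_map.bin_ids[u - 1]) > sep[0]
                    for u in used)
                if ok:
                    used.append(c)
                    return c
            if sep[0] < 0.5:
                raise RuntimeError("could not place planted effects; "
                                   "map too small")
            sep[0] /= 2.0
            logger.warning("relaxing planted-effect separation to %.2g cM",
                           sep[0])

    effects: list[tuple[EffectDescriptor, float]] = []
    for _ in range(n_main):
        b = pick_bin()
        beta = 1.1 * (1 if rng.random() < 0.5 else -1)
        effects.append((EffectDescriptor("A", b, b), beta))
    fams = ["AA", "AD", "DA", "DD"]
    for t in range(n_epistatic):
        b1, b2 = pick_bin(), pick_bin()
        i, j = min(b1, b2), max(b1, b2)
        beta = 1.3 * (1 if rng.random() < 0.5 else -1)
        effects.append((EffectDescriptor(fams[t % 4], i, j), beta))

    truth = SimTruth(effects=effects, mu=0.0, sigma2_e=1.0)
    # enforce |beta| >= 0.5 sd(y) at heritability h2: bump sub-threshold
    # effects toward the bound (converges because the variance-weighted
    # equal-size configuration sits above it)
    for _ in range(100):
        var_g = float(np.var(genetic_values(G, truth), ddof=1))
        sd_y = math.sqrt(var_g / h2) if var_g > 0 else 1.0
        floor = 0.51 * sd_y
        bumped = False
        for t, (d, beta) in enumerate(truth.effects):
            if abs(beta) < floor:
                truth.effects[t] = (d, math.copysign(floor, beta))
                bumped = True
        if not bumped:
            break
    var_g = float(np.var(genetic_values(G, truth), ddof=1))
    truth.sigma2_e = var_g * (1.0 - h2) / h2 if var_g > 0 else 1.0
    return truth


def recovery_trial(seed: int, n_chrom: int = 10, bins_per_chrom: int = 20,
                   n_ril: int = 240, n_cross: int = 278,
                   n_main: int = 2, n_epistatic: int = 4, h2: float = 0.6,
                   a: float = 0.5, b: float = 0.5,
                   tol_cM: float = 5.0, alpha: float = 0.01,
                   max_sweeps: int = 50) -> "RecoveryScore":
    """Simulate, fit the full epistatic model, and score the recovery.

    One end-to-end regression trial: IMF2 genotypes along the map,
    planted sparse effects, shrinkage fit at fixed (a, b), t-test at
    ``alpha`` and power/FDR at ``tol_cM``.
    """
    from .design import build_design_spec
    from .eblasso import FitControls, PriorSpec, fit
    from .report import significance_test

    rng = np.random.default_rng(seed)
    cfg = SimConfig(n_chrom=n_chrom, bins_per_chrom=bins_per_chrom,
                    n_ril=n_ril, n_cross=n_cross, seed=seed)
    bin_map = make_map(cfg)
    rils = simulate_rils(cfg, bin_map, rng)
    imf2 = derive_imf2(rils, n_cross, rng=rng)
    truth = default_truth(bin_map, imf2, rng, n_main=n_main,
                          n_epistatic=n_epistatic, h2=h2)
    y = simulate_phenotype(imf2, truth, rng=rng)
    spec = build_design_spec(imf2, include_interactions=True)
    result = fit(imf2, y, spec, PriorSpec(a, b),
                 FitControls(track_objective=False, max_sweeps=max_sweeps))
    reports = significance_test(result, n=y.n, alpha=alpha)
    return score_recovery(reports, truth, bin_map, tol_cM)


@dataclass
class RecoveryScore:
    power: float
    fdr: float
    n_truth: int
    n_significant: int
    n_hits: int
    no_reports: bool = False
    hits: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "power": self.power, "fdr": self.fdr, "n_truth": self.n_truth,
            "n_significant": self.n_significant, "n_hits": self.n_hits,
            "no_reports": self.no_reports, "hits": self.hits,
        }, indent=2, sort_keys=True)


def _bins_match(rep: EffectDescriptor, true: EffectDescriptor,
                bin_map: BinMap, tol_cM: float) -> bool:
    """Every involved bin within tol of the corresponding true bin.

    Main effects compare their single bin; interactions take the better
    of the two bin-to-bin assignments (bipartite matching on two nodes).
    """
    ids = bin_map.bin_ids

    def d(x: int, y: int) -> float:
        return cm_distance(bin_map, ids[x - 1], ids[y - 1])

    if rep.is_main != true.is_main:
        return False
    if rep.is_main:
        return d(rep.i, true.i) <= tol_cM
    straight = max(d(rep.i, true.i), d(rep.j, true.j))
    crossed = max(d(rep.i, true.j), d(rep.j, true.i))
    return min(straight, crossed) <= tol_cM


def score_recovery(reports: Sequence[EffectReport], truth: SimTruth,
                   bin_map: BinMap, tol_cM: float = 5.0) -> RecoveryScore:
    """Power and FDR of the significant reports against the planted truth.

    A true effect is a hit when some significant report of the same
    class (main vs interaction) has all bins within ``tol_cM``; a report
    is a false discovery when it matches no true effect.  Empty report
    lists give power 0 and FDR 0 with ``no_reports`` flagged.
    """
    sig = [r for r in reports if r.significant]
    if not sig:
        return RecoveryScore(power=0.0, fdr=0.0, n_truth=len(truth.effects),
                             n_significant=0, n_hits=0, no_reports=True)
    matched_reports = set()
    hits = []
    n_hits = 0
    for t_pos, (t_desc, t_beta) in enumerate(truth.effects):
        matches = [r_pos for r_pos, r in enumerate(sig)
                   if _bins_match(r.desc, t_desc, bin_map, tol_cM)]
        if matches:
            n_hits += 1
            matched_reports.update(matches)
            hits.append({"truth": t_desc.label(), "beta": t_beta,
                         "reported_by": [sig[r].desc.label() for r in matches]})
    n_false = len(sig) - len(matched_reports)
    return RecoveryScore(
        power=n_hits / len(truth.effects) if truth.effects else 0.0,
        fdr=n_false / len(sig),
        n_truth=len(truth.effects),
        n_significant=len(sig),
        n_hits=n_hits,
        hits=hits,
    )
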