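"""Three-step five-fold cross-validation over the (a, b) hyperprior grid.

Step 1 screens a = b over {0.001, 0.01, 0.1, 1}.  Step 2 fixes b at the
step-1 winner and walks a through a fixed 15-value set.  Step 3 fixes a
at the step-2 winner and walks b from 0.01 to 10 (decade steps below 1,
unit steps above).  In steps 2 and 3 the walk stops early once the
current prediction error exceeds the running minimum by one standard
error of that minimum (the one-SE early stop).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .design import DesignSpec, find_excluded_columns
from .eblasso import FitControls, PriorSpec, fit, predict
from .maps import GenotypeMatrix, PhenotypeVector

logger = logging.getLogger(__name__)

N_FOLDS = 5

STEP1_GRID: list[tuple[float, float]] = [(v, v) for v in (0.001, 0.01, 0.1, 1.0)]
STEP2_A_VALUES: list[float] = [-0.9, -0.8, -0.7, -0.6, -0.5, -0.4, -0.3, -0.2,
                               -0.1, -0.01, 0.01, 0.05, 0.1, 0.5, 1.0]


def step3_b_grid() -> list[float]:
    """b from 0.01 to 10: decade steps below 1, unit steps above."""
    return [0.01, 0.1] + [float(v) for v in range(1, 11)]


def prediction_error(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Sum of squared prediction residuals."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between observed and predicted")
    d = y_true - y_pred
    return float(d @ d)


def kfold_split(n: int, k: int = N_FOLDS, seed: Optional[int] = None) -> np.ndarray:
    """Seed-reproducible fold assignment: array of fold ids in [0, k)."""
    if n < k:
        raise ValueError(f"need n >= {k} observations, got {n}")
    rng = np.random.default_rng(seed)
    ids = np.arange(n) % k
    return ids[rng.permutation(n)]


@dataclass
class CVEntry:
    a: float
    b: float
    per_fold_pe: list[float]

    @property
    def pe_mean(self) -> float:
        return float(np.mean(self.per_fold_pe))

    @property
    def pe_se(self) -> float:
        return float(np.std(self.per_fold_pe, ddof=1)
                     / np.sqrt(len(self.per_fold_pe)))


@dataclass
class CVResult:
    table: list[CVEntry]
    best: tuple[float, float]
    step_log: list[str] = field(default_factory=list)


def _better(cand: CVEntry, incumbent: Optional[CVEntry]) -> bool:
    # ties broken toward stronger shrinkage: larger b, then larger a
    if incumbent is None:
        return True
    if cand.pe_mean != incumbent.pe_mean:
        return cand.pe_mean < incumbent.pe_mean
    return (cand.b, cand.a) > (incumbent.b, incumbent.a)


def cv_path(G: GenotypeMatrix, y: PhenotypeVector, spec: DesignSpec,
            controls: Optional[FitControls] = None,
            seed: Optional[int] = None,
            early_stop: bool = True) -> CVResult:
    """Run the three CV steps and return the full table and best (a, b)."""
    if controls is None:
        controls = FitControls()
    folds = kfold_split(y.n, N_FOLDS, seed)
    # per-fold training design specs (exclusions depend on the rows kept)
    fold_data = []
    for f in range(N_FOLDS):
        tr = np.flatnonzero(folds != f)
        te = np.flatnonzero(folds == f)
        G_tr = G.subset_rows(tr)
        sub_spec = DesignSpec(spec.m, spec.include_interactions,
                              find_excluded_columns(G_tr,
                                                    spec.include_interactions))
        fold_data.append((G_tr, y.subset(tr), sub_spec, G.subset_rows(te),
                          y.subset(te)))

    cache: dict[tuple[float, float], CVEntry] = {}

    def evaluate(a: float, b: float) -> CVEntry:
        key = (a, b)
        if key in cache:
            return cache[key]
        prior = PriorSpec(a, b)
        pes = []
        for G_tr, y_tr, sub_spec, G_te, y_te in fold_data:
            f = fit(G_tr, y_tr, sub_spec, prior, controls)
            pes.append(prediction_error(y_te.values, predict(f, G_te)))
        entry = CVEntry(a, b, pes)
        cache[key] = entry
        logger.info("CV (a=%g, b=%g): PE_mean=%.6g PE_se=%.3g", a, b,
                    entry.pe_mean, entry.pe_se)
        return entry

    table: list[CVEntry] = []
    step_log: list[str] = []
    best: Optional[CVEntry] = None

    def walk(grid: list[tuple[float, float]], step_name: str,
             stoppable: bool) -> None:
        nonlocal best
        for a, b in grid:
            entry = evaluate(a, b)
            table.append(entry)
            if _better(entry, best):
                best = entry
            if (stoppable and early_stop
                    and entry.pe_mean > best.pe_mean + best.pe_se):
                step_log.append(f"{step_name}: early stop at (a={a}, b={b})")
                break
        step_log.append(f"{step_name}: best so far (a={best.a}, b={best.b}) "
                        f"PE_mean={best.pe_mean:.6g}")

    walk(STEP1_GRID, "step1", stoppable=False)
    b1 = best.b
    walk([(a, b1) for a in STEP2_A_VALUES], "step2", stoppable=True)
    a2 = best.a
    walk([(a2, b) for b in step3_b_grid()], "step3", stoppable=True)

    return CVResult(table=table, best=(best.a, best.b), step_log=step_log)


def write_cv_table(result: CVResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("a\tb\tPE_mean\tPE_se\t" +
                 "\t".join(f"PE_fold{f+1}" for f in range(N_FOLDS)) + "\n")
        for e in result.table:
            fh.write(f"{e.a!r}\t{e.b!r}\t{e.pe_mean!r}\t{e.pe_se!r}\t" +
                     "\t".join(repr(p) for p in e.per_fold_pe) + "\n")
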