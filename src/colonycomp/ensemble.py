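"""Monte Carlo ensembles over random founder configurations.

Drives repeated realisations (fresh configuration -> AFS score -> PDE
solve -> competitive outcome), fits summary statistics, regresses outcome
on AFS, traces the variability-vs-founder-density relation, checks
robustness to cell-picking noise in the inoculum, and sweeps the
antagonistic parameters.  Every record carries the seed that reproduces
it in isolation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .afs import afs as afs_score
from .founders import FounderConfiguration, FounderError, place_founders, sample_inoculum
from .mesh import TriangularMesh
from .pde import (
    ModelParams,
    SolverError,
    SolverSettings,
    competitive_outcome,
    initial_state_from_config,
    solve,
)

log = logging.getLogger(__name__)


class EnsembleError(ValueError):
    pass


@dataclass
class EnsembleResult:
    """Per-realisation records plus bookkeeping.

    ``records`` columns: N, seed, afs1, outcome, sep_stat, status
    (``ok`` / ``failed`` / ``skipped``); failed realisations are kept in
    the table but excluded from statistics.
    """

    records: pd.DataFrame
    mode: str
    base_seed: int

    @property
    def ok(self) -> pd.DataFrame:
        return self.records[self.records.status == "ok"]

    @property
    def n_failed(self) -> int:
        return int((self.records.status != "ok").sum())


@dataclass
class SummaryStats:
    mu: float
    sigma: float
    slope: float
    intercept: float
    pearson_rho: float
    n: int


def fit_normal(samples) -> tuple[float, float]:
    """Moment fit of a normal: sample mean and unbiased sd."""
    x = np.asarray(samples, float)
    if len(x) < 2:
        raise EnsembleError("need at least two samples to fit a normal")
    return float(x.mean()), float(x.std(ddof=1))


def inter_type_separation(config: FounderConfiguration) -> float:
    """Mean over microcolonies of the distance to the nearest microcolony
    of the other strain (initial inter-type separation statistic)."""
    pos, s = config.positions, config.strains
    if not ((s == 1).any() and (s == 2).any()):
        raise EnsembleError("both strains must be present")
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    other = s[:, None] != s[None, :]
    d = np.where(other, d, np.inf)
    return float(d.min(axis=1).mean())


def _realise(
    mesh: TriangularMesh,
    N: int,
    seed: int,
    params: ModelParams,
    settings: SolverSettings | None,
    ratio_rule: str = "fixed_half",
    sample=None,
) -> dict:
    """One realisation; PDE is skipped when settings is None (AFS only)."""
    config = place_founders(mesh, N, ratio_rule=ratio_rule, sample=sample, seed=seed)
    rec = {"N": N, "seed": seed, "afs1": afs_score(config),
           "outcome": np.nan, "sep_stat": np.nan, "status": "ok"}
    both = (config.strains == 1).any() and (config.strains == 2).any()
    if both:
        rec["sep_stat"] = inter_type_separation(config)
    if settings is not None:
        state = initial_state_from_config(config, mesh, k=params.k)
        rec["outcome"] = competitive_outcome(solve(state, params, settings))
    return rec


def run_ensemble(
    mesh: TriangularMesh,
    N: int,
    n_reps: int,
    params: ModelParams | None = None,
    settings: SolverSettings | None = None,
    ratio_rule: str = "fixed_half",
    base_seed: int = 0,
) -> EnsembleResult:
    """``n_reps`` independent realisations at founder density ``N``.

    Realisation ``rep`` uses seed ``base_seed + rep``, so any record can
    be reproduced in isolation.  ``settings=None`` computes AFS only
    (cheap geometry-only ensembles).  Realisations failing solver checks
    are recorded as failed and excluded from statistics, never resampled.
    """
    if n_reps < 1:
        raise EnsembleError("n_reps must be >= 1")
    params = params or ModelParams.isogenic()
    rows = []
    for rep in range(n_reps):
        seed = base_seed + rep
        try:
            rows.append(_realise(mesh, N, seed, params, settings, ratio_rule))
        except SolverError as exc:
            log.warning("realisation N=%d seed=%d failed: %s", N, seed, exc)
            rows.append({"N": N, "seed": seed, "afs1": np.nan, "outcome": np.nan,
                         "sep_stat": np.nan, "status": "failed"})
        if rep % 20 == 19:
            log.info("ensemble N=%d: %d/%d realisations done", N, rep + 1, n_reps)
    return EnsembleResult(pd.DataFrame(rows), params.mode, base_seed)


def afs_outcome_regression(result: EnsembleResult) -> SummaryStats:
    """Least-squares regression of competitive outcome on AFS_1.

    The slope quantifies deterministically how founder geometry unfolds
    into outcome variability; rho is the Pearson correlation.
    """
    ok = result.ok.dropna(subset=["afs1", "outcome"])
    if len(ok) < 10:
        raise EnsembleError("need >= 10 complete records for the regression")
    if np.isclose(ok.afs1.std(ddof=1), 0.0):
        raise EnsembleError("degenerate AFS variance")
    fit = stats.linregress(ok.afs1, ok.outcome)
    mu, sigma = fit_normal(ok.outcome)
    return SummaryStats(mu, sigma, float(fit.slope), float(fit.intercept),
                        float(fit.rvalue), len(ok))


def std_std_curve(
    mesh: TriangularMesh,
    Ns: list[int],
    n_reps: int,
    params: ModelParams | None = None,
    settings: SolverSettings | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Per-density standard deviations of AFS_1 and of the outcome.

    With ``settings=None`` only the (cheap) AFS column is filled.  Both
    sds are expected to decrease with founder density; their relation
    across densities links geometric to dynamic variability.
    """
    if n_reps < 2:
        raise EnsembleError("sd undefined for n_reps < 2")
    rows = []
    for i, N in enumerate(Ns):
        res = run_ensemble(mesh, N, n_reps, params, settings,
                           base_seed=base_seed + 100_000 * i)
        ok = res.ok
        sd_afs = float(ok.afs1.std(ddof=1))
        sd_out = float(ok.outcome.std(ddof=1)) if settings is not None else np.nan
        rows.append({"N": N, "sd_afs1": sd_afs, "sd_outcome": sd_out, "n_ok": len(ok)})
    return pd.DataFrame(rows)


def ratio_robustness_ensemble(
    mesh: TriangularMesh,
    intended_total: float,
    culture_ratio: float,
    n_reps: int,
    params: ModelParams | None = None,
    settings: SolverSettings | None = None,
    base_seed: int = 0,
) -> EnsembleResult:
    """Ensemble with per-realisation strain counts from the cell-picking
    model instead of a fixed half/half split.

    Zero-count draws (or draws exceeding the inoculum capacity) are
    skipped and counted, never resampled.
    """
    if n_reps < 1:
        raise EnsembleError("n_reps must be >= 1")
    params = params or ModelParams.isogenic()
    n_avail = len(mesh.inoculum_node_ids)
    rows = []
    for rep in range(n_reps):
        seed = base_seed + rep
        sample = sample_inoculum(culture_ratio, intended_total, seed=seed)
        if sample.total == 0 or sample.total > n_avail:
            rows.append({"N": sample.total, "seed": seed, "afs1": np.nan,
                         "outcome": np.nan, "sep_stat": np.nan, "status": "skipped"})
            continue
        try:
            rec = _realise(mesh, sample.total, seed, params, settings,
                           ratio_rule="from_sample", sample=sample)
            rec["n1"] = sample.n1
            rows.append(rec)
        except (SolverError, FounderError) as exc:
            log.warning("picking realisation seed=%d failed: %s", seed, exc)
            rows.append({"N": sample.total, "seed": seed, "afs1": np.nan,
                         "outcome": np.nan, "sep_stat": np.nan, "status": "failed"})
    return EnsembleResult(pd.DataFrame(rows), params.mode, base_seed)


def parameter_sweep(
    mesh: TriangularMesh,
    r_values,
    d_values,
    c_values,
    N: int,
    n_reps: int,
    settings: SolverSettings | None = None,
    k: float = 1.0,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Grid sweep of the antagonistic parameters.

    For each (r, d, c): the well-mixed classification, and (when
    ``n_reps`` > 0 and ``settings`` given) the low-founder-density PDE
    ensemble mean outcome with a coexistence flag (mean weaker-strain
    outcome within (0.05, 0.95)).
    """
    from .wellmixed import winner_analysis

    rows = []
    for gi, (r, d, c) in enumerate(itertools.product(r_values, d_values, c_values)):
        params = (ModelParams.isogenic() if c == 0 and r == 1 and d == 1 and k == 1
                  else ModelParams.antagonism(r=r, d=d, c=c, k=k))
        cls = winner_analysis(params).classification
        row = {"r": r, "d": d, "c": c, "wellmixed_class": cls,
               "mean_outcome": np.nan, "coexistence": np.nan}
        if n_reps > 0 and settings is not None:
            res = run_ensemble(mesh, N, n_reps, params, settings,
                               base_seed=base_seed + 10_000 * gi)
            mean_out = float(res.ok.outcome.mean())
            weaker_mean = 1.0 - mean_out if cls == "strain1_wins" else mean_out
            row["mean_outcome"] = mean_out
            row["coexistence"] = bool(0.05 < weaker_mean < 0.95)
        rows.append(row)
    return pd.DataFrame(rows)
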