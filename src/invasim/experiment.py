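"""Factorial persistence grids and diversity-invasibility scans.

Every run is reproducible from ``(seed, config)``: the seed feeds a
``SeedSequence`` whose children drive guild-size sampling, community
generation and invader assembly separately, so two runs sharing a seed and
community config face the *same* native community even when the invader
settings differ.  Grid and scan cells derive disjoint child seeds from the
base seed, keyed by the cell coordinates — adding replicates, rules or grid
values never perturbs the draws of existing cells.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community_gen import GuildSizes, generate_stable_community, sample_guild_sizes
from .config import RULES, SimulationConfig
from .dynamics import ExtinctionReport, apply_extinctions, integrate
from .invasion_setup import assemble_invaded_system

logger = logging.getLogger(__name__)

__all__ = ["GridSpec", "RunRecord", "GridResult", "compute_persistence",
           "run_single", "run_grid", "run_diversity_scan"]

_DEFAULT_F_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


@dataclass
class GridSpec:
    """Factorial design over (F1, F2, rule, adaptive) with replication."""

    F1_values: tuple = _DEFAULT_F_GRID
    F2_values: tuple = _DEFAULT_F_GRID
    rules: tuple = RULES
    adaptive_flags: tuple = (False, True)
    replicates: int = 4
    base_seed: int = 0

    def validate(self) -> None:
        for F in list(self.F1_values) + list(self.F2_values):
            if not 0.0 <= F <= 1.0:
                raise ValueError(f"grid values must lie in [0, 1], got {F}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for rule in self.rules:
            if rule not in RULES:
                raise ValueError(f"unknown rule {rule!r}")


@dataclass
class RunRecord:
    """One simulated invasion: design point, community summary and outcome."""

    seed: int
    F1: float
    F2: float
    rule: str
    adaptive: bool
    S_P: int = 0
    S_M: int = 0
    S_H: int = 0
    diversity: int = 0
    persistence: float = np.nan
    persistence_plants: float = np.nan
    persistence_mutualists: float = np.nan
    persistence_herbivores: float = np.nan
    invasion_success: bool = False
    invader_density: float = np.nan
    n_mut_links: int = 0
    realized_mut_links: int = 0
    T_mut: float = np.nan
    failed: bool = False
    fail_reason: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GridResult:
    """Per-run table plus the cell-level mean-persistence table."""

    runs: pd.DataFrame
    cells: pd.DataFrame
    n_failed: int = 0


def compute_persistence(report: ExtinctionReport, sizes: GuildSizes):
    """Fraction of native species surviving, overall and per guild.

    The invader is excluded from both numerator and denominator.
    """
    n_p = int(report.plants.sum())
    n_m = int(report.mutualists.sum())
    n_h = int(report.herbivores.sum())
    overall = (n_p + n_m + n_h) / sizes.total
    per_guild = {"plants": n_p / sizes.S_P,
                 "mutualists": n_m / sizes.S_M,
                 "herbivores": n_h / sizes.S_H}
    return overall, per_guild


def _child_rngs(seed: int, n: int):
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def run_single(F1: float, F2: float, rule: str, adaptive: bool, seed: int,
               cfg: SimulationConfig) -> RunRecord:
    """Full protocol for one run: sample sizes, generate a stable native
    community, assemble the invaded system, integrate, apply thresholds.

    Failures (stability-screen exhaustion, solver blow-up) yield a record
    flagged ``failed`` rather than an exception, so factorial sweeps can
    report and exclude them.
    """
    cfg.validate()
    inv = replace(cfg.invader, F1=F1, F2=F2, rule=rule, adaptive=adaptive)
    rec = RunRecord(seed=seed, F1=F1, F2=F2, rule=rule, adaptive=adaptive)
    size_rng, comm_rng, inv_rng = _child_rngs(seed, 3)
    try:
        sizes = sample_guild_sizes(cfg.community, size_rng)
        rec.S_P, rec.S_M, rec.S_H = sizes.S_P, sizes.S_M, sizes.S_H
        rec.diversity = sizes.total
        comm = generate_stable_community(sizes, cfg.community, comm_rng,
                                         cfg.integration, seed=seed)
        system = assemble_invaded_system(comm, inv, inv_rng)
        result = integrate(system, cfg.integration)
    except (RuntimeError, ValueError) as exc:
        logger.warning("run (seed=%d, F1=%.2f, F2=%.2f, %s) failed: %s",
                       seed, F1, F2, rule, exc)
        rec.failed = True
        rec.fail_reason = str(exc)
        return rec

    thr = cfg.integration.extinction_threshold
    report = apply_extinctions(result.final, thr)
    rec.persistence, per_guild = compute_persistence(report, sizes)
    rec.persistence_plants = per_guild["plants"]
    rec.persistence_mutualists = per_guild["mutualists"]
    rec.persistence_herbivores = per_guild["herbivores"]
    rec.invasion_success = report.invader_alive
    rec.invader_density = result.final.P_k
    rec.n_mut_links = system.n_mut_links
    rec.T_mut = system.T_mut
    if result.final.alpha is not None:
        rec.realized_mut_links = int(np.sum(result.final.alpha > thr))
    else:
        rec.realized_mut_links = system.n_mut_links
    return rec


def _cell_seed(base_seed: int, *coords: int) -> int:
    ss = np.random.SeedSequence((int(base_seed),) + tuple(int(c) for c in coords))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_grid(spec: GridSpec, cfg: SimulationConfig) -> GridResult:
    """One run per (F1, F2, rule, adaptive, replicate); cell means over the
    successful replicates, with failure counts reported per cell."""
    spec.validate()
    records = []
    for rule in spec.rules:
        i_rule = RULES.index(rule)
        for adaptive in spec.adaptive_flags:
            for F1 in spec.F1_values:
                for F2 in spec.F2_values:
                    for rep in range(spec.replicates):
                        seed = _cell_seed(spec.base_seed, round(F1 * 10_000),
                                          round(F2 * 10_000), i_rule,
                                          int(adaptive), rep)
                        records.append(
                            run_single(F1, F2, rule, adaptive, seed, cfg).to_dict())
    runs = pd.DataFrame.from_records(records)
    ok = runs[~runs["failed"]]
    cells = (ok.groupby(["rule", "adaptive", "F1", "F2"], as_index=False)
               .agg(mean_persistence=("persistence", "mean"),
                    invasion_rate=("invasion_success", "mean"),
                    n=("persistence", "size")))
    return GridResult(runs=runs, cells=cells, n_failed=int(runs["failed"].sum()))


def run_diversity_scan(fixed_param: str, fixed_value: float, varied_values,
                       rule: str, adaptive: bool, n_communities: int,
                       cfg: SimulationConfig, base_seed: int = 0) -> pd.DataFrame:
    """Invasion outcomes across communities of varying richness.

    ``fixed_param`` is ``"F1"`` or ``"F2"``; each value in ``varied_values``
    sets the other normalized degree.  For every varied value,
    ``n_communities`` independent communities are generated with sizes
    sampled from the configured guild ranges; the resulting (diversity,
    invasion_success) pairs feed the diversity-invasibility fit.
    """
    if fixed_param not in ("F1", "F2"):
        raise ValueError("fixed_param must be 'F1' or 'F2'")
    if n_communities < 1:
        raise ValueError("n_communities must be >= 1")
    records = []
    for v in varied_values:
        F1, F2 = ((fixed_value, v) if fixed_param == "F1" else (v, fixed_value))
        for j in range(n_communities):
            seed = _cell_seed(base_seed, 777, round(float(v) * 10_000),
                              RULES.index(rule), int(adaptive), j)
            rec = run_single(F1, F2, rule, adaptive, seed, cfg)
            d = rec.to_dict()
            d["varied_param"] = "F2" if fixed_param == "F1" else "F1"
            d["varied_value"] = v
            records.append(d)
    return pd.DataFrame.from_records(records)
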