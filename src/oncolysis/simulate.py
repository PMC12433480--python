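"""Synthetic screen data with known ground truth.

Emulates the shape of the study's raw inputs so every downstream stage is
testable without the deposited data: logistic confluence growth with
MOI-dependent Hill-type killing after an onset delay, cumulative dead-cell
density, secreted-cytokine kinetics proportional to killed biomass, and
negative-binomial expression counts with planted receptor-gene effects.

The default design mirrors the study conditions: confluence sampled every
2 h up to 170 h, the MOI grid {0.001, 0.01, 0.1, 1, 10} PFU/cell plus an
untreated condition, triplicate wells, and three biological repeats per
cell line.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .kinetics import WellSeries

__all__ = [
    "CellLineTruth",
    "SimulationDesign",
    "GAMMA_DEAD",
    "simulate_confluence",
    "simulate_cytotox",
    "simulate_flt3l",
    "simulate_counts",
    "simulate_panel",
    "default_panel",
    "default_design",
    "graded_panel",
]

#: dead cells per mm^2 produced per percent confluence killed.  The absolute
#: scale cancels in the confluence-normalized death index, so an arbitrary
#: unit conversion of 1 is fixed here.
GAMMA_DEAD = 1.0

#: planted susceptibility-linked genes, named after the study's candidates.
RECEPTOR_GENES = ("NECTIN1", "NECTIN2", "ITGB6", "RIGI", "ISG15", "OAS1")


@dataclass(frozen=True)
class CellLineTruth:
    """Ground-truth growth/kill parameters for one simulated cell line.

    g: intrinsic growth rate (1/h); K: carrying capacity (confluence %,
    <= 100); C0: initial confluence (%); kmax: maximal kill rate (1/h) —
    kmax = 0 makes the line a true null with no MOI effect; m50: MOI of
    half-maximal killing (PFU/cell); h: Hill coefficient; tau: killing onset
    delay (h); beta: secreted FLT3L per unit killed biomass (pg/mL per
    %.h); sigma: multiplicative lognormal noise SD on the log scale.
    """

    name: str
    g: float = 0.04
    K: float = 95.0
    C0: float = 8.0
    kmax: float = 0.05
    m50: float = 0.1
    h: float = 1.2
    tau: float = 24.0
    beta: float = 2.0
    sigma: float = 0.05

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("cell line needs a name")
        vals = (self.g, self.K, self.C0, self.kmax, self.m50, self.h, self.tau,
                self.beta, self.sigma)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"{self.name}: non-finite parameter")
        if not 0 < self.C0 < self.K <= 100:
            raise ValueError(f"{self.name}: need 0 < C0 < K <= 100")
        if self.g <= 0 or self.m50 <= 0 or self.h <= 0:
            raise ValueError(f"{self.name}: g, m50, h must be positive")
        if self.kmax < 0 or self.tau < 0 or self.beta < 0 or self.sigma < 0:
            raise ValueError(f"{self.name}: rates must be non-negative")

    def kill_rate(self, moi: float) -> float:
        """Hill-type kill rate k(m); exactly zero for the untreated condition."""
        if moi == 0:
            return 0.0
        mh = moi**self.h
        return self.kmax * mh / (mh + self.m50**self.h)


@dataclass(frozen=True)
class SimulationDesign:
    """Observation design: MOI grid, time grid, replication, seed."""

    moi_grid: Tuple[float, ...] = (0.0, 0.001, 0.01, 0.1, 1.0, 10.0)
    t_end: float = 170.0
    dt: float = 2.0
    n_wells: int = 3
    n_repeats: int = 3
    seed: int = 0
    refine: int = 4  # Euler substeps per sampling interval

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt >= self.t_end:
            raise ValueError("dt must be smaller than t_end")
        n = self.t_end / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("t_end must be a multiple of dt")
        if sum(1 for m in self.moi_grid if m == 0) != 1:
            raise ValueError("moi_grid must contain 0 (untreated) exactly once")
        if any(m < 0 for m in self.moi_grid):
            raise ValueError("MOIs must be non-negative")
        if self.n_wells < 1 or self.n_repeats < 1:
            raise ValueError("n_wells and n_repeats must be >= 1")
        if self.refine < 1:
            raise ValueError("refine must be >= 1")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.t_end + 0.5 * self.dt, self.dt)


def _trajectory(
    truth: CellLineTruth, moi: float, design: SimulationDesign
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free Euler trajectory: (times, confluence, killed biomass).

    C'(t) = g C (1 - C/K) - k(m) C 1[t > tau]; the killed-biomass integral
    int k(m) C(s) 1[s > tau] ds accumulates on the same refined grid and
    feeds both the dead-cell channel and the secretion model.
    """
    times = design.times
    k = truth.kill_rate(moi)
    h_step = design.dt / design.refine
    C = truth.C0
    killed = 0.0
    conf = np.empty_like(times)
    kil = np.empty_like(times)
    conf[0], kil[0] = C, 0.0
    t = 0.0
    for i in range(1, times.size):
        for _ in range(design.refine):
            active = k if t > truth.tau else 0.0
            dC = truth.g * C * (1.0 - C / truth.K) - active * C
            killed += active * C * h_step
            C = max(C + dC * h_step, 0.0)
            t += h_step
        conf[i], kil[i] = C, killed
    return times, conf, kil


def _iter_conditions(design: SimulationDesign):
    for rep in range(1, design.n_repeats + 1):
        for moi in design.moi_grid:
            for well in range(1, design.n_wells + 1):
                yield f"r{rep}", moi, f"w{well}"


def simulate_confluence(
    truth: CellLineTruth,
    design: SimulationDesign,
    rng: Optional[np.random.Generator] = None,
) -> List[WellSeries]:
    """Simulate confluence wells for one cell line.

    Per well the noise is multiplicative lognormal (exp(sigma Z) per
    timepoint) and values are clipped to [0, 100].
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    cache = {m: _trajectory(truth, m, design)[1] for m in design.moi_grid}
    wells = []
    for rep, moi, well in _iter_conditions(design):
        base = cache[moi]
        noise = (
            np.exp(truth.sigma * rng.standard_normal(base.size))
            if truth.sigma > 0
            else 1.0
        )
        wells.append(
            WellSeries(
                cell_line=truth.name,
                moi=moi,
                times=design.times,
                confluence=np.clip(base * noise, 0.0, 100.0),
                repeat=rep,
                replicate=well,
            )
        )
    return wells


def simulate_cytotox(
    truth: CellLineTruth,
    design: SimulationDesign,
    rng: Optional[np.random.Generator] = None,
) -> List[WellSeries]:
    """Simulate wells carrying both confluence and dead-cell density.

    Dead-cell density is GAMMA_DEAD times the cumulative killed biomass,
    non-decreasing before noise and identically zero for null (kmax = 0)
    lines and untreated wells.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    cache = {m: _trajectory(truth, m, design) for m in design.moi_grid}
    wells = []
    for rep, moi, well in _iter_conditions(design):
        _, conf, killed = cache[moi]
        dead = GAMMA_DEAD * killed
        if truth.sigma > 0:
            conf = conf * np.exp(truth.sigma * rng.standard_normal(conf.size))
            dead = dead * np.exp(truth.sigma * rng.standard_normal(dead.size))
        wells.append(
            WellSeries(
                cell_line=truth.name,
                moi=moi,
                times=design.times,
                confluence=np.clip(conf, 0.0, 100.0),
                dead_per_mm2=dead,
                repeat=rep,
                replicate=well,
            )
        )
    return wells


def simulate_flt3l(
    truth: CellLineTruth,
    design: SimulationDesign,
    timepoints: Sequence[float] = (24.0, 48.0, 72.0),
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Secreted FLT3L concentration per condition at the requested hours.

    F(t) = beta x killed biomass up to t, with multiplicative replicate
    noise; zero (before noise) for untreated wells.  Timepoints must lie on
    the simulation grid.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    grid = design.times
    tps = [float(t) for t in timepoints]
    for t in tps:
        if not np.any(np.isclose(grid, t)):
            raise ValueError(f"timepoint {t} h not on the simulation grid")
    idx = [int(np.argmin(np.abs(grid - t))) for t in tps]
    cache = {m: _trajectory(truth, m, design)[2] for m in design.moi_grid}
    rows = []
    for rep, moi, well in _iter_conditions(design):
        f = truth.beta * cache[moi][idx]
        if truth.sigma > 0:
            f = f * np.exp(truth.sigma * rng.standard_normal(f.size))
        for t, val in zip(tps, f):
            rows.append(
                {
                    "cell_line": truth.name,
                    "treatment": "UT" if moi == 0 else "OV",
                    "moi": moi,
                    "repeat": rep,
                    "replicate": well,
                    "time_h": t,
                    "flt3l_pg_ml": val,
                }
            )
    return pd.DataFrame(rows)


def simulate_counts(
    truths: Sequence[CellLineTruth],
    scores: Mapping[str, float],
    n_genes: int = 520,
    receptor_genes: Sequence[str] = RECEPTOR_GENES,
    b1: float = 2.0,
    seed: int = 0,
    dispersion: float = 0.1,
    n_replicates: int = 3,
    b0: float = 7.0,
    depth_sigma: float = 0.3,
) -> Tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts with a planted susceptibility effect.

    Receptor genes get log2 mean b0 - b1 * z(score) per line: susceptible
    lines (low score, negative z) express them more, so recovering a
    *negative* Spearman estimate against the susceptibility rank is the
    planted signal.  Background genes draw a per-gene base mean independent
    of score.  Per-sample depth factors are lognormal(0, depth_sigma) so the
    size-factor estimator is genuinely exercised.  Returns the count matrix
    and a ground-truth table (gene, planted flag, base log2 mean).
    """
    lines = [t.name for t in truths]
    if len(lines) < 2:
        raise ValueError("need at least 2 cell lines")
    if len(set(lines)) != len(lines):
        raise ValueError("duplicate cell line names")
    receptor_genes = list(receptor_genes)
    if len(set(receptor_genes)) != len(receptor_genes):
        raise ValueError("duplicate gene names in receptor set")
    if n_genes < len(receptor_genes):
        raise ValueError("n_genes smaller than the receptor gene set")
    missing = [l for l in lines if l not in scores]
    if missing:
        raise ValueError(f"no score for lines: {missing}")

    rng = np.random.default_rng(seed)
    s = np.array([float(scores[l]) for l in lines])
    sd = s.std()
    z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)

    n_background = n_genes - len(receptor_genes)
    genes = receptor_genes + [f"GENE{i:05d}" for i in range(n_background)]
    base_bg = rng.uniform(3.0, 10.0, size=n_background)

    log2_mean = np.empty((n_genes, len(lines)))
    log2_mean[: len(receptor_genes), :] = b0 - b1 * z[None, :]
    log2_mean[len(receptor_genes):, :] = base_bg[:, None]

    samples = [f"{l}_rep{j}" for l in lines for j in range(1, n_replicates + 1)]
    depth = np.exp(depth_sigma * rng.standard_normal(len(samples)))
    mu = (2.0 ** log2_mean).repeat(n_replicates, axis=1) * depth[None, :]

    if dispersion > 0:
        size = 1.0 / dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)

    df = pd.DataFrame(counts, index=genes, columns=samples)
    mapping = {f"{l}_rep{j}": l for l in lines for j in range(1, n_replicates + 1)}
    truth = pd.DataFrame(
        {
            "gene": genes,
            "planted": [g in receptor_genes for g in genes],
            "b1": [b1 if g in receptor_genes else 0.0 for g in genes],
            "base_log2_mean": np.concatenate(
                [np.full(len(receptor_genes), b0), base_bg]
            ),
        }
    )
    return CountMatrix(counts=df, sample_to_line=mapping), truth


def simulate_panel(
    truths: Sequence[CellLineTruth],
    design: SimulationDesign,
    cytotox: bool = False,
) -> List[WellSeries]:
    """Simulate every line of a panel with independent per-line substreams."""
    children = np.random.SeedSequence(design.seed).spawn(len(truths))
    wells: List[WellSeries] = []
    sim = simulate_cytotox if cytotox else simulate_confluence
    for truth, ss in zip(truths, children):
        wells.extend(sim(truth, design, rng=np.random.default_rng(ss)))
    return wells


def default_design(seed: int = 0, **overrides) -> SimulationDesign:
    """The study observation design (2 h grid to 170 h, five MOIs + UT)."""
    return SimulationDesign(seed=seed, **overrides)


def default_panel() -> List[CellLineTruth]:
    """Eleven cell lines graded from high to low susceptibility.

    Names follow the study panel; kill parameters are graded so the most
    susceptible lines respond at the lowest MOIs while MiaPaca2 is nearly
    inert, emulating the reported ordering.
    """
    spec = [
        # name, g, kmax, m50
        ("BXPC3", 0.045, 0.10, 0.003),
        ("ASPC1", 0.040, 0.09, 0.005),
        ("SW1990", 0.042, 0.08, 0.02),
        ("Capan-1", 0.035, 0.08, 0.03),
        ("U87", 0.050, 0.07, 0.08),
        ("938-mel", 0.048, 0.07, 0.3),
        ("PaTu8988t", 0.038, 0.06, 0.5),
        ("624-mel", 0.046, 0.06, 0.8),
        ("SUIT2", 0.040, 0.05, 3.0),
        ("LN229", 0.052, 0.05, 5.0),
        ("MiaPaca2", 0.043, 0.01, 50.0),
    ]
    return [CellLineTruth(name=n, g=g, kmax=k, m50=m) for n, g, k, m in spec]


def graded_panel(n_lines: int, kmax: float = 0.08) -> List[CellLineTruth]:
    """A panel of ``n_lines`` with log-spaced half-maximal kill MOIs.

    Useful for recovery studies that need a panel size different from the
    study's eleven lines while keeping a monotone susceptibility gradient.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    m50s = np.logspace(-2.5, 1.5, n_lines)
    return [
        CellLineTruth(name=f"LINE{i + 1:02d}", kmax=kmax, m50=float(m))
        for i, m in enumerate(m50s)
    ]
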