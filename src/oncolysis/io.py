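"""File formats, configuration and the pipeline driver.

All tables are tidy UTF-8 CSV/TSV with a period decimal separator; MOI is
serialized as a decimal (0.001), untreated as 0.  The driver chains the
imaging, scoring and expression stages and writes a JSON manifest that fully
determines the outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .doseresp import SusceptibilityScorer
from .expression import CountMatrix, correlate_with_susceptibility, normalize_expression
from .kinetics import WellSeries, auc_table
from .simulate import (
    SimulationDesign,
    default_panel,
    simulate_counts,
    simulate_panel,
)

logger = logging.getLogger("oncolysis.io")

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "PipelineReport",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_counts_tsv",
    "read_counts_mtx",
    "write_counts_tsv",
    "run_pipeline",
]

TIMESERIES_COLUMNS = [
    "cell_line",
    "treatment",
    "moi",
    "repeat",
    "replicate",
    "time_h",
    "confluence_pct",
]
_WELL_KEY = ["cell_line", "moi", "repeat", "replicate"]


class SchemaError(ValueError):
    """Input table does not match the documented schema."""


# ---------------------------------------------------------------------------
# time-series tables


def write_timeseries_csv(wells: Sequence[WellSeries], path) -> None:
    rows = []
    for w in wells:
        for i, t in enumerate(w.times):
            row = {
                "cell_line": w.cell_line,
                "treatment": "UT" if w.moi == 0 else "OV",
                "moi": w.moi,
                "repeat": w.repeat,
                "replicate": w.replicate,
                "time_h": t,
                "confluence_pct": w.confluence[i],
            }
            if w.dead_per_mm2 is not None:
                row["dead_per_mm2"] = w.dead_per_mm2[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_timeseries_csv(path) -> List[WellSeries]:
    """Read the long-format well table into validated :class:`WellSeries`.

    Rows with confluence outside [0, 100] are dropped with a logged warning;
    duplicated (well, time) rows and missing/non-numeric columns are errors.
    """
    df = pd.read_csv(path)
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col in ("moi", "time_h", "confluence_pct"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            bad = (df.index[df[col].isna()] + 2).tolist()
            raise SchemaError(f"{path}: non-numeric {col} at file line(s) {bad}")
    has_dead = "dead_per_mm2" in df.columns
    if has_dead:
        df["dead_per_mm2"] = pd.to_numeric(df["dead_per_mm2"], errors="coerce")

    out_of_range = (df["confluence_pct"] < 0) | (df["confluence_pct"] > 100)
    if out_of_range.any():
        logger.warning(
            "%s: dropped %d row(s) with confluence outside [0, 100]",
            path,
            int(out_of_range.sum()),
        )
        df = df.loc[~out_of_range]

    dup = df.duplicated(subset=_WELL_KEY + ["time_h"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise SchemaError(f"{path}: duplicated (well, time) at file line(s) {rows}")

    wells = []
    for (line, moi, rep, repl), g in df.groupby(_WELL_KEY, sort=True):
        g = g.sort_values("time_h")
        wells.append(
            WellSeries(
                cell_line=str(line),
                moi=float(moi),
                times=g["time_h"].to_numpy(),
                confluence=g["confluence_pct"].to_numpy(),
                dead_per_mm2=(
                    g["dead_per_mm2"].to_numpy()
                    if has_dead and g["dead_per_mm2"].notna().all()
                    else None
                ),
                repeat=str(rep),
                replicate=str(repl),
            )
        )
    return wells


# ---------------------------------------------------------------------------
# count matrices


def _read_sample_map(sample_map_path) -> Dict[str, str]:
    m = pd.read_csv(sample_map_path)
    for col in ("sample", "cell_line"):
        if col not in m.columns:
            raise SchemaError(f"{sample_map_path}: missing column {col!r}")
    return dict(zip(m["sample"].astype(str), m["cell_line"].astype(str)))


def read_counts_tsv(path, sample_map_path) -> CountMatrix:
    """Genes x samples TSV (first column gene names) plus a sample-map CSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    mapping = _read_sample_map(sample_map_path)
    unmapped = [s for s in df.columns if s not in mapping]
    if unmapped:
        raise SchemaError(f"{path}: sample(s) absent from map: {unmapped}")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise SchemaError(f"{path}: non-numeric counts")
    if np.any(vals != np.round(vals)):
        raise SchemaError(f"{path}: counts must be integers")
    return CountMatrix(counts=df.astype(np.int64), sample_to_line=mapping)


def read_counts_mtx(mtx_path, genes_path, samples_path, sample_map_path) -> CountMatrix:
    """MatrixMarket triplet counts with gene/sample name sidecars."""
    from scipy.io import mmread

    mat = np.asarray(mmread(mtx_path).todense())
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    if mat.shape != (len(genes), len(samples)):
        raise SchemaError(
            f"{mtx_path}: shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(samples)} samples)"
        )
    df = pd.DataFrame(mat, index=genes, columns=samples)
    mapping = _read_sample_map(sample_map_path)
    unmapped = [s for s in samples if s not in mapping]
    if unmapped:
        raise SchemaError(f"{mtx_path}: sample(s) absent from map: {unmapped}")
    if np.any(mat != np.round(mat)):
        raise SchemaError(f"{mtx_path}: counts must be integers")
    return CountMatrix(counts=df.astype(np.int64), sample_to_line=mapping)


def write_counts_tsv(cm: CountMatrix, counts_path, sample_map_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"sample": list(cm.sample_to_line), "cell_line": list(cm.sample_to_line.values())}
    ).to_csv(sample_map_path, index=False)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Run configuration for the full screen analysis."""

    outdir: str = "results"
    alpha: float = 0.05
    baseline_mode: str = "divide"
    p_method: str = "auto"
    seed: int = 0
    timeseries: Optional[str] = None  # CSV path; None -> simulate
    counts: Optional[str] = None  # TSV path; None -> simulate
    sample_map: Optional[str] = None
    gene_set: Optional[List[str]] = None
    b1: float = 2.0  # planted effect size when simulating counts
    n_genes: int = 520

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.baseline_mode not in ("divide", "subtract"):
            raise ValueError(f"unknown baseline_mode {self.baseline_mode!r}")
        if self.p_method not in ("auto", "exact", "montecarlo", "t_approx"):
            raise ValueError(f"unknown p_method {self.p_method!r}")
        if (self.counts is None) != (self.sample_map is None):
            raise ValueError("counts and sample_map must be given together")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineReport:
    """Artifacts and in-memory results of one pipeline run."""

    dose_response_path: Path
    ranking_path: Path
    correlations_path: Path
    manifest_path: Path
    summary: pd.DataFrame = field(repr=False)
    ranking: pd.DataFrame = field(repr=False)
    correlations: pd.DataFrame = field(repr=False)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute imaging -> scoring -> expression and write all artifacts.

    Emits per-line dose-response records, the susceptibility ranking, the
    gene-level correlation table and a JSON manifest (config, seed, versions,
    row counts).  Any stage failure is re-raised annotated with the stage
    name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "growth_kinetics"
    try:
        if config.timeseries is not None:
            wells = read_timeseries_csv(config.timeseries)
        else:
            logger.info("[simulate] generating the default 11-line panel")
            wells = simulate_panel(
                default_panel(), SimulationDesign(seed=config.seed)
            )
        aucs = auc_table(wells, baseline_mode=config.baseline_mode)

        stage = "dose_response"
        scorer = SusceptibilityScorer(alpha=config.alpha).fit(aucs)
        summary = scorer.summary()

        stage = "expression"
        if config.counts is not None:
            cm = read_counts_tsv(config.counts, config.sample_map)
        else:
            truths = default_panel()
            cm, _ = simulate_counts(
                truths,
                scores=scorer.scores_.to_dict(),
                n_genes=config.n_genes,
                b1=config.b1,
                seed=config.seed + 1,
            )
        norm = normalize_expression(cm)
        corr = correlate_with_susceptibility(
            norm,
            ranks=scorer.ranks_.to_dict(),
            gene_set=config.gene_set,
            p_method=config.p_method,
            seed=config.seed,
        )
    except Exception:
        logger.error("pipeline failed during stage %s", stage)
        raise

    stage = "write"
    dr_path = outdir / "dose_response.csv"
    rank_path = outdir / "ranking.csv"
    corr_path = outdir / "correlations.csv"
    manifest_path = outdir / "manifest.json"

    summary.to_csv(dr_path, index=False)
    ranking = summary[["cell_line", "susceptibility_rank", "score"]].sort_values(
        "susceptibility_rank"
    )
    ranking.to_csv(rank_path, index=False)
    corr.to_csv(corr_path, index=False)
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {
            "oncolysis": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "rows": {
            "dose_response": int(len(summary)),
            "ranking": int(len(ranking)),
            "correlations": int(len(corr)),
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", outdir)
    return PipelineReport(
        dose_response_path=dr_path,
        ranking_path=rank_path,
        correlations_path=corr_path,
        manifest_path=manifest_path,
        summary=summary,
        ranking=ranking,
        correlations=corr,
    )
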