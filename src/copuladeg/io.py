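"""Reading fold-change tables and running the end-to-end pipeline."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import fisher_combine, rankprod, stouffer_combine
from .copula import FoldChangeMatrix
from .estimation import FitConfig, FitResult, fit
from .inference import PosteriorTable, SelectionTable, posterior_probs, select_degs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline settings."""

    input_path: str
    id_col: str = "gene_id"
    col1: str = "study1"
    col2: str = "study2"
    alpha: float = 0.05
    fit: FitConfig = field(default_factory=FitConfig)
    baselines: bool = False
    pval_cols: tuple[str, str] | None = None
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


def read_fold_changes(
    path: str | Path,
    id_col: str = "gene_id",
    col1: str = "study1",
    col2: str = "study2",
) -> FoldChangeMatrix:
    """Load a TSV/CSV fold-change table into a FoldChangeMatrix.

    Rows with a missing or non-finite value in either study column are
    dropped (count logged); duplicate gene ids are a hard error, as is a
    usable table of fewer than 10 genes.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep)
    for col in (id_col, col1, col2):
        if col not in frame.columns:
            raise ValueError(f"column '{col}' not found in {path}")
    values = frame[[col1, col2]].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    keep = np.isfinite(values).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d gene(s) with missing/non-finite values", n_dropped)
    ids = frame.loc[keep, id_col].astype(str).to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate gene ids in input")
    if keep.sum() < 10:
        raise ValueError(f"only {int(keep.sum())} usable genes (< 10)")
    return FoldChangeMatrix(
        gene_ids=ids, values=values[keep], study_names=(col1, col2)
    )


def _format_float(x: float) -> str:
    return f"{x:.6g}"


def write_results(
    out_dir: str | Path,
    data: FoldChangeMatrix,
    result: FitResult,
    posteriors: PosteriorTable,
    selection: SelectionTable,
    alpha: float,
    baseline_frame: pd.DataFrame | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the per-gene TSV and JSON summary; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = data.n_genes
    rank = np.empty(n, dtype=int)
    rank[selection.order] = np.arange(1, n + 1)
    table = pd.DataFrame(
        {
            "gene_id": data.gene_ids,
            "x1": data.values[:, 0],
            "x2": data.values[:, 1],
            "p0": posteriors.probs[:, 0],
            "p1": posteriors.probs[:, 1],
            "p2": posteriors.probs[:, 2],
            "label": posteriors.labels,
            "rank": rank,
            "cum_error": selection.cum_error[rank - 1],
            "selected": selection.selected,
        }
    )
    if baseline_frame is not None:
        table = pd.concat([table, baseline_frame.reset_index(drop=True)], axis=1)
    genes_path = out_dir / "genes.tsv"
    table.to_csv(genes_path, sep="\t", index=False, float_format="%.6g")

    counts = {int(k): int(v) for k, v in zip(*np.unique(posteriors.labels, return_counts=True))}
    summary = {
        "theta": result.theta.to_dict(),
        "converged": result.converged,
        "n_iter": result.n_iter,
        "loglik_trace_length": int(len(result.loglik_trace)),
        "final_loglik": float(result.loglik_trace[-1]),
        "alpha": alpha,
        "i_max": selection.i_max,
        "n_genes": n,
        "label_counts": {str(k): counts.get(k, 0) for k in (0, 1, 2)},
    }
    if seed is not None:
        summary["seed"] = seed
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    return {"genes": genes_path, "summary": summary_path}


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """read -> fit -> posteriors -> selection (-> baselines) -> files."""
    data = read_fold_changes(config.input_path, config.id_col, config.col1, config.col2)
    logger.info("read %d genes from %s", data.n_genes, config.input_path)
    result = fit(data, config.fit)
    if not result.converged:
        logger.warning("model fit did NOT converge; results may be unreliable")
    posteriors = posterior_probs(data, result.theta)
    selection = select_degs(posteriors, config.alpha)
    logger.info(
        "i_max=%d selected at alpha=%.3g; theta=%s",
        selection.i_max,
        config.alpha,
        result.theta.to_dict(),
    )
    baseline_frame = None
    if config.baselines:
        rp = rankprod(data)
        baseline_frame = pd.DataFrame(
            {"rankprod": rp.rp, "rp_direction": rp.direction}
        )
        if config.pval_cols is not None:
            sep = "," if str(config.input_path).endswith(".csv") else "\t"
            raw = pd.read_csv(config.input_path, sep=sep)
            pv = raw.set_index(raw[config.id_col].astype(str)).loc[
                data.gene_ids, list(config.pval_cols)
            ].to_numpy(float)
            baseline_frame["fisher_p"] = fisher_combine(pv)
            baseline_frame["stouffer_p"] = stouffer_combine(pv)
    return write_results(
        config.out_dir,
        data,
        result,
        posteriors,
        selection,
        config.alpha,
        baseline_frame=baseline_frame,
        seed=config.fit.seed,
    )
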