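"""Delimited-text I/O for expression matrices, gene lists, and run outputs.

Matrices are TSV/CSV with a header row and an id column; the default
orientation is samples in rows (n x genes), matching how the model consumes
them.  Output files carry a ``#``-prefixed header comment echoing the package
version, seed, and parameters so every artifact is self-describing, and
readers here skip such comments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model_selection import (
    CVPlan,
    Q2_THRESHOLD,
    cv_tune_lambda,
    q_squared_path,
    select_n_components,
)
from .network import export_edges, rank_regulators, roc_auc
from .pls import fit_hb_pls, save_model

__all__ = [
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "read_gene_list",
    "write_table",
    "run_pipeline",
]

log = logging.getLogger("hbpls")


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path, genes_in_rows: bool = False) -> pd.DataFrame:
    """Load an expression matrix; returns samples x genes.

    ``genes_in_rows=True`` transposes on load.  Duplicate identifiers,
    non-numeric cells and ragged rows are rejected with messages naming the
    offender.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited file: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated row id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicated column id {dup!r}")
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        raise ValueError(f"{path}: non-numeric values in column {bad[0]!r}")
    df = df.astype(float)
    if genes_in_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep=_sep_for(path))


def read_gene_list(path) -> list[str]:
    """Newline-delimited gene ids; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a result table as TSV with an optional ``#`` header comment."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    x_path: str
    y_path: str
    out_dir: str
    positives_path: str | None = None
    genes_in_rows: bool = False
    lam: float | None = None  # None -> CV-tuned
    K: int | None = None  # None -> Q2-selected
    M: float | None = None
    n_folds: int = 5
    n_lambda: int = 20
    K_max: int = 5
    K_cv: int = 2
    top_n: int = 50
    edge_threshold: float = 0.0
    seed: int = 0
    extra: dict = field(default_factory=dict)


def _header(config: RunConfig, **kw) -> str:
    parts = [f"hbpls v{__version__}", f"seed={config.seed}"]
    parts += [f"{k}={v}" for k, v in kw.items()]
    return "; ".join(parts)


def run_pipeline(config: RunConfig) -> dict:
    """Read inputs, tune, fit, rank, evaluate, and write all artifacts.

    Returns a dict of the fitted model and paths of the written files.
    Stage failures are re-raised with the stage name prepended.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read-inputs"
    try:
        X = read_matrix(config.x_path, genes_in_rows=config.genes_in_rows)
        Y = read_matrix(config.y_path, genes_in_rows=config.genes_in_rows)
        shared = X.index.intersection(Y.index)
        if len(shared) < 2:
            raise ValueError("X and Y share fewer than 2 sample ids")
        X, Y = X.loc[shared], Y.loc[shared]
        positives = (
            read_gene_list(config.positives_path) if config.positives_path else None
        )

        stage = "tune-lambda"
        plan = CVPlan(n_folds=config.n_folds, seed=config.seed, K_max=config.K_cv)
        if config.lam is None:
            lam, cv_table = cv_tune_lambda(X.to_numpy(), Y.to_numpy(), plan)
            write_table(cv_table, out / "cv_lambda.tsv", _header(config, stage="cv"))
            log.info("selected lambda=%.6g by %d-fold CV", lam, plan.resolved_folds(len(X)))
        else:
            lam = config.lam

        stage = "select-components"
        if config.K is None:
            qs = q_squared_path(X.to_numpy(), Y.to_numpy(), lam, config.K_max, plan)
            K = select_n_components(qs, config.K_max)
            write_table(
                qs.per_component,
                out / "q2_components.tsv",
                _header(config, lam=lam, threshold=Q2_THRESHOLD),
            )
            log.info("selected K=%d by the Q2 criterion", K)
        else:
            K = config.K

        stage = "fit"
        model = fit_hb_pls(
            X.to_numpy(),
            Y.to_numpy(),
            lam,
            K,
            tf_ids=list(X.columns),
            gene_ids=list(Y.columns),
            M=config.M,
        )
        save_model(model, out / "model.json")

        stage = "rank"
        ranking = rank_regulators(model, top_n=config.top_n)
        write_table(ranking.table, out / "ranking.tsv", _header(config, lam=lam, K=K))
        edges = export_edges(model, config.edge_threshold)
        write_table(edges, out / "edges.tsv", _header(config, lam=lam, K=K))

        roc = None
        if positives:
            stage = "evaluate"
            connectivity = np.abs(model.A).sum(axis=1)
            roc = roc_auc(connectivity, model.tf_ids, positives)
            write_table(
                pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}),
                out / "roc.tsv",
                _header(config, lam=lam, K=K, auroc=f"{roc.auroc:.4f}"),
            )
            log.info("AuROC vs %d positives: %.4f", roc.n_positives, roc.auroc)

        stage = "log"
        (out / "run_log.txt").write_text(
            _header(config, lam=lam, K=K, x=config.x_path, y=config.y_path) + "\n"
        )
        return {"model": model, "lam": lam, "K": K, "roc": roc, "out_dir": str(out)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
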