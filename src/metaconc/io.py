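"""Table readers/writers and the end-to-end pipeline.

Fixed tabular dialect: tab-separated values, ``.`` decimal separator, ``NA``
for missing cells, concentrations in mol/L, logarithms base 10 everywhere.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chem import PARAMETER_NAMES, descriptor_table, read_sdf, read_smi
from .errors import MetaconcError, PipelineStageError, TableFormatError
from .groups import AMINO_ACIDS, PHOSPHATE_COUNTS, PHOSPHORYLATED_NUCLEOTIDES
from .stats import (
    ConcentrationDataset,
    DEFAULT_FEATURES,
    filter_small,
    grid_to_frame,
    correlation_grid,
    loo_predict,
    per_phosphate_fold,
    subgroup_correlations,
)

NA = "NA"


# ---------------------------------------------------------------- descriptors
def write_descriptor_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index_label="id", float_format="%.6g")


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    if "id" not in df.columns:
        raise TableFormatError(f"{path}: descriptor table needs an 'id' column")
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise TableFormatError(f"{path}: duplicate ids {sorted(set(dup))[:5]}")
    return df.set_index("id")


# ------------------------------------------------------------- concentrations
def read_concentration_table(path: str | Path, source: str = "") -> list[ConcentrationDataset]:
    """Read a metabolite x condition concentration table (mol/L).

    First column holds metabolite ids; each further column is one condition.
    ``NA`` (or empty) cells are recorded as missing, never as zero.  Malformed
    numeric cells and duplicate ids raise :class:`TableFormatError` naming
    the offending row and column.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise TableFormatError(f"{path}: need an id column plus >=1 condition column")
    id_col = raw.columns[0]
    ids = raw[id_col].str.strip()
    dup = ids[ids.duplicated()]
    if len(dup):
        raise TableFormatError(f"{path}: duplicate metabolite ids {sorted(set(dup))[:5]}")

    datasets = []
    for col in raw.columns[1:]:
        entries: dict[str, float] = {}
        for row_i, (mid, cell) in enumerate(zip(ids, raw[col]), start=2):
            cell = cell.strip()
            if cell in ("", NA, "na", "NaN", "nan"):
                continue
            try:
                value = float(cell)
            except ValueError:
                raise TableFormatError(
                    f"{path}: malformed value {cell!r} at row {row_i}, column {col!r}"
                ) from None
            if not (value > 0) or not math.isfinite(value):
                raise TableFormatError(
                    f"{path}: non-positive concentration {cell!r} at row {row_i}, "
                    f"column {col!r}"
                )
            entries[mid] = value
        datasets.append(ConcentrationDataset(source=source, condition=col, entries=entries))
    return datasets


def write_concentration_table(datasets: Sequence[ConcentrationDataset], path: str | Path) -> None:
    wide = pd.concat([d.to_series().rename(d.condition) for d in datasets], axis=1)
    wide.to_csv(path, sep="\t", na_rep=NA, index_label="id", float_format="%.6g")


# --------------------------------------------------------------------- config
@dataclass
class RunConfig:
    """Everything the full pipeline needs; flags of the CLI mirror this."""

    concentrations: Path
    structures: Optional[Path] = None  # .smi or .sdf
    descriptors: Optional[Path] = None  # precomputed descriptor TSV
    external_logp_logs: Optional[Path] = None  # TSV: id, LogP, LogS
    out_dir: Path = Path("results")
    mw_max: float = 300.0
    n_perm: int = 100_000
    fdr_rate: float = 0.01
    features: tuple[str, ...] = DEFAULT_FEATURES
    parameters: tuple[str, ...] = PARAMETER_NAMES
    seed: int = 1
    n_points: int = 960
    amino_acid_ids: tuple[str, ...] = AMINO_ACIDS
    nucleotide_ids: tuple[str, ...] = PHOSPHORYLATED_NUCLEOTIDES
    phosphate_counts: dict = field(default_factory=lambda: dict(PHOSPHATE_COUNTS))

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.fdr_rate < 1):
            raise ValueError("fdr_rate must be in (0, 1)")
        if self.mw_max <= 0:
            raise ValueError("mw_max must be positive")
        if self.descriptors is None and self.structures is None:
            raise ValueError("need either a structure file or a descriptor table")


# ------------------------------------------------------------------- pipeline
def _load_descriptors(cfg: RunConfig) -> pd.DataFrame:
    if cfg.descriptors is not None:
        return read_descriptor_table(cfg.descriptors)
    path = Path(cfg.structures)
    records = read_sdf(path) if path.suffix.lower() == ".sdf" else read_smi(path)
    external = {}
    if cfg.external_logp_logs is not None:
        ext = read_descriptor_table(cfg.external_logp_logs)
        external = {
            mid: {"logp": row.get("LogP"), "logs": row.get("LogS")}
            for mid, row in ext.iterrows()
        }
    return descriptor_table(records, external=external, n_points=cfg.n_points, seed=cfg.seed)


def run_pipeline(cfg: RunConfig) -> dict:
    """Descriptors -> per-condition filtering -> correlation grid with one
    FDR family -> leave-one-out prediction -> subgroup analyses.

    Writes ``correlation_grid.tsv``, ``predictions.tsv``, ``summary.json``
    and ``run.log`` into ``cfg.out_dir`` and returns the summary dict.  Any
    stage failure raises :class:`PipelineStageError` and removes partial
    outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = [
        f"metaconc {__version__} (numpy {np.__version__}, pandas {pd.__version__})",
        f"seed={cfg.seed} n_perm={cfg.n_perm} fdr_rate={cfg.fdr_rate} mw_max={cfg.mw_max}",
    ]

    def stage(name, fn):
        try:
            return fn()
        except MetaconcError as exc:
            for p in written:
                p.unlink(missing_ok=True)
            raise PipelineStageError(name, exc) from exc
        except (OSError, ValueError) as exc:
            for p in written:
                p.unlink(missing_ok=True)
            raise PipelineStageError(name, exc) from exc

    descriptors = stage("descriptors", lambda: _load_descriptors(cfg))
    log_lines.append(f"descriptors: {len(descriptors)} metabolites")

    datasets = stage(
        "read-concentrations", lambda: read_concentration_table(cfg.concentrations)
    )
    log_lines.append(f"conditions: {len(datasets)}")

    tables = {}
    retained = {}
    for ds in datasets:
        table, dropped = stage(
            f"filter:{ds.condition}", lambda ds=ds: filter_small(ds, descriptors, cfg.mw_max)
        )
        tables[ds.condition] = table
        measured = len(ds.entries)
        retained[ds.condition] = {
            "measured": measured,
            "analyzed": int(len(table)),
            "dropped": dropped,
        }
        log_lines.append(f"filter {ds.condition}: kept {len(table)}/{measured} ({dropped})")

    grid = stage(
        "correlation-grid",
        lambda: correlation_grid(
            tables, cfg.parameters, n_perm=cfg.n_perm, fdr_rate=cfg.fdr_rate, seed=cfg.seed
        ),
    )
    n_family = sum(1 for g in grid if g.p_perm is not None)
    log_lines.append(
        f"correlation grid: {len(tables)} conditions x {len(cfg.parameters)} parameters, "
        f"FDR family size {n_family} at rate {cfg.fdr_rate}"
    )

    predictions = {}
    for cond, table in tables.items():
        try:
            predictions[cond] = loo_predict(table, cfg.features, condition=cond)
        except MetaconcError as exc:
            log_lines.append(f"prediction {cond}: skipped ({exc})")

    subgroups = {}
    for cond, table in tables.items():
        for group_name, ids, param in (
            ("amino_acids", cfg.amino_acid_ids, "NPSA"),
            ("nucleotides", cfg.nucleotide_ids, "NCA"),
        ):
            try:
                res = subgroup_correlations(table, ids, param, condition=cond)
                subgroups[f"{cond}/{group_name}/{param}"] = {
                    "r": res.r, "r2": res.r2, "n": res.n_used,
                }
            except MetaconcError:
                continue
        try:
            subgroups[f"{cond}/fold_per_phosphate"] = per_phosphate_fold(
                table, cfg.phosphate_counts
            )
        except MetaconcError:
            continue

    grid_frame = grid_to_frame(grid)
    grid_path = out / "correlation_grid.tsv"
    grid_frame.to_csv(grid_path, sep="\t", na_rep=NA, index=False, float_format="%.6g")
    written.append(grid_path)

    pred_frame = pd.concat(
        [rep.rows.assign(condition=cond) for cond, rep in predictions.items()]
    ) if predictions else pd.DataFrame()
    pred_path = out / "predictions.tsv"
    pred_frame.to_csv(pred_path, sep="\t", na_rep=NA, float_format="%.6g")
    written.append(pred_path)

    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "n_conditions": len(datasets),
        "fdr_family_size": n_family,
        "fdr_rate": cfg.fdr_rate,
        "n_significant": int(sum(bool(g.significant) for g in grid)),
        "retained": retained,
        "predictions": {
            cond: {
                "n": int(len(rep.rows)),
                "r2_fit": rep.r2_fit,
                "accuracy_1oom": rep.accuracy_1oom,
                "baseline_1oom": rep.baseline_1oom,
                "mean_fold_deviation": rep.mean_fold_deviation,
                "mean_of_folds": rep.mean_of_folds,
                "coefficients": dict(
                    zip(rep.model.features, rep.model.coefficients.tolist())
                ),
                "intercept": rep.model.intercept,
                "outliers": rep.outliers,
            }
            for cond, rep in predictions.items()
        },
        "subgroups": subgroups,
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(summary_path)

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
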