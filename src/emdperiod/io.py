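"""Readers, writers and the end-to-end pipeline.

Matrices are tab-delimited text, probesets x time points, either plain
(header row, first column = probeset id) or the textual GEO series-matrix
dialect (metadata lines starting with ``!``; the table sits between
``!series_matrix_table_begin`` and ``!series_matrix_table_end``).

Output tables use fixed column orders, ratios to 3 decimals and p-values in
scientific notation with 4 significant digits, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import emdperiod
from emdperiod.combinatorics import ProbesetClassification, classify_batch
from emdperiod.coexpression import (
    background_distribution,
    read_complexes,
    summarize_complex,
    validate_genes,
)
from emdperiod.emd import EMDConfig, ExpressionProfile, TimeGrid, emd_decompose
from emdperiod.periodicity import PeriodicityResult, build_null, detect
from emdperiod.synthetic import make_dataset

__all__ = [
    "read_matrix",
    "write_matrix",
    "decomposition_table",
    "detection_table",
    "classification_table",
    "complex_summary_table",
    "write_table",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_PVAL_FMT = "{:.3e}"  # 4 significant digits
_RATIO_FMT = "{:.3f}"


def _parse_table(lines: list[str], path, offset: int) -> pd.DataFrame:
    header = lines[0].rstrip("\n").split("\t")
    n_cols = len(header)
    if n_cols < 2:
        raise ValueError(f"{path}: header line {offset} has no time-point columns")
    ids: list[str] = []
    rows: list[list[float]] = []
    for k, line in enumerate(lines[1:], start=offset + 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != n_cols:
            raise ValueError(
                f"{path}: line {k} has {len(fields)} fields, expected {n_cols}"
            )
        pid = fields[0].strip().strip('"')
        vals = []
        for c, cell in enumerate(fields[1:], start=2):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: line {k}, column {c}: non-numeric cell {cell!r}"
                ) from None
        ids.append(pid)
        rows.append(vals)
    frame = pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=pd.Index(ids, name=header[0].strip().strip('"') or "probeset_id"),
        columns=[h.strip().strip('"') for h in header[1:]],
    )
    return frame


def read_matrix(path, drop_incomplete: bool = False) -> pd.DataFrame:
    """Load an expression matrix from plain TSV or GEO series-matrix text.

    Probeset ids must be unique and all values finite; rows with missing
    values fail the load unless ``drop_incomplete`` is set, in which case
    they are dropped with a log entry.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines(keepends=False)
    if any(line.startswith("!series_matrix_table_begin") for line in lines):
        begin = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
        try:
            end = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
        except StopIteration:
            raise ValueError(f"{path}: missing !series_matrix_table_end") from None
        table_lines = lines[begin + 1 : end]
        offset = begin + 2  # 1-based line number of the header
    elif lines and lines[0].startswith("!"):
        raise ValueError(f"{path}: metadata lines present but no series-matrix table section")
    else:
        table_lines = lines
        offset = 1
    if not table_lines:
        raise ValueError(f"{path}: no table found")

    # missing-value handling: blank cells are caught as non-numeric above,
    # so scan for textual NA markers first and blank them consistently
    cleaned = []
    na_markers = {"", "na", "nan", "null"}
    incomplete: set[int] = set()
    for k, line in enumerate(table_lines):
        if k == 0:
            cleaned.append(line)
            continue
        fields = line.rstrip("\n").split("\t")
        if any(f.strip().strip('"').lower() in na_markers for f in fields[1:]):
            incomplete.add(k)
        cleaned.append(line)
    if incomplete and not drop_incomplete:
        first = sorted(incomplete)[0]
        raise ValueError(
            f"{path}: {len(incomplete)} rows with missing values "
            f"(first at table line {first + offset}); pass drop_incomplete to skip them"
        )
    if incomplete:
        for k in sorted(incomplete):
            pid = cleaned[k].split("\t", 1)[0]
            logger.warning("dropping row %s: missing values", pid)
        cleaned = [l for k, l in enumerate(cleaned) if k not in incomplete]

    frame = _parse_table(cleaned, path, offset)
    dup = frame.index[frame.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate probeset ids: {', '.join(map(str, dup[:5]))}")
    return frame


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g")


def decomposition_table(decomps: list) -> pd.DataFrame:
    """Long-format table: probeset_id, component (imf1..imfn, residual), t1..tT."""
    rows = []
    for d in decomps:
        n = d.residual.size
        for i, imf in enumerate(d.imfs):
            rows.append([d.probeset_id, f"imf{i+1}", *imf])
        rows.append([d.probeset_id, "residual", *d.residual])
    n = decomps[0].residual.size if decomps else 0
    return pd.DataFrame(rows, columns=["probeset_id", "component", *[f"t{i+1}" for i in range(n)]])


def detection_table(results: list[PeriodicityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "probeset_id": r.probeset_id,
                "acf": r.acf_value,
                "p_value": _PVAL_FMT.format(r.p_value),
                "periodic": r.periodic,
            }
            for r in results
        ],
        columns=["probeset_id", "acf", "p_value", "periodic"],
    )


def classification_table(classifications: list[ProbesetClassification]) -> pd.DataFrame:
    rows = []
    for c in classifications:
        rows.append(
            {
                "probeset_id": c.probeset_id,
                "label": c.label,
                "original_p": _PVAL_FMT.format(c.original.p_value),
                "optimal_mask": c.optimal.mask_label() if c.optimal else "none",
                "optimal_p": _PVAL_FMT.format(c.optimal.p_value) if c.optimal else "",
                "n_imfs": c.n_imfs,
                "n_subsets_tested": c.n_subsets_tested,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "probeset_id",
            "label",
            "original_p",
            "optimal_mask",
            "optimal_p",
            "n_imfs",
            "n_subsets_tested",
        ],
    )


def complex_summary_table(summaries: list, category_counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Per-complex summary mirroring the standard coexpression table layout."""
    rows = []
    for s in summaries:
        cats = category_counts.get(s.complex_id, {})
        rows.append(
            {
                "complex_id": s.complex_id,
                "complex_name": s.name,
                "n_proteins": s.n_members,
                "n_genes_in_matrix": s.n_members_in_matrix,
                "periodic_genes": cats.get("PERIODIC_BOTH", 0),
                "putative_periodic_genes": cats.get("PERIODIC_EMD_ONLY", 0),
                "total_gene_pairs": s.n_total_pairs,
                "coexpressed_gene_pairs": s.n_coexpressed,
                "ratio": _RATIO_FMT.format(s.ratio) if s.ratio is not None else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "complex_id",
            "complex_name",
            "n_proteins",
            "n_genes_in_matrix",
            "periodic_genes",
            "putative_periodic_genes",
            "total_gene_pairs",
            "coexpressed_gene_pairs",
            "ratio",
        ],
    )


def write_table(table: pd.DataFrame, path) -> None:
    """TSV with fixed column order, 6-significant-digit floats, trailing newline."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class PipelineConfig:
    """Configuration of a full decompose -> detect -> search -> validate run."""

    out_dir: Path
    matrix_path: Path | None = None
    complexes_path: Path | None = None
    seed: int = 17
    alpha: float = 0.05
    n_points: int = 36
    interval_minutes: float = 25.0
    period_minutes: float = 300.0
    null_reps: int = 100_000
    include_residual: bool = False
    percentile: float = 95.0
    background_samples: int = 1_000_000
    drop_incomplete: bool = False
    simulate: tuple[int, int, int] | None = None  # (n_periodic, n_underdetected, n_null)
    emd: EMDConfig = field(default_factory=EMDConfig)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        emd_cfg = EMDConfig(**raw.pop("emd", {}))
        simulate = raw.pop("simulate", None)
        cfg = cls(out_dir=Path(raw.pop("out_dir")), emd=emd_cfg)
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, value)
        if simulate is not None:
            cfg.simulate = tuple(int(v) for v in simulate)
        if cfg.matrix_path is not None:
            cfg.matrix_path = Path(cfg.matrix_path)
        if cfg.complexes_path is not None:
            cfg.complexes_path = Path(cfg.complexes_path)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all outputs plus a JSON run manifest.

    Returns the manifest.  On a stage failure the exception propagates
    after the manifest (with the failure point) has been written, so
    partial outputs stay inspectable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": emdperiod.__version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "grid": {
            "n_points": config.n_points,
            "interval_minutes": config.interval_minutes,
            "period_minutes": config.period_minutes,
        },
        "null_reps": config.null_reps,
        "include_residual": config.include_residual,
        "stages": {},
    }

    def _save_manifest(failure: str | None = None) -> None:
        if failure:
            manifest["failed_at"] = failure
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")

    stage = "load"
    try:
        if config.simulate is not None:
            n_p, n_u, n_n = config.simulate
            matrix, truth = make_dataset(n_p, n_u, n_n, base_seed=config.seed)
            write_matrix(matrix, out / "matrix.tsv")
            write_table(truth, out / "truth.tsv")
            manifest["stages"]["simulate"] = {"rows": int(matrix.shape[0])}
        elif config.matrix_path is not None:
            matrix = read_matrix(config.matrix_path, drop_incomplete=config.drop_incomplete)
        else:
            raise ValueError("either matrix_path or simulate must be configured")
        grid = TimeGrid(matrix.shape[1], config.interval_minutes, config.period_minutes)
        manifest["stages"]["load"] = {"rows": int(matrix.shape[0]), "n_points": grid.n_points}

        stage = "detect"
        null = build_null(grid, n_reps=config.null_reps, seed=config.seed)
        results, det_summary = detect(matrix, grid, null, alpha=config.alpha)
        write_table(detection_table(results), out / "detect.tsv")
        manifest["stages"]["detect"] = {
            "n_total": det_summary.n_total,
            "n_periodic": det_summary.n_periodic,
            "pct_periodic": round(det_summary.pct_periodic, 2),
        }

        stage = "search"
        classes, cls_summary, skipped = classify_batch(
            matrix,
            grid,
            null,
            alpha=config.alpha,
            include_residual=config.include_residual,
            emd_config=config.emd,
        )
        write_table(classification_table(classes), out / "classes.tsv")
        decomps = [
            emd_decompose(ExpressionProfile(str(pid), row), config.emd)
            for pid, row in zip(matrix.index, matrix.to_numpy(dtype=float))
            if np.ptp(row) > 0
        ]
        write_table(decomposition_table(decomps), out / "imfs.tsv")
        manifest["stages"]["search"] = {
            "n_periodic": cls_summary.n_periodic,
            "n_putative_periodic": cls_summary.n_putative_periodic,
            "n_non_detectable": cls_summary.n_non_detectable,
            "n_periodic_combined": cls_summary.n_periodic_combined,
            "n_skipped": cls_summary.n_skipped,
            "skipped": [{"probeset_id": p, "reason": r} for p, r in skipped],
        }

        if config.complexes_path is not None:
            stage = "validate"
            complexes = read_complexes(config.complexes_path)
            background = background_distribution(
                matrix, n_samples=config.background_samples, seed=config.seed
            )
            label_map = {c.probeset_id: c.label for c in classes}
            summaries, cat_counts = [], {}
            all_edges, all_nodes, all_unmapped = [], [], []
            for cdef in complexes:
                summ = summarize_complex(cdef, matrix, background, percentile=config.percentile)
                validations, unmapped, edges, nodes = validate_genes(
                    cdef, label_map, matrix, summ
                )
                summaries.append(summ)
                counts: dict[str, int] = {}
                for v in validations:
                    counts[v.category] = counts.get(v.category, 0) + 1
                cat_counts[cdef.complex_id] = counts
                edges.insert(0, "complex_id", cdef.complex_id)
                nodes.insert(0, "complex_id", cdef.complex_id)
                all_edges.append(edges)
                all_nodes.append(nodes)
                all_unmapped.extend((cdef.complex_id, g) for g in unmapped)
            write_table(complex_summary_table(summaries, cat_counts), out / "complex_summary.tsv")
            write_table(pd.concat(all_edges, ignore_index=True), out / "network_edges.tsv")
            write_table(pd.concat(all_nodes, ignore_index=True), out / "network_nodes.tsv")
            manifest["stages"]["validate"] = {
                "n_complexes": len(complexes),
                "percentile": config.percentile,
                "background_samples": config.background_samples,
                "unmapped_genes": [
                    {"complex_id": c, "gene_id": g} for c, g in all_unmapped
                ],
            }
    except Exception as exc:
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        _save_manifest(failure=stage)
        raise

    _save_manifest()
    return manifest
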