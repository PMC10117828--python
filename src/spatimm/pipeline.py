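"""End-to-end orchestration.

Stage order: registration (align every marker slide to the middle
reference slide) → region derivation → per-marker quantification and
colocalization → Immunoscore → cohort statistics (group comparisons,
ROC-dichotomized Kaplan–Meier/log-rank, multivariate Cox, advanced-stage
subset).  Runs are deterministic given a config and input; a failing
patient is excluded from cohort statistics and enumerated in the manifest
rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .immunoscore import cohort_immunoscore
from .io import read_annotation, read_cell_table, read_clinical
from .quantify import parameter_columns, parameter_vector
from .regions import RegionAnnotation
from .registration import MarkerPointPattern, align_to_reference
from .stats import (
    clinical_design_matrix,
    compare_groups,
    cox_multivariate,
    km_logrank,
    roc_cutoff,
    stage_subset,
)

__all__ = ["RunManifest", "PipelineResult", "run_pipeline", "cohort_statistics", "render_report"]


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    failed_patients: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(vars(self), fh, indent=1, default=str)


@dataclass
class PipelineResult:
    parameters: pd.DataFrame
    clinical: pd.DataFrame
    tables: dict
    manifest: RunManifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_cohort_dir(indir: str | Path, config: PipelineConfig):
    """Read a cohort directory (synthetic or real) into memory."""
    indir = Path(indir)
    meta_path = indir / "cohort.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        extent = tuple(meta["slide_extent"])
    else:
        meta = {}
        extent = None
    clinical = read_clinical(indir / "clinical.csv")
    patients = {}
    checksums = {}
    failed = {}
    for pdir in sorted(p for p in indir.iterdir() if p.is_dir()):
        cells = pdir / "cells.csv"
        ann = pdir / "annotation.geojson"
        if not cells.exists() or not ann.exists():
            continue
        try:
            pe = extent
            if pe is None:
                df = pd.read_csv(cells)
                pad = 100.0
                pe = (
                    df.x_um.min() - pad, df.y_um.min() - pad,
                    df.x_um.max() + pad, df.y_um.max() + pad,
                )
            slides, n_rej = read_cell_table(cells, pe, resolution=config.resolution)
            annotation = read_annotation(ann, im_width=config.im_width)
        except Exception as err:  # noqa: BLE001 - per-patient isolation
            failed[pdir.name] = repr(err)
            warnings.warn(f"patient {pdir.name} failed to load: {err!r}", stacklevel=2)
            continue
        patients[pdir.name] = {
            "slides": slides,
            "annotation": annotation,
            "extent": pe,
            "rejected_rows": n_rej,
        }
        checksums[str(cells.relative_to(indir))] = _sha256(cells)
        checksums[str(ann.relative_to(indir))] = _sha256(ann)
    checksums["clinical.csv"] = _sha256(indir / "clinical.csv")
    return patients, clinical, checksums, failed


def register_patient(
    slides: dict[str, MarkerPointPattern], config: PipelineConfig
) -> dict[str, MarkerPointPattern]:
    """Align one patient's slide stack to its middle (or configured) slide."""
    ordered = [m for m in config.markers if m in slides]
    stack = [slides[m] for m in ordered]
    results = align_to_reference(
        stack,
        reference_index=config.reference_index,
        target_side=config.target_side,
        sigma=config.raster_sigma,
        nonrigid=config.nonrigid,
    )
    return {m: r.transformed for m, r in zip(ordered, results)}


def quantify_patient(
    slides: dict[str, MarkerPointPattern],
    annotation: RegionAnnotation,
    extent: tuple[float, float, float, float],
    config: PipelineConfig,
) -> dict[str, float]:
    positives = {m: p.positive_pattern() for m, p in slides.items()}
    return parameter_vector(
        positives, annotation, extent,
        resolution=config.resolution,
        tile_side=config.tile_side,
        im_side=config.im_side,
        disjoint_regions=config.disjoint_regions,
        mh_tile_side=config.mh_tile_side,
    )


def _fdr(p: pd.Series) -> pd.Series:
    from scipy.stats import false_discovery_control

    ok = p.notna()
    out = pd.Series(np.nan, index=p.index)
    if ok.sum():
        out[ok] = false_discovery_control(p[ok].to_numpy(), method="bh")
    return out


def _univariate_table(
    parameters: pd.DataFrame, clinical: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """ROC-cutoff dichotomization + log-rank per parameter per endpoint."""
    rows = {}
    endpoints = {"DFS": ("dfs_months", "dfs_event"), "OS": ("os_months", "os_event")}
    for param in parameters.columns:
        if param == "Immunoscore_category":
            continue
        row = {}
        for name, (tcol, ecol) in endpoints.items():
            merged = pd.concat(
                [parameters[param], clinical[[tcol, ecol]]], axis=1, join="inner"
            ).dropna()
            try:
                cut = roc_cutoff(merged[param].to_numpy(), merged[ecol].to_numpy())
                strata = np.where(merged[param].to_numpy() > cut.threshold, "high", "low")
                if len(np.unique(strata)) < 2:
                    raise ValueError("degenerate dichotomization")
                km = km_logrank(merged[tcol].to_numpy(), merged[ecol].to_numpy(), strata)
                row[f"{name}_cutoff"] = cut.threshold
                row[f"{name}_p"] = km.p_value
            except ValueError as err:
                row[f"{name}_cutoff"] = np.nan
                row[f"{name}_p"] = np.nan
                warnings.warn(f"univariate {param}/{name}: {err}", stacklevel=2)
        rows[param] = row
    table = pd.DataFrame(rows).T
    if config.fdr:
        for name in endpoints:
            table[f"{name}_p_fdr"] = _fdr(table[f"{name}_p"])
    return table


def _cox_tables(
    parameters: pd.DataFrame, clinical: pd.DataFrame, univariate: pd.DataFrame,
    config: PipelineConfig,
) -> dict[str, pd.DataFrame]:
    """Tables of multivariate Cox p-values for DFS and OS.

    Clinical covariate rows come from the covariates-only model; each
    parameter significant in the corresponding univariate analysis is then
    added (as its ROC-dichotomized indicator) to the covariates in its own
    model and reported with its Wald p.
    """
    design = clinical_design_matrix(clinical, ki67_threshold=config.ki67_threshold)
    out = {}
    for name, (tcol, ecol) in {"DFS": ("dfs_months", "dfs_event"), "OS": ("os_months", "os_event")}.items():
        base = pd.concat([clinical[[tcol, ecol]], design], axis=1).dropna()
        rows = []
        try:
            res = cox_multivariate(base, tcol, ecol)
            for cov in design.columns:
                rows.append((cov, float(res.summary.loc[cov, "p"]), res.converged))
        except ValueError as err:
            warnings.warn(f"Cox base model ({name}): {err}", stacklevel=2)
            for cov in design.columns:
                rows.append((cov, np.nan, False))
        sig = univariate.index[univariate[f"{name}_p"] < config.alpha]
        for param in sig:
            cut = univariate.loc[param, f"{name}_cutoff"]
            indicator = (parameters[param] > cut).astype(float).rename("param_high")
            data = pd.concat([clinical[[tcol, ecol]], design, indicator], axis=1).dropna()
            try:
                res = cox_multivariate(data, tcol, ecol)
                rows.append((param, float(res.summary.loc["param_high", "p"]), res.converged))
            except ValueError as err:
                warnings.warn(f"Cox {param} ({name}): {err}", stacklevel=2)
                rows.append((param, np.nan, False))
        out[name] = pd.DataFrame(rows, columns=["parameter", "p", "converged"]).set_index("parameter")
    return out


def cohort_statistics(
    parameters: pd.DataFrame, clinical: pd.DataFrame, config: PipelineConfig
) -> dict[str, pd.DataFrame]:
    """The full statistical layer on an assembled parameter table."""
    params = parameters[[c for c in parameters.columns if c != "Immunoscore_category"]]
    common = params.index.intersection(clinical.index)
    if len(common) < 2:
        raise ValueError("fewer than 2 evaluable patients; statistics skipped")
    params = params.loc[common]
    clin = clinical.loc[common]

    er = compare_groups(params, clin["recurrence"], ("ER", "LR"),
                        equal_var=not config.welch, alpha=config.alpha)
    dm = compare_groups(params, clin["metastasis"], ("DM", "non-DM"),
                        equal_var=not config.welch, alpha=config.alpha)
    group = pd.DataFrame(
        {"ER_LR_p": er.table["p"], "DM_nonDM_p": dm.table["p"]}, index=params.columns
    )
    if config.fdr:
        group["ER_LR_p_fdr"] = _fdr(group["ER_LR_p"])
        group["DM_nonDM_p_fdr"] = _fdr(group["DM_nonDM_p"])

    uni_all = _univariate_table(params, clin, config)
    tables = {"group_comparison": group, "univariate_all": uni_all}

    late = stage_subset(clin, rule=config.stage_subset_rule)
    if len(late) >= 2 and late["dfs_event"].sum() >= 1:
        tables["univariate_late"] = _univariate_table(params.loc[late.index], late, config)
    else:
        warnings.warn("advanced-stage subset too small; late-stage tables skipped", stacklevel=2)

    cox = _cox_tables(params, clin, uni_all, config)
    tables["cox_dfs"] = cox["DFS"]
    tables["cox_os"] = cox["OS"]
    return tables


def run_pipeline(
    source, config: PipelineConfig | None = None, outdir: str | Path | None = None,
    register: bool = True,
) -> PipelineResult:
    """Run the full pipeline on a cohort directory or in-memory cohort.

    ``source`` is either a path to a cohort directory (``clinical.csv``
    plus per-patient ``cells.csv`` / ``annotation.geojson``) or a
    :class:`spatimm.synthetic.Cohort`.  Writes ``parameters.tsv``, the
    statistics TSVs, ``config.yaml`` and ``manifest.json`` to ``outdir``
    when given.
    """
    config = config or PipelineConfig()
    manifest = RunManifest(config=vars(config) | {"markers": list(config.markers)})
    t0 = time.perf_counter()

    if isinstance(source, (str, Path)):
        patients, clinical, checksums, failed = load_cohort_dir(source, config)
        manifest.input_checksums = checksums
        manifest.failed_patients.update(failed)
    else:  # in-memory synthetic Cohort
        from .stats import records_to_frame

        clinical = records_to_frame([p.clinical for p in source.patients])
        patients = {
            p.patient_id: {
                "slides": p.slides,
                "annotation": RegionAnnotation.from_polygon(
                    _annotation_in_reference_frame(p, source.spec), im_width=config.im_width
                ),
                "extent": source.spec.slide_extent,
                "rejected_rows": 0,
            }
            for p in source.patients
        }
    manifest.timings_s["load"] = time.perf_counter() - t0

    for pid, data in patients.items():
        if data.get("rejected_rows"):
            manifest.warnings.append(f"{pid}: {data['rejected_rows']} malformed cell row(s) rejected")

    rows = {}
    t0 = time.perf_counter()
    treg = 0.0
    for pid, data in patients.items():
        try:
            t1 = time.perf_counter()
            slides = register_patient(data["slides"], config) if register else data["slides"]
            treg += time.perf_counter() - t1
            rows[pid] = quantify_patient(slides, data["annotation"], data["extent"], config)
        except Exception as err:  # noqa: BLE001 - per-patient isolation is the contract
            manifest.failed_patients[pid] = repr(err)
            warnings.warn(f"patient {pid} failed and is excluded: {err!r}", stacklevel=2)
    manifest.timings_s["register"] = treg
    manifest.timings_s["quantify"] = time.perf_counter() - t0 - treg
    parameters = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=parameter_columns())
    parameters.index.name = "patient_id"
    if len(parameters) < 2:
        raise ValueError("fewer than 2 evaluable patients; statistics skipped")

    t0 = time.perf_counter()
    scored = cohort_immunoscore(
        parameters, boundary=config.immunoscore_boundary, method=config.percentile_method
    )
    parameters["Immunoscore"] = scored["Immunoscore"]
    parameters["Immunoscore_category"] = scored["Immunoscore_category"]
    manifest.timings_s["immunoscore"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tables = cohort_statistics(parameters, clinical, config)
    manifest.timings_s["stats"] = time.perf_counter() - t0

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        parameters.to_csv(outdir / "parameters.tsv", sep="\t")
        clinical.to_csv(outdir / "clinical_used.tsv", sep="\t")
        for name, table in tables.items():
            table.to_csv(outdir / f"{name}.tsv", sep="\t")
        config.to_yaml(outdir / "config.yaml")
        manifest.write(outdir / "manifest.json")
    return PipelineResult(parameters, clinical, tables, manifest)


def _annotation_in_reference_frame(patient, spec):
    from .io import _transform_polygon

    markers = list(spec.markers)
    ref_marker = markers[len(markers) // 2]
    return _transform_polygon(patient.geometry.tc_polygon, patient.transforms[ref_marker])


def render_report(outdir: str | Path, plots: bool = True, alpha: float = 0.05) -> Path:
    """Human-readable summary of a pipeline run directory.

    Writes ``report.md`` with per-table significant-parameter counts and,
    when ``plots`` is on, Kaplan–Meier figures for each parameter
    significant in the all-patient univariate analysis.
    """
    outdir = Path(outdir)
    lines = ["# Spatial immune-profiling report", ""]
    tables = {}
    for name in ("group_comparison", "univariate_all", "univariate_late", "cox_dfs", "cox_os"):
        path = outdir / f"{name}.tsv"
        if path.exists():
            tables[name] = pd.read_csv(path, sep="\t", index_col=0)
    if not tables:
        lines.append("no evaluable parameters")
    for name, table in tables.items():
        pcols = [c for c in table.columns if c.endswith("_p") or c == "p"]
        lines.append(f"## {name}")
        lines.append("")
        for c in pcols:
            nsig = int((table[c] < alpha).sum())
            lines.append(f"- `{c}`: {nsig} of {table[c].notna().sum()} parameters with p < {alpha}")
        lines.append("")
    if plots and "univariate_all" in tables:
        _km_plots(outdir, tables["univariate_all"], alpha, lines)
    report = outdir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report


def _km_plots(outdir: Path, univariate: pd.DataFrame, alpha: float, lines: list) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    params_path = outdir / "parameters.tsv"
    clin_path = outdir / "clinical_used.tsv"
    if not params_path.exists() or not clin_path.exists():
        lines.append("(plots skipped: run tables not found)")
        return
    parameters = pd.read_csv(params_path, sep="\t", index_col=0)
    clinical = pd.read_csv(clin_path, sep="\t", index_col=0)
    plot_dir = outdir / "plots"
    plot_dir.mkdir(exist_ok=True)
    for name, (tcol, ecol) in {"DFS": ("dfs_months", "dfs_event"), "OS": ("os_months", "os_event")}.items():
        sig = univariate.index[univariate[f"{name}_p"] < alpha]
        for param in sig:
            cut = univariate.loc[param, f"{name}_cutoff"]
            merged = pd.concat([parameters[param], clinical[[tcol, ecol]]], axis=1).dropna()
            high = merged[param] > cut
            fig, ax = plt.subplots(figsize=(4, 3))
            for label, mask in (("high", high), ("low", ~high)):
                if mask.sum() == 0:
                    continue
                KaplanMeierFitter().fit(
                    merged.loc[mask, tcol], merged.loc[mask, ecol], label=label
                ).plot_survival_function(ax=ax)
            ax.set_title(f"{param} ({name}, p={univariate.loc[param, f'{name}_p']:.4f})")
            ax.set_xlabel("months")
            ax.set_ylabel("survival")
            fig.tight_layout()
            safe = param.replace("+", "plus").replace("/", "_")
            fig.savefig(plot_dir / f"{name}_{safe}.png", dpi=100)
            plt.close(fig)
    lines.append(f"KM plots written to {plot_dir.name}/")
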