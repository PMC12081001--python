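"""End-to-end pipeline: simulate-or-load → QC → cluster → markers →
lineage / sex → programs → TF codes → identity mapping.

The pipeline is driven by a JSON-compatible nested config; unknown keys are
rejected (no silent typo acceptance) and every threshold is range-checked.
All randomness flows from one root seed expanded into per-stage seeds, which
are recorded in the report.  Every artifact is written as TSV/JSON under the
output directory; a failure at any stage leaves the partial outputs plus a
MANIFEST naming the failed stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import cluster_cells, embed_pca
from .identity import (
    annotate_by_marker_panel,
    assign_identity_by_max,
    cluster_mean_profiles,
    correlate_bulk,
    select_marker_positive_clusters,
)
from .io import TF_CLASSES, read_mtx_bundle, write_json, write_tables
from .lineage import assign_lineage
from .markers import rank_markers, top_markers
from .programs import (
    classify_neurotransmitters,
    coexpression_counts,
    select_cluster_defining_np,
    tf_np_correlation,
)
from .qc import (
    NormalizedMatrix,
    compute_cell_qc,
    filter_cells,
    log_normalize,
    scale_genes,
    scaled_average_expression,
    select_hvgs,
)
from .sexdiff import pseudobulk_sex_de, sex_bias_clusters
from .simulate import (
    PAN_GLIAL,
    SimulationConfig,
    generate_atlas,
    generate_bulk_reference,
    save_atlas,
)
from .tfcodes import (
    binarize_tf_markers,
    count_unique_codes,
    jaccard_matrix,
    order_by_similarity,
    shared_code_groups,
)

__all__ = [
    "ConfigError",
    "PipelineError",
    "validate_config",
    "run_pipeline",
    "default_config",
    "recovery_config",
]

log = logging.getLogger("t2atlas")


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_SCHEMA = {
    "input": dict,
    "qc": {"min_genes": (int, 0, 1_000_000), "max_genes": (int, 0, 10_000_000), "max_pct_mito": (float, 0.0, 100.0)},
    "normalization": {"scale_factor": (float, 1e-12, 1e12)},
    "clustering": {
        "n_hvg": (int, 0, 1_000_000),
        "n_components": (int, 1, 10_000),
        "k_neighbors": (int, 1, 10_000),
        "resolution": (float, 1e-9, 1e6),
    },
    "markers": {"min_pct": (float, 0.0, 1.0), "min_log2fc": (float, 0.0, 100.0), "alpha": (float, 0.0, 1.0)},
    "nt": {"threshold": (float, -100.0, 100.0), "scale": (str,)},
    "np": {"max_clusters": (int, 1, 10_000), "alpha": (float, 0.0, 1.0), "min_log2fc": (float, 0.0, 100.0)},
    "tf": {"alpha": (float, 0.0, 1.0)},
    "sex": {"alpha": (float, 0.0, 1.0), "min_abs_log2_ratio": (float, 0.0, 100.0)},
    "identity": {"n_variable": (int, 3, 1_000_000), "bulk_noise_sd": (float, 0.0, 100.0), "n_bulk_references": (int, 0, 10_000)},
    "glia": {"marker": (str,), "min_mean": (float, 0.0, 100.0), "min_pct": (float, 0.0, 1.0), "min_positive_frac": (float, 0.0, 1.0)},
    "seed": (int, 0, 2**31 - 1),
    "out_dir": (str,),
}


def default_config() -> dict:
    return {
        "input": {"simulate": {}},
        "qc": {"min_genes": 200, "max_genes": 2500, "max_pct_mito": 5.0},
        "normalization": {"scale_factor": 1e4},
        "clustering": {"n_hvg": 1000, "n_components": 50, "k_neighbors": 15, "resolution": 1.0},
        "markers": {"min_pct": 0.1, "min_log2fc": 0.25, "alpha": 0.05},
        "nt": {"threshold": 2.0, "scale": "lognorm"},
        "np": {"max_clusters": 5, "alpha": 0.05, "min_log2fc": 1.0},
        "tf": {"alpha": 0.05},
        "sex": {"alpha": 0.05, "min_abs_log2_ratio": 1.0},
        "identity": {"n_variable": 2000, "bulk_noise_sd": 0.1, "n_bulk_references": 3},
        "glia": {"marker": PAN_GLIAL, "min_mean": 1.0, "min_pct": 0.5, "min_positive_frac": 0.5},
        "seed": 0,
        "out_dir": "t2atlas_out",
    }


def recovery_config(seed: int = 0) -> dict:
    """The parameter-recovery configuration: 30 planted clusters × ~300
    cells (9,000 cells, 2,000 genes, female / male / mixed samples, 3
    sex-biased clusters) analyzed with 700 HVGs and Leiden resolution 4.0.

    The analysis parameters come from a design-stage sweep: with sparse
    TF-code programs, restricting PCA to ~700 variable genes keeps the code
    signal above the random-matrix noise floor, and resolution 4.0 resolves
    all 30 communities at ~300 cells each without over-splitting.
    """
    cfg = default_config()
    cfg["input"] = {
        "simulate": {
            "samples": [
                ["female_1", "female", 3000],
                ["male_1", "male", 3000],
                ["mixed_1", "mixed", 3000],
            ],
            "n_clusters": 30,
            "n_genes": 2000,
            "de_log2fc": 2.0,
            "sex_bias_program": {5: "male", 11: "female", 17: "male"},
        }
    }
    cfg["clustering"] = {"n_hvg": 700, "n_components": 50, "k_neighbors": 15, "resolution": 4.0}
    cfg["seed"] = seed
    return cfg


def _check_section(name, schema, section, errors):
    for key, value in section.items():
        if key not in schema:
            errors.append(f"{name}.{key}: unknown key")
            continue
        rule = schema[key]
        if rule[0] is int and isinstance(value, bool):
            errors.append(f"{name}.{key}: expected int, got bool")
            continue
        if rule[0] is float and isinstance(value, int) and not isinstance(value, bool):
            value = float(value)
        if not isinstance(value, rule[0]):
            errors.append(f"{name}.{key}: expected {rule[0].__name__}, got {type(value).__name__}")
            continue
        if len(rule) == 3 and not (rule[1] <= value <= rule[2]):
            errors.append(f"{name}.{key}: value {value} outside [{rule[1]}, {rule[2]}]")


def validate_config(config) -> dict:
    """Parse + range-check a config (dict or path); unknown keys are errors.

    Returns the fully-defaulted config dict, or raises :class:`ConfigError`
    listing every problem with its key path.
    """
    if isinstance(config, (str, Path)):
        try:
            config = json.loads(Path(config).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config: {exc}") from exc
    errors: list = []
    merged = default_config()
    for key, value in config.items():
        if key not in _SCHEMA:
            errors.append(f"{key}: unknown key")
            continue
        if key == "input":
            if not isinstance(value, dict) or set(value) - {"simulate", "load"} or len(value) != 1:
                errors.append("input: must be {'simulate': {...}} or {'load': {...}}")
            else:
                merged["input"] = value
        elif isinstance(_SCHEMA[key], dict):
            if not isinstance(value, dict):
                errors.append(f"{key}: expected a section object")
            else:
                _check_section(key, _SCHEMA[key], value, errors)
                merged[key] = {**merged[key], **value}
        else:
            _check_section("", {key: _SCHEMA[key]}, {key: value}, errors)
            merged[key] = value

    if "simulate" in merged["input"]:
        sim = merged["input"]["simulate"]
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        for key in sim:
            if key not in known:
                errors.append(f"input.simulate.{key}: unknown key")
    elif "load" in merged["input"]:
        load = merged["input"]["load"]
        for key in load:
            if key not in {"bundle", "metadata", "orientation"}:
                errors.append(f"input.load.{key}: unknown key")
        if "bundle" not in load:
            errors.append("input.load.bundle: required")
    if merged["nt"]["scale"] not in ("lognorm", "scaled"):
        errors.append("nt.scale: must be 'lognorm' or 'scaled'")
    if errors:
        raise ConfigError("; ".join(errors))
    return merged


def _stage(report, name):
    log.info("stage %s", name)
    report["stages"].append(name)
    return time.time()


def run_pipeline(config, out_dir=None) -> dict:
    """Execute every stage and return the report dict (also written as JSON)."""
    config = validate_config(config if isinstance(config, dict) else config)
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config["seed"])
    seeds = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in zip(
        ("simulate", "pca", "leiden", "bulk"), root.spawn(4)
    )}
    report = {
        "version": __version__,
        "config": config,
        "seed": config["seed"],
        "stage_seeds": seeds,
        "stages": [],
        "counts": {},
        "timings": {},
    }
    stage = "setup"
    try:
        # ------------------------------------------------ input
        stage = "input"
        t0 = _stage(report, stage)
        truth = None
        if "simulate" in config["input"]:
            sim_kwargs = dict(config["input"]["simulate"])
            sim_kwargs.setdefault("seed", seeds["simulate"])
            if "samples" in sim_kwargs:
                sim_kwargs["samples"] = [tuple(s) for s in sim_kwargs["samples"]]
            if "sex_bias_program" in sim_kwargs:
                sim_kwargs["sex_bias_program"] = {
                    int(c): s for c, s in sim_kwargs["sex_bias_program"].items()
                }
            sim_config = SimulationConfig(**sim_kwargs)
            matrix, annotation, gene_ann, truth = generate_atlas(sim_config)
            save_atlas(matrix, annotation, gene_ann, truth, out / "atlas")
        else:
            load = config["input"]["load"]
            matrix, gene_ann = read_mtx_bundle(
                load["bundle"], orientation=load.get("orientation", "genes_by_cells")
            )
            if gene_ann is None:
                raise ValueError("bundle lacks gene_annotation.tsv; annotation required")
            meta_path = load.get("metadata", str(Path(load["bundle"]) / "metadata.tsv"))
            annotation = pd.read_csv(meta_path, sep="\t", index_col="cell_id")
        report["counts"]["cells_loaded"] = matrix.n_cells
        report["counts"]["genes"] = matrix.n_genes
        report["timings"][stage] = time.time() - t0

        # ------------------------------------------------ qc
        stage = "qc"
        t0 = _stage(report, stage)
        qc_table = compute_cell_qc(matrix, gene_ann)
        filtered = filter_cells(matrix, qc_table, **config["qc"])
        if filtered.n_cells == 0:
            raise ValueError("QC filter removed every cell")
        qc_out = qc_table.copy()
        qc_out["passed"] = qc_out.index.isin(filtered.cell_ids)
        write_tables({"qc": qc_out.reset_index()}, out)
        annotation = annotation.loc[filtered.cell_ids]
        report["counts"]["cells_filtered_out"] = matrix.n_cells - filtered.n_cells
        report["counts"]["cells_kept"] = filtered.n_cells
        report["timings"][stage] = time.time() - t0

        # ------------------------------------------------ lineage
        stage = "lineage"
        t0 = _stage(report, stage)
        lineage = assign_lineage(filtered, gene_ann)
        annotation = annotation.assign(lineage=lineage)
        report["counts"]["n_T2"] = int((lineage == "T2").sum())
        report["counts"]["n_T1"] = int((lineage == "T1").sum())
        report["timings"][stage] = time.time() - t0

        # ------------------------------------------------ normalize + cluster
        stage = "cluster"
        t0 = _stage(report, stage)
        norm = log_normalize(filtered, config["normalization"]["scale_factor"])
        hvg_idx = select_hvgs(norm, n_top=config["clustering"]["n_hvg"])
        scaled = scale_genes(
            NormalizedMatrix(norm.X[:, hvg_idx], norm.cell_ids, norm.gene_ids[hvg_idx], norm.scale_factor)
        )
        n_comp = min(config["clustering"]["n_components"], scaled.shape[0] - 1, scaled.shape[1] - 1)
        emb = embed_pca(scaled, n_components=n_comp, seed=seeds["pca"])
        clusters = cluster_cells(
            emb,
            k_neighbors=config["clustering"]["k_neighbors"],
            resolution=config["clustering"]["resolution"],
            seed=seeds["leiden"],
        )
        clusters.index = norm.cell_ids
        annotation = annotation.assign(cluster=clusters)
        annotation.index.name = "cell_id"
        write_tables({"clusters": annotation.reset_index()}, out)
        report["counts"]["n_clusters"] = int(clusters.nunique())
        report["timings"][stage] = time.time() - t0

        # ------------------------------------------------ markers
        stage = "markers"
        t0 = _stage(report, stage)
        mk = config["markers"]
        marker_table = rank_markers(norm, clusters, min_pct=mk["min_pct"], min_log2fc=mk["min_log2fc"])
        write_tables({"markers": marker_table}, out)
        tops = top_markers(marker_table, n=10) if not marker_table.empty else {}
        report["top_markers"] = {str(c): genes[:5] for c, genes in tops.items()}
        report["timings"][stage] = time.time() - t0

        # ------------------------------------------------ neurotransmitters
        stage = "neurotransmitters"
        t0 = _stage(report, stage)
        profile = classify_neurotransmitters(
            norm, gene_ann, threshold=config["nt"]["threshold"], scale=config["nt"]["scale"]
        )
        upset = coexpression_counts(profile)
        write_tables({"nt_profile": profile.reset_index(), "upset_counts": upset}, out)
        report["nt_combinations"] = upset.set_index("combination")["count"].to_dict()
        report["timings"][stage] = time.time() - t0

        # ------------------------------------------------ neuropeptides
        stage = "neuropeptides"
        t0 = _stage(report, stage)
        np_cfg = config["np"]
        np_map = select_cluster_defining_np(
            marker_table, gene_ann, max_clusters=np_cfg["max_clusters"],
            alpha=np_cfg["alpha"], min_log2fc=np_cfg["min_log2fc"],
        )
        corr, np_top = tf_np_correlation(norm, gene_ann)
        write_tables(
            {
                "np_clusters": pd.DataFrame(
                    [(g, ";".join(map(str, cs))) for g, cs in sorted(np_map.items())],
                    columns=["neuropeptide", "clusters"],
                ),
                "tf_np_corr": corr.reset_index(),
            },
            out,
        )
        report["cluster_defining_np"] = {g: list(map(int, cs)) for g, cs in np_map.items()}
        report["np_top_tfs"] = {g: v for g, v in np_top.items() if v is not None}
        report["timings"][stage] = time.time() - t0

        # ------------------------------------------------ tf codes
        stage = "tf_codes"
        t0 = _stage(report, stage)
        uniqueness = {}
        for cls in TF_CLASSES:
            code = binarize_tf_markers(
                marker_table, gene_ann, cls,
                cluster_ids=sorted(clusters.unique()), alpha=config["tf"]["alpha"],
            )
            n_unique, pct = count_unique_codes(code)
            groups = shared_code_groups(code)
            jac = jaccard_matrix(code)
            order = order_by_similarity(jac) if len(jac) > 1 else list(jac.index)
            uniqueness[cls] = {
                "n_unique": n_unique,
                "pct_unique": pct,
                "shared_groups": [list(map(int, g)) for g in groups],
                "heatmap_order": list(map(int, order)),
            }
            write_tables(
                {f"binary_code_{cls}": code.to_frame().reset_index(names="cluster"),
                 f"jaccard_{cls}": jac.reset_index(names="cluster")},
                out,
            )
        write_json(uniqueness, out / "uniqueness_report.json")
        report["tf_uniqueness"] = {
            cls: {"n_unique": u["n_unique"], "pct_unique": u["pct_unique"]}
            for cls, u in uniqueness.items()
        }
        report["timings"][stage] = time.time() - t0

        # ------------------------------------------------ sex
        stage = "sex"
        t0 = _stage(report, stage)
        sexes = set(annotation["sex"])
        if {"female", "male"} <= sexes:
            bias = sex_bias_clusters(
                annotation, clusters,
                alpha=config["sex"]["alpha"],
                min_abs_log2_ratio=config["sex"]["min_abs_log2_ratio"],
            )
            write_tables({"sex_bias": bias}, out)
            report["sex_biased_clusters"] = {
                str(int(r["cluster"])): r["biased"]
                for _, r in bias.iterrows() if r["biased"] != "none"
            }
            try:
                pseudo = pseudobulk_sex_de(filtered, annotation, clusters)
                write_tables({"pseudobulk_de": pseudo.stats}, out)
                top_f = pseudo.stats.nlargest(5, "mean_log2fc")["gene"].tolist()
                top_m = pseudo.stats.nsmallest(5, "mean_log2fc")["gene"].tolist()
                report["sex_de_top_female"] = top_f
                report["sex_de_top_male"] = top_m
            except ValueError as exc:
                report["sex_de_skipped"] = str(exc)
        else:
            report["sex_skipped"] = f"need female and male samples, have {sorted(sexes)}"
        report["timings"][stage] = time.time() - t0

        # ------------------------------------------------ glia
        stage = "glia"
        t0 = _stage(report, stage)
        gcfg = config["glia"]
        scaled_avg = scaled_average_expression(norm, clusters)
        if gcfg["marker"] in norm.gene_ids:
            glial = select_marker_positive_clusters(
                norm, clusters, gcfg["marker"],
                min_mean=gcfg["min_mean"], min_pct=gcfg["min_pct"],
            )
            panels = {
                s: list(gene_ann.index[gene_ann["glial_panel"] == s])
                for s in gene_ann["glial_panel"].unique()
                if s not in ("none", "pan_glial")
            }
            labels = (
                annotate_by_marker_panel(
                    scaled_avg.loc[glial], panels, min_positive_frac=gcfg["min_positive_frac"]
                )
                if glial and panels
                else {}
            )
            report["glial_clusters"] = {str(int(c)): labels.get(c, "unannotated") for c in glial}
        else:
            report["glia_skipped"] = f"marker {gcfg['marker']!r} absent"
        report["timings"][stage] = time.time() - t0

        # ------------------------------------------------ identity
        stage = "identity"
        t0 = _stage(report, stage)
        icfg = config["identity"]
        profiles = cluster_mean_profiles(norm, clusters)
        if truth is not None and icfg["n_bulk_references"] > 0:
            # reference profiles built from planted clusters via derived labels
            chosen_derived = sorted(clusters.unique())[: icfg["n_bulk_references"]]
            from .simulate import SyntheticTruth  # local: reuse profile+noise machinery

            ref_truth = SyntheticTruth(
                cell_cluster=clusters, cell_lineage=truth.cell_lineage,
                cell_sex=truth.cell_sex, cell_sex_program=truth.cell_sex_program,
                planted_codes={}, planted_nt={}, planted_np={}, planted_bias=set(),
                gene_roles=gene_ann, glial_clusters=[], glial_subtype={},
            )
            reference = generate_bulk_reference(
                norm, ref_truth, chosen_derived,
                noise_sd=icfg["bulk_noise_sd"], seed=seeds["bulk"],
            )
            coef = correlate_bulk(profiles, reference, n_variable=icfg["n_variable"])
            assignments = assign_identity_by_max(coef)
            write_tables({"assignments": assignments}, out)
            report["identity_assignments"] = {
                str(int(r["cluster"])): r["neuron_type"]
                for _, r in assignments.iterrows() if r["neuron_type"]
            }
        report["timings"][stage] = time.time() - t0

        write_json(report, out / "report.json")
        (out / "MANIFEST").write_text("complete\n")
        return report
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        (out / "MANIFEST").write_text(f"incomplete: failed at stage {stage}: {exc}\n")
        write_json(report, out / "report.json")
        raise PipelineError(stage, exc) from exc
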