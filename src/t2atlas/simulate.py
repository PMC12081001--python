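"""Synthetic snRNA-seq atlas generator with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: ~N neuronal clusters plus a minority of glial clusters, negative
binomial counts (mean/inverse-dispersion parameterization, variance
``mu + mu^2 / theta``) on lognormal per-cell depths, permanent-lineage
transgene labels (FLP/GFP/RFP detectable only in T2 cells), female / male /
mixed samples with sex-marker programs (yp1/2/3 and dsx female;
lncRNA:roX1/2 and fru male), one marker gene per fast-acting
neurotransmitter system, cluster-defining neuropeptides, per-class TF
combinatorial codes, and glial marker panels behind the pan-glial gene repo.

Two effect-size regimes coexist deliberately: combinatorial TF programs use
a moderate ``de_log2fc`` (recoverable only statistically), while identity
programs — neurotransmitter, neuropeptide, glial and sex markers — use a
strong ``marker_log2fc`` over a low off-state baseline, because their real
counterparts are high-dynamic-range genes whose thresholded detection the
analyses rely on.  Mixed-sex samples draw cells 50/50 from the female and
male expression programs but are labeled ``sex="mixed"``, mirroring pooled
sorting rounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    NT_ROLE_OF_GENE,
    TF_CLASSES,
    CountMatrix,
    make_gene_annotation,
    write_gene_annotation,
    write_mtx_bundle,
)
from .identity import BulkReference
from .qc import NormalizedMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_atlas",
    "generate_bulk_reference",
    "save_atlas",
    "load_truth",
]

TRANSGENES = ("FLP", "GFP", "RFP")
FEMALE_GENES = ("yp1", "yp2", "yp3", "dsx")
MALE_GENES = ("lncRNA:roX1", "lncRNA:roX2", "fru")
NT_GENES = tuple(NT_ROLE_OF_GENE)

#: 13 cluster-defining neuropeptide genes (real fly neuropeptide symbols).
NEUROPEPTIDES = (
    "AstA", "AstC", "CCAP", "Crz", "Dh31", "Dh44", "Lk",
    "Mip", "Ms", "NPF", "Proc", "Tk", "sNPF",
)

PAN_GLIAL = "repo"

DEFAULT_GLIAL_PANELS = {
    "astrocyte": ["alrm", "Gat", "Eaat1"],
    "cortex": ["wrapper", "Indy"],
    "ensheathing": ["zyd", "trol"],
    "astrocyte_like": ["CG9394", "Obp44a"],
    "perineurial": ["Tret1-1", "Pis"],
    "subperineurial": ["moody", "Mdr65"],
    "chiasm": ["Optix", "CG31235"],
}

#: Per-cell probabilities of carrying 0 / 1 / 2 neurotransmitter programs in
#: a freshly drawn cluster program (matches the rough prevalence structure of
#: adult central-brain atlases: ~40% of neurons below threshold for every
#: fast-acting system, most of the rest single-system).
NT_N_PROGRAM_P = (0.40, 0.48, 0.12)

#: Relative weights of the 7 systems when drawing cluster programs
#: (cholinergic most common, octopaminergic rarest).
NT_WEIGHTS = {
    "VAChT": 0.40,
    "VGlut": 0.25,
    "Gad1": 0.18,
    "Tbh": 0.07,
    "ple": 0.04,
    "SerT": 0.04,
    "Tdc2": 0.02,
}


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic atlas.  See the methods note for units."""

    n_genes: int = 2000
    n_clusters: int = 30
    cluster_proportions: object = "uniform"  # simplex vector or "uniform"
    depth_mean: float = 1000.0       # expected total counts per cell
    depth_shape: float = 0.35        # lognormal sigma of depth
    dispersion: float = 2.0          # NB inverse-dispersion theta
    baseline_logmean_sd: float = 1.0
    de_log2fc: float = 2.0           # TF-code program effect
    marker_log2fc: float = 11.0      # identity-program effect (NT/NP/glial panels)
    sex_effect_log2fc: float = 4.0   # sex-marker effect (yp/dsx vs roX/fru)
    frac_mito_genes: float = 0.05
    mito_rate_per_cell: float = 0.02
    samples: list = field(
        default_factory=lambda: [
            ("female_1", "female", 3000),
            ("male_1", "male", 3000),
            ("mixed_1", "mixed", 3000),
        ]
    )
    frac_t2: float = 0.5
    transgene_rate: float = 0.8      # per-transgene capture probability in T2 cells
    n_tf_per_class: dict = field(
        default_factory=lambda: {
            "zinc_finger": 40,
            "helix_turn_helix": 25,
            "homeodomain": 30,
            "basic_domain": 12,
            "unknown_dbd": 15,
            "hmg": 8,
        }
    )
    code_density: float = 0.3
    nt_program: dict | None = None   # cluster -> subset of NT marker genes
    np_program: dict | None = None   # cluster -> subset of neuropeptide genes
    sex_bias_program: dict = field(default_factory=dict)  # cluster -> enriched sex
    sex_bias_log2fc: float = 2.0
    frac_glial_clusters: float = 0.1
    glial_panels: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GLIAL_PANELS.items()})
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return sum(n for _, _, n in self.samples)

    def proportions(self) -> np.ndarray:
        if isinstance(self.cluster_proportions, str):
            if self.cluster_proportions != "uniform":
                raise InvalidConfigError(
                    f"unknown cluster_proportions {self.cluster_proportions!r}"
                )
            return np.full(self.n_clusters, 1.0 / self.n_clusters)
        p = np.asarray(self.cluster_proportions, dtype=float)
        if len(p) != self.n_clusters or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise InvalidConfigError("cluster_proportions must be a simplex vector of length n_clusters")
        return p

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise InvalidConfigError("n_cells and n_genes must be positive")
        if self.n_clusters <= 0:
            raise InvalidConfigError("n_clusters must be positive")
        for name in ("depth_mean", "depth_shape", "dispersion", "baseline_logmean_sd"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        for name in ("frac_mito_genes", "mito_rate_per_cell", "frac_t2", "transgene_rate", "code_density", "frac_glial_clusters"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        for sid, sex, n in self.samples:
            if sex not in ("female", "male", "mixed"):
                raise InvalidConfigError(f"sample {sid}: unknown sex {sex!r}")
            if n <= 0:
                raise InvalidConfigError(f"sample {sid}: n_cells must be positive")
        for c, s in self.sex_bias_program.items():
            if s not in ("female", "male"):
                raise InvalidConfigError(f"sex_bias_program[{c}] must be 'female' or 'male'")
            if not 0 <= c < self.n_clusters:
                raise InvalidConfigError(f"sex_bias_program references unknown cluster {c}")
        self.proportions()


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated atlas."""

    cell_cluster: pd.Series
    cell_lineage: pd.Series
    cell_sex: pd.Series          # the sample label: female / male / mixed
    cell_sex_program: pd.Series  # the expression program actually drawn
    planted_codes: dict          # tf_class -> clusters × TFs DataFrame of 0/1
    planted_nt: dict             # cluster -> tuple of NT marker genes
    planted_np: dict             # cluster -> tuple of neuropeptide genes
    planted_bias: set            # {(cluster, direction)}
    gene_roles: pd.DataFrame
    glial_clusters: list
    glial_subtype: dict          # glial cluster -> panel subtype
    bulk_types: dict = field(default_factory=dict)  # cluster -> synthetic neuron-type name


def _gene_universe(config: SimulationConfig) -> tuple[list, dict]:
    """Gene id list plus role structures; raises when n_genes is too small."""
    panels = config.glial_panels
    panel_genes = [g for genes in panels.values() for g in genes]
    tf_ids = {
        cls: [f"tf_{cls}_{i:02d}" for i in range(config.n_tf_per_class.get(cls, 0))]
        for cls in TF_CLASSES
    }
    named = (
        list(TRANSGENES)
        + list(NT_GENES)
        + list(FEMALE_GENES)
        + list(MALE_GENES)
        + list(NEUROPEPTIDES)
        + [PAN_GLIAL]
        + panel_genes
        + [t for ids in tf_ids.values() for t in ids]
    )
    if len(set(named)) != len(named):
        raise InvalidConfigError("duplicate gene names across programs")
    n_mito = int(round(config.frac_mito_genes * config.n_genes))
    mito = [f"mt:gene{i:03d}" for i in range(n_mito)]
    n_filler = config.n_genes - len(named) - n_mito
    if n_filler < 0:
        raise InvalidConfigError(
            f"n_genes={config.n_genes} too small for {len(named)} program genes "
            f"+ {n_mito} mito genes"
        )
    filler = [f"gene{i:04d}" for i in range(n_filler)]
    gene_ids = named + mito + filler
    return gene_ids, tf_ids


def _draw_programs(config: SimulationConfig, rng: np.random.Generator):
    """Planted TF codes, NT and NP programs, and glial cluster structure."""
    n_glial = int(round(config.frac_glial_clusters * config.n_clusters))
    glial_clusters = list(range(config.n_clusters - n_glial, config.n_clusters))
    neuronal = [c for c in range(config.n_clusters) if c not in glial_clusters]
    subtypes = list(config.glial_panels)
    glial_subtype = {
        c: subtypes[i % len(subtypes)] for i, c in enumerate(glial_clusters)
    }

    codes = {}
    for cls in TF_CLASSES:
        n_tf = config.n_tf_per_class.get(cls, 0)
        codes[cls] = (
            rng.random((config.n_clusters, n_tf)) < config.code_density
        ).astype(np.int8)

    nt_program = config.nt_program
    if nt_program is None:
        nt_program = {}
        genes = np.array(list(NT_WEIGHTS))
        w = np.array(list(NT_WEIGHTS.values()))
        w = w / w.sum()
        for c in neuronal:
            k = rng.choice(len(NT_N_PROGRAM_P), p=NT_N_PROGRAM_P)
            chosen = rng.choice(genes, size=k, replace=False, p=w)
            nt_program[c] = tuple(sorted(chosen))
        for c in glial_clusters:
            nt_program[c] = ()
    else:
        nt_program = {c: tuple(v) for c, v in nt_program.items()}
        for g in {g for v in nt_program.values() for g in v}:
            if g not in NT_GENES:
                raise InvalidConfigError(f"nt_program references unknown gene {g!r}")

    np_program = config.np_program
    if np_program is None:
        np_program = {c: [] for c in range(config.n_clusters)}
        for npep in NEUROPEPTIDES:
            k = int(rng.choice([1, 1, 1, 2]))  # most NPs define 1 cluster, some 2
            for c in rng.choice(neuronal, size=min(k, len(neuronal)), replace=False):
                np_program[int(c)].append(npep)
        np_program = {c: tuple(sorted(v)) for c, v in np_program.items()}
    else:
        np_program = {c: tuple(v) for c, v in np_program.items()}
        for g in {g for v in np_program.values() for g in v}:
            if g not in NEUROPEPTIDES:
                raise InvalidConfigError(f"np_program references unknown gene {g!r}")

    return codes, nt_program, np_program, glial_clusters, glial_subtype


def generate_atlas(config: SimulationConfig):
    """Generate one synthetic atlas.

    Returns ``(CountMatrix, CellAnnotation, GeneAnnotation, SyntheticTruth)``.
    Deterministic for a fixed config (all randomness flows from
    ``config.seed``).  T1 cells have exactly zero transgene counts.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_prog, rng_cells, rng_counts = (np.random.default_rng(s) for s in root.spawn(3))

    gene_ids, tf_ids = _gene_universe(config)
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)
    codes, nt_program, np_program, glial_clusters, glial_subtype = _draw_programs(
        config, rng_prog
    )

    # --- gene annotation -------------------------------------------------
    tf_class_of = {t: cls for cls, ids in tf_ids.items() for t in ids}
    nt_role = {g: NT_ROLE_OF_GENE[g] for g in NT_GENES}
    glial_panel_of = {PAN_GLIAL: "pan_glial"}
    for subtype, genes in config.glial_panels.items():
        for g in genes:
            glial_panel_of[g] = subtype
    gene_ann = make_gene_annotation(
        gene_ids,
        is_mito={g: g.startswith("mt:") for g in gene_ids},
        is_transgene={g: g in TRANSGENES for g in gene_ids},
        tf_class=tf_class_of,
        nt_role=nt_role,
        is_neuropeptide={g: g in NEUROPEPTIDES for g in gene_ids},
        glial_panel=glial_panel_of,
    )

    # --- baseline expression weights ------------------------------------
    # Relative expression weights (normalized per cell later).  Three regimes:
    # filler genes span a lognormal range; TF genes sit at a controlled
    # moderate baseline so the de_log2fc on-effect is statistically (not
    # trivially) recoverable; identity-program genes (NT / NP / glial panels)
    # are near-silent off and strongly on, like their real counterparts; sex
    # markers are low-but-nonzero in the other sex.
    base = np.exp(rng_prog.normal(0.0, config.baseline_logmean_sd, size=n_genes))
    for ids in tf_ids.values():
        for t in ids:
            base[gene_index[t]] = 2.0 * np.exp(rng_prog.normal(0.0, 0.25))
    identity_genes = set(NT_GENES) | set(NEUROPEPTIDES) | {PAN_GLIAL} | set(glial_panel_of)
    for g in identity_genes:
        base[gene_index[g]] = 0.02
    for g in FEMALE_GENES + MALE_GENES:
        base[gene_index[g]] = 0.05
    base[[gene_index[t] for t in TRANSGENES]] = 0.0  # transgenes drawn separately
    mito_mask = gene_ann["is_mito"].to_numpy()

    # --- cell-level structure -------------------------------------------
    cell_ids, sample_of, sex_label, sex_prog = [], [], [], []
    for sid, sex, n in config.samples:
        cell_ids += [f"{sid}_cell{i:05d}" for i in range(n)]
        sample_of += [sid] * n
        sex_label += [sex] * n
        if sex == "mixed":
            sex_prog += list(rng_cells.choice(["female", "male"], size=n))
        else:
            sex_prog += [sex] * n
    n_cells = len(cell_ids)
    sex_prog = np.array(sex_prog)

    p_base = config.proportions()
    bias = np.zeros(config.n_clusters)
    for c, s in config.sex_bias_program.items():
        bias[c] = config.sex_bias_log2fc / 2.0 * (1 if s == "male" else -1)
    cluster = np.empty(n_cells, dtype=int)
    for sex in ("female", "male"):
        mask = sex_prog == sex
        mult = np.exp2(bias if sex == "male" else -bias)
        p = p_base * mult
        p = p / p.sum()
        cluster[mask] = rng_cells.choice(config.n_clusters, size=int(mask.sum()), p=p)
    lineage = np.where(rng_cells.random(n_cells) < config.frac_t2, "T2", "T1")
    mu_depth = np.log(config.depth_mean) - config.depth_shape**2 / 2.0
    depth = rng_cells.lognormal(mu_depth, config.depth_shape, size=n_cells)

    # --- per-(cluster, sex-program) mean vectors ------------------------
    de = 2.0**config.de_log2fc
    marker = 2.0**config.marker_log2fc
    weights = {}
    for c in range(config.n_clusters):
        w = base.copy()
        for cls in TF_CLASSES:
            on = codes[cls][c].astype(bool)
            for t, flag in zip(tf_ids[cls], on):
                if flag:
                    w[gene_index[t]] *= de
        for g in nt_program.get(c, ()):
            w[gene_index[g]] *= marker
        for g in np_program.get(c, ()):
            w[gene_index[g]] *= marker
        if c in glial_clusters:
            w[gene_index[PAN_GLIAL]] *= marker
            for g in config.glial_panels[glial_subtype[c]]:
                w[gene_index[g]] *= marker
        sex_eff = 2.0**config.sex_effect_log2fc
        for sex, sex_genes in (("female", FEMALE_GENES), ("male", MALE_GENES)):
            ws = w.copy()
            for g in sex_genes:
                ws[gene_index[g]] *= sex_eff
            # pin the mitochondrial share of expected counts to the configured
            # per-cell rate after all program multipliers
            if mito_mask.any() and config.mito_rate_per_cell > 0:
                target = (
                    config.mito_rate_per_cell
                    / (1 - config.mito_rate_per_cell)
                    * ws[~mito_mask].sum()
                )
                ws[mito_mask] *= target / ws[mito_mask].sum()
            weights[(c, sex)] = ws / ws.sum()

    # --- negative binomial draw -----------------------------------------
    theta = config.dispersion
    blocks = []
    for key in sorted({(int(c), s) for c, s in zip(cluster, sex_prog)}):
        c, sex = key
        idx = np.flatnonzero((cluster == c) & (sex_prog == sex))
        mu = depth[idx, None] * weights[key][None, :]
        p_nb = theta / (theta + mu)
        counts = rng_counts.negative_binomial(theta, p_nb)
        blocks.append((idx, counts))
    rows, cols, vals = [], [], []
    for idx, counts in blocks:
        r, cix = np.nonzero(counts)
        rows.append(idx[r])
        cols.append(cix)
        vals.append(counts[r, cix])
    X = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_cells, n_genes),
        dtype=np.int64,
    )

    # --- transgene counts (T2 only, hard zero for T1) -------------------
    t2_mask = lineage == "T2"
    tg_cols = [gene_index[t] for t in TRANSGENES]
    tg = sp.lil_matrix((n_cells, n_genes), dtype=np.int64)
    t2_idx = np.flatnonzero(t2_mask)
    for j in tg_cols:
        detected = t2_idx[rng_counts.random(t2_idx.size) < config.transgene_rate]
        tg[detected, j] = 1 + rng_counts.poisson(0.7, size=detected.size)
    X = (X + tg.tocsr()).tocsr()

    matrix = CountMatrix(X, pd.Index(cell_ids), pd.Index(gene_ids))
    cell_index = pd.Index(cell_ids, name="cell_id")
    annotation = pd.DataFrame(
        {"sample": sample_of, "sex": sex_label}, index=cell_index
    )
    truth = SyntheticTruth(
        cell_cluster=pd.Series(cluster, index=cell_index, name="cluster"),
        cell_lineage=pd.Series(lineage, index=cell_index, name="lineage"),
        cell_sex=pd.Series(sex_label, index=cell_index, name="sex"),
        cell_sex_program=pd.Series(sex_prog, index=cell_index, name="sex_program"),
        planted_codes={
            cls: pd.DataFrame(codes[cls], index=range(config.n_clusters), columns=tf_ids[cls])
            for cls in TF_CLASSES
        },
        planted_nt={c: tuple(v) for c, v in nt_program.items()},
        planted_np={c: tuple(v) for c, v in np_program.items()},
        planted_bias={(c, s) for c, s in config.sex_bias_program.items()},
        gene_roles=gene_ann,
        glial_clusters=glial_clusters,
        glial_subtype=glial_subtype,
    )
    return matrix, annotation, gene_ann, truth


def generate_bulk_reference(
    norm: NormalizedMatrix,
    truth: SyntheticTruth,
    chosen_clusters: list,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> BulkReference:
    """Synthetic bulk RNA-seq profiles of chosen clusters.

    One profile per chosen cluster: the cluster's mean log-normalized
    expression plus iid Gaussian noise (sd ``noise_sd``) per gene, labeled
    with a synthetic neuron-type name recorded in ``truth.bulk_types``.
    """
    rng = np.random.default_rng(seed)
    labels = truth.cell_cluster.reindex(norm.cell_ids)
    rows = {}
    for c in chosen_clusters:
        mask = (labels == c).to_numpy()
        if not mask.any():
            raise ValueError(f"unknown or empty cluster {c!r}")
        mean = np.asarray(norm.X[mask].mean(axis=0)).ravel()
        name = f"neuron_type_c{c}"
        rows[name] = mean + rng.normal(0.0, noise_sd, size=mean.size)
        truth.bulk_types[c] = name
    profiles = pd.DataFrame.from_dict(rows, orient="index", columns=norm.gene_ids)
    profiles.index.name = "neuron_type"
    return BulkReference(profiles)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_atlas(matrix, annotation, gene_ann, truth, out_dir) -> None:
    """Write the 10x-style bundle plus metadata.tsv and truth.json."""
    out_dir = Path(out_dir)
    write_mtx_bundle(matrix, out_dir, gene_annotation=gene_ann)
    annotation.to_csv(out_dir / "metadata.tsv", sep="\t", index_label="cell_id")
    payload = {
        "cell_cluster": truth.cell_cluster.tolist(),
        "cell_lineage": truth.cell_lineage.tolist(),
        "cell_sex": truth.cell_sex.tolist(),
        "cell_sex_program": truth.cell_sex_program.tolist(),
        "planted_codes": {
            cls: {"clusters": df.index.tolist(), "tfs": df.columns.tolist(), "matrix": df.to_numpy().tolist()}
            for cls, df in truth.planted_codes.items()
        },
        "planted_nt": {str(c): list(v) for c, v in truth.planted_nt.items()},
        "planted_np": {str(c): list(v) for c, v in truth.planted_np.items()},
        "planted_bias": sorted([c, s] for c, s in truth.planted_bias),
        "glial_clusters": truth.glial_clusters,
        "glial_subtype": {str(c): s for c, s in truth.glial_subtype.items()},
        "bulk_types": {str(c): t for c, t in truth.bulk_types.items()},
        "cell_ids": truth.cell_cluster.index.tolist(),
    }
    (out_dir / "truth.json").write_text(json.dumps(payload))


def load_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    idx = pd.Index(payload["cell_ids"], name="cell_id")
    gene_roles = pd.DataFrame()  # gene annotation travels in the bundle
    return SyntheticTruth(
        cell_cluster=pd.Series(payload["cell_cluster"], index=idx, name="cluster"),
        cell_lineage=pd.Series(payload["cell_lineage"], index=idx, name="lineage"),
        cell_sex=pd.Series(payload["cell_sex"], index=idx, name="sex"),
        cell_sex_program=pd.Series(payload["cell_sex_program"], index=idx, name="sex_program"),
        planted_codes={
            cls: pd.DataFrame(d["matrix"], index=d["clusters"], columns=d["tfs"])
            for cls, d in payload["planted_codes"].items()
        },
        planted_nt={int(c): tuple(v) for c, v in payload["planted_nt"].items()},
        planted_np={int(c): tuple(v) for c, v in payload["planted_np"].items()},
        planted_bias={(c, s) for c, s in payload["planted_bias"]},
        gene_roles=gene_roles,
        glial_clusters=payload["glial_clusters"],
        glial_subtype={int(c): s for c, s in payload["glial_subtype"].items()},
        bulk_types={int(c): t for c, t in payload["bulk_types"].items()},
    )
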