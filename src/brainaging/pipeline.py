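"""End-to-end orchestration: synthesize -> spectra -> signatures -> enrichment
-> transcriptome, with a machine-readable report.

Every stage writes its outputs as plain files under the configured output
directory and records its key numbers in ``report.json``; seeds for every
random stage are taken from the single pipeline seed and echoed in the
report, so a re-run with the same config reproduces the report
bit-identically. Stages run in dependency order; a stage invoked without
its predecessors in the same run resumes from the files a previous run
left in the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as io
from . import synthetic_data as syn
from .errors import BrainAgingError, ConfigError, DataError
from .genomic_enrichment import (
    annotate_mutations,
    class_spectrum_test,
    enrichment,
    expression_quintiles,
    sample_matched_controls,
    snv_rate_by_length,
    strand_bias,
)
from .mutation_spectra import Spectrum96, build_spectrum, cosine_sim
from .signature_inference import (
    attribute_exposures,
    burden_age_regression,
    nmf_decompose,
    select_rank,
    spectra_matrix,
)
from .transcriptome_aging import (
    celltype_mean_logged_cpm,
    classify_gene_programs,
    compare_correlations,
    de_by_cell_type,
    de_frame,
    length_decile_foldchange,
    shared_down_permutation,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "spectra", "signatures", "enrich", "transcriptome")

#: synthetic cell type -> classification column
CLASSIFY_MAP = {"ExN": "excitatory", "InN": "inhibitory", "Micro": "microglia", "Endo": "endothelia"}


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    generator: dict = field(default_factory=dict)
    k_range: list[int] = field(default_factory=lambda: list(range(1, 9)))
    n_restarts: int = 50
    attribution: str = "matched_reference"  # or "de_novo"
    control_multiplier: int = 10
    n_boot: int = 1000
    n_perm: int = 1000
    stability_threshold: float = 0.9
    min_error_improvement: float = 0.05
    min_pct: float = 0.25
    lfc_threshold: float = 0.5
    alpha: float = 0.05
    quintile_cell_type: str = "ExN"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems = []
    for s in config.stages:
        if s not in STAGES:
            problems.append(f"stages: unknown stage {s!r}")
    if not isinstance(config.seed, int):
        problems.append("seed: must be an integer")
    if config.n_perm < 1:
        problems.append(f"n_perm: must be >= 1, got {config.n_perm}")
    if config.n_boot < 1:
        problems.append(f"n_boot: must be >= 1, got {config.n_boot}")
    if config.n_restarts < 1:
        problems.append(f"n_restarts: must be >= 1, got {config.n_restarts}")
    if config.control_multiplier < 1:
        problems.append(f"control_multiplier: must be >= 1, got {config.control_multiplier}")
    if not config.k_range or min(config.k_range) < 1 or max(config.k_range) > 96:
        problems.append(f"k_range: must be nonempty within [1, 96], got {config.k_range}")
    if config.attribution not in ("matched_reference", "de_novo"):
        problems.append(f"attribution: must be matched_reference or de_novo, got {config.attribution!r}")
    if not (0 < config.alpha < 1):
        problems.append(f"alpha: must be in (0, 1), got {config.alpha}")
    if not (0 <= config.min_pct <= 1):
        problems.append(f"min_pct: must be in [0, 1], got {config.min_pct}")
    if config.lfc_threshold < 0:
        problems.append(f"lfc_threshold: must be >= 0, got {config.lfc_threshold}")
    try:
        syn.GeneratorConfig(seed=config.seed, **config.generator)
    except (ConfigError, TypeError) as exc:
        problems.append(f"generator: {exc}")
    return problems


class _Workspace:
    """In-memory products of completed stages, with file-based resume."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.gen = syn.GeneratorConfig(seed=config.seed, **config.generator)
        self._cache: dict = {}

    def _load(self, key):
        out = self.out
        if key == "reference":
            path = out / "reference.fa"
            if path.exists():
                return io.load_reference(path)
        elif key == "genes":
            path = out / "genes.gff3"
            if path.exists():
                return io.read_gene_annotation(path, "gff3")
        elif key == "mask":
            path = out / "callable_mask.bed"
            if path.exists():
                return io.read_bed_intervals(path)
        elif key == "catalog":
            manifest = out / "vcf" / "manifest.tsv"
            if manifest.exists():
                return io.read_catalog(manifest)
        elif key == "expression":
            if (out / "counts.mtx").exists():
                return io.read_counts(out / "counts")
        raise DataError(
            f"stage requires {key!r}: run the simulate stage first (or point out_dir "
            "at a directory holding its outputs)"
        )

    def get(self, key):
        if key not in self._cache:
            self._cache[key] = self._load(key)
        return self._cache[key]

    def put(self, key, value):
        self._cache[key] = value


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and write report.json."""
    problems = validate_config(config)
    if problems:
        raise ConfigError("; ".join(problems))
    ws = _Workspace(config)
    report: dict = {
        "package": "brainaging",
        "seed": config.seed,
        "stages_run": [s for s in STAGES if s in config.stages],
        "config": dataclasses.asdict(config),
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("pipeline: running stage %s", stage)
        try:
            report[stage] = _STAGE_FUNCS[stage](ws)
        except BrainAgingError as exc:
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    (ws.out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(ws: _Workspace) -> dict:
    cfg = ws.gen
    genome, genes, mask = syn.make_toy_genome(cfg)
    catalog, truth = syn.simulate_mutation_catalog(cfg, genome, genes, mask)
    counts, etruth = syn.simulate_expression(cfg, genes)
    out = ws.out
    io.write_fasta(genome, out / "reference.fa")
    io.write_gff3(genes, out / "genes.gff3")
    io.write_bed(mask, out / "callable_mask.bed")
    syn.write_catalog_vcfs(catalog, out / "vcf")
    io.write_counts(counts, out / "counts")
    truth.to_json(out / "catalog_truth.json")
    etruth.to_json(out / "expression_truth.json")
    for key, val in (
        ("reference", genome),
        ("genes", genes),
        ("mask", mask),
        ("catalog", catalog),
        ("expression", counts),
        ("catalog_truth", truth),
        ("expression_truth", etruth),
    ):
        ws.put(key, val)
    return {
        "n_genes": len(genes),
        "n_mutations": len(catalog),
        "n_cells_scwgs": int(truth.cells.shape[0]),
        "n_nuclei": counts.n_cells,
        "generator_seed": cfg.seed,
    }


def _per_cell_spectra(ws: _Workspace) -> dict[str, Spectrum96]:
    catalog = ws.get("catalog")
    reference = ws.get("reference")
    by_cell: dict[str, list] = {}
    for m in catalog:
        by_cell.setdefault(m.cell_id, []).append(m)
    return {cell: build_spectrum(muts, reference)[0] for cell, muts in sorted(by_cell.items())}


def _cell_ages(ws: _Workspace, cells: list[str]) -> np.ndarray:
    donors = {d.donor_id: d.age_years for d in io.load_donor_fixture()}
    ages = ws.gen.donor_ages
    # synthetic donor ids are positional: d01.. follow config order
    age_of = {f"d{i + 1:02d}": a for i, a in enumerate(ages)}
    age_of.update({k: v for k, v in donors.items() if k not in age_of})
    return np.array([age_of[c.split("_")[0]] for c in cells])


def _stage_spectra(ws: _Workspace) -> dict:
    spectra = _per_cell_spectra(ws)
    ws.put("per_cell_spectra", spectra)
    V, cells = spectra_matrix(spectra)
    ws.put("spectra_matrix", (V, cells))
    agg = Spectrum96(V.sum(axis=1))
    agg.to_tsv(ws.out / "aggregate_spectrum.tsv")
    pd.DataFrame(V, columns=cells).to_csv(ws.out / "per_cell_spectra.tsv", sep="\t", index=False)
    gen = ws.gen
    return {
        "n_cells": len(cells),
        "aggregate_total": agg.total,
        "cosine_to_sbs5like": cosine_sim(agg.counts, gen.sig_a1_ref),
        "cosine_to_sbs30like": cosine_sim(agg.counts, gen.sig_a2_ref),
    }


def _stage_signatures(ws: _Workspace) -> dict:
    cfg = ws.config
    if "spectra_matrix" not in ws._cache:
        _stage_spectra(ws)
    V, cells = ws._cache["spectra_matrix"]
    chosen_k, table = select_rank(
        V,
        k_range=cfg.k_range,
        n_restarts=cfg.n_restarts,
        seed=cfg.seed,
        stability_threshold=cfg.stability_threshold,
        min_error_improvement=cfg.min_error_improvement,
    )
    table.to_csv(ws.out / "rank_selection.tsv", sep="\t", index=False)
    fit = nmf_decompose(V, k=max(chosen_k, 2), n_restarts=cfg.n_restarts, seed=cfg.seed)
    sig_df, _ = fit.to_frames(cells)
    references = None
    if cfg.attribution == "matched_reference":
        references = np.column_stack([ws.gen.sig_a1_ref, ws.gen.sig_a2_ref])
    exposures, basis, path = attribute_exposures(V, sig_df.to_numpy(), references)
    exp_df = pd.DataFrame(exposures, index=sig_df.columns, columns=cells)
    basis_df = pd.DataFrame(basis, index=sig_df.index, columns=sig_df.columns)
    sig_df.rename_axis("context").to_csv(ws.out / "signatures.tsv", sep="\t")
    exp_df.rename_axis("signature").to_csv(ws.out / "exposures.tsv", sep="\t")
    basis_df.rename_axis("context").to_csv(ws.out / "attribution_basis.tsv", sep="\t")
    ws.put("signatures", sig_df)
    ws.put("exposures", exp_df)
    ws.put("attribution_basis", basis_df)

    ages = _cell_ages(ws, cells)
    gen = ws.gen
    regs = {}
    totals = V.sum(axis=0)
    regs["total"] = burden_age_regression(totals, ages)
    for name in sig_df.columns:
        regs[name] = burden_age_regression(exp_df.loc[name].to_numpy(), ages)
    reg_out = {
        name: {"slope": r.slope, "intercept": r.intercept, "r_squared": r.r_squared,
               "p_value": r.p_value, "n": r.n}
        for name, r in regs.items()
    }
    (ws.out / "burden_regressions.json").write_text(json.dumps(reg_out, indent=2, sort_keys=True))
    return {
        "chosen_k": chosen_k,
        "attribution_path": path,
        "rank_table": table.to_dict(orient="list"),
        "cosine_A1_to_sbs5like": cosine_sim(sig_df["A1"].to_numpy(), gen.sig_a1_ref),
        "cosine_A2_to_sbs30like": cosine_sim(sig_df["A2"].to_numpy(), gen.sig_a2_ref)
        if "A2" in sig_df
        else None,
        "regressions": reg_out,
    }


def _stage_enrich(ws: _Workspace) -> dict:
    cfg = ws.config
    catalog = ws.get("catalog")
    reference = ws.get("reference")
    genes = ws.get("genes")
    mask = ws.get("mask")
    annotated = annotate_mutations(catalog, genes, reference)
    controls = sample_matched_controls(
        annotated, mask, reference, multiplier=cfg.control_multiplier, seed=cfg.seed
    )
    from .genomic_enrichment import assign_genes

    assign_genes(controls, genes)

    scores = {g.gene_id: g.mean_expression.get(cfg.quintile_cell_type, 0.0) for g in genes}
    qmap = expression_quintiles(scores, include_zero=True)

    # per-signature attribution uses the same basis the exposures were
    # quantified against (matched references by default, de novo otherwise)
    sig_kwargs = {}
    if "attribution_basis" not in ws._cache and (ws.out / "attribution_basis.tsv").exists():
        ws.put(
            "attribution_basis",
            pd.read_csv(ws.out / "attribution_basis.tsv", sep="\t", index_col="context"),
        )
        ws.put("exposures", pd.read_csv(ws.out / "exposures.tsv", sep="\t", index_col="signature"))
    if "attribution_basis" in ws._cache:
        sig_df = ws._cache["attribution_basis"]
        exp_df = ws._cache["exposures"]
        sig_kwargs = dict(
            signatures=sig_df.to_numpy(),
            signature_weights=exp_df.sum(axis=1).to_numpy(),
            signature_names=list(sig_df.columns),
        )

    results = {}
    for partition in ("genic_vs_intergenic", "expression_quintiles"):
        res = enrichment(
            annotated,
            controls,
            partition,
            quintile_map=qmap,
            n_boot=cfg.n_boot,
            seed=cfg.seed,
            **sig_kwargs,
        )
        results[partition] = [dataclasses.asdict(r) for r in res]
    pd.json_normalize([r for rs in results.values() for r in rs]).to_csv(
        ws.out / "enrichment.tsv", sep="\t", index=False
    )

    sb = strand_bias(annotated, quintile_map=qmap)
    sb_df = pd.DataFrame([dataclasses.asdict(r) for r in sb])
    sb_df.to_csv(ws.out / "strand_bias.tsv", sep="\t", index=False)

    by_class: dict[str, list] = {}
    gene_class = {g.gene_id: g.gene_class for g in genes}
    for a in annotated:
        if a.gene_id is not None:
            by_class.setdefault(gene_class.get(a.gene_id, "other"), []).append(a)
    rate_fits = {}
    for cls in ("housekeeping", "neuron_specific"):
        members = [g for g in genes if g.gene_class == cls]
        if len(members) >= 10:
            tbl, fit = snv_rate_by_length(by_class.get(cls, []), members)
            tbl.to_csv(ws.out / f"snv_rate_by_length.{cls}.tsv", sep="\t", index=False)
            rate_fits[cls] = {"slope": fit.slope, "r_squared": fit.r_squared, "p_value": fit.p_value}

    spec_test = None
    if by_class.get("housekeeping") and by_class.get("neuron_specific"):
        df = class_spectrum_test(by_class["housekeeping"], by_class["neuron_specific"])
        df.to_csv(ws.out / "class_spectrum_test.tsv", sep="\t", index=False)
        spec_test = df.to_dict(orient="list")

    tc_all = next(
        r for r in sb if r.substitution_class == "T>C" and r.quantile == "all"
    )
    return {
        "n_observed": len(annotated),
        "n_controls": len(controls),
        "enrichment": results,
        "tc_fraction_transcribed": tc_all.fraction_transcribed,
        "snv_rate_fits": rate_fits,
        "class_spectrum_test": spec_test,
    }


def _stage_transcriptome(ws: _Workspace) -> dict:
    cfg = ws.config
    cm = ws.get("expression")
    de = de_by_cell_type(
        cm, min_pct=cfg.min_pct, lfc_threshold=cfg.lfc_threshold, alpha=cfg.alpha
    )
    df = de_frame(de)
    df.to_csv(ws.out / "differential_expression.tsv", sep="\t", index=False)

    # Classification thresholds are absolute logged-CPM values calibrated to a
    # genome-wide gene panel. The toy annotation carries per-type logged-CPM
    # profiles in those units, so classify from it when present; means
    # recovered from the counts (whose CPM scale depends on panel size) are
    # the fallback for externally supplied data.
    genes = ws.get("genes")
    profile = pd.DataFrame(
        {CLASSIFY_MAP[ct]: {g.gene_id: g.mean_expression.get(ct, np.nan) for g in genes}
         for ct in CLASSIFY_MAP}
    )
    if profile.isna().all().all():
        means = celltype_mean_logged_cpm(cm)
        rename = {ct: col for ct, col in CLASSIFY_MAP.items() if ct in means.columns}
        profile = means.rename(columns=rename)
    classes = classify_gene_programs(profile.dropna())
    classes.rename_axis("gene_id").to_csv(ws.out / "gene_classes.tsv", sep="\t")

    down_sets = {
        ct: {r.gene_id for r in res if r.significant and r.direction == "down"}
        for ct, res in de.items()
    }
    norm_detect = cm.counts > 0
    expressed_sets = {}
    for ct in de:
        a = cm.cells_where(cell_type=ct, age_group="adult")
        e = cm.cells_where(cell_type=ct, age_group="elderly")
        frac_a = norm_detect[:, a].mean(axis=1)
        frac_e = norm_detect[:, e].mean(axis=1)
        ok = (frac_a >= 0.25) & (frac_e >= 0.20)
        expressed_sets[ct] = set(np.array(cm.gene_ids)[ok]) | down_sets[ct]
    categories = {ct: syn.CELLTYPE_CATEGORY.get(ct, "glial") for ct in de}
    observed, perm_counts, perm_p = shared_down_permutation(
        down_sets, expressed_sets, categories, n_perm=cfg.n_perm, seed=cfg.seed
    )
    json.dump(
        {
            "observed_shared": observed,
            "permutation_max": int(perm_counts.max()),
            "permutation_mean": float(perm_counts.mean()),
            "p_value": perm_p,
        },
        open(ws.out / "shared_down_permutation.json", "w"),
        indent=2,
    )

    lengths = pd.Series({g.gene_id: g.length for g in genes})
    gene_class = pd.Series({g.gene_id: g.gene_class for g in genes})
    decile_fits = {}
    r_by_class = {}
    target_ct = cfg.quintile_cell_type if cfg.quintile_cell_type in de else next(iter(de))
    lfc_ct = pd.Series({r.gene_id: r.log2_fc for r in de[target_ct]})
    for cls in ("housekeeping", "neuron_specific"):
        ids = gene_class[gene_class == cls].index.intersection(lfc_ct.index)
        if len(ids) >= 10:
            summary, fit = length_decile_foldchange(lfc_ct[ids], lengths[ids])
            summary.to_csv(ws.out / f"length_decile_fc.{cls}.tsv", sep="\t", index=False)
            decile_fits[cls] = {"slope": fit.slope, "r_squared": fit.r_squared, "p_value": fit.p_value}
            r_by_class[cls] = (np.sign(fit.slope) * np.sqrt(fit.r_squared), len(ids))
    rz = None
    if len(r_by_class) == 2:
        (r1, n1), (r2, n2) = r_by_class["housekeeping"], r_by_class["neuron_specific"]
        z, p = compare_correlations(r1, n1, r2, n2)
        rz = {"z": z, "p_value": p}

    n_sig = int(df["significant"].sum()) if len(df) else 0
    return {
        "n_cell_types": len(de),
        "n_significant": n_sig,
        "n_down": int((df["significant"] & (df["direction"] == "down")).sum()) if len(df) else 0,
        "shared_down": {"observed": observed, "p_value": perm_p},
        "length_decile_fits": decile_fits,
        "r_to_z_contrast": rz,
        "n_housekeeping": int((classes["gene_class"] == "housekeeping").sum()),
        "n_neuron_specific": int((classes["gene_class"] == "neuron_specific").sum()),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "spectra": _stage_spectra,
    "signatures": _stage_signatures,
    "enrich": _stage_enrich,
    "transcriptome": _stage_transcriptome,
}
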