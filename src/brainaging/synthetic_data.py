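"""Synthetic corpus generator for the aging-cortex analyses.

Emulates the statistical structure the downstream analyses assume, at desk
scale: per-neuron somatic-SNV catalogs drawn from a two-signature mixture
whose per-year rates default to the study's fitted clock rates (13.8/yr for
the T>C-dominant component, 1.8/yr for the C>T-dominant one), with
expression-dependent genic placement and transcriptional strand asymmetry;
and single-nucleus count matrices with planted aging effects (a
housekeeping decline scaled by gene length, stable neuron-identity genes,
and a cross-cell-type shared downregulated gene set).

Every random draw flows from ``GeneratorConfig.seed`` through three
independent child streams (genome, catalog, expression), so identical
seeds give byte-identical corpora and each stage can be re-run alone.

Per-cell burdens are Poisson around the age trend, optionally (and by
default) modulated by per-cell per-signature Gamma factors. The extra
scatter both matches the dispersion visible in the study's burden-vs-age
fits (R^2 well below the near-1 value pure Poisson noise would give) and
makes the per-cell signature proportions vary, without which no
factorization could separate two components that share a common age trend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .io_formats import (
    CountMatrix,
    GeneModel,
    GenomicInterval,
    MutationRecord,
    donor_ages,
)
from .mutation_spectra import CONTEXT_LABELS, SUB_CLASSES

_BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3}
_INT_TO_BASE = "ACGT"

#: Synthetic cell types and their analysis categories. The first four carry
#: the cell types the housekeeping/neuron-specific classification requires.
CELL_TYPES = ("ExN", "InN", "Micro", "Endo", "Oligo", "Astro")
CELLTYPE_CATEGORY = {
    "ExN": "excitatory",
    "InN": "inhibitory",
    "Micro": "glial",
    "Endo": "endothelial",
    "Oligo": "glial",
    "Astro": "glial",
}
#: Cell types in which the shared downregulated set is planted:
#: one excitatory, one inhibitory, two glial.
SHARED_DOWN_CELLTYPES = ("ExN", "InN", "Oligo", "Astro")


def load_signature_fixture(name: str) -> np.ndarray:
    """Load a packaged synthetic 96-vector ('sbs5like' or 'sbs30like')."""
    fname = f"signature_{name}_synthetic.tsv"
    with resources.files("brainaging.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    v = df.set_index("context")["probability"].reindex(list(CONTEXT_LABELS)).to_numpy()
    if np.any(~np.isfinite(v)) or np.any(v < 0):
        raise DataError(f"{fname}: fixture must be nonnegative and complete")
    return v / v.sum()


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic corpus; defaults are the study conditions."""

    seed: int = 0
    donor_ages: list[float] = field(default_factory=donor_ages)
    cells_per_donor: int = 5
    rate_a1: float = 13.8  # T>C-dominant clock component, sSNVs/year
    rate_a2: float = 1.8  # C>T-dominant component, sSNVs/year
    sig_a1_ref: np.ndarray | None = None  # default: packaged SBS5-like
    sig_a2_ref: np.ndarray | None = None  # default: packaged SBS30-like
    genome_length: int = 2_000_000
    n_genes: int = 1000
    genic_weight_by_quintile: tuple[float, ...] = (1.0, 1.3, 1.6, 2.0, 2.5)
    a2_intergenic_weight: float = 2.0
    strand_asymmetry: float = 0.65  # genic T>C: P(pyrimidine on template strand)
    # Gamma shape of per-cell burden multipliers (mean 1); None = pure Poisson.
    # Defaults are back-calculated from the study's burden-age fit quality
    # (R^2 of 0.94 and 0.31 for the two components over the Table-1 ages).
    dispersion_a1: float | None = 50.0
    dispersion_a2: float | None = 1.4
    n_celltypes: int = 6
    hk_decline_max: float = -1.0  # planted log2FC at the shortest housekeeping decile
    shared_down_genes: int = 30
    shared_down_lfc: float = -1.0
    frac_housekeeping: float = 0.30
    frac_neuron_specific: float = 0.20
    nuclei_per_donor_per_type: int = 40
    nb_theta: float = 10.0  # negative-binomial size of expression counts
    library_size: float = 5000.0  # expected counts per nucleus (adult baseline)
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.sig_a1_ref is None:
            self.sig_a1_ref = load_signature_fixture("sbs5like")
        if self.sig_a2_ref is None:
            self.sig_a2_ref = load_signature_fixture("sbs30like")
        for name in ("sig_a1_ref", "sig_a2_ref"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (96,) or np.any(v < 0) or not np.isclose(v.sum(), 1.0):
                raise ConfigError(f"{name} must be a nonnegative 96-vector summing to 1")
            setattr(self, name, v)
        if len(self.genic_weight_by_quintile) != 5 or min(self.genic_weight_by_quintile) <= 0:
            raise ConfigError("genic_weight_by_quintile needs 5 positive weights")
        if not (0.5 <= self.strand_asymmetry <= 1.0):
            raise ConfigError("strand_asymmetry must lie in [0.5, 1]")
        if self.a2_intergenic_weight <= 0:
            raise ConfigError("a2_intergenic_weight must be positive")
        if not (4 <= self.n_celltypes <= len(CELL_TYPES)):
            raise ConfigError(f"n_celltypes must be in [4, {len(CELL_TYPES)}]")
        if self.rate_a1 < 0 or self.rate_a2 < 0:
            raise ConfigError("rates must be nonnegative")

    @property
    def cell_types(self) -> tuple[str, ...]:
        return CELL_TYPES[: self.n_celltypes]

    def _stream(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((int(self.seed), stage)))


def age_to_group(age: float) -> str:
    if age < 1:
        return "infant"
    return "adult" if age < 70 else "elderly"


# ---------------------------------------------------------------------------
# toy genome


def make_toy_genome(
    config: GeneratorConfig,
) -> tuple[dict[str, str], list[GeneModel], list[GenomicInterval]]:
    """Random reference, non-overlapping gene annotation, and callable mask.

    Bases are i.i.d. uniform; gene lengths are log-normal with
    neuron-specific genes drawn longer on average than housekeeping genes;
    each gene carries a class label, per-cell-type mean logged-CPM
    expression consistent with that class, and a scalar expression score
    (the excitatory-neuron mean) used for quintile placement.
    """
    if config.genome_length < 100 * config.n_genes:
        raise ConfigError(
            f"genome_length {config.genome_length} < 100 x n_genes; "
            "increase genome_length or reduce n_genes"
        )
    rng = config._stream(0)
    L, n = config.genome_length, config.n_genes

    seq_int = rng.integers(0, 4, size=L)
    seq = "".join(_INT_TO_BASE[i] for i in seq_int)

    n_hk = int(round(config.frac_housekeeping * n))
    n_ns = int(round(config.frac_neuron_specific * n))
    classes = ["housekeeping"] * n_hk + ["neuron_specific"] * n_ns + ["other"] * (n - n_hk - n_ns)
    lengths = np.empty(n, dtype=int)
    lengths[:n_hk] = rng.lognormal(np.log(600), 0.45, n_hk).astype(int)
    lengths[n_hk : n_hk + n_ns] = rng.lognormal(np.log(1600), 0.45, n_ns).astype(int)
    lengths[n_hk + n_ns :] = rng.lognormal(np.log(800), 0.6, n - n_hk - n_ns).astype(int)
    lengths = np.clip(lengths, 60, None)
    if lengths.sum() > 0.8 * L:
        raise ConfigError(
            f"cannot pack {lengths.sum()} gene bp into a {L} bp genome; "
            "increase genome_length"
        )

    order = rng.permutation(n)
    gap_total = L - int(lengths.sum())
    gaps = np.floor(rng.dirichlet(np.ones(n + 1)) * gap_total).astype(int)

    types = list(config.cell_types)
    genes: list[GeneModel] = []
    cursor = 0
    for rank, gi in enumerate(order):
        cursor += int(gaps[rank])
        start, end = cursor, cursor + int(lengths[gi])
        cursor = end
        cls = classes[gi]
        means: dict[str, float] = {}
        if cls == "housekeeping":
            base = rng.uniform(0.25, 1.4)
            for t in types:
                means[t] = base + rng.uniform(-0.045, 0.045)
        elif cls == "neuron_specific":
            for t in types:
                if t in ("ExN", "InN"):
                    means[t] = rng.uniform(0.25, 1.2)
                else:
                    means[t] = rng.uniform(0.0, 0.08)
        else:
            for t in types:
                means[t] = max(0.0, rng.uniform(-0.4, 1.0))
        genes.append(
            GeneModel(
                gene_id=f"g{gi:04d}",
                chrom=config.chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                gene_class=cls,
                mean_expression=means,
                expression_score=means["ExN"],
            )
        )
    assert cursor <= L
    mask = [GenomicInterval(config.chrom, 0, L)]
    return {config.chrom: seq}, genes, mask


# ---------------------------------------------------------------------------
# mutation catalog


@dataclass
class CatalogTruth:
    """Ground truth of a simulated catalog, sufficient to score recovery."""

    config_rates: tuple[float, float]
    cells: pd.DataFrame  # cell_id, donor_id, age, n_a1, n_a2
    labels: list[str]  # per mutation, aligned with the catalog: "A1" or "A2"

    def to_json(self, path) -> None:
        payload = {
            "config_rates": list(self.config_rates),
            "cells": self.cells.to_dict(orient="list"),
            "labels": self.labels,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "CatalogTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            config_rates=tuple(d["config_rates"]),
            cells=pd.DataFrame(d["cells"]),
            labels=list(d["labels"]),
        )


def _site_tables(seq: str, genes: list[GeneModel], mask, quintile_by_gene):
    """Per-position stratum/placement arrays for positions 1..L-2."""
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(s.shape, -1, dtype=np.int8)
    for b, i in _BASE_TO_INT.items():
        code[s == ord(b)] = i
    central = code[1:-1].astype(np.int64)
    left = code[:-2].astype(np.int64)
    right = code[2:].astype(np.int64)

    stratum = np.empty_like(central)
    is_c = central == 1
    is_t = central == 3
    is_g = central == 2
    is_a = central == 0
    stratum[is_c] = left[is_c] * 4 + right[is_c]
    stratum[is_t] = 16 + left[is_t] * 4 + right[is_t]
    stratum[is_g] = (3 - right[is_g]) * 4 + (3 - left[is_g])
    stratum[is_a] = 16 + (3 - right[is_a]) * 4 + (3 - left[is_a])
    pyr_on_plus = is_c | is_t

    n_sites = central.size
    gene_idx = np.full(n_sites, -1, dtype=np.int64)
    gene_plus = np.zeros(n_sites, dtype=bool)
    quintile = np.zeros(n_sites, dtype=np.int64)
    for k, g in enumerate(genes):
        lo, hi = max(g.start - 1, 0), min(g.end - 1, n_sites)
        gene_idx[lo:hi] = k
        gene_plus[lo:hi] = g.strand == "+"
        quintile[lo:hi] = quintile_by_gene[g.gene_id]

    callable_mask = np.zeros(n_sites, dtype=bool)
    for iv in mask:
        callable_mask[max(iv.start - 1, 0) : min(iv.end - 1, n_sites)] = True
    return stratum, pyr_on_plus, gene_idx, gene_plus, quintile, callable_mask


class _StratumSampler:
    """Weighted samplers per (stratum, placement category) for one signature."""

    def __init__(self, positions, weights):
        self.positions = positions
        self.cum = np.cumsum(weights) if len(weights) else np.array([])
        self.total = float(self.cum[-1]) if len(weights) else 0.0

    def sample(self, rng, k):
        u = rng.random(k) * self.total
        return self.positions[np.searchsorted(self.cum, u)]


def simulate_mutation_catalog(
    config: GeneratorConfig,
    genome: dict[str, str],
    annotation: list[GeneModel],
    mask: list[GenomicInterval] | None = None,
) -> tuple[list[MutationRecord], CatalogTruth]:
    """Simulate per-cell somatic-SNV catalogs from the two-signature clock.

    Per cell of a donor aged ``a``: the component burdens are Poisson with
    means ``a * rate * G`` (G a per-cell Gamma multiplier when dispersion is
    configured); contexts are drawn from the component's 96-vector; each
    mutation's position is drawn among callable sites carrying its exact
    trinucleotide, re-weighted by expression quintile (A1) or toward
    intergenic space (A2); genic T>C placements respect the configured
    strand asymmetry. Context mixtures are preserved exactly because all
    re-weighting happens within a trinucleotide stratum.
    """
    from .genomic_enrichment import expression_quintiles

    chrom = config.chrom
    if chrom not in genome:
        raise DataError(f"chromosome {chrom!r} absent from genome")
    seq = genome[chrom]
    if mask is None:
        mask = [GenomicInterval(chrom, 0, len(seq))]
    scores = {g.gene_id: (g.expression_score or 0.0) for g in annotation}
    quintile_by_gene = expression_quintiles(scores, include_zero=True)

    stratum, pyr_plus, gene_idx, gene_plus, quintile, callable_mask = _site_tables(
        seq, annotation, mask, quintile_by_gene
    )

    genic = gene_idx >= 0
    template_match = gene_plus ^ pyr_plus  # pyrimidine sits on the template strand
    qw = np.asarray(config.genic_weight_by_quintile)

    weights = {
        "A1": np.where(genic, qw[np.clip(quintile - 1, 0, 4)], 1.0),
        "A2": np.where(genic, 1.0, config.a2_intergenic_weight),
    }
    sigs = {"A1": config.sig_a1_ref, "A2": config.sig_a2_ref}
    rates = {"A1": config.rate_a1, "A2": config.rate_a2}
    disp = {"A1": config.dispersion_a1, "A2": config.dispersion_a2}

    # per (signature, stratum): samplers over intergenic / genic-template / genic-coding
    samplers: dict[str, list[tuple]] = {}
    needed = {
        name: {(0 if j < 48 else 16) + j % 16 for j in np.nonzero(sig)[0]}
        for name, sig in sigs.items()
    }
    missing: list[str] = []
    for name in sigs:
        per_stratum = []
        w = weights[name]
        for st in range(32):
            sel = (stratum == st) & callable_mask
            if not sel.any():
                if st in needed[name]:
                    missing.append(f"{name}:stratum{st}")
                per_stratum.append(None)
                continue
            idx = np.nonzero(sel)[0]
            cat_inter = idx[~genic[idx]]
            g_idx = idx[genic[idx]]
            cat_gt = g_idx[template_match[g_idx]]
            cat_gc = g_idx[~template_match[g_idx]]
            per_stratum.append(
                (
                    _StratumSampler(cat_inter, w[cat_inter]),
                    _StratumSampler(cat_gt, w[cat_gt]),
                    _StratumSampler(cat_gc, w[cat_gc]),
                )
            )
        samplers[name] = per_stratum
    if missing:
        raise DataError(f"no callable sites for required contexts: {missing}")

    rng = config._stream(1)
    alt_base = {0: "A", 1: "G", 2: "T", 3: "A", 4: "C", 5: "G"}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    records: list[MutationRecord] = []
    labels: list[str] = []
    cell_rows = []
    for di, age in enumerate(config.donor_ages):
        donor = f"d{di + 1:02d}"
        for ci in range(config.cells_per_donor):
            cell = f"{donor}_c{ci:02d}"
            counts = {}
            for name in ("A1", "A2"):
                lam = age * rates[name]
                a = disp[name]
                if a is not None and lam > 0:
                    lam = lam * rng.gamma(a, 1.0 / a)
                counts[name] = int(rng.poisson(lam))
            cell_rows.append(
                {
                    "cell_id": cell,
                    "donor_id": donor,
                    "age": age,
                    "n_a1": counts["A1"],
                    "n_a2": counts["A2"],
                }
            )
            for name in ("A1", "A2"):
                n_mut = counts[name]
                if n_mut == 0:
                    continue
                ctx_counts = rng.multinomial(n_mut, sigs[name])
                for j in np.nonzero(ctx_counts)[0]:
                    c = int(ctx_counts[j])
                    st = (0 if j < 48 else 16) + j % 16
                    s_inter, s_gt, s_gc = samplers[name][st]
                    w_gen = s_gt.total + s_gc.total
                    p_gen = w_gen / (w_gen + s_inter.total) if (w_gen + s_inter.total) else 0.0
                    n_gen = rng.binomial(c, p_gen)
                    n_int = c - n_gen
                    if j // 16 == 4 and s_gt.total and s_gc.total:  # genic T>C strand skew
                        n_t = rng.binomial(n_gen, config.strand_asymmetry)
                    elif w_gen:
                        n_t = rng.binomial(n_gen, s_gt.total / w_gen) if s_gt.total else 0
                    else:
                        n_t = 0
                    drawn = []
                    if n_int:
                        drawn.append(s_inter.sample(rng, n_int))
                    if n_t:
                        drawn.append(s_gt.sample(rng, n_t))
                    if n_gen - n_t:
                        drawn.append(s_gc.sample(rng, n_gen - n_t))
                    for site in np.concatenate(drawn) if drawn else []:
                        pos = int(site) + 1  # site tables start at genomic position 1
                        ref = seq[pos]
                        alt = alt_base[j // 16]
                        if ref not in "CT":  # pyrimidine on the minus strand
                            alt = comp[alt]
                        records.append(
                            MutationRecord(
                                cell_id=cell,
                                donor_id=donor,
                                chrom=chrom,
                                pos=pos,
                                ref=ref,
                                alt=alt,
                            )
                        )
                        labels.append(name)
    truth = CatalogTruth(
        config_rates=(config.rate_a1, config.rate_a2),
        cells=pd.DataFrame(cell_rows),
        labels=labels,
    )
    return records, truth


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ExpressionTruth:
    """Planted aging effects of a simulated expression matrix."""

    planted_lfc: pd.DataFrame  # genes x cell types, log2(elderly/adult)
    shared_down_genes: list[str]
    hk_decile: pd.Series  # housekeeping gene -> length decile (1 = shortest)

    def to_json(self, path) -> None:
        payload = {
            "planted_lfc": self.planted_lfc.to_dict(),
            "shared_down_genes": self.shared_down_genes,
            "hk_decile": self.hk_decile.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))


def _length_deciles(genes: list[GeneModel]) -> pd.Series:
    ordered = sorted(genes, key=lambda g: (g.length, g.gene_id))
    n = len(ordered)
    return pd.Series(
        {g.gene_id: min(i * 10 // n, 9) + 1 for i, g in enumerate(ordered)}, dtype=int
    )


def simulate_expression(
    config: GeneratorConfig, annotation: list[GeneModel]
) -> tuple[CountMatrix, ExpressionTruth]:
    """Negative-binomial count matrix with planted aging effects.

    In elderly cells, housekeeping genes are downregulated with a planted
    log2 fold change interpolated linearly from ``hk_decline_max`` at the
    shortest length decile to 0 at the longest; neuron-specific genes are
    untouched; ``shared_down_genes`` genes drawn from the 'other' class are
    downregulated in one excitatory, one inhibitory and two glial cell
    types. The truth record stores every planted effect.
    """
    rng = config._stream(2)
    types = list(config.cell_types)
    hk = [g for g in annotation if g.gene_class == "housekeeping"]
    if len(hk) < 10:
        raise DataError(f"only {len(hk)} housekeeping genes; need at least one per decile")
    gene_ids = [g.gene_id for g in annotation]
    base = pd.DataFrame(
        {t: [g.mean_expression.get(t, 0.0) for g in annotation] for t in types},
        index=gene_ids,
    )

    planted = pd.DataFrame(0.0, index=gene_ids, columns=types)
    hk_decile = _length_deciles(hk)
    for g in hk:
        d = hk_decile[g.gene_id]
        lfc = config.hk_decline_max * (10 - d) / 9.0
        planted.loc[g.gene_id, :] = lfc

    other_expressed = [
        g.gene_id
        for g in annotation
        if g.gene_class == "other"
        and all(g.mean_expression.get(t, 0.0) > 0.25 for t in SHARED_DOWN_CELLTYPES if t in types)
    ]
    n_shared = min(config.shared_down_genes, len(other_expressed))
    shared = list(rng.choice(other_expressed, size=n_shared, replace=False)) if n_shared else []
    for gid in shared:
        for t in SHARED_DOWN_CELLTYPES:
            if t in types:
                planted.loc[gid, t] = config.shared_down_lfc

    lam_adult = np.expm1(base.to_numpy())  # CPM-like relative rates per type
    scale = {
        t: config.library_size / max(lam_adult[:, k].sum(), 1e-9)
        for k, t in enumerate(types)
    }

    cells, metas, cols = [], [], []
    for di, age in enumerate(config.donor_ages):
        donor = f"d{di + 1:02d}"
        group = age_to_group(age)
        for t in types:
            k = types.index(t)
            mu = lam_adult[:, k] * scale[t]
            if group == "elderly":
                mu = mu * np.power(2.0, planted[t].to_numpy())
            theta = config.nb_theta
            p = theta / (theta + np.maximum(mu, 1e-12))
            for ci in range(config.nuclei_per_donor_per_type):
                cell = f"{donor}_{t}_n{ci:03d}"
                draw = rng.negative_binomial(theta, p)
                draw[mu <= 0] = 0
                cells.append(draw)
                cols.append(cell)
                metas.append({"cell_id": cell, "cell_type": t, "donor_id": donor, "age_group": group})

    counts = np.column_stack(cells).astype(int)
    meta = pd.DataFrame(metas).set_index("cell_id")
    cm = CountMatrix(gene_ids=gene_ids, cell_ids=cols, counts=counts, cell_meta=meta)
    truth = ExpressionTruth(planted_lfc=planted, shared_down_genes=[str(s) for s in shared], hk_decile=hk_decile)
    return cm, truth


# ---------------------------------------------------------------------------
# corpus serialization


def write_catalog_vcfs(records: list[MutationRecord], out_dir) -> Path:
    """Write one VCF per cell plus a manifest TSV; returns the manifest path."""
    from .io_formats import write_vcf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_cell: dict[tuple[str, str], list[MutationRecord]] = {}
    for r in records:
        by_cell.setdefault((r.cell_id, r.donor_id), []).append(r)
    rows = []
    for (cell, donor), recs in sorted(by_cell.items()):
        fname = f"{cell}.vcf"
        write_vcf(recs, out_dir / fname)
        rows.append({"cell_id": cell, "donor_id": donor, "path": fname})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
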