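"""Domain types and file I/O for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open; conversion to and from the
1-based conventions of VCF and GFF3 happens only at the file boundary.
Chromosome names are taken verbatim from inputs; ``normalize_chrom`` maps
"chr1" <-> "1" when a caller needs to reconcile conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ParseError, ValidationError

log = logging.getLogger(__name__)

AGE_GROUPS = ("infant", "adult", "elderly")


@dataclass(frozen=True)
class DonorMeta:
    """One donor: age in years, sex, age group, and per-assay cell counts."""

    donor_id: str
    age_years: float
    sex: str
    group: str
    n_nuclei: int
    n_scwgs_cells: int

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValidationError(f"donor {self.donor_id}: negative age")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"donor {self.donor_id}: sex must be M or F")
        if self.group not in AGE_GROUPS:
            raise ValidationError(f"donor {self.donor_id}: unknown group {self.group!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with strand ('+', '-', or '.')."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValidationError(
                f"inverted or empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV with cell/donor provenance; position is 0-based."""

    cell_id: str
    donor_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or self.alt not in "ACGT" or len(self.ref) != 1 or len(self.alt) != 1:
            raise ValidationError(f"not a single-nucleotide substitution: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValidationError(f"ref equals alt at {self.chrom}:{self.pos}")
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos}")


@dataclass
class GeneModel:
    """A gene: coordinates, strand, optional class label and expression summary.

    ``mean_expression`` maps cell-type name to mean logged CPM;
    ``expression_score`` is the scalar activity used for quintile binning.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_class: str | None = None
    mean_expression: dict[str, float] = field(default_factory=dict)
    expression_score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass
class CountMatrix:
    """Genes x cells integer counts with per-cell metadata.

    ``cell_meta`` is indexed by cell_id with columns ``cell_type``,
    ``donor_id`` and ``age_group``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.any(self.counts < 0):
            raise ValidationError("negative counts")
        missing = set(self.cell_ids) - set(self.cell_meta.index)
        if missing:
            raise ValidationError(f"{len(missing)} cells missing from cell_meta")
        for col in ("cell_type", "donor_id", "age_group"):
            if col not in self.cell_meta.columns:
                raise ValidationError(f"cell_meta lacks column {col!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cells_where(self, **conditions) -> np.ndarray:
        """Boolean mask over cells matching all metadata equality conditions."""
        meta = self.cell_meta.loc[self.cell_ids]
        mask = np.ones(self.n_cells, dtype=bool)
        for col, val in conditions.items():
            mask &= (meta[col] == val).to_numpy()
        return mask


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Map chromosome naming between 'chr1' and '1' styles."""
    if style == "chr":
        return name if name.startswith("chr") else f"chr{name}"
    if style == "plain":
        return name[3:] if name.startswith("chr") else name
    raise DataError(f"unknown chromosome style {style!r}")


# ---------------------------------------------------------------------------
# donor fixture


def load_donor_fixture() -> list[DonorMeta]:
    """The 13 study donors with printed ages, sexes, and cell counts."""
    with resources.files("brainaging.data").joinpath("donor_metadata.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        DonorMeta(
            donor_id=str(r.donor_id),
            age_years=float(r.age_years),
            sex=str(r.sex),
            group=str(r.group),
            n_nuclei=int(r.n_nuclei),
            n_scwgs_cells=int(r.n_scwgs_cells),
        )
        for r in df.itertuples()
    ]


def donor_ages() -> list[float]:
    return [d.age_years for d in load_donor_fixture()]


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path, cell_id: str, donor_id: str) -> list[MutationRecord]:
    """Read biallelic SNVs from a VCF into MutationRecords (0-based positions).

    Indels and multiallelic records are skipped with a logged count.
    """
    import cyvcf2

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MutationRecord] = []
    skipped = 0
    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on malformed headers
        raise ParseError(f"{path}: cannot open as VCF ({exc})") from exc
    for i, v in enumerate(vcf):
        try:
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                skipped += 1
                continue
            ref, alt = v.REF.upper(), v.ALT[0].upper()
            if ref not in "ACGT" or alt not in "ACGT":
                skipped += 1
                continue
            records.append(
                MutationRecord(
                    cell_id=cell_id,
                    donor_id=donor_id,
                    chrom=v.CHROM,
                    pos=v.POS - 1,
                    ref=ref,
                    alt=alt,
                )
            )
        except Exception as exc:
            raise ParseError(f"{path}: malformed record #{i + 1}: {exc}") from exc
    if skipped:
        log.info("read_vcf(%s): skipped %d non-SNV/multiallelic records", path, skipped)
    return records


def write_vcf(records, path, reference_name: str = "synthetic") -> None:
    """Write MutationRecords as a minimal VCF 4.2 file (1-based positions)."""
    chroms = sorted({r.chrom for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            fh.write(f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\n")


def read_manifest(path) -> pd.DataFrame:
    """Per-cell VCF manifest: columns cell_id, donor_id, path."""
    df = pd.read_csv(path, sep="\t")
    for col in ("cell_id", "donor_id", "path"):
        if col not in df.columns:
            raise ParseError(f"{path}: manifest lacks column {col!r}")
    return df


def read_catalog(manifest_path) -> list[MutationRecord]:
    """Read every per-cell VCF named in a manifest into one catalog."""
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    out: list[MutationRecord] = []
    for r in manifest.itertuples():
        p = Path(r.path)
        if not p.is_absolute():
            p = base / p
        out.extend(read_vcf(p, cell_id=str(r.cell_id), donor_id=str(r.donor_id)))
    return out


# ---------------------------------------------------------------------------
# gene annotation (GFF3 / BED) and masks


def read_gene_annotation(path, dialect: str) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive) or BED (0-based half-open).

    Overlapping genes are retained as-is; overlap resolution is deferred to
    mutation annotation.
    """
    if dialect == "bed":
        return _read_bed_genes(path)
    if dialect == "gff3":
        return _read_gff3_genes(path)
    raise DataError(f"unknown annotation dialect {dialect!r}")


def _read_bed_genes(path) -> list[GeneModel]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "name": str, "strand": str},
    )
    genes = []
    for i, r in enumerate(df.itertuples()):
        try:
            genes.append(
                GeneModel(
                    gene_id=str(r.name),
                    chrom=str(r.chrom),
                    start=int(r.start),
                    end=int(r.end),
                    strand=str(r.strand) if str(r.strand) in "+-" else ".",
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: line {i + 1}: {exc}") from exc
    return genes


def _read_gff3_genes(path) -> list[GeneModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:
        raise ParseError(f"{path}: GFF3 parse failure: {exc}") from exc
    genes = []
    for feat in db.features_of_type("gene"):
        if feat.start > feat.end:
            raise ValidationError(
                f"{path}: gene {feat.id}: start {feat.start} > end {feat.end}"
            )
        attrs = dict(feat.attributes)
        g = GeneModel(
            gene_id=attrs.get("ID", [feat.id])[0],
            chrom=feat.seqid,
            start=feat.start - 1,  # GFF3 is 1-based inclusive
            end=feat.end,
            strand=feat.strand if feat.strand in "+-" else ".",
            gene_class=attrs.get("gene_class", [None])[0],
        )
        if "expression_score" in attrs:
            g.expression_score = float(attrs["expression_score"][0])
        for key, vals in attrs.items():
            if key.startswith("mean_expr_"):
                g.mean_expression[key[len("mean_expr_") :]] = float(vals[0])
        genes.append(g)
    return genes


def write_gff3(genes, path, source: str = "brainaging") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = [f"ID={g.gene_id}"]
            if g.gene_class is not None:
                attrs.append(f"gene_class={g.gene_class}")
            if g.expression_score is not None:
                attrs.append(f"expression_score={g.expression_score:.6g}")
            for ct in sorted(g.mean_expression):
                attrs.append(f"mean_expr_{ct}={g.mean_expression[ct]:.6g}")
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                + ";".join(attrs)
                + "\n"
            )


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Plain BED intervals (e.g. a callable-region mask)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {i + 1}: fewer than 3 BED fields")
            try:
                iv = GenomicInterval(
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    parts[5] if len(parts) >= 6 and parts[5] in "+-" else ".",
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}: line {i + 1}: {exc}") from exc
            rows.append(iv)
    return rows


def write_bed(intervals, path, names=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t.\t{iv.strand}\n")


def genes_to_bed(genes, path) -> None:
    write_bed([g.interval for g in genes], path, names=[g.gene_id for g in genes])


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_reference(path) -> dict[str, str]:
    """Load a FASTA into an in-memory chromosome -> sequence dict."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


# ---------------------------------------------------------------------------
# count matrices


def write_counts(cm: CountMatrix, prefix) -> None:
    """Write a CountMatrix as MTX triplet plus gene/cell sidecars and metadata TSV."""
    from scipy import io as spio
    from scipy import sparse

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(cm.counts))
    pd.Series(cm.gene_ids).to_csv(str(prefix) + ".genes.tsv", sep="\t", index=False, header=False)
    pd.Series(cm.cell_ids).to_csv(str(prefix) + ".cells.tsv", sep="\t", index=False, header=False)
    cm.cell_meta.loc[cm.cell_ids].rename_axis("cell_id").to_csv(
        str(prefix) + ".cellmeta.tsv", sep="\t"
    )


def read_counts(prefix) -> CountMatrix:
    from scipy import io as spio

    prefix = str(prefix)
    counts = np.asarray(spio.mmread(prefix + ".mtx").todense()).astype(int)
    gene_ids = pd.read_csv(prefix + ".genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    cell_ids = pd.read_csv(prefix + ".cells.tsv", sep="\t", header=None)[0].astype(str).tolist()
    meta = pd.read_csv(prefix + ".cellmeta.tsv", sep="\t", index_col="cell_id")
    return CountMatrix(gene_ids=gene_ids, cell_ids=cell_ids, counts=counts, cell_meta=meta)
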