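"""Trinucleotide-context annotation and 96-channel mutation spectra.

Somatic single-nucleotide variants are summarized in the conventional
96-channel representation: each substitution is collapsed so the mutated
base is a pyrimidine (C or T), and the channel is the substitution class
(C>A, C>G, C>T, T>A, T>C, T>G) together with the 5' and 3' flanking
bases. Channels are ordered lexicographically by (class, 5' flank,
3' flank), the layout used by COSMIC signature tables, and all
serialization uses channel labels such as ``A[C>T]G`` rather than bare
indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContextUnassignableError, DataError

BASES = "ACGT"
PYRIMIDINES = "CT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The six pyrimidine-centered substitution classes, in canonical order.
SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channel labels, e.g. "A[C>A]A", in (class, 5', 3') lexicographic order.
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUB_CLASSES
    for five in BASES
    for three in BASES
)

_LABEL_TO_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def context_index(sub: str, five: str, three: str) -> int:
    return _LABEL_TO_INDEX[f"{five}[{sub}]{three}"]


def class_of_context(idx: int) -> str:
    """Substitution class (one of six) for a 96-channel index."""
    return SUB_CLASSES[idx // 16]


def canonical_context(ref: str, alt: str, left: str, right: str) -> tuple[int, bool]:
    """Map a substitution with flanks to its pyrimidine-centered channel.

    Returns ``(index, complemented)`` where ``complemented`` is True when
    the substitution had a purine reference and was reverse-complemented
    (so the reported flanks are those of the opposite strand).

    Raises
    ------
    ContextUnassignableError
        If any base is not one of A/C/G/T (e.g. an N in a flank).
    DataError
        If ``ref == alt``.
    """
    for b in (ref, alt, left, right):
        if b not in COMPLEMENT:
            raise ContextUnassignableError(
                f"non-ACGT base {b!r} in context {left}[{ref}>{alt}]{right}"
            )
    if ref == alt:
        raise DataError(f"ref equals alt ({ref}); not a substitution")
    if ref in PYRIMIDINES:
        return context_index(f"{ref}>{alt}", left, right), False
    # purine-centered: flip to the other strand, which swaps and complements flanks
    return (
        context_index(
            f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}", COMPLEMENT[right], COMPLEMENT[left]
        ),
        True,
    )


@dataclass
class Spectrum96:
    """Counts over the 96 trinucleotide substitution channels."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise DataError(f"spectrum must have 96 channels, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise DataError("spectrum counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise DataError("cannot normalize a zero-total spectrum")
        return self.counts / self.total

    def __add__(self, other: "Spectrum96") -> "Spectrum96":
        return Spectrum96(self.counts + other.counts)

    def class_totals(self) -> dict[str, float]:
        c = self.counts.reshape(6, 16).sum(axis=1)
        return dict(zip(SUB_CLASSES, c.tolist()))

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXT_LABELS), name="count")

    def to_tsv(self, path) -> None:
        df = self.to_series().rename_axis("context").reset_index()
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Spectrum96":
        from .errors import ParseError

        df = pd.read_csv(path, sep="\t")
        s = df.set_index(df.columns[0])[df.columns[1]]
        missing = set(CONTEXT_LABELS) - set(s.index)
        if missing:
            raise ParseError(
                f"{path}: missing {len(missing)} context labels, e.g. {sorted(missing)[:3]}"
            )
        return cls(s.reindex(list(CONTEXT_LABELS)).to_numpy(dtype=float))

    @classmethod
    def zeros(cls) -> "Spectrum96":
        return cls(np.zeros(96))


@dataclass
class AnnotatedMutation:
    """A mutation with its canonical context and (optional) gene placement."""

    record: "MutationRecord"  # noqa: F821 - forward ref to io_formats
    context96: int
    complemented: bool
    gene_id: str | None = None
    region: str = "intergenic"  # "genic" or "intergenic"
    tx_strand: str = "not_applicable"  # "transcribed" | "untranscribed" | "not_applicable"

    @property
    def sub_class(self) -> str:
        return class_of_context(self.context96)


def _fetch_triplet(reference: Mapping[str, str], chrom: str, pos: int, record=None) -> str:
    try:
        seq = reference[chrom]
    except KeyError:
        raise DataError(f"chromosome {chrom!r} absent from reference") from None
    if isinstance(seq, str):
        n = len(seq)
    else:  # pyfaidx FastaRecord
        n = len(seq)
    if pos < 1 or pos + 1 >= n:
        raise DataError(
            f"position {chrom}:{pos} too close to a reference edge for context lookup"
            + (f" (record {record})" if record is not None else "")
        )
    return str(seq[pos - 1 : pos + 2]).upper()


def annotate_contexts(
    mutations: Iterable,
    reference: Mapping[str, str],
    drop_unassignable: bool = True,
) -> tuple[list[AnnotatedMutation], int]:
    """Assign the canonical 96-channel context to each mutation.

    ``reference`` is any mapping from chromosome name to sequence (a plain
    dict of strings or a ``pyfaidx.Fasta``). Mutations whose flanks contain
    non-ACGT bases are dropped and counted (``drop_unassignable=True``) or
    raise.
    """
    out: list[AnnotatedMutation] = []
    dropped = 0
    for m in mutations:
        triplet = _fetch_triplet(reference, m.chrom, m.pos, record=m)
        if triplet[1] != m.ref:
            raise DataError(
                f"reference mismatch at {m.chrom}:{m.pos}: catalog ref {m.ref}, genome {triplet[1]}"
            )
        try:
            idx, comp = canonical_context(m.ref, m.alt, triplet[0], triplet[2])
        except ContextUnassignableError:
            if drop_unassignable:
                dropped += 1
                continue
            raise
        out.append(AnnotatedMutation(record=m, context96=idx, complemented=comp))
    return out, dropped


def build_spectrum(
    mutations: Sequence, reference: Mapping[str, str]
) -> tuple[Spectrum96, list[AnnotatedMutation]]:
    """Build the 96-channel spectrum of a catalog against a reference.

    Returns the spectrum (summing to the number of assignable mutations)
    and the per-mutation context annotations. N-containing contexts are
    dropped, not imputed.
    """
    annotated, _ = annotate_contexts(mutations, reference)
    counts = np.zeros(96)
    for a in annotated:
        counts[a.context96] += 1
    return Spectrum96(counts), annotated


def spectrum_from_annotated(annotated: Iterable[AnnotatedMutation]) -> Spectrum96:
    counts = np.zeros(96)
    for a in annotated:
        counts[a.context96] += 1
    return Spectrum96(counts)


def cosine_sim(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two nonnegative 96-vectors (scale-invariant)."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if np.any(u < 0) or np.any(v < 0):
        raise DataError("cosine_sim expects nonnegative vectors")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DataError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def spectrum_difference(a: Spectrum96, b: Spectrum96) -> pd.DataFrame:
    """Per-channel and per-class frequency differences, a minus b.

    Both spectra are normalized to frequencies before subtraction. Returns
    a frame with one row per channel plus six aggregate rows (one per
    substitution class, labeled by the bare class).
    """
    fa, fb = a.frequencies(), b.frequencies()
    per_bin = pd.DataFrame(
        {
            "context": list(CONTEXT_LABELS),
            "class": [class_of_context(i) for i in range(96)],
            "freq_a": fa,
            "freq_b": fb,
            "difference": fa - fb,
        }
    )
    per_class = (
        per_bin.groupby("class", sort=False)[["freq_a", "freq_b", "difference"]]
        .sum()
        .reset_index()
        .assign(context=lambda d: d["class"])
    )
    return pd.concat([per_bin, per_class], ignore_index=True)
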