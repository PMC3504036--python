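"""Domain types and haplotype/event conversion.

Coordinates are 1-based and closed throughout.  Gene coordinates count from
the first base of the start codon; amplicon coordinates count from the 5'
end of the labelled forward strand and include any universal-adaptor bases.

The central currency is :class:`PolymorphismEvent`: a single sample-level
difference from a reference gene, leftmost-normalized, with adjacent
substituted bases merged into one multi-nucleotide event and a run of
deleted/inserted bases kept as one event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio import Align

from .exceptions import (
    OutOfAmpliconError,
    UnsupportedDivergenceError,
    ValidationError,
)

NUCLEOTIDES = frozenset("ACGTN")

SUBSTITUTION = "substitution"
DELETION = "deletion"
INSERTION = "insertion"
KINDS = (SUBSTITUTION, DELETION, INSERTION)

DEFAULT_MAX_INDEL = 50


def _check_sequence(seq: str, what: str = "sequence") -> str:
    if not seq:
        raise ValidationError(f"{what} must be non-empty")
    seq = seq.upper()
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise ValidationError(f"{what} contains non-nucleotide characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class GeneSpec:
    """A reference gene: name, length and (optionally) its sequence."""

    name: str
    length_bp: int
    reference_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError("gene length must be positive")
        if self.reference_sequence is not None:
            seq = _check_sequence(self.reference_sequence, f"gene {self.name}")
            object.__setattr__(self, "reference_sequence", seq)
            if len(seq) != self.length_bp:
                raise ValidationError(
                    f"gene {self.name}: length_bp={self.length_bp} but sequence has {len(seq)} bp"
                )


@dataclass(frozen=True)
class AmpliconSpec:
    """Mapping between gene coordinates and labelled-amplicon coordinates.

    ``product_length_L`` includes adaptor bases for two-step label schemes.
    ``forward_start`` is the gene coordinate of the first *templated* base of
    the forward primer: for a sense amplicon that is the lowest templated
    coordinate, for an antisense amplicon the highest (the labelled forward
    strand runs towards decreasing gene coordinates).
    """

    gene: GeneSpec
    product_length_L: int
    forward_start: int
    strand: str = "sense"
    adaptor_len_fwd: int = 0
    adaptor_len_rev: int = 0
    label_scheme: str = "direct"
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("sense", "antisense"):
            raise ValidationError(f"unknown strand {self.strand!r}")
        if self.adaptor_len_fwd < 0 or self.adaptor_len_rev < 0:
            raise ValidationError("adaptor lengths must be non-negative")
        if self.product_length_L < self.adaptor_len_fwd + self.adaptor_len_rev + 1:
            raise ValidationError("product length smaller than adaptors")
        lo, hi = self.templated_span
        if lo < 1 or hi > self.gene.length_bp:
            raise ValidationError(
                f"amplicon [{lo}, {hi}] not contained in gene "
                f"{self.gene.name} [1, {self.gene.length_bp}]"
            )

    @property
    def templated_length(self) -> int:
        return self.product_length_L - self.adaptor_len_fwd - self.adaptor_len_rev

    @property
    def templated_span(self) -> tuple[int, int]:
        """Gene-coordinate interval (closed) covered by templated bases."""
        if self.strand == "sense":
            return self.forward_start, self.forward_start + self.templated_length - 1
        return self.forward_start - self.templated_length + 1, self.forward_start


@dataclass(frozen=True, order=True)
class PolymorphismEvent:
    """One sample-level difference from the reference gene."""

    sample: str
    gene: str
    position_g: int
    kind: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.position_g < 1:
            raise ValidationError("positions are 1-based")
        if self.kind == SUBSTITUTION:
            if len(self.ref_allele) != len(self.alt_allele) or not self.ref_allele:
                raise ValidationError("substitution alleles must be equal-length, non-empty")
            if self.ref_allele == self.alt_allele:
                raise ValidationError("substitution alleles must differ")
        elif self.kind == DELETION:
            if self.alt_allele or not self.ref_allele:
                raise ValidationError("deletion must have ref allele and empty alt allele")
        elif self.kind == INSERTION:
            if self.ref_allele or not self.alt_allele:
                raise ValidationError("insertion must have alt allele and empty ref allele")

    @property
    def weight(self) -> int:
        """Mutated base pairs contributed by this event."""
        return max(len(self.ref_allele), len(self.alt_allele))

    @property
    def ref_span(self) -> tuple[int, int]:
        """Closed interval of reference coordinates occupied by the event.

        Insertions occupy the zero-width boundary before ``position_g`` and
        are reported as ``(position_g, position_g - 1)``.
        """
        return self.position_g, self.position_g + len(self.ref_allele) - 1


@dataclass(frozen=True)
class MismatchSite:
    """One heteroduplex mismatch, located in amplicon coordinates."""

    position_p: int
    event: PolymorphismEvent | None = None


def gene_to_amplicon(position_g: int, spec: AmpliconSpec) -> int:
    """Map a gene coordinate onto the labelled-forward-strand coordinate."""
    lo, hi = spec.templated_span
    if not lo <= position_g <= hi:
        raise OutOfAmpliconError(
            f"gene position {position_g} outside templated span [{lo}, {hi}]"
        )
    if spec.strand == "sense":
        return position_g - spec.forward_start + 1 + spec.adaptor_len_fwd
    return spec.forward_start - position_g + 1 + spec.adaptor_len_fwd


def amplicon_to_gene(position_p: int, spec: AmpliconSpec) -> int:
    """Inverse of :func:`gene_to_amplicon` on the templated span."""
    lo = spec.adaptor_len_fwd + 1
    hi = spec.adaptor_len_fwd + spec.templated_length
    if not lo <= position_p <= hi:
        raise OutOfAmpliconError(
            f"amplicon position {position_p} outside templated band [{lo}, {hi}]"
        )
    if spec.strand == "sense":
        return position_p - 1 - spec.adaptor_len_fwd + spec.forward_start
    return spec.forward_start - (position_p - 1 - spec.adaptor_len_fwd)


def mutant_base_count(events: Iterable[PolymorphismEvent]) -> int:
    """Total mutated base pairs: sum of event weights over sample-events."""
    return sum(e.weight for e in events)


# ---------------------------------------------------------------------------
# enumerate / apply
# ---------------------------------------------------------------------------

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 0
_aligner.mismatch_score = -1
# unit mismatch cost, affine gaps: open 2, extend 1 (first gap base costs 3)
_aligner.open_gap_score = -3
_aligner.extend_gap_score = -1


def _merge_substitution_runs(columns: list[tuple[int, str, str]]) -> list[tuple[int, str, str]]:
    """Collapse adjacent substituted bases into MNP runs."""
    merged: list[tuple[int, str, str]] = []
    for pos, r, a in columns:
        if merged and merged[-1][0] + len(merged[-1][1]) == pos:
            p0, r0, a0 = merged[-1]
            merged[-1] = (p0, r0 + r, a0 + a)
        else:
            merged.append((pos, r, a))
    return merged


def _left_normalize_deletion(ref: str, pos: int, run: str) -> tuple[int, str]:
    while pos > 1 and ref[pos - 2] == run[-1]:
        run = ref[pos - 2] + run[:-1]
        pos -= 1
    return pos, run


def _left_normalize_insertion(ref: str, pos: int, run: str) -> tuple[int, str]:
    while pos > 1 and ref[pos - 2] == run[-1]:
        run = ref[pos - 2] + run[:-1]
        pos -= 1
    return pos, run


def enumerate_polymorphisms(
    ref_seq: str,
    query_seq: str,
    gene: GeneSpec | None = None,
    sample: str = "",
    max_indel: int = DEFAULT_MAX_INDEL,
) -> list[PolymorphismEvent]:
    """Minimal leftmost-normalized event list turning ``ref_seq`` into ``query_seq``.

    Equal-length pairs are compared position-wise; unequal-length pairs are
    globally aligned (unit mismatch cost, affine gaps open 2 / extend 1,
    leftmost ties).  Adjacent substituted bases merge into one MNP event and
    each run of inserted or deleted bases is one event.
    """
    gene_name = gene.name if gene is not None else ""
    ref_seq = _check_sequence(ref_seq, "reference")
    query_seq = _check_sequence(query_seq, "query")
    if abs(len(ref_seq) - len(query_seq)) > max_indel:
        raise UnsupportedDivergenceError(
            f"length difference {abs(len(ref_seq) - len(query_seq))} exceeds "
            f"max-indel bound {max_indel}"
        )
    if gene is not None and len(ref_seq) != gene.length_bp:
        raise ValidationError("reference length disagrees with gene spec")

    sub_columns: list[tuple[int, str, str]] = []
    indels: list[PolymorphismEvent] = []

    if len(ref_seq) == len(query_seq):
        for i, (r, q) in enumerate(zip(ref_seq, query_seq)):
            if r != q:
                sub_columns.append((i + 1, r, q))
    else:
        alignment = _aligner.align(ref_seq, query_seq)[0]
        for (rs, re), (qs, qe) in zip(*alignment.aligned):
            for k in range(re - rs):
                r, q = ref_seq[rs + k], query_seq[qs + k]
                if r != q:
                    sub_columns.append((rs + k + 1, r, q))
        # gaps: walk the aligned block boundaries
        blocks = list(zip(*alignment.aligned))
        prev_r, prev_q = 0, 0
        for (rs, re), (qs, qe) in blocks + [((len(ref_seq), None), (len(query_seq), None))]:
            if rs > prev_r:  # deletion of ref bases prev_r..rs-1 (0-based)
                pos, run = _left_normalize_deletion(ref_seq, prev_r + 1, ref_seq[prev_r:rs])
                indels.append(
                    PolymorphismEvent(sample, gene_name, pos, DELETION, run, "")
                )
            if qs > prev_q:  # insertion of query bases before ref position prev_r+1
                pos, run = _left_normalize_insertion(ref_seq, prev_r + 1, query_seq[prev_q:qs])
                indels.append(
                    PolymorphismEvent(sample, gene_name, pos, INSERTION, "", run)
                )
            prev_r, prev_q = re, qe
            if re is None:
                break

    events = [
        PolymorphismEvent(sample, gene_name, pos, SUBSTITUTION, r, a)
        for pos, r, a in _merge_substitution_runs(sub_columns)
    ]
    events.extend(indels)
    events.sort(key=lambda e: (e.position_g, e.kind))
    return events


def _check_non_overlapping(events: Sequence[PolymorphismEvent]) -> None:
    prev_end = 0
    prev = None
    for e in sorted(events, key=lambda e: (e.ref_span[0], e.ref_span[1])):
        start, end = e.ref_span
        if start <= prev_end:
            raise ValidationError(f"overlapping events: {prev} and {e}")
        prev_end = max(prev_end, end)
        prev = e


def apply_events(ref_seq: str, events: Sequence[PolymorphismEvent]) -> str:
    """Reconstruct the haplotype carrying ``events`` on top of ``ref_seq``."""
    ref_seq = _check_sequence(ref_seq, "reference")
    events = sorted(events, key=lambda e: (e.position_g, e.kind))
    _check_non_overlapping(events)
    out: list[str] = []
    cursor = 0  # 0-based index of next unconsumed ref base
    for e in events:
        pos0 = e.position_g - 1
        if pos0 < cursor or e.ref_span[1] > len(ref_seq):
            raise ValidationError(f"event out of range or overlapping: {e}")
        if e.kind == INSERTION and pos0 > len(ref_seq):
            raise ValidationError(f"insertion beyond sequence end: {e}")
        out.append(ref_seq[cursor:pos0])
        if e.ref_allele and ref_seq[pos0 : pos0 + len(e.ref_allele)] != e.ref_allele:
            raise ValidationError(
                f"reference allele mismatch at {e.position_g}: expected "
                f"{e.ref_allele!r}, found {ref_seq[pos0:pos0 + len(e.ref_allele)]!r}"
            )
        out.append(e.alt_allele)
        cursor = pos0 + len(e.ref_allele)
    out.append(ref_seq[cursor:])
    return "".join(out)


def with_identity(event: PolymorphismEvent, sample: str, gene: str) -> PolymorphismEvent:
    """Relabel an event with sample/gene identifiers."""
    return replace(event, sample=sample, gene=gene)
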