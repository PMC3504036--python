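"""Shared format readers/writers: FASTA, TSV dialects, VCF 4.2, metadata.

All writers are deterministic: stable ordering, UTF-8, Unix newlines, TSV
with "." for missing values.  FASTA wraps at 60 columns on write.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .exceptions import ParseError, ValidationError
from .gelsim import GelLane
from .variantmodel import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    AmpliconSpec,
    GeneSpec,
    PolymorphismEvent,
)

POLYMORPHISM_COLUMNS = ["sample", "gene", "position", "kind", "ref", "alt"]
BAND_COLUMNS = ["sample", "amplicon", "channel", "size_bp"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValidationError(f"{path}: duplicate FASTA identifier {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w", newline="\n") as handle:
        SeqIO.write(records, handle, "fasta")  # biopython wraps at 60 columns


# ---------------------------------------------------------------------------
# polymorphism tables
# ---------------------------------------------------------------------------


def write_polymorphism_table(events: Iterable[PolymorphismEvent], path: str | Path) -> None:
    rows = [
        {
            "sample": e.sample,
            "gene": e.gene,
            "position": e.position_g,
            "kind": e.kind,
            "ref": e.ref_allele or ".",
            "alt": e.alt_allele or ".",
        }
        for e in sorted(events)
    ]
    frame = pd.DataFrame(rows, columns=POLYMORPHISM_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_polymorphism_table(path: str | Path) -> list[PolymorphismEvent]:
    try:
        frame = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(POLYMORPHISM_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    events = []
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            events.append(
                PolymorphismEvent(
                    sample=row.sample,
                    gene=row.gene,
                    position_g=int(row.position),
                    kind=row.kind,
                    ref_allele="" if row.ref == "." else row.ref,
                    alt_allele="" if row.alt == "." else row.alt,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return events


# ---------------------------------------------------------------------------
# band tables
# ---------------------------------------------------------------------------


def write_band_table(lanes: Iterable[GelLane], path: str | Path) -> None:
    rows = []
    for lane in sorted(lanes, key=lambda l: l.sample):
        name = lane.amplicon.name or lane.amplicon.gene.name
        for size in sorted(lane.bands_700):
            rows.append({"sample": lane.sample, "amplicon": name, "channel": 700, "size_bp": size})
        for size in sorted(lane.bands_800):
            rows.append({"sample": lane.sample, "amplicon": name, "channel": 800, "size_bp": size})
    frame = pd.DataFrame(rows, columns=BAND_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_band_table(path: str | Path) -> pd.DataFrame:
    """Band rows as a frame (sample, amplicon, channel, size_bp)."""
    try:
        frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(BAND_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col in ("channel", "size_bp"):
        try:
            frame[col] = frame[col].astype(int)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric values in column {col!r}") from exc
    bad = set(frame["channel"]) - {700, 800}
    if bad:
        raise ParseError(f"{path}: unknown channels {sorted(bad)}")
    return frame


def bands_by_sample(frame: pd.DataFrame) -> dict[str, tuple[list[int], list[int]]]:
    """{sample: (sizes_700, sizes_800)} from a band-table frame."""
    out: dict[str, tuple[list[int], list[int]]] = {}
    for sample, group in frame.groupby("sample"):
        out[str(sample)] = (
            sorted(group.loc[group["channel"] == 700, "size_bp"]),
            sorted(group.loc[group["channel"] == 800, "size_bp"]),
        )
    return out


# ---------------------------------------------------------------------------
# presence matrices
# ---------------------------------------------------------------------------


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    """Sample x position grid; header row of position labels, "+"/""/1/0 cells."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, dtype=str)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc
    try:
        frame.columns = [int(c) for c in frame.columns]
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric position labels") from exc
    return frame


def write_presence_matrix(per_sample: Mapping[str, set[int]], path: str | Path) -> None:
    positions = sorted({p for s in per_sample.values() for p in s})
    with open(path, "w", newline="\n") as handle:
        handle.write("sample\t" + "\t".join(map(str, positions)) + "\n")
        for sample in sorted(per_sample):
            cells = ["+" if p in per_sample[sample] else "" for p in positions]
            handle.write(sample + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(
    events: Iterable[PolymorphismEvent],
    path: str | Path,
    reference_sequences: Mapping[str, str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """VCF 4.2 with one record per (gene, position, alleles); samples in INFO.

    Indels are left-anchored per VCF convention: a deletion at internal
    position P is written at POS = P - 1 with the preceding base as anchor
    (``N`` when no reference sequence is available).  Unknown alleles are
    written as ``N``.
    """
    reference_sequences = reference_sequences or {}
    grouped: dict[tuple[str, int, str, str, str], list[str]] = {}
    for e in events:
        key = (e.gene, e.position_g, e.kind, e.ref_allele, e.alt_allele)
        grouped.setdefault(key, []).append(e.sample)

    lines = [
        "##fileformat=VCFv4.2",
        f"##source=cleavescan {__version__}",
        '##INFO=<ID=SAMPLES,Number=.,Type=String,Description="Carrier samples">',
        '##INFO=<ID=KIND,Number=1,Type=String,Description="Event kind">',
    ]
    contigs = sorted({g for g, *_ in grouped} | set(contig_lengths or {}))
    for gene in contigs:
        if contig_lengths and gene in contig_lengths:
            lines.append(f"##contig=<ID={gene},length={contig_lengths[gene]}>")
        else:
            lines.append(f"##contig=<ID={gene}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    def anchor(gene: str, pos0: int) -> str:
        seq = reference_sequences.get(gene)
        return seq[pos0 - 1] if seq and 1 <= pos0 <= len(seq) else "N"

    for (gene, pos, kind, ref, alt), samples in sorted(grouped.items()):
        if kind == SUBSTITUTION:
            vpos, vref, valt = pos, ref or "N", alt or "N"
        elif kind == DELETION:
            vpos = max(pos - 1, 1)
            base = anchor(gene, vpos) if pos > 1 else anchor(gene, 1)
            vref = base + (ref or "N")
            valt = base
        elif kind == INSERTION:
            vpos = max(pos - 1, 1)
            base = anchor(gene, vpos)
            vref = base
            valt = base + (alt or "N")
        else:  # pragma: no cover
            raise ValidationError(f"unknown kind {kind!r}")
        info = f"SAMPLES={','.join(sorted(set(samples)))};KIND={kind}"
        lines.append(f"{gene}\t{vpos}\t.\t{vref}\t{valt}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# amplicon specs and run metadata
# ---------------------------------------------------------------------------


def read_amplicon_json(path: str | Path) -> AmpliconSpec:
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        gene = GeneSpec(name=raw["gene"], length_bp=int(raw["gene_length_bp"]))
        return AmpliconSpec(
            gene=gene,
            product_length_L=int(raw["product_length_L"]),
            forward_start=int(raw["forward_start"]),
            strand=raw.get("strand", "sense"),
            adaptor_len_fwd=int(raw.get("adaptor_len_fwd", 0)),
            adaptor_len_rev=int(raw.get("adaptor_len_rev", 0)),
            label_scheme=raw.get("label_scheme", "direct"),
            name=raw.get("name", ""),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing amplicon field {exc}") from exc


def write_metadata(path: str | Path, command: str, params: Mapping, seed: int | None) -> None:
    payload = {
        "tool": "cleavescan",
        "version": __version__,
        "command": command,
        "seed": seed,
        "params": {k: v for k, v in sorted(params.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
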