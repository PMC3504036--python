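"""Summary statistics: detection rate, screened base pairs, mutation frequency.

Two counting conventions coexist and both are exposed:

* ``base-weighted`` — every mutated base pair counts (a 2-bp MNP counts 2,
  a 6-bp deletion 6).  This is the convention behind per-gene event totals
  and the screened-bp / mutation-frequency arithmetic.
* ``occurrence`` — every per-sample event at a position counts 1.  This is
  the convention behind detection-rate numerators and denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import UndefinedStatisticError, ValidationError
from .variantmodel import PolymorphismEvent

BASE_WEIGHTED = "base-weighted"
OCCURRENCE = "occurrence"


@dataclass(frozen=True)
class DetectionStats:
    """Detected (A1) versus sequencing-confirmed (A2) event counts."""

    A1: int
    A2: int
    false_positives: int = 0

    @property
    def rate(self) -> float:
        return self.A1 / self.A2

    @property
    def rate_percent(self) -> int:
        """Whole-percent display convention (69/108 prints as 64)."""
        return round(100 * self.A1 / self.A2)


@dataclass(frozen=True)
class FrequencyStats:
    """Mutation density over a screened panel."""

    n_samples: int
    gene_length_bp: int
    mutant_bases: int

    @property
    def screened_bp(self) -> int:
        return self.n_samples * self.gene_length_bp

    @property
    def bp_per_mutation(self) -> float:
        if self.mutant_bases <= 0:
            raise UndefinedStatisticError("no mutant bases: frequency undefined")
        return self.screened_bp / self.mutant_bases

    @property
    def kb_per_mutation(self) -> float:
        """Display convention: kb rounded to 2 decimals."""
        return round(self.bp_per_mutation / 1000.0, 2)


def detection_rate(
    detected: Mapping[str, set],
    confirmed: Mapping[str, set],
) -> DetectionStats:
    """A1/A2 over per-sample per-position occurrences.

    A1 counts detections among confirmed sites only; detections without a
    sequencing-confirmed counterpart are reported as ``false_positives`` and
    excluded from A1.
    """
    samples = set(detected) | set(confirmed)
    a1 = a2 = fp = 0
    for s in samples:
        det = set(detected.get(s, set()))
        conf = set(confirmed.get(s, set()))
        a1 += len(det & conf)
        a2 += len(conf)
        fp += len(det - conf)
    if a2 == 0:
        raise UndefinedStatisticError("no confirmed events: detection rate undefined")
    return DetectionStats(A1=a1, A2=a2, false_positives=fp)


def screened_bp(n_samples: int, gene_length_bp: int) -> int:
    """Total base pairs screened: samples x gene length."""
    if n_samples <= 0 or gene_length_bp <= 0:
        raise ValidationError("sample count and gene length must be positive")
    return n_samples * gene_length_bp


def mutation_frequency(screened: int, mutant_bases: int) -> float:
    """Base pairs screened per mutated base pair."""
    if mutant_bases <= 0:
        raise UndefinedStatisticError("zero mutants: frequency undefined")
    return screened / mutant_bases


def tabulate_events(
    events: Iterable[PolymorphismEvent],
    mode: str = BASE_WEIGHTED,
) -> pd.DataFrame:
    """Per-(gene, position) counts plus per-gene totals.

    Returns a frame indexed by (gene, position) with columns ``count`` and
    ``n_samples``; ``count`` follows ``mode``.  The per-gene total of
    base-weighted counts equals ``mutant_base_count`` of the same events.
    """
    if mode not in (BASE_WEIGHTED, OCCURRENCE):
        raise ValidationError(f"unknown counting mode {mode!r}")
    rows: dict[tuple[str, int], dict[str, int]] = {}
    for e in events:
        key = (e.gene, e.position_g)
        cell = rows.setdefault(key, {"count": 0, "n_samples": 0})
        cell["count"] += e.weight if mode == BASE_WEIGHTED else 1
        cell["n_samples"] += 1
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if frame.empty:
        frame = pd.DataFrame(columns=["count", "n_samples"], dtype=int)
        frame.index = pd.MultiIndex.from_tuples([], names=["gene", "position"])
        return frame
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["gene", "position"])
    return frame.sort_index()


def gene_totals(events: Iterable[PolymorphismEvent], mode: str = BASE_WEIGHTED) -> dict[str, int]:
    """Per-gene event totals under the chosen counting convention."""
    table = tabulate_events(events, mode=mode)
    if table.empty:
        return {}
    return table["count"].groupby(level="gene").sum().to_dict()


def stats_report(
    events: Iterable[PolymorphismEvent],
    n_samples: int,
    gene_lengths: Mapping[str, int],
    detection: Mapping[str, DetectionStats] | None = None,
) -> pd.DataFrame:
    """Per-gene report frame: screened bp, mutant bases, kb/mutation, A1/A2."""
    events = list(events)
    totals = gene_totals(events, mode=BASE_WEIGHTED)
    distinct = (
        tabulate_events(events).groupby(level="gene").size().to_dict() if events else {}
    )
    rows = []
    for gene, length in gene_lengths.items():
        freq = FrequencyStats(n_samples, length, totals.get(gene, 0))
        row = {
            "gene": gene,
            "n_samples": n_samples,
            "gene_length_bp": length,
            "screened_bp": freq.screened_bp,
            "mutant_bases": freq.mutant_bases,
            "distinct_positions": distinct.get(gene, 0),
            "kb_per_mutation": freq.kb_per_mutation if freq.mutant_bases else float("nan"),
        }
        if detection and gene in detection:
            d = detection[gene]
            row.update(A1=d.A1, A2=d.A2, rate_percent=d.rate_percent)
        rows.append(row)
    return pd.DataFrame(rows)
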