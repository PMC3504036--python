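"""Synthetic reference genes and sample cohorts, plus packaged table fixtures.

The generator reproduces the statistical structure every pipeline stage has
to cope with: cohorts dominated by shared haplotypes, per-gene mutation
densities from roughly one event per 1.2 kb down to one per 7.3 kb,
multi-allelic recurrent positions, short MNPs and deletions, and optional
dense mutation bursts (many events packed into a ~30 bp window).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import variantmodel as vm
from .exceptions import GenerationError, ValidationError

_MAX_PLACEMENT_TRIES = 200

_FIXTURE_SHA256 = {
    "family_accd_bands.tsv": "675717b25f7054d99ad64757e7966c7382ca070014adc50a0f889f4434216f55",
    "family_atp6_presence.tsv": "4dc265359ed205b410bb88041255d9b6691700e69cb74d08a895759310c93f47",
    "intraspecific_panel_events.tsv": "533d8707a8c1b8b77742e70348b8b8da3d4f3a651f3e9469088268321ac3b5a7",
    "family_accd_scan.tsv": "cb0c80af299d0bfb36262b95c869cd2f73709888cfbb5ca5aafd2f9a23e3eb80",
    "family_atp6_scan.tsv": "c52196853841288661604e75a41173308f5c907e3027fe41ced60db6b5f641fe",
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters for one synthetic cohort."""

    genes: tuple[tuple[str, int], ...]
    n_samples: int
    seed: int = 0
    haplotype_clusters: tuple[tuple[int, float], ...] = ()  # (cluster size, expected events)
    per_site_rate: float = 0.0  # substitutions per bp per non-clustered haplotype
    mnp_prob: float = 0.0
    deletion_prob: float = 0.0
    deletion_length_range: tuple[int, int] = (2, 6)
    recurrent_position_prob: float = 0.0
    cluster_burst: tuple[int, int] | None = None  # (n_events, window_bp)

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or not self.genes:
            raise ValidationError("need positive sample count and at least one gene")
        for name, length in self.genes:
            if length <= 0:
                raise ValidationError(f"gene {name}: non-positive length")
        if not (0.0 <= self.mnp_prob and 0.0 <= self.deletion_prob
                and self.mnp_prob + self.deletion_prob <= 1.0):
            raise ValidationError("event-kind mixture weights must lie in [0,1], sum <= 1")
        if not 0.0 <= self.recurrent_position_prob <= 1.0:
            raise ValidationError("recurrent_position_prob must lie in [0, 1]")
        if sum(size for size, _ in self.haplotype_clusters) > self.n_samples:
            raise ValidationError("haplotype clusters exceed sample count")
        lo, hi = self.deletion_length_range
        if lo < 1 or hi < lo:
            raise ValidationError("bad deletion length range")


@dataclass
class Cohort:
    """References, haplotypes and ground-truth events of one synthetic run."""

    config: CohortConfig
    references: dict[str, str]
    haplotypes: dict[str, dict[str, str]]  # sample -> gene -> sequence
    truth: list[vm.PolymorphismEvent]

    @property
    def samples(self) -> list[str]:
        return list(self.haplotypes)

    def truth_by_sample_gene(self) -> dict[tuple[str, str], list[vm.PolymorphismEvent]]:
        out: dict[tuple[str, str], list[vm.PolymorphismEvent]] = {}
        for e in self.truth:
            out.setdefault((e.sample, e.gene), []).append(e)
        return out

    def write(self, outdir: str | Path) -> None:
        from . import io as cio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_fasta(self.references, outdir / "reference.fasta")
        for gene, _ in self.config.genes:
            cio.write_fasta(
                {s: self.haplotypes[s][gene] for s in self.samples},
                outdir / f"samples_{gene}.fasta",
            )
        cio.write_polymorphism_table(self.truth, outdir / "truth.tsv")
        sidecar = asdict(self.config)
        (outdir / "cohort.json").write_text(json.dumps(sidecar, indent=2) + "\n")


def _draw_event(
    rng: np.random.Generator,
    ref: str,
    occupied: set[int],
    config: CohortConfig,
    registry: dict[int, vm.PolymorphismEvent],
    window: tuple[int, int] | None = None,
) -> vm.PolymorphismEvent:
    """One non-overlapping event on ``ref``; raises after capped retries."""
    length = len(ref)
    lo, hi = window if window else (1, length)
    for _ in range(_MAX_PLACEMENT_TRIES):
        u = rng.random()
        if u < config.deletion_prob:
            lo_d, hi_d = config.deletion_length_range
            kind, w = vm.DELETION, int(rng.integers(lo_d, hi_d + 1))
        elif u < config.deletion_prob + config.mnp_prob:
            kind, w = vm.SUBSTITUTION, 2
        else:
            kind, w = vm.SUBSTITUTION, 1

        pos = None
        if (
            kind == vm.SUBSTITUTION
            and w == 1
            and registry
            and rng.random() < config.recurrent_position_prob
        ):
            pos = int(rng.choice(sorted(registry)))
        if pos is None:
            pos = int(rng.integers(lo, hi - w + 2))
        # events stay >= 1 unchanged base apart so they never merge
        guard = set(range(pos - 1, pos + w + 1))
        if guard & occupied or pos + w - 1 > length:
            continue
        span = set(range(pos, pos + w))
        ref_allele = ref[pos - 1 : pos - 1 + w]
        if kind == vm.DELETION:
            # leftmost-normalized by construction: forbid left-context match
            if pos > 1 and ref[pos - 2] == ref_allele[-1]:
                continue
            event = vm.PolymorphismEvent("", "", pos, vm.DELETION, ref_allele, "")
        else:
            alt = "".join(
                str(rng.choice([b for b in "ACGT" if b != r])) for r in ref_allele
            )
            event = vm.PolymorphismEvent("", "", pos, vm.SUBSTITUTION, ref_allele, alt)
        occupied.update(span)
        if event.kind == vm.SUBSTITUTION and event.weight == 1:
            registry.setdefault(pos, event)
        return event
    raise GenerationError(
        "could not place event without overlap; lower the event density"
    )


def generate(config: CohortConfig) -> Cohort:
    """Generate a cohort; fixed seed means byte-identical outputs.

    The truth table is re-derived with ``enumerate_polymorphisms`` from the
    built haplotypes, so it is guaranteed to round-trip exactly.
    """
    rng = np.random.default_rng(config.seed)
    references = {
        name: "".join(rng.choice(list("ACGT"), size=length))
        for name, length in config.genes
    }
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]

    # assign samples to shared-haplotype clusters; remainder are singletons
    assignments: list[tuple[str, int | None]] = []
    cursor = 0
    for ci, (size, _) in enumerate(config.haplotype_clusters):
        for _ in range(size):
            assignments.append((samples[cursor], ci))
            cursor += 1
    for s in samples[cursor:]:
        assignments.append((s, None))

    registry_per_gene: dict[str, dict[int, vm.PolymorphismEvent]] = {
        g: {} for g, _ in config.genes
    }
    cluster_events: dict[int, dict[str, list[vm.PolymorphismEvent]]] = {}
    haplotypes: dict[str, dict[str, str]] = {}
    truth: list[vm.PolymorphismEvent] = []

    burst_used = False

    def events_for_gene(gene: str, n_events: int) -> list[vm.PolymorphismEvent]:
        nonlocal burst_used
        ref = references[gene]
        occupied: set[int] = set()
        events: list[vm.PolymorphismEvent] = []
        if config.cluster_burst and not burst_used:
            burst_used = True
            n_burst, window_bp = config.cluster_burst
            if window_bp >= len(ref):
                raise GenerationError("burst window wider than gene")
            if n_burst > (window_bp + 1) // 2 + 1:
                raise GenerationError(
                    f"cannot fit {n_burst} separated events into {window_bp} bp"
                )
            start = int(rng.integers(2, len(ref) - window_bp))
            # dense bursts need systematic packing: evenly spaced SNPs
            step = max(2, window_bp // max(n_burst - 1, 1))
            for k in range(n_burst):
                pos = start + k * step
                ref_base = ref[pos - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                events.append(
                    vm.PolymorphismEvent("", "", pos, vm.SUBSTITUTION, ref_base, alt)
                )
                occupied.update({pos})
        for _ in range(n_events):
            events.append(
                _draw_event(rng, ref, occupied, config, registry_per_gene[gene])
            )
        return sorted(events, key=lambda e: e.position_g)

    for sample, cluster in assignments:
        haplotypes[sample] = {}
        for gene, length in config.genes:
            if cluster is not None:
                if cluster not in cluster_events:
                    cluster_events[cluster] = {}
                if gene not in cluster_events[cluster]:
                    expected = config.haplotype_clusters[cluster][1]
                    n_events = int(rng.poisson(expected))
                    cluster_events[cluster][gene] = events_for_gene(gene, n_events)
                events = cluster_events[cluster][gene]
            else:
                n_events = int(rng.binomial(length, config.per_site_rate))
                events = events_for_gene(gene, n_events)
            hap = vm.apply_events(references[gene], events)
            haplotypes[sample][gene] = hap
            derived = vm.enumerate_polymorphisms(
                references[gene], hap, sample=sample
            )
            truth.extend(vm.with_identity(e, sample, gene) for e in derived)

    return Cohort(
        config=config, references=references, haplotypes=haplotypes, truth=truth
    )


def references_for_events(
    events: Sequence[vm.PolymorphismEvent],
    gene_lengths: Mapping[str, int],
    seed: int = 0,
) -> dict[str, str]:
    """Random reference sequences consistent with an event table.

    Backgrounds are uniform random; bases covered by any event's reference
    allele are planted so ``apply_events``/haplotype reconstruction succeed.
    Conflicting reference alleles at one position raise.
    """
    rng = np.random.default_rng(seed)
    refs: dict[str, list[str]] = {
        g: list("".join(rng.choice(list("ACGT"), size=length)))
        for g, length in gene_lengths.items()
    }
    for e in events:
        if e.gene not in refs:
            raise ValidationError(f"event references unknown gene {e.gene!r}")
        row = refs[e.gene]
        for k, base in enumerate(e.ref_allele):
            i = e.position_g - 1 + k
            if i >= len(row):
                raise ValidationError(f"event beyond gene end: {e}")
            row[i] = base
    # second pass: detect genuine conflicts between events
    planted: dict[tuple[str, int], str] = {}
    for e in events:
        for k, base in enumerate(e.ref_allele):
            key = (e.gene, e.position_g + k)
            if planted.setdefault(key, base) != base:
                raise ValidationError(f"conflicting reference alleles at {key}")
    return {g: "".join(row) for g, row in refs.items()}


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


@dataclass
class ScanComparisonBlock:
    """Position/allele matrix with per-sample scan outcomes for one gene."""

    frame: pd.DataFrame
    reference: str
    samples: tuple[str, ...]

    def confirmed_sets(self) -> dict[str, set[int]]:
        """Per-sample positions whose allele differs from the reference."""
        out = {s: set() for s in self.samples}
        for _, row in self.frame.iterrows():
            for s in self.samples:
                if row[s] != row["ref"]:
                    out[s].add(int(row["position"]))
        return out

    def detected_sets(self) -> dict[str, set[int]]:
        """Per-sample positions marked as detected ('+')."""
        out = {s: set() for s in self.samples}
        for _, row in self.frame.iterrows():
            for s in self.samples:
                if row[f"det_{s}"] == "+":
                    out[s].add(int(row["position"]))
        return out


@dataclass
class Fixtures:
    band_table: pd.DataFrame  # per-site dual-channel band sizes with carriers
    presence_matrix: pd.DataFrame  # mt-gene sample x position grid
    panel_events: list[vm.PolymorphismEvent]  # intraspecific panel truth
    scan_accd: ScanComparisonBlock
    scan_atp6: ScanComparisonBlock
    panel_gene_lengths: dict[str, int]
    panel_n_samples: int


def _read_fixture(name: str) -> str:
    data = resources.files("cleavescan.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise ValidationError(f"fixture {name} corrupted (sha256 {digest})")
    return data.decode()


def make_fixtures() -> Fixtures:
    """Packaged, checksum-pinned study tables as structured fixtures."""
    from io import StringIO

    band = pd.read_csv(StringIO(_read_fixture("family_accd_bands.tsv")), sep="\t")
    band["samples"] = band["samples"].map(lambda s: tuple(s.split(",")))

    presence = pd.read_csv(
        StringIO(_read_fixture("family_atp6_presence.tsv")), sep="\t", index_col=0,
        keep_default_na=False,
    )
    presence.columns = [int(c) for c in presence.columns]

    events_frame = pd.read_csv(
        StringIO(_read_fixture("intraspecific_panel_events.tsv")), sep="\t",
        keep_default_na=False,
    )
    events = [
        vm.PolymorphismEvent(
            sample=r["sample"], gene=r["gene"], position_g=int(r["position"]),
            kind=r["kind"], ref_allele=r["ref"], alt_allele=r["alt"],
        )
        for _, r in events_frame.iterrows()
    ]

    def block(name: str, reference: str, samples: tuple[str, ...]) -> ScanComparisonBlock:
        frame = pd.read_csv(StringIO(_read_fixture(name)), sep="\t", keep_default_na=False)
        return ScanComparisonBlock(frame=frame, reference=reference, samples=samples)

    return Fixtures(
        band_table=band,
        presence_matrix=presence,
        panel_events=events,
        scan_accd=block("family_accd_scan.tsv", "A64", ("A65", "A67", "A68", "A69")),
        scan_atp6=block("family_atp6_scan.tsv", "A24", ("A67", "A76", "A83", "A90")),
        panel_gene_lengths={"accD": 1470, "matK": 1575, "rbcL": 1440},
        panel_n_samples=96,
    )
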