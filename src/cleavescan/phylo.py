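"""Haplotype phylogenetics: K2P distances, neighbour joining, bootstrap.

The distance is the two-parameter correction
``D = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))`` with ``P``/``Q`` the
transition/transversion proportions over pairwise-complete sites (gaps and
N excluded per pair).  Trees come from the classic Saitou-Nei agglomeration
with a lexicographic tie-break on the Q-criterion; bootstrap supports count
how often each internal bipartition of the full-data tree recurs across
column-resampled replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import SaturationError, ValidationError
from .variantmodel import DELETION, PolymorphismEvent, apply_events

# nucleotide encoding: A=0, C=1, G=2, T=3, anything else excluded pairwise
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_PURINE = {0, 2}


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pair_codes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-site class: 0 identical, 1 transition, 2 transversion, 3 excluded."""
    codes = np.zeros(a.shape, dtype=np.uint8)
    valid = (a != 255) & (b != 255)
    diff = valid & (a != b)
    purine_a = (a == 0) | (a == 2)
    purine_b = (b == 0) | (b == 2)
    transition = diff & (purine_a == purine_b)
    codes[transition] = 1
    codes[diff & ~transition] = 2
    codes[~valid] = 3
    return codes


def k2p_from_counts(n_same: int, n_ts: int, n_tv: int) -> float:
    total = n_same + n_ts + n_tv
    if total == 0:
        raise ValidationError("no pairwise-complete sites")
    P, Q = n_ts / total, n_tv / total
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P undefined for P={P:.4f}, Q={Q:.4f}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise ValidationError("sequences must be aligned to equal length")
    codes = _pair_codes(_encode(seq_a), _encode(seq_b))
    counts = np.bincount(codes, minlength=4)
    return k2p_from_counts(int(counts[0]), int(counts[1]), int(counts[2]))


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        n = len(self.taxa)
        if D.shape != (n, n):
            raise ValidationError("matrix shape disagrees with taxa")
        if np.isnan(D).any() or np.isinf(D).any():
            raise ValidationError("distances must be finite")
        if not np.allclose(D, D.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0):
            raise ValidationError("diagonal must be zero")
        if (D < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        object.__setattr__(self, "D", D)


def k2p_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """All-pairs K2P matrix; identical sequences are deduplicated internally."""
    taxa = tuple(sequences)
    seq_of = {t: sequences[t] for t in taxa}
    uniq: dict[str, list[str]] = {}
    for t in taxa:
        uniq.setdefault(seq_of[t], []).append(t)
    reps = list(uniq)
    enc = [_encode(s) for s in reps]
    n = len(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    D = np.zeros((n, n))
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            d = k2p(reps[i], reps[j])
            for ti in uniq[reps[i]]:
                for tj in uniq[reps[j]]:
                    D[index[ti], index[tj]] = D[index[tj], index[ti]] = d
    return DistanceMatrix(taxa=taxa, D=D)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class Node:
    name: str = ""
    children: list[tuple["Node", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree (serialized rooted at an arbitrary trifurcation)."""

    root: Node
    taxa: tuple[str, ...]
    supports: dict[frozenset, int] | None = None
    n_replicates: int | None = None
    clamped_branches: int = 0

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each normalized to exclude the anchor taxon."""
        anchor = min(self.taxa)
        full = set(self.taxa)
        out: set[frozenset] = set()

        def visit(node: Node) -> set[str]:
            below: set[str] = set()
            for child, _ in node.children:
                below |= visit(child)
            if not node.children:
                below.add(node.name)
            side = below if anchor not in below else full - below
            if 2 <= len(side) <= len(full) - 2:
                out.add(frozenset(side))
            return below

        visit(self.root)
        return out

    def has_clade(self, taxa: Iterable[str]) -> bool:
        """True if ``taxa`` forms one side of a bipartition of the tree."""
        group = set(taxa)
        anchor = min(self.taxa)
        side = group if anchor not in group else set(self.taxa) - group
        return frozenset(side) in self.bipartitions()

    def support_for(self, taxa: Iterable[str]) -> int | None:
        if self.supports is None:
            return None
        group = set(taxa)
        anchor = min(self.taxa)
        side = group if anchor not in group else set(self.taxa) - group
        return self.supports.get(frozenset(side))

    def to_newick(self) -> str:
        anchor = min(self.taxa)
        full = set(self.taxa)

        def fmt(node: Node) -> str:
            if not node.children:
                return node.name
            inner = ",".join(f"{fmt(c)}:{length:.6f}" for c, length in node.children)
            label = ""
            if self.supports is not None:
                below = set(node.leaves())
                side = below if anchor not in below else full - below
                sup = self.supports.get(frozenset(side))
                if sup is not None:
                    label = str(sup)
            return f"({inner}){label}"

        return fmt(self.root) + ";"


def nj(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour joining.

    Q-criterion ties break on the lexicographically smallest pair of cluster
    labels (a cluster is labelled by its smallest leaf).  Negative branch
    length estimates are clamped to zero and counted.
    """
    n = len(dm.taxa)
    if n < 2:
        raise ValidationError("need at least 2 taxa")
    # canonical taxon order: results independent of input ordering
    order = sorted(range(n), key=lambda i: dm.taxa[i])
    taxa = tuple(dm.taxa[i] for i in order)
    D = dm.D[np.ix_(order, order)].copy()
    nodes: list[Node] = [Node(name=t) for t in taxa]
    labels: list[str] = list(taxa)
    clamped = 0

    def clamp(v: float) -> float:
        nonlocal clamped
        if v < 0:
            clamped += 1
            return 0.0
        return v

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        Q[np.tril_indices(m)] = np.inf  # search i < j only
        qmin = Q.min()
        cand = np.argwhere(Q == qmin)
        i, j = min(
            ((int(a), int(b)) for a, b in cand),
            key=lambda ij: tuple(sorted((labels[ij[0]], labels[ij[1]]))),
        )
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = Node(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        new_d = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], new_d[keep]])
        D = np.hstack([D, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    if len(nodes) == 2:
        half = clamp(0.5 * D[0, 1])
        root = Node(children=[(nodes[0], half), (nodes[1], D[0, 1] - half)])
    else:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        l0 = clamp(0.5 * (d01 + d02 - d12))
        l1 = clamp(0.5 * (d01 + d12 - d02))
        l2 = clamp(0.5 * (d02 + d12 - d01))
        root = Node(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
    if clamped:
        warnings.warn(f"clamped {clamped} negative branch length(s) to zero")
    _collapse_zero_internal(root)
    return PhyloTree(root=root, taxa=taxa, clamped_branches=clamped)


def _collapse_zero_internal(node: Node, eps: float = 1e-12) -> None:
    """Merge internal edges of ~zero length into their parent (-> multifurcation).

    Ties between identical sequences otherwise resolve into arbitrary
    zero-length bifurcations; collapsing them makes the star tree explicit
    and keeps bipartitions meaningful.
    """
    merged: list[tuple[Node, float]] = []
    for child, length in node.children:
        _collapse_zero_internal(child, eps)
        if child.children and length <= eps:
            merged.extend(child.children)
        else:
            merged.append((child, length))
    node.children = merged


def path_length_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths (for additivity checks)."""
    index = {t: i for i, t in enumerate(tree.taxa)}
    n = len(tree.taxa)
    D = np.zeros((n, n))

    def visit(node: Node) -> dict[str, float]:
        if not node.children:
            return {node.name: 0.0}
        sides: list[dict[str, float]] = []
        for child, length in node.children:
            below = visit(child)
            sides.append({t: d + length for t, d in below.items()})
        for a in range(len(sides)):
            for b in range(a + 1, len(sides)):
                for ta, da in sides[a].items():
                    for tb, db in sides[b].items():
                        D[index[ta], index[tb]] = D[index[tb], index[ta]] = da + db
        merged: dict[str, float] = {}
        for s in sides:
            merged.update(s)
        return merged

    visit(tree.root)
    return DistanceMatrix(taxa=tree.taxa, D=D)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    alignment: Mapping[str, str],
    n_reps: int = 1000,
    seed: int | None = None,
) -> PhyloTree:
    """NJ tree of ``alignment`` with bootstrap supports on its bipartitions.

    Columns are resampled with replacement per replicate; replicate ``r``
    draws from the ``r``-th spawned RNG stream, so results do not depend on
    evaluation order.  Identical sequences are deduplicated when computing
    distances (their distance is exactly zero), which keeps large panels of
    shared haplotypes fast without changing any distance.
    """
    if n_reps < 1:
        raise ValidationError("need at least one replicate")
    taxa = tuple(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValidationError("alignment rows must have equal length")
    n_cols = lengths.pop()
    if n_cols < 1:
        raise ValidationError("alignment must have at least one column")

    full_tree = nj(k2p_matrix(alignment))
    target = full_tree.bipartitions()
    supports = {bp: 0 for bp in target}

    # precompute per-unique-pair site classes once
    uniq: dict[str, list[str]] = {}
    for t in taxa:
        uniq.setdefault(alignment[t], []).append(t)
    reps = list(uniq)
    pair_codes: dict[tuple[int, int], np.ndarray] = {}
    for i in range(len(reps)):
        ei = _encode(reps[i])
        for j in range(i + 1, len(reps)):
            pair_codes[(i, j)] = _pair_codes(ei, _encode(reps[j]))

    index = {t: k for k, t in enumerate(taxa)}
    n = len(taxa)
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(streams[r])
        cols = rng.integers(0, n_cols, size=n_cols)
        D = np.zeros((n, n))
        ok = True
        for (i, j), codes in pair_codes.items():
            counts = np.bincount(codes[cols], minlength=4)
            try:
                d = k2p_from_counts(int(counts[0]), int(counts[1]), int(counts[2]))
            except (SaturationError, ValidationError):
                ok = False
                break
            for ti in uniq[reps[i]]:
                for tj in uniq[reps[j]]:
                    D[index[ti], index[tj]] = D[index[tj], index[ti]] = d
        if not ok:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_tree = nj(DistanceMatrix(taxa=taxa, D=D))
        for bp in rep_tree.bipartitions():
            if bp in supports:
                supports[bp] += 1
    full_tree.supports = supports
    full_tree.n_replicates = n_reps
    return full_tree


# ---------------------------------------------------------------------------
# alignment assembly
# ---------------------------------------------------------------------------


def concat_alignment(
    gene_alignments: Mapping[str, Mapping[str, str]],
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate per-gene alignments; returns (supermatrix, partitions).

    Genes are concatenated in mapping order; every gene must cover the same
    sample set.  Partitions are (gene, start, end) 1-based closed intervals.
    """
    genes = list(gene_alignments)
    if not genes:
        raise ValidationError("no gene alignments given")
    samples = set(gene_alignments[genes[0]])
    for g in genes:
        if set(gene_alignments[g]) != samples:
            missing = samples ^ set(gene_alignments[g])
            raise ValidationError(f"gene {g}: sample set mismatch ({sorted(missing)[:5]})")
    out = {s: [] for s in sorted(samples)}
    partitions = []
    offset = 0
    for g in genes:
        aln = gene_alignments[g]
        width = {len(v) for v in aln.values()}
        if len(width) != 1:
            raise ValidationError(f"gene {g}: rows of unequal length")
        w = width.pop()
        partitions.append((g, offset + 1, offset + w))
        offset += w
        for s in out:
            out[s].append(aln[s])
    return {s: "".join(parts) for s, parts in out.items()}, partitions


def reconstruct_haplotypes(
    reference: str,
    events_by_sample: Mapping[str, Sequence[PolymorphismEvent]],
    samples: Sequence[str],
) -> dict[str, str]:
    """Gapped per-sample sequences for one gene from reference-anchored events.

    Deleted bases become ``-`` columns, so all rows stay reference-length and
    aligned without realignment; insertions are not representable this way
    and are rejected.  Samples without events get the reference row.
    """
    out: dict[str, str] = {}
    for s in samples:
        events = list(events_by_sample.get(s, ()))
        row = list(reference)
        for e in sorted(events, key=lambda e: e.position_g):
            i = e.position_g - 1
            if e.kind == DELETION:
                if reference[i : i + len(e.ref_allele)] != e.ref_allele:
                    raise ValidationError(f"reference allele mismatch for {e}")
                for k in range(len(e.ref_allele)):
                    row[i + k] = "-"
            elif e.kind == "substitution":
                if reference[i : i + len(e.ref_allele)] != e.ref_allele:
                    raise ValidationError(f"reference allele mismatch for {e}")
                for k, b in enumerate(e.alt_allele):
                    row[i + k] = b
            else:
                raise ValidationError("insertions are not representable in gapped rows")
        out[s] = "".join(row)
    return out
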