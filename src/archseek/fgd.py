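"""Functional genome distribution (FGD).

Turns all-vs-all ORFeome similarity into genome-genome functional distances,
clusters the genomes with UPGMA, and mines conserved / cluster-specific gene
sets from best-hit e-values.

The per-ORF score against a target genome is the self-normalised bit-score
ratio ``s = min(1, best_hit_bits / self_bits)`` (0 with no qualifying hit).
Genome-level similarity ``S(A, B)`` is the mean of ``s`` over the ORFs of A
(ORFs shorter than 30 residues are excluded as noise), and the symmetric
distance is ``D(A, B) = 1 - (S(A, B) + S(B, A)) / 2``, which is 0 on the
diagonal and bounded by [0, 1] by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .io_formats import OrfSet
from .similarity import AlignParams, best_hits, self_bit_scores

__all__ = [
    "DistanceMatrix",
    "GeneSets",
    "MIN_ORF_LEN",
    "coverage_score",
    "fgd_distance_matrix",
    "upgma",
    "mine_gene_sets",
]

logger = logging.getLogger(__name__)

MIN_ORF_LEN = 30  # residues; shorter ORFs are excluded from genome means
_SYMMETRY_TOL = 1e-9


@dataclass
class DistanceMatrix:
    """Symmetric functional distances in [0, 1] with genome labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0, atol=_SYMMETRY_TOL):
            raise ValueError("distance matrix has a non-zero diagonal")
        if not np.allclose(self.values, self.values.T, atol=_SYMMETRY_TOL):
            raise ValueError("distance matrix is not symmetric")
        if (self.values < -_SYMMETRY_TOL).any() or (self.values > 1 + _SYMMETRY_TOL).any():
            raise ValueError("distance matrix entries outside [0, 1]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


@dataclass
class GeneSets:
    """Conserved-core and cluster-specific ORF ids of a reference genome."""

    conserved_core: set[str]
    cluster_specific: set[str]


def coverage_score(best_hit_bits: float | None, self_bits: float) -> float:
    """Self-normalised bit-score ratio in [0, 1]."""
    if self_bits <= 0:
        raise ValueError("self_bits must be positive (degenerate ORF)")
    if best_hit_bits is None:
        return 0.0
    return min(1.0, best_hit_bits / self_bits)


def _directed_similarity(
    query_set: OrfSet,
    hit_table: pd.DataFrame,
    self_bits: dict[str, float],
) -> float:
    bits_by_query = dict(zip(hit_table["query_orf"], hit_table["bitscore"]))
    scores = []
    for orf in query_set:
        if len(orf) < MIN_ORF_LEN:
            continue
        sb = self_bits[orf.orf_id]
        if sb <= 0:
            continue
        scores.append(coverage_score(bits_by_query.get(orf.orf_id), sb))
    if not scores:
        raise ValueError(
            f"genome {query_set.genome_id!r} has no scorable ORFs "
            f"(all shorter than {MIN_ORF_LEN} residues?)"
        )
    return float(np.mean(scores))


def fgd_distance_matrix(
    genomes: list[OrfSet],
    params: AlignParams | None = None,
    hits: dict[tuple[str, str], pd.DataFrame] | None = None,
) -> DistanceMatrix:
    """Symmetric FGD distance matrix over a panel of ORFeomes.

    ``hits`` may supply precomputed best-hit tables keyed by
    ``(query_genome, target_genome)``; missing pairs are computed with
    :func:`archseek.similarity.best_hits`.
    """
    params = params or AlignParams()
    for g in genomes:
        if len(g) == 0:
            raise ValueError(f"genome {g.genome_id!r} has zero ORFs")
    labels = [g.genome_id for g in genomes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate genome labels in panel")
    hits = dict(hits) if hits else {}
    by_label = {g.genome_id: g for g in genomes}
    selfbits = {g.genome_id: self_bit_scores(g, params) for g in genomes}

    n = len(genomes)
    S = np.eye(n)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                continue
            table = hits.get((a, b))
            if table is None:
                logger.debug("computing best hits %s -> %s", a, b)
                table = best_hits(by_label[a], by_label[b], params)
            S[i, j] = _directed_similarity(by_label[a], table, selfbits[a])
    D = 1.0 - (S + S.T) / 2.0
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, 1.0)
    return DistanceMatrix(labels, D)


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """UPGMA dendrogram of a distance matrix.

    Iteratively merges the closest pair of clusters; the distance from a
    merged cluster to any other is the size-weighted average (i.e. the
    arithmetic mean over the original leaf pairs), and the merge node sits
    at half the merge distance.  Among equal minimal distances the pair whose
    sorted label pair is lexicographically smallest is merged first, making
    the result deterministic.
    """
    if len(dm.labels) < 2:
        raise ValueError("UPGMA requires at least 2 genomes")
    dm.validate()

    # cluster state: id -> (min_leaf_label, size, height, newick)
    clusters = {
        i: (lab, 1, 0.0, lab) for i, lab in enumerate(dm.labels)
    }
    dist = {
        frozenset((i, j)): float(dm.values[i, j])
        for i in range(len(dm.labels))
        for j in range(i + 1, len(dm.labels))
    }
    next_id = len(dm.labels)

    while len(clusters) > 1:
        best_key = None
        best = None
        for pair, d in dist.items():
            i, j = sorted(pair)
            lab_pair = tuple(sorted((clusters[i][0], clusters[j][0])))
            key = (d, lab_pair)
            if best is None or key < best:
                best = key
                best_key = pair
        i, j = sorted(best_key)
        d = dist[best_key]
        (lab_i, n_i, h_i, nw_i) = clusters[i]
        (lab_j, n_j, h_j, nw_j) = clusters[j]
        height = d / 2.0
        newick = (
            f"({nw_i}:{height - h_i:.10g},{nw_j}:{height - h_j:.10g})"
        )
        new = next_id
        next_id += 1
        for k in list(clusters):
            if k in (i, j):
                continue
            dk = (
                n_i * dist[frozenset((i, k))] + n_j * dist[frozenset((j, k))]
            ) / (n_i + n_j)
            dist[frozenset((new, k))] = dk
        for pair in [p for p in dist if i in p or j in p]:
            del dist[pair]
        del clusters[i], clusters[j]
        clusters[new] = (min(lab_i, lab_j), n_i + n_j, height, newick)

    (_, _, _, newick) = next(iter(clusters.values()))
    tree = dendropy.Tree.get(data=newick + ";", schema="newick")
    return tree


def merge_order(dm: DistanceMatrix) -> list[tuple[tuple[str, ...], float]]:
    """The UPGMA merge sequence as (sorted member-leaf tuple, height) pairs.

    Exposed for cross-checking against independent agglomeration oracles.
    """
    if len(dm.labels) < 2:
        return []
    members = {i: (lab,) for i, lab in enumerate(dm.labels)}
    clusters = {i: (lab, 1, 0.0) for i, lab in enumerate(dm.labels)}
    dist = {
        frozenset((i, j)): float(dm.values[i, j])
        for i in range(len(dm.labels))
        for j in range(i + 1, len(dm.labels))
    }
    next_id = len(dm.labels)
    order = []
    while len(clusters) > 1:
        best_key, best = None, None
        for pair, d in dist.items():
            i, j = sorted(pair)
            lab_pair = tuple(sorted((clusters[i][0], clusters[j][0])))
            key = (d, lab_pair)
            if best is None or key < best:
                best, best_key = key, pair
        i, j = sorted(best_key)
        d = dist[best_key]
        lab_i, n_i, _ = clusters[i]
        lab_j, n_j, _ = clusters[j]
        new = next_id
        next_id += 1
        merged = tuple(sorted(members[i] + members[j]))
        order.append((merged, d / 2.0))
        for k in list(clusters):
            if k in (i, j):
                continue
            dist[frozenset((new, k))] = (
                n_i * dist[frozenset((i, k))] + n_j * dist[frozenset((j, k))]
            ) / (n_i + n_j)
        for pair in [p for p in dist if i in p or j in p]:
            del dist[pair]
        members[new] = merged
        clusters[new] = (min(lab_i, lab_j), n_i + n_j, d / 2.0)
        del clusters[i], clusters[j], members[i], members[j]
    return order


def mine_gene_sets(
    reference: OrfSet,
    hits: dict[tuple[str, str], pd.DataFrame],
    cluster: list[str],
    cutoff: float = 1e-100,
    e_floor: float = 1e-3,
) -> GeneSets:
    """Mine conserved-core and cluster-specific ORFs of a reference genome.

    ``hits`` maps ``(reference_genome, target_genome)`` to best-hit tables;
    the set of target genomes defines the panel.  ``conserved_core`` contains
    reference ORFs hit at e-value <= ``cutoff`` in every cluster genome;
    ``cluster_specific`` additionally requires no hit at e-value <= ``e_floor``
    in any genome outside the cluster.
    """
    if cutoff > e_floor:
        raise ValueError("cutoff must be <= e_floor")
    if not cluster:
        raise ValueError("cluster is empty")
    if reference.genome_id not in cluster:
        raise ValueError(
            f"reference genome {reference.genome_id!r} is not in the cluster"
        )
    panel = sorted({tgt for (q, tgt) in hits if q == reference.genome_id})
    outside = [g for g in panel if g not in cluster]
    evalue_of: dict[str, dict[str, float]] = {}
    for g in panel:
        table = hits[(reference.genome_id, g)]
        evalue_of[g] = dict(zip(table["query_orf"], table["evalue"]))

    conserved, specific = set(), set()
    for orf in reference:
        oid = orf.orf_id
        in_all = all(
            evalue_of[g].get(oid, float("inf")) <= cutoff
            for g in cluster
            if g in evalue_of
        )
        if not in_all:
            continue
        conserved.add(oid)
        if all(evalue_of[g].get(oid, float("inf")) > e_floor for g in outside):
            specific.add(oid)
    return GeneSets(conserved_core=conserved, cluster_specific=specific)
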