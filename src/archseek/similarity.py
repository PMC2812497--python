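"""Built-in pairwise protein similarity search.

A stand-in for an external BLASTP run: Smith-Waterman local alignment with
affine gaps (via Biopython's ``PairwiseAligner``), Karlin-Altschul bit scores
and e-values, and a best-hit search between two ORF sets.  Externally produced
BLAST tabular files are drop-in replacements via
:func:`archseek.io_formats.read_hit_table`.

Scoring conventions
-------------------
* BLOSUM62 by default, with ``X`` scored 0 against everything.
* A gap of length ``k`` costs ``gap_open + k * gap_extend`` (BLAST
  convention; 11 + k at the defaults).
* ``bit = (lambda * raw - ln K) / ln 2``; ``E = m * n * 2**(-bit)`` where
  ``m`` and ``n`` are the query and subject lengths.  The gapped
  Karlin-Altschul parameters default to the standard BLOSUM62/11/1 values
  (lambda = 0.267, K = 0.041).  No composition-based statistics and no
  low-complexity masking are applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import OrfSet, make_hit_table

__all__ = ["AlignParams", "Alignment", "align_pair", "best_hits", "self_bit_scores"]

MAX_SEQ_LEN_DEFAULT = 50_000


@dataclass
class AlignParams:
    """Alignment scoring and e-value parameters."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    evalue_ceiling: float = 10.0
    max_len: int = MAX_SEQ_LEN_DEFAULT
    # optional shared k-mer seed prefilter; exact-off by default so the
    # brute-force DP oracle equivalence holds
    seed_prefilter: bool = False
    seed_k: int = 5
    min_seed_hits: int = 1
    _aligner: Align.PairwiseAligner | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    @property
    def aligner(self) -> Align.PairwiseAligner:
        if self._aligner is None:
            matrix = substitution_matrices.load(self.matrix_name)
            matrix = _zero_x(matrix)
            aligner = Align.PairwiseAligner()
            aligner.mode = "local"
            aligner.substitution_matrix = matrix
            # first gapped position costs open+extend, each further one extend
            aligner.open_gap_score = -(self.gap_open + self.gap_extend)
            aligner.extend_gap_score = -self.gap_extend
            self._aligner = aligner
        return self._aligner

    def bit_score(self, raw: float) -> float:
        return (self.karlin_lambda * raw - math.log(self.karlin_k)) / math.log(2)

    def evalue(self, bit: float, m: int, n: int) -> float:
        return m * n * 2.0 ** (-bit)


def _zero_x(matrix):
    arr = substitution_matrices.Array(alphabet=matrix.alphabet, dims=2)
    for a in matrix.alphabet:
        for b in matrix.alphabet:
            arr[a, b] = 0.0 if ("X" in (a, b)) else matrix[a, b]
    return arr


@dataclass(frozen=True)
class Alignment:
    """A local alignment with its raw score, bit score and e-value."""

    raw_score: int
    bit_score: float
    evalue: float
    query_interval: tuple[int, int] | None = None  # 0-based half-open
    subject_interval: tuple[int, int] | None = None

    @property
    def is_hit(self) -> bool:
        return self.raw_score > 0


def _check_seq(seq: str, params: AlignParams, what: str) -> None:
    if not seq:
        raise ValueError(f"{what} sequence is empty")
    if len(seq) > params.max_len:
        raise ValueError(
            f"{what} sequence of length {len(seq)} exceeds the cap "
            f"({params.max_len}); use an external search tool for such inputs"
        )


def align_pair(a: str, b: str, params: AlignParams | None = None) -> Alignment:
    """Smith-Waterman local alignment of two protein sequences.

    ``raw_score == 0`` means no reportable hit (no positively scoring local
    alignment exists).
    """
    params = params or AlignParams()
    _check_seq(a, params, "query")
    _check_seq(b, params, "subject")
    score = int(params.aligner.score(a, b))
    if score <= 0:
        return Alignment(0, float("-inf"), float("inf"))
    aln = next(iter(params.aligner.align(a, b)))
    qiv = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    siv = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    bit = params.bit_score(score)
    return Alignment(score, bit, params.evalue(bit, len(a), len(b)), qiv, siv)


def _score(a: str, b: str, params: AlignParams) -> int:
    return int(params.aligner.score(a, b))


def _kmers(seq: str, k: int) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def best_hits(
    queries: OrfSet,
    targets: OrfSet,
    params: AlignParams | None = None,
) -> pd.DataFrame:
    """Best subject in ``targets`` for every query ORF.

    Only hits with ``evalue <= params.evalue_ceiling`` are reported; queries
    with no qualifying hit are absent from the table.  Ties are broken by
    highest bit score, then lexicographically smallest subject id.
    """
    params = params or AlignParams()
    if len(targets) == 0:
        warnings.warn(f"empty target set {targets.genome_id!r}", stacklevel=2)
        return make_hit_table([])

    target_orfs = sorted(targets, key=lambda o: o.orf_id)
    if params.seed_prefilter:
        kmer_index = {o.orf_id: _kmers(o.protein, params.seed_k) for o in target_orfs}

    rows = []
    for q in queries:
        if params.seed_prefilter:
            qk = _kmers(q.protein, params.seed_k)
            candidates = [
                t
                for t in target_orfs
                if len(qk & kmer_index[t.orf_id]) >= params.min_seed_hits
            ]
        else:
            candidates = target_orfs
        best = None  # (evalue, -bitscore, subject_id, raw)
        for t in candidates:
            raw = _score(q.protein, t.protein, params)
            if raw <= 0:
                continue
            bit = params.bit_score(raw)
            ev = params.evalue(bit, len(q.protein), len(t.protein))
            if ev > params.evalue_ceiling:
                continue
            key = (ev, -bit, t.orf_id)
            if best is None or key < best[0]:
                best = (key, raw)
        if best is not None:
            (ev, neg_bit, sid), _raw = best
            rows.append(
                {
                    "query_orf": q.orf_id,
                    "query_genome": queries.genome_id,
                    "subject_orf": sid,
                    "subject_db": targets.genome_id,
                    "evalue": ev,
                    "bitscore": -neg_bit,
                }
            )
    return make_hit_table(rows)


def self_bit_scores(orfset: OrfSet, params: AlignParams | None = None) -> dict[str, float]:
    """Bit score of each ORF aligned to itself (the coverage normaliser)."""
    params = params or AlignParams()
    out = {}
    for orf in orfset:
        raw = _score(orf.protein, orf.protein, params)
        out[orf.orf_id] = params.bit_score(raw) if raw > 0 else 0.0
    return out
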