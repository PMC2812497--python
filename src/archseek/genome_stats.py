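"""Nucleotide-level genome statistics.

Windowed G+C content and GC skew ``(G - C) / (G + C)`` along the replicon,
cumulative-skew prediction of the replication origin (the global minimum of
the cumulative series marks the polarity switch), the codon adaptation index
(CAI), and a composite horizontal-gene-transfer flag that combines atypical
G+C, low CAI and a non-methanogen top hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "CompositionProfile",
    "composition_profile",
    "CaiModel",
    "compute_cai",
    "flag_hgt",
]

_CODON_TABLE = unambiguous_dna_by_id[11]  # bacterial/archaeal code
STOP_CODONS = frozenset(_CODON_TABLE.stop_codons)

# amino acid -> synonymous codon family
SYNONYMOUS: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    SYNONYMOUS.setdefault(aa, []).append(codon)
for fam in SYNONYMOUS.values():
    fam.sort()

# codons excluded from the CAI geometric mean: Met and Trp (no synonymous
# choice) and stops
_CAI_EXCLUDED = STOP_CODONS | {"ATG", "TGG"}


@dataclass
class CompositionProfile:
    """Windowed composition along a replicon (starts are 1-based)."""

    window: int
    step: int
    starts: np.ndarray
    gc: np.ndarray
    skew: np.ndarray
    cum_skew: np.ndarray
    oric_candidate: int  # polarity switch at the cumulative-skew minimum
    terminus_candidate: int  # polarity switch at the maximum


def composition_profile(
    seq: str,
    window: int = 5000,
    step: int = 500,
    circular: bool = True,
) -> CompositionProfile:
    """Per-window GC fraction and GC skew with cumulative-skew extrema.

    Windows start every ``step`` bases; on circular replicons they wrap
    around the end so the whole molecule is tiled.  ``N`` bases are ignored
    in both numerator and denominator.
    """
    if window <= 0 or step <= 0 or window < step:
        raise ValueError("require window >= step > 0")
    seq = seq.upper()
    n = len(seq)
    if n < window:
        raise ValueError(f"sequence length {n} is shorter than the window")
    arr = np.frombuffer(seq.encode(), dtype="S1")
    bad = ~np.isin(arr, np.array([b"A", b"C", b"G", b"T", b"N"]))
    if bad.any():
        pos = int(np.argmax(bad)) + 1
        raise ValueError(f"illegal base at position {pos}")

    if circular:
        starts0 = np.arange(0, n, step)
        ext = np.concatenate([arr, arr[: window - 1]])
    else:
        starts0 = np.arange(0, n - window + 1, step)
        ext = arr
    is_g = np.concatenate([[0], np.cumsum(ext == b"G")])
    is_c = np.concatenate([[0], np.cumsum(ext == b"C")])
    is_n = np.concatenate([[0], np.cumsum(ext == b"N")])
    g = is_g[starts0 + window] - is_g[starts0]
    c = is_c[starts0 + window] - is_c[starts0]
    nn = is_n[starts0 + window] - is_n[starts0]
    denom = window - nn
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(denom > 0, (g + c) / np.maximum(denom, 1), 0.0)
        skew = np.where((g + c) > 0, (g - c) / np.maximum(g + c, 1), 0.0)
    cum = np.cumsum(skew)
    # the polarity switch sits at the end of the extremal window: skew is
    # negative approaching the origin and positive after it
    oric = int((starts0[int(np.argmin(cum))] + window) % n) + 1
    term = int((starts0[int(np.argmax(cum))] + window) % n) + 1
    return CompositionProfile(
        window=window,
        step=step,
        starts=starts0 + 1,
        gc=gc,
        skew=skew,
        cum_skew=cum,
        oric_candidate=oric,
        terminus_candidate=term,
    )


# ---------------------------------------------------------------------------
# codon adaptation index


@dataclass
class CaiModel:
    """Relative adaptiveness ``w`` per codon, fitted on a reference gene set.

    ``w = frequency / max synonymous frequency``; codons never observed in
    the reference get the pseudo-floor 0.01 so the geometric mean stays
    defined.
    """

    w: dict[str, float]

    PSEUDO_FLOOR = 0.01

    @classmethod
    def from_reference(cls, genes: Iterable[str]) -> "CaiModel":
        counts: dict[str, int] = {}
        for gene in genes:
            for codon in _iter_codons(gene):
                counts[codon] = counts.get(codon, 0) + 1
        w: dict[str, float] = {}
        for fam in SYNONYMOUS.values():
            fam_counts = {c: counts.get(c, 0) for c in fam}
            top = max(fam_counts.values())
            if top == 0:
                # amino acid absent from the reference: flat w of 1 for its
                # whole family (no information to prefer any codon)
                for c in fam:
                    w[c] = 1.0
                continue
            for c in fam:
                w[c] = fam_counts[c] / top if fam_counts[c] > 0 else cls.PSEUDO_FLOOR
        return cls(w)


def _iter_codons(gene: str):
    gene = gene.upper().replace("U", "T")
    if len(gene) % 3 != 0:
        raise ValueError(f"gene length {len(gene)} not divisible by 3")
    for i in range(0, len(gene), 3):
        codon = gene[i : i + 3]
        if codon in STOP_CODONS:
            if i != len(gene) - 3:
                raise ValueError(f"internal stop codon {codon} at position {i + 1}")
            continue  # terminal stop is allowed, never scored
        yield codon


def compute_cai(gene: str, model: CaiModel) -> float:
    """Geometric mean of codon relative adaptiveness over a gene.

    Met (ATG), Trp (TGG) and stop codons are excluded from the mean; codons
    containing ambiguous bases are skipped.
    """
    logs = []
    for codon in _iter_codons(gene):
        if codon in _CAI_EXCLUDED or codon not in model.w:
            continue
        logs.append(np.log(model.w[codon]))
    if not logs:
        raise ValueError("gene has no scorable codons")
    return float(np.exp(np.mean(logs)))


# ---------------------------------------------------------------------------
# HGT flagging


def flag_hgt(
    orf_stats: pd.DataFrame,
    z_cut: float = 2.0,
    cai_q: float = 0.25,
) -> pd.DataFrame:
    """Composite horizontal-gene-transfer flag.

    ``orf_stats`` needs columns ``orf_id``, ``gc`` (per-ORF G+C fraction),
    ``cai`` and ``top_hit_group``.  An ORF is flagged iff its standardized
    GC deviation satisfies ``|gc_z| >= z_cut``, its CAI falls in the lowest
    ``cai_q`` quantile of the genome, and its top hit is a non-methanogen
    (``top_hit_group == "other"``).  At least 20 ORFs are required to
    estimate the genome GC distribution.
    """
    if len(orf_stats) < 20:
        raise ValueError("need at least 20 ORFs to estimate the GC distribution")
    out = orf_stats.copy()
    gc = out["gc"].to_numpy(dtype=float)
    sd = gc.std()
    if sd == 0:
        out["gc_z"] = 0.0
    else:
        out["gc_z"] = (gc - gc.mean()) / sd
    out["cai_percentile"] = _scipy_stats.rankdata(out["cai"], method="average") / len(out)
    out["flagged"] = (
        (out["gc_z"].abs() >= z_cut)
        & (out["cai_percentile"] <= cai_q)
        & (out["top_hit_group"] == "other")
    )
    return out
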