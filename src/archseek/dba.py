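"""Differential BLAST analysis (DBA).

Each ORF's best-hit e-value against two databases — an in-group panel of
methanogen ORFeomes ("db") and an out-group representing the remainder of
known proteins ("nr") — is discretized into an integer trust level
``T = floor(-log10 e)``, floored at e = 1e-3 and capped at 200.  The
differential ``delta = T_nr - T_db`` and a four-way class summarise where
each gene is conserved:

* ``methanogen_specific`` — strong in-group hit, no out-group hit
* ``nonmethanogen_only`` — the mirror image
* ``shared`` — strong hits on both sides (and all borderline cases,
  conservatively)
* ``orphan`` — no hit on either side

Taxon exclusion (removing in-group genera from the out-group database) is the
caller's responsibility.
"""

from __future__ import annotations

import math
from typing import Iterable

import pandas as pd

__all__ = [
    "trust_level",
    "build_trust_profiles",
    "dba_classify",
    "DBA_CLASSES",
]

DBA_CLASSES = ("methanogen_specific", "nonmethanogen_only", "shared", "orphan")

T_CAP_DEFAULT = 200
E_FLOOR_DEFAULT = 1e-3


def trust_level(
    evalue: float | None,
    e_floor: float = E_FLOOR_DEFAULT,
    t_cap: int = T_CAP_DEFAULT,
) -> int:
    """Discretize a best-hit e-value into an integer trust level.

    Absent hits and e-values above ``e_floor`` map to 0; an e-value of
    exactly 0 maps to the cap; otherwise ``min(t_cap, floor(-log10 e))``.
    Monotone non-increasing in the e-value.
    """
    if evalue is None:
        return 0
    if evalue < 0:
        raise ValueError("negative e-value")
    if evalue == 0.0:
        return t_cap
    if evalue > e_floor:
        return 0
    return min(t_cap, math.floor(-math.log10(evalue)))


def _best_evalues(tables: Iterable[pd.DataFrame]) -> dict[str, float]:
    best: dict[str, float] = {}
    for table in tables:
        for q, e in zip(table["query_orf"], table["evalue"]):
            if q not in best or e < best[q]:
                best[q] = float(e)
    return best


def build_trust_profiles(
    orf_ids: list[str],
    hits_db: pd.DataFrame | Iterable[pd.DataFrame],
    hits_nr: pd.DataFrame | Iterable[pd.DataFrame],
    e_floor: float = E_FLOOR_DEFAULT,
    t_cap: int = T_CAP_DEFAULT,
) -> pd.DataFrame:
    """Per-ORF trust levels against the two databases.

    ``hits_db`` / ``hits_nr`` are best-hit tables (one or several, e.g. one
    per panel genome); the strongest e-value per ORF across tables is used.
    """
    if isinstance(hits_db, pd.DataFrame):
        hits_db = [hits_db]
    if isinstance(hits_nr, pd.DataFrame):
        hits_nr = [hits_nr]
    e_db = _best_evalues(hits_db)
    e_nr = _best_evalues(hits_nr)
    rows = [
        {
            "orf_id": oid,
            "t_db": trust_level(e_db.get(oid), e_floor, t_cap),
            "t_nr": trust_level(e_nr.get(oid), e_floor, t_cap),
        }
        for oid in orf_ids
    ]
    return pd.DataFrame(rows, columns=["orf_id", "t_db", "t_nr"])


def classify_one(t_db: int, t_nr: int, tau_present: int = 10, tau_absent: int = 3) -> str:
    if t_db >= tau_present and t_nr < tau_absent:
        return "methanogen_specific"
    if t_nr >= tau_present and t_db < tau_absent:
        return "nonmethanogen_only"
    if t_db >= tau_present and t_nr >= tau_present:
        return "shared"
    if t_db < tau_absent and t_nr < tau_absent:
        return "orphan"
    return "shared"  # borderline: conservative


def dba_classify(
    profiles: pd.DataFrame,
    tau_present: int = 10,
    tau_absent: int = 3,
) -> pd.DataFrame:
    """Classify every ORF and report the differential delta = t_nr - t_db."""
    if not tau_absent < tau_present:
        raise ValueError("require tau_absent < tau_present")
    out = profiles.copy()
    out["delta"] = out["t_nr"] - out["t_db"]
    out["dba_class"] = [
        classify_one(int(d), int(n), tau_present, tau_absent)
        for d, n in zip(out["t_db"], out["t_nr"])
    ]
    return out
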