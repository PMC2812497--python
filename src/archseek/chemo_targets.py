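"""Chemogenomic target selection: three-way gene-set intersection.

Candidate enzymes for small-molecule inhibition are the genes identified
simultaneously by three independent analyses — functional-genome-distribution
conservation, differential-homology methanogen specificity, and a curated
metabolic-profile list — i.e. the central region of the three-set Venn
diagram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["VennReport", "intersect_targets", "read_id_list"]

REGIONS = (
    "fgd_only",
    "dba_only",
    "metabolic_only",
    "fgd_dba",
    "fgd_metabolic",
    "dba_metabolic",
    "core",
)


@dataclass
class VennReport:
    """Counts and member lists for all 7 regions of three ORF-id sets.

    ``core`` (the triple intersection) holds the chemogenomic candidates.
    Member lists are lexicographically sorted.
    """

    members: dict[str, list[str]]

    @property
    def counts(self) -> dict[str, int]:
        return {region: len(ids) for region, ids in self.members.items()}

    @property
    def candidates(self) -> list[str]:
        return self.members["core"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"region": r, "count": len(self.members[r]),
                 "members": ",".join(self.members[r])}
                for r in REGIONS
            ]
        )


def intersect_targets(
    fgd_set: set[str],
    dba_set: set[str],
    metabolic_set: set[str],
    reference_ids: set[str] | None = None,
) -> VennReport:
    """Exact three-set algebra over ORF ids from one reference genome.

    Ids absent from ``reference_ids`` (when given) trigger a warning listing
    the unknowns but are kept in the report.
    """
    f, d, m = set(fgd_set), set(dba_set), set(metabolic_set)
    if reference_ids is not None:
        unknown = sorted((f | d | m) - set(reference_ids))
        if unknown:
            warnings.warn(
                f"{len(unknown)} id(s) not in the reference ORF set: "
                + ", ".join(unknown),
                stacklevel=2,
            )
    members = {
        "fgd_only": f - d - m,
        "dba_only": d - f - m,
        "metabolic_only": m - f - d,
        "fgd_dba": (f & d) - m,
        "fgd_metabolic": (f & m) - d,
        "dba_metabolic": (d & m) - f,
        "core": f & d & m,
    }
    return VennReport({r: sorted(ids) for r, ids in members.items()})


def read_id_list(path: str | Path) -> set[str]:
    """Read a newline-delimited ORF-id list (the curated-input carrier)."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out
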