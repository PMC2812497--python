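"""Reverse-vaccinology surface-protein cascade.

Pools membrane/surface ORFs (one or more predicted transmembrane helices or a
signal peptide), removes non-specific and special classes (top hit outside
the methanogen panel, no homology at all, transposases, adhesins), refines by
conservation across the panel, splits the survivors into Group A (<= 4 TMH,
amenable to heterologous expression) and Group B (> 4 TMH, suited to a
synthetic-peptide approach), and extracts extracellular loop peptides as
antigen candidates.

The built-in transmembrane-helix and signal-peptide predictors are simplified
hydropathy heuristics, deliberately light-weight stand-ins for full
HMM/neural-network topology predictors; the cascade preferentially consumes
imported prediction tables and falls back to the built-ins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "KYTE_DOOLITTLE",
    "Topology",
    "CascadeReport",
    "predict_tmh",
    "predict_signal_peptide",
    "predict_signal_peptide_combined",
    "cascade_filter",
    "extract_surface_loops",
]

# Kyte & Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

HELIX_MIN = 15
HELIX_MAX = 35
MIN_CENTRE_RUN = 8  # shortest run of hydrophobic window centres kept

SP_H_THRESHOLDS = {"strict": 1.8, "default": 1.5, "loose": 1.2}


@dataclass
class Loop:
    """A non-helix segment (1-based inclusive residue interval)."""

    start: int
    end: int
    side: str  # "inside" or "outside"

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class Topology:
    """Predicted membrane topology: helices, orientation, derived loops."""

    helices: list[tuple[int, int]]  # 1-based inclusive intervals
    orientation: str  # "N_in" or "N_out"
    loops: list[Loop] = field(default_factory=list)
    n_residues: int = 0

    @property
    def tmh_count(self) -> int:
        return len(self.helices)


def _hydropathy(seq: str) -> list[float]:
    try:
        return [KYTE_DOOLITTLE[ch] for ch in seq]
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r}") from None


def _window_means(values: list[float], window: int) -> list[float]:
    if len(values) < window:
        return []
    acc = sum(values[:window])
    out = [acc / window]
    for i in range(window, len(values)):
        acc += values[i] - values[i - window]
        out.append(acc / window)
    return out


def _split_region(start: int, end: int) -> list[tuple[int, int]]:
    """Split a residue region into helix-sized (15-35) pieces."""
    length = end - start + 1
    if length <= HELIX_MAX:
        return [(start, end)]
    k = math.ceil(length / HELIX_MAX)
    base, extra = divmod(length, k)
    pieces = []
    pos = start
    for i in range(k):
        size = base + (1 if i < extra else 0)
        pieces.append((pos, pos + size - 1))
        pos += size
    return [p for p in pieces if p[1] - p[0] + 1 >= HELIX_MIN]


def _pad_short_regions(
    regions: list[tuple[int, int]], n: int
) -> list[tuple[int, int]]:
    """Extend sub-minimum regions symmetrically to HELIX_MIN residues,
    staying inside the sequence and clear of neighbouring regions."""
    out: list[tuple[int, int]] = []
    for idx, (start, end) in enumerate(regions):
        deficit = HELIX_MIN - (end - start + 1)
        if deficit > 0:
            left_bound = out[-1][1] + 1 if out else 1
            right_bound = regions[idx + 1][0] - 1 if idx + 1 < len(regions) else n
            grow_left = min(deficit // 2 + deficit % 2, start - left_bound)
            start -= grow_left
            grow_right = min(deficit - grow_left, right_bound - end)
            end += grow_right
        if end - start + 1 >= HELIX_MIN:
            out.append((start, end))
    return out


def predict_tmh(seq: str, window: int = 19, threshold: float = 1.6) -> Topology:
    """Sliding-window hydropathy prediction of transmembrane helices.

    Mean Kyte-Doolittle hydropathy is computed over ``window``-residue
    sliding windows and assigned to each window's central residue; maximal
    runs of above-threshold centres become candidate helices, trimmed or
    split to the 15-35 residue length bound (runs shorter than 8 centres
    are discarded as noise; runs of 8-14 are padded to the 15-residue
    physical minimum).  Orientation follows the positive-inside rule: K+R
    are counted
    in the 15 loop residues flanking each helix on each side, summed over
    all loops, and the side with the higher count is called inside
    (tie -> N_in).  Sequences shorter than ``window`` yield zero helices.
    """
    values = _hydropathy(seq.upper())
    n = len(seq)
    means = _window_means(values, window)
    half = (window - 1) // 2  # centre offset of a window
    regions: list[tuple[int, int]] = []
    run_start = None
    for i, m in enumerate(means + [float("-inf")]):  # sentinel flushes last run
        if m >= threshold and run_start is None:
            run_start = i
        elif m < threshold and run_start is not None:
            if i - run_start >= MIN_CENTRE_RUN:
                # 1-based residue interval of the centre run
                regions.append((run_start + half + 1, (i - 1) + half + 1))
            run_start = None
    regions = _pad_short_regions(regions, n)
    helices: list[tuple[int, int]] = []
    for start, end in regions:
        helices.extend(_split_region(start, end))

    loops = _derive_loops(helices, n)
    orientation = _orientation(seq, helices, loops)
    even_is_inside = orientation == "N_in"
    for idx, loop in enumerate(loops):
        loop.side = "inside" if (idx % 2 == 0) == even_is_inside else "outside"
    return Topology(helices=helices, orientation=orientation, loops=loops, n_residues=n)


def _derive_loops(helices: list[tuple[int, int]], n: int) -> list[Loop]:
    if not helices:
        return [Loop(1, n, "inside")] if n else []
    loops = []
    prev_end = 0
    for s, e in helices:
        if s - 1 >= prev_end + 1:
            loops.append(Loop(prev_end + 1, s - 1, ""))
        else:
            loops.append(Loop(prev_end + 1, prev_end, ""))  # empty placeholder
        prev_end = e
    loops.append(Loop(prev_end + 1, n, "") if prev_end < n else Loop(prev_end + 1, prev_end, ""))
    return loops


def _orientation(seq: str, helices: list[tuple[int, int]], loops: list[Loop]) -> str:
    if not helices:
        return "N_in"
    counts = [0, 0]  # [same side as N-terminus, other side]
    for idx, loop in enumerate(loops):
        if len(loop) <= 0:
            continue
        flank = _flank_residues(seq, loop, helices, idx)
        kr = sum(1 for ch in flank if ch in "KR")
        counts[idx % 2] += kr
    # higher K+R count = inside; tie -> N terminus inside
    return "N_in" if counts[0] >= counts[1] else "N_out"


def _flank_residues(seq: str, loop: Loop, helices, idx: int) -> str:
    """Up to 15 loop residues adjacent to each neighbouring helix."""
    s, e = loop.start - 1, loop.end  # 0-based half-open
    segment = seq[s:e]
    if len(segment) <= 15:
        return segment
    parts = []
    if idx > 0:  # preceded by a helix: take the first 15
        parts.append(segment[:15])
    if idx < len(helices):  # followed by a helix: take the last 15
        parts.append(segment[-15:])
    return "".join(parts) if parts else segment


def predict_signal_peptide(
    seq: str, stringency: str = "default"
) -> tuple[bool, int | None]:
    """Heuristic N-terminal signal-peptide call.

    Positive iff, within the first 45 residues, the sequence shows the
    classic tripartite architecture: (n) at least one K/R in residues 1-5,
    (h) an 8-residue window within residues 4-30 whose mean hydropathy meets
    the stringency threshold (strict 1.8 / default 1.5 / loose 1.2), and
    (c) an A-x-A motif whose second A lies at position 16-40.  The returned
    cleavage position is the residue immediately after that motif.
    """
    try:
        h_thresh = SP_H_THRESHOLDS[stringency]
    except KeyError:
        raise ValueError(f"unknown stringency {stringency!r}") from None
    seq = seq.upper()
    if len(seq) < 25:
        return False, None
    head = seq[:45]

    n_ok = any(ch in "KR" for ch in head[:5])
    if not n_ok:
        return False, None

    values = _hydropathy(head)
    h_ok = False
    for start in range(3, 23):  # 8-residue windows fully within residues 4-30
        if start + 8 > len(head):
            break
        if sum(values[start : start + 8]) / 8.0 >= h_thresh:
            h_ok = True
            break
    if not h_ok:
        return False, None

    for pos in range(15, min(40, len(head))):  # 0-based index of second A
        if head[pos] == "A" and pos >= 2 and head[pos - 2] == "A":
            return True, pos + 2  # cleavage site: residue after the motif
    return False, None


def predict_signal_peptide_combined(
    seq: str, stringencies: tuple[str, ...] = ("strict", "default", "loose")
) -> tuple[bool, int | None]:
    """Combine several stringency presets: positive under ANY preset.

    Mirrors running three differently trained signal-peptide models and
    pooling the verdicts.  The cleavage site of the first positive preset
    (in the order given) is reported.
    """
    for s in stringencies:
        flag, cleavage = predict_signal_peptide(seq, s)
        if flag:
            return True, cleavage
    return False, None


# ---------------------------------------------------------------------------
# cascade


@dataclass
class CascadeReport:
    """Audited output of the surface-target cascade."""

    step_counts: list[tuple[str, int]]
    group_a: list[str]  # tmh_count <= 4
    group_b: list[str]  # tmh_count > 4
    audit: pd.DataFrame  # orf_id, status, removed_at, reason

    def count(self, step: str) -> int:
        for name, n in self.step_counts:
            if name == step:
                return n
        raise KeyError(step)


CASCADE_STEPS = ("input", "membrane_or_sp", "specific", "conserved")


def cascade_filter(
    features: pd.DataFrame,
    min_conservation: int = 1,
    panel_size: int = 1,
) -> CascadeReport:
    """Run the four-step surface-target cascade over a feature table.

    Step 1 keeps ORFs with >= 1 TMH or a signal peptide; step 2 drops ORFs
    whose top hit is outside the methanogen panel (or absent), transposases,
    and adhesin-like ORFs (each with its own recorded reason); step 3 keeps
    ORFs conserved in at least ``min_conservation`` panel genomes (the
    configurable proxy for manual curation); step 4 partitions the survivors
    into Group A (<= 4 TMH) and Group B (> 4 TMH).
    """
    if min_conservation > panel_size:
        raise ValueError("min_conservation cannot exceed panel_size")
    if (features["tmh_count"] < 0).any():
        bad = features.loc[features["tmh_count"] < 0, "orf_id"].tolist()
        raise ValueError(f"negative tmh_count for ORFs: {bad}")

    status: dict[str, tuple[str, str]] = {}  # orf_id -> (removed_at, reason)
    surviving = list(features["orf_id"])
    rows = features.set_index("orf_id")

    def drop(oid: str, step: str, reason: str) -> None:
        status[oid] = (step, reason)

    counts = [("input", len(surviving))]

    kept = []
    for oid in surviving:
        r = rows.loc[oid]
        if r["tmh_count"] >= 1 or bool(r["sp_flag"]):
            kept.append(oid)
        else:
            drop(oid, "membrane_or_sp", "no TMH and no signal peptide")
    surviving = kept
    counts.append(("membrane_or_sp", len(surviving)))

    kept = []
    for oid in surviving:
        r = rows.loc[oid]
        if r["top_hit_group"] in ("other", "none"):
            drop(oid, "specific", f"top hit group '{r['top_hit_group']}'")
        elif bool(r["is_transposase"]):
            drop(oid, "specific", "transposase")
        elif bool(r["is_adhesin"]):
            drop(oid, "specific", "adhesin-like (handled separately)")
        else:
            kept.append(oid)
    surviving = kept
    counts.append(("specific", len(surviving)))

    kept = []
    for oid in surviving:
        if rows.loc[oid, "conservation_count"] >= min_conservation:
            kept.append(oid)
        else:
            drop(oid, "conserved",
                 f"conserved in {rows.loc[oid, 'conservation_count']} "
                 f"< {min_conservation} panel genomes")
    surviving = kept
    counts.append(("conserved", len(surviving)))

    group_a = [oid for oid in surviving if rows.loc[oid, "tmh_count"] <= 4]
    group_b = [oid for oid in surviving if rows.loc[oid, "tmh_count"] > 4]

    audit = pd.DataFrame(
        [
            {
                "orf_id": oid,
                "status": "kept" if oid not in status else "removed",
                "removed_at": status.get(oid, ("", ""))[0],
                "reason": status.get(oid, ("", ""))[1],
            }
            for oid in features["orf_id"]
        ]
    )
    return CascadeReport(counts, group_a, group_b, audit)


@dataclass(frozen=True)
class LoopPeptide:
    start: int  # 1-based inclusive
    end: int
    sequence: str


def extract_surface_loops(
    seq: str,
    topology: Topology,
    l_min: int = 8,
    l_max: int = 40,
) -> list[LoopPeptide]:
    """Extracellular loop peptides of a membrane protein.

    Returns every loop labelled outside whose length is within
    ``[l_min, l_max]``, with residue coordinates; N-/C-terminal tails count
    as loops.
    """
    out = []
    for loop in topology.loops:
        if len(loop) <= 0 or loop.side != "outside":
            continue
        if l_min <= len(loop) <= l_max:
            out.append(LoopPeptide(loop.start, loop.end, seq[loop.start - 1 : loop.end]))
    return out
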