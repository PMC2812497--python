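"""Synthetic ORFeome clades with full ground truth.

Generates a panel of related proteomes diverged along a known tree, with
clade-specific versus universally conserved gene families, membrane proteins
carrying planted transmembrane helices and signal peptides, and horizontally
transferred genes with atypical G+C and codon usage — the statistical
structure every upstream analysis stage assumes, so the whole pipeline is
testable without downloads.

Model
-----
* A root proteome of gene families is sampled from a background amino-acid
  distribution; along each branch every site substitutes with probability
  ``1 - exp(-b)`` (branch length ``b`` in expected substitutions/site) to a
  uniformly chosen different residue.  Substitution is uniform rather than
  matrix-biased so the identity-versus-path-length relation stays in closed
  form: expected pairwise identity between two leaves is approximately
  ``exp(-path length)``.
* Families are lost independently on each branch with a small probability;
  clade-specific families are emitted only inside the designated clade.
  Gene gain is modelled only as clade-specific presence.
* Genes are back-translated under a genome codon model biased toward the
  host G+C; HGT genes instead use a "foreign" donor model whose G+C is
  offset and whose synonymous preferences are randomly re-drawn.
* Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .io_formats import Orf, OrfSet
from .surface_targets import KYTE_DOOLITTLE

__all__ = [
    "SimConfig",
    "SimResult",
    "DEFAULT_TREE",
    "simulate_clade",
    "plant_surface_features",
    "leaf_path_lengths",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# background residue frequencies (roughly natural proteome composition)
BACKGROUND_FREQS = {
    "A": 0.083, "R": 0.057, "N": 0.044, "D": 0.054, "C": 0.014,
    "Q": 0.040, "E": 0.062, "G": 0.072, "H": 0.022, "I": 0.053,
    "L": 0.090, "K": 0.057, "M": 0.024, "F": 0.039, "P": 0.050,
    "S": 0.069, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.067,
}

HELIX_RESIDUES = "ILVFMA"
SP_HYDROPHOBIC = "LIVF"

# default 6-leaf ultrametric tree; merge heights pairwise separated so UPGMA
# can recover the topology from any monotone transform of path length
DEFAULT_TREE = (
    "(((A:0.08,B:0.08):0.12,C:0.20):0.15,"
    "((D:0.12,E:0.12):0.12,F:0.24):0.11);"
)
DEFAULT_CLADE = ("A", "B", "C")

_CODON_OF = {}  # aa -> list of codons, standard code
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables  # noqa: E402

for _codon, _aa in _tables[11].forward_table.items():
    _CODON_OF.setdefault(_aa, []).append(_codon)
for _fam in _CODON_OF.values():
    _fam.sort()
STOPS = sorted(_tables[11].stop_codons)


@dataclass
class SimConfig:
    """Study conditions for a simulated clade.

    Branch lengths are expected substitutions per site; gene lengths are in
    codons.  ``seed`` is mandatory — there is no implicit randomness.
    """

    seed: int
    tree: str = DEFAULT_TREE
    clade: tuple[str, ...] = DEFAULT_CLADE
    n_core_families: int = 200
    n_clade_specific: int = 50
    n_hgt: int = 20
    gene_len_mean: float = 300.0
    gene_len_sd: float = 60.0
    gene_len_min: int = 80
    loss_prob: float = 0.02
    membrane_fraction: float = 0.1
    sp_fraction: float = 0.1
    host_gc: float = 0.30
    donor_gc_offset: float = 0.12

    def __post_init__(self) -> None:
        for name in ("loss_prob", "membrane_fraction", "sp_fraction", "host_gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimResult:
    """Simulated panel: proteomes, nucleotide genomes and the truth table."""

    orfsets: list[OrfSet]
    genomes: dict[str, str]
    truth: pd.DataFrame
    config: SimConfig

    def orfset(self, leaf: str) -> OrfSet:
        for s in self.orfsets:
            if s.genome_id == leaf:
                return s
        raise KeyError(leaf)


# ---------------------------------------------------------------------------
# primitives


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aas = list(BACKGROUND_FREQS)
    probs = np.array([BACKGROUND_FREQS[a] for a in aas])
    probs = probs / probs.sum()
    return "".join(rng.choice(aas, size=length, p=probs))


def _mutate(seq: str, branch_length: float, rng: np.random.Generator) -> str:
    if branch_length <= 0:
        return seq
    p = 1.0 - np.exp(-branch_length)
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < p)
    for i in hits:
        current = chars[i]
        choices = [a for a in AMINO_ACIDS if a != current]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _base_weight(codon: str, gc: float) -> float:
    w = 1.0
    for b in codon:
        w *= gc / 2.0 if b in "GC" else (1.0 - gc) / 2.0
    return w


_MODEL_SHARPNESS = 3.0  # translational-selection-like peaking of preferences


def _codon_model(gc: float, rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
    """Per-amino-acid synonymous codon probabilities.

    Base weights follow the target G+C, sharpened so each family has a
    clearly preferred codon (as translational selection produces in real
    genomes).  With ``rng`` given, preferences are additionally shuffled by
    Dirichlet noise — the "foreign" donor model for transferred genes,
    whose codon usage is decoupled from the host's.
    """
    model = {}
    for aa, fam in _CODON_OF.items():
        w = np.array([_base_weight(c, gc) for c in fam]) ** _MODEL_SHARPNESS
        if rng is not None and len(fam) > 1:
            w = w * rng.dirichlet(np.ones(len(fam)) * 0.5)
        model[aa] = w / w.sum()
    w = np.array([_base_weight(c, gc) for c in STOPS]) ** _MODEL_SHARPNESS
    model["*"] = w / w.sum()
    return model


def _back_translate(protein: str, model: dict[str, np.ndarray], rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        fam = _CODON_OF.get(aa)
        if fam is None:  # X or unknown: neutral codon
            codons.append("NNN")
            continue
        codons.append(fam[rng.choice(len(fam), p=model[aa])])
    codons.append(STOPS[rng.choice(len(STOPS), p=model["*"])])
    return "".join(codons)


def _mean_kd(seq: str) -> float:
    return sum(KYTE_DOOLITTLE[c] for c in seq) / len(seq)


def _sample_helix(rng: np.random.Generator) -> str:
    while True:
        length = int(rng.integers(19, 26))
        helix = "".join(
            HELIX_RESIDUES[rng.integers(len(HELIX_RESIDUES))] for _ in range(length)
        )
        if _mean_kd(helix) >= 2.0:
            return helix


_SP_LEN = 21  # planted signal peptides occupy residues 1-21


def _plant_sp(seq: str, rng: np.random.Generator) -> tuple[str, int]:
    """Overwrite the N-terminus with an n/h/c signal-peptide template.

    Returns the new sequence and the cleavage position (1-based, the residue
    after the A-x-A motif).
    """
    kr = "KR"
    h = "".join(SP_HYDROPHOBIC[rng.integers(4)] for _ in range(12))
    polar = "".join("STN"[rng.integers(3)] for _ in range(3))
    template = "M" + kr[rng.integers(2)] + kr[rng.integers(2)] + h + "ASA" + polar
    assert len(template) == _SP_LEN
    return template + seq[_SP_LEN:], 19


def _plant_helices(
    seq: str, n_helices: int, rng: np.random.Generator, first_pos: int = 6
) -> tuple[str, list[tuple[int, int]]] | None:
    """Overwrite segments with hydrophobic helices separated by long loops.

    ``first_pos`` is the earliest 1-based start for the first helix.  Returns
    None if even a single helix does not fit.
    """
    min_gap, max_gap = 18, 30
    tail = 5
    chars = list(seq)
    intervals = []
    n = n_helices
    while n >= 1:
        # worst-case length requirement for n helices
        need = (first_pos - 1) + n * 25 + (n - 1) * min_gap + tail
        if need <= len(seq):
            break
        n -= 1
    if n < 1:
        return None
    pos = first_pos - 1  # 0-based
    placed = 0
    while placed < n:
        helix = _sample_helix(rng)
        if pos + len(helix) + tail > len(seq):
            break
        chars[pos : pos + len(helix)] = helix
        intervals.append((pos + 1, pos + len(helix)))
        placed += 1
        pos += len(helix) + int(rng.integers(min_gap, max_gap + 1))
    if not intervals:
        return None
    return "".join(chars), intervals


def plant_surface_features(
    proteome: OrfSet,
    membrane_fraction: float,
    sp_fraction: float,
    seed: int | np.random.Generator = 0,
) -> tuple[OrfSet, pd.DataFrame]:
    """Plant transmembrane helices and/or signal peptides into an ORF set.

    A ``membrane_fraction`` of genes receives 1-7 hydrophobic helices
    (19-25 residues, mean Kyte-Doolittle >= 2.0) separated by long loops;
    an independent ``sp_fraction`` receives an N-terminal signal-peptide
    template.  Genes too short to host the requested features are skipped
    with a warning.  Returns the modified ORF set and truth rows recording
    every planted interval.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = proteome.ids
    n = len(ids)
    n_mem = int(round(membrane_fraction * n))
    n_sp = int(round(sp_fraction * n))
    mem_ids = set(rng.choice(ids, size=n_mem, replace=False)) if n_mem else set()
    sp_ids = set(rng.choice(ids, size=n_sp, replace=False)) if n_sp else set()

    new_orfs, rows, skipped = [], [], []
    for orf in proteome:
        seq = orf.protein
        intervals: list[tuple[int, int]] = []
        cleavage = None
        if orf.orf_id in sp_ids:
            if len(seq) >= _SP_LEN + 10:
                seq, cleavage = _plant_sp(seq, rng)
            else:
                skipped.append(orf.orf_id)
        if orf.orf_id in mem_ids:
            first = _SP_LEN + 4 if cleavage is not None else 6
            planted = _plant_helices(seq, int(rng.integers(1, 8)), rng, first_pos=first)
            if planted is None:
                skipped.append(orf.orf_id)
            else:
                seq, intervals = planted
        new_orfs.append(Orf(orf.orf_id, seq, orf.nucleotide, orf.start, orf.end, orf.strand))
        rows.append(
            {
                "orf_id": orf.orf_id,
                "is_membrane": bool(intervals),
                "helix_intervals": ";".join(f"{a}-{b}" for a, b in intervals),
                "is_sp": cleavage is not None,
                "sp_cleavage": cleavage if cleavage is not None else -1,
            }
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} gene(s) too short to host requested features: "
            + ", ".join(sorted(set(skipped))[:5]),
            stacklevel=2,
        )
    return OrfSet(proteome.genome_id, new_orfs), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clade simulation


def _parse_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels")
    return tree


def leaf_path_lengths(newick: str) -> dict[tuple[str, str], float]:
    """Patristic path lengths between all leaf pairs of a Newick tree."""
    tree = _parse_tree(newick)
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            out[(t1.label, t2.label)] = float(pdm.patristic_distance(t1, t2))
    return out


def simulate_clade(cfg: SimConfig) -> SimResult:
    """Simulate a clade of ORFeomes with nucleotide genomes and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    tree = _parse_tree(cfg.tree)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    for c in cfg.clade:
        if c not in leaves:
            raise ValueError(f"clade member {c!r} is not a leaf of the tree")

    families = [f"F{i:04d}" for i in range(1, cfg.n_core_families + 1)]
    specific = [f"C{i:04d}" for i in range(1, cfg.n_clade_specific + 1)]
    all_fams = families + specific

    lengths = {
        fam: max(cfg.gene_len_min, int(round(rng.normal(cfg.gene_len_mean, cfg.gene_len_sd))))
        for fam in all_fams
    }
    root = {fam: _random_protein(rng, lengths[fam]) for fam in all_fams}

    # plant membrane / signal-peptide features at the root so descendants
    # inherit them (coordinates are stable: no indels are simulated)
    root_set = OrfSet("root", [Orf(fam, seq) for fam, seq in root.items()])
    root_set, feat_truth = plant_surface_features(
        root_set, cfg.membrane_fraction, cfg.sp_fraction, rng
    )
    root = {o.orf_id: o.protein for o in root_set}
    feat_by_fam = feat_truth.set_index("orf_id").to_dict("index")

    # evolve along the tree (preorder; deterministic traversal)
    leaf_proteomes: dict[str, dict[str, str]] = {}

    def _descend(node, proteome: dict[str, str]) -> None:
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            child_prot = {}
            for fam in all_fams:
                if fam not in proteome:
                    continue
                if cfg.loss_prob > 0 and rng.random() < cfg.loss_prob:
                    continue
                child_prot[fam] = _mutate(proteome[fam], b, rng)
            if child.is_leaf():
                leaf_proteomes[child.taxon.label] = child_prot
            else:
                _descend(child, child_prot)

    _descend(tree.seed_node, root)

    host_model = _codon_model(cfg.host_gc)
    donor_model = _codon_model(cfg.host_gc + cfg.donor_gc_offset, rng)
    hgt_host = cfg.clade[0]
    hgt_fams = [f"H{i:04d}" for i in range(1, cfg.n_hgt + 1)]

    orfsets, genomes, rows = [], {}, []
    for leaf in leaves:
        proteome = leaf_proteomes[leaf]
        entries = []  # (family, protein, nucleotide, is_hgt)
        for fam in all_fams:
            if fam not in proteome:
                continue
            if fam.startswith("C") and leaf not in cfg.clade:
                continue  # clade-specific families exist only inside the clade
            nt = _back_translate(proteome[fam], host_model, rng)
            entries.append((fam, proteome[fam], nt, False))
        if leaf == hgt_host:
            for fam in hgt_fams:
                length = max(
                    cfg.gene_len_min,
                    int(round(rng.normal(cfg.gene_len_mean, cfg.gene_len_sd))),
                )
                prot = _random_protein(rng, length)
                nt = _back_translate(prot, donor_model, rng)
                entries.append((fam, prot, nt, True))

        genome_parts, orfs = [], []
        pos = 0
        for fam, prot, nt, is_hgt in entries:
            spacer_len = int(rng.integers(100, 201))
            spacer = "".join(
                "ATGC"[i]
                for i in rng.choice(4, size=spacer_len, p=[0.4, 0.4, 0.1, 0.1])
            )
            genome_parts.append(spacer)
            pos += spacer_len
            start = pos + 1
            genome_parts.append(nt)
            pos += len(nt)
            oid = f"{leaf}_{fam}"
            orfs.append(Orf(oid, prot, nucleotide=nt, start=start, end=pos, strand="+"))
            feat = feat_by_fam.get(fam, {})
            rows.append(
                {
                    "genome": leaf,
                    "orf_id": oid,
                    "family": fam,
                    "is_core": fam.startswith("F"),
                    "is_clade_specific": fam.startswith("C"),
                    "is_hgt": is_hgt,
                    "is_membrane": bool(feat.get("is_membrane", False)),
                    "helix_intervals": feat.get("helix_intervals", ""),
                    "is_sp": bool(feat.get("is_sp", False)),
                    "sp_cleavage": int(feat.get("sp_cleavage", -1)),
                    # DarkHorse-style lineage evidence, planted as truth:
                    # transferred genes carry a non-methanogen top hit
                    "top_hit_group": "other" if is_hgt else "methanogen",
                    "length_aa": len(prot),
                }
            )
        genomes[leaf] = "".join(genome_parts)
        orfsets.append(OrfSet(leaf, orfs))

    truth = pd.DataFrame(rows)
    # emitted-presence ground truth: a family is clade-restricted when it
    # occurs in >= 2 clade genomes and nowhere outside the clade.  This
    # covers the planted clade-specific families and the rare core family
    # eroded out of the whole out-group by ancestral loss, which in the
    # emitted data genuinely is specific to the clade.
    presence = truth.groupby("family")["genome"].agg(set)
    clade_set = set(cfg.clade)
    restricted = {
        fam: (gs <= clade_set and len(gs) >= 2) for fam, gs in presence.items()
    }
    truth["is_clade_restricted"] = truth["family"].map(restricted)
    return SimResult(orfsets=orfsets, genomes=genomes, truth=truth, config=cfg)
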