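"""Readers and writers for every external format the pipeline touches.

All downstream modules consume the domain types produced here: :class:`OrfSet`
for predicted proteomes, pandas ``DataFrame`` hit tables for best-hit homology
records, and plain-text exports (Newick, BED, TSV) for results.

Conventions
-----------
* ORF coordinates are stored 1-based inclusive (GenBank convention); BED
  export converts to 0-based half-open.
* Protein alphabet is the 20 standard residues plus ``X``.  The ambiguity
  codes ``B``, ``Z`` and ``U`` are remapped to ``X`` with a warning; any other
  character is rejected with its position.
* Hit tables use the 12-column BLAST tabular dialect (outfmt 6) and are
  reduced to one best hit per (query, subject-database): lowest e-value,
  ties broken by highest bit score, then lexicographic subject id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Orf",
    "OrfSet",
    "HIT_COLUMNS",
    "FEATURE_COLUMNS",
    "read_sequences",
    "read_hit_table",
    "reduce_best_hits",
    "make_hit_table",
    "read_feature_table",
    "write_feature_table",
    "write_fasta",
    "write_newick",
    "write_bed",
    "write_tsv",
    "read_distance_matrix",
    "write_distance_matrix",
]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
_AMBIGUOUS_REMAP = {"B": "X", "Z": "X", "U": "X"}

HIT_COLUMNS = [
    "query_orf",
    "query_genome",
    "subject_orf",
    "subject_db",
    "evalue",
    "bitscore",
]

FEATURE_COLUMNS = [
    "orf_id",
    "tmh_count",
    "tmh_intervals",
    "sp_flag",
    "localization",
    "top_hit_group",
    "is_transposase",
    "is_adhesin",
    "conservation_count",
]


@dataclass(frozen=True)
class Orf:
    """A single predicted ORF: protein sequence plus optional provenance."""

    orf_id: str
    protein: str
    nucleotide: str | None = None
    start: int | None = None  # 1-based inclusive on the source replicon
    end: int | None = None
    strand: str | None = None  # "+" or "-"

    def __len__(self) -> int:
        return len(self.protein)


@dataclass
class OrfSet:
    """One genome's predicted proteome, in input order."""

    genome_id: str
    orfs: list[Orf] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for orf in self.orfs:
            if orf.orf_id in seen:
                raise ValueError(
                    f"duplicate ORF id {orf.orf_id!r} in genome {self.genome_id!r}"
                )
            seen.add(orf.orf_id)
            if not orf.protein:
                raise ValueError(f"ORF {orf.orf_id!r} has an empty protein sequence")
            if orf.start is not None and orf.end is not None:
                if not (1 <= orf.start <= orf.end):
                    raise ValueError(
                        f"ORF {orf.orf_id!r} has invalid coordinates "
                        f"[{orf.start}, {orf.end}]"
                    )

    def __len__(self) -> int:
        return len(self.orfs)

    def __iter__(self):
        return iter(self.orfs)

    def __getitem__(self, orf_id: str) -> Orf:
        try:
            return self._index()[orf_id]
        except KeyError:
            raise KeyError(f"no ORF {orf_id!r} in genome {self.genome_id!r}") from None

    def _index(self) -> dict[str, Orf]:
        # rebuilt lazily; OrfSet instances are small and rarely mutated
        return {o.orf_id: o for o in self.orfs}

    @property
    def ids(self) -> list[str]:
        return [o.orf_id for o in self.orfs]


def clean_protein(seq: str, label: str = "") -> str:
    """Validate a protein sequence, remapping B/Z/U to X.

    Raises ``ValueError`` naming the first illegal character and its 1-based
    position.
    """
    seq = seq.upper()
    out = []
    remapped = []
    for pos, ch in enumerate(seq, start=1):
        if ch in _AMBIGUOUS_REMAP:
            remapped.append((pos, ch))
            ch = "X"
        elif ch not in PROTEIN_ALPHABET:
            raise ValueError(
                f"illegal residue {ch!r} at position {pos} in {label or 'sequence'}"
            )
        out.append(ch)
    if remapped:
        warnings.warn(
            f"{label or 'sequence'}: remapped {len(remapped)} ambiguous residue(s) "
            f"(B/Z/U) to X, first at position {remapped[0][0]}",
            stacklevel=2,
        )
    return "".join(out)


def clean_nucleotide(seq: str, label: str = "") -> str:
    seq = seq.upper().replace("U", "T")
    for pos, ch in enumerate(seq, start=1):
        if ch not in NUCLEOTIDE_ALPHABET:
            raise ValueError(
                f"illegal base {ch!r} at position {pos} in {label or 'sequence'}"
            )
    return seq


# ---------------------------------------------------------------------------
# sequence input


def read_sequences(
    path: str | Path,
    kind: str = "protein_fasta",
    genome_id: str | None = None,
):
    """Read sequences from ``path``.

    kind="protein_fasta"
        returns an :class:`OrfSet` (record order preserved).
    kind="nucleotide_fasta"
        returns a dict ``{record_id: sequence}`` of validated ACGTN strings.
    kind="genbank_lite"
        returns ``(OrfSet, genome_sequence)``; ORFs are CDS features keyed by
        locus_tag, with translations taken from ``/translation`` when present
        and otherwise derived from the nucleotide span by standard-code
        translation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gid = genome_id if genome_id is not None else path.stem

    if kind == "protein_fasta":
        orfs = []
        for rec in SeqIO.parse(str(path), "fasta"):
            if not rec.id:
                raise ValueError(f"{path}: FASTA record with empty header")
            orfs.append(Orf(rec.id, clean_protein(str(rec.seq), rec.id)))
        return OrfSet(gid, orfs)

    if kind == "nucleotide_fasta":
        out = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in out:
                raise ValueError(f"{path}: duplicate record id {rec.id!r}")
            out[rec.id] = clean_nucleotide(str(rec.seq), rec.id)
        return out

    if kind == "genbank_lite":
        return _read_genbank_lite(path, gid)

    raise ValueError(f"unknown kind {kind!r}")


def _read_genbank_lite(path: Path, genome_id: str):
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # truncated / malformed record
        raise ValueError(f"{path}: cannot parse GenBank record: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    rec = records[0]
    genome_seq = clean_nucleotide(str(rec.seq), rec.id) if len(rec.seq) else ""
    orfs = []
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        locus = feat.qualifiers.get("locus_tag", [None])[0]
        if locus is None:
            raise ValueError(f"{path}: CDS feature without /locus_tag")
        start = int(feat.location.start) + 1  # to 1-based inclusive
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        nt = str(feat.extract(rec.seq)) if genome_seq else None
        if "translation" in feat.qualifiers:
            prot = feat.qualifiers["translation"][0]
        else:
            if not nt:
                raise ValueError(
                    f"{path}: CDS {locus} lacks /translation and no ORIGIN "
                    "sequence is available"
                )
            prot = str(Seq(nt).translate(table=11, to_stop=True))
        orfs.append(
            Orf(locus, clean_protein(prot, locus), nucleotide=nt,
                start=start, end=end, strand=strand)
        )
    return OrfSet(genome_id, orfs), genome_seq


# ---------------------------------------------------------------------------
# hit tables


def make_hit_table(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Build a hit table DataFrame from row mappings, filling defaults."""
    df = pd.DataFrame(list(rows))
    for col in HIT_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col not in ("evalue", "bitscore") else float("nan")
    return df[HIT_COLUMNS].reset_index(drop=True)


def reduce_best_hits(df: pd.DataFrame) -> pd.DataFrame:
    """Keep one best hit per (query_orf, subject_db).

    Lowest e-value wins; ties broken by highest bit score, then by
    lexicographically smallest subject id (deterministic).
    """
    if df.empty:
        return df.copy()
    ordered = df.sort_values(
        ["query_orf", "subject_db", "evalue", "bitscore", "subject_orf"],
        ascending=[True, True, True, False, True],
        kind="mergesort",
    )
    best = ordered.groupby(["query_orf", "subject_db"], sort=True).head(1)
    return best.reset_index(drop=True)


def read_hit_table(
    path: str | Path,
    dialect: str = "tabular12",
    query_genome: str = "",
    subject_db: str = "",
    db_of: Callable[[str], str] | None = None,
    reduce: bool = True,
) -> pd.DataFrame:
    """Read a 12-column BLAST tabular file into a best-hit table.

    ``subject_db`` labels every row; alternatively ``db_of`` maps each
    subject id to its database label (for files pooling several databases).
    An empty file yields an empty table (not an error).
    """
    if dialect != "tabular12":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            query, subject = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric evalue/bitscore"
                ) from None
            if evalue < 0:
                raise ValueError(f"{path}:{lineno}: negative e-value")
            rows.append(
                {
                    "query_orf": query,
                    "query_genome": query_genome,
                    "subject_orf": subject,
                    "subject_db": db_of(subject) if db_of else subject_db,
                    "evalue": evalue,
                    "bitscore": bitscore,
                }
            )
    df = make_hit_table(rows)
    return reduce_best_hits(df) if reduce else df


# ---------------------------------------------------------------------------
# feature tables (TMHMM / SignalP style imports)


def _parse_intervals(text: str) -> list[tuple[int, int]]:
    if not text or text in ("-", "."):
        return []
    out = []
    for part in text.split(";"):
        a, b = part.split("-")
        out.append((int(a), int(b)))
    return out


def _format_intervals(intervals: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{a}-{b}" for a, b in intervals) if intervals else "-"


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a per-ORF feature TSV (documented column map in the header)."""
    df = pd.read_csv(path, sep="\t", dtype={"orf_id": str})
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature columns {missing}")
    df = df[FEATURE_COLUMNS].copy()
    df["tmh_intervals"] = df["tmh_intervals"].astype(str).map(_parse_intervals)
    for col in ("sp_flag", "is_transposase", "is_adhesin"):
        df[col] = df[col].astype(bool)
    _validate_features(df)
    return df


def _validate_features(df: pd.DataFrame) -> None:
    for _, row in df.iterrows():
        ivs = row["tmh_intervals"]
        if row["tmh_count"] < 0:
            raise ValueError(f"ORF {row['orf_id']}: negative tmh_count")
        if len(ivs) != row["tmh_count"]:
            raise ValueError(
                f"ORF {row['orf_id']}: tmh_count {row['tmh_count']} does not "
                f"match {len(ivs)} interval(s)"
            )
        prev_end = 0
        for a, b in ivs:
            if a <= prev_end:
                raise ValueError(
                    f"ORF {row['orf_id']}: tmh_intervals overlap or are unsorted"
                )
            prev_end = b


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["tmh_intervals"] = out["tmh_intervals"].map(_format_intervals)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# output writers


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_newick(tree, path: str | Path) -> None:
    """Write a dendropy tree as Newick with branch lengths, ';'-terminated."""
    text = tree.as_string(schema="newick", suppress_rooting=True).strip()
    if not text.endswith(";"):
        text += ";"
    Path(path).write_text(text + "\n")


def write_bed(
    orfset: OrfSet,
    path: str | Path,
    names: Mapping[str, str] | None = None,
    scores: Mapping[str, float] | None = None,
) -> None:
    """Export ORF coordinates as BED (0-based half-open).

    ``names`` supplies the name column per ORF (e.g. a DBA class) and
    ``scores`` the score column, clamped to 0-1000.
    """
    missing = [o.orf_id for o in orfset if o.start is None or o.end is None]
    if missing:
        raise ValueError(
            f"BED export requested but ORFs lack coordinates: {', '.join(missing)}"
        )
    with open(path, "w") as fh:
        for orf in orfset:
            name = names.get(orf.orf_id, orf.orf_id) if names else orf.orf_id
            raw = scores.get(orf.orf_id, 0) if scores else 0
            score = int(min(1000, max(0, raw)))
            strand = orf.strand or "+"
            fh.write(
                f"{orfset.genome_id}\t{orf.start - 1}\t{orf.end}\t"
                f"{name}\t{score}\t{strand}\n"
            )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_distance_matrix(labels: Sequence[str], matrix, path: str | Path) -> None:
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t", index_label="genome"
    )


def read_distance_matrix(path: str | Path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return list(df.index), df.to_numpy(dtype=float)
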