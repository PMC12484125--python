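"""Protein catalog: record model, FASTA/TSV I/O, inclusion filtering,
representative-strain selection.

The catalog holds one :class:`ProteinRecord` per annotated decarboxylase
gene, with enough taxonomy and provenance (species, genus, phylum, strain,
culture collection, genome completeness) to drive the downstream
prevalence and representative-selection steps.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .families import AADCFamily, map_ec_to_family

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: X marks an ambiguous residue; it never counts as a match anywhere.
SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS + "X")

TRUSTED_COLLECTIONS = frozenset({"ATCC", "NCTC", "DSM"})

METADATA_COLUMNS = (
    "record_id",
    "species",
    "genus",
    "phylum",
    "strain",
    "ec",
    "collection",
    "complete_genome",
)


class CatalogError(Exception):
    """Base class for catalog input problems."""


class FastaFormatError(CatalogError):
    pass


class MetadataError(CatalogError):
    pass


class Collection(enum.Enum):
    ATCC = "ATCC"
    NCTC = "NCTC"
    DSM = "DSM"
    OTHER = "OTHER"

    @classmethod
    def parse(cls, text: str) -> "Collection":
        """Map a culture-collection label to the enum; unknowns become OTHER."""
        try:
            return cls(text.strip().upper())
        except ValueError:
            return cls.OTHER


@dataclass
class ProteinRecord:
    """One enzyme sequence with taxonomy, EC annotation and provenance."""

    record_id: str
    species: str
    genus: str
    phylum: str
    strain: str
    ec: str
    sequence: str
    collection: Collection = Collection.OTHER
    complete_genome: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.record_id}: empty sequence")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.record_id}: invalid residues {sorted(bad)}"
            )
        parts = self.ec.split(".")
        if len(parts) != 4 or not all(p.isdigit() for p in parts):
            raise ValueError(f"record {self.record_id}: malformed EC {self.ec!r}")

    @property
    def family(self) -> AADCFamily | None:
        return map_ec_to_family(self.ec)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SpeciesAbundance:
    """Relative abundances of one species across samples (fractions)."""

    species: str
    abundances: Sequence[float]

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.abundances):
            raise ValueError(f"{self.species}: negative abundance")


@dataclass
class Catalog:
    """A set of records plus species and family indices."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MetadataError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species_index(self) -> dict[str, list[ProteinRecord]]:
        idx: dict[str, list[ProteinRecord]] = defaultdict(list)
        for r in self.records:
            idx[r.species].append(r)
        return dict(idx)

    @property
    def family_index(self) -> dict[AADCFamily, list[ProteinRecord]]:
        """Records grouped by AADC family; unmapped ECs are excluded (logged)."""
        idx: dict[AADCFamily, list[ProteinRecord]] = defaultdict(list)
        for r in self.records:
            fam = r.family
            if fam is None:
                logger.info(
                    "record %s: EC %s maps to no AADC family; excluded from "
                    "family analyses",
                    r.record_id,
                    r.ec,
                )
                continue
            idx[fam].append(r)
        return dict(idx)

    def species(self) -> list[str]:
        return sorted({r.species for r in self.records})


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA file into ``(record_id, sequence)`` pairs.

    Sequences are uppercased and terminal stop characters (``*``) stripped;
    record order is preserved.
    """
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has empty sequence")
        out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Metadata and abundance tables
# ---------------------------------------------------------------------------

def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "t"}:
        return True
    if text in {"false", "0", "no", "f"}:
        return False
    raise MetadataError(f"cannot parse boolean {value!r}")


def read_metadata(path: str | Path) -> dict[str, dict]:
    """Read the tab-separated metadata table into per-record field dicts.

    Required columns: ``record_id species genus phylum strain ec collection
    complete_genome``.  Unknown collection strings map to OTHER.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise MetadataError(f"{path}: missing columns {sorted(missing)}")
    if df["record_id"].duplicated().any():
        dupes = sorted(df.loc[df["record_id"].duplicated(), "record_id"])
        raise MetadataError(f"{path}: duplicate record ids {dupes}")
    out: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        out[row.record_id] = {
            "record_id": row.record_id,
            "species": row.species,
            "genus": row.genus,
            "phylum": row.phylum,
            "strain": row.strain,
            "ec": row.ec,
            "collection": Collection.parse(row.collection),
            "complete_genome": _parse_bool(row.complete_genome),
        }
    return out


def load_catalog(fasta_path: str | Path, metadata_path: str | Path) -> Catalog:
    """Join a FASTA file with its metadata table into a Catalog."""
    seqs = dict(read_fasta(fasta_path))
    meta = read_metadata(metadata_path)
    missing = sorted(set(meta) - set(seqs))
    if missing:
        raise CatalogError(f"metadata rows without sequences: {missing[:5]}")
    records = [
        ProteinRecord(sequence=seqs[rid], **fields) for rid, fields in meta.items()
    ]
    return Catalog(records)


def read_abundance(path: str | Path) -> list[SpeciesAbundance]:
    """Read a species x sample relative-abundance table (fractions)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [
        SpeciesAbundance(species=str(sp), abundances=list(df.loc[sp]))
        for sp in df.index
    ]


# ---------------------------------------------------------------------------
# Inclusion filter and representative selection
# ---------------------------------------------------------------------------

def filter_prevalent_species(
    abundances: Sequence[SpeciesAbundance],
    threshold: float = 1e-4,
    min_samples: int = 2,
) -> list[str]:
    """Species whose relative abundance strictly exceeds ``threshold`` in at
    least ``min_samples`` samples.

    Defaults encode the usual prevalence rule for gut-microbiome surveys:
    above 0.01% (as a fraction, 1e-4) in at least two samples.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    kept = []
    for sp in abundances:
        n_hit = sum(1 for a in sp.abundances if a > threshold)
        if n_hit >= min_samples:
            kept.append(sp.species)
    return kept


def _representative_rank(record: ProteinRecord) -> tuple[int, str]:
    trusted = record.collection.name in TRUSTED_COLLECTIONS
    if record.complete_genome and trusted:
        tier = 0
    elif trusted:
        tier = 1
    else:
        tier = 2
    return (tier, record.record_id)


def select_representative(strains: Sequence[ProteinRecord]) -> ProteinRecord:
    """Pick one representative strain record for a species/family group.

    Complete genomes in ATCC/NCTC/DSM collections outrank incomplete
    collection entries, which outrank everything else; ties break on the
    lexicographically smallest record id so the choice is deterministic.
    """
    if not strains:
        raise ValueError("select_representative: empty strain list")
    return min(strains, key=_representative_rank)


def select_representatives(catalog: Catalog) -> Catalog:
    """Reduce a catalog to one representative record per species per family."""
    groups: dict[tuple[str, str], list[ProteinRecord]] = defaultdict(list)
    for rec in catalog.records:
        groups[(rec.species, rec.ec)].append(rec)
    reps = [select_representative(g) for g in groups.values()]
    reps.sort(key=lambda r: r.record_id)
    return Catalog(reps)
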