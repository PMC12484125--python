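"""Synthetic AADC catalogs with known ground truth.

The generator emulates the structure of a gut-microbiome decarboxylase
survey: per-family sequence sets sharing a planted 4-residue PLP-binding
tetrad ending in the catalytic lysine, tunable within-family divergence,
near-identical strain replicates, family-specific length models
(including the bimodal short/long lysine-decarboxylase classes and short
motif-free pyruvoyl-type arginine decarboxylases), per-family species
inclusion probabilities, and injected foreign-motif outliers.

Two deliberate simplifications keep the ground truth unambiguous:
substitutions are uniform over the alternative residues (no rate matrix),
and the planted catalytic lysine is the *only* lysine in a simulated
sequence — the background alphabet excludes K, so motif-free families
contain no lysine at all and a recovered conserved-K column can only be
the planted one.  Real sequences carry background lysines; see the
methods note for what this does and does not let the tests show.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import AMINO_ACIDS, Catalog, Collection, ProteinRecord, write_fasta
from .families import FAMILIES, FAMILY_BY_NAME, MOTIF_GROUP_NAME

#: Background alphabet: the 19 standard residues other than lysine.
BACKGROUND_ALPHABET = AMINO_ACIDS.replace("K", "")
_BG = np.frombuffer(BACKGROUND_ALPHABET.encode(), dtype=np.uint8)

MIN_SIMULATED_LENGTH = 12


class SimulationError(Exception):
    pass


@dataclass(frozen=True)
class LengthComponent:
    weight: float
    mean: float
    sd: float
    min_length: int
    max_length: int


@dataclass(frozen=True)
class FamilySimSpec:
    """Simulation settings for one AADC family.

    ``planted_tetrad`` is the 4-residue PLP motif ending in K, or the
    empty string for families simulated as motif-free (pyruvoyl-like).
    ``divergence`` is the per-site substitution probability outside the
    motif; ``motif_region`` the fractional window (of the shortest
    sequence) in which the catalytic K is placed.
    """

    family_name: str
    planted_tetrad: str
    length_model: tuple[LengthComponent, ...]
    divergence: float = 0.15
    motif_region: tuple[float, float] = (0.35, 0.55)
    freeze_motif: bool = True  # set False to allow motif erosion
    #: with True, each mixture component descends from its own ancestor
    #: (distinct evolutionary classes, e.g. pyruvoyl vs PLP arginine
    #: decarboxylases); with False the components are homologous length
    #: variants of one ancestor (e.g. short vs extended lysine forms)
    independent_components: bool = False

    def __post_init__(self) -> None:
        if self.planted_tetrad and (
            len(self.planted_tetrad) != 4 or not self.planted_tetrad.endswith("K")
        ):
            raise SimulationError(f"bad planted tetrad {self.planted_tetrad!r}")
        if not 0 <= self.divergence < 1:
            raise SimulationError("divergence must be in [0,1)")
        total = sum(c.weight for c in self.length_model)
        if abs(total - 1.0) > 1e-9:
            raise SimulationError("length-model weights must sum to 1")


def normal_lengths(mean: float, sd: float, lo: int, hi: int) -> tuple[LengthComponent, ...]:
    return (LengthComponent(1.0, mean, sd, lo, hi),)


def point_lengths(length: int) -> tuple[LengthComponent, ...]:
    return (LengthComponent(1.0, length, 0.0, length, length),)


def mixture_lengths(*components: tuple[float, float, float, int, int]) -> tuple[LengthComponent, ...]:
    return tuple(LengthComponent(*c) for c in components)


# ---------------------------------------------------------------------------
# Core sequence machinery
# ---------------------------------------------------------------------------

def _draw_lengths(
    spec: FamilySimSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    weights = np.array([c.weight for c in spec.length_model])
    comp = rng.choice(len(spec.length_model), size=n, p=weights)
    out = np.empty(n, dtype=int)
    for i, k in enumerate(comp):
        c = spec.length_model[k]
        val = int(round(rng.normal(c.mean, c.sd))) if c.sd > 0 else int(round(c.mean))
        out[i] = min(max(val, c.min_length), c.max_length)
    if out.min() < MIN_SIMULATED_LENGTH:
        raise SimulationError(
            f"{spec.family_name}: simulated length {out.min()} too short"
        )
    return out, comp


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator,
            frozen: slice | None) -> np.ndarray:
    """Substitute each site with probability ``rate``, uniformly over the
    18 alternative background residues; ``frozen`` positions never change."""
    out = codes.copy()
    hits = rng.random(len(codes)) < rate
    if frozen is not None:
        hits[frozen] = False
    idx = np.nonzero(hits)[0]
    if len(idx):
        offsets = rng.integers(1, len(_BG), size=len(idx))
        out[idx] = (out[idx] + offsets) % len(_BG)
    return out


def _render(codes: np.ndarray, length: int, tetrad: str, k_pos: int | None) -> str:
    chars = bytearray(_BG[codes[:length]])
    if tetrad and k_pos is not None:
        chars[k_pos - 4 : k_pos] = tetrad.encode()
    return chars.decode()


@dataclass
class _FamilyDraw:
    """Internal: one simulated family as code arrays plus motif placement."""

    spec: FamilySimSpec
    ancestor: np.ndarray
    seq_codes: list[np.ndarray]
    lengths: np.ndarray
    k_position: int | None  # 1-based, common to all members

    def sequence(self, i: int) -> str:
        return _render(
            self.seq_codes[i], int(self.lengths[i]),
            self.spec.planted_tetrad, self.k_position,
        )


def _simulate_family_draw(
    spec: FamilySimSpec, n: int, rng: np.random.Generator
) -> _FamilyDraw:
    if n < 1:
        raise SimulationError("n must be >= 1")
    lengths, comps = _draw_lengths(spec, n, rng)
    min_len, max_len = int(lengths.min()), int(lengths.max())
    k_pos: int | None = None
    frozen: slice | None = None
    if spec.planted_tetrad:
        lo, hi = spec.motif_region
        k_pos = int(round((lo + (hi - lo) * rng.random()) * min_len))
        k_pos = min(max(k_pos, 4), min_len)
        if min_len < 4:
            raise SimulationError("sequence too short to host the motif")
        if spec.freeze_motif:
            frozen = slice(k_pos - 4, k_pos)
    if spec.independent_components:
        ancestors = {
            int(k): rng.integers(0, len(_BG), size=max_len).astype(np.int64)
            for k in sorted(set(int(c) for c in comps))
        }
        seq_codes = [
            _mutate(ancestors[int(c)], spec.divergence, rng, frozen) for c in comps
        ]
        ancestor = ancestors[min(ancestors)]
    else:
        ancestor = rng.integers(0, len(_BG), size=max_len).astype(np.int64)
        seq_codes = [_mutate(ancestor, spec.divergence, rng, frozen) for _ in range(n)]
    return _FamilyDraw(spec, ancestor, seq_codes, lengths, k_pos)


def simulate_family(
    spec: FamilySimSpec,
    n: int,
    seed: int | np.random.Generator,
) -> tuple[list[ProteinRecord], list[int | None]]:
    """Simulate ``n`` members of one family from a common ancestor.

    Returns the records (with placeholder taxonomy) and, per record, the
    1-based position of the planted catalytic K (None for motif-free
    families).  Reproducible given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draw = _simulate_family_draw(spec, n, rng)
    fam = FAMILY_BY_NAME[spec.family_name]
    records = [
        ProteinRecord(
            record_id=f"{spec.family_name.lower()}_{i:04d}",
            species=f"Synthetica specimen{i:04d}",
            genus="Synthetica",
            phylum="Syntheticota",
            strain="",
            ec=fam.ec,
            sequence=draw.sequence(i),
        )
        for i in range(n)
    ]
    return records, [draw.k_position] * n


# ---------------------------------------------------------------------------
# Default study profile
# ---------------------------------------------------------------------------

def default_family_specs() -> dict[str, FamilySimSpec]:
    """The default simulation profile: nine families with the canonical
    tetrads of the PLP-dependent groups (SGHK glutamate, SFSK aspartate-4,
    NCHK lysine, DPHK tyrosine, DAHK aromatic/tryptophan), motif-free
    pyruvoyl histidine and aspartate-1 families, a mixed short/long
    motif-free arginine family (the short component under 200 residues,
    pyruvoyl-like), and a bimodal lysine-decarboxylase length model."""
    return {
        "ArgDC": FamilySimSpec(
            "ArgDC", "", mixture_lengths(
                (0.25, 165, 10, 120, 199), (0.75, 630, 45, 400, 790)
            ),
            independent_components=True,
        ),
        "LysDC": FamilySimSpec(
            "LysDC", "NCHK", mixture_lengths(
                (0.6, 485, 10, 450, 520), (0.4, 715, 12, 680, 739)
            ),
        ),
        "TrpDC": FamilySimSpec("TrpDC", "DAHK", normal_lengths(470, 30, 335, 513)),
        "AAADC": FamilySimSpec("AAADC", "DAHK", normal_lengths(470, 30, 335, 513)),
        "A4DC": FamilySimSpec("A4DC", "SFSK", normal_lengths(540, 25, 467, 588)),
        "GluDC": FamilySimSpec("GluDC", "SGHK", normal_lengths(480, 18, 459, 551)),
        "HisDC": FamilySimSpec("HisDC", "", normal_lengths(300, 20, 295, 380)),
        "A1DC": FamilySimSpec("A1DC", "", normal_lengths(120, 6, 113, 142)),
        "TyrDC": FamilySimSpec("TyrDC", "DPHK", normal_lengths(625, 5, 615, 635)),
    }


#: Default per-family species inclusion probabilities, patterned on the
#: observed prevalence ordering in gut surveys (arginine most common,
#: aromatic/tryptophan rarest).
DEFAULT_INCLUSION = {
    "ArgDC": 0.60,
    "A1DC": 0.50,
    "GluDC": 0.27,
    "A4DC": 0.21,
    "HisDC": 0.07,
    "LysDC": 0.06,
    "TyrDC": 0.05,
    "TrpDC": 0.03,
    "AAADC": 0.03,
}


@dataclass(frozen=True)
class CatalogSimSpec:
    """Catalog-level simulation settings.

    ``taxa`` maps phylum -> genus -> species count.  ``inclusion`` gives
    each family's probability that a species carries it; with
    ``duplicate_aromatic`` the TrpDC and AAADC annotations are emitted as
    identical twin records for the same species (as dual annotations of
    one protein).  Outliers replace a species' enzyme with a fresh draw
    from ``outlier_source_family`` while keeping the original annotation.
    """

    seed: int
    taxa: dict[str, dict[str, int]]
    inclusion: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INCLUSION))
    strains_per_species: int = 1
    strain_divergence: float = 0.03
    outlier_rate: float = 0.0
    outlier_source_family: str = "AAADC"
    duplicate_aromatic: bool = True
    n_samples: int = 5
    n_rare_species: int = 3


def default_taxa(n_species: int) -> dict[str, dict[str, int]]:
    """Distribute species over three phyla and ~10-species genera."""
    shares = (("Bacteroidota", 0.45), ("Bacillota", 0.40), ("Pseudomonadota", 0.15))
    taxa: dict[str, dict[str, int]] = {}
    assigned = 0
    for i, (phylum, frac) in enumerate(shares):
        n = int(round(frac * n_species)) if i < len(shares) - 1 else n_species - assigned
        assigned += n
        genera = {}
        g = 0
        while n > 0:
            take = min(10, n)
            genera[f"{phylum[:4]}genus{g:02d}"] = take
            n -= take
            g += 1
        taxa[phylum] = genera
    return taxa


@dataclass
class GroundTruth:
    """What the generator planted: per-record truth and per-family
    realized inclusion."""

    records: pd.DataFrame  # record_id, species, family, tetrad, k_position,
    #                        is_outlier, source_family
    family_inclusion: dict[str, dict]  # family -> {p_planted, n_species,
    #                                    denominator, prevalence}
    denominator_species: list[str]

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def simulate_catalog(
    spec: CatalogSimSpec,
    family_specs: dict[str, FamilySimSpec] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[Catalog, pd.DataFrame, GroundTruth]:
    """Simulate a full catalog: records, abundance table and ground truth.

    Returns ``(catalog, abundance_frame, ground_truth)``; when ``out_dir``
    is given, also writes ``catalog.fasta``, ``metadata.tsv``,
    ``abundance.tsv`` and ``ground_truth.tsv`` in the formats the I/O
    module consumes.
    """
    if family_specs is None:
        family_specs = default_family_specs()
    rng = np.random.default_rng(spec.seed)
    species: list[tuple[str, str, str]] = []  # (species, genus, phylum)
    for phylum in sorted(spec.taxa):
        for genus in sorted(spec.taxa[phylum]):
            for i in range(spec.taxa[phylum][genus]):
                species.append((f"{genus} sp{i:03d}", genus, phylum))
    n_species = len(species)
    if n_species == 0:
        raise SimulationError("no species in taxa")

    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    family_inclusion: dict[str, dict] = {}
    rec_counter = 0
    collections = [Collection.ATCC, Collection.NCTC, Collection.DSM, Collection.OTHER]

    aromatic_members: np.ndarray | None = None
    aromatic_draw: _FamilyDraw | None = None
    aromatic_outliers: np.ndarray | None = None

    for fam in FAMILIES:
        fspec = family_specs.get(fam.name)
        p = spec.inclusion.get(fam.name, 0.0)
        if fspec is None or p == 0.0:
            family_inclusion[fam.name] = {
                "p_planted": p, "n_species": 0,
                "denominator": n_species, "prevalence": 0.0,
            }
            continue
        twin = spec.duplicate_aromatic and fam.name in ("TrpDC", "AAADC")
        if twin and aromatic_members is not None:
            members, draw, outlier_mask = aromatic_members, aromatic_draw, aromatic_outliers
        else:
            members = np.nonzero(rng.random(n_species) < p)[0]
            draw = (
                _simulate_family_draw(fspec, len(members), rng)
                if len(members) else None
            )
            # Foreign-motif outliers model mis-annotated PLP enzymes, so
            # they are only injected into motif-bearing families other
            # than the source family's own motif group.
            foreign = (
                MOTIF_GROUP_NAME[fam.name]
                != MOTIF_GROUP_NAME[spec.outlier_source_family]
            )
            rate = spec.outlier_rate if (fspec.planted_tetrad and foreign) else 0.0
            outlier_mask = rng.random(len(members)) < rate
            if twin:
                aromatic_members, aromatic_draw = members, draw
                aromatic_outliers = outlier_mask

        family_inclusion[fam.name] = {
            "p_planted": p,
            "n_species": int(len(members)),
            "denominator": n_species,
            "prevalence": 100.0 * len(members) / n_species,
        }

        for slot, sp_idx in enumerate(members):
            sp_name, genus, phylum = species[sp_idx]
            is_outlier = bool(outlier_mask[slot])
            if is_outlier:
                src_spec = family_specs[spec.outlier_source_family]
                odraw = _simulate_family_draw(src_spec, 1, rng)
                base_codes, base_len = odraw.seq_codes[0], int(odraw.lengths[0])
                tetrad, k_pos = src_spec.planted_tetrad, odraw.k_position
                source = MOTIF_GROUP_NAME[spec.outlier_source_family]
            else:
                base_codes, base_len = draw.seq_codes[slot], int(draw.lengths[slot])
                tetrad, k_pos = fspec.planted_tetrad, draw.k_position
                source = ""
            frozen = slice(k_pos - 4, k_pos) if tetrad else None
            for s in range(spec.strains_per_species):
                codes = (
                    base_codes
                    if s == 0
                    else _mutate(base_codes, spec.strain_divergence, rng, frozen)
                )
                rec_id = f"g{rec_counter:06d}"
                rec_counter += 1
                rec = ProteinRecord(
                    record_id=rec_id,
                    species=sp_name,
                    genus=genus,
                    phylum=phylum,
                    strain=f"ST{s + 1:02d}",
                    ec=fam.ec,
                    sequence=_render(codes, base_len, tetrad, k_pos),
                    collection=collections[int(rng.integers(0, 4))],
                    complete_genome=bool(rng.random() < 0.5),
                )
                records.append(rec)
                truth_rows.append({
                    "record_id": rec_id,
                    "species": sp_name,
                    "family": fam.name,
                    "tetrad": tetrad,
                    "k_position": k_pos if tetrad else "",
                    "is_outlier": is_outlier,
                    "source_family": source,
                })

    # Abundance table: prevalent species clear the inclusion rule in at
    # least two samples; rare tail species never do.
    sample_cols = [f"sample{j + 1:02d}" for j in range(spec.n_samples)]
    abund_rows = {}
    for sp_name, _, _ in species:
        vals = rng.uniform(0.0, 5e-3, size=spec.n_samples)
        guaranteed = rng.choice(spec.n_samples, size=2, replace=False)
        vals[guaranteed] = rng.uniform(2e-4, 5e-3, size=2)
        abund_rows[sp_name] = vals
    for j in range(spec.n_rare_species):
        abund_rows[f"Raregenus sp{j:03d}"] = rng.uniform(0.0, 9e-5, size=spec.n_samples)
    abundance = pd.DataFrame.from_dict(abund_rows, orient="index", columns=sample_cols)
    abundance.index.name = "species"

    catalog = Catalog(records)
    truth = GroundTruth(
        records=pd.DataFrame(
            truth_rows,
            columns=["record_id", "species", "family", "tetrad", "k_position",
                     "is_outlier", "source_family"],
        ),
        family_inclusion=family_inclusion,
        denominator_species=[s for s, _, _ in species],
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([(r.record_id, r.sequence) for r in records], out / "catalog.fasta")
        meta = pd.DataFrame(
            [
                {
                    "record_id": r.record_id,
                    "species": r.species,
                    "genus": r.genus,
                    "phylum": r.phylum,
                    "strain": r.strain,
                    "ec": r.ec,
                    "collection": r.collection.value,
                    "complete_genome": str(r.complete_genome).lower(),
                }
                for r in records
            ]
        )
        meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
        abundance.to_csv(out / "abundance.tsv", sep="\t", float_format="%.8f")
        truth.to_tsv(out / "ground_truth.tsv")
    return catalog, abundance, truth


# ---------------------------------------------------------------------------
# Config file
# ---------------------------------------------------------------------------

def load_sim_config(path: str | Path) -> CatalogSimSpec:
    """Read a catalog simulation spec from a YAML file.

    Schema: ``seed`` (int, required); ``n_species`` (int, expanded to the
    default taxonomy) or an explicit ``taxa`` mapping; optional
    ``inclusion`` mapping, ``strains_per_species``, ``strain_divergence``,
    ``outlier_rate``, ``outlier_source_family``, ``n_samples``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "seed" not in cfg:
        raise SimulationError(f"{path}: simulation config requires a seed")
    if "taxa" in cfg:
        taxa = cfg["taxa"]
    elif "n_species" in cfg:
        taxa = default_taxa(int(cfg["n_species"]))
    else:
        raise SimulationError(f"{path}: give either taxa or n_species")
    kwargs = {
        k: cfg[k]
        for k in (
            "inclusion", "strains_per_species", "strain_divergence",
            "outlier_rate", "outlier_source_family", "duplicate_aromatic",
            "n_samples", "n_rare_species",
        )
        if k in cfg
    }
    return CatalogSimSpec(seed=int(cfg["seed"]), taxa=taxa, **kwargs)
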