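"""Prevalence, abundance-by-genus, class-variety and protein-length
profiling of an AADC catalog.

All counts operate on representative records (one record per species per
family); a species contributes at most once to a family's prevalence no
matter how many strains or paralogs carry the annotation.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import Catalog
from .families import FAMILIES, AADCFamily

logger = logging.getLogger(__name__)


class ProfilingError(Exception):
    pass


@dataclass
class PrevalenceTable:
    """Per-family species counts and percentages over a stated denominator,
    plus per-genus enzyme totals and the species -> families presence map."""

    denominator: int
    per_family: dict[str, tuple[int, float]]  # family -> (species count, percent)
    per_genus: dict[str, int]
    variety: dict[str, set[str]]  # species -> family names present

    def percent(self, family_name: str) -> float:
        return self.per_family[family_name][1]

    def rounded_percent(self, family_name: str) -> int:
        return round(self.per_family[family_name][1])


def prevalence(catalog: Catalog, denominator_species: list[str]) -> PrevalenceTable:
    """Fraction of catalogued species carrying each AADC family.

    ``denominator_species`` is the full list of species under study (the
    prevalence denominator, reported explicitly alongside every
    percentage).  Catalog species outside the denominator are excluded
    with a warning.
    """
    if not denominator_species:
        raise ProfilingError("empty denominator species list")
    denom_set = set(denominator_species)
    denominator = len(denom_set)
    species_families: dict[str, set[str]] = defaultdict(set)
    genus_counts: Counter = Counter()
    for rec in catalog.records:
        if rec.species not in denom_set:
            logger.warning(
                "species %s not in denominator list; record %s excluded",
                rec.species,
                rec.record_id,
            )
            continue
        fam = rec.family
        if fam is None:
            continue
        species_families[rec.species].add(fam.name)
        genus_counts[rec.genus] += 1
    per_family = {}
    for fam in FAMILIES:
        count = sum(1 for fams in species_families.values() if fam.name in fams)
        per_family[fam.name] = (count, 100.0 * count / denominator)
    return PrevalenceTable(
        denominator=denominator,
        per_family=per_family,
        per_genus=dict(genus_counts),
        variety=dict(species_families),
    )


def genus_totals(
    catalog: Catalog, count_identical_groups_once: bool = True
) -> dict[str, int]:
    """Total representative AADCs per genus, summed across families.

    TrpDC and AAADC annotations frequently point at the very same protein;
    with ``count_identical_groups_once`` a species' TrpDC/AAADC records
    with identical sequences contribute a single count.
    """
    totals: Counter = Counter()
    dual = {"TrpDC", "AAADC"}
    seen_dual: dict[tuple[str, str], str] = {}
    for rec in catalog.records:
        fam = rec.family
        if fam is None:
            continue
        if count_identical_groups_once and fam.name in dual:
            key = (rec.species, rec.sequence)
            if key in seen_dual:
                continue
            seen_dual[key] = rec.record_id
        totals[rec.genus] += 1
    return dict(totals)


def variety_matrix(catalog: Catalog) -> tuple[pd.DataFrame, dict[str, int]]:
    """Species x family presence/absence matrix plus per-species variety
    (number of distinct AADC families present)."""
    species = catalog.species()
    data = pd.DataFrame(
        False, index=species, columns=[f.name for f in FAMILIES], dtype=bool
    )
    for rec in catalog.records:
        fam = rec.family
        if fam is not None:
            data.loc[rec.species, fam.name] = True
    variety = {sp: int(data.loc[sp].sum()) for sp in species}
    return data, variety


@dataclass
class LengthStats:
    """Protein-length summary for one family: n, min, max, range and
    mode(s).  ``modes`` lists every most-frequent length; ``mode_label``
    renders a point mode as "630" and an interval of adjacent modal
    lengths as "470-484"."""

    family_name: str
    n: int
    minimum: int
    maximum: int
    modes: list[int]
    mode_bin_width: int = 1

    @property
    def range(self) -> int:
        return self.maximum - self.minimum

    @property
    def mode_label(self) -> str:
        if len(self.modes) == 1:
            return str(self.modes[0])
        return f"{min(self.modes)}-{max(self.modes)}"


def length_stats(
    lengths: list[int], mode_bin_width: int = 1, family_name: str = ""
) -> LengthStats:
    """Min/max/range and modal length(s) of a family's proteins.

    With ``mode_bin_width`` > 1 lengths are binned first and the modal
    bin's member lengths are reported, mirroring tabulations that give an
    interval mode when the modal mass spans adjacent lengths.
    """
    if not lengths:
        raise ProfilingError("length_stats: empty length list")
    if any(l <= 0 for l in lengths):
        raise ProfilingError("length_stats: non-positive length")
    if mode_bin_width < 1:
        raise ProfilingError("mode_bin_width must be >= 1")
    lo, hi = min(lengths), max(lengths)
    if mode_bin_width == 1:
        freq = Counter(lengths)
        top = max(freq.values())
        modes = sorted(l for l, c in freq.items() if c == top)
    else:
        bins = Counter((l - lo) // mode_bin_width for l in lengths)
        top_bin = min(b for b, c in bins.items() if c == max(bins.values()))
        modes = sorted(
            l for l in set(lengths) if (l - lo) // mode_bin_width == top_bin
        )
    return LengthStats(
        family_name=family_name,
        n=len(lengths),
        minimum=lo,
        maximum=hi,
        modes=modes,
        mode_bin_width=mode_bin_width,
    )


@dataclass
class BimodalityReport:
    """Best 1-D two-cluster split of a length distribution."""

    lower_mean: float
    upper_mean: float
    lower_n: int
    upper_n: int
    gap: float  # distance between the closest members of the two clusters
    single_cluster: bool = False


def bimodality_report(lengths: list[int]) -> BimodalityReport:
    """Split lengths into two clusters minimizing within-cluster variance.

    Surfaces short/long length classes such as the ancestral (~480-490 aa)
    versus extended (~710-755 aa) lysine-decarboxylase forms.  All-equal
    input degenerates to a single cluster.
    """
    if len(lengths) < 4:
        raise ProfilingError("bimodality_report needs n >= 4")
    xs = np.sort(np.asarray(lengths, dtype=float))
    if xs[0] == xs[-1]:
        return BimodalityReport(float(xs[0]), float(xs[0]), len(xs), 0, 0.0, True)
    best_split, best_ss = None, np.inf
    for k in range(1, len(xs)):
        lower, upper = xs[:k], xs[k:]
        ss = ((lower - lower.mean()) ** 2).sum() + ((upper - upper.mean()) ** 2).sum()
        if ss < best_ss:
            best_ss, best_split = ss, k
    lower, upper = xs[:best_split], xs[best_split:]
    return BimodalityReport(
        lower_mean=float(lower.mean()),
        upper_mean=float(upper.mean()),
        lower_n=len(lower),
        upper_n=len(upper),
        gap=float(upper[0] - lower[-1]),
    )
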