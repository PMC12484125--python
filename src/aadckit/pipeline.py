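"""End-to-end pipeline: inclusion filter -> representative selection ->
per-family alignment -> percent-identity/outliers -> motif/cofactor ->
reassignment -> prevalence and length profiling, with every stage writing
tab-separated reports.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align import (
    GroupIdentitySummary,
    MultipleAlignment,
    OutlierReport,
    PercentIdentityMatrix,
    build_msa,
    detect_outliers,
    pim_from_msa,
    read_external_alignment,
    summarize_group,
    write_alignment,
    write_pim,
)
from .catalog import (
    Catalog,
    filter_prevalent_species,
    load_catalog,
    read_abundance,
    select_representatives,
)
from .families import FAMILIES, FAMILY_BY_NAME, MOTIF_GROUP_NAME, CofactorClass
from .motif import (
    ConsensusMotif,
    TetradMotif,
    consensus_motif,
    extract_family_tetrads,
    extract_tetrad,
    find_conserved_lysine_column,
    predict_cofactor,
    reassign_outliers,
)
from .profiling import (
    bimodality_report,
    genus_totals,
    length_stats,
    prevalence,
    variety_matrix,
)

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; every threshold is configurable
    and recorded in the run log."""

    fasta: str
    metadata: str
    out_dir: str
    abundance: str | None = None
    external_alignment_dir: str | None = None  # per-family <Family>.aln files
    abundance_threshold: float = 1e-4
    min_samples: int = 2
    min_conservation: float = 0.7
    minority_fraction: float = 0.10
    outlier_threshold: float = 30.0
    short_length_cutoff: int = 200
    mode_bin_width: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**cfg)


@dataclass
class PipelineResult:
    catalog: Catalog
    representatives: Catalog
    denominator_species: list[str]
    alignments: dict[str, MultipleAlignment]
    pims: dict[str, PercentIdentityMatrix]
    group_summaries: dict[str, GroupIdentitySummary]
    outliers: dict[str, list[OutlierReport]]
    tetrads: dict[str, dict[str, TetradMotif]]
    consensus: dict[str, ConsensusMotif]
    cofactor_calls: dict[str, object]
    prevalence_table: object
    out_dir: Path


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_load(config: PipelineConfig) -> tuple[Catalog, list[str]]:
    """Load inputs; apply the abundance inclusion filter when given."""
    for path in (config.fasta, config.metadata):
        if not Path(path).exists():
            raise PipelineError("load", f"input file not found: {path}")
    catalog = load_catalog(config.fasta, config.metadata)
    if config.abundance:
        if not Path(config.abundance).exists():
            raise PipelineError("load", f"input file not found: {config.abundance}")
        abundances = read_abundance(config.abundance)
        denominator = filter_prevalent_species(
            abundances, config.abundance_threshold, config.min_samples
        )
        kept = set(denominator)
        catalog = Catalog([r for r in catalog.records if r.species in kept])
    else:
        denominator = catalog.species()
    return catalog, sorted(denominator)


def stage_align(
    representatives: Catalog, config: PipelineConfig, out: Path | None = None
) -> tuple[dict[str, MultipleAlignment], dict[str, PercentIdentityMatrix]]:
    """Per-family multiple alignment and percent-identity matrix.

    External (e.g. Clustal Omega) alignments named ``<Family>.aln`` or
    ``<Family>.fasta`` in ``external_alignment_dir`` take precedence over
    the internal center-star aligner.
    """
    msas: dict[str, MultipleAlignment] = {}
    pims: dict[str, PercentIdentityMatrix] = {}
    for fam, recs in sorted(
        representatives.family_index.items(), key=lambda kv: kv[0].name
    ):
        if len(recs) < 2:
            continue
        msa = None
        if config.external_alignment_dir:
            ext = Path(config.external_alignment_dir)
            for name, fmt in ((f"{fam.name}.aln", "clustal"),
                              (f"{fam.name}.fasta", "fasta")):
                if (ext / name).exists():
                    msa = read_external_alignment(ext / name, fmt)
                    break
        if msa is None:
            pairs = sorted((r.record_id, r.sequence) for r in recs)
            msa = build_msa(pairs)
        msas[fam.name] = msa
        pims[fam.name] = pim_from_msa(msa)
        if out is not None:
            write_alignment(msa, out / f"msa_{fam.name}.fasta")
            write_pim(pims[fam.name], out / f"pim_{fam.name}.tsv")
    return msas, pims


def stage_motif(
    representatives: Catalog,
    msas: dict[str, MultipleAlignment],
    pims: dict[str, PercentIdentityMatrix],
    config: PipelineConfig,
) -> tuple[
    dict[str, dict[str, TetradMotif]],
    dict[str, ConsensusMotif],
    dict[str, list[OutlierReport]],
    dict[str, object],
]:
    """Tetrad extraction, consensus, outlier detection + reassignment and
    cofactor calls, per family."""
    by_id = {r.record_id: r for r in representatives.records}

    outliers: dict[str, list[OutlierReport]] = {}
    flagged_ids: set[str] = set()
    for fam_name, pim in pims.items():
        if len(pim.ids) < 3:
            continue
        outliers[fam_name] = detect_outliers(pim, config.outlier_threshold)
        flagged_ids.update(r.record_id for r in outliers[fam_name] if r.flagged)

    # The conserved-lysine column is located on the coherent core of each
    # group (flagged outliers excluded, so a few mis-annotations cannot
    # mask the family's motif); tetrads are then read off every row,
    # outliers included, at that column.
    tetrads: dict[str, dict[str, TetradMotif]] = {}
    for fam_name, msa in msas.items():
        keep = [i for i, rid in enumerate(msa.ids) if rid not in flagged_ids]
        core = msa
        if 2 <= len(keep) < len(msa.ids):
            core = MultipleAlignment(
                ids=[msa.ids[i] for i in keep], rows=[msa.rows[i] for i in keep]
            )
        k_col = find_conserved_lysine_column(core, config.min_conservation)
        fam_tets: dict[str, TetradMotif] = {}
        if k_col is not None:
            for rid in msa.ids:
                t = extract_tetrad(rid, msa, k_col)
                if t is not None:
                    fam_tets[rid] = t
        tetrads[fam_name] = fam_tets
    # The TrpDC and AAADC annotations form one motif group; when each is a
    # singleton (too small to align on its own) their members are pooled so
    # the group can still contribute a consensus.
    if not (tetrads.get("TrpDC") or tetrads.get("AAADC")):
        pooled = sorted(
            (r.record_id, r.sequence)
            for r in representatives.records
            if r.family is not None and r.family.name in ("TrpDC", "AAADC")
        )
        if len(pooled) >= 2:
            pooled_msa = build_msa(pooled)
            pooled_tets = extract_family_tetrads(pooled_msa, config.min_conservation)
            for fam_name in ("TrpDC", "AAADC"):
                if fam_name in msas or not pooled_tets:
                    continue
                tetrads[fam_name] = {
                    rid: t for rid, t in pooled_tets.items()
                    if by_id[rid].family.name == fam_name
                }

    # Consensus per motif group (TrpDC and AAADC share one group), from
    # non-outlier members only; ArgDC is heterogeneous by construction and
    # gets no single consensus.
    consensus: dict[str, ConsensusMotif] = {}
    by_group: dict[str, list[TetradMotif]] = {}
    for fam_name, fam_tetrads in tetrads.items():
        if fam_name == "ArgDC":
            continue
        group = MOTIF_GROUP_NAME[fam_name]
        by_group.setdefault(group, [])
        existing = {t.record_id for t in by_group[group]}
        by_group[group].extend(
            t
            for t in fam_tetrads.values()
            if t.record_id not in existing and t.record_id not in flagged_ids
        )
    for group, ts in sorted(by_group.items()):
        if ts:
            consensus[group] = consensus_motif(
                ts, config.minority_fraction, family_name=group
            )
    known = list(consensus.values())

    for fam_name, reps in outliers.items():
        seqs = {r.record_id: by_id[r.record_id].sequence for r in reps}
        reassign_outliers(
            reps, tetrads.get(fam_name, {}), known,
            own_family_name=fam_name, sequences=seqs,
        )

    calls: dict[str, object] = {}
    for rec in representatives.records:
        if rec.family is None:
            continue
        found = rec.record_id in tetrads.get(rec.family.name, {})
        calls[rec.record_id] = predict_cofactor(
            rec, found, config.short_length_cutoff
        )
    return tetrads, consensus, outliers, calls


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def _write_reports(result: PipelineResult, config: PipelineConfig) -> None:
    out = result.out_dir
    prev = result.prevalence_table
    pd.DataFrame(
        [
            {
                "family": fam.name,
                "species_count": prev.per_family[fam.name][0],
                "percent": round(prev.per_family[fam.name][1], 4),
                "percent_rounded": prev.rounded_percent(fam.name),
                "denominator": prev.denominator,
            }
            for fam in FAMILIES
        ]
    ).to_csv(out / "prevalence.tsv", sep="\t", index=False)

    totals_once = genus_totals(result.representatives, True)
    totals_all = genus_totals(result.representatives, False)
    pd.DataFrame(
        [
            {"genus": g, "total_aadc": totals_once[g],
             "total_aadc_per_annotation": totals_all[g]}
            for g in sorted(totals_once, key=lambda g: (-totals_once[g], g))
        ]
    ).to_csv(out / "genus_totals.tsv", sep="\t", index=False)

    matrix, variety = variety_matrix(result.representatives)
    matrix.astype(int).to_csv(out / "variety_matrix.tsv", sep="\t")
    pd.DataFrame(
        [{"species": sp, "variety": variety[sp]} for sp in sorted(variety)]
    ).to_csv(out / "variety_counts.tsv", sep="\t", index=False)

    length_rows = []
    for fam, recs in sorted(
        result.representatives.family_index.items(), key=lambda kv: kv[0].name
    ):
        stats = length_stats(
            [r.length for r in recs], config.mode_bin_width, fam.name
        )
        length_rows.append({
            "family": fam.name, "ec": fam.ec, "range": stats.range,
            "max": stats.maximum, "min": stats.minimum,
            "mode": stats.mode_label, "n": stats.n,
        })
    pd.DataFrame(length_rows).to_csv(out / "length_stats.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "family": fam_name,
                "average_percent_identity": (
                    "N/A" if not s.applicable else round(s.average_identity, 2)
                ),
                "minimum_percent_identity": (
                    "N/A" if not s.applicable else round(s.minimum_identity, 2)
                ),
            }
            for fam_name, s in sorted(result.group_summaries.items())
        ]
    ).to_csv(out / "group_identity.tsv", sep="\t", index=False)

    motif_rows = []
    groups_seen = set()
    for fam in FAMILIES:
        group = MOTIF_GROUP_NAME[fam.name]
        if group in groups_seen:
            continue
        groups_seen.add(group)
        cons = result.consensus.get(group)
        if fam.cofactor_class is CofactorClass.PYRUVOYL:
            pattern, primary, secondary = "Pyruvoyl-dependent", "N/A", "N/A"
        elif cons is None:
            pattern, primary, secondary = "Unable to determine", "N/A", "N/A"
        else:
            pattern = cons.pattern
            primary = cons.primary_motif
            secondary = ", ".join(cons.secondary_motifs) or "N/A"
        motif_rows.append({
            "family": group, "plp_motif": pattern,
            "primary_motif": primary, "secondary_motifs": secondary,
        })
    pd.DataFrame(motif_rows).to_csv(out / "motif_summary.tsv", sep="\t", index=False)

    rec_rows = []
    for rec in result.representatives.records:
        fam = rec.family
        if fam is None:
            continue
        tet = result.tetrads.get(fam.name, {}).get(rec.record_id)
        call = result.cofactor_calls.get(rec.record_id)
        cand = ""
        for rep in result.outliers.get(fam.name, []):
            if rep.record_id == rec.record_id and rep.candidate_family:
                cand = rep.candidate_family
        rec_rows.append({
            "record_id": rec.record_id,
            "family": fam.name,
            "lysine_position": tet.lysine_position if tet else "",
            "tetrad": tet.tetrad if tet else "",
            "cofactor": call.call.value if call else "",
            "basis": call.basis.value if call else "",
            "candidate_family": cand,
        })
    pd.DataFrame(rec_rows).to_csv(out / "motif_records.tsv", sep="\t", index=False)

    out_rows = []
    for fam_name, reps in sorted(result.outliers.items()):
        for rep in reps:
            out_rows.append({
                "family": fam_name,
                "record_id": rep.record_id,
                "max_identity": round(rep.max_identity_to_group, 2),
                "mean_identity": round(rep.mean_identity_to_group, 2),
                "flagged": rep.flagged,
                "lowest_in_group": rep.lowest_in_group,
                "candidate_family": rep.candidate_family or "",
            })
    pd.DataFrame(
        out_rows,
        columns=["family", "record_id", "max_identity", "mean_identity",
                 "flagged", "lowest_in_group", "candidate_family"],
    ).to_csv(out / "outliers.tsv", sep="\t", index=False)

    bimodal_rows = []
    for fam, recs in sorted(
        result.representatives.family_index.items(), key=lambda kv: kv[0].name
    ):
        lengths = [r.length for r in recs]
        if len(lengths) < 4:
            continue
        rep = bimodality_report(lengths)
        bimodal_rows.append({
            "family": fam.name,
            "lower_mean": round(rep.lower_mean, 1),
            "upper_mean": round(rep.upper_mean, 1),
            "lower_n": rep.lower_n, "upper_n": rep.upper_n,
            "gap": round(rep.gap, 1), "single_cluster": rep.single_cluster,
        })
    pd.DataFrame(
        bimodal_rows,
        columns=["family", "lower_mean", "upper_mean", "lower_n", "upper_n",
                 "gap", "single_cluster"],
    ).to_csv(out / "length_bimodality.tsv", sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the full report bundle to ``out_dir``.

    Deterministic given fixed inputs and config; any stage failure raises
    :class:`PipelineError` naming the stage, with partial outputs left in
    place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "tool_version": __version__,
        "parameters": asdict(config),
        "input_checksums": {},
    }
    stage = "load"
    try:
        catalog, denominator = stage_load(config)
        for path in (config.fasta, config.metadata, config.abundance):
            if path:
                log["input_checksums"][str(path)] = _checksum(path)
        stage = "representatives"
        representatives = select_representatives(catalog)
        stage = "align"
        msas, pims = stage_align(representatives, config, out)
        summaries = {}
        for fam in FAMILIES:
            recs = [
                r for r in representatives.records
                if r.family is not None and r.family.name == fam.name
            ]
            if not recs:
                continue
            summaries[fam.name] = summarize_group(pims.get(fam.name), fam)
        stage = "motif"
        tetrads, consensus, outliers, calls = stage_motif(
            representatives, msas, pims, config
        )
        stage = "profiling"
        prev = prevalence(representatives, denominator)
        result = PipelineResult(
            catalog=catalog,
            representatives=representatives,
            denominator_species=denominator,
            alignments=msas,
            pims=pims,
            group_summaries=summaries,
            outliers=outliers,
            tetrads=tetrads,
            consensus=consensus,
            cofactor_calls=calls,
            prevalence_table=prev,
            out_dir=out,
        )
        stage = "report"
        _write_reports(result, config)
    except PipelineError:
        raise
    except Exception as exc:
        log["failed_stage"] = stage
        with open(out / "run_log.yaml", "w") as fh:
            yaml.safe_dump(log, fh, sort_keys=True)
        raise PipelineError(stage, str(exc)) from exc
    log["n_records"] = len(catalog)
    log["n_representatives"] = len(representatives)
    log["denominator_species"] = len(denominator)
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return result
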