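"""End-to-end orchestration: evidence filter, LCRs, profiles, categories,
phospho overlay and plate normalization, reported as TSV + JSON + log.

When no evidence table is supplied the two-peptide filter is skipped
(annotation-only mode) and every protein in the FASTA is retained, so the
pipeline can run on a bare sequence deposit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import io as sio
from .classify import (
    DEFAULT_CATALOG,
    SMPClassification,
    apply_peptide_rule,
    category_counts,
    classify_protein,
    presence_partition,
)
from .ella import normalize_plate
from .lcr import LCRParams, detect_lcrs
from .model import CANONICAL_EXTRACTS, ShellomeError
from .phospho import PHOSPHO_THRESHOLD, likely_sites, overlay_lcr
from .physchem import DEFAULT_PKA, DE_FRACTION_CUTOFF, PI_ACIDIC_CUTOFF, profile

logger = logging.getLogger("shellome")

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, outputs and every threshold the stages use.

    Defaults reproduce the canonical constants: 10-residue windows with
    >= 50% / >= 40%+20% composition over stretches of > 14 / > 19 residues;
    acidity at pI < 3.5 and Asp+Glu > 20%; likely phosphorylation at
    probability > 0.5; acceptance at more than one peptide in total.
    """

    fasta: str
    outdir: str
    domains: str | None = None
    features: str | None = None
    evidence: str | None = None
    phospho: str | None = None
    plate: str | None = None
    lcr_params: LCRParams = field(default_factory=LCRParams)
    pka_set: str = DEFAULT_PKA
    catalog: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CATALOG))
    pi_acidic: float = PI_ACIDIC_CUTOFF
    de_fraction: float = DE_FRACTION_CUTOFF
    phospho_threshold: float = PHOSPHO_THRESHOLD
    min_peptides: int = 2
    extract_ids: tuple[str, ...] = CANONICAL_EXTRACTS
    clamp_negative: bool = False


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ShellomeError as exc:
                raise ShellomeError(f"stage {name}: {exc}") from exc
        return wrapped
    return decorator


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Outputs under ``config.outdir``: classification.tsv (one row per accepted
    protein), lcr.tsv, profile.tsv, overlay.tsv, reactivity.tsv (when inputs
    are given), summary.json and run.log. Returns the summary dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    params = config.lcr_params
    logger.info(
        "thresholds: window=%d single>=%.0f%% run>=%d pair>=%.0f%%/%.0f%% run>=%d "
        "pI<%s D+E>%s phospho>%s min_peptides=%d pka=%s",
        params.window_len, 100 * params.single_min_frac, params.single_min_run,
        100 * params.pair_first_min_frac, 100 * params.pair_second_min_frac,
        params.pair_min_run, config.pi_acidic, config.de_fraction,
        config.phospho_threshold, config.min_peptides, config.pka_set,
    )

    records = _stage("core_io")(sio.read_fasta)(config.fasta)
    by_id = {r.id: r for r in records}
    domains_by_id: dict[str, list] = {}
    if config.domains:
        for hit in _stage("core_io")(sio.read_domain_table)(config.domains):
            domains_by_id.setdefault(hit.protein_id, []).append(hit)
    flags_by_id = {}
    if config.features:
        flags_by_id = {f.protein_id: f
                       for f in _stage("core_io")(sio.read_features_table)(config.features)}

    # --- evidence filter -----------------------------------------------
    presences: dict[str, frozenset[str]] = {}
    if config.evidence:
        evidence = _stage("core_io")(sio.read_evidence_table)(
            config.evidence, config.extract_ids)
        accepted_ids = _stage("classify")(apply_peptide_rule)(evidence, config.min_peptides)
        accepted = [r for r in records if r.id in accepted_ids]
        presences = {r.id: evidence.presence(r.id) for r in accepted}
        logger.info("evidence filter: %d of %d proteins accepted "
                    "(>= %d peptides in total)", len(accepted), len(records),
                    config.min_peptides)
    else:
        accepted = list(records)
        logger.warning("no evidence table supplied: peptide filter skipped, "
                       "all %d proteins retained", len(records))

    # --- per-protein stages ---------------------------------------------
    lcrs = {r.id: _stage("lcr_detect")(detect_lcrs)(r, params) for r in accepted}
    profiles = {r.id: _stage("physchem")(profile)(r, config.pka_set) for r in accepted}
    classifications: dict[str, SMPClassification] = {}
    for r in accepted:
        classifications[r.id] = _stage("classify")(classify_protein)(
            r, domains_by_id.get(r.id, []), lcrs[r.id], config.catalog,
            presences.get(r.id), config.extract_ids)

    overlays = {}
    if config.phospho:
        tracks = _stage("core_io")(sio.read_phospho_table)(config.phospho)
        for track in tracks:
            if track.protein_id not in by_id:
                logger.warning("phospho track for unknown protein %s skipped",
                               track.protein_id)
                continue
            if track.protein_id not in classifications:
                continue
            rec = by_id[track.protein_id]
            track.cross_check(rec)
            overlays[track.protein_id] = _stage("phospho")(overlay_lcr)(
                track.protein_id,
                likely_sites(track, config.phospho_threshold),
                lcrs[track.protein_id], len(rec.sequence))

    reactivity = None
    if config.plate:
        plate = _stage("core_io")(sio.read_plate_csv)(config.plate)
        reactivity = _stage("ella")(normalize_plate)(plate, config.clamp_negative)

    # --- write the bundle -------------------------------------------------
    _write_lcr_tsv(lcrs, outdir / "lcr.tsv")
    _write_profile_tsv(profiles, outdir / "profile.tsv")
    _write_classification_table(accepted, classifications, flags_by_id,
                                domains_by_id, outdir / "classification.tsv")
    if overlays:
        _write_overlay_tsv(overlays, outdir / "overlay.tsv")
    if reactivity is not None:
        _write_reactivity_tsv(reactivity, outdir / "reactivity.tsv")

    summary = {
        "schema_version": SCHEMA_VERSION,
        "n_input": len(records),
        "n_accepted": len(accepted),
        "category_counts": category_counts(classifications.values()),
        "presence_counts": (presence_partition(presences, config.extract_ids)
                            if presences else None),
        "acidic_proteins": sorted(pid for pid, p in profiles.items() if p.is_acidic),
        "thresholds": {
            "window_len": params.window_len,
            "single_min_frac": params.single_min_frac,
            "single_min_run": params.single_min_run,
            "pair_first_min_frac": params.pair_first_min_frac,
            "pair_second_min_frac": params.pair_second_min_frac,
            "pair_min_run": params.pair_min_run,
            "pi_acidic": config.pi_acidic,
            "de_fraction": config.de_fraction,
            "phospho_threshold": config.phospho_threshold,
            "min_peptides": config.min_peptides,
            "pka_set": config.pka_set,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _write_lcr_tsv(lcrs: dict, path: Path) -> None:
    rows = [
        {"protein_id": r.protein_id, "kind": r.kind, "residues": r.residues,
         "label": r.label, "start": r.start, "end": r.end, "length": r.length}
        for regions in lcrs.values() for r in regions
    ]
    pd.DataFrame(rows, columns=["protein_id", "kind", "residues", "label",
                                "start", "end", "length"]).to_csv(
        path, sep="\t", index=False)


def _write_profile_tsv(profiles: dict, path: Path) -> None:
    rows = [
        {"protein_id": p.protein_id, "length": p.length,
         "mw": round(p.molecular_weight, 2), "pI": round(p.pI, 2),
         "asp_glu_pct": round(100 * p.asp_glu_fraction, 1),
         "is_acidic": p.is_acidic}
        for p in profiles.values()
    ]
    pd.DataFrame(rows, columns=["protein_id", "length", "mw", "pI",
                                "asp_glu_pct", "is_acidic"]).to_csv(
        path, sep="\t", index=False)


def _write_classification_table(accepted, classifications, flags_by_id, domains_by_id,
                  path: Path) -> None:
    rows = []
    for rec in accepted:
        c = classifications[rec.id]
        flags = flags_by_id.get(rec.id)
        domains = domains_by_id.get(rec.id, [])
        rows.append({
            "protein_id": rec.id,
            "category": c.category,
            "subcategory": c.subcategory,
            "signal_peptide": ("Yes" if flags.signal_peptide else "No") if flags else "",
            "tm": flags.tm_count if flags else "",
            "lcr_1aa": ";".join(c.lcr_labels_single),
            "lcr_2aa": ";".join(c.lcr_labels_pair),
            "domains": ";".join(sorted({d.accession for d in domains})),
            "bmsp_like": c.bmsp_like,
            "presence_class": c.presence_class if c.presence else "",
        })
    pd.DataFrame(rows, columns=["protein_id", "category", "subcategory",
                                "signal_peptide", "tm", "lcr_1aa", "lcr_2aa",
                                "domains", "bmsp_like", "presence_class"]
                 ).to_csv(path, sep="\t", index=False)


def _write_overlay_tsv(overlays: dict, path: Path) -> None:
    rows = [
        {"protein_id": s.protein_id, "n_likely": s.n_likely,
         "n_in_lcr": s.n_in_lcr, "frac_in_lcr": round(s.frac_in_lcr, 4),
         "undefined_base": s.undefined_base}
        for s in overlays.values()
    ]
    pd.DataFrame(rows, columns=["protein_id", "n_likely", "n_in_lcr",
                                "frac_in_lcr", "undefined_base"]).to_csv(
        path, sep="\t", index=False)


def _write_reactivity_tsv(reactivity, path: Path) -> None:
    rows = [
        {"lectin": lectin, "mean_percent": round(mean, 3),
         "sd_percent": round(sd, 3)}
        for lectin, (mean, sd) in reactivity.values.items()
    ]
    pd.DataFrame(rows, columns=["lectin", "mean_percent", "sd_percent"]
                 ).to_csv(path, sep="\t", index=False)
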