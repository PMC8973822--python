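"""End-to-end orchestration: simulate (or ingest) -> segment -> measure ->
test -> report, plus the cohort analysis sub-pipeline.

Every run is fully reproducible from (config, base seed); a config
fingerprint is recorded in every report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import coloc, datasets, segment, stats, synthgen
from .cohort import (CarrierTable, carrier_frequency, contingency_test,
                     filter_rare, tally_carriers)

__all__ = ["RunConfig", "RunReport", "default_genotype_alphas",
           "run_imaging_pipeline", "run_cohort_analysis", "load_config"]

log = logging.getLogger(__name__)


def default_genotype_alphas() -> dict[str, float]:
    """Default genotype map: wild type and likely-benign variants are
    membrane-dominant (alpha 0.8); predicted-damaging mutants are
    ER-retained (alpha 0.1)."""
    alphas = {datasets.WT_LABEL: 0.8}
    alphas.update({g: 0.8 for g in datasets.BENIGN_VARIANTS})
    alphas.update({g: 0.1 for g in datasets.DAMAGING_MUTANTS})
    return alphas


@dataclass
class RunConfig:
    genotype_alphas: dict[str, float] = field(default_factory=default_genotype_alphas)
    wt_label: str = datasets.WT_LABEL
    images_per_genotype: int = 20
    comarkers: tuple[str, ...] = ("PM", "ER")
    scene: synthgen.SceneSpec = field(default_factory=synthgen.SceneSpec)
    segmentation: segment.SegmentationParams = field(
        default_factory=segment.SegmentationParams)
    min_cells: int = 30
    enforce_min_cells: bool = True
    randomization_test: bool = False
    background_subtract: float = 0.0
    base_seed: int = 0
    out_dir: Path = Path("celloc_out")
    write_images: bool = False
    variant_table: Optional[Path] = None
    roster_table: Optional[Path] = None
    maf_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.wt_label not in self.genotype_alphas:
            raise ValueError(
                f"wt_label {self.wt_label!r} missing from genotype map")

    def fingerprint(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            raise TypeError(type(o).__name__)
        blob = json.dumps(dataclasses.asdict(self), default=default,
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_fingerprint: str
    stage_counts: dict[str, int] = field(default_factory=dict)
    dropped_cells: int = 0
    summaries: list[dict] = field(default_factory=list)
    omnibus: dict[str, dict] = field(default_factory=dict)
    posthoc: list[dict] = field(default_factory=list)
    cohort_tables: list[dict] = field(default_factory=list)
    frequencies: list[dict] = field(default_factory=list)
    contingency: dict[str, dict] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


# ---------------------------------------------------------------------------
# imaging pipeline

def run_imaging_pipeline(config: RunConfig) -> RunReport:
    """Simulate scenes per genotype and comarker, segment, measure per-cell
    colocalization, and run the group statistics versus wild type."""
    report = RunReport(config_fingerprint=config.fingerprint())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    all_records: list[coloc.ColocRecord] = []
    n_images = n_segmented = 0
    t0 = time.perf_counter()

    for comarker in config.comarkers:
        specs = [
            config.scene.replace(alpha=a, genotype_label=g, comarker=comarker)
            for g, a in config.genotype_alphas.items()
        ]
        stacks, masks = [], []
        for spec, stack, truth in synthgen.generate_dataset(
                specs, config.images_per_genotype, base_seed=config.base_seed):
            n_images += 1
            mask = segment.extract_rois(stack.channels["protein"],
                                        config.segmentation)
            n_segmented += mask.n_cells
            stacks.append(stack)
            masks.append(mask)
            if config.write_images:
                synthgen.write_scene(stack, truth, spec, out / "images")
        all_records.extend(coloc.measure_dataset(
            stacks, masks, background_subtract=config.background_subtract))
    report.timings_s["simulate_segment_measure"] = time.perf_counter() - t0

    df = coloc.records_to_frame(all_records)
    df.to_csv(out / "measurements.tsv", sep="\t", index=False)
    report.stage_counts = {
        "images": n_images,
        "cells_segmented": n_segmented,
        "cells_measured": len(df),
    }
    report.dropped_cells = n_segmented - len(df)

    t0 = time.perf_counter()
    summaries = stats.summarize_groups(df)
    report.summaries = [s.__dict__ for s in summaries]
    pd.DataFrame(report.summaries).to_csv(out / "summary.tsv", sep="\t",
                                          index=False)

    results = stats.compare_to_wt(df, config.wt_label,
                                  min_cells=config.min_cells,
                                  enforce_min_cells=config.enforce_min_cells)
    posthoc_rows = []
    for comarker, (anova, comparisons) in results.items():
        report.omnibus[comarker] = anova.__dict__
        for c in comparisons:
            row = {"comarker": comarker, **c.__dict__}
            posthoc_rows.append(row)
    report.posthoc = posthoc_rows
    pd.DataFrame([report.omnibus[c] | {"comarker": c} for c in report.omnibus]
                 ).to_csv(out / "omnibus.tsv", sep="\t", index=False)
    pd.DataFrame(posthoc_rows).to_csv(out / "posthoc.tsv", sep="\t",
                                      index=False)
    # box-summary JSON for external plotting
    (out / "box_summary.json").write_text(json.dumps(report.summaries,
                                                     indent=2))
    report.timings_s["stats"] = time.perf_counter() - t0

    (out / "run_report.json").write_text(report.to_json())
    return report


# ---------------------------------------------------------------------------
# cohort pipeline

def _read_roster_tsv(path: Path) -> tuple[dict[str, list[str]],
                                          dict[str, list[str]]]:
    df = pd.read_csv(path, sep="\t")
    required = {"individual_id", "cohort", "variant_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: roster needs columns {sorted(required)}")
    rosters: dict[str, dict[str, list[str]]] = {"patients": {}, "controls": {}}
    for i, row in df.iterrows():
        cohort = str(row["cohort"])
        if cohort not in rosters:
            raise ValueError(
                f"{path} line {i + 2}: unknown cohort {cohort!r} "
                "(expected 'patients' or 'controls')")
        rosters[cohort].setdefault(str(row["individual_id"]), []).append(
            str(row["variant_id"]))
    return rosters["patients"], rosters["controls"]


def run_cohort_analysis(config: RunConfig) -> RunReport:
    """Rarity filter -> classify -> tally -> frequencies -> contingency.

    Without explicit input files the bundled Belgian-cohort demo roster and
    the localization-study variant annotation table are used.
    """
    report = RunReport(config_fingerprint=config.fingerprint())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.variant_table is not None:
        vdf = pd.read_csv(config.variant_table, sep="\t")
        from .cohort import VariantRecord, classify_variant
        variants = []
        for i, row in vdf.iterrows():
            try:
                cls = row.get("variant_class") or classify_variant(
                    str(row["cdna_hgvs"]), str(row.get("protein_hgvs", "")))
                variants.append(VariantRecord(
                    variant_id=str(row["variant_id"]),
                    cdna_hgvs=str(row["cdna_hgvs"]),
                    protein_hgvs=str(row.get("protein_hgvs", "")),
                    variant_class=cls,
                    maf_gnomad_nfe=_maybe_float(row.get("maf_gnomad_nfe")),
                    maf_evs=_maybe_float(row.get("maf_evs")),
                    maf_1kg=_maybe_float(row.get("maf_1kg")),
                    in_excluded_region=bool(row.get("in_excluded_region",
                                                    False)),
                ))
            except (KeyError, ValueError) as exc:
                raise ValueError(
                    f"{config.variant_table} line {i + 2}: {exc}") from exc
    else:
        variants = datasets.localization_study_variants()

    rare = filter_rare(variants, config.maf_cutoff)

    demo = datasets.belgian_cohort()
    if config.roster_table is not None:
        patients, controls = _read_roster_tsv(config.roster_table)
        classes = {v.variant_id: v.variant_class for v in variants}
        n_pat = len(patients) or 1
        n_ctl = len(controls) or 1
    else:
        patients, controls = demo.patient_roster, demo.control_roster
        classes = demo.variant_classes
        n_pat, n_ctl = demo.n_patients, demo.n_controls

    tables = [
        tally_carriers(patients, classes, "patients", n_pat),
        tally_carriers(controls, classes, "controls", n_ctl),
    ]
    report.cohort_tables = [dataclasses.asdict(t) for t in tables]

    freq_rows = []
    for t in tables:
        for metric, count in [("any_rare", t.carriers_any),
                              *sorted(t.carriers_by_class.items()),
                              ("multi_variant", t.multi_variant_carriers)]:
            pct, exact = carrier_frequency(count, t.cohort_size)
            freq_rows.append({"cohort": t.cohort, "metric": metric,
                              "count": count, "cohort_size": t.cohort_size,
                              "percent": pct, "exact": str(exact)})
    if config.roster_table is None:
        for name, (pos, tot), dec in [
                ("apoe_e4_missense_carriers", demo.apoe_e4_missense_carriers, 1),
                ("apoe_e4_full_cohort", demo.apoe_e4_full_cohort, 1),
                ("familial_history_missense_carriers", demo.familial_history, 1)]:
            pct, exact = carrier_frequency(pos, tot, decimals=dec)
            freq_rows.append({"cohort": "patients", "metric": name,
                              "count": pos, "cohort_size": tot,
                              "percent": pct, "exact": str(exact)})
    report.frequencies = freq_rows
    pd.DataFrame(freq_rows).to_csv(out / "carrier_frequencies.tsv", sep="\t",
                                   index=False)

    pt, ct = tables
    multi = contingency_test(
        pt.multi_variant_carriers, pt.cohort_size - pt.multi_variant_carriers,
        ct.multi_variant_carriers, ct.cohort_size - ct.multi_variant_carriers)
    report.contingency["multi_variant_carriers"] = dataclasses.asdict(multi)
    any_rare = contingency_test(
        pt.carriers_any, pt.cohort_size - pt.carriers_any,
        ct.carriers_any, ct.cohort_size - ct.carriers_any)
    report.contingency["any_rare"] = dataclasses.asdict(any_rare)
    if config.roster_table is None:
        e4c, e4t = demo.apoe_e4_missense_carriers
        e4f, e4ft = demo.apoe_e4_full_cohort
        apoe = contingency_test(e4c, e4t - e4c,
                                e4f - e4c, (e4ft - e4t) - (e4f - e4c))
        report.contingency["apoe_e4_enrichment"] = dataclasses.asdict(apoe)

    report.stage_counts = {
        "variants_in": len(variants),
        "variants_rare": len(rare),
        "patient_carriers": len(patients),
        "control_carriers": len(controls),
    }
    (out / "contingency.json").write_text(
        json.dumps(report.contingency, indent=2))
    (out / "cohort_report.json").write_text(report.to_json())
    return report


def _maybe_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


# ---------------------------------------------------------------------------
# config files

def load_config(path: Path) -> RunConfig:
    """Build a RunConfig from a YAML file with blocks mirroring the stages
    (``synthgen:``, ``segmentation:``, ``coloc:``, ``stats:``, ``cohort:``)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    syn = raw.get("synthgen", {})
    if "genotype_alphas" in syn:
        kwargs["genotype_alphas"] = {str(k): float(v)
                                     for k, v in syn.pop("genotype_alphas").items()}
    if "images_per_genotype" in syn:
        kwargs["images_per_genotype"] = int(syn.pop("images_per_genotype"))
    if syn:
        kwargs["scene"] = synthgen.SceneSpec.from_dict(
            {**synthgen.SceneSpec().to_dict(), **syn})
    if "segmentation" in raw:
        kwargs["segmentation"] = segment.SegmentationParams(**raw["segmentation"])
    co = raw.get("coloc", {})
    if "comarkers" in co:
        kwargs["comarkers"] = tuple(co["comarkers"])
    if "randomization_test" in co:
        kwargs["randomization_test"] = bool(co["randomization_test"])
    if "background_subtract" in co:
        kwargs["background_subtract"] = float(co["background_subtract"])
    st = raw.get("stats", {})
    for key in ("wt_label", "min_cells", "enforce_min_cells"):
        if key in st:
            kwargs[key] = st[key]
    ch = raw.get("cohort", {})
    for key in ("variant_table", "roster_table"):
        if key in ch:
            kwargs[key] = Path(ch[key])
    if "maf_cutoff" in ch:
        kwargs["maf_cutoff"] = float(ch["maf_cutoff"])
    for key in ("base_seed", "out_dir", "write_images"):
        if key in raw:
            kwargs[key] = raw[key]
    if "out_dir" in kwargs:
        kwargs["out_dir"] = Path(kwargs["out_dir"])
    return RunConfig(**kwargs)
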