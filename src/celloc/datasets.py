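"""Bundled demo data: the Belgian ABCA7 case/control cohort tallies and the
missense-variant annotation table used by the localization study.

The individual-level roster is synthetic: it is constructed to reconcile
simultaneously with all published cohort-level tallies (variant-occurrence
counts per class, distinct-carrier counts, and compound-carrier counts) of
the Belgian Alzheimer cohort (1376 patients, 976 controls).  Individual
identifiers and variant-to-individual assignments are therefore invented;
only the marginal counts are real.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import VariantRecord

__all__ = [
    "localization_study_variants",
    "BelgianCohort",
    "belgian_cohort",
    "DAMAGING_MUTANTS",
    "BENIGN_VARIANTS",
    "WT_LABEL",
]

WT_LABEL = "WT"

#: missense mutations with predicted damaging effect taken into the
#: localization experiment (protein HGVS labels)
DAMAGING_MUTANTS = ("p.L620P", "p.G826R", "p.A845V", "p.R880Q", "p.R989H",
                    "p.G1731S", "p.G1820S", "p.R1932C", "p.P1952R", "p.F2100S")

#: likely benign / protective variants included as positive controls
BENIGN_VARIANTS = ("p.E188G", "p.G215S", "p.R1349Q", "p.G1527A")


def localization_study_variants() -> list[VariantRecord]:
    """Annotation records of the 14 variants in the localization study:
    cDNA/protein HGVS, GnomAD non-Finnish-European MAF (%), and in silico
    predictor scores (PolyPhen-2 HumDiv, SIFT, CADD; stored, never computed).
    """
    rows = [
        # cdna, protein, polyphen2, sift, cadd, maf_nfe_percent
        ("c.1859T>C", "p.L620P", 1.000, 0.00, 31.0, 0.055),
        ("c.2476G>A", "p.G826R", 0.533, 0.23, 20.7, 0.075),
        ("c.2534C>T", "p.A845V", 1.000, 0.00, 25.2, None),
        ("c.2639G>A", "p.R880Q", 0.999, 0.00, 28.7, 0.198),
        ("c.2966G>A", "p.R989H", 1.000, 0.00, 28.2, 0.011),
        ("c.5191G>A", "p.G1731S", 1.000, 0.01, 26.5, 0.0035),
        ("c.5458G>A", "p.G1820S", 0.994, 0.03, 32.0, 0.046),
        ("c.5794C>T", "p.R1932C", 1.000, 0.00, 26.3, 0.0047),
        ("c.5855C>G", "p.P1952R", 1.000, 0.00, 24.9, None),
        ("c.6299T>C", "p.F2100S", 0.977, 0.00, 26.1, None),
        ("c.563A>G", "p.E188G", 0.244, 0.46, 13.13, 47.4),
        ("c.643G>A", "p.G215S", 0.029, 0.92, 0.100, 6.34),
        ("c.4046G>A", "p.R1349Q", 0.002, 0.40, 0.267, 43.2),
        ("c.4580G>C", "p.G1527A", 0.000, 0.89, 3.349, 83.0),
    ]
    return [
        VariantRecord(
            variant_id=prot, cdna_hgvs=cdna, protein_hgvs=prot,
            variant_class="missense", maf_gnomad_nfe=maf,
            predictor_scores={"polyphen2_humdiv": pp2, "sift": sift,
                              "cadd": cadd},
        )
        for cdna, prot, pp2, sift, cadd, maf in rows
    ]


@dataclass(frozen=True)
class BelgianCohort:
    """Cohort-level counts plus a synthetic individual-level roster."""

    n_patients: int
    n_controls: int
    patient_roster: dict[str, list[str]]
    control_roster: dict[str, list[str]]
    variant_classes: dict[str, str]
    # APOE e4 carriage among patient missense carriers vs genotyped cohort
    apoe_e4_missense_carriers: tuple[int, int]  # (positive, total)
    apoe_e4_full_cohort: tuple[int, int]
    # positive familial history among missense carriers with available info
    familial_history: tuple[int, int]


def _roster(prefix: str, composition: list[tuple[int, list[str]]],
            classes: dict[str, str]) -> dict[str, list[str]]:
    """Expand (count, class-pattern) blocks into individual -> variants."""
    roster: dict[str, list[str]] = {}
    idx = 0
    counters = {cls: 0 for cls in set(c for _, pat in composition for c in pat)}
    for count, pattern in composition:
        for _ in range(count):
            idx += 1
            variants = []
            for cls in pattern:
                counters[cls] += 1
                vid = f"{prefix}_{cls}_{counters[cls]:03d}"
                classes[vid] = cls
                variants.append(vid)
            roster[f"{prefix}_{idx:04d}"] = variants
    return roster


def belgian_cohort() -> BelgianCohort:
    """The Belgian case/control screen, as a reconciling synthetic roster.

    Patients (n=1376): 101 rare missense occurrences in 96 carriers, 10
    noncanonical splice, 4 indels; 11 compound carriers (5 missense+missense,
    4 missense+PTC, 2 missense+splice).  Controls (n=976): 50 missense in 46
    carriers, 7 splice, 2 indels; 5 compound carriers (4 missense+missense,
    1 missense+PTC).  PTC partners appear in the roster but are not counted
    in the missense/splice/indel occurrence tallies.
    """
    classes: dict[str, str] = {}
    patients = _roster("pat", [
        (5, ["missense", "missense"]),
        (4, ["missense", "ptc"]),
        (2, ["missense", "splice"]),
        (85, ["missense"]),
        (8, ["splice"]),
        (4, ["indel"]),
    ], classes)
    controls = _roster("ctl", [
        (4, ["missense", "missense"]),
        (1, ["missense", "ptc"]),
        (41, ["missense"]),
        (7, ["splice"]),
        (2, ["indel"]),
    ], classes)
    return BelgianCohort(
        n_patients=1376, n_controls=976,
        patient_roster=patients, control_roster=controls,
        variant_classes=classes,
        apoe_e4_missense_carriers=(66, 96),
        apoe_e4_full_cohort=(790, 1350),
        familial_history=(43, 73),
    )
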