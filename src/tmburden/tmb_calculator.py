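"""Turn filtered variant sets into tumor-mutational-burden values.

TMB is the number of protein-altering (MODERATE/HIGH impact) mutations per
megabase of the counting region: 75 Mb for the whole-exome capture region,
7 Mb for the 1059-gene cancer panel. Region sizes are configured constants;
:func:`tmburden.variant_core.region_from_bed` can derive a size from
intervals instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .somatic_filtering import (
    DB_THRESHOLD,
    FilterCriterion,
    apply_criterion,
    count_protein_altering,
)
from .variant_core import (
    AnnotatedVariant,
    ConfigError,
    DataError,
    PatientSample,
    PopulationFrequencyTable,
    RegionDefinition,
)


@dataclass(frozen=True)
class TMBRecord:
    """Per-patient TMB under one (criterion, region) combination."""

    patient_id: str
    group: str
    region: str
    criterion: str
    counted_mutations: int
    tmb: float


def compute_tmb(
    variants: frozenset[AnnotatedVariant],
    region: RegionDefinition,
) -> tuple[int, float]:
    """Count protein-altering variants in a region and divide by its size.

    If the region carries a gene set, only variants annotated to one of its
    genes are counted; variants with no gene annotation cannot be attributed
    to a panel and are excluded from panel counts (they still count toward
    regions without a gene set).
    """
    if region.size_mb <= 0:
        raise ConfigError(f"region {region.name!r}: size_mb must be > 0")
    if region.gene_set is not None:
        variants = frozenset(
            v for v in variants if v.gene and v.gene in region.gene_set
        )
    count = count_protein_altering(variants)
    return count, count / region.size_mb


def tmb_profile(
    patient: PatientSample,
    db: Optional[PopulationFrequencyTable],
    criteria: Iterable[FilterCriterion],
    regions: Iterable[RegionDefinition],
    partial: bool = False,
    fold: bool = False,
) -> list[TMBRecord]:
    """TMB records for one patient over all (criterion, region) pairs.

    Output order is stable: criteria in input order, regions inner. With
    ``partial=True`` a germline-paired criterion is silently skipped for a
    patient lacking a germline set; otherwise that raises.
    """
    records: list[TMBRecord] = []
    for criterion in criteria:
        if criterion.mode != DB_THRESHOLD and patient.germline_variants is None:
            if partial:
                continue
            raise DataError(
                f"patient {patient.patient_id}: criterion {criterion.label} "
                "requires a matched germline set (use partial=True to skip)"
            )
        retained = apply_criterion(
            patient.tumor_variants, criterion,
            db=db, germline=patient.germline_variants, fold=fold,
        )
        for region in regions:
            count, tmb = compute_tmb(retained, region)
            records.append(
                TMBRecord(
                    patient_id=patient.patient_id,
                    group=patient.group,
                    region=region.name,
                    criterion=criterion.label,
                    counted_mutations=count,
                    tmb=tmb,
                )
            )
    return records


def cohort_tmb(
    patients: Iterable[PatientSample],
    db: Optional[PopulationFrequencyTable],
    criteria: Iterable[FilterCriterion],
    regions: Iterable[RegionDefinition],
    partial: bool = False,
) -> list[TMBRecord]:
    """Concatenated tmb_profile over a cohort, patient order preserved."""
    criteria = list(criteria)
    regions = list(regions)
    out: list[TMBRecord] = []
    for p in patients:
        out.extend(tmb_profile(p, db, criteria, regions, partial=partial))
    return out
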