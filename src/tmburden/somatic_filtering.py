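"""Non-somatic variant filtering criteria.

Candidate somatic mutations are defined by removing presumed germline
variants from the tumor call set, either with the patient's matched germline
sample (the gold standard) or with population allele-frequency databases at
a frequency threshold tau:

* ``germline``  — exclude tumor variants present in the matched germline set.
* ``db:0``      — exclude tumor variants reported in ANY database.
* ``db:<tau>``  — exclude tumor variants whose frequency in ANY database is
  >= tau (the exclusion boundary is inclusive: a variant at exactly tau is
  removed).

The database rule is a logical OR over named databases, not a pooled
frequency, so additional catalogs participate without code change. A
database entry with allele count 0 is treated as "not reported".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .variant_core import (
    AnnotatedVariant,
    COUNTED_IMPACTS,
    ConfigError,
    DataError,
    PopulationFrequencyTable,
)

GERMLINE_PAIRED = "GERMLINE_PAIRED"
DB_THRESHOLD = "DB_THRESHOLD"


@dataclass(frozen=True)
class FilterCriterion:
    """One of the somatic-identification criteria.

    The canonical four are ``TMB_Germline``, ``TMB_DB0``, ``TMB_DB0.001``
    and ``TMB_DB0.01``; arbitrary thresholds are allowed via ``db:<float>``.
    """

    mode: str
    tau: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in (GERMLINE_PAIRED, DB_THRESHOLD):
            raise ConfigError(f"unknown criterion mode {self.mode!r}")
        if self.mode == DB_THRESHOLD:
            if self.tau is None or not (0.0 <= self.tau <= 1.0):
                raise ConfigError(f"db criterion needs tau in [0,1], got {self.tau}")
        elif self.tau is not None:
            raise ConfigError("germline criterion takes no tau")
        if not self.label:
            label = ("TMB_Germline" if self.mode == GERMLINE_PAIRED
                     else f"TMB_DB{self.tau:g}")
            object.__setattr__(self, "label", label)

    @classmethod
    def from_spec(cls, spec: str) -> "FilterCriterion":
        """Parse a criterion string: ``germline``, ``db:0``, ``db:0.001`` ..."""
        spec = spec.strip()
        if spec.lower() == "germline":
            return cls(mode=GERMLINE_PAIRED)
        if spec.lower().startswith("db:"):
            try:
                tau = float(spec[3:])
            except ValueError as exc:
                raise ConfigError(f"bad criterion spec {spec!r}") from exc
            return cls(mode=DB_THRESHOLD, tau=tau)
        raise ConfigError(f"bad criterion spec {spec!r}")


#: The four criteria used throughout the analyses, in increasing leniency.
CANONICAL_CRITERIA = (
    FilterCriterion(mode=GERMLINE_PAIRED),
    FilterCriterion(mode=DB_THRESHOLD, tau=0.0),
    FilterCriterion(mode=DB_THRESHOLD, tau=0.001),
    FilterCriterion(mode=DB_THRESHOLD, tau=0.01),
)


def filter_paired_germline(
    tumor: frozenset[AnnotatedVariant],
    germline: Optional[frozenset[AnnotatedVariant]],
) -> frozenset[AnnotatedVariant]:
    """Tumor variants whose key is absent from the matched germline set."""
    if germline is None:
        raise DataError(
            "no matched germline set: use a database criterion (db:<tau>) "
            "for tumor-only samples"
        )
    germline_keys = {v.key for v in germline}
    return frozenset(v for v in tumor if v.key not in germline_keys)


def filter_by_database(
    tumor: frozenset[AnnotatedVariant],
    db: PopulationFrequencyTable,
    criterion: FilterCriterion,
    fold: bool = False,
) -> frozenset[AnnotatedVariant]:
    """Tumor variants retained under a database-threshold criterion.

    tau = 0 excludes any variant reported in any database; tau > 0 excludes
    a variant iff some database reports frequency >= tau. Variants absent
    from the table are always retained. ``fold=True`` folds frequencies to
    the minor allele before comparison.
    """
    if criterion.mode != DB_THRESHOLD:
        raise ConfigError("filter_by_database requires a DB_THRESHOLD criterion")
    tau = criterion.tau
    retained = []
    for v in tumor:
        af = db.max_af(v.key, fold=fold)
        if af is None:
            retained.append(v)
        elif tau > 0.0 and af < tau:
            retained.append(v)
    return frozenset(retained)


def apply_criterion(
    tumor: frozenset[AnnotatedVariant],
    criterion: FilterCriterion,
    db: Optional[PopulationFrequencyTable] = None,
    germline: Optional[frozenset[AnnotatedVariant]] = None,
    fold: bool = False,
) -> frozenset[AnnotatedVariant]:
    """Dispatch a criterion to the appropriate filter."""
    if criterion.mode == GERMLINE_PAIRED:
        return filter_paired_germline(tumor, germline)
    if db is None:
        db = PopulationFrequencyTable()
    return filter_by_database(tumor, db, criterion, fold=fold)


def count_protein_altering(variants: frozenset[AnnotatedVariant]) -> int:
    """Number of variants with MODERATE or HIGH impact."""
    return sum(1 for v in variants if v.impact in COUNTED_IMPACTS)
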