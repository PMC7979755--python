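"""Domain types and file I/O for variants, patients, regions and frequency tables.

The unit of analysis is a decomposed, normalized single-alternate variant
(:class:`VariantKey`). Variant identity is exact ``(chrom, pos, ref, alt)``
equality — inputs are declared pre-normalized, so no left-alignment or allele
trimming is attempted here.

Readers consume VCF v4.2 (via cyvcf2) and plain TSV dialects; writers emit
TSVs that round-trip losslessly through their paired readers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
#: Impact categories counted as protein-altering for TMB purposes.
COUNTED_IMPACTS = frozenset({"HIGH", "MODERATE"})


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a biallelic variant: 1-based VCF coordinates, exact alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise DataError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise DataError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass(frozen=True, order=True)
class AnnotatedVariant:
    """A variant plus the annotations the pipeline consumes: impact and gene.

    ``impact`` is one of HIGH/MODERATE/LOW/MODIFIER (the conventional
    functional-consequence ladder); MODERATE and HIGH are treated as
    protein-altering. ``gene`` may be empty when the annotation source gave
    none; such variants still count toward whole-exome TMB but cannot be
    attributed to a gene panel.
    """

    key: VariantKey
    impact: str
    gene: str = ""

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_LEVELS:
            raise DataError(
                f"impact must be one of {IMPACT_LEVELS}, got {self.impact!r}"
            )

    @property
    def counted(self) -> bool:
        """True if the variant is protein-altering (MODERATE or HIGH impact)."""
        return self.impact in COUNTED_IMPACTS


@dataclass
class PatientSample:
    """One patient's variant call sets and group label.

    ``germline_variants`` is ``None`` when no matched normal was sequenced
    (tumor-only patients), which restricts the patient to database-based
    filtering criteria.
    """

    patient_id: str
    group: str
    tumor_variants: frozenset[AnnotatedVariant]
    germline_variants: Optional[frozenset[AnnotatedVariant]] = None

    def __post_init__(self) -> None:
        if not self.group:
            raise DataError(f"patient {self.patient_id}: empty group label")
        for name, vs in (("tumor", self.tumor_variants),
                         ("germline", self.germline_variants)):
            if vs is None:
                continue
            keys = [v.key for v in vs]
            if len(set(keys)) != len(keys):
                raise DataError(
                    f"patient {self.patient_id}: duplicate keys in {name} set"
                )


@dataclass(frozen=True)
class DatabaseRecord:
    """One database's report of a variant: allele frequency and counts."""

    af: float
    ac: Optional[int] = None
    an: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.af <= 1.0):
            raise DataError(f"af outside [0,1]: {self.af}")
        if self.ac is not None and self.an is not None:
            if self.ac > self.an:
                raise DataError(f"ac ({self.ac}) > an ({self.an})")


class PopulationFrequencyTable:
    """Map from variant key to per-database allele-frequency records.

    Emulates the role of the public catalogs (1000 Genomes, ExAC, ESP6500):
    a key absent from the table means the variant is not reported in any
    database. Databases are an open-ended named set, so additional catalogs
    need no code change.
    """

    def __init__(
        self,
        entries: Optional[Mapping[VariantKey, Mapping[str, DatabaseRecord]]] = None,
    ) -> None:
        self._entries: dict[VariantKey, dict[str, DatabaseRecord]] = {
            k: dict(v) for k, v in (entries or {}).items()
        }

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._entries

    def get(self, key: VariantKey) -> dict[str, DatabaseRecord]:
        """Per-database records for ``key`` (empty dict if unreported)."""
        return self._entries.get(key, {})

    def add(self, key: VariantKey, database: str, record: DatabaseRecord) -> None:
        dbmap = self._entries.setdefault(key, {})
        if database in dbmap:
            raise DataError(f"duplicate record for {key} in database {database!r}")
        dbmap[database] = record

    def items(self):
        return self._entries.items()

    def max_af(self, key: VariantKey, fold: bool = False) -> Optional[float]:
        """Largest reported frequency across databases, or None if unreported.

        Databases reporting ac == 0 are ignored (sites-only exports may list
        zero-count alleles). With ``fold=True`` frequencies are folded to the
        minor allele, min(af, 1-af).
        """
        best: Optional[float] = None
        for rec in self._entries.get(key, {}).values():
            if rec.ac is not None and rec.ac == 0:
                continue
            af = min(rec.af, 1.0 - rec.af) if fold else rec.af
            if best is None or af > best:
                best = af
        return best


@dataclass(frozen=True)
class RegionDefinition:
    """A counting region: a name, its size in megabases, optional gene set.

    The defaults used in the analyses are a 75 Mb whole-exome capture region
    and a 7 Mb panel of 1059 cancer-related genes.
    """

    name: str
    size_mb: float
    gene_set: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.size_mb <= 0:
            raise ConfigError(f"region {self.name!r}: size_mb must be > 0")
        if self.gene_set is not None and len(self.gene_set) == 0:
            raise ConfigError(f"region {self.name!r}: gene_set given but empty")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_annotated_vcf(
    path: str | Path,
    impact_info_key: str = "IMPACT",
    gene_info_key: str = "GENE",
) -> frozenset[AnnotatedVariant]:
    """Read a VCF v4.2 into a set of annotated single-alternate variants.

    Multi-allelic records are decomposed into one variant per alternate
    allele (all alternates share the record's impact/gene annotation).
    Records failing FILTER (anything other than PASS or missing) are dropped.
    A record without the impact INFO key is kept with impact MODIFIER and a
    warning, mirroring annotation pipelines that leave non-coding records
    unlabeled.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad files
        raise DataError(f"unreadable VCF {path}: {exc}") from exc

    out: set[AnnotatedVariant] = set()
    try:
        for i, rec in enumerate(vcf):
            # cyvcf2: FILTER is None for PASS or '.'
            if rec.FILTER is not None:
                continue
            impact = rec.INFO.get(impact_info_key)
            if impact is None:
                warnings.warn(
                    f"{path.name} record {rec.CHROM}:{rec.POS}: missing INFO "
                    f"{impact_info_key}; assigning MODIFIER"
                )
                impact = "MODIFIER"
            impact = str(impact).upper()
            if impact not in IMPACT_LEVELS:
                raise DataError(
                    f"{path.name} record {rec.CHROM}:{rec.POS}: "
                    f"unknown impact {impact!r}"
                )
            gene = rec.INFO.get(gene_info_key)
            gene = "" if gene is None else str(gene)
            for alt in rec.ALT:
                if alt in (None, ""):
                    continue
                out.add(
                    AnnotatedVariant(
                        key=VariantKey(str(rec.CHROM), int(rec.POS),
                                       str(rec.REF), str(alt)),
                        impact=impact,
                        gene=gene,
                    )
                )
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"garbled VCF {path}: {exc}") from exc
    return frozenset(out)


_FREQ_COLUMNS = ["CHROM", "POS", "REF", "ALT", "DB", "AF"]


def read_frequency_table(path: str | Path) -> PopulationFrequencyTable:
    """Read a per-(variant, database) TSV of allele frequencies.

    Required columns CHROM, POS, REF, ALT, DB, AF; optional AC, AN. A blank
    AF with AC and AN present is computed as AC/AN. Duplicate
    (variant, database) rows and inconsistent counts are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str, "REF": str, "ALT": str,
                                            "DB": str})
    missing = [c for c in _FREQ_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")

    table = PopulationFrequencyTable()
    for row in df.itertuples(index=True):
        rownum = row.Index + 2  # 1-based, counting the header line
        ac = None if not hasattr(row, "AC") or pd.isna(row.AC) else int(row.AC)
        an = None if not hasattr(row, "AN") or pd.isna(row.AN) else int(row.AN)
        if pd.isna(row.AF):
            if ac is None or an is None or an == 0:
                raise DataError(f"{path} row {rownum}: AF blank and AC/AN unusable")
            af = ac / an
        else:
            af = float(row.AF)
        if not (0.0 <= af <= 1.0):
            raise DataError(f"{path} row {rownum}: AF {af} outside [0,1]")
        if ac is not None and an is not None and ac > an:
            raise DataError(f"{path} row {rownum}: AC {ac} > AN {an}")
        key = VariantKey(str(row.CHROM), int(row.POS), str(row.REF), str(row.ALT))
        try:
            table.add(key, str(row.DB), DatabaseRecord(af=af, ac=ac, an=an))
        except DataError as exc:
            raise DataError(f"{path} row {rownum}: {exc}") from exc
    return table


def write_frequency_table(table: PopulationFrequencyTable,
                          path: str | Path) -> None:
    """Write a frequency table to the TSV dialect read_frequency_table reads."""
    rows = []
    for key, dbmap in sorted(table.items()):
        for db in sorted(dbmap):
            rec = dbmap[db]
            rows.append({"CHROM": key.chrom, "POS": key.pos, "REF": key.ref,
                         "ALT": key.alt, "DB": db, "AF": rec.af,
                         "AC": rec.ac, "AN": rec.an})
    df = pd.DataFrame(rows, columns=_FREQ_COLUMNS + ["AC", "AN"])
    df.to_csv(path, sep="\t", index=False)


_TMB_COLUMNS = ["patient_id", "group", "region", "criterion",
                "counted_mutations", "tmb"]


def write_tmb_table(records: Iterable, path: str | Path) -> None:
    """Write per-patient, per-criterion TMB records to TSV.

    Row order is stable (patient, then region, then criterion, in input
    order within a patient) and the file round-trips through
    :func:`read_tmb_table`.
    """
    rows = [
        {
            "patient_id": r.patient_id,
            "group": r.group,
            "region": r.region,
            "criterion": r.criterion,
            "counted_mutations": r.counted_mutations,
            "tmb": repr(r.tmb),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_TMB_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_tmb_table(path: str | Path) -> pd.DataFrame:
    """Read a TMB table TSV into a typed DataFrame."""
    df = pd.read_csv(
        path, sep="\t", float_precision="round_trip",
        dtype={"patient_id": str, "group": str, "region": str,
               "criterion": str, "counted_mutations": int, "tmb": float},
    )
    missing = [c for c in _TMB_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    return df


def write_vcf(
    variants: Iterable[AnnotatedVariant],
    path: str | Path,
    sample_id: str = "SAMPLE",
    impact_info_key: str = "IMPACT",
    gene_info_key: str = "GENE",
) -> None:
    """Write annotated variants as a minimal uncompressed VCF v4.2.

    All records are emitted as PASS with a heterozygous genotype placeholder;
    this writer exists so simulated cohorts exercise the same VCF reader as
    real data would.
    """

    def _sort_key(v: AnnotatedVariant):
        k = v.key
        return (len(k.chrom), k.chrom, k.pos, k.ref, k.alt)

    sorted_variants = sorted(variants, key=_sort_key)
    contigs = []
    for v in sorted_variants:
        if v.key.chrom not in contigs:
            contigs.append(v.key.chrom)
    lines = [
        "##fileformat=VCFv4.2",
        f'##INFO=<ID={impact_info_key},Number=1,Type=String,'
        'Description="Predicted functional impact category">',
        f'##INFO=<ID={gene_info_key},Number=1,Type=String,'
        'Description="Gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        *[f"##contig=<ID={c}>" for c in contigs],
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}",
    ]
    for v in sorted_variants:
        info = f"{impact_info_key}={v.impact}"
        if v.gene:
            info += f";{gene_info_key}={v.gene}"
        lines.append(
            f"{v.key.chrom}\t{v.key.pos}\t.\t{v.key.ref}\t{v.key.alt}"
            f"\t.\tPASS\t{info}\tGT\t0/1"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_panel(path: str | Path) -> frozenset[str]:
    """Read a newline-delimited gene symbol list (blank lines, '#' comments skipped)."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line)
    if not symbols:
        raise DataError(f"{path}: empty gene panel")
    return frozenset(symbols)


def region_from_bed(name: str, path: str | Path,
                    gene_set: Optional[frozenset[str]] = None) -> RegionDefinition:
    """Build a region whose size is the merged length of BED intervals.

    Intervals are half-open [start, end); overlapping or bookended intervals
    are merged per chromosome before summing.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise DataError(f"{path} line {ln}: fewer than 3 BED columns")
        start, end = int(parts[1]), int(parts[2])
        if end < start:
            raise DataError(f"{path} line {ln}: end < start")
        by_chrom.setdefault(parts[0], []).append((start, end))
    total = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    if total == 0:
        raise DataError(f"{path}: no intervals")
    return RegionDefinition(name=name, size_mb=total / 1e6, gene_set=gene_set)
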