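"""Synthetic cohorts with population structure and a finite-sample database.

The generator emulates the statistical structure that drives differential
TMB inflation between ancestry groups:

* **Germline variation.** A panel of polymorphic sites with ancestral
  frequencies drawn from a rare-skewed Beta site-frequency spectrum.
  Population-specific frequencies follow the Balding–Nichols model:
  ``p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` with divergence ``F`` (FST), so
  ``E[p_k] = p`` and ``Var[p_k] = F p (1-p)``. A configurable fraction of
  sites is private to one population (frequency zero elsewhere).
* **Public database.** Allele counts obtained by binomial sampling of a
  finite number of diploid individuals per population — by default a
  60,000-individual catalog that is 54.9% European and 8.6% African, the
  unequal composition whose consequences the analysis quantifies. Sites
  with zero sampled copies are absent from the database.
* **Somatic mutations.** Per-patient counts Poisson with a gamma-distributed
  rate (mutations/Mb), placed at positions disjoint from the germline panel
  by default, with impact labels assigned like panel sites.

Patient genotypes are Hardy–Weinberg binomial draws from the patient's
population frequencies. Group labels (e.g. self-reported race) are attached
to populations only through explicit config, since labels are a proxy for
ancestry rather than ancestry itself.

All randomness derives from one integer seed through documented
``numpy.random.SeedSequence`` spawn keys — ``(0,)`` site panel, ``(1,)``
database, ``(2, i)`` patient ``i`` — so any patient can be regenerated
independently of the rest of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .somatic_filtering import DB_THRESHOLD, FilterCriterion, CANONICAL_CRITERIA
from .tmb_calculator import TMBRecord
from .variant_core import (
    AnnotatedVariant,
    ConfigError,
    DatabaseRecord,
    PatientSample,
    PopulationFrequencyTable,
    RegionDefinition,
    VariantKey,
    write_frequency_table,
    write_vcf,
)

_BASES = np.array(["A", "C", "G", "T"])
_IMPACTS = np.array(["LOW", "MODERATE", "HIGH"])


def _gene_name(idx: int) -> str:
    return f"G{idx:05d}"


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic cohort.

    Defaults encode the study conditions: 575 White / 126 Black patients, a
    75 Mb exome, a 1059-gene (7 Mb) cancer panel, and a public database of
    60,000 individuals of which 54.9% are European and 8.6% African.
    """

    n_patients_by_group: dict[str, int] = field(
        default_factory=lambda: {"White": 575, "Black": 126})
    group_to_pop: dict[str, str] = field(
        default_factory=lambda: {"White": "EUR", "Black": "AFR"})
    n_sites: int = 200_000
    sfs_alpha: float = 0.15
    sfs_beta: float = 8.0
    fst_by_pop: dict[str, float] = field(
        default_factory=lambda: {"EUR": 0.1, "AFR": 0.1})
    private_rate_by_pop: dict[str, float] = field(
        default_factory=lambda: {"EUR": 0.05, "AFR": 0.15})
    db_samples_by_pop: dict[str, int] = field(
        default_factory=lambda: {"EUR": 32_940, "AFR": 5_160})
    db_name: str = "SIMDB"
    somatic_rate_mean: float = 8.0       # mutations per Mb, all impacts
    somatic_dispersion: float = 5.0      # gamma shape; inf = no overdispersion
    p_counted_impact: float = 0.7        # P(MODERATE or HIGH)
    p_high_given_counted: float = 0.2
    germline_sensitivity: float = 1.0    # detection prob per sample
    collision_rate: float = 0.0          # somatic placed on panel sites
    region: RegionDefinition = field(
        default_factory=lambda: RegionDefinition("exome", 75.0))
    n_genes: int = 11_346
    panel_genes: int = 1_059
    panel_size_mb: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        pops = set(self.fst_by_pop)
        if not pops:
            raise ConfigError("no populations configured")
        for g, p in self.group_to_pop.items():
            if p not in pops:
                raise ConfigError(f"group {g!r} maps to unknown population {p!r}")
        for g in self.n_patients_by_group:
            if g not in self.group_to_pop:
                raise ConfigError(f"group {g!r} has no population mapping")
        for g, n in self.n_patients_by_group.items():
            if n < 0:
                raise ConfigError(f"negative patient count for group {g!r}")
        for pop, f in self.fst_by_pop.items():
            if not (0.0 <= f < 1.0):
                raise ConfigError(f"fst for {pop!r} must be in [0,1), got {f}")
        for pop in self.private_rate_by_pop:
            if pop not in pops:
                raise ConfigError(f"private rate for unknown population {pop!r}")
        if sum(self.private_rate_by_pop.values()) > 1.0:
            raise ConfigError("private rates sum to more than 1")
        for pop, n in self.db_samples_by_pop.items():
            if pop not in pops:
                raise ConfigError(f"db samples for unknown population {pop!r}")
            if n < 0:
                raise ConfigError(f"negative db sample count for {pop!r}")
        for name, p in (("p_counted_impact", self.p_counted_impact),
                        ("p_high_given_counted", self.p_high_given_counted),
                        ("germline_sensitivity", self.germline_sensitivity),
                        ("collision_rate", self.collision_rate)):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {p}")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.somatic_rate_mean <= 0:
            raise ConfigError("somatic_rate_mean must be > 0")
        if self.somatic_dispersion <= 0:
            raise ConfigError("somatic_dispersion must be > 0")
        if self.sfs_alpha <= 0 or self.sfs_beta <= 0:
            raise ConfigError("sfs shape parameters must be > 0")
        if not (0 < self.panel_genes <= self.n_genes):
            raise ConfigError("panel_genes must be in (0, n_genes]")

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(sorted(self.fst_by_pop))

    def panel_region(self) -> RegionDefinition:
        """The cancer-gene-panel counting region (first panel_genes genes)."""
        return RegionDefinition(
            name="panel",
            size_mb=self.panel_size_mb,
            gene_set=frozenset(_gene_name(i) for i in range(self.panel_genes)),
        )

    # -- YAML round trip ----------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        kwargs: dict = {}
        if "populations" in d:
            pops = d.pop("populations")
            kwargs["fst_by_pop"] = {p: v["fst"] for p, v in pops.items()}
            kwargs["private_rate_by_pop"] = {
                p: v.get("private_rate", 0.0) for p, v in pops.items()}
            kwargs["db_samples_by_pop"] = {
                p: v.get("db_samples", 0) for p, v in pops.items()}
        if "groups" in d:
            kwargs["n_patients_by_group"] = dict(d.pop("groups"))
        if "region" in d:
            r = d.pop("region")
            kwargs["region"] = RegionDefinition(r.get("name", "exome"),
                                                float(r["size_mb"]))
        known = set(cls.__dataclass_fields__)
        for k, v in d.items():
            if k not in known:
                raise ConfigError(f"unknown config key {k!r}")
            kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "groups": dict(self.n_patients_by_group),
            "group_to_pop": dict(self.group_to_pop),
            "populations": {
                p: {
                    "fst": self.fst_by_pop[p],
                    "private_rate": self.private_rate_by_pop.get(p, 0.0),
                    "db_samples": self.db_samples_by_pop.get(p, 0),
                }
                for p in self.populations
            },
            "n_sites": self.n_sites,
            "sfs_alpha": self.sfs_alpha,
            "sfs_beta": self.sfs_beta,
            "db_name": self.db_name,
            "somatic_rate_mean": self.somatic_rate_mean,
            "somatic_dispersion": self.somatic_dispersion,
            "p_counted_impact": self.p_counted_impact,
            "p_high_given_counted": self.p_high_given_counted,
            "germline_sensitivity": self.germline_sensitivity,
            "collision_rate": self.collision_rate,
            "region": {"name": self.region.name, "size_mb": self.region.size_mb},
            "n_genes": self.n_genes,
            "panel_genes": self.panel_genes,
            "panel_size_mb": self.panel_size_mb,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Site frequency panel
# ---------------------------------------------------------------------------

@dataclass
class SiteFrequencyPanel:
    """Realized per-population frequencies for the germline site panel.

    Stored as parallel arrays over sites. ``owner`` is the population index
    of a private site and -1 for shared sites. Panel positions are even
    integers so simulated somatic positions (odd) can never collide unless
    collisions are requested explicitly.
    """

    populations: tuple[str, ...]
    chrom: np.ndarray        # int, 1..22
    pos: np.ndarray          # int
    ref: np.ndarray          # unicode length-1
    alt: np.ndarray
    p_anc: np.ndarray
    p_by_pop: dict[str, np.ndarray]
    impact: np.ndarray       # index into _IMPACTS
    gene_idx: np.ndarray
    owner: np.ndarray        # -1 shared, else population index

    @property
    def n_sites(self) -> int:
        return self.p_anc.size

    @property
    def counted(self) -> np.ndarray:
        """Boolean mask of protein-altering (MODERATE/HIGH) sites."""
        return self.impact >= 1

    def key(self, i: int) -> VariantKey:
        return VariantKey(f"chr{self.chrom[i]}", int(self.pos[i]),
                          str(self.ref[i]), str(self.alt[i]))

    def variant(self, i: int) -> AnnotatedVariant:
        return AnnotatedVariant(
            key=self.key(i),
            impact=str(_IMPACTS[self.impact[i]]),
            gene=_gene_name(int(self.gene_idx[i])),
        )


def balding_nichols(p_anc: np.ndarray, fst: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw population frequencies around ancestral ones at divergence fst.

    ``Beta(p(1-F)/F, (1-p)(1-F)/F)``; at F = 0 the distribution degenerates
    to a point mass at p_anc and no draws are consumed.
    """
    if not (0.0 <= fst < 1.0):
        raise ConfigError(f"fst must be in [0,1), got {fst}")
    if fst == 0.0:
        return np.array(p_anc, dtype=float, copy=True)
    scale = (1.0 - fst) / fst
    return rng.beta(np.asarray(p_anc) * scale, (1.0 - np.asarray(p_anc)) * scale)


def draw_site_panel(config: SimulationConfig,
                    rng: Optional[np.random.Generator] = None) -> SiteFrequencyPanel:
    """Draw the germline site panel: identities, frequencies, annotations."""
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(0,)))
    n = config.n_sites
    pops = config.populations

    chrom = (np.arange(n) % 22) + 1
    pos = (np.arange(n) // 22 + 1) * 2        # even positions
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
    ref = _BASES[ref_idx]
    alt = _BASES[alt_idx]

    p_anc = rng.beta(config.sfs_alpha, config.sfs_beta, n)
    # clip away exact 0/1 so Balding-Nichols shapes stay positive
    p_anc = np.clip(p_anc, 1e-12, 1.0 - 1e-12)

    # private-site ownership: one multinomial cut of a single uniform
    u = rng.random(n)
    owner = np.full(n, -1, dtype=int)
    lo = 0.0
    for k, pop in enumerate(pops):
        rate = config.private_rate_by_pop.get(pop, 0.0)
        owner[(u >= lo) & (u < lo + rate)] = k
        lo += rate

    p_by_pop: dict[str, np.ndarray] = {}
    for k, pop in enumerate(pops):
        p = balding_nichols(p_anc, config.fst_by_pop[pop], rng)
        p[(owner >= 0) & (owner != k)] = 0.0
        p_by_pop[pop] = p

    ui = rng.random(n)
    p_c = config.p_counted_impact
    impact = np.zeros(n, dtype=np.int8)
    impact[ui < p_c] = 1
    impact[ui < p_c * config.p_high_given_counted] = 2

    gene_idx = rng.integers(0, config.n_genes, n)

    return SiteFrequencyPanel(
        populations=pops, chrom=chrom, pos=pos, ref=ref, alt=alt,
        p_anc=p_anc, p_by_pop=p_by_pop, impact=impact,
        gene_idx=gene_idx, owner=owner,
    )


# ---------------------------------------------------------------------------
# Public database
# ---------------------------------------------------------------------------

def draw_db_counts(panel: SiteFrequencyPanel,
                   db_samples_by_pop: dict[str, int],
                   rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Binomially sample database allele counts per site.

    ac[i] = sum over populations of Binomial(2 N_pop, p_pop[i]);
    an = 2 * sum N_pop. Sites with ac == 0 are unreported.
    """
    if sum(db_samples_by_pop.values()) < 1:
        raise ConfigError("database needs at least one sampled individual")
    ac = np.zeros(panel.n_sites, dtype=np.int64)
    an = 0
    for pop in panel.populations:
        n_pop = int(db_samples_by_pop.get(pop, 0))
        if n_pop == 0:
            continue
        ac += rng.binomial(2 * n_pop, panel.p_by_pop[pop])
        an += 2 * n_pop
    return ac, an


def build_public_db(panel: SiteFrequencyPanel,
                    db_samples_by_pop: dict[str, int],
                    rng: Optional[np.random.Generator] = None,
                    db_name: str = "SIMDB",
                    seed: int = 0) -> PopulationFrequencyTable:
    """Materialize a finite-sample public database as a frequency table."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    ac, an = draw_db_counts(panel, db_samples_by_pop, rng)
    table = PopulationFrequencyTable()
    for i in np.nonzero(ac)[0]:
        table.add(panel.key(int(i)), db_name,
                  DatabaseRecord(af=float(ac[i] / an), ac=int(ac[i]), an=an))
    return table


# ---------------------------------------------------------------------------
# Patients
# ---------------------------------------------------------------------------

@dataclass
class _PatientDraws:
    """Raw per-patient draws shared by the object and counting paths."""

    carrier_idx: np.ndarray      # panel site indices with genotype >= 1
    genotype: np.ndarray         # 1 or 2, aligned with carrier_idx
    in_tumor: np.ndarray         # bool, aligned with carrier_idx
    in_germline: np.ndarray      # bool, aligned with carrier_idx
    som_impact: np.ndarray       # index into _IMPACTS per somatic mutation
    som_gene: np.ndarray         # gene index per somatic mutation
    som_site: np.ndarray         # panel site index if colliding, else -1


def _draw_patient(panel: SiteFrequencyPanel, pop: str,
                  config: SimulationConfig,
                  rng: np.random.Generator) -> _PatientDraws:
    p = panel.p_by_pop[pop]
    # genotype ~ Binomial(2, p) via one uniform: [0,p^2) hom-alt,
    # [p^2, 2p - p^2) het, else hom-ref
    u = rng.random(panel.n_sites)
    carrier = u < p * (2.0 - p)
    carrier_idx = np.nonzero(carrier)[0]
    genotype = np.where(u[carrier_idx] < p[carrier_idx] ** 2, 2, 1).astype(np.int8)

    sens = config.germline_sensitivity
    m = carrier_idx.size
    if sens >= 1.0:
        in_tumor = np.ones(m, dtype=bool)
        in_germline = np.ones(m, dtype=bool)
    else:
        in_tumor = rng.random(m) < sens
        in_germline = rng.random(m) < sens

    k = config.somatic_dispersion
    mu = config.somatic_rate_mean
    rate = mu if np.isinf(k) else rng.gamma(k, mu / k)
    n_som = rng.poisson(rate * config.region.size_mb)
    us = rng.random(n_som)
    p_c = config.p_counted_impact
    som_impact = np.zeros(n_som, dtype=np.int8)
    som_impact[us < p_c] = 1
    som_impact[us < p_c * config.p_high_given_counted] = 2
    som_gene = rng.integers(0, config.n_genes, n_som)
    som_site = np.full(n_som, -1, dtype=np.int64)
    if config.collision_rate > 0.0:
        coll = rng.random(n_som) < config.collision_rate
        som_site[coll] = rng.integers(0, panel.n_sites, int(coll.sum()))
    return _PatientDraws(carrier_idx=carrier_idx, genotype=genotype,
                         in_tumor=in_tumor, in_germline=in_germline,
                         som_impact=som_impact, som_gene=som_gene,
                         som_site=som_site)


def _somatic_variants(draws: _PatientDraws, panel: SiteFrequencyPanel,
                      patient_index: int) -> list[AnnotatedVariant]:
    """Materialize somatic mutations with cohort-unique odd positions.

    Positions are bookkeeping identities only (no linkage or hotspot
    structure is modeled), so non-colliding mutations get sequential odd
    positions disjoint from the panel's even positions.
    """
    out = []
    base = patient_index * 1_000_003
    for j in range(draws.som_impact.size):
        site = draws.som_site[j]
        if site >= 0:
            out.append(panel.variant(int(site)))
            continue
        serial = base + j
        key = VariantKey(f"chr{serial % 22 + 1}", (serial // 22 + 1) * 2 + 1,
                         "A", "T")
        out.append(AnnotatedVariant(
            key=key, impact=str(_IMPACTS[draws.som_impact[j]]),
            gene=_gene_name(int(draws.som_gene[j]))))
    return out


def simulate_patient(
    panel: SiteFrequencyPanel,
    group: str,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    patient_id: str = "P0",
    patient_index: int = 0,
) -> tuple[PatientSample, frozenset[AnnotatedVariant], frozenset[AnnotatedVariant]]:
    """Simulate one patient: sample plus (true somatic, true germline) sets."""
    pop = config.group_to_pop.get(group)
    if pop is None or pop not in panel.p_by_pop:
        raise ConfigError(f"group {group!r} has no configured population")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(2, patient_index)))
    draws = _draw_patient(panel, pop, config, rng)

    germ_truth = frozenset(panel.variant(int(i)) for i in draws.carrier_idx)
    by_idx = {int(i): panel.variant(int(i)) for i in draws.carrier_idx}
    tumor_germ = {by_idx[int(i)]
                  for i, t in zip(draws.carrier_idx, draws.in_tumor) if t}
    germ_sample = {by_idx[int(i)]
                   for i, g in zip(draws.carrier_idx, draws.in_germline) if g}
    somatic = frozenset(_somatic_variants(draws, panel, patient_index))

    sample = PatientSample(
        patient_id=patient_id, group=group,
        tumor_variants=frozenset(tumor_germ | set(somatic)),
        germline_variants=frozenset(germ_sample),
    )
    return sample, somatic, germ_truth


@dataclass
class SyntheticCohort:
    """A simulated cohort with its database and per-patient truth sets."""

    patients: list[PatientSample]
    db_table: PopulationFrequencyTable
    truth: dict[str, tuple[frozenset[AnnotatedVariant], frozenset[AnnotatedVariant]]]
    panel: SiteFrequencyPanel
    config: SimulationConfig

    def emit(self, outdir: str | Path) -> dict[str, Path]:
        """Write the cohort to standard files: VCFs, TSVs, panel list.

        Emits per-patient tumor and germline VCFs, the database frequency
        TSV, a cohort metadata TSV, a truth TSV, and the panel gene list.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        vcf_dir = outdir / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        paths: dict[str, Path] = {}
        meta_rows, truth_rows = [], []
        for p in self.patients:
            tpath = vcf_dir / f"{p.patient_id}.tumor.vcf"
            write_vcf(p.tumor_variants, tpath, sample_id=p.patient_id)
            gpath = None
            if p.germline_variants is not None:
                gpath = vcf_dir / f"{p.patient_id}.germline.vcf"
                write_vcf(p.germline_variants, gpath, sample_id=p.patient_id)
            meta_rows.append({
                "patient_id": p.patient_id, "group": p.group,
                "tumor_vcf": f"vcf/{tpath.name}",
                "germline_vcf": f"vcf/{gpath.name}" if gpath else "",
            })
            somatic, germ = self.truth[p.patient_id]
            for origin, vs in (("somatic", somatic), ("germline", germ)):
                for v in sorted(vs):
                    truth_rows.append({
                        "patient_id": p.patient_id, "origin": origin,
                        "CHROM": v.key.chrom, "POS": v.key.pos,
                        "REF": v.key.ref, "ALT": v.key.alt,
                        "IMPACT": v.impact, "GENE": v.gene,
                    })
        paths["metadata"] = outdir / "cohort_metadata.tsv"
        pd.DataFrame(meta_rows).to_csv(paths["metadata"], sep="\t", index=False)
        paths["truth"] = outdir / "truth.tsv"
        pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
        paths["frequency_table"] = outdir / "frequency_table.tsv"
        write_frequency_table(self.db_table, paths["frequency_table"])
        paths["panel_genes"] = outdir / "panel_genes.txt"
        paths["panel_genes"].write_text(
            "\n".join(_gene_name(i) for i in range(self.config.panel_genes)) + "\n")
        paths["vcf_dir"] = vcf_dir
        return paths


def _patient_ids(config: SimulationConfig) -> list[tuple[str, str]]:
    """Stable (patient_id, group) order: groups sorted, ids zero-padded."""
    out = []
    i = 0
    for group in sorted(config.n_patients_by_group):
        for _ in range(config.n_patients_by_group[group]):
            out.append((f"P{i:04d}", group))
            i += 1
    return out


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate a full cohort: panel, database, patients, truth.

    Deterministic given ``config.seed``. Database individuals are simulated
    separately from cohort patients (patients are never in the database).
    Intended for object-level work at modest sizes; replicate studies use
    :func:`simulate_cohort_tmb`, which shares this function's draws.
    """
    panel = draw_site_panel(config)
    db_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1,)))
    db_table = build_public_db(panel, config.db_samples_by_pop, rng=db_rng,
                               db_name=config.db_name)
    patients, truth = [], {}
    for idx, (pid, group) in enumerate(_patient_ids(config)):
        sample, somatic, germ = simulate_patient(
            panel, group, config, patient_id=pid, patient_index=idx)
        patients.append(sample)
        truth[pid] = (somatic, germ)
    return SyntheticCohort(patients=patients, db_table=db_table, truth=truth,
                           panel=panel, config=config)


# ---------------------------------------------------------------------------
# Fast counting path
# ---------------------------------------------------------------------------

def simulate_cohort_tmb(
    config: SimulationConfig,
    criteria: Sequence[FilterCriterion] = CANONICAL_CRITERIA,
    regions: Optional[Sequence[RegionDefinition]] = None,
) -> list[TMBRecord]:
    """Simulate a cohort and compute its TMB table without materializing sets.

    Consumes exactly the same random draws as :func:`simulate_cohort`
    followed by filtering and counting, and produces the identical TMB
    records — verified by an exact-equality test — but in vectorized form,
    which is what makes replicate studies at realistic site counts cheap.
    If ``regions`` is None the exome and panel regions from the config are
    used.
    """
    panel = draw_site_panel(config)
    db_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1,)))
    ac, an = draw_db_counts(panel, config.db_samples_by_pop, db_rng)
    af = ac / an if an > 0 else np.zeros_like(ac, dtype=float)
    reported = ac > 0

    if regions is None:
        regions = (config.region, config.panel_region())
    region_gene_masks = []
    for r in regions:
        if r.gene_set is None:
            region_gene_masks.append(None)
        else:
            in_panel = np.zeros(config.n_genes, dtype=bool)
            for g in r.gene_set:
                idx = int(g[1:])
                if idx < config.n_genes:
                    in_panel[idx] = True
            region_gene_masks.append(in_panel)

    # per-criterion site retention mask (database criteria only)
    site_retained = {}
    for crit in criteria:
        if crit.mode == DB_THRESHOLD:
            if crit.tau == 0.0:
                site_retained[crit.label] = ~reported
            else:
                site_retained[crit.label] = ~reported | (af < crit.tau)

    counted_site = panel.counted
    records: list[TMBRecord] = []
    for idx, (pid, group) in enumerate(_patient_ids(config)):
        pop = config.group_to_pop[group]
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(2, idx)))
        d = _draw_patient(panel, pop, config, rng)

        cidx = d.carrier_idx
        tumor_c = cidx[d.in_tumor]                 # germline-origin, in tumor
        counted_tc = counted_site[tumor_c]
        som_counted = d.som_impact >= 1
        colliding = d.som_site >= 0
        # somatic mutations landing on a panel site are filtered like the site
        som_free = ~colliding
        for crit in criteria:
            if crit.mode == DB_THRESHOLD:
                keep = site_retained[crit.label]
                germ_part = int(np.count_nonzero(counted_tc & keep[tumor_c]))
                coll_keep = keep[d.som_site[colliding]]
            else:
                germ_only = d.in_tumor & ~d.in_germline
                germ_part = int(np.count_nonzero(
                    counted_site[cidx[germ_only]]))
                coll_keep = np.ones(int(colliding.sum()), dtype=bool)
            for region, gmask in zip(regions, region_gene_masks):
                if gmask is None:
                    g = germ_part
                    som_part = int(np.count_nonzero(som_counted & som_free))
                    coll_part = int(np.count_nonzero(
                        counted_site[d.som_site[colliding]] & coll_keep))
                else:
                    if crit.mode == DB_THRESHOLD:
                        keep = site_retained[crit.label]
                        g = int(np.count_nonzero(
                            counted_tc & keep[tumor_c] & gmask[
                                panel.gene_idx[tumor_c]]))
                    else:
                        sel = cidx[d.in_tumor & ~d.in_germline]
                        g = int(np.count_nonzero(
                            counted_site[sel] & gmask[panel.gene_idx[sel]]))
                    som_part = int(np.count_nonzero(
                        som_counted & som_free & gmask[d.som_gene]))
                    coll_part = int(np.count_nonzero(
                        counted_site[d.som_site[colliding]] & coll_keep
                        & gmask[panel.gene_idx[d.som_site[colliding]]]))
                count = g + som_part + coll_part
                records.append(TMBRecord(
                    patient_id=pid, group=group, region=region.name,
                    criterion=crit.label, counted_mutations=count,
                    tmb=count / region.size_mb))
    return records
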