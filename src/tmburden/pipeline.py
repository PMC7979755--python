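"""End-to-end orchestration: simulate or read a cohort, filter, count, compare.

``run_pipeline`` realizes the whole analysis as one reproducible call:
per-patient TMB under the requested criteria and regions, group summaries,
t-tests, the group x criterion interaction ANOVA, cross-criterion Pearson
correlations, TMB-high classification, and a machine-readable run manifest
(config echo, seed, version, input checksums). Identical config + seed
yields byte-identical TMB tables.

``make_fixture`` writes a hand-authored 3-patient micro-cohort whose TMB
table is known exactly; the test suite freezes those expectations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .cohort_stats import (
    classify_tmb_high,
    correlation_matrix,
    interaction_anova,
    records_to_frame,
    student_t_test,
    summarize_groups,
    tmb_wide,
)
from .somatic_filtering import CANONICAL_CRITERIA, FilterCriterion
from .synthetic_cohort import SimulationConfig, simulate_cohort_tmb
from .tmb_calculator import cohort_tmb
from .variant_core import (
    ConfigError,
    DataError,
    PatientSample,
    RegionDefinition,
    read_annotated_vcf,
    read_frequency_table,
    read_gene_panel,
    write_tmb_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"                      # "simulate" | "vcf"
    out_dir: Path = Path("tmburden_out")
    seed: int = 0
    criteria: Sequence[str] = ("germline", "db:0", "db:0.001", "db:0.01")
    tmb_high_threshold: float = 10.0
    # simulate mode
    sim_config: Optional[SimulationConfig] = None
    # vcf mode
    metadata_path: Optional[Path] = None        # patient_id/group/vcf columns
    frequency_table_path: Optional[Path] = None
    panel_genes_path: Optional[Path] = None
    exome_size_mb: float = 75.0
    panel_size_mb: float = 7.0

    def validate(self) -> None:
        if self.mode not in ("simulate", "vcf"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not self.criteria:
            raise ConfigError("criteria list is empty")
        if self.mode == "vcf":
            for name, p in (("metadata", self.metadata_path),
                            ("frequency table", self.frequency_table_path)):
                if p is None or not Path(p).exists():
                    raise ConfigError(f"vcf mode requires an existing {name} path")
            if (self.panel_genes_path is not None
                    and not Path(self.panel_genes_path).exists()):
                raise ConfigError("panel gene list path does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _load_vcf_cohort(config: RunConfig):
    meta = pd.read_csv(config.metadata_path, sep="\t",
                       dtype=str).fillna("")
    for col in ("patient_id", "group", "tumor_vcf"):
        if col not in meta.columns:
            raise DataError(f"{config.metadata_path}: missing column {col!r}")
    base = Path(config.metadata_path).parent
    patients = []
    for row in meta.itertuples():
        tumor = read_annotated_vcf(base / row.tumor_vcf)
        germline = None
        gv = getattr(row, "germline_vcf", "")
        if gv:
            germline = read_annotated_vcf(base / gv)
        patients.append(PatientSample(
            patient_id=row.patient_id, group=row.group,
            tumor_variants=tumor, germline_variants=germline))
    db = read_frequency_table(config.frequency_table_path)
    return patients, db


def _regions(config: RunConfig) -> list[RegionDefinition]:
    regions = [RegionDefinition("exome", config.exome_size_mb)]
    if config.panel_genes_path is not None:
        genes = read_gene_panel(config.panel_genes_path)
        regions.append(RegionDefinition("panel", config.panel_size_mb,
                                        gene_set=genes))
    return regions


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns a map of output names to paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    criteria = [FilterCriterion.from_spec(s) for s in config.criteria]
    inputs: dict[str, str] = {}

    if config.mode == "simulate":
        sim = config.sim_config or SimulationConfig(seed=config.seed)
        if sim.seed != config.seed:
            from dataclasses import replace
            sim = replace(sim, seed=config.seed)
        logger.info("simulating cohort: %s patients, %d sites",
                    sim.n_patients_by_group, sim.n_sites)
        records = simulate_cohort_tmb(sim, criteria=criteria)
        config_echo = {"mode": "simulate", "sim": sim.to_dict()}
    else:
        patients, db = _load_vcf_cohort(config)
        logger.info("read %d patients from %s", len(patients),
                    config.metadata_path)
        regions = _regions(config)
        records = cohort_tmb(patients, db, criteria, regions, partial=True)
        config_echo = {"mode": "vcf",
                       "metadata": str(config.metadata_path),
                       "frequency_table": str(config.frequency_table_path),
                       "panel_genes": str(config.panel_genes_path)}
        for key in ("metadata_path", "frequency_table_path",
                    "panel_genes_path"):
            p = getattr(config, key)
            if p is not None:
                inputs[key] = _sha256(Path(p))

    df = records_to_frame(records)
    paths: dict[str, Path] = {}

    paths["tmb_table"] = out / "tmb_table.tsv"
    write_tmb_table(records, paths["tmb_table"])
    logger.info("wrote %d TMB records", len(records))

    summary = summarize_groups(df)
    paths["group_summary"] = out / "group_summary.tsv"
    summary.to_csv(paths["group_summary"], sep="\t", index=False)

    # per-criterion t-tests between the two largest groups, per region
    groups = df["group"].value_counts().index.tolist()
    trows = []
    if len(groups) >= 2:
        ga, gb = groups[0], groups[1]
        for (region, criterion), sub in df.groupby(["region", "criterion"]):
            a = sub.loc[sub["group"] == ga, "tmb"].to_numpy()
            b = sub.loc[sub["group"] == gb, "tmb"].to_numpy()
            if a.size < 2 or b.size < 2:
                logger.warning("t-test skipped for %s/%s: group too small",
                               region, criterion)
                continue
            r = student_t_test(a, b)
            trows.append({"region": region, "criterion": criterion,
                          "group_a": ga, "group_b": gb,
                          "t": r.t, "df": r.df, "p": r.p})
    paths["t_tests"] = out / "t_tests.tsv"
    pd.DataFrame(trows, columns=["region", "criterion", "group_a",
                                 "group_b", "t", "df", "p"]).to_csv(
        paths["t_tests"], sep="\t", index=False)

    arows = []
    for region, sub in df.groupby("region"):
        if sub["group"].nunique() < 2 or sub["criterion"].nunique() < 2:
            continue
        res = interaction_anova(sub)
        arows.append({"region": region, "f": res.f, "df_num": res.df_num,
                      "df_den": res.df_den, "p": res.p,
                      "ss_group": res.ss_table.loc["group", "ss"],
                      "ss_criterion": res.ss_table.loc["criterion", "ss"],
                      "ss_interaction": res.ss_table.loc["interaction", "ss"],
                      "ss_residual": res.ss_table.loc["residual", "ss"]})
    paths["anova"] = out / "anova.tsv"
    pd.DataFrame(arows).to_csv(paths["anova"], sep="\t", index=False)

    for region in df["region"].unique():
        wide = tmb_wide(df, region)
        if len(wide) >= 3:
            corr = correlation_matrix(wide)
            p = out / f"correlations_{region}.tsv"
            corr.to_csv(p, sep="\t")
            paths[f"correlations_{region}"] = p

    th = classify_tmb_high(df, threshold=config.tmb_high_threshold)
    paths["tmb_high"] = out / "tmb_high.tsv"
    th.counts.to_csv(paths["tmb_high"], sep="\t", index=False)
    paths["tmb_high_discordance"] = out / "tmb_high_discordance.tsv"
    th.discordant.to_csv(paths["tmb_high_discordance"], sep="\t", index=False)

    manifest = {
        "tool": "tmburden",
        "version": __version__,
        "seed": config.seed,
        "config": config_echo,
        "criteria": [c.label for c in criteria],
        "tmb_high_threshold": config.tmb_high_threshold,
        "input_checksums": inputs,
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)}
                    for k, v in paths.items()},
        "n_tests": {"t_tests": len(trows), "anova": len(arows)},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest"] = mpath
    return paths


# ---------------------------------------------------------------------------
# Hand-authored micro-cohort fixture
# ---------------------------------------------------------------------------

_VCF_HEADER = ("##fileformat=VCFv4.2\n"
               '##INFO=<ID=IMPACT,Number=1,Type=String,Description='
               '"Predicted functional impact category">\n'
               '##INFO=<ID=GENE,Number=1,Type=String,Description='
               '"Gene symbol">\n'
               '##FILTER=<ID=q10,Description="Low quality">\n'
               '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
               + "".join(f"##contig=<ID=chr{i}>\n" for i in range(1, 14))
               + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sid}\n")

# patient F1 (Black): 6 counted somatic; one rare (0.004) and one unreported
# germline variant leak through database filters.
_F1_TUMOR = [
    ("chr1", 101, "A", "T", "PASS", "IMPACT=HIGH;GENE=TP53"),
    ("chr1", 201, "C", "G", "PASS", "IMPACT=MODERATE;GENE=KRAS"),
    ("chr2", 101, "G", "A", "PASS", "IMPACT=MODERATE;GENE=EGFR"),
    ("chr2", 201, "T", "C", "PASS", "IMPACT=HIGH;GENE=BRAF"),
    ("chr3", 101, "A", "G", "PASS", "IMPACT=MODERATE"),
    ("chr3", 201, "C", "T", "PASS", "IMPACT=MODERATE"),
    ("chr4", 101, "G", "T", "PASS", "IMPACT=LOW"),
    ("chr5", 101, "A", "C", "PASS", "IMPACT=MODERATE;GENE=GENEX"),
    ("chr5", 201, "T", "G", "PASS", "IMPACT=HIGH;GENE=TP53"),
    ("chr6", 101, "C", "A", "PASS", "IMPACT=MODERATE"),
]
_F1_GERMLINE = [
    ("chr5", 101, "A", "C", "PASS", "IMPACT=MODERATE;GENE=GENEX"),
    ("chr5", 201, "T", "G", "PASS", "IMPACT=HIGH;GENE=TP53"),
    ("chr6", 101, "C", "A", "PASS", "IMPACT=MODERATE"),
    ("chr6", 201, "G", "C", "PASS", "IMPACT=MODERATE"),
]

# patient F2 (White): 3 counted somatic; 9 counted variants survive db:0.01,
# so tumor-only filtering at 1% inflates the count by 6.
_F2_TUMOR = [
    ("chr1", 301, "A", "T", "PASS", "IMPACT=MODERATE;GENE=TP53"),
    ("chr2", 301, "C", "T", "PASS", "IMPACT=HIGH"),
    ("chr3", 301, "G", "C", "PASS", "IMPACT=MODERATE;GENE=KRAS"),
    ("chr7", 101, "A", "G", "PASS", "IMPACT=MODERATE;GENE=PIK3CA"),
    ("chr7", 201, "C", "T", "PASS", "IMPACT=HIGH"),
    ("chr7", 301, "G", "A", "PASS", "IMPACT=MODERATE"),
    ("chr8", 101, "T", "A", "PASS", "IMPACT=MODERATE;GENE=EGFR"),
    ("chr8", 201, "A", "C", "PASS", "IMPACT=HIGH"),
    ("chr8", 301, "C", "G", "PASS", "IMPACT=MODERATE"),
    ("chr9", 101, "G", "T", "PASS", "IMPACT=LOW"),
    ("chr9", 201, "T", "C", "PASS", "IMPACT=MODERATE"),
]
_F2_GERMLINE = [
    ("chr7", 101, "A", "G", "PASS", "IMPACT=MODERATE;GENE=PIK3CA"),
    ("chr7", 201, "C", "T", "PASS", "IMPACT=HIGH"),
    ("chr7", 301, "G", "A", "PASS", "IMPACT=MODERATE"),
    ("chr8", 101, "T", "A", "PASS", "IMPACT=MODERATE;GENE=EGFR"),
    ("chr8", 201, "A", "C", "PASS", "IMPACT=HIGH"),
    ("chr8", 301, "C", "G", "PASS", "IMPACT=MODERATE"),
    ("chr9", 101, "G", "T", "PASS", "IMPACT=LOW"),
    ("chr9", 201, "T", "C", "PASS", "IMPACT=MODERATE"),
]

# patient F3 (Black): includes a multi-allelic record (decomposes to two
# somatic variants) and a non-PASS record that must be dropped.
_F3_TUMOR = [
    ("chr10", 101, "A", "T", "PASS", "IMPACT=HIGH;GENE=BRAF"),
    ("chr10", 201, "C", "A", "PASS", "IMPACT=MODERATE"),
    ("chr10", 301, "G", "T", "PASS", "IMPACT=MODERATE;GENE=TP53"),
    ("chr11", 101, "T", "G", "PASS", "IMPACT=MODERATE"),
    ("chr12", 101, "A", "G", "PASS", "IMPACT=MODERATE"),
    ("chr12", 201, "C", "T", "PASS", "IMPACT=HIGH;GENE=EGFR"),
    ("chr12", 301, "G", "C", "PASS", "IMPACT=MODERATE"),
    ("chr13", 101, "A", "G,T", "PASS", "IMPACT=MODERATE"),
    ("chr13", 201, "T", "A", "q10", "IMPACT=HIGH;GENE=TP53"),
]
_F3_GERMLINE = [
    ("chr12", 101, "A", "G", "PASS", "IMPACT=MODERATE"),
    ("chr12", 201, "C", "T", "PASS", "IMPACT=HIGH;GENE=EGFR"),
    ("chr12", 301, "G", "C", "PASS", "IMPACT=MODERATE"),
]

_FIXTURE_FREQ = """CHROM\tPOS\tREF\tALT\tDB\tAF\tAC\tAN
chr5\t101\tA\tC\t1000G\t0.3\t\t
chr5\t201\tT\tG\t1000G\t0.004\t\t
chr5\t201\tT\tG\tExAC\t0.0005\t\t
chr7\t101\tA\tG\tExAC\t0.002\t\t
chr7\t201\tC\tT\t1000G\t0.0005\t\t
chr8\t101\tT\tA\tExAC\t0.009\t\t
chr8\t201\tA\tC\t1000G\t0.0008\t\t
chr8\t201\tA\tC\tExAC\t0.003\t\t
chr8\t301\tC\tG\tExAC\t\t1\t10000
chr9\t201\tT\tC\t1000G\t0.45\t\t
chr12\t201\tC\tT\t1000G\t0.02\t\t
chr12\t301\tG\tC\tExAC\t0.0003\t\t
"""

_FIXTURE_PANEL = ["TP53", "KRAS", "BRAF", "EGFR", "PIK3CA"]

#: counted mutations per patient: {patient: {region: (germline, db0, db0.001, db0.01)}}
FIXTURE_EXPECTED_COUNTS = {
    "F1": {"exome": (6, 7, 7, 8), "panel": (4, 4, 4, 5)},
    "F2": {"exome": (3, 4, 6, 9), "panel": (2, 2, 2, 4)},
    "F3": {"exome": (6, 7, 8, 8), "panel": (2, 2, 2, 2)},
}
FIXTURE_GROUPS = {"F1": "Black", "F2": "White", "F3": "Black"}


def _write_fixture_vcf(path: Path, sid: str, rows) -> None:
    lines = [_VCF_HEADER.format(sid=sid).rstrip("\n")]
    for chrom, pos, ref, alt, flt, info in rows:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{flt}\t{info}\tGT\t0/1")
    path.write_text("\n".join(lines) + "\n")


def make_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the 3-patient micro-cohort fixture; returns its file paths."""
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    for pid, tumor, germ in (("F1", _F1_TUMOR, _F1_GERMLINE),
                             ("F2", _F2_TUMOR, _F2_GERMLINE),
                             ("F3", _F3_TUMOR, _F3_GERMLINE)):
        _write_fixture_vcf(outdir / "vcf" / f"{pid}.tumor.vcf", pid, tumor)
        _write_fixture_vcf(outdir / "vcf" / f"{pid}.germline.vcf", pid, germ)
    freq = outdir / "frequency_table.tsv"
    freq.write_text(_FIXTURE_FREQ)
    panel = outdir / "panel_genes.txt"
    panel.write_text("\n".join(_FIXTURE_PANEL) + "\n")
    meta = outdir / "cohort_metadata.tsv"
    rows = ["patient_id\tgroup\ttumor_vcf\tgermline_vcf"]
    for pid in ("F1", "F2", "F3"):
        rows.append(f"{pid}\t{FIXTURE_GROUPS[pid]}\tvcf/{pid}.tumor.vcf"
                    f"\tvcf/{pid}.germline.vcf")
    meta.write_text("\n".join(rows) + "\n")
    return {"metadata": meta, "frequency_table": freq, "panel_genes": panel,
            "vcf_dir": outdir / "vcf"}


def fixture_run_config(fixture_dir: str | Path, out_dir: str | Path,
                       seed: int = 0) -> RunConfig:
    """RunConfig for the packaged fixture in vcf mode."""
    fixture_dir = Path(fixture_dir)
    return RunConfig(
        mode="vcf", out_dir=Path(out_dir), seed=seed,
        metadata_path=fixture_dir / "cohort_metadata.tsv",
        frequency_table_path=fixture_dir / "frequency_table.tsv",
        panel_genes_path=fixture_dir / "panel_genes.txt",
    )
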