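"""Replicate-level experiments on synthetic cohorts.

These are the study designs the analysis scripts and acceptance checks run:

* a *disparity* scenario — two groups of unequal size drawn from diverged
  populations, with the under-represented group carrying population-private
  variants and contributing few samples to the public database; and
* an *exchangeable* scenario — identical divergence, private-variant rate
  and database representation for both groups, under which every group
  contrast is null by construction.

Each replicate simulates a cohort, computes per-patient TMB under the four
canonical criteria, and summarizes group means, inflation relative to
paired-germline filtering, and the group x criterion interaction test.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_stats import interaction_anova, records_to_frame
from .synthetic_cohort import SimulationConfig, simulate_cohort_tmb
from .variant_core import RegionDefinition

GERMLINE_LABEL = "TMB_Germline"
DB_LABELS = ("TMB_DB0", "TMB_DB0.001", "TMB_DB0.01")


def disparity_scenario(
    seed: int,
    n_white: int = 160,
    n_black: int = 40,
    db_total: int = 6_000,
    db_frac_eur: float = 0.549,
    db_frac_afr: float = 0.086,
    fst: float = 0.1,
    private_rate_afr: float = 0.1,
    n_sites: int = 200_000,
) -> SimulationConfig:
    """Scaled-down analogue of the study cohort with database under-representation.

    Both groups share the somatic mutation rate; only germline divergence,
    population-private variation, and database composition differ.
    """
    return SimulationConfig(
        n_patients_by_group={"White": n_white, "Black": n_black},
        group_to_pop={"White": "EUR", "Black": "AFR"},
        n_sites=n_sites,
        fst_by_pop={"EUR": fst, "AFR": fst},
        private_rate_by_pop={"EUR": 0.0, "AFR": private_rate_afr},
        db_samples_by_pop={"EUR": round(db_total * db_frac_eur),
                           "AFR": round(db_total * db_frac_afr)},
        seed=seed,
    )


def exchangeable_scenario(
    seed: int,
    n_per_group: int = 100,
    db_samples_per_pop: int = 1_500,
    fst: float = 0.1,
    n_sites: int = 20_000,
) -> SimulationConfig:
    """Null scenario: groups identical in divergence, privacy and sampling."""
    return SimulationConfig(
        n_patients_by_group={"White": n_per_group, "Black": n_per_group},
        group_to_pop={"White": "EUR", "Black": "AFR"},
        n_sites=n_sites,
        fst_by_pop={"EUR": fst, "AFR": fst},
        private_rate_by_pop={"EUR": 0.0, "AFR": 0.0},
        db_samples_by_pop={"EUR": db_samples_per_pop,
                           "AFR": db_samples_per_pop},
        seed=seed,
    )


def group_mean_table(records_df: pd.DataFrame, region: str = "exome") -> pd.DataFrame:
    """Group x criterion mean TMB for one region."""
    sub = records_df[records_df["region"] == region]
    return sub.pivot_table(index="group", columns="criterion", values="tmb",
                           aggfunc="mean")


def inflation_table(records_df: pd.DataFrame,
                    region: str = "exome") -> pd.DataFrame:
    """Per-group mean inflation (database TMB minus paired-germline TMB)."""
    means = group_mean_table(records_df, region)
    out = means[list(DB_LABELS)].sub(means[GERMLINE_LABEL], axis=0)
    out.columns = [f"inflation_{c}" for c in DB_LABELS]
    return out


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Independent replicate seeds derived from one base seed (< 2**31)."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def run_replicates(
    config_for_seed: Callable[[int], SimulationConfig],
    n_replicates: int,
    base_seed: int,
    region: str = "exome",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Simulate replicates and summarize each: means, inflation, interaction.

    Returns one row per replicate with per-group germline means, per-group
    inflation under each database criterion, and the interaction F and p.
    """
    rows = []
    for rep, seed in enumerate(replicate_seeds(base_seed, n_replicates)):
        cfg = config_for_seed(seed)
        df = records_to_frame(simulate_cohort_tmb(cfg))
        sub = df[df["region"] == region]
        means = group_mean_table(sub, region)
        infl = inflation_table(sub, region)
        res = interaction_anova(sub)
        row = {"replicate": rep, "seed": seed,
               "interaction_f": res.f, "interaction_p": res.p,
               "reject": res.p < alpha}
        for grp in means.index:
            row[f"mean_germline_{grp}"] = means.loc[grp, GERMLINE_LABEL]
            for lab in DB_LABELS:
                row[f"mean_{lab}_{grp}"] = means.loc[grp, lab]
                row[f"inflation_{lab}_{grp}"] = infl.loc[grp,
                                                         f"inflation_{lab}"]
        rows.append(row)
    return pd.DataFrame(rows)


def db_size_sweep(
    base_seed: int,
    afr_db_samples: Sequence[int] = (64, 516, 3_294),
    n_replicates: int = 5,
    **scenario_kwargs,
) -> pd.DataFrame:
    """Inflation disparity as the under-represented group's database sample shrinks.

    For each database size for the AFR population (EUR fixed), runs
    replicates of the disparity scenario and reports the mean inflation gap
    (Black minus White) under the most lenient criterion.
    """
    rows = []
    for n_afr in afr_db_samples:
        def cfg(seed: int, n_afr=n_afr) -> SimulationConfig:
            base = disparity_scenario(seed, **scenario_kwargs)
            db = dict(base.db_samples_by_pop)
            db["AFR"] = int(n_afr)
            return replace(base, db_samples_by_pop=db)

        reps = run_replicates(cfg, n_replicates, base_seed + n_afr)
        gap = (reps["inflation_TMB_DB0.01_Black"]
               - reps["inflation_TMB_DB0.01_White"])
        rows.append({"afr_db_samples": n_afr,
                     "mean_inflation_gap": float(gap.mean()),
                     "sd_inflation_gap": float(gap.std(ddof=1))})
    return pd.DataFrame(rows)
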