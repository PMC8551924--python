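"""Seeded simulation studies over the full pipeline.

These drive the calibration questions the synthetic cohorts exist to answer:
does the BH-thresholded correlation screen control the false-discovery
proportion at q, does it recover planted effects, and does the MRF
permutation contrast select genes on a high-frequency gained arm?
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import association_screen as assoc
from . import pathway_network as pathway
from .drug_screen import HitCallConfig, build_cytotoxicity_matrix
from .genomic_profiling import core_panel, segment_probes_to_genes
from .synthetic_cohort import (
    CohortConfig,
    generate_cohort,
    planted_pairs_for_target_r,
    population_nonnull_pairs,
)

__all__ = ["fdp_experiment", "arm_selection_experiment"]


def _cohort_seed(seed: int, replicate: int) -> int:
    # keep derived seeds in int32 range
    return (int(seed) * 10_007 + replicate) % (2**31 - 1)


def screen_cohort(config: CohortConfig, seed: int,
                  screen_config: assoc.ScreenConfig = assoc.ScreenConfig()):
    """Generate one cohort and run it through profiling + screening.

    Returns (association table, truth).
    """
    cohort = generate_cohort(config, seed)
    profile = segment_probes_to_genes(cohort.probe_table, list(config.panel))
    cyto = build_cytotoxicity_matrix(cohort.plates, HitCallConfig())
    table = assoc.run_screen(profile, cyto, screen_config)
    return table, cohort.truth


def fdp_experiment(
    n_cohorts: int = 20,
    seed: int = 1,
    n_planted: int = 50,
    target_r: float = 0.95,
    q: float = 0.1,
) -> dict:
    """Empirical FDP/power of the BH screen on planted synthetic cohorts.

    Each replicate simulates a 13-sample cohort on the 131-gene core panel x
    418 drugs with ``n_planted`` gene-drug pairs whose slopes imply population
    |r| ~= target_r, runs the full probe->screen->BH pipeline at FDR q, and
    records the false-discovery proportion (0 when nothing is discovered) and
    the sensitivity against the planted truth.
    """
    base = CohortConfig(panel=tuple(core_panel()))
    screen_config = assoc.ScreenConfig(fdr_threshold=q)
    fdps, sens, n_disc = [], [], []
    for i in range(n_cohorts):
        rep_seed = _cohort_seed(seed, i)
        plant_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=rep_seed, spawn_key=(7,))
        )
        pairs = planted_pairs_for_target_r(base, n_planted, target_r, rng=plant_rng)
        config = replace(base, planted_pairs=pairs)
        table, truth = screen_cohort(config, rep_seed, screen_config)
        sig = table[table["significant"]]
        discovered = set(zip(sig["gene_id"], sig["drug_id"]))
        planted = truth.planted_set
        nonnull = population_nonnull_pairs(config)
        false = len(discovered - nonnull)
        fdps.append(false / len(discovered) if discovered else 0.0)
        sens.append(len(discovered & planted) / len(planted))
        n_disc.append(len(discovered))
    fdps = np.asarray(fdps)
    return {
        "n_cohorts": n_cohorts,
        "q": q,
        "mean_fdp": float(fdps.mean()),
        "se_fdp": float(fdps.std(ddof=1) / np.sqrt(n_cohorts)) if n_cohorts > 1 else 0.0,
        "fdps": [float(x) for x in fdps],
        "mean_sensitivity": float(np.mean(sens)),
        "mean_discoveries": float(np.mean(n_disc)),
    }


def arm_selection_experiment(
    n_replicates: int = 10,
    seed: int = 1,
    arm: str = "17q",
    n_permutations: int = 100,
    coupling_scale: float = 1.0,
) -> dict:
    """Selection probability of genes on a high-frequency gained arm.

    Each replicate simulates a cohort (default arm rates include the 17q gain
    at 0.69), scores genes with the MRF real-vs-permuted contrast on a
    synthetic FI network, and records the fraction of the arm's genes whose
    mean-difference falls outside +/-0.01.
    """
    panel = core_panel()
    config = CohortConfig(panel=tuple(panel))
    arm_genes = [g.gene_id for g in panel if g.arm_name == arm]
    if not arm_genes:
        raise ValueError(f"no panel genes on arm {arm}")
    fractions = []
    for i in range(n_replicates):
        rep_seed = _cohort_seed(seed, i)
        cohort = generate_cohort(config, rep_seed)
        profile = segment_probes_to_genes(cohort.probe_table, panel)
        fi = pathway.synthetic_fi_network(panel, seed=rep_seed)
        scores = pathway.impact_scores(
            fi, profile,
            pathway.PermutationConfig(n_permutations=n_permutations, seed=rep_seed),
            coupling_scale=coupling_scale,
        )
        present = [g for g in arm_genes if g in scores.index]
        sel = scores.loc[present, "selected"]
        fractions.append(float(sel.mean()))
    return {
        "arm": arm,
        "n_replicates": n_replicates,
        "fraction_selected": [float(f) for f in fractions],
        "mean_fraction_selected": float(np.mean(fractions)),
    }
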