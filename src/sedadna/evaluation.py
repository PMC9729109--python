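"""Calibration and validation experiments for the pipeline.

Self-contained, seeded experiments that measure how well each stage recovers
known truth from its own synthetic inputs: damage-parameter recovery and
false-positive rates, LCA agreement with a brute-force oracle, burial-age
calibration and endmember summaries, thermal-age scenarios, and end-to-end
cohort recall/leakage. Used by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .damage import MismatchMatrix, fit_damage
from .geochron import (
    BurialConfig,
    ThermalConfig,
    arrhenius_ratio,
    burial_age_pdf,
    combine_pdfs,
    summarize_max_age,
    thermal_age,
)
from .lca import decode_mismatches
from .pipeline import synthetic_cohort_metrics
from .simulate import (
    DamageParams,
    SimulationConfig,
    make_taxonomy_and_refs,
    make_temperature_history,
    simulate_geochron_inputs,
    simulate_reads,
)
from .taxonomy import Taxonomy, lca_of_set


# ---------------------------------------------------------------- damage

def _truth_counts(reads, truth, k_positions=15):
    m = MismatchMatrix(k_positions)
    for rec in truth.itertuples(index=False):
        m.add_read(1, reads[rec.read_id], decode_mismatches(rec.injected))
    return m.counts[1]


def damage_recovery_experiment(
    n_replicates: int = 100,
    n_reads: int = 5_000,
    seed: int = 0,
    a: float = 0.40,
    q: float = 0.30,
    c: float = 0.01,
) -> dict:
    """Repeatedly simulate damaged reads, tally and fit; report the median
    absolute D_max error against the injected A + c and the fraction of
    replicates passing the lambda_LR >= 1.5 authentication rule."""
    _, refs = make_taxonomy_and_refs(1, 1, 3000, seed=seed)
    errors, lr_pass = [], 0
    for rep in range(n_replicates):
        config = SimulationConfig(
            taxon_abundances={sp: 1.0 for sp in refs},
            damage=DamageParams(a=a, q=q, c=c),
            n_reads=n_reads,
            seed=seed + 1000 + rep,
        )
        reads, truth, _ = simulate_reads(refs, config)
        fit = fit_damage(_truth_counts(reads, truth))
        errors.append(abs(fit.d_max - (a + c)))
        lr_pass += fit.lambda_lr >= 1.5
    return {
        "median_dmax_abs_error": float(np.median(errors)),
        "lr_pass_rate": lr_pass / n_replicates,
        "n_replicates": n_replicates,
        "n_reads": n_reads,
    }


def null_damage_lr_rate(
    n_replicates: int = 60, n_reads: int = 2_000, seed: int = 0, c: float = 0.01
) -> dict:
    """False-authentication rate: fraction of undamaged (A = 0) replicates
    whose fitted lambda_LR still reaches 1.5."""
    out = damage_recovery_experiment(
        n_replicates=n_replicates, n_reads=n_reads, seed=seed, a=0.0, q=0.3, c=c
    )
    return {
        "false_lr_rate": out["lr_pass_rate"],
        "n_replicates": n_replicates,
        "n_reads": n_reads,
    }


# ---------------------------------------------------------------- LCA oracle

def _random_taxonomy(rng: np.random.Generator, n_nodes: int) -> Taxonomy:
    tax = Taxonomy()
    tax.add_node(0, 0, "no rank", "root")
    for i in range(1, n_nodes):
        tax.add_node(i, int(rng.integers(0, i)), "clade", f"n{i}")
    return tax


def _brute_force_lca(tax: Taxonomy, nodes: set[int]) -> int:
    """Independent oracle: intersect all root-paths, take the deepest."""
    common = set(tax.lineage(next(iter(nodes))))
    for n in nodes:
        common &= set(tax.lineage(n))
    return max(common, key=tax.depth)


def lca_oracle_agreement(n_instances: int = 1_000, seed: int = 0) -> dict:
    """Agreement of the pairwise-lifting LCA with root-path intersection on
    random rooted trees of up to 50 nodes."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        tax = _random_taxonomy(rng, int(rng.integers(2, 51)))
        nodes = set(rng.integers(0, len(tax), size=int(rng.integers(1, 6))).tolist())
        agree += lca_of_set(tax, nodes) == _brute_force_lca(tax, nodes)
    return {"agreement_rate": agree / n_instances, "n_instances": n_instances}


# ---------------------------------------------------------------- burial age

#: production-ratio endmembers bracketing the surface 26Al:10Be ratio
R0_ENDMEMBERS = (6.75, 7.42)
#: steady-erosion endmember for slowly eroding high-latitude bedrock (cm/Myr)
MAX_EROSION_CM_MYR = 500.0


def burial_endmember_summary(
    true_age_myr: float = 2.7,
    r0_true: float = 7.0,
    noise_cv: float = 0.05,
    n_samples: int = 3,
    seed: int = 0,
    n_draws: int = 50_000,
) -> dict:
    """Simulate a deeply shielded sample trio at a known burial age, then run
    the full endmember analysis: per-sample Monte-Carlo age PDFs, combined
    (product) PDFs for each production-ratio x erosion scenario, and the
    midpoint between the extreme +/-3 sigma limits across scenarios."""
    pairs, _ = simulate_geochron_inputs(
        true_age_myr, r0=r0_true, noise_cv=noise_cv, n_samples=n_samples, seed=seed
    )
    scenario_pdfs = []
    scenarios = []
    for r0 in R0_ENDMEMBERS:
        for erosion in (0.0, MAX_EROSION_CM_MYR):
            config = BurialConfig(r0=r0, erosion_rate_cm_myr=erosion)
            pdfs = [
                burial_age_pdf(
                    rec.n26, rec.n10, rec.n26_sigma, rec.n10_sigma,
                    config, n_draws=n_draws, seed=seed + 17 * i,
                )
                for i, rec in enumerate(pairs.itertuples(index=False))
            ]
            combined = combine_pdfs(pdfs)
            scenario_pdfs.append(combined)
            scenarios.append(
                {"r0": r0, "erosion_cm_myr": erosion, "median": combined.summary()["median"]}
            )
    summary = summarize_max_age(scenario_pdfs)
    return {
        "true_age_myr": true_age_myr,
        "midpoint_myr": summary["midpoint_myr"],
        "half_range_myr": summary["half_range_myr"],
        "scenarios": scenarios,
        "n_samples": n_samples,
    }


def burial_calibration_coverage(
    n_repetitions: int = 100,
    true_age_myr: float = 2.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    n_draws: int = 20_000,
) -> dict:
    """Fraction of seeded repetitions in which the combined PDF's central
    95% interval contains the simulated true age (trio of samples)."""
    config = BurialConfig(r0=6.75)
    covered = 0
    for rep in range(n_repetitions):
        pairs, _ = simulate_geochron_inputs(
            true_age_myr, r0=config.r0, noise_cv=noise_cv, n_samples=3,
            seed=seed + 31 * rep,
        )
        pdfs = [
            burial_age_pdf(
                rec.n26, rec.n10, rec.n26_sigma, rec.n10_sigma,
                config, n_draws=n_draws, seed=seed + 31 * rep + i,
            )
            for i, rec in enumerate(pairs.itertuples(index=False))
        ]
        combined = combine_pdfs(pdfs)
        lo, hi = combined.quantile(0.025), combined.quantile(0.975)
        covered += lo <= true_age_myr <= hi
    return {"coverage_rate": covered / n_repetitions, "n_repetitions": n_repetitions}


# ---------------------------------------------------------------- thermal age

def thermal_scenarios(age_yr: float = 2.0e6, mat_c: float = -17.0) -> dict:
    """Thermal-age scenarios for a polar deposit of the given age: constant
    present-day MAT, and a glacial-interglacial stepped history scaled to
    the same present-day MAT. Reports, per scenario, the thermal age at the
    10 C reference and the internal-consistency factor age / thermal_age
    (which equals the reciprocal time-averaged Arrhenius rate ratio)."""
    config = ThermalConfig()
    out = {}
    const = make_temperature_history(
        {"kind": "constant", "mat_c": mat_c, "duration_yr": age_yr}
    )
    tau_const = thermal_age(const, age_yr, config)
    out["constant"] = {
        "thermal_age_kyr": tau_const / 1e3,
        "age_over_thermal_age": age_yr / tau_const,
        "arrhenius_factor": 1.0 / arrhenius_ratio(273.15 + mat_c, config),
    }
    cycles = make_temperature_history(
        {
            "kind": "glacial_cycles",
            "present_mat_c": mat_c,
            "glacial_cooling_c": 10.0,
            "period_yr": 100_000.0,
            "glacial_fraction": 0.5,
            "duration_yr": age_yr,
        }
    )
    tau_cyc = thermal_age(cycles, age_yr, config)
    out["glacial_cycles"] = {
        "thermal_age_kyr": tau_cyc / 1e3,
        "age_over_thermal_age": age_yr / tau_cyc,
    }
    return out


# ---------------------------------------------------------------- end-to-end

def cohort_experiment(n_seeds: int = 20, seed: int = 0, **kwargs) -> dict:
    """Recall of truth genera and contaminant leakage across seeded cohorts."""
    recalls, leaks = [], []
    for i in range(n_seeds):
        m = synthetic_cohort_metrics(seed + 101 * i, **kwargs)
        recalls.append(m["recall"])
        leaks.append(m["leaked_contaminant_genera"])
    return {
        "mean_recall": float(np.mean(recalls)),
        "min_recall": float(np.min(recalls)),
        "total_leaked_genera": int(np.sum(leaks)),
        "n_seeds": n_seeds,
    }
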