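"""Synthetic-study evaluation suites.

These routines measure, on the generator's study conditions, the
operating characteristics the pipeline relies on: the sign behaviour of
the preservation Z_summary under module dissolution, planted-module
recovery, recovery of the phenotype-coupled causal module as the METM,
and the direction of the flexibility regressions under graded
dissolution.  They are used by the test suite and by the reproduction
script; all randomness is seed-derived.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .flexibility import flexibility_profiles, flexibility_regression
from .network import ModulePartition, build_network, detect_modules, module_eigengene
from .preservation import preservation_table, preservation_z
from .responders import module_trait_correlation, select_metm, stratify
from .simulate import SimulationConfig, simulate_study

__all__ = [
    "preservation_sign_rates",
    "module_recovery_aris",
    "metm_recovery",
    "flexibility_direction",
]


def _truth_partition(study) -> ModulePartition:
    assign = pd.Series(study.truth["assignment"])
    return ModulePartition(assignment=assign[assign != "background"])


def preservation_sign_rates(
    n_seeds: int = 10,
    seed0: int = 0,
    n_permutations: int = 100,
    power: float = 6.0,
) -> dict:
    """Z_summary sign behaviour: one fully dissolved module vs intact modules.

    Study conditions: 2000 genes, five planted modules (rho = 0.7), 41
    treated vs 21 control subjects; the first module is dissolved to zero
    within-module correlation in the treated arm at Day 30.  The truth
    partition is evaluated against the control Day-30 reference network.
    Returns per-seed Z values and the fraction of seeds with dissolved
    Z < 0 and with the largest intact module's Z > 2.
    """
    dissolved_z, intact_z = [], []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            dissolved_modules=(0,), dissolution_factor=0.0, deg_genes=0,
            seed=seed0 + k,
        )
        study = simulate_study(cfg)
        ref = build_network(study.samples_for("control", "Day30"), power, with_tom=False)
        test = build_network(study.samples_for("DHI", "Day30"), power, with_tom=False)
        res = preservation_table(
            preservation_z(ref, test, _truth_partition(study), n_permutations, seed=seed0 + k)
        ).set_index("module_label")
        dissolved_z.append(float(res.loc["M1", "z_summary"]))
        intact_z.append(float(res.loc["M2", "z_summary"]))
    dissolved_z = np.array(dissolved_z)
    intact_z = np.array(intact_z)
    return {
        "dissolved_z": dissolved_z.tolist(),
        "intact_z": intact_z.tolist(),
        "dissolved_negative_rate": float((dissolved_z < 0).mean()),
        "intact_above_2_rate": float((intact_z > 2).mean()),
    }


def module_recovery_aris(n_seeds: int = 10, seed0: int = 0, power: float = 6.0) -> list[float]:
    """Adjusted Rand index of detected vs planted modules, per seed.

    Detection runs at default settings on the treated baseline (Day 0)
    data of the default study (2000 genes, five modules, rho = 0.7).
    """
    aris = []
    for k in range(n_seeds):
        study = simulate_study(SimulationConfig(seed=seed0 + k))
        x = study.samples_for("DHI", "Day0")
        net = build_network(x, power)
        part = detect_modules(net.tom, expression=x)
        truth = [study.truth["assignment"][g] for g in x.gene_ids]
        pred = [part.assignment[g] for g in x.gene_ids]
        aris.append(float(adjusted_rand_score(truth, pred)))
    return aris


def metm_recovery(
    n_seeds: int = 10,
    seed0: int = 0,
    power: float = 6.0,
    min_stratum_n: int = 8,
    max_scan: int = 40,
) -> dict:
    """Does responder analysis recover the phenotype-coupled causal module?

    For each seed: simulate the default study with dissolution disabled
    (isolating the phenotype coupling), detect modules on the treated
    baseline, compute each module's eigengene change from Day 0 to Day 30
    per treated subject, correlate the changes with delta-AF inside the
    best-effect stratum (dAF >= 40), and run METM selection.  A seed
    counts as a win when the selected module is the detected module with
    the largest overlap with the planted causal module.  Seeds whose best
    stratum has fewer than ``min_stratum_n`` subjects are skipped (the
    within-stratum correlation test is underpowered below that size);
    scanning proceeds from ``seed0`` until ``n_seeds`` usable seeds.
    """
    wins, used_seeds = [], []
    seed = seed0
    while len(wins) < n_seeds and seed < seed0 + max_scan:
        cfg = SimulationConfig(dissolved_modules=(), deg_genes=0, seed=seed)
        seed += 1
        study = simulate_study(cfg)
        strata = stratify(study.metadata)
        best = next(s for s in strata if s.name == "best")
        if best.n < min_stratum_n:
            continue
        x0 = study.samples_for("DHI", "Day0")
        x30 = study.samples_for("DHI", "Day30")
        net0 = build_network(x0, power)
        part = detect_modules(net0.tom, expression=x0)
        if not part.module_labels:
            wins.append(False)
            used_seeds.append(seed - 1)
            continue
        changes = {}
        for lab in part.module_labels:
            genes = part.genes_in(lab)
            me0 = module_eigengene(x0, genes)
            me30 = module_eigengene(x30, genes)
            me0.index = [s.rsplit("_", 1)[0] for s in me0.index]
            me30.index = [s.rsplit("_", 1)[0] for s in me30.index]
            changes[lab] = (me30 - me0.loc[me30.index]).loc[best.subjects]
        daf = study.metadata.drop_duplicates("subject_id").set_index("subject_id")["delta_af"]
        corr = module_trait_correlation(pd.DataFrame(changes), daf)
        picked = select_metm(corr)
        causal_genes = {
            g for g, l in study.truth["assignment"].items()
            if l == study.truth["causal_module"]
        }
        causal_label = max(
            part.module_labels,
            key=lambda l: len(causal_genes & set(part.genes_in(l))),
        )
        wins.append(picked == causal_label)
        used_seeds.append(seed - 1)
    return {
        "wins": [bool(w) for w in wins],
        "recovery_rate": float(np.mean(wins)) if wins else float("nan"),
        "seeds": used_seeds,
    }


def flexibility_direction(n_seeds: int = 10, seed0: int = 0, power: float = 6.0) -> dict:
    """Direction of the flexibility regressions under graded dissolution.

    Six cohorts of 10 treated subjects instantiate a 39-gene module whose
    within-module correlation is dissolved progressively as the cohort's
    response decreases (dAF 50 -> 0 as dissolution 1.0 -> 0.0).  A win is
    a negative OLS slope of the topological distance D on delta-AF
    together with a positive slope of the instantiated edge count.
    """
    factors = (1.0, 0.8, 0.6, 0.4, 0.2, 0.0)
    dafs = (50.0, 40.0, 30.0, 20.0, 10.0, 0.0)
    wins, d_slopes, e_slopes = [], [], []
    for k in range(n_seeds):
        nets, means = {}, {}
        genes = None
        for i, (factor, daf) in enumerate(zip(factors, dafs)):
            cfg = SimulationConfig(
                n_genes=60, module_sizes=(39,), n_treated=10, n_control=2,
                dissolved_modules=(0,), dissolution_factor=factor, deg_genes=0,
                seed=(seed0 + k) * 100 + i,
            )
            study = simulate_study(cfg)
            if genes is None:
                genes = [g for g, l in study.truth["assignment"].items() if l == "M1"]
            x = study.samples_for("DHI", "Day30").subset_genes(genes)
            nets[f"bin{i + 1}"] = build_network(x, power, with_tom=False)
            means[f"bin{i + 1}"] = daf
        profiles = flexibility_profiles(genes, nets, means, reference="bin1")
        fit_d, fit_e = flexibility_regression(profiles)
        d_slopes.append(fit_d.slope)
        e_slopes.append(fit_e.slope)
        wins.append(fit_d.slope < 0 and fit_e.slope > 0)
    return {
        "wins": [bool(w) for w in wins],
        "direction_rate": float(np.mean(wins)),
        "d_slopes": d_slopes,
        "edge_slopes": e_slopes,
    }
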