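"""Reference evaluations of the pipeline under its stated study conditions.

Each function simulates data with the synthetic cohort generator at the
documented condition (mixture fractions, read depths, group sizes, effect
sizes), runs the corresponding analysis stage, and returns summary metrics.
They are deterministic given their seed and sized to run on a single CPU in
minutes; the methods note records the problem sizes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from . import ecology
from .ddpcr import DropletCounts, quantify
from .hostfrac import TaxProfile, subsample_nonhuman
from .markers import MarkerPanel
from .methylprofile import aggregate_sample
from .models import (
    ClassifierSpec,
    build_features,
    fit_calprotectin_lmm,
    train_cv_classifier,
)
from .synthio import (
    CohortConfig,
    MixtureSpec,
    PlantedEffect,
    generate_marker_panel,
    simulate_bisulfite_reads,
    simulate_cohort,
    simulate_ddpcr,
)

__all__ = [
    "deconvolution_recovery",
    "ddpcr_benchmark",
    "qc_boundaries",
    "species_classifier_benchmark",
    "ordination_richness_correlation",
    "lmm_benchmark",
    "classifier_parity",
    "subsample_control",
]


def deconvolution_recovery(
    n_replicates: int = 50,
    reads_per_marker: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Recover a (0.5, 0.3, 0.2) three-cell-type mixture from reads.

    Reads are simulated at conversion 0.99 and substitution error 0.001; a
    replicate passes when every recovered fraction is within +/-0.03 of
    truth.
    """
    truth = {"neutrophil": 0.5, "colon": 0.3, "T_cell": 0.2}
    panel = generate_marker_panel(
        3, 1, 150, 5, seed=seed, cell_type_names=list(truth)
    )
    mix = MixtureSpec(truth, 5.0)
    rng = np.random.default_rng(seed)
    ok = 0
    max_errs = []
    for _ in range(n_replicates):
        reads = simulate_bisulfite_reads(
            panel, mix, reads_per_marker, 0.99, 0.001, seed=int(rng.integers(2**31))
        )
        prof = aggregate_sample(reads, panel)
        errs = [
            abs(prof.per_cell_type_fraction[ct] / 100.0 - f)
            for ct, f in truth.items()
        ]
        max_errs.append(max(errs))
        ok += max(errs) <= 0.03
    return {
        "recovery_rate": ok / n_replicates,
        "median_max_abs_error": float(np.median(max_errs)),
        "n_replicates": n_replicates,
    }


def ddpcr_benchmark(n_reactions: int = 100, seed: int = 0) -> dict[str, float]:
    """Closed-form equivalence and simulation round trip.

    The closed-form check compares quantify() against an independently
    coded Poisson correction on fixed droplet counts; the round trip
    simulates reactions at 20,000 droplets with 100-10,000 true copies.
    """
    max_diff = 0.0
    for total, neg in ((20_000, 10_000), (20_000, 19_999), (15_000, 3_000), (10_000, 9_999)):
        q = quantify(DropletCounts(total, total - neg, neg))
        lam = -math.log(neg / total)
        oracle_copies = lam * total
        max_diff = max(max_diff, abs(q.copies - oracle_copies))
        max_diff = max(max_diff, abs(q.mass_pg - oracle_copies * 3.3))
    rng = np.random.default_rng(seed)
    rel_err, within = [], []
    for _ in range(n_reactions):
        true = float(rng.uniform(100, 10_000))
        d = simulate_ddpcr(true, 20_000, seed=int(rng.integers(2**31)))
        q = quantify(d)
        rel_err.append(abs(q.copies - true) / true)
        lam = true / 20_000
        se = math.sqrt(20_000 * (math.exp(lam) - 1))
        within.append(abs(q.copies - true) <= 3 * se)
    return {
        "closed_form_max_abs_diff": max_diff,
        "roundtrip_median_rel_err_pct": float(np.median(rel_err) * 100),
        "roundtrip_within_3se_fraction": float(np.mean(within)),
        "n_reactions": n_reactions,
    }


def qc_boundaries(seed: int = 0) -> dict[str, float]:
    """Exercise each printed QC threshold exactly at its boundary.

    Returns 1.0 per rule when the boundary behaves as printed.
    """
    from .inflammetrics import cap_calprotectin
    from .methylprofile import match_read

    panel = generate_marker_panel(1, 1, 150, 5, seed=seed)
    marker = panel.markers[0]
    # fully converted (methylated) read, then mutate non-C positions to
    # control similarity exactly: 150 positions, 30 mismatches = 80.0%
    base = list(marker.sequence)
    protected = set()
    for o in marker.cpg_offsets:
        protected.update((o, o + 1))
    for i, b in enumerate(base):
        if b == "C" and i not in marker.cpg_offsets:
            base[i] = "T"
    mutable = [
        i for i, b in enumerate(base)
        if i not in protected and marker.sequence[i] != "C"
    ]
    flip = {"A": "G", "G": "A", "T": "A", "C": "A"}

    def with_mismatches(k):
        read = list(base)
        for i in mutable[:k]:
            read[i] = flip[read[i]]
        return "".join(read)

    at_80 = match_read(with_mismatches(30), panel)  # 120/150 = 80%
    below_80 = match_read(with_mismatches(31), panel)  # 119/150 = 79.33%
    similarity_ok = float(at_80 is not None and below_80 is None)

    # fraction-sum window first: all-unmethylated reads give a 100% fraction
    # (inside 5-150%); an all-methylated sample gives 0% (< 5%, fail)
    unmeth = list(base)
    for o in marker.cpg_offsets:
        unmeth[o] = "T"
    # read-count boundary uses unmethylated reads so only the count can fail
    p999 = aggregate_sample(["".join(unmeth)] * 999, panel)
    p1000 = aggregate_sample(["".join(unmeth)] * 1000, panel)
    min_reads_ok = float(
        (not p999.qc_pass and p999.qc_reason == "low_reads") and p1000.qc_pass
    )

    p_sum_low = aggregate_sample(["".join(base)] * 1000, panel)
    p_sum_ok = aggregate_sample(["".join(unmeth)] * 1000, panel)
    sum_window_ok = float(
        (not p_sum_low.qc_pass and p_sum_low.qc_reason == "fraction_sum")
        and p_sum_ok.qc_pass
    )

    cap_ok = float(
        cap_calprotectin(2100.0) == (2100.0, False)
        and cap_calprotectin(2100.01) == (2100.0, True)
        and cap_calprotectin(3500.0) == (2100.0, True)
    )
    return {
        "similarity_80_boundary_ok": similarity_ok,
        "min_reads_1000_boundary_ok": min_reads_ok,
        "fraction_sum_window_ok": sum_window_ok,
        "calprotectin_cap_2100_ok": cap_ok,
    }


def species_classifier_benchmark(
    n_null_species: int = 1000,
    n_seeds: int = 20,
    n_per_group: int = 50,
    fold: float = 20.0,
    seed: int = 0,
) -> dict[str, float]:
    """Exact small-sample p, null FDR calibration, planted-effect recovery."""
    p_exact = float(
        stats.mannwhitneyu(
            [4, 5, 6], [1, 2, 3], alternative="greater", method="exact"
        ).pvalue
    )

    rng = np.random.default_rng(seed)
    n = 20
    blocks = [rng.lognormal(0, 1, size=(3 * n, n_null_species))]
    m = pd.DataFrame(blocks[0].T, columns=[f"s{i}" for i in range(3 * n)])
    groups = pd.Series(
        ["Control"] * n + ["CD"] * n + ["UC"] * n, index=m.columns
    )
    out = ecology.classify_species(m, groups)
    null_frac = float((out["category"] != "UNCHANGED").mean())

    correct = 0
    for s in range(n_seeds):
        r = np.random.default_rng(seed * 1000 + s)
        base = r.lognormal(0, 0.5, size=(n_per_group, 60))
        cd = r.lognormal(0, 0.5, size=(n_per_group, 60))
        uc = r.lognormal(0, 0.5, size=(n_per_group, 60))
        cd[:, 0] /= fold
        uc[:, 0] /= fold  # IBD_LOST
        cd[:, 1] *= fold  # CD_EXPANDED
        data = np.vstack([base, cd, uc]).T
        mm = pd.DataFrame(data, columns=[f"s{i}" for i in range(3 * n_per_group)],
                          index=[f"sp{i}" for i in range(60)])
        gg = pd.Series(
            ["Control"] * n_per_group + ["CD"] * n_per_group + ["UC"] * n_per_group,
            index=mm.columns,
        )
        res = ecology.classify_species(mm, gg)
        correct += (
            res.loc["sp0", "category"] == "IBD_LOST"
            and res.loc["sp1", "category"] == "CD_EXPANDED"
        )
    return {
        "exact_mw_p_123_vs_456": p_exact,
        "null_categorized_fraction": null_frac,
        "planted_recovery_rate": correct / n_seeds,
        "n_null_species": n_null_species,
        "n_seeds": n_seeds,
    }


def ordination_richness_correlation(seed: int = 0) -> dict[str, float]:
    """Spearman correlation between |PC1| and species count on a cohort
    with the default Control/CD/UC richness gradient."""
    cfg = CohortConfig(
        n_per_group={"Control": 30, "CD": 30, "UC": 30},
        n_species_pool=400,
        reads_per_marker=0,
        seed=seed,
    )
    cohort = simulate_cohort(cfg)
    res = ecology.rclr_pcoa(cohort.species_pct, n_components=2)
    counts = (cohort.species_pct > 0).sum(axis=0).reindex(res.coordinates.index)
    pc1 = res.coordinates["PC1"]
    rho_signed, _ = ecology.spearman(pc1, counts)
    # the PC sign convention is arbitrary, so the association strength is
    # the magnitude of the correlation with (signed) PC1
    return {
        "spearman_pc1_species_count_magnitude": abs(float(rho_signed)),
        "spearman_signed_pc1_species_count": float(rho_signed),
        "n_samples": int(len(counts)),
    }


def lmm_benchmark(n_replicates: int = 100, seed: int = 0) -> dict[str, float]:
    """Coverage of the planted treatment coefficient and the noiseless fit.

    Each replicate: 400 samples over 100 subjects (4 repeated measures),
    calprotectin generated with treatment coefficient -159.04.
    """

    def one(s, noise):
        cfg = CohortConfig(
            n_per_group={"Control": 34, "CD": 33, "UC": 33},
            samples_per_subject=4,
            n_species_pool=20,
            reads_per_marker=0,
            seed=s,
            calprotectin_model={
                "intercept": 1200.0, "human_pct": 40.0, "active": 250.0,
                "treatment_advancement": -159.04, "age": -1.5,
                "subject_sd": 100.0, "noise_sd": noise,
            },
        )
        c = simulate_cohort(cfg)
        cl = c.clinical.copy()
        cl["human_pct"] = cl["sample_id"].map(
            {k: v["human_pct"] for k, v in c.truth["samples"].items()}
        )
        return fit_calprotectin_lmm(cl)

    rng = np.random.default_rng(seed)
    covered = 0
    betas = []
    for _ in range(n_replicates):
        res = one(int(rng.integers(2**31)), 120.0)
        lo, hi = res.ci("treatment_advancement")
        covered += lo <= -159.04 <= hi
        betas.append(res.coef("treatment_advancement"))
    noiseless = one(int(rng.integers(2**31)), 0.0)
    return {
        "treatment_beta_mean": float(np.mean(betas)),
        "ci_coverage": covered / n_replicates,
        "noiseless_r2_conditional": float(noiseless.r2_conditional),
        "n_replicates": n_replicates,
    }


def classifier_parity(seed: int = 0, nrounds: int = 200) -> dict[str, float]:
    """Presence-absence vs relative-abundance AUC on presence-driven signal,
    plus the null-label AUC at n = 400."""
    cfg = CohortConfig(
        n_per_group={"Control": 30, "CD": 30, "UC": 30},
        n_species_pool=200,
        reads_per_marker=0,
        seed=seed,
        species_seed=seed + 1,
    )
    c = simulate_cohort(cfg)
    groups = c.clinical.set_index("sample_id")["group"]
    y = (groups != "Control").astype(int)
    rc = c.read_counts.set_index("sample_id")
    hp = 100 * rc["human_reads"] / rc["total_reads"]
    aucs = {}
    for rep in ("presence_absence", "relative_abundance"):
        X = build_features(
            c.species_pct, rep,
            ("species", "species_count", "human_reads_pct"), human_reads_pct=hp,
        )
        aucs[rep] = train_cv_classifier(
            X, y.loc[X.index], ClassifierSpec(seed=seed, nrounds=nrounds)
        ).auc

    rng = np.random.default_rng(seed)
    n = 400
    Xn = pd.DataFrame(
        rng.normal(size=(n, 100)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"f{i}" for i in range(100)],
    )
    yn = pd.Series(rng.integers(0, 2, n), index=Xn.index)
    auc_null = train_cv_classifier(
        Xn, yn, ClassifierSpec(seed=seed, nrounds=nrounds)
    ).auc
    return {
        "auc_presence_absence": aucs["presence_absence"],
        "auc_relative_abundance": aucs["relative_abundance"],
        "auc_parity_gap": abs(aucs["presence_absence"] - aucs["relative_abundance"]),
        "auc_null_labels": auc_null,
    }


def subsample_control(seed: int = 0, depth: int = 1_000_000) -> dict[str, float]:
    """Depth-subsampling control: richness is monotone and the Control-vs-IBD
    gap keeps its sign at the fixed non-human depth."""
    cfg = CohortConfig(
        n_per_group={"Control": 25, "CD": 25, "UC": 25},
        n_species_pool=400,
        reads_per_marker=0,
        seed=seed,
    )
    c = simulate_cohort(cfg)
    prof = TaxProfile(matrix=c.species_pct, read_counts=c.read_counts)
    sub, rep = subsample_nonhuman(prof, depth=depth, seed=seed)
    before = (prof.matrix > 0).sum(axis=0)
    after = (sub.matrix > 0).sum(axis=0)
    monotone = float((after <= before[after.index]).mean())
    groups = c.clinical.set_index("sample_id")["group"]

    def gap(counts):
        g = groups.reindex(counts.index)
        return float(counts[g == "Control"].median() - counts[g != "Control"].median())

    return {
        "monotone_fraction": monotone,
        "richness_gap_before": gap(before),
        "richness_gap_after": gap(after),
        "gap_sign_retained": float(gap(before) > 0 and gap(after) > 0),
        "n_dropped": len(rep.dropped_samples),
    }
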