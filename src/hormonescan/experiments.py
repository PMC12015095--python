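"""Validation experiments: parameter recovery, calibration, and power.

These routines run the full generative model → pipeline → inference loop
at pre-registered settings and summarize how well the statistics recover
the truth.  They back both the test suite and ``scripts/acceptance.py``.
All randomness derives from the ``seed`` argument; replicate seeds are
drawn from a ``numpy`` SeedSequence spawned from it.
"""

from __future__ import annotations

import dataclasses
import logging
from contextlib import contextmanager
from typing import Sequence

import numpy as np
import pandas as pd

from .gene_scan import direction_summary, fit_gene, select_testable
from .models import model_ssd
from .phylo import tip_labels
from .simulate import SimulationConfig, simulate_species_dataset
from .traits import add_ssd_columns, build_species_table


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@contextmanager
def _quiet_joins():
    """Mute the per-replicate join/drop log chatter inside batch loops."""
    lg = logging.getLogger("hormonescan.traits")
    old = lg.level
    lg.setLevel(logging.ERROR)
    try:
        yield
    finally:
        lg.setLevel(old)


def _one_fit(config: SimulationConfig):
    """Simulate one dataset under ``config`` and fit the species-level model."""
    ds = simulate_species_dataset(config)
    with _quiet_joins():
        table = build_species_table(ds.traits, ds.counts, tip_labels(ds.tree))
    fit = model_ssd(table, ds.tree, hre_class="ARE", lam="ML",
                    min_n=min(20, len(table)))
    return fit, ds


def recovery_grid(
    seed: int,
    lams: Sequence[float] = (0.0, 0.5, 1.0),
    ns: Sequence[int] = (64, 256),
    n_reps: int = 50,
    beta_are: float = 0.5,
    beta_body: float = 0.3,
) -> pd.DataFrame:
    """Mean coefficient estimates and median lambda across the grid.

    One row per (lambda, n) cell with the Monte-Carlo summaries of the
    ML fits across ``n_reps`` independently simulated trees and datasets.
    """
    rows = []
    cell_seeds = _child_seeds(seed, len(lams) * len(ns))
    i = 0
    for lam in lams:
        for n in ns:
            rep_seeds = _child_seeds(cell_seeds[i], n_reps)
            i += 1
            b_are, b_body, lam_hat = [], [], []
            for s in rep_seeds:
                cfg = SimulationConfig(seed=s, n_species=n, lam=lam,
                                       beta_are=beta_are, beta_body=beta_body)
                fit, _ = _one_fit(cfg)
                b_are.append(fit.params["ln_are"])
                b_body.append(fit.params["ln_body"])
                lam_hat.append(fit.lam)
            rows.append(
                {
                    "lambda_true": lam, "n_species": n, "n_reps": n_reps,
                    "beta_are_true": beta_are, "beta_body_true": beta_body,
                    "beta_are_mean": float(np.mean(b_are)),
                    "beta_body_mean": float(np.mean(b_body)),
                    "lambda_median": float(np.median(lam_hat)),
                }
            )
    return pd.DataFrame(rows)


def null_calibration(
    seed: int, n: int = 128, n_reps: int = 500, alpha: float = 0.05
) -> float:
    """Type-I error of the ARE-effect test when beta_are = 0."""
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        cfg = SimulationConfig(seed=s, n_species=n, beta_are=0.0)
        fit, _ = _one_fit(cfg)
        if fit.pvalues["ln_are"] < alpha:
            rejections += 1
    return rejections / n_reps


def burst_power(
    seed: int,
    n_reps: int = 50,
    n: int = 64,
    burst_fraction: float = 0.33,
    burst_multiplier: float = 4.0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """The clade-burst scenario: one clade with a multiplied ARE rate.

    Returns the fraction of replicates with a positive, significant ARE
    effect under the standing effect size, the same fraction under
    beta_are = 0 (which should stay at the nominal level), and the mean
    ratio of burst-clade to outgroup ARE counts.
    """
    out = {"positive_significant_rate": 0.0, "null_rejection_rate": 0.0}
    ratios = []
    seeds = _child_seeds(seed, 2 * n_reps)
    for k, beta_key in ((0, "positive_significant_rate"), (1, "null_rejection_rate")):
        hitcount = 0
        for s in seeds[k * n_reps : (k + 1) * n_reps]:
            cfg = SimulationConfig(
                seed=s, n_species=n,
                burst_fraction=burst_fraction, burst_multiplier=burst_multiplier,
            )
            if k == 1:
                cfg = dataclasses.replace(cfg, beta_are=0.0)
            fit, ds = _one_fit(cfg)
            sig = fit.pvalues["ln_are"] < alpha
            if k == 0:
                if sig and fit.params["ln_are"] > 0:
                    hitcount += 1
                totals = ds.counts.set_index("species")["are_count"]
                burst = [sp for sp in totals.index if sp in set(ds.burst_clade)]
                rest = [sp for sp in totals.index if sp not in set(ds.burst_clade)]
                ratios.append(totals[burst].mean() / totals[rest].mean())
            elif sig:
                hitcount += 1
        out[beta_key] = hitcount / n_reps
    out["burst_count_ratio_mean"] = float(np.mean(ratios))
    return out


def gene_direction_experiment(
    seed: int,
    n_species: int = 24,
    n_genes: int = 40,
    min_species: int = 10,
) -> dict[str, float]:
    """Direction summary under a planted positive effect and under the null.

    In the planted run per-gene counts share the species-level Brownian
    rates, so every gene's count co-varies with SSD and the positive
    proportion should exceed the binomial 95% band around 0.5.  The null
    run draws an independent rate history per gene (counts independent of
    SSD and across genes), for which the proportion should sit inside the
    band.
    """
    out: dict[str, float] = {}
    seeds = _child_seeds(seed, 2)
    for label, beta in (("planted", SimulationConfig.beta_are), ("null", 0.0)):
        cfg = SimulationConfig(
            seed=seeds[0 if label == "planted" else 1],
            n_species=n_species, n_genes=n_genes, beta_are=beta,
            gene_rate_mode="shared" if label == "planted" else "independent",
        )
        ds = simulate_species_dataset(cfg)
        traits = add_ssd_columns(ds.traits)
        long = ds.per_gene_counts.rename(columns={"ARE": "count"})[
            ["gene_id", "species", "count"]
        ]
        eligible = select_testable(long, min_species=min_species)
        records = [
            fit_gene(g, long, traits, ds.tree, hre_class="ARE",
                     flank=cfg.plant_flank)
            for g in eligible
        ]
        summary = direction_summary(records)
        out[f"{label}_prop_positive"] = float(summary["prop_positive"].iloc[0])
        out[f"{label}_n_genes"] = int(summary["n_genes"].iloc[0])
    half_width = 1.96 * 0.5 / np.sqrt(out["planted_n_genes"])
    out["null_band_half_width"] = float(half_width)
    return out


def pgls_vs_ols(seed: int, n_datasets: int = 20, n: int = 40) -> float:
    """Max |PGLS - OLS| coefficient deviation where they must coincide.

    Covers lambda fixed at 0 on Yule trees and ML lambda on star trees;
    the OLS reference is solved by direct normal equations.
    """
    from .models import PhyloGLS
    from .simulate import sim_tree
    from .phylo import phylo_vcv

    worst = 0.0
    for s in _child_seeds(seed, n_datasets):
        rng = np.random.default_rng(s)
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        design = np.column_stack([np.ones(n), X])
        beta_ols = np.linalg.solve(design.T @ design, design.T @ y)

        tree = sim_tree(n, seed=s)
        C, _ = phylo_vcv(tree)
        fit0 = PhyloGLS(lam=0.0).fit(X, y, C=C)
        worst = max(worst, float(np.max(np.abs(fit0.params_.to_numpy() - beta_ols))))

        star = np.eye(n)  # star phylogeny: equal depths, no shared history
        fit_star = PhyloGLS(lam="ML").fit(X, y, C=star)
        worst = max(worst, float(np.max(np.abs(fit_star.params_.to_numpy() - beta_ols))))
    return worst
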