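"""End-to-end orchestration: cohort -> fits -> population model -> seed maps
-> virtual resections -> summary report.

The pipeline runs on a synthetic cohort with known ground truth and writes
tidy tables for every stage.  A single master seed fans out into per-stage,
per-patient substreams so that any stage rerun with the same configuration
is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from .fitting import FitMap, ParameterGrid, fit_patient, per_patient_c_at, population_fit
from .network import threshold_network
from .resection import (resection_covariate_scan, stepwise_regression,
                        log_delta_r, virtual_resection_effect, COVARIATE_COLUMNS)
from .seeds import recursive_seed_optimization, seed_likelihood_map
from .sir import SpreadParams
from .stats import group_compare, roc_auc
from .synth import TrueParams, make_cohort


@dataclass
class RunConfig:
    out_dir: str = "epispread_run"
    rng_seed: int = 0
    # cohort
    n_sf: int = 11
    n_nsf: int = 4
    n_rois: int = 246
    true_beta: float = 1e-3
    true_gamma: float = 1e-3
    true_kappa_frac: float = 0.10
    # dynamics / fitting
    n_realizations: int = 10_000
    scan_realizations: int = 1000
    n_fit_iterations: int = 10
    T: int = 1000
    beta_grid: tuple = None
    gamma_grid: tuple = None
    kappa_frac_grid: tuple = None
    max_seed_size: int = 5
    n_random_seeds: int = 20
    # stage toggles
    run_fit: bool = True
    run_population: bool = True
    run_seed_maps: bool = True
    run_resection: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def grid(self) -> ParameterGrid:
        kw = {}
        if self.beta_grid:
            kw["beta"] = tuple(self.beta_grid)
        if self.gamma_grid:
            kw["gamma"] = tuple(self.gamma_grid)
        if self.kappa_frac_grid:
            kw["kappa_frac"] = tuple(self.kappa_frac_grid)
        return ParameterGrid(**kw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} rng_seed={cfg.rng_seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.rng_seed)

    def sub() -> int:
        return int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))

    report: dict = {"config_hash": cfg.config_hash(), "rng_seed": cfg.rng_seed}

    tp = TrueParams(beta=cfg.true_beta, gamma=cfg.true_gamma,
                    kappa_frac=cfg.true_kappa_frac)
    cohort = make_cohort(n_sf=cfg.n_sf, n_nsf=cfg.n_nsf, true_params=tp,
                         n_rois=cfg.n_rois, rng_seed=sub())
    manifest = [p.manifest() for p in cohort]
    (out / "cohort_manifest.json").write_text(json.dumps(manifest, indent=1))
    labels = np.array([p.outcome_label == "SF" for p in cohort])

    fitmaps: List[FitMap] = []
    best_params: List[dict] = []
    if cfg.run_fit:
        grid = cfg.grid()
        for k, pat in enumerate(cohort):
            fm = fit_patient(pat.network.weights, pat.ra, pat.seeg_pattern,
                             grid=grid, n_realizations=cfg.n_realizations,
                             n_fit_iterations=cfg.n_fit_iterations,
                             T=cfg.T, rng_seed=sub())
            fitmaps.append(fm)
            best_params.append(fm.best_params)
            _write(fm.table, out / f"fitmap_patient{k:02d}.tsv", cfg)
        c_best = np.array([bp["C"] for bp in best_params])
        cmp_fit = group_compare(c_best[labels], c_best[~labels], paired=False)
        roc_fit = roc_auc(c_best, labels)
        report["individual_fit"] = {
            "C_mean": float(c_best.mean()),
            "C_sf_minus_nsf": cmp_fit.mean_diff,
            "t": cmp_fit.t, "dof": cmp_fit.dof, "p": cmp_fit.p,
            "auc": roc_fit.auc,
            "best_params": best_params,
        }

    if cfg.run_population and fitmaps:
        pop = population_fit(fitmaps)
        _write(pop.table, out / "fitmap_population.tsv", cfg)
        bp = pop.best_params
        c_at = per_patient_c_at(fitmaps, bp["beta"], bp["gamma"], bp["kappa_frac"])
        cmp_pop = group_compare(c_at[labels], c_at[~labels], paired=False)
        roc_pop = roc_auc(c_at, labels)
        report["population_fit"] = {
            "best_params": bp,
            "C_sf_minus_nsf": cmp_pop.mean_diff,
            "t": cmp_pop.t, "dof": cmp_pop.dof, "p": cmp_pop.p,
            "auc": roc_pop.auc,
        }

    seed_maps = []
    if cfg.run_seed_maps and best_params:
        c_ra_members, c_non_ra = [], []
        for k, (pat, bp) in enumerate(zip(cohort, best_params)):
            thr = threshold_network(pat.network.weights, bp["kappa_frac"])
            smap = seed_likelihood_map(
                thr, pat.seeg_pattern, bp["beta"], bp["gamma"], pat.ra,
                T=cfg.T, n_realizations=cfg.scan_realizations, rng_seed=sub())
            seed_maps.append(smap)
            _write(smap.table, out / f"seedmap_patient{k:02d}.tsv", cfg)
            t = smap.table[~smap.table["excluded"]]
            c_ra_members.append(float(t[t["in_RA"]]["C_R"].mean()))
            c_non_ra.append(float(t[~t["in_RA"]]["C_R"].mean()))
        cmp_ra = group_compare(c_ra_members, c_non_ra, paired=True)
        report["seed_likelihood"] = {
            "C_RA_minus_NRA": cmp_ra.mean_diff,
            "t": cmp_ra.t, "dof": cmp_ra.dof, "p": cmp_ra.p,
        }

    if cfg.run_resection and best_params:
        rows = []
        for k, (pat, bp) in enumerate(zip(cohort, best_params)):
            thr = threshold_network(pat.network.weights, bp["kappa_frac"])
            nested = recursive_seed_optimization(
                thr, pat.seeg_pattern, bp["beta"], bp["gamma"], pat.ra,
                max_size=cfg.max_seed_size, T=cfg.T,
                n_realizations=cfg.scan_realizations,
                scan_realizations=max(cfg.scan_realizations // 2, 100),
                rng_seed=sub())
            from .network import out_connectivity
            from .sir import rescale_beta_for_seed
            e_ra = out_connectivity(thr, pat.ra)
            for seed in nested.seeds:
                e_seed = out_connectivity(thr, seed)
                beta_s = rescale_beta_for_seed(bp["beta"], e_ra, e_seed)
                params = SpreadParams(beta=beta_s, gamma=bp["gamma"], T=cfg.T,
                                      n_realizations=cfg.scan_realizations,
                                      rng_seed=sub())
                oc = virtual_resection_effect(thr, pat.ra, seed, params,
                                              kappa=thr.mean_degree)
                row = oc.row()
                row.update(patient=k, seed_size=len(seed),
                           outcome=pat.outcome_label)
                rows.append(row)
        outcomes = pd.DataFrame(rows)
        _write(outcomes, out / "resection_outcomes.tsv", cfg)
        scan = resection_covariate_scan(outcomes)
        _write(scan, out / "resection_covariate_scan.tsv", cfg)
        y = log_delta_r(outcomes["delta_R"].to_numpy())
        X = outcomes[[c for c in COVARIATE_COLUMNS if c in outcomes.columns]]
        X = X.loc[:, X.notna().all() & np.isfinite(X).all()]
        sw = stepwise_regression(y, X)
        report["resection"] = {
            "delta_r_by_size": {
                int(s): float(g["delta_R"].mean())
                for s, g in outcomes.groupby("seed_size")},
            "auc_by_size": {
                int(s): roc_auc(g["delta_R"],
                                g["outcome"] == "SF").auc
                for s, g in outcomes.groupby("seed_size")},
            "stepwise_selected": sw.selected,
            "stepwise_r2": sw.r2,
            "stepwise_r2_adj": sw.r2_adj,
        }

    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
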