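"""Virtual populations and synthetic-data generators.

Virtual subjects are drawn with demographics uniform within the study
ranges, CYP2C9 genotypes multinomial from ethnicity-specific frequency
tables, and log-normal inter-individual variability on enzyme abundance,
organ volumes/flows and luminal bile salts.  Each subject owns an
independent RNG stream spawned from the master seed, so populations are
bit-reproducible and stable under resizing.

The synthetic generators replace the study's digitized observations:
noisy percent-dissolved curves for dissolution fitting, individual plasma
profiles with proportional residual error for the evaluation statistics,
and response-time profiles for the PD metrics.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .drug import DrugModel, Formulation, PDParams
from .gut import build_fasted_gi
from .pbpk import (PKResult, SubjectPhysiology, _FLOWS, _VOLUMES,
                   simulate_pk)

__all__ = ["PopulationSpec", "CAUCASIAN_FREQS", "CHINESE_FREQS",
           "sample_population", "generate_synthetic_dissolution",
           "generate_synthetic_observed_pk", "run_trials", "TrialSummary",
           "population_pk"]

#: CYP2C9 genotype frequencies (wild type through poor metabolizers).
CAUCASIAN_FREQS = {"1*/1*": 0.65, "1*/2*": 0.20, "1*/3*": 0.10,
                   "2*/2*": 0.025, "2*/3*": 0.02, "3*/3*": 0.005}
CHINESE_FREQS = {"1*/1*": 0.975, "1*/2*": 0.0, "1*/3*": 0.0249,
                 "2*/2*": 0.0, "2*/3*": 0.0, "3*/3*": 0.0001}


@dataclass
class PopulationSpec:
    ethnicity: str = "NEurCaucasian"     # or "Chinese"
    n_subjects: int = 100
    n_trials: int = 10
    female_ratio: float = 0.0
    age_range: tuple = (20.0, 45.0)
    weight_range: tuple = (60.0, 85.0)
    genotype_freqs: dict[str, float] | None = None
    cv_abundance: float = 0.30
    cv_bile_salt: float = 0.25
    cv_flows: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.genotype_freqs is None:
            self.genotype_freqs = dict(
                CHINESE_FREQS if self.ethnicity == "Chinese"
                else CAUCASIAN_FREQS)
        tot = sum(self.genotype_freqs.values())
        if not self.genotype_freqs or tot <= 0:
            raise ValueError("empty genotype frequency table")
        if abs(tot - 1.0) > 1e-6:
            self.genotype_freqs = {g: f / tot
                                   for g, f in self.genotype_freqs.items()}


def _lognormal(rng, cv):
    s = np.sqrt(np.log(1.0 + cv * cv))
    return float(np.exp(rng.normal(-s * s / 2.0, s)))


def sample_population(spec: PopulationSpec) -> list[SubjectPhysiology]:
    """Draw ``spec.n_subjects * spec.n_trials`` virtual subjects
    (deterministic under the spec seed)."""
    genos = list(spec.genotype_freqs)
    probs = np.array([spec.genotype_freqs[g] for g in genos])
    master = np.random.default_rng(spec.seed)
    geno_idx = master.choice(len(genos), size=spec.n_subjects * spec.n_trials,
                             p=probs)
    subjects = []
    for i in range(spec.n_subjects * spec.n_trials):
        rng = np.random.default_rng([spec.seed, i])
        bw = rng.uniform(*spec.weight_range)
        age = rng.uniform(*spec.age_range)
        sex = "F" if rng.uniform() < spec.female_ratio else "M"
        scale = bw / 70.0
        vols = {k: v * scale * _lognormal(rng, spec.cv_flows)
                for k, v in _VOLUMES.items()}
        flows = {k: q * scale * _lognormal(rng, spec.cv_flows)
                 for k, q in _FLOWS.items()}
        gi = build_fasted_gi(variability_cv=spec.cv_flows, rng=rng,
                             bile_salt_cv=spec.cv_bile_salt)
        subjects.append(SubjectPhysiology(
            body_weight=bw, genotype=genos[geno_idx[i]],
            volumes=vols, flows=flows,
            v_plasma=3.1 * scale, v_venous=3.2 * scale,
            v_arterial=1.4 * scale,
            liver_weight=1650.0 * scale,
            cyp2c9_abundance=54.0 * _lognormal(rng, spec.cv_abundance),
            sex=sex, age=age, gi=gi))
    return subjects


def sample_pd_params(base: PDParams, rng: np.random.Generator) -> PDParams:
    """One subject's PD parameters: log-normal inter-individual variability
    on keo and IC50 with the endpoint's reported CVs."""
    s1 = np.sqrt(np.log(1.0 + base.keo_cv ** 2))
    s2 = np.sqrt(np.log(1.0 + base.ic50_cv ** 2))
    return PDParams(keo=base.keo * np.exp(rng.normal(-s1 * s1 / 2, s1)),
                    ic50=base.ic50 * np.exp(rng.normal(-s2 * s2 / 2, s2)),
                    keo_cv=0.0, ic50_cv=0.0, baseline=base.baseline,
                    endpoint=base.endpoint)


def generate_synthetic_dissolution(experiment, params, bins, aq, mic,
                                   noise_cv: float = 0.02, seed: int = 0,
                                   **sim_kw):
    """Simulated dissolution profile with multiplicative Gaussian noise,
    clipped to [0, 100].  Zero noise returns the exact model output."""
    from .dissolution import DissolutionProfile, simulate_experiment
    prof = simulate_experiment(experiment, params, bins, aq, mic, **sim_kw)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        noisy = prof.percent_dissolved * (1.0 + rng.normal(
            0.0, noise_cv, size=prof.percent_dissolved.size))
        prof = DissolutionProfile(prof.times, np.clip(noisy, 0.0, 100.0))
    return prof


def generate_synthetic_observed_pk(drug: DrugModel, spec: PopulationSpec,
                                   dose: float = 100.0, route: str = "oral",
                                   residual_cv: float = 0.2, seed: int = 0,
                                   sample_times=None, **sim_kw
                                   ) -> pd.DataFrame:
    """Per-subject 'observed' plasma profiles: model simulation plus
    proportional residual error.  Returns a tidy table
    (subject, genotype, time_h, conc_mg_L, conc_true_mg_L)."""
    subjects = sample_population(spec)[: spec.n_subjects]
    st = np.asarray(sample_times if sample_times is not None
                    else [0.25, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 12, 24], float)
    rows = []
    for i, subj in enumerate(subjects):
        res = simulate_pk(drug, subj, dose=dose, route=route, **sim_kw)
        ct = np.interp(st, res.times, res.conc_plasma)
        rng = np.random.default_rng([seed, 7919, i])
        obs = ct * (1.0 + rng.normal(0.0, residual_cv, size=st.size)) \
            if residual_cv > 0 else ct.copy()
        for t, co, ctr in zip(st, obs, ct):
            rows.append((i, subj.genotype, t, max(co, 1e-9), ctr))
    return pd.DataFrame(rows, columns=["subject", "genotype", "time_h",
                                       "conc_mg_L", "conc_true_mg_L"])


@dataclass
class TrialSummary:
    times: np.ndarray
    mean: np.ndarray
    p5: np.ndarray
    p95: np.ndarray
    metrics: pd.DataFrame                  # per subject
    by_genotype: dict[str, pd.DataFrame]


def population_pk(drug: DrugModel, subjects, dose: float = 100.0,
                  route: str = "oral",
                  formulation: Formulation | None = None,
                  t_end: float = 30.0, rtol: float = 1e-6,
                  cyp_multiplier=None) -> list[PKResult]:
    """Simulate each subject once under a common design."""
    return [simulate_pk(drug, s, dose=dose, route=route,
                        formulation=formulation, t_end=t_end, rtol=rtol,
                        cyp_multiplier=cyp_multiplier)
            for s in subjects]


def run_trials(drug: DrugModel, spec: PopulationSpec, dose: float = 100.0,
               route: str = "oral", formulation: Formulation | None = None,
               t_end: float = 30.0, rtol: float = 1e-6) -> TrialSummary:
    """n_trials x n_subjects clinical-trial simulation with 5th/95th
    percentile trajectories and per-genotype stratification."""
    subjects = sample_population(spec)
    results = population_pk(drug, subjects, dose, route, formulation,
                            t_end, rtol)
    tt = results[0].times
    conc = np.vstack([r.conc_plasma for r in results])
    rows = []
    for i, (s, r) in enumerate(zip(subjects, results)):
        m = r.metrics
        rows.append((i, i // spec.n_subjects, s.genotype, m.cmax, m.tmax,
                     m.auc_last, m.auc_inf, m.cl_f, r.fa))
    met = pd.DataFrame(rows, columns=["subject", "trial", "genotype", "cmax",
                                      "tmax", "auc_last", "auc_inf", "cl_f",
                                      "fa"])
    by_g = {g: d.drop(columns="genotype")
            for g, d in met.groupby("genotype")}
    return TrialSummary(times=tt, mean=conc.mean(axis=0),
                        p5=np.percentile(conc, 5, axis=0),
                        p95=np.percentile(conc, 95, axis=0),
                        metrics=met, by_genotype=by_g)
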