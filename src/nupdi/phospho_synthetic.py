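"""Synthetic DIA phosphoproteomics precursor tables.

Emulates the statistical structure the post-processing chain assumes:
log-normal precursor intensities, biological triplicates of a
kinase-active and a kinase-dead condition over a meiotic time course,
intensity-dependent (left-censored) plus completely-at-random
missingness, and a set of planted differential phosphosites that switch
on at a programmed induction timepoint.  A truth table lists every
planted site and its effect so parameter recovery is checkable
end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .phospho_pipeline import PrecursorTable

__all__ = ["PhosphoSimConfig", "simulate_precursor_table"]

RESIDUES = ("S", "T", "Y")


@dataclass
class PhosphoSimConfig:
    """Study design and effect/missingness model for one simulation.

    Defaults describe triplicates of a kinase-active ("Cdc5") vs.
    kinase-dead ("Cdc5KD") induction time course sampled hourly for five
    hours, with effects switching on at the 2-hour induction timepoint;
    intensities are log-normal (log2 mean 14, SD 2) with replicate noise
    of 0.5 log2 units.
    """

    n_proteins: int = 100
    sites_per_protein: int = 2
    precursors_per_site: int = 1
    fraction_multiphospho: float = 0.0
    baseline_mean: float = 14.0  # log2 a.u.
    baseline_sd: float = 2.0
    noise_sd: float = 0.5  # replicate noise, log2 units
    n_planted: int = 0
    planted_log2fc: float = 2.0
    onset_timepoint: float = 2.0  # hours after induction
    replicates: tuple[int, ...] = (1, 2, 3)
    timepoints: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    conditions: tuple[str, str] = ("Cdc5", "Cdc5KD")  # (active, control)
    missing_car_rate: float = 0.0
    missing_logistic_midpoint: float | None = None  # log2 units; None = off
    missing_logistic_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins * self.sites_per_protein <= 0:
            raise ValueError("simulation needs at least one site")
        if not 0.0 <= self.missing_car_rate <= 1.0:
            raise ValueError("missingness rate must be in [0, 1]")
        if not 0.0 <= self.fraction_multiphospho <= 1.0:
            raise ValueError("multiphospho fraction must be in [0, 1]")
        n_sites = self.n_proteins * self.sites_per_protein
        if self.n_planted > n_sites:
            raise ValueError("more planted sites than simulated sites")


def simulate_precursor_table(
    config: PhosphoSimConfig,
) -> tuple[PrecursorTable, pd.DataFrame]:
    """Generate a precursor table plus the planted-effect truth table.

    Intensity model per precursor i and sample s:

        x_is = baseline_i + effect_i * [condition(s) = active]
                          * [timepoint(s) >= onset] + eps_is

    with eps ~ Normal(0, noise_sd).  Missingness combines a logistic
    term in the true intensity (lower -> more missing, emulating DIA
    detection limits) with a completely-at-random rate.  The returned
    table is on the linear scale (the pipeline starts by log2
    transforming), with NaN for missing.
    """
    rng = np.random.default_rng(config.seed)
    active, control = config.conditions
    sample_meta = []
    for cond in (active, control):
        for rep in config.replicates:
            for tp in config.timepoints:
                sid = f"{cond}_r{rep}_t{tp:g}"
                sample_meta.append(dict(sample_id=sid, condition=cond,
                                        replicate=rep, timepoint=float(tp)))
    samples = pd.DataFrame(sample_meta).set_index("sample_id")

    n_sites = config.n_proteins * config.sites_per_protein
    proteins = [f"P{p:04d}" for p in range(config.n_proteins)
                for _ in range(config.sites_per_protein)]
    positions, seen = [], {}
    for prot in proteins:
        pos = seen.get(prot, 0) * 37 + 17  # distinct positions per protein
        seen[prot] = seen.get(prot, 0) + 1
        positions.append(pos)
    residues = [RESIDUES[rng.integers(0, 2)] for _ in range(n_sites)]
    planted_idx = rng.choice(n_sites, size=config.n_planted, replace=False)
    effects = np.zeros(n_sites)
    effects[planted_idx] = config.planted_log2fc

    prec_rows, prec_ann, truths = [], [], []
    onset = config.onset_timepoint
    is_active = (samples["condition"] == active).to_numpy()
    post_onset = (samples["timepoint"] >= onset).to_numpy()
    for i in range(n_sites):
        baseline = rng.normal(config.baseline_mean, config.baseline_sd)
        site_label = f"{residues[i]}{positions[i]}"
        n_prec = max(1, config.precursors_per_site)
        for k in range(n_prec):
            multi = rng.random() < config.fraction_multiphospho
            if multi and i + 1 < n_sites and proteins[i + 1] == proteins[i]:
                sites_str = f"{site_label}+{residues[i+1]}{positions[i+1]}"
            else:
                sites_str = site_label
            true_x = (baseline + rng.normal(0, 0.3)  # per-precursor offset
                      + effects[i] * (is_active & post_onset))
            x = true_x + rng.normal(0, config.noise_sd, len(samples))
            p_miss = np.full(len(samples), config.missing_car_rate)
            if config.missing_logistic_midpoint is not None:
                p_det = expit((x - config.missing_logistic_midpoint)
                              / config.missing_logistic_scale)
                p_miss = 1.0 - (1.0 - p_miss) * p_det
            x_lin = np.power(2.0, x)
            x_lin[rng.random(len(samples)) < p_miss] = np.nan
            pid = f"{proteins[i]}_{sites_str}_c{k}"
            prec_rows.append(pd.Series(x_lin, index=samples.index, name=pid))
            prec_ann.append(dict(precursor_id=pid, protein=proteins[i],
                                 sites=sites_str,
                                 confidence="high" if rng.random() < 0.8 else "low"))
        truths.append(dict(protein=proteins[i], residue=residues[i],
                           position=positions[i],
                           site_id=f"{proteins[i]}:{site_label}",
                           planted=bool(effects[i] != 0),
                           log2fc_true=float(effects[i]),
                           onset_timepoint=onset))
    intens = pd.DataFrame(prec_rows)
    ann = pd.DataFrame(prec_ann).set_index("precursor_id")
    table = PrecursorTable(intensities=intens, samples=samples,
                           annotations=ann, is_log2=False)
    return table, pd.DataFrame(truths)
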