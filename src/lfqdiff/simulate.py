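"""Synthetic label-free study generator.

Emulates the statistical structure of a two-group liver-tissue LFQ study:
8 treated + 7 control patients measured in technical duplicate over ~6000
proteins.  Log2 intensities are normal around a protein baseline (so linear
intensities are log-normal); replicate correlation arises from a shared
per-patient random effect; a small planted fraction of proteins is shifted
in the treated group; and cells drop out with a probability that decreases
logistically in log2 abundance (left-censored, MNAR missingness — the
regime downshifted-normal imputation presumes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import GROUP_CONTROL, GROUP_TREATED, IntensityMatrix, StudyDesign

__all__ = ["SimulationConfig", "SimulationTruth", "generate_study"]


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic study.

    Defaults state the emulated design: 8 treated vs 7 control patients,
    2 technical replicates each, 6000 proteins; log2 baselines N(25, 2)
    (typical LFQ dynamic range), patient effect SD 0.4 and replicate noise
    SD 0.25 so technical variability is below biological variability;
    1% of proteins planted at |delta| = 1.25 log2 units (fold change ~2.4,
    the magnitude scale of real calls); dropout midpoint 21.5 / slope 1.0,
    which yields roughly 10% overall missingness concentrated at low
    abundance.
    """

    n_treated: int = 8
    n_control: int = 7
    n_replicates: int = 2
    n_proteins: int = 6000
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    patient_sd: float = 0.4
    replicate_sd: float = 0.25
    replicate_batch_sd: float = 0.0  # optional run-order batch direction
    planted_fraction: float = 0.01
    planted_delta: float = 1.25
    dropout_midpoint: float = 21.5  # log2 abundance at 50% dropout
    dropout_slope: float = 1.0  # 0 disables dropout entirely
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_treated", "n_control", "n_replicates", "n_proteins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must lie in [0, 1]")
        for name in ("baseline_sd", "patient_sd", "replicate_sd", "replicate_batch_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dropout_slope < 0:
            raise ValueError("dropout_slope must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth of a generated study."""

    proteins: pd.DataFrame  # protein_id, planted, true_delta
    config: SimulationConfig

    @property
    def planted_ids(self) -> list[str]:
        return self.proteins.loc[self.proteins["planted"], "protein_id"].tolist()


def generate_study(
    config: SimulationConfig | None = None, **kwargs
) -> tuple[IntensityMatrix, StudyDesign, SimulationTruth]:
    """Generate (linear-scale intensity matrix, design, truth), seed-deterministic.

    Cell model on the log2 scale:

        x[i, p, r] = base_i + delta_i * 1[p treated] + u[i, p] + b_i * 1[r = 2] + e[i, p, r]

    with base_i ~ N(baseline_mean, baseline_sd^2), patient effect
    u ~ N(0, patient_sd^2), optional batch direction b_i ~ N(0,
    replicate_batch_sd^2) applied to the second replicate, and replicate
    noise e ~ N(0, replicate_sd^2).  Planted proteins receive delta_i =
    +-planted_delta (random sign).  Each cell is then set missing with
    probability expit(-(x - dropout_midpoint) * dropout_slope); with
    dropout_slope = 0 the matrix is complete.
    """
    if config is None:
        config = SimulationConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    c = config

    n_patients = c.n_treated + c.n_control
    patients = [f"T{i + 1:02d}" for i in range(c.n_treated)] + [
        f"C{i + 1:02d}" for i in range(c.n_control)
    ]
    groups = [GROUP_TREATED] * c.n_treated + [GROUP_CONTROL] * c.n_control
    records = []
    for p, g in zip(patients, groups):
        for r in range(1, c.n_replicates + 1):
            records.append((f"{p}_r{r}", p, g, r))
    design = StudyDesign.from_records(records)

    protein_ids = [f"SYN{i + 1:05d}" for i in range(c.n_proteins)]
    gene_names = [f"G{i + 1:05d}" for i in range(c.n_proteins)]

    base = rng.normal(c.baseline_mean, c.baseline_sd, size=c.n_proteins)
    n_planted = round(c.planted_fraction * c.n_proteins)
    planted = np.zeros(c.n_proteins, dtype=bool)
    planted[rng.choice(c.n_proteins, size=n_planted, replace=False)] = True
    signs = rng.choice([-1.0, 1.0], size=c.n_proteins)
    true_delta = np.where(planted, signs * c.planted_delta, 0.0)

    u = rng.normal(0.0, c.patient_sd, size=(c.n_proteins, n_patients))
    batch = (
        rng.normal(0.0, c.replicate_batch_sd, size=c.n_proteins)
        if c.replicate_batch_sd > 0
        else np.zeros(c.n_proteins)
    )

    n_samples = n_patients * c.n_replicates
    log2 = np.empty((c.n_proteins, n_samples))
    treated_flag = np.array([g == GROUP_TREATED for g in groups], dtype=float)
    for j, (sample, patient, group, rep) in enumerate(records):
        p_idx = patients.index(patient)
        mean = base + true_delta * treated_flag[p_idx] + u[:, p_idx]
        if rep == 2:
            mean = mean + batch
        log2[:, j] = mean + rng.normal(0.0, c.replicate_sd, size=c.n_proteins)

    if c.dropout_slope > 0:
        p_miss = expit(-(log2 - c.dropout_midpoint) * c.dropout_slope)
        missing = rng.random(log2.shape) < p_miss
    else:
        missing = np.zeros(log2.shape, dtype=bool)

    values = np.exp2(log2)
    values[missing] = np.nan
    matrix = IntensityMatrix(
        protein_ids=protein_ids,
        samples=[r[0] for r in records],
        values=values,
        gene_names=gene_names,
        scale="linear",
    )
    truth = SimulationTruth(
        proteins=pd.DataFrame(
            {"protein_id": protein_ids, "planted": planted, "true_delta": true_delta}
        ),
        config=c,
    )
    return matrix, design, truth
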