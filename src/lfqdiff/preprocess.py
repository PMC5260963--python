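"""Detection filtering, log transformation, imputation and row standardisation.

Missing label-free intensities are left-censored: proteins near the
instrument's detection limit drop out preferentially.  The imputation step
therefore draws replacements from a normal distribution shifted into the
lower tail of each sample's observed abundance distribution (Perseus-style
"downshifted normal": centre ``mu - shift*sigma``, spread ``width*sigma``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import IntensityMatrix


@dataclass
class ImputationParams:
    """Parameters of downshifted-normal imputation.

    width
        SD of the imputation distribution as a fraction of the per-sample
        observed SD (default 0.3).
    shift
        Downshift of its centre in per-sample observed SDs (default 1.8).
    per_sample
        Compute mu/sigma per sample column (True, default) or from the whole
        observed matrix (False).
    """

    width: float = 0.3
    shift: float = 1.8
    seed: int = 0
    per_sample: bool = True

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("imputation width must be > 0")
        if self.shift < 0:
            raise ValueError("imputation shift must be >= 0")


def filter_by_detection(matrix: IntensityMatrix, min_fraction: float = 0.5) -> IntensityMatrix:
    """Keep proteins observed in strictly more than ``min_fraction`` of samples.

    The boundary is exclusive: with 30 samples and the default 0.5, a protein
    seen in exactly 15 runs is removed, one seen in 16 is kept.
    """
    if not (0 <= min_fraction < 1):
        raise ValueError("min_fraction must lie in [0, 1)")
    frac = matrix.observed.sum(axis=1) / matrix.n_samples
    keep = np.flatnonzero(frac > min_fraction)
    return matrix.select_proteins(keep)


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """log2-transform observed intensities; missing cells stay missing."""
    if matrix.scale != "linear":
        raise ValueError(f"matrix is already on scale {matrix.scale!r}, expected linear")
    obs = matrix.observed
    if (matrix.values[obs] <= 0).any():
        raise ValueError("observed intensities must be positive for log2 transform")
    out = matrix.copy()
    out.values[obs] = np.log2(out.values[obs])
    out.scale = "log2"
    return out


def impute_downshifted(
    matrix: IntensityMatrix, params: ImputationParams | None = None
) -> IntensityMatrix:
    """Fill missing cells with draws from a downshifted normal distribution.

    With ``per_sample=True`` each sample column s contributes its own observed
    mean mu_s and SD sigma_s (n-1 convention) and missing cells in that column
    are drawn from Normal(mu_s - shift*sigma_s, (width*sigma_s)^2).  Observed
    cells are never altered; the result is deterministic given ``seed``.
    """
    if params is None:
        params = ImputationParams()
    if matrix.scale != "log2":
        raise ValueError("imputation expects a log2-scale matrix")
    rng = np.random.default_rng(params.seed)
    out = matrix.copy()
    obs = matrix.observed

    n_obs = obs.sum(axis=0)
    too_few = [s for s, n in zip(matrix.samples, n_obs) if n < 3]
    if too_few:
        raise ValueError(f"samples with fewer than 3 observed values: {too_few}")

    if params.per_sample:
        for j in range(matrix.n_samples):
            col_obs = matrix.values[obs[:, j], j]
            mu = col_obs.mean()
            sigma = col_obs.std(ddof=1)
            miss = np.flatnonzero(~obs[:, j])
            if miss.size:
                out.values[miss, j] = rng.normal(
                    mu - params.shift * sigma, params.width * sigma, size=miss.size
                )
    else:
        all_obs = matrix.values[obs]
        mu = all_obs.mean()
        sigma = all_obs.std(ddof=1)
        miss = np.argwhere(~obs)
        if miss.size:
            out.values[~obs] = rng.normal(
                mu - params.shift * sigma, params.width * sigma, size=len(miss)
            )
    return out


def zscore_rows(matrix: IntensityMatrix) -> IntensityMatrix:
    """Standardise each protein row to mean 0, SD 1 (population convention).

    Requires a complete matrix; zero-variance rows are an error because they
    carry no clustering information and would divide by zero.
    """
    if not matrix.is_complete:
        raise ValueError("zscore_rows requires a complete (imputed) matrix")
    mu = matrix.values.mean(axis=1, keepdims=True)
    sd = matrix.values.std(axis=1, ddof=0, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        names = [matrix.protein_ids[i] for i in flat[:10]]
        raise ValueError(f"zero-variance rows cannot be z-scored: {names}")
    out = matrix.copy()
    out.values = (matrix.values - mu) / sd
    out.scale = "zscore"
    return out
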