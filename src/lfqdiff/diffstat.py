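"""s0-moderated Welch testing with patient-level permutation FDR.

The inferential unit is the patient, not the MS run: technical replicates
are averaged on the log2 scale before any statistic is computed, and group
labels are permuted over patients only.  The moderated statistic is the
SAM-style

    d = delta / (SE + s0),        SE = sqrt(s1^2/n1 + s2^2/n2)

where ``delta`` is the treated-minus-control mean log2 difference.  The
constant s0 damps the significance of proteins whose fold change is small
even when their variance is tiny; with s0 = 0, d is the classical Welch t.
The reported ``welch_p`` is always the unmoderated Welch p-value
(Welch-Satterthwaite degrees of freedom); s0 enters only the permutation
statistic used for the FDR, so a protein is called significant when both
welch_p < alpha_p and the permutation q-value < alpha_fdr.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GROUP_CONTROL, GROUP_TREATED, IntensityMatrix, StudyDesign

__all__ = [
    "ModeratedTestParams",
    "DifferentialAbundanceModel",
    "DifferentialAbundanceResults",
    "patient_level_matrix",
    "signed_fold_change",
    "moderated_welch_t",
    "permutation_fdr",
    "run_differential_test",
    "summarize_significant",
]


@dataclass
class ModeratedTestParams:
    """Tuning constants of the moderated test.

    s0
        Moderation constant added to the standard error (default 0.05).  In
        ``sd_percentile`` mode s0 is instead a percentile in [0, 1] and the
        constant is that quantile of the per-protein SE distribution.
    n_permutations
        Group-label permutations drawn for the FDR (default 5000); when this
        meets or exceeds the number of distinct non-identity assignments the
        test becomes exact over all of them.
    """

    s0: float = 0.05
    n_permutations: int = 5000
    seed: int = 0
    alpha_p: float = 0.05
    alpha_fdr: float = 0.05
    s0_mode: str = "additive_constant"

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.s0_mode not in ("additive_constant", "sd_percentile"):
            raise ValueError(f"unknown s0_mode {self.s0_mode!r}")
        if self.s0_mode == "sd_percentile" and not 0 <= self.s0 <= 1:
            raise ValueError("in sd_percentile mode s0 must be a percentile in [0, 1]")


# ----------------------------------------------------------------------
# building blocks
# ----------------------------------------------------------------------

def patient_level_matrix(
    matrix: IntensityMatrix, design: StudyDesign
) -> tuple[IntensityMatrix, np.ndarray]:
    """Average technical replicates (log2 scale) into one column per patient.

    Returns the collapsed matrix (columns = patients, design order) and the
    aligned array of group labels.  Single-replicate patients pass through
    unchanged.
    """
    if not matrix.is_complete:
        raise ValueError("collapse requires a complete (imputed) matrix")
    design.validate_matrix(matrix)
    col = {s: j for j, s in enumerate(matrix.samples)}
    patients = design.patients
    out = np.empty((matrix.n_proteins, len(patients)))
    groups = []
    for p_idx, patient in enumerate(patients):
        ss = design.samples_of(patient)
        missing = [s for s in ss if s not in col]
        if missing:
            raise ValueError(f"replicates of patient {patient!r} absent from matrix: {missing}")
        out[:, p_idx] = matrix.values[:, [col[s] for s in ss]].mean(axis=1)
        groups.append(design.group_of(patient))
    collapsed = IntensityMatrix(
        protein_ids=list(matrix.protein_ids),
        samples=patients,
        values=out,
        gene_names=list(matrix.gene_names),
        peptide_counts=None if matrix.peptide_counts is None else matrix.peptide_counts.copy(),
        scale=matrix.scale,
    )
    return collapsed, np.asarray(groups)


def signed_fold_change(delta_log2):
    """Signed linear fold change: 2^delta for delta >= 0, -2^(-delta) otherwise.

    Antisymmetric; delta = 0 maps to +1, so |FC| >= 1 always.
    """
    delta = np.asarray(delta_log2, dtype=float)
    fc = np.where(delta >= 0, 2.0**delta, -(2.0 ** (-delta)))
    return fc if fc.ndim else float(fc)


def _welch_components(A: np.ndarray, B: np.ndarray):
    """Vectorised Welch pieces for proteins x n group matrices."""
    n1, n2 = A.shape[1], B.shape[1]
    m1, m2 = A.mean(axis=1), B.mean(axis=1)
    v1 = A.var(axis=1, ddof=1)
    v2 = B.var(axis=1, ddof=1)
    delta = m1 - m2
    se2 = v1 / n1 + v2 / n2
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return m1, m2, delta, se, df


def moderated_welch_t(values_a, values_b, s0: float = 0.0):
    """Moderated Welch statistic for one protein.

    Returns ``(d, welch_p, df, se, delta)`` where d = delta/(se + s0) and
    welch_p is the two-sided p of the unmoderated statistic delta/se with
    Welch-Satterthwaite degrees of freedom.  Identical constant groups give
    d = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    _, _, delta, se, df = _welch_components(a[None, :], b[None, :])
    delta, se, df = float(delta[0]), float(se[0]), float(df[0])
    if se == 0.0:
        if delta == 0.0:
            return 0.0, 1.0, float("nan"), 0.0, 0.0
        d = delta / s0 if s0 > 0 else math.copysign(math.inf, delta)
        return d, 0.0, float("nan"), 0.0, delta
    t = delta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    d = delta / (se + s0)
    return d, float(p), df, se, delta


def _d_statistic(values: np.ndarray, treated_mask: np.ndarray, s0: float) -> np.ndarray:
    """Moderated d for all proteins given a boolean treated mask over patients."""
    A = values[:, treated_mask]
    B = values[:, ~treated_mask]
    _, _, delta, se, _ = _welch_components(A, B)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = delta / (se + s0)
    d[np.isnan(d)] = 0.0  # 0/0: no difference, no evidence
    return d


def _distinct_assignments(n: int, n_treated: int, identity: tuple[int, ...]):
    """All distinct treated-index assignments, identity excluded."""
    combos = [c for c in itertools.combinations(range(n), n_treated) if c != identity]
    return combos


def permutation_fdr(
    patient_values: np.ndarray,
    groups: np.ndarray,
    params: ModeratedTestParams,
    s0_constant: float | None = None,
) -> np.ndarray:
    """Permutation q-values for the moderated statistic.

    Group labels are reassigned over patients, drawing uniformly without
    replacement from the distinct C(n, n_treated) assignments (identity
    excluded); the same permutation is applied to every protein in a run so
    between-protein correlation survives under the null.  For protein i with
    observed |d_i|,

        q_i = min(1, mean_b #{j : |d^null_bj| >= |d_i|} / #{j : |d_j| >= |d_i|})

    followed by enforcement of monotone non-increase in |d|.  Requesting at
    least as many runs as there are distinct assignments yields the exact
    test over all of them.
    """
    groups = np.asarray(groups)
    treated = groups == GROUP_TREATED
    n = len(groups)
    n1, n2 = int(treated.sum()), int((~treated).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 patients for permutation FDR")
    s0 = params.s0 if s0_constant is None else s0_constant

    d_obs = _d_statistic(patient_values, treated, s0)
    abs_obs = np.abs(d_obs)

    identity = tuple(np.flatnonzero(treated))
    combos = _distinct_assignments(n, n1, identity)
    rng = np.random.default_rng(params.seed)
    if params.n_permutations >= len(combos):
        chosen = combos
    else:
        idx = rng.choice(len(combos), size=params.n_permutations, replace=False)
        chosen = [combos[i] for i in idx]
    B = len(chosen)

    order = np.argsort(abs_obs, kind="stable")
    sorted_abs = abs_obs[order]
    null_ge = np.zeros(len(abs_obs))
    mask = np.zeros(n, dtype=bool)
    for combo in chosen:
        mask[:] = False
        mask[list(combo)] = True
        d_null = np.abs(_d_statistic(patient_values, mask, s0))
        d_null.sort()
        # for each observed threshold t: #null >= t
        counts = len(d_null) - np.searchsorted(d_null, sorted_abs, side="left")
        null_ge[order] += counts

    # observed counts with >= semantics
    r = len(abs_obs) - np.searchsorted(sorted_abs, sorted_abs, side="left")
    R = np.empty_like(null_ge)
    R[order] = r
    with np.errstate(divide="ignore", invalid="ignore"):
        q_raw = np.minimum(1.0, (null_ge / B) / R)

    # enforce: larger |d| never gets a larger q
    desc = np.argsort(-abs_obs, kind="stable")
    q_sorted = q_raw[desc]
    q_mono = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_raw)
    q[desc] = q_mono
    return q


# ----------------------------------------------------------------------
# model / results
# ----------------------------------------------------------------------

class DifferentialAbundanceModel:
    """Two-group differential-abundance model for a label-free study.

    Parameters
    ----------
    matrix
        Complete (filtered, imputed) log2-scale intensity matrix over MS runs.
    design
        Sample design; technical replicates are averaged into patient columns
        before any statistic is computed.
    params
        :class:`ModeratedTestParams`; keyword overrides accepted.

    ``fit()`` returns a :class:`DifferentialAbundanceResults`.
    """

    def __init__(
        self,
        matrix: IntensityMatrix,
        design: StudyDesign,
        params: ModeratedTestParams | None = None,
        **kwargs,
    ) -> None:
        if params is None:
            params = ModeratedTestParams(**kwargs)
        elif kwargs:
            raise TypeError("pass either params or keyword overrides, not both")
        if matrix.scale != "log2":
            raise ValueError("model expects a log2-scale matrix")
        self.params = params
        self.design = design
        self.matrix = matrix
        self.patient_matrix, self.groups = patient_level_matrix(matrix, design)
        sizes = {g: int((self.groups == g).sum()) for g in (GROUP_TREATED, GROUP_CONTROL)}
        if min(sizes.values()) < 2:
            raise ValueError(f"each group needs >= 2 patients, got {sizes}")

    def _s0_constant(self, se: np.ndarray) -> float:
        if self.params.s0_mode == "sd_percentile":
            return float(np.quantile(se, self.params.s0))
        return self.params.s0

    def fit(self) -> "DifferentialAbundanceResults":
        p = self.params
        values = self.patient_matrix.values
        treated = self.groups == GROUP_TREATED
        A, B = values[:, treated], values[:, ~treated]
        m1, m2, delta, se, df = _welch_components(A, B)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta / se
        welch_p = np.where(
            se > 0, 2.0 * stats.t.sf(np.abs(t), df), np.where(delta == 0, 1.0, 0.0)
        )
        s0_const = self._s0_constant(se)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(se + s0_const > 0, delta / (se + s0_const), 0.0)
        q = permutation_fdr(values, self.groups, p, s0_constant=s0_const)
        significant = (welch_p < p.alpha_p) & (q < p.alpha_fdr)

        linear = 2.0**values
        cv = linear.std(axis=1, ddof=1) / linear.mean(axis=1)

        frame = pd.DataFrame(
            {
                "protein_id": self.patient_matrix.protein_ids,
                "gene_names": self.patient_matrix.gene_names,
                "mean_treated": m1,
                "mean_control": m2,
                "delta_log2": delta,
                "fold_change": signed_fold_change(delta),
                "se": se,
                "df": df,
                "d": d,
                "welch_p": welch_p,
                "q": q,
                "coefficient_of_variation": cv,
                "significant": significant,
            }
        )
        return DifferentialAbundanceResults(self, frame, s0_const)


class DifferentialAbundanceResults:
    """Per-protein estimates, p/q-values and significance calls."""

    def __init__(self, model: DifferentialAbundanceModel, frame: pd.DataFrame, s0_constant: float):
        self.model = model
        self.frame = frame
        self.s0_constant = s0_constant

    @property
    def params(self) -> ModeratedTestParams:
        return self.model.params

    @property
    def n_significant(self) -> int:
        return int(self.frame["significant"].sum())

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]].reset_index(drop=True)

    def summarize_significant(self) -> pd.DataFrame:
        return summarize_significant(self.significant)

    def summary(self) -> str:
        p = self.params
        sizes = {g: int((self.model.groups == g).sum()) for g in (GROUP_TREATED, GROUP_CONTROL)}
        lines = [
            "Differential abundance (s0-moderated Welch, permutation FDR)",
            "=" * 62,
            f"proteins tested        {len(self.frame):>10d}",
            f"patients (treated/control) {sizes[GROUP_TREATED]:>4d} / {sizes[GROUP_CONTROL]}",
            f"s0 constant            {self.s0_constant:>10.4g}  (mode: {p.s0_mode})",
            f"permutations           {p.n_permutations:>10d}  (seed {p.seed})",
            f"alpha_p / alpha_fdr    {p.alpha_p:>10.3g} / {p.alpha_fdr:.3g}",
            f"significant proteins   {self.n_significant:>10d}"
            f"  ({100 * self.n_significant / max(len(self.frame), 1):.1f}%)",
        ]
        summ = self.summarize_significant()
        if not summ.empty:
            lines.append("-" * 62)
            lines.append(summ.to_string(index=False))
        return "\n".join(lines)


def run_differential_test(
    matrix: IntensityMatrix,
    design: StudyDesign,
    params: ModeratedTestParams | None = None,
) -> pd.DataFrame:
    """Functional facade: fit the model and return the per-protein frame."""
    return DifferentialAbundanceModel(matrix, design, params=params).fit().frame


def summarize_significant(results: pd.DataFrame) -> pd.DataFrame:
    """Counts, medians and IQRs of up- and down-regulated fold changes.

    Accepts any frame with a ``fold_change`` column (model results or the
    packaged reference table).  Medians/quartiles are rounded to 1 decimal.
    """
    if results.empty or "fold_change" not in results.columns:
        return pd.DataFrame(
            columns=["direction", "n", "median_fc", "q1_fc", "q3_fc"]
        )
    fc = results["fold_change"].to_numpy(dtype=float)
    rows = []
    for direction, vals in (("up", fc[fc > 0]), ("down", fc[fc < 0])):
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "direction": direction,
                "n": int(vals.size),
                "median_fc": round(float(med), 1),
                "q1_fc": round(float(q1), 1),
                "q3_fc": round(float(q3), 1),
            }
        )
    return pd.DataFrame(rows)
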