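"""Normalized ERP magnitude (NM) and its relation to behavioral performance.

The linear model: a participant answering a fraction ``a`` of trials
correctly attends the correct word on that fraction of trials, so the
correct-condition ERP mixes P300b epochs (weight ``a``) with zero-mean
epochs (weight ``1 - a``) and its magnitude is ``a`` times the
attended-condition magnitude measured in the command-following task.
Dividing the correct-condition magnitude by the attended magnitude
therefore yields a dimensionless NM that estimates the accuracy itself —
e.g. an attended magnitude of 4 uV at 75% performance predicts a
correct-condition magnitude of 3 uV.

Magnitudes are means over the spatiotemporal region selected by the
cluster-mass test; one NM is computed per participant and memory-set size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ERP

__all__ = [
    "NMRecord",
    "region_mean",
    "predicted_correct_magnitude",
    "compute_nm",
    "glm_performance",
    "per_setsize_correlation",
    "GLMTermTest",
    "GLMPerformanceResult",
]

Region = tuple[np.ndarray, np.ndarray]  # (channel indices, time indices)


@dataclass(frozen=True)
class NMRecord:
    """One participant x set-size observation of the NM model."""

    participant: str
    set_size: int
    correct_magnitude: float  # uV, region mean of the correct-condition ERP
    attended_magnitude: float  # uV, same region, attended-condition ERP
    nm: float  # correct_magnitude / attended_magnitude
    performance: float  # behavioral accuracy in [0, 1]


def region_mean(erp: ERP | np.ndarray, region: Region) -> float:
    """Mean voltage over the selected (electrode, time) points."""
    ch_idx, t_idx = np.asarray(region[0], int), np.asarray(region[1], int)
    if ch_idx.size == 0 or ch_idx.size != t_idx.size:
        raise ValueError("region must be a nonempty set of (channel, time) points")
    data = erp.data if isinstance(erp, ERP) else np.asarray(erp)
    if ch_idx.max() >= data.shape[0] or t_idx.max() >= data.shape[1]:
        raise ValueError("region indices outside ERP dimensions")
    return float(data[ch_idx, t_idx].mean())


def predicted_correct_magnitude(attended_magnitude: float, performance: float) -> float:
    """Correct-condition magnitude predicted by the linear scaling model."""
    if not 0.0 <= performance <= 1.0:
        raise ValueError(f"performance {performance} outside [0, 1]")
    return attended_magnitude * performance


def compute_nm(
    attended_erp: ERP,
    correct_erps: Mapping[int, ERP],
    region: Region,
    performance: Mapping[int, float],
    participant: str = "p00",
) -> list[NMRecord]:
    """One NM record per memory-set size for one participant.

    A non-positive attended magnitude makes the ratio unstable; such
    participants are excluded with a warning (empty list returned).
    """
    attended_mag = region_mean(attended_erp, region)
    if attended_mag <= 0:
        warnings.warn(
            f"{participant}: attended-region magnitude {attended_mag:.3g} uV <= 0; "
            "NM undefined, participant excluded"
        )
        return []
    records = []
    for size in sorted(correct_erps):
        mag = region_mean(correct_erps[size], region)
        records.append(
            NMRecord(
                participant=participant, set_size=size,
                correct_magnitude=mag, attended_magnitude=attended_mag,
                nm=mag / attended_mag, performance=float(performance[size]),
            )
        )
    return records


def records_frame(records: Sequence[NMRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


@dataclass(frozen=True)
class GLMTermTest:
    term: str
    chi2: float
    df: int
    p_value: float


@dataclass
class GLMPerformanceResult:
    """Sequential likelihood-ratio tests of set size, NM, and their
    interaction on performance."""

    terms: dict[str, GLMTermTest]
    family: str
    n_records: int
    params: pd.Series

    def __getitem__(self, term: str) -> GLMTermTest:
        return self.terms[term]


def glm_performance(
    records: Sequence[NMRecord],
    trials_per_cell: int = 8,
    family: str = "binomial",
) -> GLMPerformanceResult:
    """GLM of performance on memory-set size (factor) and NM (covariate).

    ``family='binomial'`` models per-cell success counts (performance x
    ``trials_per_cell``) with a logit link; ``family='gaussian'`` fits the
    proportions with an identity link.  Terms are tested by sequential
    likelihood-ratio chi-squares: set size (df = levels-1), then NM (df=1),
    then the interaction.
    """
    import statsmodels.api as sm
    from patsy import dmatrix

    df = records_frame(records)
    if len(df) < 3 or df["set_size"].nunique() < 2:
        raise ValueError("need >= 3 records spanning >= 2 set sizes")
    if family not in ("binomial", "gaussian"):
        raise ValueError(f"unknown family {family!r}")

    formulas = [
        "1",
        "C(set_size)",
        "C(set_size) + nm",
        "C(set_size) * nm",
    ]
    if family == "binomial":
        successes = np.rint(df["performance"] * trials_per_cell)
        endog = np.column_stack([successes, trials_per_cell - successes])
        fam = sm.families.Binomial()
    else:
        endog = df["performance"].to_numpy()
        fam = sm.families.Gaussian()

    fits = []
    for f in formulas:
        exog = np.asarray(dmatrix(f, df))
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            raise ValueError(f"rank-deficient design for term set {f!r}")
        fits.append(sm.GLM(endog, exog, family=fam).fit())

    names = ["set_size", "nm", "set_size:nm"]
    terms: dict[str, GLMTermTest] = {}
    for name, reduced, full in zip(names, fits[:-1], fits[1:]):
        chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
        dof = int(full.df_model - reduced.df_model)
        terms[name] = GLMTermTest(name, chi2, dof,
                                  float(stats.chi2.sf(chi2, dof)))
    full = fits[-1]
    design_info = dmatrix(formulas[-1], df).design_info
    params = pd.Series(full.params, index=design_info.column_names)
    return GLMPerformanceResult(terms=terms, family=family,
                                n_records=len(df), params=params)


def per_setsize_correlation(records: Sequence[NMRecord],
                            set_size: int) -> tuple[float, float]:
    """Pearson correlation between NM and performance at one set size."""
    sel = [r for r in records if r.set_size == set_size]
    if len(sel) < 3:
        raise ValueError(f"need >= 3 records at set size {set_size}")
    nm = np.array([r.nm for r in sel])
    perf = np.array([r.performance for r in sel])
    if np.ptp(nm) == 0 or np.ptp(perf) == 0:
        raise ValueError(
            f"correlation undefined at set size {set_size}: zero variance "
            "(ceiling or floor performance)"
        )
    r, p = stats.pearsonr(nm, perf)
    return float(r), float(p)
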