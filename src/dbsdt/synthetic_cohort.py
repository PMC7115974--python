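"""Synthetic cohorts with the statistical structure the analysis assumes.

The real cohort (children assessed for pallidal DBS, with 1-year BFMDRS-m
outcome) is access-restricted, so this module generates stand-in cohorts that
emulate its published marginals: roughly 60% positive outcome among acquired
dystonia cases at the any-improvement (>0%) threshold, 18/96 with unavailable
CMCT, and the etiology mix of the referral cohort.

The planted outcome model is

    pct_change = mu0 + beta_cmct * 1[CMCT abnormal]
               + beta_sev * max(0, baseline - s0) + Gaussian noise

so the outcome truly depends on CMCT status and on baseline severity above a
hinge cut-off ``s0``, while sex and MRI are pure noise by construction — a
feature-subset search over such a cohort should select CMCT (and severity) and
should not select sex or MRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from dbsdt.cohort_model import (
    Cohort,
    CohortError,
    LimbStatus,
    NeurophysStatus,
    PatientRecord,
    binarize_outcome,
    code_limb_status,
    default_schema,
    percent_improvement,
)

__all__ = ["SimParams", "default_params", "generate_cohort", "TABLE1_CMCT_COUNTS"]

# Referral-cohort etiology counts (patients with satisfactory CMCT data):
# isolated genetic, complex genetic, acquired CP, acquired metabolic,
# acquired other, acquired degenerative.
TABLE1_CMCT_COUNTS = (22, 21, 82, 19, 35, 12)

_BFM_LO, _BFM_HI = 5.0, 120.0


@dataclass
class SimParams:
    """Generator settings; defaults are the published study marginals.

    Probabilities for CMCT/SEP are unconditional category probabilities
    (``normal`` receives the remainder).  The outcome model coefficients are
    on the % change scale: ``mu0`` is the mean % change for a child with
    normal CMCT and baseline at or below ``s0``; ``beta_cmct`` (negative)
    shifts children with abnormal CMCT toward worse outcomes; ``beta_sev``
    adds % change per BFMDRS-m point of baseline severity above ``s0``.
    """

    n: int = 96
    etiology_probs: tuple[float, ...] = (0.0, 0.0, 82 / 148, 19 / 148, 35 / 148, 12 / 148)
    p_cmct_abnormal: float = 0.154
    p_cmct_na: float = 18 / 96
    p_sep_abnormal: float = 0.20
    p_sep_na: float = 42 / 96
    baseline_mean: float = 70.0
    baseline_sd: float = 25.0
    mu0: float = 5.0
    beta_cmct: float = -25.0
    beta_sev: float = 0.5
    s0: float = 80.0
    noise_sd: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_cmct_abnormal": self.p_cmct_abnormal,
            "p_cmct_na": self.p_cmct_na,
            "p_sep_abnormal": self.p_sep_abnormal,
            "p_sep_na": self.p_sep_na,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise CohortError(f"{name} = {p} outside [0, 1]")
        if self.p_cmct_abnormal + self.p_cmct_na > 1.0:
            raise CohortError("p_cmct_abnormal + p_cmct_na exceeds 1")
        if self.p_sep_abnormal + self.p_sep_na > 1.0:
            raise CohortError("p_sep_abnormal + p_sep_na exceeds 1")
        if len(self.etiology_probs) != 6:
            raise CohortError("etiology_probs must have 6 entries")
        if any(p < 0 for p in self.etiology_probs):
            raise CohortError("etiology_probs must be non-negative")
        if abs(sum(self.etiology_probs) - 1.0) > 1e-9:
            raise CohortError(f"etiology_probs sums to {sum(self.etiology_probs)}, not 1")
        if self.n < 1:
            raise CohortError("n must be positive")
        if self.baseline_sd <= 0 or self.noise_sd < 0:
            raise CohortError("baseline_sd must be > 0 and noise_sd >= 0")


def default_params(mode: str = "acquired") -> SimParams:
    """Study-condition defaults.

    ``"acquired"`` — the 96-child acquired-dystonia analysis cohort; etiology
    probabilities are the referral cohort's acquired groups renormalized.
    ``"full"`` — a 133-child whole cohort with the referral cohort's
    etiology proportions (genetic groups included).
    """
    if mode == "acquired":
        return SimParams()
    if mode == "full":
        total = sum(TABLE1_CMCT_COUNTS)
        return SimParams(
            n=133,
            etiology_probs=tuple(c / total for c in TABLE1_CMCT_COUNTS),
        )
    raise CohortError(f"unknown mode {mode!r}; expected 'acquired' or 'full'")


_ETIOLOGY_LEVELS = (
    "isolated_genetic",
    "complex_genetic",
    "acquired_cp",
    "acquired_metabolic",
    "acquired_other",
    "acquired_degenerative",
)


def _draw_limbs(
    status: NeurophysStatus, rng: np.random.Generator
) -> tuple[LimbStatus, ...]:
    """Expand a patient-level status to a consistent 4-limb recording list."""
    if status is NeurophysStatus.NA:
        return (LimbStatus.UNSATISFACTORY,) * 4
    if status is NeurophysStatus.ABNORMAL:
        n_abn = 1 + rng.binomial(3, 0.4)
        rest = [
            LimbStatus.NORMAL if rng.random() < 0.8 else LimbStatus.UNSATISFACTORY
            for _ in range(4 - n_abn)
        ]
        limbs = [LimbStatus.ABNORMAL] * n_abn + rest
    else:
        limbs = [
            LimbStatus.NORMAL if rng.random() < 0.85 else LimbStatus.UNSATISFACTORY
            for _ in range(4)
        ]
        if all(l is LimbStatus.UNSATISFACTORY for l in limbs):
            limbs[0] = LimbStatus.NORMAL
    rng.shuffle(limbs)
    return tuple(limbs)


def _draw_status(p_abnormal: float, p_na: float, n: int, rng: np.random.Generator):
    u = rng.random(n)
    out = np.full(n, "normal", dtype=object)
    out[u < p_abnormal] = "abnormal"
    out[(u >= p_abnormal) & (u < p_abnormal + p_na)] = "NA"
    return out


def generate_cohort(params: Optional[SimParams] = None, seed: Optional[int] = None) -> Cohort:
    """Generate a labelled synthetic cohort (deterministic given the seed).

    Labels are the any-improvement (>0% change) binarization; the continuous
    % change is kept on every record so downstream stages can re-binarize at
    other thresholds.  Limb-level CMCT/SEP lists are drawn consistently with
    the patient-level status.  Follow-up BFMDRS-m is derived from the planted
    % change and clipped to the scale range [0, 120] (the % change is then
    recomputed from the clipped score, so record fields stay consistent).
    """
    params = params if params is not None else default_params()
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n

    etiology_idx = rng.choice(6, size=n, p=np.asarray(params.etiology_probs))
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    mri = np.where(rng.random(n) < 0.5, "normal", "abnormal")
    cmct_status = _draw_status(params.p_cmct_abnormal, params.p_cmct_na, n, rng)
    sep_status = _draw_status(params.p_sep_abnormal, params.p_sep_na, n, rng)

    a = (_BFM_LO - params.baseline_mean) / params.baseline_sd
    b = (_BFM_HI - params.baseline_mean) / params.baseline_sd
    baseline = stats.truncnorm.rvs(
        a, b, loc=params.baseline_mean, scale=params.baseline_sd, size=n, random_state=rng
    )

    noise = rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd > 0 else np.zeros(n)
    pct = (
        params.mu0
        + params.beta_cmct * (cmct_status == "abnormal")
        + params.beta_sev * np.maximum(0.0, baseline - params.s0)
        + noise
    )

    records, labels = [], []
    for i in range(n):
        cmct = NeurophysStatus(cmct_status[i])
        sep = NeurophysStatus(sep_status[i])
        cmct_limbs = _draw_limbs(cmct, rng)
        sep_limbs = _draw_limbs(sep, rng)
        assert code_limb_status(cmct_limbs) is cmct
        assert code_limb_status(sep_limbs) is sep
        followup = float(np.clip(baseline[i] * (1.0 - pct[i] / 100.0), 0.0, _BFM_HI))
        pct_i = percent_improvement(float(baseline[i]), followup)
        rec = PatientRecord(
            id=f"S{i:04d}",
            sex=str(sex[i]),
            etiology=_ETIOLOGY_LEVELS[etiology_idx[i]],
            mri=str(mri[i]),
            baseline_bfm=float(baseline[i]),
            followup_bfm=followup,
            pct_change=pct_i,
            cmct_limbs=cmct_limbs,
            sep_limbs=sep_limbs,
            cmct=cmct,
            sep=sep,
        )
        records.append(rec)
        labels.append(binarize_outcome(pct_i, 0.0, "strict_gt"))
    cohort = Cohort(records, default_schema(), labels)
    cohort.validate()
    return cohort
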