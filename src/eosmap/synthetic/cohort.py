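"""Synthetic patient cohorts with AI scores, EoEHSS scores and severity.

Each slide receives the four whole-slide AI scores (PEC, SEC, PBZ, SBZ),
EoEHSS grade/stage scores (0..3) for the eight histologic features, and the
derived severity label.  The generator reproduces the statistical shape of
a real EoE cohort rather than any particular dataset:

- PEC is a zero-inflated, overdispersed count: inactive slides are mostly
  zero with a small sub-clinical tail (< 15), active slides draw a
  heavy-tailed negative binomial above the clinical cutoff of 15, reaching
  the hundreds.
- SEC is zero below the activity cutoff (no HPF can reach a count of 15 if
  the peak does not) and rises monotonically with PEC above it.
- The basal-zone driver mixes the realized eosinophil severity with an
  independent component, weighted by ``eos_bz_coupling``; PBZ is a bounded
  monotone transform of the driver, and SBZ rises with PBZ once PBZ clears
  the 15% spatial threshold.  With coupling 1 and no noise, PBZ is a strict
  monotone function of PEC; with coupling 0 it is independent of PEC.
- EoEHSS scores are noisy monotone bins of the matching AI score.  BZH
  grade uses the clinical epithelial-thickness cut points (15%, 33%, 66%);
  the gap the clinical scale leaves between "not present" and ">15%" is
  mapped to grade 1.  EI cut points are conventions (1, 15, 60 eosinophils
  for grade; 5%, 33%, 66% of qualifying HPFs for stage) and configurable.
- The severity label applies the remission rule: severe iff PEC >= 15 or
  the EoEHSS total exceeds 3 (see :mod:`eosmap.severity`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..severity import HSS_FEATURES, hss_total_from_row, severity_truth_row

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "COHORT_COLUMNS",
    "bzh_grade_from_fraction",
    "bzh_stage_from_fraction",
    "ei_grade_from_count",
    "ei_stage_from_fraction",
]

#: Mandated cohort-table columns, in order; the six remaining EoEHSS
#: feature grade/stage columns follow them.
COHORT_COLUMNS = [
    "patient_id",
    "slide_id",
    "pec",
    "sec",
    "pbz",
    "sbz",
    "ei_grade",
    "ei_stage",
    "bzh_grade",
    "bzh_stage",
    "hss_total",
    "severe",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``slides_per_patient`` is the per-patient maximum (1..3, uniform);
    ``activity_prevalence`` the probability a patient's slides are active
    (PEC >= 15); ``pec_dispersion`` the negative-binomial shape of the
    active tail (smaller = heavier tail); ``eos_bz_coupling`` the weight of
    the eosinophil severity in the basal-zone driver; ``noise_sd`` the
    Gaussian noise applied to the bounded scores and to the values binned
    into EoEHSS scores.
    """

    n_patients: int
    slides_per_patient: int = 3
    activity_prevalence: float = 0.45
    pec_dispersion: float = 1.2
    eos_bz_coupling: float = 0.6
    noise_sd: float = 0.05
    seed: int = 0
    active_pec_mean_excess: float = 35.0
    inactive_zero_prob: float = 0.5
    ei_grade_cuts: tuple[float, float, float] = (1, 15, 60)
    ei_stage_cuts: tuple[float, float, float] = (0.05, 0.33, 0.66)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 1 <= self.slides_per_patient <= 3:
            raise ValueError("slides_per_patient must lie in [1, 3]")
        if not 0.0 <= self.activity_prevalence <= 1.0:
            raise ValueError("activity_prevalence must lie in [0, 1]")
        if self.pec_dispersion <= 0:
            raise ValueError("pec_dispersion must be positive")
        if not 0.0 <= self.eos_bz_coupling <= 1.0:
            raise ValueError("eos_bz_coupling must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def bzh_grade_from_fraction(f: float) -> int:
    """BZH grade from the peak basal-zone thickness fraction.

    Clinical bins: 0 when BZH is absent, 1 for fractions up to 33%
    (the clinical scale's (0, 15%] gap is mapped to grade 1), 2 for
    33-66%, 3 above 66%.
    """
    if f <= 0:
        return 0
    if f < 0.33:
        return 1
    if f <= 0.66:
        return 2
    return 3


def bzh_stage_from_fraction(f: float) -> int:
    """BZH stage from the fraction of epithelium showing any BZH."""
    if f <= 0:
        return 0
    if f < 0.33:
        return 1
    if f <= 0.66:
        return 2
    return 3


def ei_grade_from_count(pec: float, cuts: tuple[float, float, float] = (1, 15, 60)) -> int:
    """EI grade from a (possibly noisy) peak eosinophil count."""
    return int(np.searchsorted(np.asarray(cuts), pec, side="right"))


def ei_stage_from_fraction(
    sec: float, cuts: tuple[float, float, float] = (0.05, 0.33, 0.66)
) -> int:
    """EI stage from a (possibly noisy) spatial eosinophil fraction."""
    if sec <= 0:
        return 0
    return int(np.searchsorted(np.asarray(cuts), sec, side="right"))


def _pec_severity(pec: np.ndarray) -> np.ndarray:
    """Saturating map of counts to a [0, 1) severity scale."""
    return pec / (pec + 25.0)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one synthetic cohort as a slide-level table.

    Deterministic for a fixed spec.  Columns are :data:`COHORT_COLUMNS`
    followed by the remaining six EoEHSS feature grade/stage columns.
    """
    rng = np.random.default_rng(spec.seed)

    patient_ids: list[str] = []
    slide_ids: list[str] = []
    active: list[bool] = []
    for p in range(spec.n_patients):
        pid = f"P{p:04d}"
        is_active = bool(rng.random() < spec.activity_prevalence)
        n_slides = int(rng.integers(1, spec.slides_per_patient + 1))
        for s in range(n_slides):
            patient_ids.append(pid)
            slide_ids.append(f"{pid}_S{s}")
            active.append(is_active)
    n = len(slide_ids)
    active_arr = np.array(active, dtype=bool)

    # --- PEC: zero-inflated overdispersed counts ---------------------------
    pec = np.zeros(n, dtype=int)
    k = spec.pec_dispersion
    mu = spec.active_pec_mean_excess
    n_act = int(active_arr.sum())
    if n_act:
        p_nb = k / (k + mu)
        pec[active_arr] = 15 + rng.negative_binomial(k, p_nb, size=n_act)
    n_inact = n - n_act
    if n_inact:
        zeros = rng.random(n_inact) < spec.inactive_zero_prob
        low = np.minimum(rng.negative_binomial(1.0, 1.0 / 5.0, size=n_inact), 14)
        pec[~active_arr] = np.where(zeros, 0, low)

    def noise(size: int) -> np.ndarray:
        return rng.normal(0.0, spec.noise_sd, size=size) if spec.noise_sd > 0 else np.zeros(size)

    # --- SEC: zero below the cutoff, monotone in PEC above it --------------
    sec = np.where(
        pec >= 15, np.clip((pec - 14.0) / (pec + 80.0) + noise(n), 0.0, 1.0), 0.0
    )

    # --- PBZ/SBZ: coupled to the realized eosinophil severity --------------
    c = spec.eos_bz_coupling
    driver = c * _pec_severity(pec.astype(float)) + (1.0 - c) * rng.random(n)
    pbz = np.clip(0.02 + 0.9 * driver + noise(n), 0.0, 1.0)
    sbz = np.where(
        pbz >= 0.15, np.clip((pbz - 0.15) / 0.85 * 0.9 + noise(n), 0.0, 1.0), 0.0
    )

    # --- EoEHSS scores: noisy monotone bins of the matching AI score -------
    pec_noisy = pec * (1.0 + noise(n) * 2.0)
    ei_grade = np.array([ei_grade_from_count(x, spec.ei_grade_cuts) for x in pec_noisy])
    ei_stage = np.array([ei_stage_from_fraction(x, spec.ei_stage_cuts) for x in sec + noise(n)])
    bzh_grade = np.array([bzh_grade_from_fraction(x) for x in pbz + noise(n)])
    bzh_stage = np.array([bzh_stage_from_fraction(x) for x in sbz + noise(n)])

    data: dict[str, np.ndarray] = {
        "patient_id": np.array(patient_ids),
        "slide_id": np.array(slide_ids),
        "pec": pec,
        "sec": sec,
        "pbz": pbz,
        "sbz": sbz,
        "ei_grade": ei_grade,
        "ei_stage": ei_stage,
        "bzh_grade": bzh_grade,
        "bzh_stage": bzh_stage,
    }

    # Remaining six features follow the slide's overall severity loosely.
    latent = 0.5 * _pec_severity(pec.astype(float)) + 0.5 * driver
    for feat in HSS_FEATURES:
        if feat in ("ei", "bzh"):
            continue
        for kind in ("grade", "stage"):
            raw = 3.0 * latent - 1.0 + rng.normal(0.0, 0.4 + spec.noise_sd, size=n)
            data[f"{feat}_{kind}"] = np.clip(np.round(raw), 0, 3).astype(int)

    df = pd.DataFrame(data)
    df["hss_total"] = df.apply(hss_total_from_row, axis=1)
    df["severe"] = df.apply(severity_truth_row, axis=1)
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    return df[COHORT_COLUMNS + extra]
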