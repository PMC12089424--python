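"""Synthetic three-group cohorts with correlated biomarkers, plus the
standard biomarker preprocessing steps (ICV adjustment, log transform,
z-scoring).

The generator draws, per person: a diagnostic group (CN / MCI / AD), a
latent cognition value from that group's normal distribution, and a set of
biomarkers that each combine a group-level shift with a loading on latent
cognition and independent residual noise.  Biomarkers are z-scored over the
full cohort.  Ground truth (latent cognition and the latent R-squared each
model should recover) is recorded so downstream recovery tests can compare
estimates against the generating process.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("CN", "MCI", "AD")

__all__ = [
    "BiomarkerSpec",
    "CohortSpec",
    "Cohort",
    "default_cohort_spec",
    "generate_cohort",
    "icv_adjust",
    "log_transform_wmh",
    "zscore",
]


@dataclass(frozen=True)
class BiomarkerSpec:
    """One biomarker: group-level targets plus a loading on latent cognition.

    ``group_means`` are the target z-scale means for (CN, MCI, AD);
    ``loading`` scales the within-group dependence on latent cognition;
    ``residual_sd`` is the independent within-person noise SD.
    """

    name: str
    group_means: tuple[float, float, float]
    loading: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError(f"residual_sd must be positive for {self.name}")


@dataclass(frozen=True)
class CohortSpec:
    n_per_group: tuple[int, int, int]
    group_cognition_means: tuple[float, float, float]
    group_cognition_sds: tuple[float, float, float]
    biomarkers: tuple[BiomarkerSpec, ...]
    phase_probabilities: tuple[float, float] = (0.5, 0.5)
    tracer_probabilities: tuple[float, float] = (0.75, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group):
            raise ValueError("group sizes must be nonnegative")
        if sum(self.n_per_group) == 0:
            raise ValueError("at least one group must be non-empty")
        if any(sd <= 0 for sd in self.group_cognition_sds):
            raise ValueError("group cognition SDs must be positive")
        for probs, label in (
            (self.phase_probabilities, "phase"),
            (self.tracer_probabilities, "tracer"),
        ):
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError(f"{label} probabilities must be nonnegative and sum to 1")


@dataclass
class Cohort:
    """Generated cohort: one row per person, with ground truth attached."""

    data: pd.DataFrame  # person_id, group, phase, tracer, true_cognition, biomarkers...
    spec: CohortSpec
    biomarker_names: tuple[str, ...]
    true_latent_r2: dict[str, float] = field(default_factory=dict)

    def write(self, data_path, metadata_path=None) -> None:
        self.data.to_csv(data_path, sep="\t", index=False)
        if metadata_path is not None:
            meta = {
                "spec": dataclasses.asdict(self.spec),
                "biomarker_names": list(self.biomarker_names),
                "true_latent_r2": self.true_latent_r2,
            }
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=2, default=list)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Cohort defaults: group sizes 482/430/172, memory-scale cognition
    means (0.86, 0.19, -0.79), and six biomarkers whose group-mean patterns
    follow the published z-score contrasts (volumes/thickness lower and
    amyloid/WMH higher in AD).  Loadings are chosen so single-biomarker
    full-sample R-squared spans roughly 0.08-0.38.
    """
    biomarkers = (
        BiomarkerSpec("wmh", (-0.23, 0.11, 0.36), loading=-0.12, residual_sd=0.95),
        BiomarkerSpec("amyloid", (-0.41, 0.10, 0.89), loading=-0.22, residual_sd=0.85),
        BiomarkerSpec("entorhinal_thickness", (0.45, -0.01, -1.22), loading=0.35, residual_sd=0.75),
        BiomarkerSpec("hippocampus", (0.47, -0.08, -1.10), loading=0.32, residual_sd=0.78),
        BiomarkerSpec("medial_temporal", (0.39, -0.04, -0.99), loading=0.22, residual_sd=0.85),
        BiomarkerSpec("lateral_temporal", (0.39, -0.05, -0.97), loading=0.22, residual_sd=0.85),
    )
    return CohortSpec(
        n_per_group=(482, 430, 172),
        group_cognition_means=(0.86, 0.19, -0.79),
        group_cognition_sds=(0.47, 0.51, 0.36),
        biomarkers=biomarkers,
        seed=seed,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort from ``spec``; reproducible given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    groups = np.repeat(np.arange(3), spec.n_per_group)
    n = groups.size
    mu = np.asarray(spec.group_cognition_means)[groups]
    sd = np.asarray(spec.group_cognition_sds)[groups]
    theta = rng.normal(mu, sd)
    phase = rng.choice([0, 1], size=n, p=spec.phase_probabilities)
    tracer = rng.choice([0, 1], size=n, p=spec.tracer_probabilities)

    cols: dict[str, np.ndarray] = {
        "person_id": np.array([f"P{i:05d}" for i in range(n)]),
        "group": np.asarray(GROUPS)[groups],
        "phase": phase,
        "tracer": tracer,
        "true_cognition": theta,
    }
    names = []
    for bm in spec.biomarkers:
        shift = np.asarray(bm.group_means)[groups]
        centered = theta - mu  # within-group deviation so group means hit targets
        raw = shift + bm.loading * centered + rng.normal(0.0, bm.residual_sd, size=n)
        cols[bm.name] = zscore(raw) if raw.std(ddof=1) > 0 else raw
        names.append(bm.name)

    df = pd.DataFrame(cols)
    cohort = Cohort(data=df, spec=spec, biomarker_names=tuple(names))
    cohort.true_latent_r2 = _latent_r2_by_model(df, names)
    return cohort


def _latent_r2_by_model(df: pd.DataFrame, biomarker_names: list[str]) -> dict[str, float]:
    """Realized latent R-squared of true cognition on phase + biomarker(s):
    OLS on the noiseless outcome, the target every downstream estimate
    should recover."""
    out = {}
    y = df["true_cognition"].to_numpy()
    for label, cols in [(bm, [bm]) for bm in biomarker_names] + [("all", biomarker_names)]:
        x = np.column_stack([np.ones(len(df)), df["phase"].to_numpy()] +
                            [df[c].to_numpy() for c in cols])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ beta
        out[label] = float(np.var(fitted, ddof=1) / np.var(y, ddof=1))
    return out


def icv_adjust(volume_raw: np.ndarray, icv_raw: np.ndarray) -> np.ndarray:
    """Remove intracranial-volume dependence from a regional volume:
    adjusted = raw - slope * (ICV - mean ICV), with slope from the
    least-squares regression of volume on ICV.

    The alternative regression direction (ICV on volume) is available via
    ``regress_icv_on_volume`` for comparison only.
    """
    return _icv_adjust_impl(volume_raw, icv_raw, regress_icv_on_volume=False)


def _icv_adjust_impl(
    volume_raw: np.ndarray, icv_raw: np.ndarray, regress_icv_on_volume: bool = False
) -> np.ndarray:
    v = np.asarray(volume_raw, dtype=float)
    icv = np.asarray(icv_raw, dtype=float)
    if v.shape != icv.shape or v.size < 3:
        raise ValueError("volume and ICV must be equal-length vectors with n >= 3")
    icv_c = icv - icv.mean()
    ss_icv = float(icv_c @ icv_c)
    if ss_icv == 0.0:
        raise ValueError("ICV is constant; adjustment slope undefined")
    if regress_icv_on_volume:
        v_c = v - v.mean()
        ss_v = float(v_c @ v_c)
        if ss_v == 0.0:
            raise ValueError("volume is constant; reversed slope undefined")
        slope = float(icv_c @ v) / ss_v
    else:
        slope = float(icv_c @ v) / ss_icv
    return v - slope * icv_c


def log_transform_wmh(wmh_cc: np.ndarray, zero_offset: float = 0.001) -> np.ndarray:
    """Natural log of white-matter-hyperintensity volumes (cc).

    Zeros are replaced by ``zero_offset`` with a logged warning; negative
    inputs are an error.
    """
    x = np.asarray(wmh_cc, dtype=float)
    if np.any(x < 0):
        raise ValueError("WMH volumes must be nonnegative")
    n_zero = int(np.sum(x == 0))
    if n_zero:
        logger.warning("log_transform_wmh: %d zero volumes replaced by offset %g", n_zero, zero_offset)
        x = np.where(x == 0, zero_offset, x)
    return np.log(x)


def zscore(values: np.ndarray) -> np.ndarray:
    """Center and scale to mean 0, SD 1 (denominator n-1)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd
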