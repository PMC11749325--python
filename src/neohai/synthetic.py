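"""Synthetic suspected-HAI cohort generator.

Patient-level data from the reference cohort are not publicly deposited, so
this module generates episode-level cohorts with the same statistical
structure, calibrated to the cohort's published marginals:

* 214 episodes with class mix proven/presumed/no HAI = 22/56/136;
* per-test positivity calibrated from the published diagnostic count
  quadruples (TP, TN, FP, FN) of the five candidate tests:
  P(test+ | any HAI) = TP/(TP+FN), P(test+ | no HAI) = FP/(FP+TN);
* per-class observed antibiotic LOT from a gamma distribution fitted by
  numeric search to the published medians/IQRs (proven 9 (7-14), presumed
  7 (5-9), no HAI 3 (2.5-3)), discretized to half-days;
* t24 CRP missing for a configurable minority (default 9/214).

CRP concentrations are class-conditionally log-normal around the 10 mg/L
cutoff; only the exceedance probability matters to the analysis, so the side
of the cutoff is drawn as a Bernoulli with the calibrated probability and
the magnitude from the matching truncated tail.  The four clinical NeoHoP
components are Bernoulli with a per-class prevalence solved so that
P(score >= 2 | class) matches the calibrated NeoHoP positivity, given the
class's CRP-component rate (components independent given class).

Every generated episode is internally consistent with its sampled class, so
the classification module recovers the intended label with zero
unclassifiable episodes (round-trip property).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy import optimize
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from .episodes import BloodCultureResult, EpisodeRecord
from .scoring import DEFAULT_CRP_CUTOFF, clip_to_device_range
from .stats import median_iqr

__all__ = [
    "DEFAULT_TEST_COUNTS",
    "LOT_TARGETS",
    "Calibration",
    "CohortConfig",
    "calibrate_from_counts",
    "generate_cohort",
    "cohort_report",
    "fit_gamma_to_median_iqr",
]

#: Default calibration counts (TP, TN, FP, FN) per candidate test, from the
#: reference cohort's published diagnostic accuracy table.
DEFAULT_TEST_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "crp_t0": (60, 135, 0, 19),
    "neohop_t0": (70, 133, 3, 8),
    "crp_t24": (65, 131, 0, 9),
    "crp_t0_and_t24_combined": (76, 131, 0, 2),
    "neohop_t0_and_crp_t24_combined": (77, 133, 3, 1),
}

#: Observed antibiotic LOT targets per class: (median, q1, q3) in days.
LOT_TARGETS: dict[str, tuple[float, float, float]] = {
    "proven": (9.0, 7.0, 14.0),
    "presumed": (7.0, 5.0, 9.0),
    "none": (3.0, 2.5, 3.0),
}


@dataclass(frozen=True)
class Calibration:
    """Per-class positivity probabilities derived from count quadruples.

    ``p_pos`` maps test name -> (P(pos | any HAI), P(pos | no HAI));
    ``component_prob`` maps class band ("hai" / "none") -> prevalence of each
    of the four clinical NeoHoP components.
    """

    p_pos: dict[str, tuple[float, float]]
    component_prob: dict[str, float]


def _neohop_positive_prob(p_crp: float, q: float) -> float:
    """P(score >= 2) with CRP component ~ Bern(p_crp), 4 clinical ~ Bern(q)."""
    p_k0 = (1 - q) ** 4
    p_k1 = 4 * q * (1 - q) ** 3
    # score >= 2 <=> (crp and k >= 1) or (not crp and k >= 2)
    return p_crp * (1 - p_k0) + (1 - p_crp) * (1 - p_k0 - p_k1)


def calibrate_from_counts(
    counts: Mapping[str, tuple[int, int, int, int]] = DEFAULT_TEST_COUNTS,
) -> Calibration:
    """Turn per-test (TP, TN, FP, FN) counts into generator probabilities.

    Raises ``ValueError`` listing the violation when counts are inconsistent
    (negative cells or empty diseased/non-diseased margins).
    """
    p_pos: dict[str, tuple[float, float]] = {}
    for name, quad in counts.items():
        if len(quad) != 4:
            raise ValueError(f"{name}: expected (tp, tn, fp, fn), got {quad!r}")
        tp, tn, fp, fn = quad
        if min(tp, tn, fp, fn) < 0:
            raise ValueError(f"{name}: counts must be >= 0, got {quad!r}")
        if tp + fn == 0 or tn + fp == 0:
            raise ValueError(f"{name}: needs diseased and non-diseased episodes")
        p_pos[name] = (tp / (tp + fn), fp / (fp + tn))

    if "crp_t0" not in p_pos or "neohop_t0" not in p_pos:
        raise ValueError("calibration requires crp_t0 and neohop_t0 counts")

    component_prob: dict[str, float] = {}
    for band, idx in (("hai", 0), ("none", 1)):
        p_crp = p_pos["crp_t0"][idx]
        target = p_pos["neohop_t0"][idx]
        f = lambda q: _neohop_positive_prob(p_crp, q) - target  # noqa: E731
        lo, hi = 0.0, 1.0
        if f(lo) > 0 or f(hi) < 0:
            raise ValueError(
                f"NeoHoP positivity target {target:.3f} not attainable for band {band!r}"
            )
        component_prob[band] = float(optimize.brentq(f, lo, hi, xtol=1e-10))
    return Calibration(p_pos=p_pos, component_prob=component_prob)


@lru_cache(maxsize=None)
def fit_gamma_to_median_iqr(
    median: float, q1: float, q3: float
) -> tuple[float, float]:
    """Fit gamma (shape, scale) matching a target median and quartiles.

    Nelder-Mead on log-parameters minimising the squared quantile error; the
    distributional form is cosmetic, only the summaries matter downstream.
    """

    def loss(log_params):
        shape, scale = np.exp(log_params)
        q = gamma_dist.ppf([0.25, 0.5, 0.75], a=shape, scale=scale)
        return float(np.sum((q - np.array([q1, median, q3])) ** 2))

    start = np.log([4.0, max(median, 0.5) / 4.0])
    res = optimize.minimize(loss, start, method="Nelder-Mead", options={"xatol": 1e-6})
    shape, scale = np.exp(res.x)
    return float(shape), float(scale)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults for the generator.

    ``class_probs`` is (proven, presumed, none); ``t24_missingness_prob``
    reflects the 9/214 episodes without a t24 measurement; ``cons_fraction``
    is the share of proven episodes grown as CoNS (of which
    ``cons_paired_fraction`` satisfy the paired-culture criterion);
    ``contaminant_prob`` is the rate of contaminant-organism cultures among
    culture-non-probative classes.
    """

    n_episodes: int = 214
    class_probs: tuple[float, float, float] = (22 / 214, 56 / 214, 136 / 214)
    test_counts: Mapping[str, tuple[int, int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_TEST_COUNTS)
    )
    lot_targets: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(LOT_TARGETS)
    )
    crp_cutoff: float = DEFAULT_CRP_CUTOFF
    crp_log_sigma: float = 0.6
    t24_missingness_prob: float = 9 / 214
    cons_fraction: float = 0.5
    cons_paired_fraction: float = 0.6
    contaminant_prob: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_episodes < 0:
            raise ValueError("n_episodes must be >= 0")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("class_probs must be 3 non-negative values summing to 1")
        for name in (
            "t24_missingness_prob",
            "cons_fraction",
            "cons_paired_fraction",
            "contaminant_prob",
        ):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.crp_log_sigma <= 0:
            raise ValueError("crp_log_sigma must be > 0")


def _truncated_lognormal(
    rng: np.random.Generator, positive_side: bool, cutoff: float, sigma: float
) -> float:
    """Draw from log-normal centred on the cutoff, truncated to one side.

    Reported to 0.1 mg/L, rounded away from the cutoff so the drawn side is
    never flipped by the reporting precision.
    """
    # With mu = ln(cutoff) the cutoff sits at the median; conditioning on the
    # requested side leaves the marginal exceedance to the Bernoulli draw.
    u = rng.uniform(0.5, 1.0) if positive_side else rng.uniform(0.0, 0.5)
    z = norm.ppf(u)
    value = round(float(np.exp(np.log(cutoff) + sigma * z)), 1)
    if positive_side:
        return max(value, cutoff)
    return min(value, cutoff - 0.1)


def _draw_crp(
    rng: np.random.Generator, p_pos: float, cutoff: float, sigma: float
) -> float:
    positive = rng.uniform() < p_pos
    value = clip_to_device_range(_truncated_lognormal(rng, positive, cutoff, sigma))
    return value if not positive else max(value, cutoff)


def _draw_lot(
    rng: np.random.Generator,
    label: str,
    targets: Mapping[str, tuple[float, float, float]],
) -> float:
    shape, scale = fit_gamma_to_median_iqr(*targets[label])
    value = float(rng.gamma(shape, scale))
    value = round(value * 2.0) / 2.0  # half-day resolution
    if label == "none":
        # antibiotics stopped within 72 h: at most 3 days, at least one dose
        return float(min(max(value, 0.5), 3.0))
    # antibiotics continued >= 5 days (proven/presumed definitions)
    return float(max(value, 5.0))


def _draw_culture(
    rng: np.random.Generator, label: str, config: CohortConfig
) -> tuple[BloodCultureResult, bool]:
    """Culture result plus whether the definition CRP must exceed the cutoff."""
    if label == "proven":
        if rng.uniform() < config.cons_fraction:
            if rng.uniform() < config.cons_paired_fraction:
                return (
                    BloodCultureResult(
                        organism_class="cons",
                        n_positive_cultures=2,
                        paired_cultures_24_48h_apart=True,
                        collected_after_72h_admission=True,
                        clinical_signs_present=True,
                    ),
                    False,
                )
            # single CoNS culture: adjudication as infection requires a
            # definition CRP >= cutoff together with clinical signs
            return (
                BloodCultureResult(
                    organism_class="cons",
                    n_positive_cultures=1,
                    collected_after_72h_admission=True,
                    clinical_signs_present=True,
                ),
                True,
            )
        return (
            BloodCultureResult(
                organism_class="pathogen",
                n_positive_cultures=1,
                collected_after_72h_admission=True,
                clinical_signs_present=True,
            ),
            False,
        )
    contaminated = rng.uniform() < config.contaminant_prob
    if contaminated:
        culture = BloodCultureResult(
            organism_class="contaminant_other",
            n_positive_cultures=1,
            collected_after_72h_admission=True,
            clinical_signs_present=(label == "presumed"),
        )
    else:
        culture = BloodCultureResult(
            organism_class="negative",
            clinical_signs_present=(label == "presumed"),
        )
    return culture, False


def generate_cohort(
    config: CohortConfig = CohortConfig(),
) -> tuple[list[EpisodeRecord], list[str]]:
    """Generate a cohort; returns (records, intended class labels).

    Reproducible given ``config.seed``; each episode's fields are mutually
    consistent with its sampled class, so classification recovers the label.
    """
    calibration = calibrate_from_counts(config.test_counts)
    rng = np.random.default_rng(config.seed)
    labels_all = ("proven", "presumed", "none")
    n = config.n_episodes
    if n == 0:
        return [], []
    classes = rng.choice(3, size=n, p=np.asarray(config.class_probs, dtype=float))
    n_subjects = max(1, int(round(0.84 * n)))
    subject_ids = rng.integers(0, n_subjects, size=n)
    cutoff, sigma = config.crp_cutoff, config.crp_log_sigma

    records: list[EpisodeRecord] = []
    labels: list[str] = []
    for i in range(n):
        label = labels_all[classes[i]]
        band = "none" if label == "none" else "hai"
        idx = 1 if band == "none" else 0

        crp_t0 = _draw_crp(rng, calibration.p_pos["crp_t0"][idx], cutoff, sigma)
        crp_t24: float | None
        t24_missing = rng.uniform() < config.t24_missingness_prob
        crp_t24 = (
            None
            if t24_missing
            else _draw_crp(rng, calibration.p_pos["crp_t24"][idx], cutoff, sigma)
        )

        culture, needs_high_crp = _draw_culture(rng, label, config)
        # Definition (laboratory) CRP: forced to the side of the cutoff the
        # class definition requires, so classification is exact.
        if label == "presumed" or needs_high_crp:
            lab_crp = _truncated_lognormal(rng, True, cutoff, sigma)
        elif label == "none":
            lab_crp = _truncated_lognormal(rng, False, cutoff, sigma)
        else:  # pathogen / paired-CoNS proven: definition CRP unconstrained
            lab_crp = _truncated_lognormal(rng, rng.uniform() < 0.9, cutoff, sigma)

        q = calibration.component_prob[band]
        clinical = rng.uniform(size=4) < q

        lot = _draw_lot(rng, label, config.lot_targets)
        records.append(
            EpisodeRecord(
                episode_id=f"E{i:05d}",
                subject_id=f"S{subject_ids[i]:05d}",
                postnatal_age_days=int(
                    np.clip(round(np.exp(rng.normal(np.log(16.0), 0.8))), 4, 120)
                ),
                crt_gt_3s=bool(clinical[0]),
                lethargy=bool(clinical[1]),
                abdominal_distention=bool(clinical[2]),
                cvc_in_situ_or_48h=bool(clinical[3]),
                crp_t0=crp_t0,
                crp_t24=crp_t24,
                lab_crp=lab_crp,
                culture=culture,
                observed_lot_days=lot,
                antibiotics_continued_ge_5d=(label != "none"),
                symptoms_short_lived=(label == "none"),
                abx_stopped_within_72h=(label == "none"),
            )
        )
        labels.append(label)
    return records, labels


def cohort_report(records: list[EpisodeRecord], labels: list[str]) -> dict:
    """Descriptive cohort summary: class mix, per-class LOT, missingness."""
    if not records:
        raise ValueError("cohort_report requires a non-empty cohort")
    n = len(records)
    out: dict = {"n_episodes": n, "classes": {}, "lot_days": {}}
    for label in ("proven", "presumed", "none"):
        idx = [i for i, lab in enumerate(labels) if lab == label]
        out["classes"][label] = {
            "n": len(idx),
            "pct": round(100.0 * len(idx) / n, 1),
        }
        if idx:
            s = median_iqr([records[i].observed_lot_days for i in idx])
            out["lot_days"][label] = {"median": s.median, "q1": s.q1, "q3": s.q3}
        else:
            out["lot_days"][label] = {"median": None, "q1": None, "q3": None}
    overall = median_iqr([r.observed_lot_days for r in records])
    out["lot_days"]["overall"] = {
        "median": overall.median,
        "q1": overall.q1,
        "q3": overall.q3,
    }
    out["missing_crp_t24"] = sum(r.crp_t24 is None for r in records)
    out["missing_crp_t0"] = sum(r.crp_t0 is None for r in records)
    return out
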