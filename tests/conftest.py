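import pytest

from neohai.episodes import BloodCultureResult, EpisodeRecord
from neohai.synthetic import CohortConfig, generate_cohort


def make_record(**overrides) -> EpisodeRecord:
    """A valid baseline episode (no-HAI-like) with selective overrides.

    Culture fields can be overridden flat (e.g. ``organism_class="cons"``)
    or via a full ``culture=BloodCultureResult(...)``.
    """
    culture_fields = {
        "organism_class": "negative",
        "n_positive_cultures": 0,
        "paired_cultures_24_48h_apart": False,
        "collected_after_72h_admission": False,
        "clinical_signs_present": False,
    }
    for key in list(overrides):
        if key in culture_fields:
            culture_fields[key] = overrides.pop(key)
    culture = overrides.pop("culture", BloodCultureResult(**culture_fields))
    base = dict(
        episode_id="E1",
        subject_id="S1",
        postnatal_age_days=16,
        crt_gt_3s=False,
        lethargy=False,
        abdominal_distention=False,
        cvc_in_situ_or_48h=False,
        crp_t0=4.0,
        crp_t24=4.0,
        lab_crp=None,
        culture=culture,
        observed_lot_days=3.0,
        antibiotics_continued_ge_5d=False,
        symptoms_short_lived=True,
        abx_stopped_within_72h=True,
    )
    base.update(overrides)
    return EpisodeRecord(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded synthetic cohort at the study's size."""
    records, labels = generate_cohort(CohortConfig(n_episodes=214, seed=11))
    return records, labels


@pytest.fixture(scope="session")
def large_cohort():
    """A seeded synthetic cohort large enough for calibration recovery."""
    records, labels = generate_cohort(CohortConfig(n_episodes=10_000, seed=7))
    return records, labels
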