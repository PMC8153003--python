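import dataclasses

import pandas as pd
import pytest

import stressmirseg as s


@pytest.fixture(scope="session")
def default_cohort():
    """One default 46-mouse cohort (12/18 HIP+mPFC, 6/10 HT)."""
    return s.generate_cohort(dataclasses.replace(s.CohortConfig(), seed=7))


@pytest.fixture(scope="session")
def default_scores(default_cohort):
    records, _ = default_cohort
    return s.composite_scores(records)


@pytest.fixture(scope="session")
def default_rq(default_cohort, default_scores):
    _, ct = default_cohort
    phen = default_scores.set_index("mouse_id")["phenotype"]
    return s.quantify_cohort(ct, phen)


def toy_behavior(stressed_rows):
    """3 controls with ASR1 {90,100,110}, ASR2 {95,100,105} and behavioral
    measures at OF {90,100,110}, EPM {95,100,105}, SM {80,100,120}, plus
    the given stressed mice."""
    rows = [
        dict(mouse_id="c1", group="control", areas="HIP", asr_baseline=500.0,
             asr1_pct=90.0, asr2_pct=95.0, of_measure=90.0, epm_measure=95.0,
             sm_measure=80.0, latent_susceptibility=0.0),
        dict(mouse_id="c2", group="control", areas="HIP", asr_baseline=500.0,
             asr1_pct=100.0, asr2_pct=100.0, of_measure=100.0,
             epm_measure=100.0, sm_measure=100.0, latent_susceptibility=0.0),
        dict(mouse_id="c3", group="control", areas="HIP", asr_baseline=500.0,
             asr1_pct=110.0, asr2_pct=105.0, of_measure=110.0,
             epm_measure=105.0, sm_measure=120.0, latent_susceptibility=0.0),
    ]
    for i, extra in enumerate(stressed_rows, 1):
        row = dict(mouse_id=f"s{i}", group="stressed", areas="HIP",
                   asr_baseline=500.0, asr1_pct=100.0, asr2_pct=100.0,
                   of_measure=100.0, epm_measure=100.0, sm_measure=100.0,
                   latent_susceptibility=0.0)
        row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)
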