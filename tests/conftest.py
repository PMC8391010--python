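import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def short_record():
    """One minute of clean synthetic signal with exact beat ground truth."""
    from cuffbp.synth import SynthConfig, generate_record

    return generate_record(SynthConfig(duration_minutes=1.0, seed=42))


@pytest.fixture(scope="session")
def cleaned_record():
    """A QC-cleaned 12-minute record with beat annotations and norm stats."""
    from cuffbp.beats import detect_beats
    from cuffbp.qc import QCRuleConfig, apply_qc
    from cuffbp.synth import SynthConfig, generate_record
    from cuffbp.windows import fit_norm_stats, normalize

    rec, truth = generate_record(SynthConfig(duration_minutes=12.0, seed=7))
    clean, report = apply_qc(
        rec, QCRuleConfig(min_total_minutes=5, truncate_minutes=12)
    )
    assert clean is not None
    ann = detect_beats(clean.channels["ABP"], clean.fs)
    stats = fit_norm_stats([clean])
    norm = normalize(clean, stats)
    return {"clean": clean, "norm": norm, "ann": ann, "stats": stats, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
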