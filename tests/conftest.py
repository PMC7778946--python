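import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def synth_data():
    """Default synthetic dataset: 10 tissues x 8 samples, 200 planted HK
    transcripts and 100 violators per criterion."""
    from hkref import synth

    return synth.generate(synth.SynthConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline(synth_data):
    """Full-data pipeline products on the default synthetic dataset."""
    from hkref import detect, io, normalize

    expr = normalize.normalize_by_tissue(
        synth_data.counts, synth_data.metadata, synth_data.annotation
    )
    stats = detect.stability_stats(expr)
    ann = io.annotation_frame(synth_data.annotation)
    calls = detect.call_hk(stats, ann)
    return {
        "data": synth_data,
        "expr": expr,
        "stats": stats,
        "ann": ann,
        "calls": calls,
    }
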