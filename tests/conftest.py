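import pytest

from finchsong.features import estimate_scaling, extract_features
from finchsong.segmentation import SyllableSegment
from finchsong.synth import (
    RenditionJitter,
    SyllableArchetype,
    default_archetypes,
    synth_syllable,
)

SR = 40_000


@pytest.fixture(scope="session")
def sr():
    return SR


def _tracks_for(archetype, jitter, n, seed0):
    out = []
    for k in range(n):
        w = synth_syllable(archetype, jitter, SR, seed=seed0 + k)
        seg = SyllableSegment(0.0, len(w) / SR, archetype.label)
        out.append(extract_features(w, SR, seg))
    return out


@pytest.fixture(scope="session")
def harmonic_archetype():
    return SyllableArchetype("h", "harmonic_stack", 600.0, 600.0, n_harmonics=4,
                             duration_ms=120)


@pytest.fixture(scope="session")
def noise_archetype():
    return SyllableArchetype("x", "noise_burst", noise_band=(2500.0, 7500.0),
                             duration_ms=110)


@pytest.fixture(scope="session")
def jittered_tracks(harmonic_archetype, noise_archetype):
    """Ten jittered renditions each of a harmonic and a noise-burst type."""
    jit = RenditionJitter(0.03, 0.05, 0.05)
    return {
        "h": _tracks_for(harmonic_archetype, jit, 10, seed0=100),
        "x": _tracks_for(noise_archetype, jit, 10, seed0=200),
    }


@pytest.fixture(scope="session")
def scaling(jittered_tracks):
    return estimate_scaling(jittered_tracks["h"] + jittered_tracks["x"])


@pytest.fixture(scope="session")
def small_repertoire():
    grammar, archetypes = default_archetypes(4)
    return grammar, archetypes
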