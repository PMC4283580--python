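import numpy as np
import pandas as pd
import pytest

from funnorm.data_model import ChannelData, ProbeManifest, SampleSheet
from funnorm.simulate import SimulationConfig, simulate_dataset

#: Small probe complement reused by fixtures that do not need sex chromosomes.
SMALL_PROBES = {"autosome.II": 800, "autosome.I_GREEN": 200,
                "autosome.I_RED": 200, "X.II": 60, "X.I_GREEN": 10,
                "X.I_RED": 10, "Y.II": 20, "Y.I_GREEN": 4, "Y.I_RED": 4}


@pytest.fixture(scope="session")
def toy_manifest() -> ProbeManifest:
    """Six probes covering all three design types plus two controls."""
    rows = [
        ("p1", "II", "chr1", False, "", "a1", ""),
        ("p2", "II", "chr2", False, "", "a2", ""),
        ("p3", "I_GREEN", "chr1", False, "", "a3", "a4"),
        ("p4", "I_GREEN", "X", False, "", "a5", "a6"),
        ("p5", "I_RED", "chr1", False, "", "a7", "a8"),
        ("p6", "I_RED", "Y", False, "", "a9", "a10"),
        ("neg1", "II", "", True, "NEGATIVE", "a11", ""),
        ("neg2", "II", "", True, "NEGATIVE", "a12", ""),
    ]
    return ProbeManifest.from_frame(pd.DataFrame(
        rows, columns=["probe_id", "design_type", "chromosome", "is_control",
                       "control_category", "address_a", "address_b"]))


@pytest.fixture(scope="session")
def toy_channels(toy_manifest) -> ChannelData:
    """Deterministic intensities: green = 10*i, red = 1000 + 10*i for
    address index i (1-based)."""
    addresses = [f"a{i}" for i in range(1, 13)]
    samples = ["s1", "s2"]
    green = pd.DataFrame(
        {s: [10.0 * i + 100.0 * j for i in range(1, 13)]
         for j, s in enumerate(samples)}, index=pd.Index(addresses))
    red = pd.DataFrame(
        {s: [1000.0 + 10.0 * i + 100.0 * j for i in range(1, 13)]
         for j, s in enumerate(samples)}, index=pd.Index(addresses))
    return ChannelData(green, red)


@pytest.fixture(scope="session")
def toy_samplesheet() -> SampleSheet:
    return SampleSheet.from_frame(pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "sex": ["MALE", "FEMALE"],
        "plate": ["plate1", "plate1"],
        "slide": ["slide1", "slide1"],
        "row": [1, 2],
        "column": [1, 1],
        "group": ["control", "case"],
        "replicate_of": ["", ""],
    }))


@pytest.fixture(scope="session")
def small_dataset():
    """12-sample, ~1300-probe dataset with all control categories."""
    cfg = SimulationConfig(seed=11, n_samples=12, probe_counts=SMALL_PROBES,
                           n_dmp=20)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_raw(small_dataset):
    from funnorm.data_model import preprocess_raw

    return preprocess_raw(small_dataset.channels, small_dataset.manifest)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
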