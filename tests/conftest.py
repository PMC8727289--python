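import pytest

from epimrd import AmpliconRegion, RegionPanel, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def toy_region():
    """A 4-CpG region, hypermethylated in AML (healthy = unmethylated)."""
    return AmpliconRegion(
        region_id="toy",
        anchor_cpg="cg_toy",
        chrom="chr1",
        cpg_positions=(100, 110, 120, 130),
        target_index=0,
        direction="hyper_in_aml",
    )


@pytest.fixture(scope="session")
def toy_panel(toy_region):
    return RegionPanel((toy_region,))
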