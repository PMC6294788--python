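import pytest

from dosecnv import SimConfig, call_cnvs, run_depth_pipeline, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded desk-scale cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def called_cohort(default_cohort):
    """The default cohort with its depth pipeline run and CNVs called."""
    c = default_cohort
    bundle = run_depth_pipeline(
        c.counts, c.totals, c.probe_map,
        n_components=c.config.n_batch_factors,
    )
    calls = call_cnvs(bundle.svd_zrpkm, c.probe_map, threshold=1.5, min_probes=3)
    return c, bundle, calls
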