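"""Shared fixtures: small synthetic datasets and the replicated factor grids.

Everything is generated in memory at test time; no data files ship with the
package.  The replicated end-to-end grids are expensive (they drive the
factor-effect recovery checks) and are therefore computed once per session.
"""

import pytest

from boarscan import stats, synthetic


@pytest.fixture(scope="session")
def tiny_dataset():
    """10 boars with 48x48 images: enough for structural pipeline tests."""
    return synthetic.make_dataset(10, seed=7, size=48)


@pytest.fixture(scope="session")
def replicate_reports():
    """Main-effects reports for 20 replicate end-to-end grids.

    Each replicate simulates a fresh 60-boar dataset and runs the full
    16-configuration grid with 10 runs, then fits the main-effects model
    for recall and precision.  Shared by the factor-effect recovery checks.
    """
    reports = []
    for rep in range(20):
        ds = synthetic.make_dataset(60, seed=1000 + rep)
        results = stats.run_grid(ds, n_runs=10, base_seed=2000 + rep)
        reports.append({
            "recall": stats.fit_main_effects(results, "recall"),
            "precision": stats.fit_main_effects(results, "precision"),
        })
    return reports
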