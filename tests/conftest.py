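import numpy as np
import pytest

import pimsflow as pf
from pimsflow.synthetic import gaussian_profile


@pytest.fixture(scope="session")
def line_geometry():
    return pf.ScanGeometry(
        probe_rate=5.0, acquisition_rate=2.0, strip_step=80.0, scans_per_line=400
    )


@pytest.fixture(scope="session")
def single_proteoform_run(line_geometry):
    """5000-ion single 9 kDa proteoform line scan plus its survey result."""
    spec = pf.ProteoformSpec(
        id="p9k",
        monoisotopic_mass=9000.0,
        total_ion_budget=5000,
        charge_mu=10.0,
        charge_sigma=1.5,
        spatial_profile=gaussian_profile(400, 0.5, 0.12),
    )
    ds = pf.simulate_line_scan(
        [spec], line_geometry, noise_ion_rate=0.0, calib_slope=1.0,
        slope_noise_cv=0.005, seed=11,
    )
    res = pf.run_survey(ds.ions, calib_slope=1.0, seed=11)
    return spec, ds, res


@pytest.fixture(scope="session")
def mixture_run(line_geometry):
    """Ten-proteoform survey with noise; shared by selection/allocation tests."""
    rng = np.random.default_rng(21)
    masses = np.array([5200, 6800, 8300, 9900, 11600, 13500, 15800, 18500, 22000, 26000], dtype=float)
    budgets = [3000, 2500, 400, 1800, 900, 2200, 600, 1200, 800, 1000]
    specs = [
        pf.ProteoformSpec(
            id=f"p{i}",
            monoisotopic_mass=m,
            total_ion_budget=b,
            charge_mu=max(5.0, m / 900.0),
            charge_sigma=1.5,
            spatial_profile=gaussian_profile(400, rng.uniform(0.15, 0.85), rng.uniform(0.06, 0.15)),
        )
        for i, (m, b) in enumerate(zip(masses, budgets))
    ]
    ds = pf.simulate_line_scan(
        specs, line_geometry, noise_ion_rate=0.5, calib_slope=1.0,
        slope_noise_cv=0.005, seed=21,
    )
    res = pf.run_survey(ds.ions, calib_slope=1.0, rel_abundance_threshold=0.005,
                        min_ion_count=5, seed=21)
    return specs, ds, res
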