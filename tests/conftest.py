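import pytest

from swsx import (
    UnitCell,
    WedgePlan,
    generate_ground_truth,
    make_polymorphs,
    simulate_wedges,
)
from swsx.scale_merge import fit_wedge_scales, merge


@pytest.fixture(scope="session")
def cubic_cell():
    return UnitCell(25.0, 25.0, 25.0)


@pytest.fixture(scope="session")
def wilson_gt(cubic_cell):
    """Wilson-mode ground truth in point group 23 to 2.0 A."""
    return generate_ground_truth(
        cubic_cell, "23", 2.0, mode="wilson",
        params={"C": 1.0, "B_true": 5.0}, seed=3,
    )


@pytest.fixture(scope="session")
def small_wedges(wilson_gt):
    """Twelve 5-degree wedges with mild noise (shared read-only fixture)."""
    poly = make_polymorphs(wilson_gt, 1, 1.0, seed=3)
    plan = WedgePlan(
        wedge_deg=5.0, frame_deg=0.2, dose_total=1.0e7, n0=2.0e-3,
        sigma_sys=0.02, bg_rate=1.0,
    )
    return simulate_wedges(poly, 12, plan, seed=4)


@pytest.fixture(scope="session")
def small_merged(small_wedges):
    scaling = fit_wedge_scales(small_wedges)
    return merge(small_wedges, scaling), scaling
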