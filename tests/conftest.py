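"""Shared fixtures: the packaged base case, its calibration (expensive, so
session-scoped) and the resulting mortality schedule."""

from __future__ import annotations

import pytest

from copdce import fixtures, mortality


@pytest.fixture(scope="session")
def base_params():
    return fixtures.base_case_parameters()


@pytest.fixture(scope="session")
def calibration(base_params):
    return mortality.calibrate(base_params.anchors, base_params)


@pytest.fixture(scope="session")
def calibrated_params(base_params, calibration):
    return mortality.apply_scales(
        base_params, calibration.state_scale, calibration.sevex_scale
    )


@pytest.fixture(scope="session")
def calibrated_schedule(calibrated_params):
    return mortality.build_schedule(
        calibrated_params.background_mortality,
        calibrated_params.excess_mortality,
        calibrated_params.settings,
    )
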