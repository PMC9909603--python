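"""Shared fixtures: trained networks reused across the heavier tests.

The two session-scoped studies below are deliberately run at a reduced
"desk" scale (fewer training instances, epochs and grid points than the
full study) so the whole suite trains on one CPU in minutes; the
qualitative behavior they probe does not depend on the full scale.
"""

import numpy as np
import pytest

from binauralnet import pipeline


@pytest.fixture(scope="session")
def pop_study():
    """Proof-of-principle study: parameter-based network, full protocol.

    100k instances as in the published protocol; epochs capped by early
    stopping on validation RMSE.
    """
    cfg = pipeline.preset("desk", seed=0, pop_patience=150, pop_restarts=1)
    return pipeline.run_proof_of_principle(cfg, eval_every=10)


@pytest.fixture(scope="session")
def wave_study(tmp_path_factory):
    """Waveform study at desk scale: small beta grid, reduced epochs."""
    cfg = pipeline.preset("desk", seed=0)
    out = tmp_path_factory.mktemp("wave_study")
    return pipeline.run_waveform_study(cfg, out_dir=out)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
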