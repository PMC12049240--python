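import numpy as np
import pytest

import modespec as ms


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture
def two_atom_block_file(tmp_path):
    """2-frame, 2-atom block trajectory with velocities (0.1, 0, 0) Å/fs."""
    path = tmp_path / "traj.blk"
    lines = []
    for _ in range(2):
        lines.append("2")
        lines.append("H 0.0 0.0 0.0 0.1 0.0 0.0")
        lines.append("O 1.0 0.0 0.0 0.1 0.0 0.0")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def nm_block_file(tmp_path):
    """3-frame, 2-mode momentum file with frames (1,0), (0,1), (-1,0)."""
    path = tmp_path / "momenta.blk"
    path.write_text("2\n1.0 0.0\n2\n0.0 1.0\n2\n-1.0 0.0\n")
    return path


@pytest.fixture
def single_mode_system():
    """Analytic single-mode fixture at 1500 cm^-1, paper-scale sampling."""
    spec = ms.OscillatorSpec(frequencies_cm1=(1500.0,), seed=3)
    traj, basis, nm = ms.generate_harmonic_trajectory(spec, 10.0, 2500)
    return spec, traj, basis, nm
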