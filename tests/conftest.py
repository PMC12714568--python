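import pandas as pd
import pytest

import protonex as px


@pytest.fixture
def probe_c13():
    """Aromatic carbon at a 600 MHz (1H) spectrometer."""
    return px.Probe("U23-C6", 150.9)


@pytest.fixture
def probe_n15():
    """Imino nitrogen at a 900 MHz (1H) spectrometer."""
    return px.Probe("U38-N3", 91.2)


@pytest.fixture
def probe_h1():
    """Imino proton at 600 MHz."""
    return px.Probe("U38-H3", 600.0)


@pytest.fixture
def relax():
    return px.RelaxParams(2.0, 20.0)


def make_r1rho_dataset(
    probes_dw: dict[px.Probe, float],
    p_minor: float,
    k_ex: float,
    sigma: float,
    seed: int,
    relax: px.RelaxParams | None = None,
    powers=(100.0, 200.0, 400.0, 900.0),
    offsets_per_power: int = 7,
    ph: float = 6.4,
) -> pd.DataFrame:
    """Two-state R1rho table over a practical spin-lock grid (shared helper)."""
    relax = relax or px.RelaxParams(2.0, 20.0)
    grid = px.default_spinlock_grid(powers, offsets_per_power, 3.0)
    frames = []
    for i, (probe, dw) in enumerate(probes_dw.items()):
        model = px.two_state(p_minor, k_ex, dw)
        frames.append(
            px.gen_r1rho_dataset(
                model, relax, [probe], grid,
                px.NoiseModel(sigma, seed + 97 * i), ph=ph,
            )
        )
    return pd.concat(frames, ignore_index=True)
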