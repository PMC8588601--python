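"""Shared fixtures: small seeded synthetic inputs for every stage."""

import numpy as np
import pytest

from wormscreen.ranking import Corpus
from wormscreen.rtquic import RtQuicPlate, WellInfo
from wormscreen.simulate import WormSimConfig, simulate_worm_recording


# Desk-scale recording geometry: same worm aspect ratio as the full-size
# default (length:width = 10:1) on a small arena so rendering stays fast.
SMALL_ARENA = (360, 270)
SMALL_WORM = dict(worm_length=60.0, worm_width=6.0)


def small_worm_config(**overrides) -> WormSimConfig:
    base = dict(
        n_worms=10, n_frames=40, fps=2.0, arena=SMALL_ARENA,
        coil_prob=0.2, turn_prob=0.2, seed=11, **SMALL_WORM,
    )
    base.update(overrides)
    return WormSimConfig(**base)


@pytest.fixture(scope="session")
def mixed_recording():
    """A short recording with all three postures present."""
    config = small_worm_config()
    stack, truth = simulate_worm_recording(config)
    return config, stack, truth


@pytest.fixture()
def toy_corpus() -> Corpus:
    """Two known and two candidate entities; cand_good shares the known
    vocabulary, cand_far is disjoint."""
    docs = {
        "k1_d": "alpha beta gamma alpha".split(),
        "k2_d": "alpha beta delta".split(),
        "cg_d": "alpha beta gamma".split(),
        "cf_d": "omega psi chi phi".split(),
    }
    return Corpus(
        documents=docs,
        entity_map={"k1": {"k1_d"}, "k2": {"k2_d"}, "cand_good": {"cg_d"},
                    "cand_far": {"cf_d"}},
        roles={"k1": "known", "k2": "known", "cand_good": "candidate",
               "cand_far": "candidate"},
    )


def make_plate(
    sample_endpoints: dict[str, list[float]],
    background_rows: list[list[float]],
    times=None,
) -> RtQuicPlate:
    """Plate with given per-replicate endpoint values (flat kinetics)."""
    if times is None:
        times = np.array([0.0, 30.0, 60.0])
    rows, well_map = [], {}
    w = 0
    for sample, endpoints in sample_endpoints.items():
        for r, endpoint in enumerate(endpoints):
            curve = np.full(len(times), endpoints[r] * 0 + 100.0)
            curve[-1] = endpoint
            well_map[f"W{w:02d}"] = WellInfo(sample=sample, replicate=r, is_background=False)
            rows.append(curve)
            w += 1
    for b, row in enumerate(background_rows):
        well_map[f"B{b:02d}"] = WellInfo(sample="diluent", replicate=b, is_background=True)
        rows.append(np.asarray(row, dtype=float))
    return RtQuicPlate(readings=np.array(rows), times=np.asarray(times), well_map=well_map)
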