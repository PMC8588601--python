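"""Synthetic RT-QuIC plates.

Background (diluent) wells read Gaussian noise around a flat mean.
Wells of truly seeding samples add a logistic thioflavin-T rise of
configurable amplitude after a lag time (with per-replicate lag jitter);
wells of non-seeding samples stay at background. Readings run every
``read_interval`` minutes up to ``duration`` hours, the assay schedule
being 45-minute reads over 60 hours by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..rtquic import RtQuicPlate, WellInfo


@dataclass
class RtQuicSimConfig:
    """One simulated plate; ``groups`` maps group name to its fraction of
    truly seeding samples (a single anonymous group uses ``frac_seeded``).

    ``background_mean`` = 1200 rfu with ``background_sd`` = 400 rfu puts
    the mean-plus-5-SD threshold near 3200 rfu, a realistic scale for the
    assay; seeded wells rise by ``seeded_amplitude`` rfu with logistic
    midpoint at ``lag_time`` hours.
    """

    n_samples_per_group: int = 8
    replicates_per_sample: int = 4
    n_background_wells: int = 8
    background_mean: float = 1200.0
    background_sd: float = 400.0
    seeded_amplitude: float = 50_000.0
    lag_time: float = 20.0  # h, logistic midpoint
    rise_rate: float = 0.5  # 1/h logistic steepness
    lag_jitter_sd: float = 2.0  # h, per-replicate midpoint jitter
    read_interval: float = 45.0  # min
    duration: float = 60.0  # h
    frac_seeded: float = 0.5
    groups: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.read_interval <= 0:
            raise ValueError("duration and read_interval must be positive")
        if self.replicates_per_sample < 1:
            raise ValueError("need at least one replicate per sample")
        if self.background_sd < 0:
            raise ValueError("background_sd must be nonnegative")
        if self.n_background_wells < 2:
            raise ValueError("need at least two background wells")
        fracs = (self.groups or {"": self.frac_seeded}).values()
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("seeded fractions must be in [0, 1]")


def simulate_rtquic_plate(
    config: RtQuicSimConfig,
) -> tuple[RtQuicPlate, dict[str, bool]]:
    """Generate one plate and the per-sample seeding ground truth.

    Within each group, ``round(frac_seeded * n)`` samples are truly
    seeding, chosen at random. Returns the plate and a mapping
    sample -> truly-seeding flag.
    """
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.duration + 1e-9, config.read_interval / 60.0)
    groups = config.groups or {"group": config.frac_seeded}

    rows: list[np.ndarray] = []
    well_map: dict[str, WellInfo] = {}
    truth: dict[str, bool] = {}
    well_no = 0

    def noise() -> np.ndarray:
        if config.background_sd == 0:
            return np.zeros(times.size)
        return rng.normal(0.0, config.background_sd, size=times.size)

    for group, frac in groups.items():
        n = config.n_samples_per_group
        n_seeded = int(round(frac * n))
        seeded_flags = np.zeros(n, dtype=bool)
        seeded_flags[rng.permutation(n)[:n_seeded]] = True
        for s in range(n):
            sample = f"{group}_s{s:02d}" if group else f"s{s:02d}"
            truth[sample] = bool(seeded_flags[s])
            for r in range(config.replicates_per_sample):
                curve = config.background_mean + noise()
                if seeded_flags[s] and config.seeded_amplitude > 0:
                    mid = config.lag_time + rng.normal(0.0, config.lag_jitter_sd)
                    curve = curve + config.seeded_amplitude / (
                        1.0 + np.exp(-config.rise_rate * (times - mid))
                    )
                well = f"W{well_no:03d}"
                well_no += 1
                well_map[well] = WellInfo(
                    sample=sample, replicate=r, is_background=False, group=group or None
                )
                rows.append(curve)

    for b in range(config.n_background_wells):
        well = f"BG{b:02d}"
        well_map[well] = WellInfo(sample="diluent", replicate=b, is_background=True)
        rows.append(config.background_mean + noise())

    plate = RtQuicPlate(readings=np.array(rows), times=times, well_map=well_map)
    return plate, truth
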