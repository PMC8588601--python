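"""RT-QuIC seeding-positivity calling and group comparison.

A plate holds thioflavin-T (ThT) fluorescence kinetics (relative
fluorescence units, rfu) for sample wells and diluent-only background
wells, read at fixed intervals (every 45 min up to 60 h by default).
The positivity threshold is the mean background fluorescence plus five
standard deviations; a replicate well is positive when its endpoint
reading strictly exceeds that threshold, and a sample is positive when
at least one of its replicates is. Group positivity counts feed a
two-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import ContingencyTable2x2, fisher_exact_two_sided

DEFAULT_ENDPOINT_H = 60.0
N_BACKGROUND_SD = 5.0


@dataclass
class WellInfo:
    sample: str
    replicate: int
    is_background: bool
    group: str | None = None


@dataclass
class RtQuicPlate:
    """Kinetic rfu readings with a well -> (sample, replicate) map."""

    readings: np.ndarray  # (n_wells, n_timepoints) rfu
    times: np.ndarray  # hours, strictly increasing
    well_map: dict[str, WellInfo]  # well id -> metadata; order matches rows
    wells: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.readings = np.asarray(self.readings, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.readings.ndim != 2:
            raise ValueError("readings must be (n_wells, n_timepoints)")
        if self.readings.shape != (len(self.well_map), self.times.size):
            raise ValueError("readings shape must match well_map and times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.wells = list(self.well_map)
        counts = {}
        for info in self.well_map.values():
            if not info.is_background:
                counts[info.sample] = counts.get(info.sample, 0) + 1
        if counts and len(set(counts.values())) > 1:
            raise ValueError(f"unequal replicate counts per sample: {counts}")
        if sum(info.is_background for info in self.well_map.values()) < 2:
            raise ValueError("need at least two background wells")

    @property
    def background_wells(self) -> list[str]:
        return [w for w, info in self.well_map.items() if info.is_background]

    @property
    def sample_wells(self) -> list[str]:
        return [w for w, info in self.well_map.items() if not info.is_background]

    @property
    def samples(self) -> list[str]:
        seen: list[str] = []
        for w in self.sample_wells:
            s = self.well_map[w].sample
            if s not in seen:
                seen.append(s)
        return seen

    def row(self, well: str) -> np.ndarray:
        return self.readings[self.wells.index(well)]


@dataclass
class RtQuicCalls:
    threshold: float
    replicate_positive: dict[str, bool]  # well -> call
    sample_positive: dict[str, bool]
    mean_curves: dict[str, np.ndarray]


def compute_threshold(plate: RtQuicPlate, n_sd: float = N_BACKGROUND_SD) -> float:
    """Mean background fluorescence plus ``n_sd`` standard deviations.

    Background statistics pool every timepoint of every diluent well;
    the SD is the sample standard deviation (divisor n - 1).
    """
    rows = [plate.row(w) for w in plate.background_wells]
    pooled = np.concatenate(rows)
    sd = pooled.std(ddof=1) if pooled.size > 1 else 0.0
    return float(pooled.mean() + n_sd * sd)


def _endpoint_index(plate: RtQuicPlate, endpoint_h: float) -> int:
    within = np.nonzero(plate.times <= endpoint_h)[0]
    if within.size == 0:
        raise ValueError(f"no timepoint at or before {endpoint_h} h")
    return int(within[-1])


def call_replicates(
    plate: RtQuicPlate,
    threshold: float,
    endpoint_h: float = DEFAULT_ENDPOINT_H,
    max_over_time: bool = False,
) -> dict[str, bool]:
    """Per-well positivity at the assay endpoint.

    A replicate is positive iff its reading at the last timepoint at or
    before ``endpoint_h`` strictly exceeds the threshold. The non-default
    ``max_over_time`` mode instead tests the well's maximum reading.
    """
    j = _endpoint_index(plate, endpoint_h)
    calls = {}
    for w in plate.sample_wells:
        row = plate.row(w)
        value = row[: j + 1].max() if max_over_time else row[j]
        calls[w] = bool(value > threshold)
    return calls


def call_samples(
    replicate_calls: dict[str, bool], well_map: dict[str, WellInfo]
) -> tuple[dict[str, bool], dict[str, int]]:
    """Sample positive iff at least one replicate is positive.

    Returns per-sample calls and per-sample positive-replicate counts.
    """
    samples: dict[str, list[bool]] = {}
    for well, call in replicate_calls.items():
        info = well_map[well]
        if info.is_background:
            continue
        samples.setdefault(info.sample, []).append(call)
    if not samples:
        raise ValueError("no sample wells among the calls")
    positive = {s: any(calls) for s, calls in samples.items()}
    n_pos = {s: sum(calls) for s, calls in samples.items()}
    return positive, n_pos


def group_contingency(
    sample_positive: dict[str, bool], groups: dict[str, str]
) -> tuple[ContingencyTable2x2, float, list[str]]:
    """2x2 positives/negatives by group, with the Fisher exact p-value.

    ``groups`` maps sample -> group label; exactly two groups are
    required. Rows follow sorted group labels.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    counts = {g: [0, 0] for g in labels}
    for sample, pos in sample_positive.items():
        g = groups[sample]
        counts[g][0 if pos else 1] += 1
    table = ContingencyTable2x2(
        a=counts[labels[0]][0],
        b=counts[labels[0]][1],
        c=counts[labels[1]][0],
        d=counts[labels[1]][1],
    )
    return table, fisher_exact_two_sided(table), labels


def mean_curves(
    plate: RtQuicPlate,
    replicate_calls: dict[str, bool],
    sample_positive: dict[str, bool],
) -> dict[str, np.ndarray]:
    """Per-sample mean kinetic curve.

    Positive samples average their positive replicates; negative samples
    average their negative replicates.
    """
    curves: dict[str, np.ndarray] = {}
    for sample in plate.samples:
        wells = [
            w
            for w in plate.sample_wells
            if plate.well_map[w].sample == sample
            and replicate_calls[w] == sample_positive[sample]
        ]
        curves[sample] = np.mean([plate.row(w) for w in wells], axis=0)
    return curves


def call_plate(
    plate: RtQuicPlate,
    endpoint_h: float = DEFAULT_ENDPOINT_H,
    n_sd: float = N_BACKGROUND_SD,
    max_over_time: bool = False,
) -> RtQuicCalls:
    """Threshold, replicate and sample calls, and mean curves in one pass."""
    threshold = compute_threshold(plate, n_sd)
    rep = call_replicates(plate, threshold, endpoint_h, max_over_time)
    sample_pos, _ = call_samples(rep, plate.well_map)
    curves = mean_curves(plate, rep, sample_pos)
    return RtQuicCalls(
        threshold=threshold,
        replicate_positive=rep,
        sample_positive=sample_pos,
        mean_curves=curves,
    )


def plate_to_frame(plate: RtQuicPlate) -> pd.DataFrame:
    """Plate as a tidy DataFrame (well, sample, replicate, is_background,
    one ``t_{hours}h`` column per timepoint)."""
    meta = pd.DataFrame(
        {
            "well": plate.wells,
            "sample": [plate.well_map[w].sample for w in plate.wells],
            "replicate": [plate.well_map[w].replicate for w in plate.wells],
            "is_background": [plate.well_map[w].is_background for w in plate.wells],
        }
    )
    values = pd.DataFrame(
        plate.readings, columns=[f"t_{t:.2f}h" for t in plate.times]
    )
    return pd.concat([meta, values], axis=1)


def frame_to_plate(df: pd.DataFrame) -> RtQuicPlate:
    """Inverse of :func:`plate_to_frame`."""
    time_cols = [c for c in df.columns if c.startswith("t_") and c.endswith("h")]
    times = np.array([float(c[2:-1]) for c in time_cols])
    well_map = {
        str(r.well): WellInfo(
            sample=str(r.sample),
            replicate=int(r.replicate),
            is_background=bool(r.is_background),
        )
        for r in df.itertuples()
    }
    return RtQuicPlate(
        readings=df[time_cols].to_numpy(float), times=times, well_map=well_map
    )
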