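"""Peak/valley classification of scaled profiles and cascade ordering.

Each scaled profile is classified by its first prominent interior
extremum: a peak or valley whose deviation from the initial sample
exceeds E_th (default 0.5 of the dynamic range).  Profiles whose putative
extrema all deviate by less than E_th0 (default 0.1) are monotone; by
convention a monotone decay peaks at the first sample age t0 and a
monotone increase has its valley at t0, so both participate in cascade
orderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hmfnet.containers import Profile, ProfileSet

DEFAULT_E_TH = 0.5
DEFAULT_E_TH0 = 0.1

#: Call types that carry a peak time, in cascade order of preference.
PEAK_CALLS = ("peak", "monotone_decay")
VALLEY_CALLS = ("valley", "monotone_increase")


@dataclass
class ExtremumCall:
    """Peak/valley/monotone classification of one scaled profile."""

    strain: str
    organ: str
    gene: str
    call: str  # peak | valley | monotone_increase | monotone_decay | none
    time: float | None
    deviation: float | None
    constant: bool = False


def _interior_extrema(values: np.ndarray) -> list[tuple[int, str]]:
    """(index, kind) of strict interior local extrema of a sampled sequence."""
    out = []
    for i in range(1, values.size - 1):
        if values[i] > values[i - 1] and values[i] > values[i + 1]:
            out.append((i, "peak"))
        elif values[i] < values[i - 1] and values[i] < values[i + 1]:
            out.append((i, "valley"))
    return out


def classify_extrema(
    profile: Profile,
    e_th: float = DEFAULT_E_TH,
    e_th0: float = DEFAULT_E_TH0,
) -> ExtremumCall:
    """Classify one scaled profile by its first prominent extremum.

    Scans interior local extrema in time order and returns the first one
    whose deviation |E(t_x) - E(t_0)| exceeds ``e_th``.  If no extremum
    qualifies and every putative extremum deviates by less than
    ``e_th0``, the profile is monotone, with direction given by the sign
    of the least-squares slope over all samples; otherwise no call is
    made.  Constant profiles are flagged and uncalled.
    """
    values = profile.scaled
    if values is None:
        raise ValueError("profile must be scaled before classification")
    times = profile.times
    if np.all(values == values[0]):
        return ExtremumCall(*profile.key, call="none", time=None, deviation=None, constant=True)

    candidates = _interior_extrema(values) if values.size >= 3 else []
    deviations = [abs(values[i] - values[0]) for i, _ in candidates]
    for (i, kind), dev in zip(candidates, deviations):
        if dev > e_th:
            return ExtremumCall(*profile.key, call=kind, time=float(times[i]), deviation=float(dev))
    if all(dev < e_th0 for dev in deviations):
        slope = np.polyfit(times, values, 1)[0]
        if slope < 0.0:
            return ExtremumCall(
                *profile.key,
                call="monotone_decay",
                time=float(times[0]),
                deviation=float(abs(values[-1] - values[0])),
            )
        if slope > 0.0:
            return ExtremumCall(
                *profile.key,
                call="monotone_increase",
                time=float(times[0]),
                deviation=float(abs(values[-1] - values[0])),
            )
    return ExtremumCall(*profile.key, call="none", time=None, deviation=None)


def classify_profiles(
    profiles: ProfileSet,
    e_th: float = DEFAULT_E_TH,
    e_th0: float = DEFAULT_E_TH0,
) -> list[ExtremumCall]:
    return [classify_extrema(p, e_th=e_th, e_th0=e_th0) for p in profiles]


def calls_frame(calls: list[ExtremumCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain": [c.strain for c in calls],
            "organ": [c.organ for c in calls],
            "gene": [c.gene for c in calls],
            "call": [c.call for c in calls],
            "time": [c.time for c in calls],
            "deviation": [c.deviation for c in calls],
        }
    )


def order_cascade(
    calls: list[ExtremumCall],
    by: str = "peak",
    reference_strain: str = "disease",
) -> tuple[list[ExtremumCall], pd.DataFrame]:
    """Order profiles of the reference strain by extremum time.

    ``by="peak"`` selects peak calls together with monotone decays (whose
    peak sits at t0); ``by="valley"`` mirrors this for valleys and
    monotone increases.  Ties are broken by (organ, gene) label.  The
    returned timing table pairs, per qualifying profile, the extremum
    time in the reference strain with the time in every other strain
    (NaN where the other strain makes no qualifying call), supporting
    cross-strain quadrant comparisons.
    """
    if by not in ("peak", "valley"):
        raise ValueError("by must be 'peak' or 'valley'")
    wanted = PEAK_CALLS if by == "peak" else VALLEY_CALLS

    qualifying = [
        c for c in calls if c.strain == reference_strain and c.call in wanted
    ]
    ordered = sorted(qualifying, key=lambda c: (c.time, c.organ, c.gene))

    other_strains = sorted({c.strain for c in calls} - {reference_strain})
    lookup = {
        (c.strain, c.organ, c.gene): c.time
        for c in calls
        if c.call in wanted
    }
    rows = []
    for c in ordered:
        row = {
            "organ": c.organ,
            "gene": c.gene,
            "call": c.call,
            f"t_{reference_strain}": c.time,
        }
        for s in other_strains:
            row[f"t_{s}"] = lookup.get((s, c.organ, c.gene), np.nan)
        rows.append(row)
    return ordered, pd.DataFrame(rows)
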