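"""In-memory containers shared across the pipeline.

A :class:`Profile` holds the mean expression trajectory of one
(strain, organ, gene) triple; a :class:`ProfileSet` is the keyed collection
of all such trajectories.  Node order within a strain is frozen as
organ-major, gene-minor (lexicographic), because the interaction matrix K
is meaningless without a fixed ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd


@dataclass
class Profile:
    """Mean expression trajectory of one (strain, organ, gene)."""

    strain: str
    organ: str
    gene: str
    times: np.ndarray  # sample ages, weeks, strictly increasing
    mean: np.ndarray  # replicate-averaged expression (-ddCt units)
    scaled: np.ndarray | None = None  # min-max scaled to [0, 1]
    n_reps: np.ndarray | None = None
    smin: float | None = None  # stored min/max so scaling is invertible
    smax: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        if self.scaled is not None:
            self.scaled = np.asarray(self.scaled, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("profile times must be strictly increasing")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.strain, self.organ, self.gene)

    @property
    def record_length(self) -> float:
        """T = last - first sample time (weeks)."""
        return float(self.times[-1] - self.times[0])


class ProfileSet:
    """Collection of expression profiles keyed by (strain, organ, gene)."""

    def __init__(self, profiles: Iterable[Profile] = ()):
        self._profiles: dict[tuple[str, str, str], Profile] = {}
        for p in profiles:
            self.add(p)

    def add(self, profile: Profile) -> None:
        self._profiles[profile.key] = profile

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self):
        return iter(sorted(self._profiles.values(), key=lambda p: p.key))

    def __getitem__(self, key: tuple[str, str, str]) -> Profile:
        return self._profiles[key]

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self._profiles

    @property
    def strains(self) -> list[str]:
        return sorted({p.strain for p in self._profiles.values()})

    def nodes(self, strain: str) -> list[tuple[str, str]]:
        """Frozen node order for one strain: organ-major, gene-minor."""
        return sorted(
            (p.organ, p.gene) for p in self._profiles.values() if p.strain == strain
        )

    def for_strain(self, strain: str) -> list[Profile]:
        """Profiles of one strain in the frozen node order."""
        return [self[(strain, organ, gene)] for organ, gene in self.nodes(strain)]

    def subset(
        self,
        organs: Iterable[str] | None = None,
        genes: Iterable[str] | None = None,
    ) -> "ProfileSet":
        organs = set(organs) if organs is not None else None
        genes = set(genes) if genes is not None else None
        kept = [
            replace(p)
            for p in self._profiles.values()
            if (organs is None or p.organ in organs)
            and (genes is None or p.gene in genes)
        ]
        return ProfileSet(kept)

    def t0(self, strain: str | None = None) -> float:
        """Earliest sample age across (a strain's) profiles, in weeks."""
        profs = (
            self._profiles.values()
            if strain is None
            else [p for p in self._profiles.values() if p.strain == strain]
        )
        return min(float(p.times[0]) for p in profs)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view (strain, organ, gene, age_weeks, mean, scaled, n_reps)."""
        rows = []
        for p in self:
            for i, t in enumerate(p.times):
                rows.append(
                    {
                        "strain": p.strain,
                        "organ": p.organ,
                        "gene": p.gene,
                        "age_weeks": t,
                        "mean": p.mean[i],
                        "scaled": None if p.scaled is None else p.scaled[i],
                        "n_reps": None if p.n_reps is None else int(p.n_reps[i]),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProfileSet":
        ps = cls()
        for (strain, organ, gene), grp in df.groupby(
            ["strain", "organ", "gene"], sort=True
        ):
            grp = grp.sort_values("age_weeks")
            scaled = grp["scaled"].to_numpy(dtype=float) if "scaled" in grp else None
            if scaled is not None and np.all(pd.isna(scaled)):
                scaled = None
            n_reps = grp["n_reps"].to_numpy() if "n_reps" in grp else None
            ps.add(
                Profile(
                    strain=strain,
                    organ=organ,
                    gene=gene,
                    times=grp["age_weeks"].to_numpy(dtype=float),
                    mean=grp["mean"].to_numpy(dtype=float),
                    scaled=scaled,
                    n_reps=n_reps,
                )
            )
        return ps


def node_label(organ: str, gene: str) -> str:
    return f"{organ}|{gene}"


@dataclass
class RunInfo:
    """Provenance attached to derived artifacts (seeds, grids, subsets)."""

    seed: int | None = None
    params: dict = field(default_factory=dict)
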