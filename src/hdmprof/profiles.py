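"""Enumeration and ranking of sensitization profiles.

A profile is a patient's exact positive set: the subset of panel molecules
to which they are sensitized. Each sensitized patient contributes to
exactly one profile (a patient positive to three molecules counts toward
that 3-set only, never its subsets), so profile counts sum exactly to the
number of sensitized patients. All-negative patients have no profile.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import ConsistencyError
from .panel_io import Cohort
from .sensitization import SensitizationMatrix, group_mask
from .summary import compute_share

PROFILE_SEPARATOR = "+"


@dataclass(frozen=True)
class Profile:
    """An exact positive molecule set with its patient count and share.

    ``members`` is in canonical panel order; ``share_pct`` is the percentage
    of the group's sensitized-to-any patients carrying exactly this set.
    """

    members: tuple[str, ...]
    count: int
    share_pct: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ConsistencyError("a profile must contain at least one molecule")

    @property
    def label(self) -> str:
        return PROFILE_SEPARATOR.join(self.members)


@dataclass
class ProfileTable:
    """Profiles sorted by count descending; ties broken by fewer members,
    then canonical panel order of the member tuple."""

    profiles: list[Profile]
    group: str
    n_sensitized: int

    @property
    def n_distinct(self) -> int:
        return len(self.profiles)


def classify_profile(profile: Profile) -> str:
    """``"mono"`` for a single-molecule profile, ``"poly"`` otherwise."""
    return "mono" if len(profile.members) == 1 else "poly"


def enumerate_profiles(cohort: Cohort, matrix: SensitizationMatrix, group: str = "all") -> ProfileTable:
    """Tally each sensitized patient's exact positive set within a group.

    Shares use the group's sensitized-to-any count as denominator. An
    all-negative group yields an empty table.
    """
    if matrix.n_patients != len(cohort):
        raise ValueError("matrix is not aligned with cohort")
    mask = group_mask(cohort, group)
    panel = matrix.panel
    counts: Counter[tuple[str, ...]] = Counter()
    for row in matrix.values[mask]:
        members = tuple(panel[j] for j in range(len(panel)) if row[j])
        if members:
            counts[members] += 1
    n_sensitized = sum(counts.values())
    order = {m: i for i, m in enumerate(panel)}
    profiles = [
        Profile(members, n, compute_share(n, n_sensitized))
        for members, n in counts.items()
    ]
    profiles.sort(key=lambda p: (-p.count, len(p.members), tuple(order[m] for m in p.members)))
    return ProfileTable(profiles, group, n_sensitized)


def top_profiles(table: ProfileTable, k: int) -> list[tuple[tuple[str, ...], float]]:
    """First ``k`` (members, share_pct) entries of the ranked table.

    Asking for more profiles than exist returns all of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return [(p.members, p.share_pct) for p in table.profiles[:k]]
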