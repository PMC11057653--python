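"""Sleep-stage label sets.

AASM scoring distinguishes wake, three NREM stages (N1, N2, N3) and REM.
Consumer wearables usually collapse these to a four-class scheme in which
N1+N2 become "light" and N3 becomes "deep" sleep.  Both vocabularies are
shipped here, together with the total mapping from fine to coarse labels
that every hypnogram-producing component validates against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

WAKE = "wake"
N1 = "N1"
N2 = "N2"
N3 = "N3"
REM = "REM"
UNSCORED = "unscored"

LIGHT = "light"
DEEP = "deep"

FINE_STAGES = (WAKE, N1, N2, N3, REM, UNSCORED)


@dataclass(frozen=True)
class StageLabelSet:
    """A named, ordered stage vocabulary plus its mapping from AASM stages.

    Parameters
    ----------
    name
        Identifier, e.g. ``"four"``.
    labels
        Ordered tuple of stage names; must be unique.
    mapping
        Total map from the fine AASM stages (wake, N1, N2, N3, REM,
        unscored) onto ``labels``.
    """

    name: str
    labels: tuple[str, ...]
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"duplicate labels in StageLabelSet {self.name!r}")
        missing = set(FINE_STAGES) - set(self.mapping)
        if missing:
            raise ValueError(
                f"mapping of StageLabelSet {self.name!r} is not total; "
                f"missing fine stages: {sorted(missing)}"
            )
        bad = set(self.mapping.values()) - set(self.labels)
        if bad:
            raise ValueError(
                f"mapping of StageLabelSet {self.name!r} targets unknown "
                f"labels: {sorted(bad)}"
            )

    def coarsen(self, fine_stage: str) -> str:
        """Map one fine (AASM) stage onto this set's vocabulary."""
        try:
            return self.mapping[fine_stage]
        except KeyError:
            raise ValueError(f"unknown fine stage {fine_stage!r}") from None


#: Wearable-style four-class set: wake / light (N1+N2) / deep (N3) / REM.
FOUR_CLASS = StageLabelSet(
    name="four",
    labels=(WAKE, LIGHT, DEEP, REM),
    mapping={
        WAKE: WAKE,
        N1: LIGHT,
        N2: LIGHT,
        N3: DEEP,
        REM: REM,
        UNSCORED: WAKE,
    },
)

#: Six-class set keeping the AASM stages distinct plus an unscored bucket.
#: The composition of six-class scoring differs between devices; this set is
#: a configurable default, not a standard.
SIX_CLASS = StageLabelSet(
    name="six",
    labels=(WAKE, N1, N2, N3, REM, UNSCORED),
    mapping={s: s for s in FINE_STAGES},
)

LABEL_SETS = {s.name: s for s in (FOUR_CLASS, SIX_CLASS)}
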