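"""Record types shared by the survival and immunohistochemistry stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

REGIONS = ("Tu", "Im", "Sd")
MARKERS = ("CD20", "CD79a")
HIGH, LOW = "high", "low"


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in months and a death/censor flag."""

    patient_id: str
    time_months: float
    event: int
    group: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.time_months) or self.time_months < 0:
            raise ValidationError(
                f"patient {self.patient_id}: time must be finite and >= 0, "
                f"got {self.time_months}"
            )
        if self.event not in (0, 1):
            raise ValidationError(
                f"patient {self.patient_id}: event must be 0 or 1, "
                f"got {self.event!r}"
            )
        if self.group is not None and self.group not in (HIGH, LOW):
            raise ValidationError(
                f"patient {self.patient_id}: group must be 'high'/'low', "
                f"got {self.group!r}"
            )


@dataclass(frozen=True)
class IHCCountRecord:
    """Manual B-cell counts for one patient, marker and tissue region.

    Counts are cells per high-power field (20x) in three randomly chosen
    fields; ``mean_count`` is their arithmetic mean. Regions: tumor (Tu),
    infiltrative margin (Im), distant stroma (Sd).
    """

    patient_id: str
    marker: str
    region: str
    counts: tuple[float, float, float]
    kappa_positive: bool | None = None
    igm_positive: bool | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValidationError(
                f"patient {self.patient_id}: region must be one of "
                f"{REGIONS}, got {self.region!r}"
            )
        if len(self.counts) != 3:
            raise ValidationError(
                f"patient {self.patient_id}: expected 3 field counts, "
                f"got {len(self.counts)}"
            )
        for c in self.counts:
            if not np.isfinite(c) or c < 0:
                raise ValidationError(
                    f"patient {self.patient_id} ({self.marker}/{self.region}):"
                    f" negative or non-finite count {c}"
                )

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.counts))


@dataclass
class GroupAssignment:
    """Per-patient high/low label with the rule that produced it."""

    labels: dict
    provenance: str  # "cluster_derived" or "mean_split"
    rule: str = ""

    def __post_init__(self):
        if self.provenance not in ("cluster_derived", "mean_split"):
            raise ValidationError(
                f"unknown provenance {self.provenance!r}"
            )
        bad = {v for v in self.labels.values()} - {HIGH, LOW}
        if bad:
            raise ValidationError(f"labels must be high/low, got {bad}")

    def ids(self, label: str) -> list:
        return [k for k, v in self.labels.items() if v == label]

    @property
    def n_high(self) -> int:
        return len(self.ids(HIGH))

    @property
    def n_low(self) -> int:
        return len(self.ids(LOW))


def attach_groups(records: list[SurvivalRecord],
                  assignment: GroupAssignment) -> list[SurvivalRecord]:
    """Copy survival records, filling ``group`` from an assignment.

    Records for patients absent from the assignment are dropped.
    """
    out = []
    for r in records:
        if r.patient_id in assignment.labels:
            out.append(SurvivalRecord(r.patient_id, r.time_months, r.event,
                                      assignment.labels[r.patient_id]))
    return out
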