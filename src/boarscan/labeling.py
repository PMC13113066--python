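"""Rule-based boar quality labeling from longitudinal semen records.

A single collection is *good* when it meets all three industry criteria
(total sperm count >= 20e9, motility > 70%, morphology > 70%), *bad* when it
meets at most one, and *intermediate* when it meets exactly two.  A
technician trash flag overrides the metrics: the collection stays in the
denominator but counts as low-quality.  A boar is labeled *underperforming*
by a two-step rule: it must have more than one low-quality collection (bad
or trash), and those must make up at least 10% of its total collections.
Everything else is *high_quality*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .synthetic import (COUNT_THRESHOLD, HIGH_QUALITY, MORPHOLOGY_THRESHOLD,
                        MOTILITY_THRESHOLD, UNDERPERFORMING, SemenRecord)

GOOD = "good"
INTERMEDIATE = "intermediate"
BAD = "bad"
TRASH = "trash"

#: a boar needs *more than one* low-quality collection ...
LOW_QUALITY_MIN_COUNT = 2
#: ... making up *at least* this fraction of its total collections.
LOW_QUALITY_MIN_FRACTION = 0.10

REQUIRED_COLUMNS = ("boar_id", "total_sperm_count", "motility", "morphology",
                    "trash_flag")


@dataclass(frozen=True)
class CollectionStatus:
    """Classification of a single collection plus its criteria count."""

    status: str
    good_count: int


@dataclass(frozen=True)
class BoarLabel:
    """Binary boar label with the counts that produced it."""

    boar_id: str
    label: str
    n_total: int
    n_low_quality: int
    low_quality_fraction: float


def good_count(record: SemenRecord) -> int:
    """Number (0-3) of quality criteria the record meets.

    The count criterion is inclusive (>= 20e9); the two percentage criteria
    are strict (> 70%).
    """
    metrics = (record.total_sperm_count, record.motility, record.morphology)
    if any(m is None or (isinstance(m, float) and math.isnan(m)) for m in metrics):
        raise ValueError(f"record for {record.boar_id!r} has missing metrics")
    if not (0.0 <= record.motility <= 100.0 and 0.0 <= record.morphology <= 100.0):
        raise ValueError("motility and morphology must lie in [0, 100]")
    if record.total_sperm_count < 0:
        raise ValueError("total_sperm_count must be non-negative")
    return (int(record.total_sperm_count >= COUNT_THRESHOLD)
            + int(record.motility > MOTILITY_THRESHOLD)
            + int(record.morphology > MORPHOLOGY_THRESHOLD))


def classify_collection(record: SemenRecord) -> CollectionStatus:
    """Classify one collection as good / intermediate / bad / trash."""
    gc = good_count(record)
    if record.trash_flag:
        return CollectionStatus(TRASH, gc)
    if gc == 3:
        return CollectionStatus(GOOD, gc)
    if gc <= 1:
        return CollectionStatus(BAD, gc)
    return CollectionStatus(INTERMEDIATE, gc)


def label_boar(statuses: Sequence[CollectionStatus], boar_id: str = "") -> BoarLabel:
    """Apply the two-step rule to a boar's collection statuses.

    Low-quality collections are the bad and trash ones; intermediate
    collections count only toward the denominator.
    """
    if len(statuses) == 0:
        raise ValueError("label_boar requires at least one collection status")
    n_total = len(statuses)
    n_low = sum(1 for s in statuses if s.status in (BAD, TRASH))
    frac = n_low / n_total
    under = n_low >= LOW_QUALITY_MIN_COUNT and frac >= LOW_QUALITY_MIN_FRACTION
    return BoarLabel(boar_id, UNDERPERFORMING if under else HIGH_QUALITY,
                     n_total, n_low, frac)


def label_dataset(records: pd.DataFrame | str) -> pd.DataFrame:
    """Label every boar in a records table (or CSV path).

    Returns one row per ``boar_id`` (sorted) with columns ``boar_id``,
    ``label``, ``n_total``, ``n_low_quality`` and ``low_quality_fraction``.
    """
    if isinstance(records, str):
        records = pd.read_csv(records)
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table is missing columns: {missing}")
    rows = []
    for boar_id, grp in records.groupby("boar_id", sort=True):
        statuses = [
            classify_collection(SemenRecord(boar_id, 0, r.total_sperm_count,
                                            r.motility, r.morphology,
                                            bool(r.trash_flag)))
            for r in grp.itertuples(index=False)
        ]
        lab = label_boar(statuses, boar_id=str(boar_id))
        rows.append((lab.boar_id, lab.label, lab.n_total, lab.n_low_quality,
                     lab.low_quality_fraction))
    return pd.DataFrame(rows, columns=["boar_id", "label", "n_total",
                                       "n_low_quality", "low_quality_fraction"])
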