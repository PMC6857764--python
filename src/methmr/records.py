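"""Summary-level association records.

An :class:`AssociationRecord` is the atom of all summary-statistic work: one
variant (or probe) association carrying the effect estimate, its standard
error, allele coding and sample size.  Exposure-side records hold the
SNP-methylation effect per SD of methylation; outcome-side records hold the
SNP-disease log-odds per allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["AssociationRecord", "records_to_frame", "frame_to_records"]

#: Canonical column order for summary-statistic tables.
SUMMARY_COLUMNS = [
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "target",
    "chrom",
    "pos",
    "note",
]


@dataclass
class AssociationRecord:
    """A single variant/probe association.

    Parameters
    ----------
    snp_id : str
        Variant identifier.
    effect_allele, other_allele : str
        Allele coding; ``beta`` is expressed per copy of ``effect_allele``.
    beta, se : float
        Effect estimate and its standard error.
    pval : float, optional
        Two-sided p-value.
    eaf : float, optional
        Effect-allele frequency.
    n : int, optional
        Sample size behind the estimate.
    target : str, optional
        What the effect is on: a CpG id (exposure side), ``"disease"``
        (outcome side) or a behaviour-trait name.
    chrom, pos : optional
        Genomic coordinates (1-based) when known; used for cis-window checks.
    note : str
        Free-text flag, e.g. ``"monomorphic"``.  Never silently empty a
        record: flagged records stay in the list.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float | None = None
    eaf: float | None = None
    n: int | None = None
    target: str | None = None
    chrom: str | None = None
    pos: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()

    @property
    def is_usable(self) -> bool:
        """Whether the record carries a finite effect and positive SE."""
        return (
            self.beta is not None
            and self.se is not None
            and math.isfinite(self.beta)
            and math.isfinite(self.se)
            and self.se > 0
        )


def records_to_frame(records: Iterable[AssociationRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame in canonical column order."""
    rows = [asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[AssociationRecord]:
    """Inverse of :func:`records_to_frame`; extra columns are ignored."""
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for col in SUMMARY_COLUMNS:
            if col in frame.columns:
                value = row[col]
                if isinstance(value, float) and math.isnan(value):
                    value = None
                kwargs[col] = value
        if kwargs.get("note") is None:
            kwargs["note"] = ""
        if kwargs.get("n") is not None:
            kwargs["n"] = int(kwargs["n"])
        if kwargs.get("pos") is not None:
            kwargs["pos"] = int(kwargs["pos"])
        records.append(AssociationRecord(**kwargs))
    return records


def index_by_snp(records: Iterable[AssociationRecord]) -> Mapping[str, AssociationRecord]:
    """Index records by ``snp_id`` (last record wins on duplicates)."""
    return {r.snp_id: r for r in records}
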