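"""Genetic-instrument construction and vetting.

LD pruning at a pairwise r2 threshold, cis-window filtering, instrument
strength (variance explained and F statistic), cross-sample replication
flags, and a summary-level scan of instruments against behaviour traits
that could confound the exposure-outcome relationship.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .meta_analysis import bh_fdr
from .records import AssociationRecord, records_to_frame

__all__ = [
    "InstrumentSet",
    "ld_prune",
    "instrument_strength",
    "replicate_instruments",
    "confounder_scan",
    "build_instrument_set",
    "CIS_WINDOW",
]

#: cis window around the CpG, 1 Mb, 1-based inclusive distance
CIS_WINDOW = 1_000_000


@dataclass
class InstrumentSet:
    """Independent mQTL instruments for one CpG.

    ``table`` columns: snp_id, effect_allele, other_allele, eaf, beta, se,
    pval, n, r2, f_stat, cis, replicated.  ``beta`` is per-allele effect on
    SD-unit methylation; retained SNPs are pairwise independent at the LD
    threshold used to build the set.
    """

    cpg_id: str
    table: pd.DataFrame
    ld_threshold: float = 0.01

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp_id"])

    def __len__(self) -> int:
        return len(self.table)


def ld_prune(
    candidates: Sequence[AssociationRecord] | Mapping[str, float],
    ld_r2: pd.DataFrame,
    threshold: float = 0.01,
) -> list[str]:
    """Greedy LD pruning in ascending p-value order.

    Candidates are visited from smallest p (ties broken lexicographically by
    snp_id, making the output independent of input order); a candidate is
    dropped if its LD r2 with any already-retained SNP is at or above the
    threshold.

    Parameters
    ----------
    candidates
        Either association records with p-values or a snp_id -> p mapping.
    ld_r2
        Square symmetric r2 matrix with unit diagonal, indexed by snp_id.
    """
    if isinstance(candidates, Mapping):
        pvals = dict(candidates)
    else:
        pvals = {r.snp_id: r.pval for r in candidates}
    missing = [s for s in pvals if s not in ld_r2.index or s not in ld_r2.columns]
    if missing:
        raise InputError(f"LD matrix missing entries for: {missing}")
    sub = ld_r2.loc[list(pvals), list(pvals)]
    if not np.allclose(sub.values, sub.values.T, atol=1e-8):
        raise InputError("LD matrix must be symmetric")
    if not np.allclose(np.diag(sub.values), 1.0, atol=1e-6):
        raise InputError("LD matrix must have unit diagonal")

    order = sorted(pvals, key=lambda s: (pvals[s], s))
    retained: list[str] = []
    for snp in order:
        if all(ld_r2.loc[snp, kept] < threshold for kept in retained):
            retained.append(snp)
    return retained


def instrument_strength(beta: float, se: float, n: int) -> tuple[float, float]:
    """Variance explained (r2) and F statistic from summary statistics.

    Uses the t-statistic identity: with ``t = beta/se``,
    ``r2 = t**2 / (t**2 + n - 2)`` and ``F = r2 (n - 2) / (1 - r2) = t**2``.
    Robust to the exposure's scaling convention, unlike the
    ``2 maf (1-maf) beta**2`` form (also available, see
    :func:`r2_from_allele_frequency`).
    """
    if se <= 0:
        raise InputError("se must be positive")
    if n <= 2:
        raise InputError("n must exceed 2")
    t2 = (beta / se) ** 2
    r2 = t2 / (t2 + n - 2)
    f_stat = r2 * (n - 2) / (1.0 - r2)
    return float(r2), float(f_stat)


def r2_from_allele_frequency(beta: float, eaf: float, exposure_var: float = 1.0) -> float:
    """Alternative r2 estimate ``2 eaf (1 - eaf) beta**2 / var(exposure)``."""
    return float(2.0 * eaf * (1.0 - eaf) * beta**2 / exposure_var)


def f_from_r2(r2: float, n: int) -> float:
    """``F = r2 (n - 2) / (1 - r2)``."""
    if not 0 <= r2 < 1:
        raise InputError("r2 must lie in [0, 1)")
    return float(r2 * (n - 2) / (1.0 - r2))


def build_instrument_set(
    cpg_id: str,
    candidates: Sequence[AssociationRecord],
    ld_r2: pd.DataFrame | None = None,
    ld_threshold: float = 0.01,
    cpg_chrom: str | None = None,
    cpg_pos: int | None = None,
    cis_window: int = CIS_WINDOW,
    allow_trans: bool = False,
) -> InstrumentSet:
    """Assemble an :class:`InstrumentSet` from candidate mQTL records.

    Applies the cis filter (|pos_SNP - pos_CpG| <= window, requiring same
    chromosome) unless ``allow_trans``, LD-prunes when an LD matrix is
    given, and attaches strength metrics.  Records without finite effect/SE
    are excluded with the cis/strength bookkeeping preserved in the table.
    """
    usable = [r for r in candidates if r.is_usable]
    if not usable:
        raise InputError(f"no usable candidate mQTLs for {cpg_id}")

    def is_cis(r: AssociationRecord) -> bool:
        if r.chrom is None or r.pos is None or cpg_pos is None:
            return False
        same_chrom = cpg_chrom is None or str(r.chrom) == str(cpg_chrom)
        return same_chrom and abs(int(r.pos) - int(cpg_pos)) <= cis_window

    kept = [r for r in usable if allow_trans or is_cis(r)]
    if not kept:
        raise InputError(
            f"no cis mQTL within {cis_window} bp for {cpg_id}; "
            "pass allow_trans=True to admit trans instruments"
        )
    if ld_r2 is not None:
        retained = set(ld_prune(kept, ld_r2, threshold=ld_threshold))
        kept = [r for r in kept if r.snp_id in retained]

    table = records_to_frame(kept)[
        ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]
    ].copy()
    strengths = [instrument_strength(r.beta, r.se, r.n) for r in kept]
    table["r2"] = [s[0] for s in strengths]
    table["f_stat"] = [s[1] for s in strengths]
    table["cis"] = [is_cis(r) for r in kept]
    table["replicated"] = "untested"
    return InstrumentSet(cpg_id=cpg_id, table=table.reset_index(drop=True),
                         ld_threshold=ld_threshold)


def replicate_instruments(
    primary: InstrumentSet,
    replication: Sequence[AssociationRecord],
    fdr_threshold: float = 0.05,
) -> InstrumentSet:
    """Flag instruments that replicate in an independent sample.

    BH-FDR is computed within the replication set; an instrument is
    ``"replicated"`` when its replication FDR is below the threshold AND the
    replication effect has the same sign as the primary effect.  Instruments
    absent from the replication table are flagged ``"untested"``.
    """
    rep = {
        (r.snp_id, r.target): r
        for r in replication
        if r.is_usable and r.pval is not None
    }
    rep_records = list(rep.values())
    fdr = (
        dict(zip(rep.keys(), bh_fdr([r.pval for r in rep_records])))
        if rep_records
        else {}
    )
    table = primary.table.copy()
    flags = []
    for _, row in table.iterrows():
        key = (row["snp_id"], primary.cpg_id)
        if key not in rep:
            flags.append("untested")
            continue
        r = rep[key]
        same_sign = np.sign(r.beta) == np.sign(row["beta"])
        flags.append("replicated" if fdr[key] < fdr_threshold and same_sign else "not_replicated")
    table["replicated"] = flags
    return replace(primary, table=table)


def confounder_scan(
    snp_ids: Sequence[str],
    trait_tables: Mapping[str, Sequence[AssociationRecord]],
    fdr_threshold: float = 0.05,
    nominal_alpha: float = 0.05,
) -> pd.DataFrame:
    """Scan instrument SNPs against behaviour-trait summary statistics.

    Returns one row per SNP x trait with effect, p, BH-FDR across all tested
    pairs in the scan, and a status column distinguishing ``significant``
    (FDR below threshold) from ``nominal`` (p below alpha but FDR above) and
    ``untested`` (SNP absent from the trait table).
    """
    rows = []
    for trait, records in trait_tables.items():
        lookup = {r.snp_id: r for r in records}
        for snp in snp_ids:
            r = lookup.get(snp)
            if r is None or r.pval is None:
                rows.append({"snp_id": snp, "trait": trait, "beta": np.nan,
                             "se": np.nan, "pval": np.nan})
            else:
                rows.append({"snp_id": snp, "trait": trait, "beta": r.beta,
                             "se": r.se, "pval": r.pval})
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    tested = out["pval"].notna()
    if tested.any():
        out.loc[tested, "fdr"] = bh_fdr(out.loc[tested, "pval"].to_numpy())
    status = np.where(
        ~tested,
        "untested",
        np.where(
            out["fdr"] < fdr_threshold,
            "significant",
            np.where(out["pval"] < nominal_alpha, "nominal", "null"),
        ),
    )
    out["status"] = status
    return out
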