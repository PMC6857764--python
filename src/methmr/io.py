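"""Table formats, configuration and pipeline orchestration.

TSV with named columns is the lingua franca.  Summary-statistic tables use
the columns snp_id, effect_allele, other_allele, eaf, beta, se, pval, n
(plus optional target/chrom/pos/note); methylation matrices have probe IDs
as row keys and sample IDs as columns; LD matrices are square TSVs with
snp_id headers.  Every written table carries provenance header lines
(``# key: value``) recording inputs, thresholds, seed and package version,
and writes are byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import DependencyError, InputError
from .records import SUMMARY_COLUMNS, AssociationRecord, frame_to_records, records_to_frame

__all__ = [
    "RunConfig",
    "read_summary_stats",
    "write_summary_stats",
    "read_matrix",
    "write_matrix",
    "read_dosages",
    "read_ld_matrix",
    "run_pipeline",
    "PIPELINE_STAGES",
]

_FLOAT_FMT = "%.17g"  # full double precision for round-trips

MANDATORY_SUMMARY_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta", "se"]


def _provenance_lines(provenance: Mapping | None) -> str:
    items = {"version": __version__}
    if provenance:
        items.update(provenance)
    return "".join(f"# {k}: {v}\n" for k, v in items.items())


def _write_frame(frame: pd.DataFrame, path, provenance=None, index=False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(_provenance_lines(provenance))
    frame.to_csv(buf, sep="\t", index=index, float_format=_FLOAT_FMT)
    path.write_text(buf.getvalue())


def read_summary_stats(
    path, column_map: Mapping[str, str] | None = None
) -> tuple[list[AssociationRecord], list[dict]]:
    """Read a summary-statistic TSV into typed records.

    ``column_map`` renames non-standard headers, e.g. ``{"b": "beta"}``.
    Malformed rows (non-numeric beta/se, missing alleles) are collected in a
    reject report — they are never silently dropped.

    Raises
    ------
    InputError
        If the file is missing or a mandatory column cannot be resolved.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    for col in MANDATORY_SUMMARY_COLUMNS:
        if col not in frame.columns:
            raise InputError(f"missing mandatory column {col!r} in {path}")

    records: list[AssociationRecord] = []
    rejects: list[dict] = []
    numeric = ["beta", "se", "eaf", "pval"]
    for i, row in frame.iterrows():
        try:
            kwargs = {
                "snp_id": str(row["snp_id"]),
                "effect_allele": str(row["effect_allele"]),
                "other_allele": str(row["other_allele"]),
            }
            for col in numeric:
                if col in frame.columns and pd.notna(row[col]):
                    kwargs[col] = float(row[col])
            if "beta" not in kwargs or "se" not in kwargs:
                raise ValueError("missing beta or se")
            for col, caster in (("n", int), ("pos", int)):
                if col in frame.columns and pd.notna(row[col]):
                    kwargs[col] = caster(float(row[col]))
            for col in ("target", "chrom", "note"):
                if col in frame.columns and pd.notna(row[col]):
                    kwargs[col] = str(row[col])
            records.append(AssociationRecord(**kwargs))
        except (ValueError, TypeError) as err:
            rejects.append({"row": int(i), "reason": str(err), "data": row.to_dict()})
    return records, rejects


def write_summary_stats(
    records: Sequence[AssociationRecord], path, provenance: Mapping | None = None
) -> None:
    """Write records as TSV with provenance headers."""
    _write_frame(records_to_frame(records), path, provenance)


def read_matrix(path) -> pd.DataFrame:
    """Read a row-keyed numeric matrix (methylation, LD, dosages) from TSV."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                        float_precision="round_trip")
    try:
        return frame.astype(float)
    except ValueError as err:
        raise InputError(f"non-numeric matrix entries in {path}: {err}") from err


def write_matrix(frame: pd.DataFrame, path, provenance: Mapping | None = None) -> None:
    _write_frame(frame, path, provenance, index=True)


def read_ld_matrix(path) -> pd.DataFrame:
    """Square symmetric LD r2 matrix with snp_id headers."""
    m = read_matrix(path)
    if list(m.index) != list(m.columns):
        raise InputError("LD matrix must have identical row and column snp_ids")
    return m


def read_dosages(path, fmt: str = "tsv") -> tuple[pd.DataFrame, list[dict]]:
    """Individuals x SNPs dosage matrix from TSV or VCF.

    The TSV layout has sample IDs as row keys and snp_ids as columns.  For
    VCF, the DS FORMAT field is used when present, otherwise dosage is the
    alternate-allele count from GT; multi-allelic records are rejected with
    a reason, never silently dropped.
    """
    if fmt == "tsv":
        m = read_matrix(path)
        bad = ~m.isin([0, 1, 2]).all()
        rejects = [
            {"snp_id": c, "reason": "dosage outside {0,1,2}"}
            for c in m.columns[bad]
            if not m[c].between(0, 2).all()
        ]
        return m, rejects
    if fmt != "vcf":
        raise InputError("format must be 'tsv' or 'vcf'")

    import pysam  # optional dependency, only needed for VCF input

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    columns: dict[str, np.ndarray] = {}
    rejects: list[dict] = []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            rejects.append({"snp_id": rec.id or f"{rec.chrom}:{rec.pos}",
                            "reason": "multi-allelic or missing ALT"})
            continue
        values = np.full(len(samples), np.nan)
        for i, sample in enumerate(samples):
            call = rec.samples[sample]
            if "DS" in call and call["DS"] is not None:
                values[i] = float(call["DS"])
            elif call.get("GT") is not None and None not in call["GT"]:
                values[i] = float(sum(call["GT"]))
        columns[rec.id or f"{rec.chrom}:{rec.pos}"] = values
    return pd.DataFrame(columns, index=samples), rejects


# ---------------------------------------------------------------------------
# pipeline orchestration

PIPELINE_STAGES = ["simulate", "ewas", "meta", "instruments", "mr"]


@dataclass
class RunConfig:
    """Configuration for the end-to-end synthetic pipeline.

    Thresholds default to the analysis conventions: FDR 0.05, LD r2 0.01,
    cis window 1 Mb, alpha 0.05.  All defaults are printed into every
    output's provenance header.
    """

    outdir: Path
    seed: int = 1
    n_studies: int = 4
    n_individuals: int = 4000
    n_snps: int = 4
    per_snp_r2: float = 0.02
    maf: float = 0.3
    theta: float = 0.0
    gamma: float = -0.5
    delta: float = 0.7
    base_logodds: float = -1.0
    n_pairs: int = 230
    matching_covariates: tuple[str, ...] = ()
    fdr_threshold: float = 0.05
    ld_threshold: float = 0.01
    cis_window: int = 1_000_000
    alpha: float = 0.05
    mr_sample_size: int = 20_000

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        if "matching_covariates" in raw and raw["matching_covariates"] is not None:
            raw["matching_covariates"] = tuple(raw["matching_covariates"])
        return cls(**raw)

    def provenance(self, **extra) -> dict:
        base = {
            "seed": self.seed,
            "fdr_threshold": self.fdr_threshold,
            "ld_threshold": self.ld_threshold,
            "cis_window": self.cis_window,
            "alpha": self.alpha,
        }
        base.update(extra)
        return base


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage '{needed_by}' needs {path.name}, produced by stage "
            f"'{stage}'; run that stage first"
        )
    return path


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict[str, Path]:
    """Execute the requested stages in dependency order.

    simulate -> ewas -> meta -> instruments -> mr.  Each stage writes TSV
    artifacts under ``config.outdir`` with provenance headers; reruns with
    the same config are byte-identical.  Returns a name -> path map of the
    artifacts written.
    """
    from . import ewas as ewas_mod
    from . import instruments as instr_mod
    from . import meta_analysis as meta_mod
    from . import two_sample_mr as mr_mod
    from . import synthetic_data as synth

    if stages is None:
        stages = PIPELINE_STAGES
    unknown = set(stages) - set(PIPELINE_STAGES)
    if unknown:
        raise InputError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in PIPELINE_STAGES if s in stages]
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    beta_gp = synth.beta_gp_for_r2(
        [config.per_snp_r2] * config.n_snps, config.maf, gamma=config.gamma
    )

    def study_config(seed, n, n_pairs):
        return synth.SimulationConfig(
            n_individuals=n, n_snps=config.n_snps, maf=config.maf,
            beta_gp=beta_gp, theta=config.theta, gamma=config.gamma,
            delta=config.delta, base_logodds=config.base_logodds,
            n_pairs=n_pairs, seed=seed,
        )

    if "simulate" in stages:
        for i in range(config.n_studies):
            cfg = study_config(config.seed * 1000 + i, config.n_individuals,
                               config.n_pairs)
            cohort = synth.simulate_cohort(cfg)
            pairs = synth.make_matched_pairs(
                cohort, config.matching_covariates, cfg.n_pairs, seed=cfg.seed
            )
            sdir = out / f"study_{i + 1}"
            prov = config.provenance(study=i + 1, study_seed=cfg.seed)
            pair_table = pd.concat(
                [
                    pd.DataFrame({"pair_id": pairs.pair_id}),
                    pairs.case_methylation.add_prefix("case_"),
                    pairs.control_methylation.add_prefix("control_"),
                    pairs.case_covariates.add_prefix("case_"),
                    pairs.control_covariates.add_prefix("control_"),
                ],
                axis=1,
            )
            _write_frame(pair_table, sdir / "pairs.tsv", prov)
            _write_frame(cohort.covariates, sdir / "covariates.tsv", prov)
        # two independent large cohorts emulate the two samples of MR
        exp_cohort = synth.simulate_cohort(
            study_config(config.seed * 1000 + 900, config.mr_sample_size, 0)
        )
        out_cohort = synth.simulate_cohort(
            study_config(config.seed * 1000 + 901, config.mr_sample_size, 0)
        )
        write_summary_stats(
            synth.export_summary_stats(exp_cohort, "exposure"),
            out / "exposure_stats.tsv", config.provenance(side="exposure"),
        )
        write_summary_stats(
            synth.export_summary_stats(out_cohort, "outcome"),
            out / "outcome_stats.tsv", config.provenance(side="outcome"),
        )
        ld = np.corrcoef(exp_cohort.genotypes.T.astype(float)) ** 2
        np.fill_diagonal(ld, 1.0)
        snp_ids = list(exp_cohort.snp_info["snp_id"])
        write_matrix(pd.DataFrame(ld, index=snp_ids, columns=snp_ids),
                     out / "ld_matrix.tsv", config.provenance())
        _write_frame(exp_cohort.snp_info, out / "snp_info.tsv", config.provenance())
        artifacts["exposure_stats"] = out / "exposure_stats.tsv"
        artifacts["outcome_stats"] = out / "outcome_stats.tsv"
        artifacts["ld_matrix"] = out / "ld_matrix.tsv"

    if "ewas" in stages:
        rows = []
        for i in range(config.n_studies):
            ptab = pd.read_csv(
                _require(out / f"study_{i + 1}" / "pairs.tsv", "simulate", "ewas"),
                sep="\t", comment="#",
            )
            cpg_cols = [c[len("case_"):] for c in ptab.columns
                        if c.startswith("case_cpg")]
            pairs = ewas_mod.MatchedPairSet(
                pair_id=ptab["pair_id"].to_numpy(),
                case_methylation=ptab[[f"case_{c}" for c in cpg_cols]].rename(
                    columns=lambda c: c[len("case_"):]),
                control_methylation=ptab[[f"control_{c}" for c in cpg_cols]].rename(
                    columns=lambda c: c[len("control_"):]),
                case_covariates=ptab[["case_confounder", "case_smoking"]].rename(
                    columns=lambda c: c[len("case_"):]),
                control_covariates=ptab[["control_confounder", "control_smoking"]].rename(
                    columns=lambda c: c[len("control_"):]),
            )
            for res in ewas_mod.ewas_scan(pairs):
                rows.append({"study": i + 1, "cpg_id": res.cpg_id,
                             "log_or": res.log_or, "or_per_sd": res.or_per_sd,
                             "se": res.se, "pval": res.pval,
                             "n_pairs": res.n_pairs, "model": res.model})
        _write_frame(pd.DataFrame(rows), out / "ewas_results.tsv",
                     config.provenance())
        artifacts["ewas_results"] = out / "ewas_results.tsv"

    if "meta" in stages:
        etab = pd.read_csv(
            _require(out / "ewas_results.tsv", "ewas", "meta"), sep="\t", comment="#"
        )
        rows = []
        for cpg, grp in etab.groupby("cpg_id"):
            pooled = meta_mod.fixed_effects_meta(grp["log_or"], grp["se"])
            rows.append({"cpg_id": cpg, "log_or": pooled.estimate,
                         "or_per_sd": float(np.exp(pooled.estimate)),
                         "se": pooled.se, "pval": pooled.pval,
                         "q": pooled.q, "i2": pooled.i2,
                         "direction": pooled.direction,
                         "n_studies": pooled.n_studies})
        meta_tab = pd.DataFrame(rows)
        meta_tab["fdr"] = meta_mod.bh_fdr(meta_tab["pval"].to_numpy())
        _write_frame(meta_tab, out / "meta_results.tsv", config.provenance())
        artifacts["meta_results"] = out / "meta_results.tsv"

    if "instruments" in stages:
        exp_records, _ = read_summary_stats(
            _require(out / "exposure_stats.tsv", "simulate", "instruments")
        )
        ld = read_ld_matrix(_require(out / "ld_matrix.tsv", "simulate", "instruments"))
        cpg_id = exp_records[0].target
        iset = instr_mod.build_instrument_set(
            cpg_id, exp_records, ld_r2=ld, ld_threshold=config.ld_threshold,
            cpg_pos=1_000_000, cis_window=config.cis_window,
        )
        _write_frame(iset.table, out / "instruments.tsv",
                     config.provenance(cpg_id=cpg_id))
        artifacts["instruments"] = out / "instruments.tsv"

    if "mr" in stages:
        itab = pd.read_csv(
            _require(out / "instruments.tsv", "instruments", "mr"),
            sep="\t", comment="#",
        )
        exp_records, _ = read_summary_stats(
            _require(out / "exposure_stats.tsv", "simulate", "mr")
        )
        out_records, _ = read_summary_stats(
            _require(out / "outcome_stats.tsv", "simulate", "mr")
        )
        keep = set(itab["snp_id"])
        harmonized, _log = mr_mod.harmonize(
            [r for r in exp_records if r.snp_id in keep],
            [r for r in out_records if r.snp_id in keep],
        )
        ratios = [mr_mod.wald_ratio(h) for h in harmonized]
        results = list(ratios)
        if len(ratios) >= 2:
            results.append(mr_mod.ivw_combine(ratios))
        if len(harmonized) >= 3:
            results.append(mr_mod.mr_egger(harmonized))
        rows = [
            {"method": r.method, "snp_id": r.snp_id or "",
             "log_or": r.estimate, "or_per_sd": r.odds_ratio, "se": r.se,
             "ci_low": r.ci95[0], "ci_high": r.ci95[1], "pval": r.pval,
             "n_instruments": r.n_instruments, "q": r.q, "q_pval": r.q_pval,
             "egger_intercept": r.intercept}
            for r in results
        ]
        _write_frame(pd.DataFrame(rows), out / "mr_results.tsv",
                     config.provenance())
        artifacts["mr_results"] = out / "mr_results.tsv"

    return artifacts
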