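"""Pipeline orchestration and publication-style table output.

All rounding (ORs 2 dp, p-values 4 dp, percentages 1 dp) happens only at
presentation time; a JSON sidecar duplicates every number unrounded so the
rounded tables are a pure function of the sidecar.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .association import (
    AssociationResult,
    run_comparisons,
    subgroup_analysis,
    SUBGROUP_FACTORS,
    STANDARD_DESIGNS,
)
from .combination import DEFAULT_MIN_COUNT, combine
from .errors import ValidationError
from .genotype_data import CohortDataset, read_cohort
from .risk_model import (
    LocusEffect,
    PolygenicModelSpec,
    fraction_explained,
    screening_benefit,
    total_variance,
)

logger = logging.getLogger("polyassoc")


def fmt_or(x: float) -> str:
    return "—" if math.isnan(x) else f"{x:.2f}"


def fmt_p(x: float) -> str:
    return "—" if math.isnan(x) else f"{x:.4f}"


def fmt_pct(x: float) -> str:
    return "—" if math.isnan(x) else f"{x:.1f}"


def significance_marker(p: float) -> str:
    """Footnote marker convention: * <0.05, † <0.01, ‡ <0.001."""
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "‡"
    if p < 0.01:
        return "†"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AnalysisConfig:
    input: str
    snps: tuple[str, ...]
    models: tuple[str, ...] = ("allelic",)
    comparisons: tuple[str, ...] = tuple(STANDARD_DESIGNS)
    subgroup_factors: tuple[str, ...] = ()
    combinations: tuple[tuple[str, ...], ...] = ()
    combination_comparisons: tuple[str, ...] = ("cases-vs-controls",)
    min_count: int = DEFAULT_MIN_COUNT
    lambda_familial: float | None = None
    effects: tuple[tuple[str, float, float], ...] = ()  # (rs, p_risk, rr)
    top_fraction: float = 0.1
    screening_reduction: float = 0.40
    baseline_risk: float = 0.01
    alpha: float = 0.05
    bonferroni: bool = False
    outdir: str = "polyassoc_out"

    def __post_init__(self):
        if not self.snps:
            raise ValidationError("SNP panel must not be empty")
        for f in self.subgroup_factors:
            if f not in SUBGROUP_FACTORS:
                raise ValidationError(f"unknown subgroup factor {f!r}")
        for combo in self.combinations:
            for rs in combo:
                if rs not in self.snps:
                    raise ValidationError(f"combination SNP {rs!r} not in panel")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("snps", "models", "comparisons", "subgroup_factors"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "combinations" in raw:
            raw["combinations"] = tuple(tuple(c) for c in raw["combinations"])
        if "effects" in raw:
            raw["effects"] = tuple(tuple(e) for e in raw["effects"])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _result_record(res: AssociationResult | None) -> dict[str, Any] | None:
    if res is None:
        return None
    return {
        "or": res.or_point,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "p": res.p_value,
        "model": res.model,
        "adjusted_for": list(res.adjusted_for),
        "effective_n": res.effective_n,
        "degenerate": res.degenerate,
    }


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence[str]]):
    lines = ["\t".join(header)]
    lines += ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: AnalysisConfig) -> dict[str, Any]:
    """Run every configured stage and emit TSV tables plus a JSON sidecar.

    Returns the (unrounded) sidecar payload.  Any stage failure aborts with
    the stage name and the offending input in the message.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sidecar: dict[str, Any] = {
        "version": __version__,
        "config_hash": cfg.digest(),
        "input": cfg.input,
    }

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    current = stage("read_cohort")
    try:
        ds = read_cohort(cfg.input)
        sidecar["n_subjects"] = ds.n_subjects
        sidecar["missingness"] = ds.missingness()

        current = stage("single_locus")
        assoc_rows, assoc_side = [], {}
        n_tests = max(len(cfg.snps), 1)
        for rs in cfg.snps:
            for model in cfg.models:
                comps = run_comparisons(ds, rs, model=model)
                rec = {}
                for comp_name in cfg.comparisons:
                    res = comps.get(comp_name)
                    if isinstance(res, list):
                        res = res[-1]
                    rec[comp_name] = _result_record(res)
                    row_res = res
                    if row_res is not None:
                        p = row_res.p_value
                        row = [
                            rs,
                            ds.snps[ds.snp_index(rs)].gene_label,
                            model,
                            comp_name,
                            fmt_or(row_res.or_point),
                            f"{fmt_or(row_res.ci_low)}–{fmt_or(row_res.ci_high)}",
                            fmt_p(p) + significance_marker(p),
                            str(row_res.effective_n),
                        ]
                        if cfg.bonferroni:
                            row.append(fmt_p(min(p * n_tests, 1.0)))
                        assoc_rows.append(row)
                assoc_side[f"{rs}:{model}"] = rec
        header = ["rs_id", "gene", "model", "comparison", "OR", "95% CI", "P", "N"]
        if cfg.bonferroni:
            header.append("P_bonferroni")
        _write_tsv(outdir / "single_locus.tsv", header, assoc_rows)
        sidecar["single_locus"] = assoc_side

        if cfg.subgroup_factors:
            current = stage("subgroups")
            sub_rows, sub_side = [], {}
            for rs in cfg.snps:
                for factor in cfg.subgroup_factors:
                    for level, res in subgroup_analysis(ds, rs, factor):
                        sub_side[f"{rs}:{factor}:{level}"] = _result_record(res)
                        sub_rows.append(
                            [
                                rs,
                                factor,
                                level,
                                fmt_or(res.or_point),
                                f"{fmt_or(res.ci_low)}–{fmt_or(res.ci_high)}",
                                fmt_p(res.p_value)
                                + significance_marker(res.p_value),
                                str(res.effective_n),
                            ]
                        )
            _write_tsv(
                outdir / "subgroups.tsv",
                ["rs_id", "factor", "level", "OR", "95% CI", "P", "N"],
                sub_rows,
            )
            sidecar["subgroups"] = sub_side

        if cfg.combinations:
            current = stage("combinations")
            combo_side = {}
            for combo in cfg.combinations:
                strata = combine(
                    ds,
                    combo,
                    min_count=cfg.min_count,
                    comparisons=cfg.combination_comparisons,
                )
                rows = []
                recs = []
                for s in strata:
                    row = ["-".join(s.labels)]
                    for g, c in s.counts.items():
                        row.append(f"{c} ({fmt_pct(s.percents[g])}%)")
                    for comp in cfg.combination_comparisons:
                        if s.is_reference:
                            row += ["1 (reference)", ""]
                        elif s.ors.get(comp) is None:
                            row += ["—", "—"]
                        else:
                            r = s.ors[comp]
                            row += [
                                fmt_or(r.or_point),
                                fmt_p(r.p_value)
                                + significance_marker(r.p_value),
                            ]
                    rows.append(row)
                    recs.append(
                        {
                            "labels": list(s.labels),
                            "dose_total": s.dose_total,
                            "counts": s.counts,
                            "percents": s.percents,
                            "reference": s.is_reference,
                            "ors": {
                                k: _result_record(v) for k, v in s.ors.items()
                            },
                        }
                    )
                name = "_".join(combo)
                group_names = list(strata[0].counts) if strata else []
                header = (
                    ["combination"]
                    + [f"{g} N (%)" for g in group_names]
                    + [
                        col
                        for comp in cfg.combination_comparisons
                        for col in (f"OR {comp}", f"P {comp}")
                    ]
                )
                _write_tsv(outdir / f"combination_{name}.tsv", header, rows)
                combo_side[name] = recs
            sidecar["combinations"] = combo_side

        if cfg.lambda_familial is not None:
            current = stage("risk_model")
            loci = tuple(LocusEffect(*e) for e in cfg.effects)
            spec = PolygenicModelSpec(
                loci, cfg.lambda_familial, cfg.screening_reduction
            )
            V = total_variance(cfg.lambda_familial)
            frac = fraction_explained(spec) if loci else 0.0
            benefit = screening_benefit(
                V, cfg.top_fraction, cfg.screening_reduction, cfg.baseline_risk
            )
            sidecar["risk_model"] = {
                "lambda": cfg.lambda_familial,
                "total_variance": V,
                "fraction_explained": frac,
                "screened_share": benefit.screened_share,
                "case_share": benefit.case_share,
                "risk_averted": benefit.risk_averted,
            }
            _write_tsv(
                outdir / "risk_model.tsv",
                ["quantity", "value"],
                [
                    ["lambda_familial", f"{cfg.lambda_familial:g}"],
                    ["total_log_risk_variance", f"{V:.6f}"],
                    ["fraction_explained", f"{frac:.4f}"],
                    ["screened_share", f"{benefit.screened_share:.4f}"],
                    ["case_share_in_screened", f"{benefit.case_share:.4f}"],
                    ["absolute_risk_averted", f"{benefit.risk_averted:.6f}"],
                ],
            )
    except Exception as exc:
        raise type(exc)(f"pipeline stage {current!r} failed: {exc}") from exc

    (outdir / "sidecar.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True, ensure_ascii=False) + "\n"
    )
    (outdir / "run.log").write_text(
        f"polyassoc {__version__}\nconfig_hash {cfg.digest()}\ninput {cfg.input}\n"
    )
    return sidecar
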