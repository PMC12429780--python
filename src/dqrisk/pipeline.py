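"""End-to-end orchestration: cohort in, consolidated report bundle out.

Stages run in the order the analysis is done: cohort acquisition
(file or synthetic), serotyping, allele-count association tests,
genotype-phenotype cross-tabulation, and risk scoring. Any stage
failure aborts with a stage-named error and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .cohort import Cohort, read_cohort, write_cohort
from .scoring import (
    GenotypePhenotypeCrosstab,
    RiskScoreResult,
    crosstab_genotype_phenotype,
    rank_combinations,
)
from .serotype import (
    CombinationMode,
    SerotypeTable,
    default_serotype_table,
    load_serotype_table,
)
from .stats import (
    AlleleCountSummary,
    TestResult,
    pairwise_group_tests,
    summarize_allele_counts,
)
from .synth import SyntheticConfig, generate_cohort, load_config

logger = logging.getLogger("dqrisk")

__all__ = ["RunConfig", "PipelineError", "ReportBundle", "run_pipeline", "render_report"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Pipeline run parameters (exactly one of input_path / synthetic)."""

    output_dir: Path
    input_path: Optional[Path] = None
    synthetic: Optional[SyntheticConfig] = None
    synthetic_config_path: Optional[Path] = None
    serotype_table_path: Optional[Path] = None
    serotype: str = "DQ2.5"
    alpha: float = 0.05
    m_tests: int = 3
    combination_mode: CombinationMode = "haplotype_pair"
    seed: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        sources = sum(
            x is not None
            for x in (self.input_path, self.synthetic, self.synthetic_config_path)
        )
        if sources != 1:
            raise PipelineError(
                "config: exactly one cohort source (input file or synthetic "
                "config) must be provided"
            )


@dataclass
class ReportBundle:
    cohort: Cohort
    summary: AlleleCountSummary
    tests: list[TestResult]
    scores: list[RiskScoreResult]
    crosstab: GenotypePhenotypeCrosstab
    manifest: dict
    output_dir: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _tests_frame(tests: list[TestResult]) -> pd.DataFrame:
    rows = []
    for t in tests:
        a, b, c, d = (
            (t.table.a, t.table.b, t.table.c, t.table.d) if t.table else (0, 0, 0, 0)
        )
        rows.append(
            {
                "feature": t.feature,
                "group_pair": "-".join(t.group_pair),
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "p_value": t.p_value,
                "threshold": t.threshold,
                "significant": t.significant,
                "degenerate": t.degenerate,
            }
        )
    return pd.DataFrame(rows)


def _scores_frame(scores: list[RiskScoreResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "combination": r.combination,
                "n_pmn_carriers": r.pmn_freqs.n_carriers,
                "n_control_carriers": r.control_freqs.n_carriers,
                "f_AA_pmn": r.pmn_freqs.f_AA,
                "f_AG_pmn": r.pmn_freqs.f_AG,
                "f_AA_ctrl": r.control_freqs.f_AA,
                "f_AG_ctrl": r.control_freqs.f_AG,
                "score": r.score,
                "low_confidence": r.low_confidence,
            }
            for r in scores
        ],
        columns=[
            "combination",
            "n_pmn_carriers",
            "n_control_carriers",
            "f_AA_pmn",
            "f_AG_pmn",
            "f_AA_ctrl",
            "f_AG_ctrl",
            "score",
            "low_confidence",
        ],
    )


def _counts_frame(summary: AlleleCountSummary) -> pd.DataFrame:
    rows = []
    for g, n in summary.group_sizes.items():
        hap = summary.haplotype_counts[g]
        snp = summary.risk_allele_counts[g]
        rows.append(
            {
                "group": g,
                "n_individuals": n,
                f"{summary.serotype}_haplotypes": hap[0],
                "other_haplotypes": hap[1],
                "rs4664308_A": snp[0],
                "rs4664308_G": snp[1],
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every analysis stage and write the report bundle to disk.

    Outputs in ``config.output_dir``: cohort.tsv, allele_counts.tsv,
    association.tsv, association.json, risk_scores.tsv, crosstab.json,
    report.md, and manifest.json (package version, seed, input hashes).
    """
    logging.basicConfig(
        level=config.log_level, format="%(levelname)s %(name)s: %(message)s"
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    input_hashes: dict[str, str] = {}
    try:
        # -- stage: serotype table -----------------------------------------
        try:
            if config.serotype_table_path is not None:
                table = load_serotype_table(config.serotype_table_path)
                input_hashes["serotype_table"] = _sha256(Path(config.serotype_table_path))
            else:
                table = default_serotype_table()
        except Exception as exc:
            raise PipelineError(f"serotype-table stage: {exc}") from exc

        # -- stage: cohort --------------------------------------------------
        try:
            if config.input_path is not None:
                cohort = read_cohort(config.input_path)
                input_hashes["cohort"] = _sha256(Path(config.input_path))
                seed_used = None
            else:
                syn = config.synthetic
                if syn is None:
                    syn = load_config(config.synthetic_config_path)
                    input_hashes["synthetic_config"] = _sha256(
                        Path(config.synthetic_config_path)
                    )
                cohort, _report = generate_cohort(syn, seed=config.seed, table=table)
                seed_used = config.seed if config.seed is not None else syn.seed
            logger.info("cohort: %d individuals %s", len(cohort), cohort.group_sizes())
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"cohort stage: {exc}") from exc

        # -- stage: association --------------------------------------------
        try:
            summary = summarize_allele_counts(cohort, config.serotype, table)
            tests = pairwise_group_tests(summary, config.alpha, config.m_tests)
        except Exception as exc:
            raise PipelineError(f"association stage: {exc}") from exc

        # -- stage: crosstab ------------------------------------------------
        try:
            crosstab = crosstab_genotype_phenotype(cohort)
        except Exception as exc:
            raise PipelineError(f"crosstab stage: {exc}") from exc

        # -- stage: scoring -------------------------------------------------
        try:
            scores = rank_combinations(cohort, table, config.combination_mode)
        except Exception as exc:
            raise PipelineError(f"scoring stage: {exc}") from exc

        # -- stage: write bundle -------------------------------------------
        manifest = {
            "package": "dqrisk",
            "version": __version__,
            "python": platform.python_version(),
            "seed": seed_used,
            "alpha": config.alpha,
            "m_tests": config.m_tests,
            "serotype": config.serotype,
            "combination_mode": config.combination_mode,
            "input_hashes": input_hashes,
        }
        _emit("cohort.tsv", lambda p: write_cohort(cohort, p))
        _emit(
            "allele_counts.tsv",
            lambda p: _counts_frame(summary).to_csv(p, sep="\t", index=False),
        )
        _emit(
            "association.tsv",
            lambda p: _tests_frame(tests).to_csv(p, sep="\t", index=False),
        )
        _emit(
            "association.json",
            lambda p: p.write_text(
                _tests_frame(tests).to_json(orient="records", indent=2)
            ),
        )
        _emit(
            "risk_scores.tsv",
            lambda p: _scores_frame(scores).to_csv(p, sep="\t", index=False),
        )
        _emit(
            "crosstab.json",
            lambda p: p.write_text(
                json.dumps(
                    {
                        "by_genotype": crosstab.by_genotype,
                        "per_group": crosstab.per_group,
                    },
                    indent=2,
                )
            ),
        )
        bundle = ReportBundle(
            cohort=cohort,
            summary=summary,
            tests=tests,
            scores=scores,
            crosstab=crosstab,
            manifest=manifest,
            output_dir=outdir,
        )
        _emit("report.md", lambda p: p.write_text(render_report(bundle)))
        _emit("manifest.json", lambda p: p.write_text(json.dumps(manifest, indent=2)))
        return bundle
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def render_report(bundle: ReportBundle) -> str:
    """One human-readable markdown page summarizing the bundle."""
    lines = ["# HLA-DQ / PLA2R1 case-control report", ""]
    lines.append("## Group sizes")
    for g, n in bundle.summary.group_sizes.items():
        lines.append(f"- {g}: {n}")
    lines.append("")

    lines.append(f"## Allele counts ({bundle.summary.serotype} and rs4664308)")
    lines.append(_counts_frame(bundle.summary).to_string(index=False))
    lines.append("")

    lines.append("## Pairwise Fisher exact tests")
    for t in bundle.tests:
        verdict = "significant" if t.significant else "not significant"
        lines.append(
            f"- {t.feature}, {t.group_pair[0]} vs {t.group_pair[1]}: "
            f"p = {t.p_value:.3f} ({verdict} at threshold {t.threshold:.4f})"
        )
    lines.append("")

    lines.append("## Risk-score ranking of HLA-DQ combinations")
    if not bundle.scores:
        lines.append("no combinations scored")
    else:
        top = bundle.scores[: min(3, len(bundle.scores))]
        bottom = bundle.scores[-min(3, len(bundle.scores)) :]
        lines.append("highest (risk):")
        for r in top:
            lines.append(
                f"- {r.combination}: score {r.score:+.3f} "
                f"(pMN carriers {r.pmn_freqs.n_carriers}, "
                f"control carriers {r.control_freqs.n_carriers})"
            )
        lines.append("lowest (protective):")
        for r in bottom:
            lines.append(
                f"- {r.combination}: score {r.score:+.3f} "
                f"(pMN carriers {r.pmn_freqs.n_carriers}, "
                f"control carriers {r.control_freqs.n_carriers})"
            )
    lines.append("")

    lines.append("## PLA2R1 phenotype by rs4664308 genotype")
    for geno, row in bundle.crosstab.by_genotype.items():
        lines.append(
            f"- {geno}: {row['any_positive']} positive, "
            f"{row['none_positive']} negative, {row['not_done']} untested"
        )
    for g, st in bundle.crosstab.per_group.items():
        if st["serology_pct_positive"] is not None:
            lines.append(
                f"- {g} serology: {st['serology_positive']}/{st['serology_tested']} "
                f"positive ({st['serology_pct_positive']:.1f}%)"
            )
    lines.append("")
    return "\n".join(lines)
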