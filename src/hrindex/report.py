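"""Report rendering and the end-to-end analysis pipeline.

Every analysis run emits a machine-readable JSON report (a pydantic model,
validated against the shipped schema in ``data/report_schema.json``) and a
human-readable text rendering whose every number is re-derivable from the
JSON twin. Rounding follows the print conventions of the clinical
literature — METs and heart-rate indices to 2 dp, heart rates and percents
to 1 dp, p-values to 2 dp with ``<0.001`` below threshold — using
round-half-away-from-zero, stated explicitly because default float
formatting differs across platforms.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

from pydantic import BaseModel, ConfigDict

from . import __version__
from .records import (Arm, ArmDescriptives, StudyRecord, read_study_table,
                      summarize_arm)
from .simulate import SyntheticConfig, generate_cohort
from .stats import ArmComparison, MethodComparison, compare_arm, pooled_summary

__all__ = [
    "round_half_away", "fmt_value", "fmt_p", "AnalysisReport",
    "render_table2", "render_report", "run_pipeline", "load_report_schema",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the print convention used
    throughout): ``round_half_away(6.505, 2) == 6.51``."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fmt_value(x: float | None, ndigits: int = 2) -> str:
    """Format a number at fixed precision; absent/undefined prints an
    em dash."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "—"
    return f"{round_half_away(x, ndigits):.{ndigits}f}"


def fmt_p(p: float) -> str:
    """p-value print style: 2 dp, with ``<0.001`` below threshold."""
    if math.isnan(p):
        return "—"
    if p < 0.001:
        return "<0.001"
    return f"{round_half_away(p, 2):.2f}"


# ---------------------------------------------------------------------------
# JSON twin

class ProvenanceBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    input_sha256: str
    input_kind: Literal["table", "synthetic"]
    seed: int | None = None
    config: dict | None = None
    version: str


class ArmSummaryBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    arm: str
    n_studies: int
    n_total: int
    n_min: int
    n_max: int
    n_median: float
    age_weighted_mean: float
    male_pct_weighted: float


class BlandAltmanBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


class TertileBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tertile: int
    n_points: int
    tm_mean: float
    hri_mean: float
    pct_diff: float
    p_value: float | None


class IdentityBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    slope: float
    intercept: float
    r: float


class ComparisonBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    arm: str
    n_points: int
    tm_mean: float
    tm_sd: float | None
    hri_mean: float
    hri_sd: float | None
    abs_diff: float
    pct_diff: float
    reference: str
    t_stat: float | None
    df: int
    p_value: float
    degenerate: bool
    significant_at_05: bool
    hr_rest_mean: float | None = None
    hr_rest_sd: float | None = None
    hr_max_mean: float | None = None
    hr_max_sd: float | None = None
    bland_altman: BlandAltmanBlock
    tertiles: list[TertileBlock]
    identity: IdentityBlock | None


class AnalysisReport(BaseModel):
    """Machine-readable twin of the rendered analysis report."""

    model_config = ConfigDict(extra="forbid")
    provenance: ProvenanceBlock
    arm_summaries: list[ArmSummaryBlock]
    comparisons: list[ComparisonBlock]


def load_report_schema() -> dict:
    """The shipped JSON schema the report validates against."""
    src = resources.files("hrindex.data") / "report_schema.json"
    return json.loads(src.read_text(encoding="utf-8"))


def _nan_none(x: float | None) -> float | None:
    if x is None or (isinstance(x, float) and (math.isnan(x) or math.isinf(x))):
        return None
    return x


def _comparison_block(result: ArmComparison,
                      records: Sequence[StudyRecord]) -> ComparisonBlock:
    c = result.comparison
    members = [r for r in records if r.arm is c.arm]
    rest = pooled_summary([r.hr_rest for r in members])
    peak = pooled_summary([r.hr_max for r in members])
    return ComparisonBlock(
        arm=c.arm.value, n_points=c.n_points,
        tm_mean=c.tm_mean, tm_sd=_nan_none(c.tm_sd),
        hri_mean=c.hri_mean, hri_sd=_nan_none(c.hri_sd),
        abs_diff=c.abs_diff, pct_diff=c.pct_diff, reference=c.reference,
        t_stat=_nan_none(c.t_stat), df=c.df, p_value=c.p_value,
        degenerate=c.degenerate,
        significant_at_05=bool(c.p_value < 0.05),
        hr_rest_mean=rest.mean, hr_rest_sd=_nan_none(rest.sd),
        hr_max_mean=peak.mean, hr_max_sd=_nan_none(peak.sd),
        bland_altman=BlandAltmanBlock(**asdict(result.bland_altman)),
        tertiles=[TertileBlock(
            tertile=row.tertile, n_points=row.n_points, tm_mean=row.tm_mean,
            hri_mean=row.hri_mean, pct_diff=row.pct_diff,
            p_value=_nan_none(row.p_value),
        ) for row in result.tertiles],
        identity=(IdentityBlock(slope=result.identity.slope,
                                intercept=result.identity.intercept,
                                r=result.identity.r)
                  if result.identity is not None else None),
    )


# ---------------------------------------------------------------------------
# Text rendering

def _mean_sd(mean: float | None, sd: float | None, ndigits: int) -> str:
    if mean is None or (isinstance(mean, float) and math.isnan(mean)):
        return "—"
    return f"{fmt_value(mean, ndigits)} ± {fmt_value(sd, ndigits)}"


def render_table2(measured: ComparisonBlock | None,
                  predicted: ComparisonBlock | None,
                  n_studies: dict[str, int] | None = None) -> str:
    """Heart-rate and oxygen-consumption summary table for the two arms.

    One row per arm with columns: Studies, Data points, HR_rest, HR_peak,
    VO2peak and HRI-VO2, each mean ± SD at the stated print precision.
    Cells without data print an em dash.
    """
    header = (f"{'Arm':<12}{'Studies':>8}{'Data points':>13}"
              f"{'HR_rest':>14}{'HR_peak':>15}{'VO2peak':>14}{'HRI-VO2':>14}")
    lines = [header, "-" * len(header)]
    for label, block in (("TM-VO2meas", measured), ("TM-VO2pred", predicted)):
        if block is None:
            continue
        studies = "—"
        if n_studies and block.arm in n_studies:
            studies = str(n_studies[block.arm])
        lines.append(
            f"{label:<12}{studies:>8}{block.n_points:>13}"
            f"{_mean_sd(block.hr_rest_mean, block.hr_rest_sd, 1):>14}"
            f"{_mean_sd(block.hr_max_mean, block.hr_max_sd, 1):>15}"
            f"{_mean_sd(block.tm_mean, block.tm_sd, 2):>14}"
            f"{_mean_sd(block.hri_mean, block.hri_sd, 2):>14}"
        )
    return "\n".join(lines)


def render_report(report: AnalysisReport) -> str:
    """Human-readable rendering; every number re-derivable from the JSON."""
    out: list[str] = []
    out.append(f"hrindex analysis report (v{report.provenance.version})")
    out.append(f"input: {report.provenance.input_kind} "
               f"sha256={report.provenance.input_sha256[:16]}…")
    out.append("")
    if report.arm_summaries:
        out.append("Arm descriptives")
        for s in report.arm_summaries:
            out.append(
                f"  {s.arm}: {s.n_studies} studies, {s.n_total} subjects "
                f"(range {s.n_min} to {s.n_max}, median {fmt_value(s.n_median, 1)}); "
                f"age {fmt_value(s.age_weighted_mean, 1)} y, "
                f"{fmt_value(s.male_pct_weighted, 1)}% male (n-weighted)"
            )
        out.append("")
    measured = next((c for c in report.comparisons if c.arm == "measured"), None)
    predicted = next((c for c in report.comparisons if c.arm == "predicted"), None)
    if measured or predicted:
        n_studies = {s.arm: s.n_studies for s in report.arm_summaries}
        out.append(render_table2(measured, predicted, n_studies or None))
        out.append("")
    for c in report.comparisons:
        out.append(f"Method comparison — {c.arm} arm vs HRI surrogate "
                   f"(reference: {c.reference})")
        out.append(
            f"  difference {fmt_value(c.abs_diff)} METs "
            f"({fmt_value(c.pct_diff, 1)}%), "
            f"paired t({c.df}) p = {fmt_p(c.p_value)}"
            + ("  [degenerate]" if c.degenerate else "")
        )
        verdict = ("significant method difference" if c.significant_at_05
                   else "no significant method difference")
        out.append(f"  verdict at alpha=0.05: {verdict}")
        ba = c.bland_altman
        out.append(
            f"  Bland-Altman: bias {fmt_value(ba.bias)} METs, "
            f"95% LoA [{fmt_value(ba.loa_low)}, {fmt_value(ba.loa_high)}]"
        )
        if c.identity is not None:
            out.append(
                f"  identity fit: slope {fmt_value(c.identity.slope)}, "
                f"intercept {fmt_value(c.identity.intercept)}, "
                f"r = {fmt_value(c.identity.r)}"
            )
        for row in c.tertiles:
            out.append(
                f"  tertile {row.tertile} (n={row.n_points}): "
                f"{fmt_value(row.pct_diff, 1)}%, "
                f"p = {fmt_p(row.p_value) if row.p_value is not None else '—'}"
            )
        out.append("")
    return "\n".join(out).rstrip() + "\n"


# ---------------------------------------------------------------------------
# Pipeline

def _comparable(records: Sequence[StudyRecord], arm: Arm) -> bool:
    members = [r for r in records if r.arm is arm]
    # a paired comparison needs at least two complete data points
    return len(members) >= 2 and all(
        r.hr_rest is not None and r.hr_max is not None and r.vo2peak is not None
        for r in members
    )


def run_pipeline(source: str | Path | SyntheticConfig,
                 out_dir: str | Path | None = None,
                 reference: Literal["hri", "treadmill"] = "hri",
                 plots: bool = False) -> AnalysisReport:
    """Run the full analysis on a study table or a synthetic configuration.

    Summarises every arm present; for arms where all records carry heart
    rates and a VO2peak value, runs the full treadmill-vs-surrogate
    comparison. When ``out_dir`` is given, writes ``report.json`` and
    ``report.txt`` (and optional identity / Bland-Altman plots); partial
    outputs are removed if any stage fails.
    """
    if isinstance(source, SyntheticConfig):
        records = generate_cohort(source)
        config_dict = {k: (v.value if isinstance(v, Arm) else
                           list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(source).items()}
        digest = hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()).hexdigest()
        provenance = ProvenanceBlock(
            input_sha256=digest, input_kind="synthetic",
            seed=source.seed, config=config_dict, version=__version__)
    else:
        path = Path(source)
        records = read_study_table(path)
        provenance = ProvenanceBlock(
            input_sha256=hashlib.sha256(path.read_bytes()).hexdigest(),
            input_kind="table", version=__version__)

    summaries: list[ArmSummaryBlock] = []
    comparisons: list[ComparisonBlock] = []
    results: dict[str, ArmComparison] = {}
    for arm in Arm:
        members = [r for r in records if r.arm is arm]
        if not members:
            continue
        s: ArmDescriptives = summarize_arm(records, arm)
        summaries.append(ArmSummaryBlock(
            arm=arm.value, n_studies=s.n_studies, n_total=s.n_total,
            n_min=s.n_min, n_max=s.n_max, n_median=s.n_median,
            age_weighted_mean=s.age_weighted_mean,
            male_pct_weighted=s.male_pct_weighted))
        if _comparable(records, arm):
            result = compare_arm(records, arm, reference=reference)
            results[arm.value] = result
            comparisons.append(_comparison_block(result, records))

    report = AnalysisReport(provenance=provenance, arm_summaries=summaries,
                            comparisons=comparisons)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            json_path = out / "report.json"
            json_path.write_text(report.model_dump_json(indent=2) + "\n",
                                 encoding="utf-8")
            written.append(json_path)
            text_path = out / "report.txt"
            text_path.write_text(render_report(report), encoding="utf-8")
            written.append(text_path)
            if plots:
                written.extend(_write_plots(results, out))
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise
    return report


def _write_plots(results: dict[str, ArmComparison], out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: list[Path] = []
    for arm, result in results.items():
        hri = result.hri_values
        tm = result.tm_values
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.scatter(hri, tm, s=18, alpha=0.7)
        lims = [min(min(hri), min(tm)), max(max(hri), max(tm))]
        ax1.plot(lims, lims, "k--", lw=1, label="line of identity")
        ax1.set_xlabel("HRI-VO2 (METs)")
        ax1.set_ylabel("treadmill VO2peak (METs)")
        ax1.set_title(f"{arm} arm")
        ax1.legend(frameon=False)
        means = [(a + b) / 2 for a, b in zip(tm, hri)]
        diffs = [a - b for a, b in zip(tm, hri)]
        ba = result.bland_altman
        ax2.scatter(means, diffs, s=18, alpha=0.7)
        for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
            ax2.axhline(y, color="k", ls=style, lw=1)
        ax2.set_xlabel("pair mean (METs)")
        ax2.set_ylabel("difference, treadmill − HRI (METs)")
        ax2.set_title("Bland–Altman")
        fig.tight_layout()
        path = out / f"comparison_{arm}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
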