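"""Full per-subject analysis orchestration and report serialization.

For each input series the pipeline runs correction -> day-night statistics ->
rhythm detection in all three unit regimes (raw ng/mL, ng/mg creatinine,
µg/h), correlates the two correction schemes, and emits the result as JSON,
a flat CSV headline table, and a plain-text report.  Reports are pure
functions of the input bytes and the configuration, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .daynight import cv_report, inversion_rate, pair_day_night, paired_t, pearson
from .rhythm import acf, interval_anova, ls_spectrum
from .timeseries_io import (
    CREATININE_UNIT,
    RAW_UNIT,
    VOLUME_UNIT,
    ChronuriaError,
    CorrectedSeries,
    UrineSeries,
    correct,
    read_series,
)

__all__ = ["AnalysisParams", "AnalysisReport", "ConfigError",
           "analyze_series", "run_pipeline", "load_config"]

log = logging.getLogger("chronuria")


class ConfigError(ChronuriaError):
    """The pipeline configuration file is unusable."""


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable thresholds of the analysis, with the conventional defaults.

    alpha — significance level; group_len — ANOVA block length in timepoints
    (8 x 12 h = 4 days); fundamental — trial-period fundamental in hours
    (720 h = 30 days); max_lag — ACF depth in sampling steps.
    """

    alpha: float = 0.05
    group_len: int = 8
    fundamental: float = 720.0
    max_lag: int = 14
    reference_period: float = 90.0  # where acrophase is quoted


@dataclass(frozen=True)
class AnalysisReport:
    subject_id: str
    payload: dict[str, Any] = field(repr=False)

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=2, sort_keys=True,
                          default=_jsonify) + "\n"

    def headline_rows(self) -> list[dict[str, Any]]:
        rows = []
        for unit, block in self.payload["units"].items():
            row: dict[str, Any] = {"subject": self.subject_id, "unit": unit}
            dn = block["day_night"]
            row.update(t=dn["t"], df=dn["df"], p=dn["p"],
                       mean_diff=dn["mean_diff"],
                       inversion_pct=dn["inversion_pct"])
            row.update(anova_F=block["interval_anova"]["F"],
                       anova_p=block["interval_anova"]["p"])
            sp = block["spectrum"]
            row.update(peak_period_h=sp["peak_band"]["best_period"],
                       peak_pr=sp["peak_pr"],
                       acrophase_ref_deg=sp["acrophase_at_reference"],
                       p_ref=sp["p_at_reference"])
            cv = block.get("cv")
            if cv:
                row.update(cv_12h_day=cv["cv_12h_day"],
                           cv_12h_night=cv["cv_12h_night"],
                           cv_24h=cv["cv_24h"], cv_48h=cv["cv_48h"])
            rows.append(row)
        rows[0]["r_between_corrections"] = \
            self.payload["correlation_between_corrections"]["r"]
        return rows

    def to_text(self, alpha: float = 0.05) -> str:
        """Plain-text summary mirroring conventional chronobiology reporting."""
        p = self.payload
        lines = [f"Subject {self.subject_id} "
                 f"(n = {p['n_intervals']} pooled 12-h intervals)", ""]
        corr = p["correlation_between_corrections"]
        lines.append(
            "Correlation between correction schemes: "
            f"r = {corr['r']:.2f}, {_fmt_p(corr['p'], alpha)}, "
            f"n = {corr['n']}")
        for unit, block in p["units"].items():
            dn = block["day_night"]
            an = block["interval_anova"]
            sp = block["spectrum"]
            lines += [
                "",
                f"[{unit}]",
                f"  mean = {block['descriptives']['mean']:.2f} +/- "
                f"{block['descriptives']['sd']:.2f}, range "
                f"{block['descriptives']['min']:.2f} - "
                f"{block['descriptives']['max']:.2f}",
                f"  day-night paired t = {dn['t']:.2f} "
                f"(df = {dn['df']}), {_fmt_p(dn['p'], alpha)}; "
                f"inversions {dn['inversion_pct']:.2f}%",
                f"  4-day interval ANOVA: F = {an['F']:.2f} "
                f"(df = {an['df_between']}, {an['df_within']}), "
                f"{_fmt_p(an['p'], alpha)}",
                f"  LS spectrum peak: {sp['peak_band']['best_period']:.1f} h "
                f"(PR = {100 * sp['peak_pr']:.1f}% of total variance); "
                f"band {sp['peak_band']['periods'][-1]:.1f}-"
                f"{sp['peak_band']['periods'][0]:.1f} h, "
                f"summed PR = {100 * sp['peak_band']['total_pr']:.1f}%",
                f"  acrophase at {sp['reference_period']:.0f} h: "
                f"{sp['acrophase_at_reference']:.0f} deg "
                f"({_fmt_p(sp['p_at_reference'], alpha)} by cosinor)",
            ]
            cv = block.get("cv")
            if cv:
                lines.append(
                    f"  % CV: 12 h day {cv['cv_12h_day']:.2f}, "
                    f"12 h night {cv['cv_12h_night']:.2f}, "
                    f"24 h {cv['cv_24h']:.2f}, 48 h {cv['cv_48h']:.2f}")
        lines.append("")
        lines.append(f"note: {p['n_tests']} significance tests were run "
                     "without multiplicity correction")
        return "\n".join(lines) + "\n"


def _fmt_p(pv: float, alpha: float) -> str:
    if pv < 0.01:
        return "p < 0.01"
    if pv < alpha:
        return f"p = {pv:.2f} (< {alpha:g})"
    return f"p = {pv:.2f} (n.s.)"


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _unit_block(corrected: CorrectedSeries, raw: UrineSeries,
                params: AnalysisParams, counter: list[int]) -> dict[str, Any]:
    values = corrected.values
    pairs = pair_day_night(corrected)
    t_res = paired_t(pairs)
    acf_res = acf(corrected, max_lag=min(params.max_lag, corrected.n - 3))
    anova_res = interval_anova(corrected, group_len=params.group_len)
    spectrum = ls_spectrum(corrected, fundamental=params.fundamental)
    ref_fit = spectrum.fit_at(params.reference_period)
    counter[0] += 3 + len(spectrum.fits)  # t, ANOVA, correlation amortised
    block: dict[str, Any] = {
        "descriptives": {
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)),
            "min": float(values.min()),
            "max": float(values.max()),
            "n": corrected.n,
        },
        "day_night": {
            **asdict(t_res),
            "n_pairs": pairs.n_pairs,
            "dropped": pairs.dropped,
            "inversion_pct": inversion_rate(pairs),
            "significant": bool(t_res.p < params.alpha),
        },
        "acf": {
            "lags": acf_res.lags,
            "coefficients": acf_res.coefficients,
            "conf_limit": acf_res.conf_limit,
            "significant_lags":
                acf_res.lags[acf_res.significant()],
        },
        "interval_anova": {
            "F": anova_res.F,
            "df_between": anova_res.df_between,
            "df_within": anova_res.df_within,
            "p": anova_res.p,
            "group_means": anova_res.group_means,
        },
        "spectrum": {
            "fundamental": spectrum.fundamental,
            "periods": spectrum.periods,
            "percent_rhythm": spectrum.percent_rhythm,
            "p_zero_amplitude":
                [f.p_zero_amplitude for f in spectrum.fits],
            "acrophase_deg": [f.acrophase for f in spectrum.fits],
            "peak_pr": float(spectrum.percent_rhythm.max()),
            "peak_band": {
                "harmonics": list(spectrum.peak_band.harmonics),
                "periods": list(spectrum.peak_band.periods),
                "total_pr": spectrum.peak_band.total_pr,
                "best_period": spectrum.peak_band.best_period,
            },
            "reference_period": ref_fit.trial_period,
            "acrophase_at_reference": ref_fit.acrophase,
            "p_at_reference": ref_fit.p_zero_amplitude,
        },
    }
    if corrected.unit != RAW_UNIT:
        block["cv"] = asdict(cv_report(corrected, raw=raw))
    return block


def analyze_series(series: UrineSeries,
                   params: AnalysisParams = AnalysisParams(),
                   source: str | None = None,
                   input_sha256: str | None = None) -> AnalysisReport:
    """Run the complete analysis for one subject across all unit regimes."""
    log.info("analyzing subject %s (n=%d)", series.subject_id, series.n)
    n_tests = [0]
    units: dict[str, Any] = {}
    corrected_cache: dict[str, CorrectedSeries] = {}
    for unit in (RAW_UNIT, CREATININE_UNIT, VOLUME_UNIT):
        log.info("  unit regime %s", unit)
        corrected = correct(series, unit)
        corrected_cache[unit] = corrected
        try:
            units[unit] = _unit_block(corrected, series, params, n_tests)
        except ChronuriaError as exc:
            raise ChronuriaError(
                f"stage '{unit}' failed for subject "
                f"{series.subject_id}: {exc}") from exc
    corr = pearson(corrected_cache[CREATININE_UNIT],
                   corrected_cache[VOLUME_UNIT])
    payload = {
        "subject": series.subject_id,
        "n_intervals": series.n,
        "units": units,
        "correlation_between_corrections": asdict(corr),
        "n_tests": n_tests[0] + 1,
        "provenance": {
            "software": f"chronuria {__version__}",
            "source": source,
            "input_sha256": input_sha256,
            "params": asdict(params),
        },
    }
    return AnalysisReport(series.subject_id, payload)


def load_config(path: str | Path) -> dict[str, Any]:
    try:
        cfg = yaml.safe_load(Path(path).read_text())
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    if not isinstance(cfg, dict) or not cfg.get("inputs"):
        raise ConfigError("config must name at least one input series "
                          "under 'inputs:'")
    if "out_dir" not in cfg:
        raise ConfigError("config must name an output directory 'out_dir:'")
    return cfg


def run_pipeline(config: str | Path | dict[str, Any]) -> list[AnalysisReport]:
    """Execute the full analysis for every configured input and write
    JSON + CSV + text reports into the configured output directory."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    if not cfg.get("inputs") or "out_dir" not in cfg:
        raise ConfigError("config needs 'inputs' and 'out_dir'")
    params = AnalysisParams(**cfg.get("params", {}))
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    reports: list[AnalysisReport] = []
    rows: list[dict[str, Any]] = []
    for item in cfg["inputs"]:
        path = Path(item["path"])
        log.info("reading %s", path)
        data = path.read_bytes()
        series = read_series(path, dialect=item.get("dialect", "auto"))
        if not isinstance(series, UrineSeries):
            raise ConfigError(
                f"{path}: full pipeline requires the raw dialect "
                "(all three unit regimes)")
        report = analyze_series(
            series, params, source=str(path),
            input_sha256=hashlib.sha256(data).hexdigest())
        stem = out_dir / f"report_{series.subject_id}"
        stem.with_suffix(".json").write_text(report.to_json())
        stem.with_suffix(".txt").write_text(report.to_text(params.alpha))
        rows.extend(report.headline_rows())
        reports.append(report)
    pd.DataFrame(rows).to_csv(out_dir / "headline.csv", index=False)
    log.info("wrote %d report(s) to %s", len(reports), out_dir)
    return reports
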