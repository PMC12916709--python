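"""Study orchestration: year-wise frontiers, period summaries, inefficiency
decomposition, returns-to-scale tallies and second-stage regressions.

The study design benchmarks each hospital only against its same-year peers
(per-year frontiers), then aggregates yearly scores into period means
(pre-pandemic 2015-2019, pandemic 2020-2021, post-pandemic 2022-2024 by
default). A pooled scope — one frontier over all hospital-years — is available
as a configuration choice, because per-year frontiers over three hospitals
have very low discriminatory power (the DMU-adequacy rule n >= max(m*s,
3*(m+s)) fails for every yearly frontier and a warning is emitted).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dea
from .bootstrap import BootstrapConfig, derive_seed, run_bootstrap
from .errors import HospDEAError, MissingOutputError, PanelValidationError
from .panel import (
    FINANCIAL_NO_SURGERY_SPEC,
    FINANCIAL_SPEC,
    OPERATIONAL_SINGLE_OUTPUT_SPEC,
    OPERATIONAL_SPEC,
    DomainSpec,
    PanelDataset,
    build_dmu_set,
    round_half_away,
    total_headcount,
    validate_panel,
)
from .second_stage import fit_truncated_regression

__all__ = [
    "PeriodScheme",
    "DecompositionTriple",
    "StudyConfig",
    "StudyReport",
    "run_study",
    "period_summary",
    "decompose_inefficiency",
    "rts_tally",
    "dmu_adequacy",
    "export_report",
]


@dataclass(frozen=True)
class PeriodScheme:
    """Named, disjoint year ranges covering the study years."""

    periods: tuple[tuple[str, int, int], ...] = (
        ("pre_pandemic", 2015, 2019),
        ("pandemic", 2020, 2021),
        ("post_pandemic", 2022, 2024),
    )

    def __post_init__(self) -> None:
        covered: set[int] = set()
        for name, lo, hi in self.periods:
            if lo > hi:
                raise ValueError(f"period {name}: empty range {lo}-{hi}")
            ys = set(range(lo, hi + 1))
            if ys & covered:
                raise ValueError(f"period {name} overlaps another period")
            covered |= ys

    @property
    def names(self) -> list[str]:
        return [p[0] for p in self.periods]

    def assign(self, year: int) -> str:
        for name, lo, hi in self.periods:
            if lo <= year <= hi:
                return name
        raise ValueError(f"year {year} not covered by the period scheme")

    def years(self, name: str) -> list[int]:
        for nm, lo, hi in self.periods:
            if nm == name:
                return list(range(lo, hi + 1))
        raise KeyError(name)


@dataclass(frozen=True)
class DecompositionTriple:
    """Input-oriented inefficiency split into pure-technical and scale parts.

    overall = 1 - TE(CRS) is the feasible equiproportional input reduction;
    pure = 1 - PTE(VRS) is attributable to organisation/technique;
    scale = PTE(VRS) - TE(CRS) to operating at a non-optimal scale.
    The identity overall = pure + scale holds exactly by construction.
    """

    overall_reduction: float
    pure_gap: float
    scale_gap: float

    def as_percent(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round_half_away(100 * self.overall_reduction, ndigits),
            round_half_away(100 * self.pure_gap, ndigits),
            round_half_away(100 * self.scale_gap, ndigits),
        )


def decompose_inefficiency(te_ccr: float, pte_bcc: float) -> DecompositionTriple:
    if not (0 < te_ccr <= 1 and 0 < pte_bcc <= 1):
        raise ValueError("scores must lie in (0, 1]")
    if te_ccr > pte_bcc + 1e-9:
        raise ValueError(
            f"inconsistent scores: TE_CCR={te_ccr} exceeds PTE_BCC={pte_bcc}"
        )
    return DecompositionTriple(
        overall_reduction=1.0 - te_ccr,
        pure_gap=1.0 - pte_bcc,
        scale_gap=pte_bcc - te_ccr,
    )


def period_summary(
    yearly: Mapping[int, float], scheme: PeriodScheme
) -> dict[str, float]:
    """Arithmetic means of yearly values per period, plus an overall mean."""
    buckets: dict[str, list[float]] = {name: [] for name in scheme.names}
    for year, value in yearly.items():
        buckets[scheme.assign(year)].append(value)
    out = {name: float(np.mean(vals)) for name, vals in buckets.items() if vals}
    out["overall"] = float(np.mean(list(yearly.values())))
    return out


def rts_tally(
    yearly_labels: Mapping[tuple[str, int], str], scheme: PeriodScheme
) -> pd.DataFrame:
    """Counts of CRS/DRS/IRS years per hospital and period."""
    hospitals = sorted({h for h, _ in yearly_labels})
    years_by_hosp = {h: sorted(y for hh, y in yearly_labels if hh == h)
                     for h in hospitals}
    rows = []
    for h in hospitals:
        for period in scheme.names:
            counts = {"crs": 0, "drs": 0, "irs": 0, "indeterminate": 0}
            expected = [y for y in years_by_hosp[h] if scheme.assign(y) == period]
            for y in expected:
                label = yearly_labels.get((h, y))
                if label is None:
                    raise PanelValidationError(f"missing RTS label for {(h, y)}")
                counts[label] += 1
            rows.append({"hospital": h, "period": period, **counts,
                         "years_in_period": len(expected)})
    return pd.DataFrame(rows)


def dmu_adequacy(m: int, s: int, n: int) -> tuple[int, bool]:
    """Rule of thumb n >= max(m*s, 3*(m+s)); returns (threshold, satisfied)."""
    if min(m, s, n) < 1:
        raise ValueError("m, s, n must all be >= 1")
    threshold = max(m * s, 3 * (m + s))
    return threshold, n >= threshold


# ---------------------------------------------------------------------------
# Full study

@dataclass(frozen=True)
class StudyConfig:
    domains: tuple[str, ...] = ("operational", "financial")
    frontier_scope: str = "per_year"  # per_year | pooled
    scheme: PeriodScheme = PeriodScheme()
    bootstrap: BootstrapConfig = BootstrapConfig()
    #: how to handle panels without surgical-procedure counts:
    #: none (fail loudly) | drop_surgical | synthetic_surgical
    fallback: str = "none"
    rts_domains: tuple[str, ...] = ("operational",)
    run_second_stage: bool = True
    dependent_score: str = "pte_bcc"  # pte_bcc | te_ccr
    use_bias_corrected: bool = True
    seed: int = 0


@dataclass
class StudyReport:
    yearly_scores: pd.DataFrame
    period_means_deterministic: pd.DataFrame
    period_means_bias_corrected: pd.DataFrame
    decomposition: pd.DataFrame
    rts_tallies: pd.DataFrame | None
    second_stage: dict[str, object]
    metadata: dict


_DOMAIN_SPECS = {"operational": OPERATIONAL_SPEC, "financial": FINANCIAL_SPEC}
_FALLBACK_SPECS = {
    "operational": OPERATIONAL_SINGLE_OUTPUT_SPEC,
    "financial": FINANCIAL_NO_SURGERY_SPEC,
}


def _resolve_spec(panel: PanelDataset, domain: str, fallback: str) -> tuple[DomainSpec, bool]:
    spec = _DOMAIN_SPECS[domain]
    has_missing = any(r.surgical_procedures is None for r in panel.records)
    if not has_missing or fallback in ("none", "synthetic_surgical"):
        return spec, False
    if fallback == "drop_surgical":
        return _FALLBACK_SPECS[domain], True
    raise ValueError(f"unknown fallback {fallback!r}")


def _fill_synthetic_surgical(panel: PanelDataset, seed: int) -> PanelDataset:
    """Impute surgical counts as a drawn share of hospitalisations (flagged)."""
    rng = np.random.default_rng(derive_seed(seed, "synthetic_surgical"))
    records = []
    for r in panel.records:
        if r.surgical_procedures is None:
            share = rng.uniform(0.2, 0.4)
            r = replace_record(r, surgical_procedures=round(share * r.hospitalisations))
        records.append(r)
    return PanelDataset(records, provenance=panel.provenance + "+synthetic_surgical")


def replace_record(record, **changes):
    from dataclasses import replace as _replace

    return _replace(record, **changes)


def _split_label(label: str) -> tuple[str, int]:
    hosp, year = label.rsplit(":", 1)
    return hosp, int(year)


def run_study(panel: PanelDataset, config: StudyConfig) -> StudyReport:
    """Execute the full benchmarking study on a panel."""
    report = validate_panel(panel)
    if not report.passed:
        raise PanelValidationError(
            f"panel failed validation: {report.errors()[:3]}"
        )
    fallback_used: dict[str, str] = {}
    if config.fallback == "synthetic_surgical" and any(
        r.surgical_procedures is None for r in panel.records
    ):
        panel = _fill_synthetic_surgical(panel, config.seed)
        fallback_used["surgical_procedures"] = "synthetic"

    scheme = config.scheme
    rows = []
    rts_labels: dict[str, dict[tuple[str, int], str]] = {}
    adequacy_warnings = []

    for domain in config.domains:
        spec, dropped = _resolve_spec(panel, domain, config.fallback)
        if dropped:
            fallback_used[domain] = spec.name
        want_rts = domain in config.rts_domains

        if config.frontier_scope == "per_year":
            groups = [(y, build_dmu_set(panel, spec, years=[y])) for y in panel.years]
        elif config.frontier_scope == "pooled":
            groups = [("pooled", build_dmu_set(panel, spec, years="all"))]
        else:
            raise ValueError(f"unknown frontier scope {config.frontier_scope!r}")

        for year, dmus in groups:
            threshold, ok = dmu_adequacy(dmus.m, dmus.s, dmus.n)
            if not ok:
                adequacy_warnings.append(
                    f"{domain}/{year}: n={dmus.n} < threshold {threshold}"
                )
                warnings.warn(adequacy_warnings[-1], stacklevel=2)
            records = dea.efficiency_table(dmus, classify=want_rts)
            boots = {}
            for model, rts in (("ccr", "crs"), ("bcc", "vrs")):
                cfg = replace_config(
                    config.bootstrap,
                    seed=derive_seed(config.bootstrap.seed, domain, year, model),
                )
                if dmus.n <= 3:
                    warnings.warn(
                        f"{domain}/{year}: bootstrap over only {dmus.n} DMUs has "
                        "little information; intervals are indicative at best",
                        stacklevel=2,
                    )
                boots[model] = {
                    est.label: est for est in run_bootstrap(dmus, rts, cfg)
                }
            for rec in records:
                hosp, yr = _split_label(rec.label)
                bc_ccr = boots["ccr"][rec.label]
                bc_bcc = boots["bcc"][rec.label]
                se_bc = bc_ccr.theta_tilde / bc_bcc.theta_tilde
                rows.append(
                    {
                        "domain": domain,
                        "hospital": hosp,
                        "year": yr,
                        "te_ccr": rec.te_ccr,
                        "pte_bcc": rec.pte_bcc,
                        "se": rec.se,
                        "te_ccr_bc": bc_ccr.theta_tilde,
                        "te_ccr_lo": bc_ccr.ci_low,
                        "te_ccr_hi": bc_ccr.ci_high,
                        "pte_bcc_bc": bc_bcc.theta_tilde,
                        "pte_bcc_lo": bc_bcc.ci_low,
                        "pte_bcc_hi": bc_bcc.ci_high,
                        "se_bc": se_bc,
                        "rts": rec.rts_label,
                    }
                )
                if want_rts and config.frontier_scope == "per_year":
                    rts_labels.setdefault(domain, {})[(hosp, yr)] = rec.rts_label

    yearly = pd.DataFrame(rows).sort_values(["domain", "hospital", "year"])
    yearly = yearly.reset_index(drop=True)

    det = _period_table(yearly, scheme, ("te_ccr", "pte_bcc", "se"))
    bc = _period_table(yearly, scheme, ("te_ccr_bc", "pte_bcc_bc", "se_bc"))
    decomposition = _decomposition_table(det, bc)
    tallies = None
    if rts_labels:
        frames = []
        for domain, labels in rts_labels.items():
            t = rts_tally(labels, scheme)
            t.insert(0, "domain", domain)
            frames.append(t)
        tallies = pd.concat(frames, ignore_index=True)

    second = {}
    if config.run_second_stage:
        for domain in config.domains:
            try:
                second[domain] = _second_stage_fit(panel, yearly, domain, config)
            except HospDEAError as exc:
                second[domain] = {"error": str(exc)}

    metadata = {
        "config": _config_dict(config),
        "panel_provenance": panel.provenance,
        "n_records": len(panel),
        "fallbacks": fallback_used,
        "adequacy_warnings": adequacy_warnings,
    }
    return StudyReport(
        yearly_scores=yearly,
        period_means_deterministic=det,
        period_means_bias_corrected=bc,
        decomposition=decomposition,
        rts_tallies=tallies,
        second_stage=second,
        metadata=metadata,
    )


def replace_config(cfg: BootstrapConfig, **changes) -> BootstrapConfig:
    from dataclasses import replace as _replace

    return _replace(cfg, **changes)


def _period_table(yearly: pd.DataFrame, scheme: PeriodScheme,
                  cols: Sequence[str]) -> pd.DataFrame:
    rows = []
    for (domain, hosp), grp in yearly.groupby(["domain", "hospital"]):
        for col in cols:
            series = dict(zip(grp["year"], grp[col]))
            sums = period_summary(series, scheme)
            for period, value in sums.items():
                rows.append(
                    {"domain": domain, "hospital": hosp, "measure": col,
                     "period": period, "mean": value}
                )
    return pd.DataFrame(rows)


def _decomposition_table(det: pd.DataFrame, bc: pd.DataFrame) -> pd.DataFrame:
    """Inefficiency decomposition of every period-mean score pair."""
    rows = []
    for source, table, ccr_col, bcc_col in (
        ("deterministic", det, "te_ccr", "pte_bcc"),
        ("bias_corrected", bc, "te_ccr_bc", "pte_bcc_bc"),
    ):
        wide = table.pivot_table(
            index=["domain", "hospital", "period"], columns="measure",
            values="mean",
        ).reset_index()
        for _, r in wide.iterrows():
            te, pte = r[ccr_col], r[bcc_col]
            try:
                tri = decompose_inefficiency(min(te, pte), pte)
            except ValueError:
                continue
            pct = tri.as_percent()
            rows.append(
                {
                    "source": source,
                    "domain": r["domain"],
                    "hospital": r["hospital"],
                    "period": r["period"],
                    "overall_reduction": tri.overall_reduction,
                    "pure_gap": tri.pure_gap,
                    "scale_gap": tri.scale_gap,
                    "overall_pct": pct[0],
                    "pure_pct": pct[1],
                    "scale_pct": pct[2],
                    "scores_consistent": bool(te <= pte + 1e-9),
                }
            )
    return pd.DataFrame(rows)


def _second_stage_fit(panel: PanelDataset, yearly: pd.DataFrame, domain: str,
                      config: StudyConfig):
    score_col = config.dependent_score + ("_bc" if config.use_bias_corrected else "")
    sub = yearly[yearly["domain"] == domain].set_index(["hospital", "year"])
    names = ["intercept", "bed_occupancy", "los", "physician_contract_share_pct"]
    if domain == "financial":
        names = ["intercept", "beds", "bed_occupancy", "los",
                 "physician_contract_share_pct", "surgery_share"]
    period_names = config.scheme.names
    dummy_names = [f"period_{p}" for p in period_names[1:]]

    ys, rows = [], []
    for r in panel.records:
        key = (r.hospital_id, r.year)
        if key not in sub.index:
            continue
        score = float(sub.loc[key, score_col])
        ys.append(max(0.0, 1.0 - score))
        phys_total = total_headcount(r, "physicians")
        contract_share = (
            100.0 * r.physicians_contract / phys_total if phys_total else 0.0
        )
        row = {"intercept": 1.0, "bed_occupancy": r.bed_occupancy,
               "los": r.avg_length_of_stay,
               "physician_contract_share_pct": contract_share}
        if domain == "financial":
            row["beds"] = r.beds
            if r.surgical_procedures is None:
                raise MissingOutputError("surgical_procedures", [key])
            row["surgery_share"] = (
                r.surgical_procedures / r.hospitalisations
                if r.hospitalisations else 0.0
            )
        for p, dn in zip(period_names[1:], dummy_names):
            row[dn] = 1.0 if config.scheme.assign(r.year) == p else 0.0
        rows.append([row[nm] for nm in names] + [row[dn] for dn in dummy_names])
    X = np.asarray(rows)
    all_names = names + dummy_names
    # a covariate with no variation (possible on generated panels) carries no
    # information and would make the design singular; drop it with a note
    keep = [j for j in range(X.shape[1])
            if j == 0 or np.ptp(X[:, j]) > 1e-12]
    dropped = [all_names[j] for j in range(X.shape[1]) if j not in keep]
    fit = fit_truncated_regression(
        np.asarray(ys), X[:, keep], names=[all_names[j] for j in keep],
        point=0.0,
    )
    fit.dropped_covariates = dropped
    return fit


def _config_dict(config: StudyConfig) -> dict:
    d = asdict(config)
    d["scheme"] = list(config.scheme.periods)
    return d


def export_report(report: StudyReport, outdir: str | Path) -> dict[str, Path]:
    """Write the report tables as CSV plus a run-metadata JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    def _save(frame: pd.DataFrame, name: str, decimals=None):
        p = outdir / name
        f = frame.copy()
        if decimals:
            for col, nd in decimals.items():
                if col in f.columns:
                    f[col] = f[col].map(lambda v: round_half_away(v, nd))
        f.to_csv(p, index=False)
        written[name] = p

    score_cols = {c: 4 for c in (
        "te_ccr", "pte_bcc", "se", "te_ccr_bc", "te_ccr_lo", "te_ccr_hi",
        "pte_bcc_bc", "pte_bcc_lo", "pte_bcc_hi", "se_bc", "mean",
    )}
    _save(report.yearly_scores, "yearly_scores.csv", score_cols)
    _save(report.period_means_deterministic, "period_means_deterministic.csv",
          score_cols)
    _save(report.period_means_bias_corrected, "period_means_bias_corrected.csv",
          score_cols)
    _save(report.decomposition, "decomposition.csv")
    if report.rts_tallies is not None:
        _save(report.rts_tallies, "rts_tallies.csv")
    for domain, fit in report.second_stage.items():
        if hasattr(fit, "summary_frame"):
            _save(fit.summary_frame(), f"second_stage_{domain}.csv",
                  {"estimate": 4, "std_error": 4, "p_value": 4})
    meta = outdir / "run_metadata.json"
    meta.write_text(json.dumps(report.metadata, indent=2, default=str))
    written["run_metadata.json"] = meta
    return written
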