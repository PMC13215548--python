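"""Configuration-driven end-to-end pipeline and tabular I/O.

Stages: simulate (optional) -> direct estimation -> smoothing/FANOVA ->
space-time fits (RW1 and RW2) -> assessment/model selection -> forecast ->
figures.  Every stage reads and writes plain CSV/JSON files under the
configured output directory, and ``run_pipeline`` finishes by writing a
manifest of every output file with its SHA-256 hash.  A single global
seed expands deterministically into per-stage seeds, so two runs of the
same config produce identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import logit

from . import direct_estimation as de
from . import functional_analysis as fa
from . import model_assessment as ma
from . import spacetime_model as st
from . import synthetic_data as sd

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_birth_histories",
    "run_pipeline",
    "stage_simulate",
    "stage_estimate",
    "stage_fanova",
    "stage_fit",
    "stage_assess",
    "stage_forecast",
    "stage_report",
]

log = logging.getLogger("u5trends")

_STAGE_NAMES = ("simulate", "estimate", "fanova", "fit_rw1", "fit_rw2", "forecast")


@dataclass
class PipelineConfig:
    """All pipeline settings; every stochastic stage gets an explicit seed."""

    output_dir: str = "u5trends_out"
    seed: int = 1
    input_csv: str | None = None  # None -> simulate
    adjacency: str | None = None  # path to YAML; None -> bundled fixture
    sdg_threshold: float = 25.0

    # truth-surface block (used only when simulating)
    truth: dict = field(default_factory=dict)
    survey: dict = field(default_factory=dict)

    fanova: dict = field(
        default_factory=lambda: {
            "n_perm": 1000, "level": 0.95, "n_interior_knots": 10, "on_smoothed": True,
        }
    )
    model: dict = field(
        default_factory=lambda: {"n_iter": 20000, "n_burn": 5000, "thin": 5}
    )
    forecast: dict = field(default_factory=lambda: {"horizon_to": 2030, "level": 0.95})

    def __post_init__(self):
        if self.sdg_threshold <= 0:
            raise ValueError("sdg_threshold must be positive")
        defaults = PipelineConfig.__dataclass_fields__
        for block in ("fanova", "model", "forecast"):
            merged = defaults[block].default_factory()
            merged.update(getattr(self, block))
            setattr(self, block, merged)

    def stage_seeds(self) -> dict:
        state = np.random.SeedSequence(self.seed).generate_state(len(_STAGE_NAMES))
        return {name: int(s % 2**31) for name, s in zip(_STAGE_NAMES, state)}

    def graph(self) -> sd.AdjacencyGraph:
        if self.adjacency:
            return sd.load_adjacency(self.adjacency)
        return sd.default_adjacency()

    def truth_spec(self) -> sd.TruthSpec:
        base = sd.default_truth_spec(seed=self.stage_seeds()["simulate"], graph=self.graph())
        t = dict(self.truth)
        kwargs = dict(
            mu=float(logit(t["mu_q5"])) if "mu_q5" in t else t.get("mu", base.mu),
            variances={**dict(base.variances), **t.get("variances", {})},
            graph=base.graph,
            year_start=t.get("year_start", base.year_start),
            year_end=t.get("year_end", base.year_end),
            temporal_order=t.get("temporal_order", base.temporal_order),
            seed=base.seed,
        )
        return sd.TruthSpec(**kwargs)

    def survey_design(self) -> sd.SurveyDesign:
        return sd.SurveyDesign(**self.survey)

    def years(self) -> list[int]:
        ts = self.truth
        return list(range(ts.get("year_start", 1990), ts.get("year_end", 2022) + 1))


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------
# birth-history I/O
# ---------------------------------------------------------------------------


def read_birth_histories(path, lenient: bool = False) -> pd.DataFrame:
    """Read and validate a birth-history CSV (the synthetic_data contract).

    Strict mode raises on the first structural problem (missing column,
    duplicated child_id) and on invalid rows; lenient mode drops invalid
    rows and records reasons in ``df.attrs["validation"]``.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        import warnings

        warnings.warn(f"{path}: empty birth-history file")
        df = pd.DataFrame(columns=sd.BIRTH_HISTORY_COLUMNS)
    missing = [c for c in sd.BIRTH_HISTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"birth-history file missing column(s): {missing}")
    dup = df["child_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicated child_id at row(s) {list(df.index[dup][:5])}"
        )

    problems = []
    ok = pd.Series(True, index=df.index)
    checks = [
        (df["weight"] <= 0, "nonpositive weight"),
        (df["birth_month"] > df["interview_month"], "birth after interview"),
        (
            df["death_age_months"].notna()
            & (df["birth_month"] + df["death_age_months"] > df["interview_month"]),
            "death after interview",
        ),
        (
            df["death_age_months"].notna()
            & ~df["death_age_months"].between(0, 59),
            "death age outside 0-59 months",
        ),
    ]
    for bad, reason in checks:
        if bad.any():
            rows = list(df.index[bad])
            problems.append({"reason": reason, "rows": rows})
            ok &= ~bad
    if problems and not lenient:
        p = problems[0]
        raise ValueError(f"invalid birth-history rows ({p['reason']}): {p['rows'][:5]}")
    out = df[ok].reset_index(drop=True)
    out.attrs["validation"] = {"n_dropped": int((~ok).sum()), "problems": problems}
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _outdir(cfg: PipelineConfig) -> Path:
    p = Path(cfg.output_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    out = _outdir(cfg)
    spec = cfg.truth_spec()
    surface = sd.simulate_truth(spec)
    births = sd.simulate_birth_histories(
        surface, cfg.survey_design(), seed=cfg.stage_seeds()["simulate"]
    )
    truth_path = out / "truth.csv"
    births_path = out / "births.csv"
    surface.to_frame().to_csv(truth_path, index=False)
    births.to_csv(births_path, index=False)
    log.info("[simulate] %d children across %d regions", len(births), spec.graph.n_regions)
    return [truth_path, births_path]


def stage_estimate(cfg: PipelineConfig) -> list[Path]:
    out = _outdir(cfg)
    src = cfg.input_csv or out / "births.csv"
    records = read_birth_histories(src)
    years = cfg.years()
    est = de.estimate_all(records, years)
    est_s = de.estimate_all(records, years, by="stratum_id")
    for df, name in ((est, "estimates.csv"), (est_s, "estimates_stratum.csv")):
        df.to_csv(out / name, index=False)
    report = {
        "missing_cells": [list(map(str, m)) for m in est.attrs["missing_cells"]],
        "regions_without_data": est.attrs["regions_without_data"],
    }
    (out / "estimation_report.json").write_text(json.dumps(report, indent=2))
    log.info(
        "[estimate] %d region-year cells, %d missing",
        len(est), len(est.attrs["missing_cells"]),
    )
    return [out / "estimates.csv", out / "estimates_stratum.csv", out / "estimation_report.json"]


def _curves_from_estimates(est: pd.DataFrame, basis, on_smoothed: bool):
    """One curve per group in an estimates table (value column: u5mr_per_1000)."""
    curves, labels = [], []
    for grp, block in est.dropna(subset=["u5mr_per_1000"]).groupby("region", sort=True):
        series = pd.Series(
            block["u5mr_per_1000"].to_numpy(), index=block["year"].to_numpy()
        )
        lam = "gcv" if on_smoothed else 0.0
        if not on_smoothed and len(series) < basis.n_basis:
            lam = 1e-8  # near-interpolation when exact fit is underdetermined
        curves.append(fa.smooth_curve(series, basis, lam=lam, label=str(grp)))
        labels.append(str(grp))
    return curves, labels


def stage_fanova(cfg: PipelineConfig) -> list[Path]:
    out = _outdir(cfg)
    fcfg = cfg.fanova
    years = cfg.years()
    basis = fa.build_basis(
        (years[0], years[-1]), fcfg["n_interior_knots"]
    )
    est = pd.read_csv(out / "estimates.csv")
    est_s = pd.read_csv(out / "estimates_stratum.csv")

    # region-level smooths for the raw-vs-smoothed panel
    region_curves, region_labels = _curves_from_estimates(est, basis, True)
    grid = np.array(years, dtype=float)
    fitted = []
    for c in region_curves:
        block = est[est.region == c.label]
        raw = block.set_index("year")["u5mr_per_1000"].reindex(years)
        fitted.append(
            pd.DataFrame(
                {"region": c.label, "year": years, "raw": raw.to_numpy(), "smoothed": c(grid)}
            )
        )
    pd.concat(fitted).to_csv(out / "fitted_curves.csv", index=False)

    mean_ci = fa.mean_curve_ci(region_curves, level=fcfg["level"], grid=grid)
    mean_ci.to_csv(out / "mean_curve.csv", index=False)

    # stratum-level curves are the replicates; division is the group factor
    strat_curves, strat_labels = _curves_from_estimates(
        est_s, basis, fcfg["on_smoothed"]
    )
    groups = [lab.rsplit("_", 1)[0] for lab in strat_labels]
    res = fa.permutation_test(
        strat_curves,
        groups,
        n_perm=fcfg["n_perm"],
        seed=cfg.stage_seeds()["fanova"],
        grid=grid,
        level=fcfg["level"],
    )
    ftab = res.to_frame()
    ftab["p_global"] = res.p_global
    ftab.to_csv(out / "fanova_f.csv", index=False)
    eff = pd.DataFrame({"grid": res.grid, "mu": res.mu})
    for g, lab in enumerate(res.groups):
        eff[f"beta_{lab}"] = res.beta[g]
    eff.to_csv(out / "fanova_effects.csv", index=False)
    coefs = pd.DataFrame(
        {c.label: c.coefficients for c in strat_curves}
    )
    coefs.to_csv(out / "curve_coefficients.csv", index=False)
    log.info("[fanova] global p = %.4f (max crit %.2f)", res.p_global, res.max_crit)
    return [
        out / "fitted_curves.csv", out / "mean_curve.csv", out / "fanova_f.csv",
        out / "fanova_effects.csv", out / "curve_coefficients.csv",
    ]


def _fit_one(cfg: PipelineConfig, order: int) -> st.PosteriorSamples:
    # fits are deterministic given the config, so cache per config object
    cache = cfg.__dict__.setdefault("_fit_cache", {})
    if order in cache:
        return cache[order]
    out = _outdir(cfg)
    est = pd.read_csv(out / "estimates.csv")
    graph = cfg.graph()
    cells = st.cells_from_estimates(est, graph.region_names, cfg.years())
    spec = st.ModelSpec(
        temporal_order=order,
        seed=cfg.stage_seeds()[f"fit_rw{order}"],
        **{k: cfg.model[k] for k in ("n_iter", "n_burn", "thin")},
    )
    cache[order] = st.gibbs_fit(cells, graph, spec)
    return cache[order]


def _write_summaries(samples: st.PosteriorSamples, out: Path, tag: str) -> list[Path]:
    summ = st.posterior_summaries(samples)
    frames = []
    for name in ("alpha", "gamma", "theta", "phi"):
        f = summ[name].copy()
        f.insert(0, "effect", name)
        f = f.rename(columns={"index": "level"})
        frames.append(f)
    effects = pd.concat(frames)
    p1 = out / f"posterior_effects_{tag}.csv"
    effects.to_csv(p1, index=False)
    p2 = out / f"posterior_u5mr_{tag}.csv"
    summ["u5mr"].to_csv(p2, index=False)
    return [p1, p2]


def stage_fit(cfg: PipelineConfig) -> list[Path]:
    out = _outdir(cfg)
    written = []
    for order in (1, 2):
        samples = _fit_one(cfg, order)
        written += _write_summaries(samples, out, f"rw{order}")
        log.info("[fit] RW%d done: %d retained draws", order, samples.n_draws)
    return written


def stage_assess(cfg: PipelineConfig) -> list[Path]:
    out = _outdir(cfg)
    est = pd.read_csv(out / "estimates.csv")
    graph = cfg.graph()
    cells = st.cells_from_estimates(est, graph.region_names, cfg.years())
    fit1, fit2 = _fit_one(cfg, 1), _fit_one(cfg, 2)
    report = ma.compare_models(fit1, fit2, cells, labels=("RW1", "RW2"))
    (out / "assessment.json").write_text(json.dumps(report.to_json_dict(), indent=2))
    report.variance_table.to_csv(out / "variance_table.csv", index=False)
    lines = ["Model comparison", "================", report.criteria.to_string(index=False),
             "", f"Selected: {report.selected_model} ({report.rule})",
             "", "Variance components", "-------------------",
             report.variance_table.to_string(index=False), ""]
    (out / "assessment.txt").write_text("\n".join(lines))
    log.info("[assess] selected %s", report.selected_model)
    return [out / "assessment.json", out / "variance_table.csv", out / "assessment.txt"]


def stage_forecast(cfg: PipelineConfig) -> list[Path]:
    out = _outdir(cfg)
    order = cfg.model.get("forecast_with_order", 2)
    samples = _fit_one(cfg, order)
    horizon = int(cfg.forecast["horizon_to"]) - int(cfg.years()[-1])
    res = st.forecast(
        samples, max(horizon, 0), seed=cfg.stage_seeds()["forecast"],
        level=cfg.forecast["level"],
    )
    res.table.to_csv(out / "forecast.csv", index=False)
    log.info("[forecast] %d regions x %d years", len(samples.regions), res.horizon)
    return [out / "forecast.csv"]


def stage_report(cfg: PipelineConfig) -> list[Path]:
    from . import figures

    out = _outdir(cfg)
    return figures.render_figures(out, sdg_threshold=cfg.sdg_threshold)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage in order and write a manifest; returns the output dir.

    A stage failure raises a stage-tagged error; files written by earlier
    stages are preserved and listed in a partial manifest.
    """
    out = _outdir(cfg)
    logging.basicConfig(level=logging.INFO)
    stages = [
        ("simulate", stage_simulate) if cfg.input_csv is None else ("estimate-input", lambda c: []),
        ("estimate", stage_estimate),
        ("fanova", stage_fanova),
        ("fit", stage_fit),
        ("assess", stage_assess),
        ("forecast", stage_forecast),
        ("report", stage_report),
    ]
    written: list[Path] = []
    try:
        for name, fn in stages:
            written += fn(cfg)
    except Exception as exc:  # tag and re-raise; keep partial manifest
        _write_manifest(out, cfg, written, failed_stage=name)
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    _write_manifest(out, cfg, written)
    return out


def _write_manifest(out: Path, cfg: PipelineConfig, files, failed_stage=None):
    manifest = {
        "seed": cfg.seed,
        "failed_stage": failed_stage,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files if p.exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
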