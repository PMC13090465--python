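"""End-to-end orchestration: calibrate, evaluate, and norm every subscale.

One :func:`run_validation_pipeline` call takes an instrument spec plus a
validated response matrix and produces, per subscale: the GRM/GRSM
calibration, global fit indices, residual correlations, the Mokken report,
reliability, the rubric verdict, and a normative table — bundled with a
run manifest (package version, seed, config hash) so reruns are
reproducible and comparable.  A stage failure is recorded for its subscale
and the remaining subscales still run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .instruments import InstrumentSpec, ResponseMatrix, sum_scores
from .irt import (
    Calibration,
    default_grid,
    eap_scores,
    fit_grm,
    infit_mean_squares,
    test_information,
)
from .mokken import mokken_report
from .model_fit import fit_indices, irt_to_loadings, residual_correlations
from .norms import NormTable, SeverityBandSpec, build_norm_table
from .reliability import reliability_report
from .rubric import compile_verdict

log = logging.getLogger("scalenorm")

__all__ = ["RunConfig", "SubscaleResult", "ReportBundle",
           "run_validation_pipeline", "render_json", "render_html"]


@dataclass
class RunConfig:
    subscales: list[str] | None = None       # None = all in the spec
    model: str = "grm"
    grid_points: int = 61
    grid_bound: float = 6.0
    tol: float = 1e-5
    max_iter: int = 500
    min_group_size: int = 30
    require_reliability: bool = True
    infit_method: str = "posterior"
    seed: int = 0


@dataclass
class SubscaleResult:
    name: str
    error: str | None = None
    calibration: Calibration | None = None
    fit: Any = None
    residuals: Any = None
    mokken: Any = None
    reliability: Any = None
    infits: Any = None
    loadings: Any = None
    verdict: Any = None
    norm_table: NormTable | None = None


@dataclass
class ReportBundle:
    instrument: str
    config: RunConfig
    manifest: dict
    subscales: dict[str, SubscaleResult] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return all(r.error is None for r in self.subscales.values())


def _config_hash(cfg: RunConfig, spec: InstrumentSpec, m: ResponseMatrix) -> str:
    payload = json.dumps(
        {
            "config": dataclasses.asdict(cfg),
            "instrument": spec.name,
            "n_persons": m.n_persons,
            "item_ids": m.item_ids,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_validation_pipeline(
    spec: InstrumentSpec, m: ResponseMatrix, cfg: RunConfig | None = None
) -> ReportBundle:
    cfg = cfg or RunConfig()
    m.validate(spec)
    grid = default_grid(cfg.grid_points, cfg.grid_bound)
    names = cfg.subscales or list(spec.subscales)
    bundle = ReportBundle(
        instrument=spec.name,
        config=cfg,
        manifest={
            "scalenorm_version": __version__,
            "seed": cfg.seed,
            "config_hash": _config_hash(cfg, spec, m),
            "n_persons": m.n_persons,
        },
    )
    for name in names:
        if name not in spec.subscales:
            bundle.subscales[name] = SubscaleResult(
                name=name, error=f"unknown subscale {name!r}"
            )
            continue
        t0 = time.perf_counter()
        res = SubscaleResult(name=name)
        bundle.subscales[name] = res
        members = list(spec.subscales[name])
        try:
            cal = fit_grm(
                m, members, model=cfg.model, grid=grid, tol=cfg.tol,
                max_iter=cfg.max_iter,
            )
            res.calibration = cal
            scores = eap_scores(m, cal)
            res.loadings = irt_to_loadings(cal)
            res.fit = fit_indices(m, cal)
            res.residuals = residual_correlations(m, cal, scores)
            res.mokken = mokken_report(m, members)
            res.reliability = reliability_report(m, members, loadings=res.loadings)
            res.infits = infit_mean_squares(m, cal, scores, method=cfg.infit_method)
            res.verdict = compile_verdict(
                fit=res.fit,
                residuals=res.residuals,
                mokken=res.mokken,
                infits=res.infits,
                reliability_rating=res.reliability.rating,
                loadings=res.loadings,
                require_reliability=cfg.require_reliability,
            )
            res.norm_table = build_norm_table(
                spec.name, name, cal, m, min_group_size=cfg.min_group_size
            )
            log.info(
                "subscale %s: status=%s (%.2fs)",
                name, res.verdict.status, time.perf_counter() - t0,
            )
        except Exception as exc:  # noqa: BLE001 - recorded per subscale
            res.error = f"{type(exc).__name__}: {exc}"
            log.warning("subscale %s failed: %s", name, res.error)
    return bundle


# ---------------------------------------------------------------------------
# rendering


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def render_json(bundle: ReportBundle) -> str:
    """Schema-stable JSON report; byte-identical across identical reruns."""
    doc: dict[str, Any] = {
        "instrument": bundle.instrument,
        "manifest": bundle.manifest,
        "config": dataclasses.asdict(bundle.config),
        "subscales": {},
    }
    for name, res in bundle.subscales.items():
        if res.error is not None:
            doc["subscales"][name] = {"error": res.error}
            continue
        cal = res.calibration
        doc["subscales"][name] = {
            "model": cal.model,
            "converged": cal.converged,
            "n_iterations": cal.n_iterations,
            "log_marginal_likelihood": cal.log_marginal_likelihood,
            "item_params": [
                {"item_id": p.item_id, "a": p.a, "b": list(p.b)}
                for p in cal.params
            ],
            "loadings": dict(zip(res.loadings.item_ids,
                                 _jsonable(res.loadings.loadings))),
            "fit": _jsonable(res.fit),
            "residuals": {
                "Q3": res.residuals.third_quartile,
                "min_r": res.residuals.min_r,
                "max_r": res.residuals.max_r,
                "flagged_pairs": _jsonable(res.residuals.flagged_pairs),
            },
            "mokken": {
                "H": res.mokken.H,
                "H_i": dict(zip(res.mokken.item_ids, _jsonable(res.mokken.H_i))),
                "n_violations": len(res.mokken.violations),
                "crit": _jsonable(res.mokken.crit),
            },
            "reliability": _jsonable(res.reliability),
            "infit": dict(zip(res.infits.item_ids, _jsonable(res.infits.item_infit))),
            "verdict": _jsonable(res.verdict),
        }
    return json.dumps(doc, indent=2, sort_keys=True)


_BADGE = {
    "supported": ("#2e7d32", "supported"),
    "not_supported": ("#c62828", "not supported"),
    "incomplete": ("#f9a825", "incomplete"),
}


def render_html(bundle: ReportBundle) -> str:
    """Human-readable report: psychometrics grid plus color-coded norm tables."""
    parts = [
        "<html><head><meta charset='utf-8'><style>",
        "body{font-family:sans-serif;margin:2em}",
        "table{border-collapse:collapse;margin:1em 0}",
        "td,th{border:1px solid #999;padding:4px 8px;text-align:center}",
        ".badge{color:white;padding:2px 8px;border-radius:4px}",
        "</style></head><body>",
        f"<h1>Instrument report: {bundle.instrument}</h1>",
        f"<p>scalenorm {bundle.manifest['scalenorm_version']}, "
        f"config {bundle.manifest['config_hash']}, "
        f"n={bundle.manifest['n_persons']}</p>",
        "<h2>Psychometric properties</h2>",
        "<table><tr><th>Subscale</th><th>&alpha;</th><th>&omega;<sub>t</sub></th>"
        "<th>H<sub>i</sub> (min-max)</th><th>Violations</th>"
        "<th>&lambda; (min-max)</th><th>RMSEA</th><th>TLI</th><th>CFI</th>"
        "<th>SRMR</th><th>Infit (min-max)</th><th>Status</th></tr>",
    ]
    for name, res in bundle.subscales.items():
        if res.error is not None:
            parts.append(
                f"<tr><td>{name}</td><td colspan=9>{res.error}</td>"
                "<td><span class='badge' style='background:#f9a825'>"
                "incomplete</span></td></tr>"
            )
            continue
        f = res.fit
        hmin, hmax = np.nanmin(res.mokken.H_i), np.nanmax(res.mokken.H_i)
        lmin, lmax = res.loadings.loadings.min(), res.loadings.loadings.max()
        imin, imax = res.infits.item_infit.min(), res.infits.item_infit.max()
        color, label = _BADGE[res.verdict.status]
        parts.append(
            f"<tr><td>{name}</td><td>{res.reliability.alpha:.2f}</td>"
            f"<td>{res.reliability.omega_total:.2f}</td>"
            f"<td>{hmin:.2f}&ndash;{hmax:.2f}</td>"
            f"<td>{len(res.mokken.violations)}</td>"
            f"<td>{lmin:.2f}&ndash;{lmax:.2f}</td>"
            f"<td>{f.RMSEA:.2f}</td><td>{f.TLI:.2f}</td><td>{f.CFI:.2f}</td>"
            f"<td>{f.SRMR:.2f}</td><td>{imin:.1f}&ndash;{imax:.1f}</td>"
            f"<td><span class='badge' style='background:{color}'>{label}"
            "</span></td></tr>"
        )
    parts.append("</table>")
    for name, res in bundle.subscales.items():
        if res.error is not None or res.norm_table is None:
            continue
        nt = res.norm_table
        colors = nt.band_spec.colors
        parts.append(f"<h2>Normative references: {name}</h2>")
        df = nt.to_frame()
        for (age, gender), gdf in df.groupby(["age_group", "gender"], sort=False):
            parts.append(f"<h3>{age}, {gender}</h3><table><tr><th>Crude</th>"
                         "<th>Z</th><th>T</th><th>Percentile</th><th>Band</th></tr>")
            for rec in gdf.itertuples(index=False):
                parts.append(
                    f"<tr style='background:{colors[rec.band]}'>"
                    f"<td>{rec.crude}</td><td>{rec.Z:.2f}</td>"
                    f"<td>{rec.T_display:.0f}</td><td>{rec.percentile:.1f}</td>"
                    f"<td>{rec.band}</td></tr>"
                )
            parts.append("</table>")
    parts.append("</body></html>")
    return "\n".join(parts)


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write report.json, report.html, and norms_<subscale>.csv under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(render_json(bundle), encoding="utf-8")
    (out / "report.html").write_text(render_html(bundle), encoding="utf-8")
    for name, res in bundle.subscales.items():
        if res.norm_table is not None:
            res.norm_table.to_frame().to_csv(
                out / f"norms_{name}.csv", index=False
            )
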