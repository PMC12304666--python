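"""Pipeline orchestration and paper-style reporting.

`run_pipeline` ties the stages together: obtain trials (from CSV or from
the named simulation presets), classify the functional-response type per
instar x treatment, fit the random predator equation, assemble the
parameter table with CL-overlap group letters, run the damage trend
regressions, and write every output plus a run manifest (seed, versions,
config hash) so any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import LogisticFit, fit_polynomial_logistic
from .damage import fit_segmented_regression, fit_time_regression, summarize_endpoints
from .datamodel import (
    DamageSeries,
    PredationTrial,
    read_damage_series,
    read_trials,
    write_damage_series,
    write_results,
    write_trials,
)
from .rogers import RogersFit, fit_rogers, predict_na
from .simulate import DAMAGE_PRESETS, FR_PRESETS, simulate_damage, simulate_trials

logger = logging.getLogger("funcresp")

__all__ = ["RunConfig", "PipelineBundle", "StageError", "run_pipeline", "render_report", "render_figures"]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on; hashable into the manifest."""

    trials_path: str | None = None
    damage_path: str | None = None
    use_presets: bool = False
    seed: int = 0
    alpha: float = 0.05
    t_hours: float | None = None  # None: take exposure from the data
    ci_method: str = "wald"
    bootstrap_b: int = 999
    damage_replicates: int = 15
    out_dir: str = "results"
    figures: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not self.use_presets and self.trials_path is None and self.damage_path is None:
            raise ValueError("configuration error: provide trials/damage CSV paths or use_presets=True")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineBundle:
    config: RunConfig
    trials: list[PredationTrial] = field(default_factory=list)
    damage: list[DamageSeries] = field(default_factory=list)
    logistic_fits: list[LogisticFit] = field(default_factory=list)
    rogers_fits: list[RogersFit] = field(default_factory=list)
    damage_trends: pd.DataFrame | None = None
    endpoints: pd.DataFrame | None = None
    complete: bool = False


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:
                raise StageError(f"stage {name!r} failed: {e}") from e
            logger.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("inputs")
def _load_inputs(config: RunConfig) -> tuple[list[PredationTrial], list[DamageSeries]]:
    trials: list[PredationTrial] = []
    damage: list[DamageSeries] = []
    if config.use_presets:
        rng_seeds = np.random.SeedSequence(config.seed).spawn(len(FR_PRESETS) + len(DAMAGE_PRESETS))
        for i, (name, params) in enumerate(sorted(FR_PRESETS.items())):
            trials.extend(simulate_trials(params, seed=int(rng_seeds[i].generate_state(1)[0] % 2**31)))
        for j, (name, dparams) in enumerate(sorted(DAMAGE_PRESETS.items())):
            damage.extend(
                simulate_damage(
                    dparams,
                    replicates=config.damage_replicates,
                    seed=int(rng_seeds[len(FR_PRESETS) + j].generate_state(1)[0] % 2**31),
                )
            )
    if config.trials_path is not None:
        trials.extend(read_trials(config.trials_path))
    if config.damage_path is not None:
        damage.extend(read_damage_series(config.damage_path))
    return trials, damage


@_stage("classify")
def _classify_all(trials, alpha):
    fits = []
    for instar, treatment in sorted({(t.predator_instar, t.treatment) for t in trials}):
        group = [t for t in trials if (t.predator_instar, t.treatment) == (instar, treatment)]
        fits.append(fit_polynomial_logistic(group, alpha=alpha))
    return fits


@_stage("fit")
def _fit_all(trials, config: RunConfig):
    fits = []
    for instar, treatment in sorted({(t.predator_instar, t.treatment) for t in trials}):
        group = [t for t in trials if (t.predator_instar, t.treatment) == (instar, treatment)]
        fits.append(
            fit_rogers(
                group,
                t=config.t_hours,
                ci_method=config.ci_method,
                bootstrap_b=config.bootstrap_b,
                alpha=config.alpha,
                seed=config.seed,
            )
        )
    return fits


@_stage("damage")
def _damage_all(damage, alpha):
    rows = []
    for treatment in sorted({s.treatment for s in damage}):
        sub = [s for s in damage if s.treatment == treatment]
        release = {s.predator_release_day for s in sub}
        segmented = len(release) == 1 and None not in release and release != {0}
        for response in ("survivors", "defoliation_pct"):
            if segmented:
                pre, post = fit_segmented_regression(sub, response, alpha=alpha)
                fits = [("pre_release", pre), ("post_release", post)]
            else:
                fits = [("full", fit_time_regression(sub, response, alpha=alpha))]
            for label, f in fits:
                rows.append(
                    {
                        "treatment": treatment, "response": response, "segment": label,
                        "slope": f.slope, "se": f.slope_se, "cl_lo": f.slope_cl[0],
                        "cl_hi": f.slope_cl[1], "r2": f.r_squared, "n": f.n_points,
                    }
                )
    return pd.DataFrame(rows, columns=["treatment", "response", "segment", "slope", "se", "cl_lo", "cl_hi", "r2", "n"]), summarize_endpoints(damage)


def run_pipeline(config: RunConfig) -> PipelineBundle:
    """Run every stage and write the report bundle under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    bundle = PipelineBundle(config=config)
    try:
        bundle.trials, bundle.damage = _load_inputs(config)
        if bundle.trials:
            bundle.logistic_fits = _classify_all(bundle.trials, config.alpha)
            bundle.rogers_fits = _fit_all(bundle.trials, config)
            write_results(bundle.logistic_fits, bundle.rogers_fits, out)
            write_trials(bundle.trials, out / "trials.csv")
        if bundle.damage:
            bundle.damage_trends, bundle.endpoints = _damage_all(bundle.damage, config.alpha)
            bundle.damage_trends.to_csv(out / "damage_regression.csv", index=False)
            bundle.endpoints.to_csv(out / "endpoints.csv", index=False)
            write_damage_series(bundle.damage, out / "damage.csv")
        (out / "report.md").write_text(render_report(bundle))
        if config.figures and bundle.rogers_fits:
            render_figures(bundle, out)
        manifest = {
            "package": "funcresp",
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        bundle.complete = True
    finally:
        logger.removeHandler(fh)
        fh.close()
    return bundle


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_report(bundle: PipelineBundle) -> str:
    """Markdown summary mirroring the coefficient table / parameter table /
    per-instar response-curve structure of a functional-response study."""
    lines = ["# Functional-response analysis report", ""]
    if not bundle.logistic_fits and not bundle.damage:
        lines += ["**Warning:** empty bundle — no trials or damage series were provided.", ""]
    if bundle.logistic_fits:
        lines += ["## Response-type classification (logistic polynomial)", ""]
        lines += ["| instar | treatment | term | estimate | chi2 | p | type |", "|---|---|---|---|---|---|---|"]
        for f in bundle.logistic_fits:
            tag = "" if f.converged else " (UNCONVERGED: " + f.diagnostic + ")"
            for term in f.retained_terms:
                s = f.terms.get(term)
                if s is None:
                    continue
                lines.append(
                    f"| {f.instar} | {f.treatment} | {term} | {s.estimate:.4f} | {s.chi2:.2f} | {s.p:.3g} | {f.response_type}{tag} |"
                )
        lines.append("")
    if bundle.rogers_fits:
        lines += ["## Random-predator parameters (95% CL; shared letters = overlapping CLs)", ""]
        lines += [
            "| instar | treatment | a' (h^-1) | Th (h) | T/Th |",
            "|---|---|---|---|---|",
        ]
        for f in bundle.rogers_fits:
            grey = "" if f.converged else f" _unconverged: {f.diagnostic}_"
            lines.append(
                f"| {f.instar} | {f.treatment} "
                f"| {f.a_hat:.3g} ({f.a_cl[0]:.3g}-{f.a_cl[1]:.3g}) "
                f"| {f.th_hat:.3g} ({f.th_cl[0]:.3g}-{f.th_cl[1]:.3g}) "
                f"| {f.tth_hat:.3g} ({f.tth_cl[0]:.3g}-{f.tth_cl[1]:.3g}){grey} |"
            )
        lines.append("")
        for instar in sorted({f.instar for f in bundle.rogers_fits}):
            lines.append(f"### Instar {instar} response curve data")
            sub = [t for t in bundle.trials if t.predator_instar == instar]
            for treatment in sorted({t.treatment for t in sub}):
                grp = [t for t in sub if t.treatment == treatment]
                by_n0 = {}
                for t in grp:
                    by_n0.setdefault(t.n0, []).append(t.na)
                means = ", ".join(
                    f"N0={n0}: {np.mean(v):.2f}±{np.std(v, ddof=1)/np.sqrt(len(v)):.2f}" for n0, v in sorted(by_n0.items())
                )
                lines.append(f"- {treatment}: {means}")
            lines.append("")
    if bundle.damage_trends is not None:
        lines += ["## Damage trend regressions", "", bundle.damage_trends.to_markdown(index=False), ""]
    if bundle.endpoints is not None:
        lines += ["## Day-7 endpoints", "", bundle.endpoints.to_markdown(index=False), ""]
    return "\n".join(lines)


def render_figures(bundle: PipelineBundle, outdir) -> list[Path]:
    """One response-curve panel per instar: predicted Na vs N0 over observed
    means ± SE, both treatments on the same axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    paths = []
    for instar in sorted({f.instar for f in bundle.rogers_fits}):
        fig, ax = plt.subplots(figsize=(5, 4))
        for f in [f for f in bundle.rogers_fits if f.instar == instar]:
            grp = [t for t in bundle.trials if (t.predator_instar, t.treatment) == (instar, f.treatment)]
            by_n0 = {}
            for t in grp:
                by_n0.setdefault(t.n0, []).append(t.na)
            n0s = np.array(sorted(by_n0))
            means = np.array([np.mean(by_n0[n]) for n in n0s])
            ses = np.array([np.std(by_n0[n], ddof=1) / np.sqrt(len(by_n0[n])) for n in n0s])
            grid = np.linspace(0, n0s.max(), 200)
            style = dict(color="k", mfc="k") if f.treatment != "control" else dict(color="k", mfc="w")
            ax.errorbar(n0s, means, yerr=ses, fmt="o", label=f.treatment, **style)
            ax.plot(grid, predict_na(f.a_hat, f.th_hat, grid, f.exposure_h), "-" if f.treatment != "control" else "--", color="k")
        ax.set_xlabel("prey offered, N0")
        ax.set_ylabel("prey consumed, Na")
        ax.set_title(f"Instar {instar}")
        ax.legend()
        p = outdir / f"response_curve_instar{instar}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
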