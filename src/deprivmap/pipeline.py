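"""End-to-end orchestration: simulate -> index -> fit -> evaluate.

A run is driven by a single config mapping (usually a YAML file) and
produces a self-describing output directory: the deprivation index
table, posterior summaries, fit diagnostics, a human-readable report in
the conventional small-area reporting layout (RR with 95% CI per
quintile, random-effect SDs, -mean log CPO, DIC, effective parameters)
and a manifest with content hashes so a run can be verified and
reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bym import BYMPoissonRegression, Priors, posterior_rr
from .evaluate import attach_diagnostics
from .index import DP2Index, assign_quintiles
from .synthetic import SimulationConfig, make_study, read_study, write_study

log = logging.getLogger("deprivmap")

__all__ = ["run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage, msg):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


def load_config(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    with open(source) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _preflight(config: dict) -> None:
    """Validate the config before any compute: files must exist."""
    if "seed" not in config:
        raise PipelineError("preflight", "a seed is mandatory")
    if "simulate" not in config:
        for key in ("tracts", "indicators", "adjacency"):
            p = config.get("inputs", {}).get(key)
            if p is None or not Path(p).exists():
                raise PipelineError(
                    "preflight",
                    f"input path for {key!r} missing or nonexistent: {p}",
                )


def _report(rr: pd.DataFrame, diag, engine: str) -> str:
    lines = ["Deprivation-mortality ecological regression", "=" * 44,
             f"engine: {engine}", "",
             f"{'Deprivation (quintiles)':<28}{'RR (95% CI)':>22}"]
    for _, r in rr.iterrows():
        name = r["parameter"]
        if name.startswith("RR Q"):
            lines.append(
                f"{name:<28}{r['estimate']:>8.2f} ({r['lo95']:.2f} - {r['hi95']:.2f})"
            )
    lines.append("")
    lines.append(f"{'Random effects (sigma)':<28}{'Mean (SD)':>22}")
    for _, r in rr.iterrows():
        if r["parameter"].startswith("sigma"):
            sd = (r["hi95"] - r["lo95"]) / 2
            lines.append(f"{r['parameter'][:12]:<28}{r['estimate']:>10.3f} ({sd:.3f})")
    lines.append("")
    lines.append(f"{'-mean(log(CPO))':<40}{diag.neg_mean_log_cpo:>12.4f}")
    lines.append(f"{'Deviance Information Criterion (DIC)':<40}{diag.dic:>12.2f}")
    lines.append(f"{'Effective number of parameters':<40}{diag.p_eff:>12.2f}")
    return "\n".join(lines) + "\n"


def run_pipeline(config, out_dir=None) -> Path:
    """Run the configured stages; return the output directory.

    Config keys (all optional except ``seed``):

    - ``simulate``: SimulationConfig fields — generate a synthetic study;
      otherwise ``inputs`` must point at tracts/indicators/adjacency files.
    - ``index``: ``enabled`` (default true), ``base``.
    - ``fit``: ``engine`` ('laplace'|'mcmc'), ``n_iter``, ``n_burn``,
      prior overrides.
    - ``out``: output directory (overridden by ``out_dir``).
    """
    config = load_config(config)
    _preflight(config)
    out = Path(out_dir or config.get("out", "deprivmap_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = {
        "seed": seed,
        "config": config,
        "version": __version__,
        "stages": [],
        "files": {},
    }

    t0 = time.time()
    if "simulate" in config:
        sim_cfg = SimulationConfig(**{**config["simulate"], "seed": seed})
        study = make_study(sim_cfg)
        paths = write_study(study, out / "data")
        log.info("simulate: %d tracts written (seed %d)", study.n, seed)
        manifest["stages"].append({"stage": "simulate", "n": study.n,
                                   "seconds": round(time.time() - t0, 2)})
    else:
        ins = config["inputs"]
        study = read_study(Path(ins["tracts"]).parent)

    graph, outcomes, indicators = study.graph, study.outcomes, study.indicators

    index_cfg = config.get("index", {})
    if index_cfg.get("enabled", True):
        t = time.time()
        specs = study.specs
        dp2 = DP2Index(specs=specs, base=index_cfg.get("base", "min"))
        values = dp2.fit_transform(indicators)
        quint = assign_quintiles(values)
        idx_df = pd.DataFrame({
            "tract_id": outcomes["tract_id"],
            "frechet": dp2.result_.frechet,
            "dp2": values,
            "quintile": quint.labels,
        })
        idx_df.to_csv(out / "index.csv", index=False)
        with open(out / "diagnostics.json", "w") as fh:
            json.dump({
                "ordering": [specs[j].name for j in dp2.ordering_],
                "correction_factors": dp2.correction_factors_.tolist(),
                "n_iterations": dp2.n_iterations_,
                "cutpoints": quint.cutpoints.tolist(),
            }, fh, indent=1)
        outcomes = outcomes.copy()
        outcomes["quintile"] = quint.labels
        manifest["stages"].append({"stage": "index",
                                   "n_iterations": dp2.n_iterations_,
                                   "seconds": round(time.time() - t, 2)})

    fit_cfg = config.get("fit", {})
    if fit_cfg.get("enabled", True):
        t = time.time()
        priors = Priors(**fit_cfg.get("priors", {}))
        model = BYMPoissonRegression(
            engine=fit_cfg.get("engine", "laplace"),
            priors=priors,
            n_iter=int(fit_cfg.get("n_iter", 20000)),
            n_burn=int(fit_cfg.get("n_burn", 5000)),
            seed=seed,
        )
        try:
            model.fit(outcomes, graph=graph)
        except Exception as exc:
            raise PipelineError("fit", str(exc)) from exc
        res = model.result_
        fixed = res.fixed.copy()
        is_beta = fixed.index.str.startswith("beta_")
        for src_col, dst in (("mean", "rr"), ("q2.5", "rr_lo95"),
                             ("q97.5", "rr_hi95")):
            fixed.loc[is_beta, dst] = np.exp(fixed.loc[is_beta, src_col])
        fixed.to_csv(out / "posterior.csv")
        res.hyper.to_csv(out / "hyper.csv")
        field = res.latent.copy()
        field.insert(0, "tract_id", outcomes["tract_id"].to_numpy())
        diag = attach_diagnostics(res)
        field["cpo"] = diag.cpo
        field.to_csv(out / "field.csv", index=False)
        rr = posterior_rr(res)
        (out / "report.txt").write_text(_report(rr, diag, model.engine))
        with open(out / "fit.json", "w") as fh:
            json.dump({k: v for k, v in res.meta.items()
                       if isinstance(v, (int, float, str, list, dict, type(None)))},
                      fh, indent=1, default=float)
        manifest["stages"].append({"stage": "fit", "engine": model.engine,
                                   "seconds": round(time.time() - t, 2)})

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out
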