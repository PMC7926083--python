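"""Config-driven experiment runner and canonical fixture generation.

An experiment configuration is a plain mapping (YAML/JSON-compatible) with
``model``, ``kernel``, ``adapt`` and ``run`` blocks plus an optional
``sweep`` block of lists; the runner executes the cartesian sweep, one
chain per cell, and collects one mixing-summary row per cell.  Everything
is reproducible from (config, seed): each cell derives its own child seed
from the run seed and the cell index.

Example
-------
>>> cfg = {
...     "model": {"name": "lgss", "rho": 0.8, "sigma_x": 0.5, "sigma_y": 0.5,
...               "T": 50, "sigma_1": 10.0, "x1": 0.0},
...     "run": {"method": "cpf_bs", "n_iter": 2000, "burn_in": 500,
...             "N": 16, "seed": 1},
... }
>>> table = run_experiment(cfg)          # doctest: +SKIP
"""

from __future__ import annotations

import itertools
import json
import logging
from copy import deepcopy
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .adaptation import AdaptConfig, AdaptationState, aai_cpf
from .diagnostics import mixing_summary
from .fk import Trajectory, cpf_bs_kernel
from .kernels import fdi_rewrite
from .models import (
    LgssParams,
    SeirParams,
    SvParams,
    lgss_model,
    mvn_static_model,
    seir_initial_reference,
    seir_model,
    simulate_lgss,
    simulate_seir,
    simulate_sv,
    sv_model,
)

__all__ = ["run_cell", "run_experiment", "make_fixtures", "load_config"]

logger = logging.getLogger("diffcpf")

# sweepable keys: dotted paths into the config mapping
_DEFAULTS = {
    "kernel": {"kind": None, "beta": None, "cov": None},
    "adapt": {
        "rule": None,
        "alpha_star": 0.8,
        "c": None,
        "eigen_floor": 0.0,
        "step_exponent": 2.0 / 3.0,
    },
}


def load_config(path) -> dict:
    """Read a YAML (or JSON) experiment configuration."""
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def _lgss_params(mb: dict) -> LgssParams:
    return LgssParams(
        rho=mb.get("rho", 1.0),
        sigma_x=mb["sigma_x"],
        sigma_y=mb["sigma_y"],
        T=mb["T"],
        sigma_1=mb.get("sigma_1"),
        fully_diffuse=mb.get("fully_diffuse", False),
    )


def _sv_params(mb: dict) -> SvParams:
    return SvParams(
        sigma_x=mb["sigma_x"],
        sigma_y=mb["sigma_y"],
        T=mb["T"],
        sigma_1=mb.get("sigma_1"),
        fully_diffuse=mb.get("fully_diffuse", False),
    )


def _build_model_and_reference(mb: dict, rng: np.random.Generator):
    """Resolve the model block into (model, initial reference trajectory)."""
    name = mb["name"]
    if name in ("lgss", "rw"):
        params = _lgss_params(dict(mb, rho=1.0) if name == "rw" else mb)
        if "observations" in mb:
            y = np.asarray(mb["observations"], dtype=float)
            x = None
        elif "data" in mb:
            y = pd.read_csv(mb["data"])["y"].to_numpy()
            x = None
        else:
            x, y = simulate_lgss(params, mb.get("x1", 0.0), rng)
        model = lgss_model(y, params)
        ref_states = (x if x is not None else y)[:, None]
        return model, Trajectory(ref_states.copy())
    if name == "sv":
        params = _sv_params(mb)
        if "data" in mb:
            y = pd.read_csv(mb["data"])["y"].to_numpy()
            x = None
        else:
            x, y = simulate_sv(params, mb.get("x1", 0.0), rng)
        model = sv_model(y, params)
        ref_states = (x if x is not None else np.log(np.abs(y) + 1e-3))[:, None]
        return model, Trajectory(ref_states.copy())
    if name == "mvn":
        model = mvn_static_model(mb["d"], mb["sigma"])
        return model, Trajectory(np.zeros((1, mb["d"])))
    if name == "seir":
        params = SeirParams(
            n_pop=mb["n_pop"],
            r0_max=mb.get("r0_max", 10.0),
            a=mb.get("a", 1.0 / 3.0),
            gamma=mb.get("gamma", 1.0 / 7.0),
            e=mb.get("e", 0.15),
            p=mb["p"],
            sigma=mb["sigma"],
            T=mb["T"],
        )
        if "data" in mb:
            y = pd.read_csv(mb["data"])["y"].to_numpy()
        else:
            init = np.array([params.n_pop - 30, 20, 10, 0, mb.get("rho1", -1.0)])
            _, y = simulate_seir(params, init, rng)
        model = seir_model(y, params)
        return model, seir_initial_reference(y, params, rng)
    raise ValueError(f"unknown model {name!r}")


def run_cell(
    config: dict,
    rng: Optional[np.random.Generator] = None,
    chain_out=None,
) -> dict:
    """Run one chain described by a (non-sweep) config; return a summary row.

    The monitored chain is the coordinate given by ``run.monitor``
    (default: time 1, dimension 0 — the coordinate diffuse initialisation
    struggles with).  ``kernel.beta`` / ``kernel.cov`` freeze the
    initialisation kernel instead of adapting it.  With ``chain_out`` the
    full per-iteration trace of the monitored coordinates (``run.keep``,
    default the time-1 state vector) is written as CSV with a JSON
    metadata sidecar.
    """
    run = config["run"]
    if rng is None:
        rng = np.random.default_rng(run["seed"])
    model, reference = _build_model_and_reference(config["model"], rng)
    kernel_block = {**_DEFAULTS["kernel"], **config.get("kernel", {})}
    adapt_block = {**_DEFAULTS["adapt"], **config.get("adapt", {})}
    n_iter, burn_in, N = run["n_iter"], run["burn_in"], run["N"]
    method = run["method"]
    monitor_k, monitor_dim = run.get("monitor", (0, 0))
    keep = run.get("keep", [(k, d) for k in (0,) for d in range(model.state_dim)])

    if method == "cpf_bs":
        chain = np.empty((n_iter, model.T, model.state_dim))
        ref = reference
        for j in range(n_iter):
            ref, _ = cpf_bs_kernel(model, ref, N, rng, pickpath=run.get("pickpath", "bs"))
            chain[j] = ref.states
        series = chain[burn_in:, monitor_k, monitor_dim]
        trace = np.stack([chain[:, k, d] for k, d in keep], axis=1)
        extra = {}
    elif method in ("dgi", "fdi"):
        cfg = AdaptConfig(
            alpha_star=adapt_block["alpha_star"],
            c=adapt_block["c"],
            eigen_floor=adapt_block["eigen_floor"],
            step_exponent=adapt_block["step_exponent"],
        )
        initial_state = None
        if method == "dgi":
            family, rule = "ar", adapt_block["rule"] or "dgi"
            if kernel_block["beta"] is not None:  # fixed-beta kernel
                rule = None
                initial_state = AdaptationState.initial(
                    model.state_dim, config=cfg, beta0=float(kernel_block["beta"])
                )
        else:
            family, rule = "rw", adapt_block["rule"] or "aswam"
            if kernel_block["cov"] is not None:  # fixed-covariance kernel
                rule = None
                initial_state = AdaptationState.initial(
                    model.state_dim,
                    config=AdaptConfig(
                        alpha_star=cfg.alpha_star, c=1.0,
                        eigen_floor=cfg.eigen_floor,
                        step_exponent=cfg.step_exponent,
                    ),
                    sigma0=np.atleast_2d(np.asarray(kernel_block["cov"], dtype=float)),
                )
            if model.m1_sample is not None:
                model = fdi_rewrite(model)
        out = aai_cpf(
            model, family, rule, n_iter, burn_in, N, rng, reference,
            config=cfg, initial_state=initial_state,
        )
        series = out.coordinate_chain(monitor_k, monitor_dim)
        trace = np.stack([out.trajectories[:, k, d] for k, d in keep], axis=1)
        kept_alpha = out.alphas[burn_in:]
        extra = {"mean_alpha": float(np.nanmean(kept_alpha))}
    else:
        raise ValueError(f"unknown method {method!r} for run_cell")

    if chain_out is not None:
        chain_out = Path(chain_out)
        cols = {f"x{k + 1}_{d + 1}": trace[:, i] for i, (k, d) in enumerate(keep)}
        pd.DataFrame({"iteration": np.arange(1, n_iter + 1), **cols}).to_csv(
            chain_out, index=False
        )
        sidecar = {
            "model": config["model"], "method": method, "N": N,
            "n_iter": n_iter, "burn_in": burn_in, "seed": run.get("seed"),
            **extra,
        }
        chain_out.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, default=str)
        )

    summ = mixing_summary(series, n_total=n_iter, N=N)
    row = {
        "model": config["model"]["name"],
        "method": method,
        "N": N,
        "n_iter": n_iter,
        "burn_in": burn_in,
        "iact": summ.iact,
        "n_eff": summ.n_eff,
        "ire": summ.ire,
        "mean": float(series.mean()),
        "var": float(series.var(ddof=1)),
        **extra,
    }
    for key in ("sigma_1", "sigma_x", "sigma", "d"):
        if key in config["model"]:
            row[key] = config["model"][key]
    if adapt_block["rule"] or method in ("dgi", "fdi"):
        row["alpha_star"] = adapt_block["alpha_star"]
    return row


def _expand_sweep(config: dict):
    """Yield concrete configs over the cartesian product of sweep lists.

    Sweep keys are dotted paths, e.g. ``{"model.sigma_1": [10, 100]}``.
    """
    sweep = config.get("sweep")
    if not sweep:
        yield deepcopy(config), {}
        return
    keys = list(sweep)
    for combo in itertools.product(*(sweep[k] for k in keys)):
        cell = deepcopy(config)
        cell.pop("sweep")
        assignment = dict(zip(keys, combo))
        for path, value in assignment.items():
            block = cell
            *parents, leaf = path.split(".")
            for part in parents:
                block = block.setdefault(part, {})
            block[leaf] = value
        yield cell, assignment


def run_experiment(config: dict, out_dir: Optional[str] = None) -> pd.DataFrame:
    """Execute the configured sweep; optionally write results + metadata.

    One chain per sweep cell; each cell gets a child seed spawned
    deterministically from ``run.seed`` and the cell index.  When
    ``out_dir`` is given, writes ``results.csv`` and a ``meta.json``
    sidecar.
    """
    rows = []
    base_seed = config["run"]["seed"]
    for idx, (cell, assignment) in enumerate(_expand_sweep(config)):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, idx]))
        logger.info("cell %d: %s", idx, assignment or "(single)")
        row = run_cell(cell, rng)
        row["cell"] = idx
        rows.append(row)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.csv", index=False)
        meta = {"config": config, "seed": base_seed, "n_cells": len(rows)}
        (out / "meta.json").write_text(json.dumps(meta, indent=2, default=str))
        logger.info("wrote %s", out / "results.csv")
    return table


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the canonical small datasets used across the test-suite.

    * ``lgss.csv`` — noisy AR(1) path, T=50, rho=0.8, sigma_x=sigma_y=0.5,
      x1=0 (columns time, x, y);
    * ``sv.csv`` — stochastic volatility path, T=50, sigma_x=sigma_y=1;
    * ``seir.csv`` — synthetic epidemic, n_pop=10^4, T=60, sigma=0.15,
      p=0.134 (columns time, S, E, I, R, rho, y).

    Returns a mapping name -> written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1]))
    files = {}

    lp = LgssParams(rho=0.8, sigma_x=0.5, sigma_y=0.5, T=50, sigma_1=10.0)
    x, y = simulate_lgss(lp, 0.0, rng)
    df = pd.DataFrame({"time": np.arange(1, lp.T + 1), "x": x, "y": y})
    files["lgss"] = out / "lgss.csv"
    df.to_csv(files["lgss"], index=False)

    sp = SvParams(sigma_x=1.0, sigma_y=1.0, T=50, sigma_1=10.0)
    x, y = simulate_sv(sp, 0.0, rng)
    df = pd.DataFrame({"time": np.arange(1, sp.T + 1), "x": x, "y": y})
    files["sv"] = out / "sv.csv"
    df.to_csv(files["sv"], index=False)

    ep = SeirParams(
        n_pop=10_000, r0_max=10.0, a=1.0 / 3.0, gamma=1.0 / 7.0,
        e=0.15, p=0.134, sigma=0.15, T=60,
    )
    init = np.array([ep.n_pop - 30, 20, 10, 0, -1.0])
    path, counts = simulate_seir(ep, init, rng)
    df = pd.DataFrame(
        {
            "time": np.arange(1, ep.T + 1),
            "S": path[:, 0].astype(int),
            "E": path[:, 1].astype(int),
            "I": path[:, 2].astype(int),
            "R": path[:, 3].astype(int),
            "rho": path[:, 4],
            "y": counts,
        }
    )
    files["seir"] = out / "seir.csv"
    df.to_csv(files["seir"], index=False)

    return {k: str(v) for k, v in files.items()}
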