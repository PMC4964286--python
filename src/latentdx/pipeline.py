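"""End-to-end analysis: counts -> priors -> Bayesian fit -> naive fit -> report.

A single flat configuration file (YAML or JSON) drives the whole run:

.. code-block:: yaml

    counts: internal_wind        # or a path to a .csv/.json counts file
    priors: internal_wind        # or a path to a prior configuration file
    gold_test: 3                 # reference test for the naive comparison
    sampler:
      chains: 3
      iterations: 60000
      burnin: 10000
      thin: 5
      seed: 20160617
    output:
      dir: results

Every effective setting (including defaulted ones) is echoed into the
emitted report for provenance.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .data import CrossClassifiedCounts, internal_wind_stroke
from .model import LatentClassModel
from .naive import NaiveEstimates, naive_accuracy
from .priors import PriorSpecification
from .results import LatentClassResults

logger = logging.getLogger("latentdx")

_SAMPLER_DEFAULTS = {
    "chains": 3,
    "iterations": 60_000,
    "burnin": 10_000,
    "thin": 5,
    "seed": 0,
}


@dataclass
class ReportBundle:
    """Everything one analysis run produced."""

    bayes: LatentClassResults | None
    naive: NaiveEstimates | None
    comparison: pd.DataFrame
    config: dict
    converged: bool


def read_counts(path_or_name: str | Path) -> CrossClassifiedCounts:
    """Resolve a counts reference: the packaged dataset name or a file path."""
    if str(path_or_name) == "internal_wind":
        return internal_wind_stroke()
    return CrossClassifiedCounts.from_file(path_or_name)


def read_priors(path_or_name: str | Path) -> PriorSpecification:
    if str(path_or_name) == "internal_wind":
        return PriorSpecification.internal_wind()
    if str(path_or_name) == "uniform":
        return PriorSpecification.uniform()
    return PriorSpecification.from_file(path_or_name)


def _load_config(config_path: str | Path) -> dict:
    path = Path(config_path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ValueError(f"cannot read config {path}: {exc}") from exc
    try:
        payload = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"{path}: malformed configuration: {exc}") from exc
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return payload


def comparison_table(
    bayes: LatentClassResults | None, naive: NaiveEstimates | None
) -> pd.DataFrame:
    """Side-by-side estimate table: latent-class vs gold-standard-assumed."""
    index = ["Se1", "Se2", "Se3", "Sp1", "Sp2", "Sp3", "prevalence"]
    table = pd.DataFrame(index=index)
    table.index.name = "parameter"
    if bayes is not None:
        post = bayes.posterior.table
        table["bayes_median"] = post["median"].reindex(index)
        table["bayes_ci_lower"] = post["ci_lower"].reindex(index)
        table["bayes_ci_upper"] = post["ci_upper"].reindex(index)
    if naive is not None:
        nf = naive.to_frame()
        table["naive_estimate"] = nf["estimate"].reindex(index)
        table["naive_ci_lower"] = nf["ci_lower"].reindex(index)
        table["naive_ci_upper"] = nf["ci_upper"].reindex(index)
    return table


def run_analysis(
    config_path: str | Path | None = None,
    config: dict | None = None,
    out_dir: str | Path | None = None,
) -> ReportBundle:
    """Run the full analysis described by a configuration.

    Writes, under the configured output directory: ``summary.csv`` (the
    side-by-side table), ``draws.csv``, ``diagnostics.json``,
    ``estimates.json`` and ``config_echo.yaml``.
    """
    if config is None:
        if config_path is None:
            config = {}
        else:
            config = _load_config(config_path)

    effective = {
        "counts": config.get("counts", "internal_wind"),
        "priors": config.get("priors", "internal_wind"),
        "gold_test": config.get("gold_test", 3),
        "models": config.get("models", ["bayes", "naive"]),
        "sampler": {**_SAMPLER_DEFAULTS, **config.get("sampler", {})},
        "output": config.get("output", {}),
    }
    if out_dir is not None:
        effective["output"] = {**effective["output"], "dir": str(out_dir)}

    counts = read_counts(effective["counts"])
    logger.info("counts loaded: n=%d, tests=%s", counts.n, counts.labels)

    bayes = None
    if "bayes" in effective["models"]:
        prior = read_priors(effective["priors"])
        s = effective["sampler"]
        logger.info(
            "fitting latent-class model: chains=%d iterations=%d seed=%s",
            s["chains"], s["iterations"], s["seed"],
        )
        t0 = time.perf_counter()
        bayes = LatentClassModel(counts, prior).fit(
            n_chains=int(s["chains"]),
            n_iterations=int(s["iterations"]),
            n_burnin=int(s["burnin"]),
            thin=int(s["thin"]),
            seed=int(s["seed"]),
        )
        logger.info("MCMC finished in %.1fs", time.perf_counter() - t0)
        for chain in bayes.chains:
            logger.debug(
                "chain %d acceptance rates: %s",
                chain.chain_id, chain.acceptance_rates,
            )

    naive = None
    if "naive" in effective["models"]:
        naive = naive_accuracy(counts, gold=int(effective["gold_test"]))

    table = comparison_table(bayes, naive)
    converged = bayes.converged if bayes is not None else True
    bundle = ReportBundle(
        bayes=bayes, naive=naive, comparison=table,
        config=effective, converged=converged,
    )

    target = effective["output"].get("dir")
    if target:
        write_report(bundle, target)
    return bundle


def write_report(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.comparison.to_csv(out / "summary.csv")
    estimates = {
        "comparison": json.loads(bundle.comparison.to_json(orient="index")),
        "converged": bundle.converged,
    }
    diagnostics = {}
    if bundle.bayes is not None:
        bundle.bayes.draws_frame().to_csv(out / "draws.csv", index=False)
        bundle.bayes.summary().to_csv(out / "posterior_summary.csv")
        diagnostics = bundle.bayes.diagnostics()
    if bundle.naive is not None:
        estimates["naive"] = json.loads(
            bundle.naive.to_frame().to_json(orient="index")
        )
    (out / "estimates.json").write_text(json.dumps(estimates, indent=1) + "\n")
    (out / "diagnostics.json").write_text(
        json.dumps(diagnostics, indent=1, default=float) + "\n"
    )
    (out / "config_echo.yaml").write_text(yaml.safe_dump(bundle.config))
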