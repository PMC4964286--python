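"""Results object for the Bayesian latent-class fit."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import PARAM_NAMES
from .sampler import (
    PosteriorSummary,
    convergence_report,
    mirror_mode_fraction,
    summarize,
)


class LatentClassResults:
    """Posterior summaries of a :class:`~latentdx.model.LatentClassModel` fit.

    Attributes
    ----------
    chains : list of PosteriorChain
        Retained draws per chain.
    posterior : PosteriorSummary
        Pooled medians, 95% equal-tailed credible intervals, MCSE, R-hat
        and effective sample sizes.
    """

    def __init__(self, model, chains, config):
        self.model = model
        self.chains = chains
        self.config = config
        self.posterior: PosteriorSummary = summarize(chains)

    # ------------------------------------------------------------ accessors

    @property
    def medians(self) -> pd.Series:
        return self.posterior.table["median"]

    @property
    def ci(self) -> pd.DataFrame:
        return self.posterior.table[["ci_lower", "ci_upper"]]

    @property
    def rhat(self) -> pd.Series:
        return self.posterior.table["rhat"]

    @property
    def ess(self) -> pd.Series:
        return self.posterior.table["ess"]

    def draws_frame(self) -> pd.DataFrame:
        """All retained draws, one row per draw, with a chain column."""
        return pd.concat([c.to_frame() for c in self.chains], ignore_index=True)

    def convergence(self, threshold: float = 1.05) -> pd.DataFrame:
        return convergence_report(self.chains, threshold=threshold)

    @property
    def converged(self) -> bool:
        return bool((self.posterior.table["rhat"] < 1.05).all())

    def diagnostics(self) -> dict:
        """Sampler health: acceptance rates, mirror-mode mass, warnings."""
        return {
            "acceptance_rates": {
                f"chain_{c.chain_id}": dict(
                    zip(PARAM_NAMES, np.round(c.acceptance_rates, 4))
                )
                for c in self.chains
            },
            "mirror_mode_fraction": mirror_mode_fraction(self.chains),
            "max_rhat": float(self.posterior.table["rhat"].max()),
            "min_ess": float(self.posterior.table["ess"].min()),
            "notes": list(self.posterior.notes),
        }

    # -------------------------------------------------------------- display

    def summary(self) -> pd.DataFrame:
        """The posterior summary table (median, 95% CI, MCSE, R-hat, ESS)."""
        return self.posterior.table.copy()

    def summary_text(self) -> str:
        df = self.summary()
        lines = [
            "Bayesian latent-class diagnostic accuracy (no gold standard)",
            f"counts n={self.model.counts.n}; tests: "
            + ", ".join(self.model.counts.labels),
            f"chains={self.config.n_chains}  iterations={self.config.n_iterations}"
            f"  burn-in={self.config.n_burnin}  thin={self.config.thin}"
            f"  seed={self.config.seed}",
            "",
            df.round(4).to_string(),
            "",
            f"max R-hat: {df['rhat'].max():.4f}   "
            f"mirror-mode fraction: {mirror_mode_fraction(self.chains):.4f}",
        ]
        return "\n".join(lines)

    def plot_trace(self, parameters=None, path: str | Path | None = None):
        """Trace plots per parameter (one panel each, chains overlaid)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        parameters = list(parameters or PARAM_NAMES)
        fig, axes = plt.subplots(
            len(parameters), 1, figsize=(8, 1.8 * len(parameters)), sharex=True
        )
        axes = np.atleast_1d(axes)
        for ax, name in zip(axes, parameters):
            i = PARAM_NAMES.index(name)
            for c in self.chains:
                ax.plot(c.draws[:, i], lw=0.4, alpha=0.8)
            ax.set_ylabel(name)
        axes[-1].set_xlabel("retained draw")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    # ----------------------------------------------------------------- I/O

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary().to_csv(out / "posterior_summary.csv")
        self.draws_frame().to_csv(out / "draws.csv", index=False)
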