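"""The symmetric subsampling experiment.

For each sample size ``k`` (diploid individuals per population, default 1 up
to full minus one), draw ``reps_per_size`` subsampled datasets without
replacement, fit each with a best-of-``runs_per_rep`` multi-start, and
summarize per-size parameter means with standard errors. Starting values for
every subsample fit are the parameters optimized on the full dataset, the
"predetermined best-fit parameters" of the protocol this package emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import FitConfig, FitResult, fit_best_of
from .model import PARAM_NAMES
from .simulate import GenotypeDataset
from .spectra import build_joint_sfs, subsample_individuals

__all__ = ["ExperimentDesign", "ExperimentResult", "run_experiment", "summarize"]

RESULT_PARAMS = PARAM_NAMES + ("theta",)


@dataclass
class ExperimentDesign:
    dataset: GenotypeDataset
    full_fit: FitResult
    sizes: list | None = None  # default 1 .. full-1
    reps_per_size: int = 25
    runs_per_rep: int = 5
    engine_R: int = 10_000
    seed: int = 0
    polarized: bool = False

    def __post_init__(self):
        full = min(self.dataset.n1, self.dataset.n2)
        if self.sizes is None:
            self.sizes = list(range(1, full))
        if any(k < 1 or k > full - 1 for k in self.sizes):
            raise ValueError(f"sizes must lie in [1, {full - 1}]")
        if self.reps_per_size < 2:
            raise ValueError("reps_per_size must be >= 2")
        if self.full_fit.failed or not np.isfinite(self.full_fit.loglik):
            raise ValueError("full_fit must be a successful fit")


@dataclass
class ExperimentResult:
    replicates: pd.DataFrame  # one row per (size, rep)
    design_seed: int
    n_failed: int
    fits: dict = field(default_factory=dict)  # (size, rep) -> FitResult


def run_experiment(design: ExperimentDesign) -> ExperimentResult:
    """Run the full subsampling protocol; deterministic given the root seed."""
    root = np.random.SeedSequence(design.seed)
    rows = []
    fits = {}
    n_failed = 0
    for size in design.sizes:
        for rep in range(design.reps_per_size):
            ss = np.random.SeedSequence(design.seed, spawn_key=(size, rep))
            rng = np.random.default_rng(ss)
            sub = subsample_individuals(design.dataset, size, rng)
            row = {
                "size": size,
                "rep": rep,
                "dropped_loci": sub.provenance["dropped_monomorphic"],
                "n_loci": sub.n_loci,
                "individuals": ";".join(sub.sample_ids),
            }
            if sub.n_loci == 0:
                n_failed += 1
                row.update({"failed": True})
                rows.append(row)
                continue
            sfs = build_joint_sfs(sub, polarized=design.polarized)
            config = FitConfig(
                start=design.full_fit.params_hat,
                perturb_fold=1.0,
                k_runs=design.runs_per_rep,
                engine_R=design.engine_R,
                engine_seed=int(ss.generate_state(1)[0] % 2**31),
                seed=int(ss.generate_state(2)[1] % 2**31),
            )
            fit = fit_best_of(sfs, config)
            fits[(size, rep)] = fit
            if fit.failed:
                n_failed += 1
                row.update({"failed": True})
            else:
                row.update(
                    {
                        "failed": False,
                        "nu1": fit.params_hat.nu1,
                        "nu2": fit.params_hat.nu2,
                        "T": fit.params_hat.T,
                        "m": fit.params_hat.m,
                        "theta": fit.theta_hat.theta_hat,
                        "loglik": fit.loglik,
                        "converged": fit.converged,
                        "hit_any_bound": any(fit.hit_bounds.values()),
                    }
                )
            rows.append(row)
    return ExperimentResult(
        replicates=pd.DataFrame(rows),
        design_seed=design.seed,
        n_failed=n_failed,
        fits=fits,
    )


def summarize(result: ExperimentResult) -> pd.DataFrame:
    """Per-size mean and SEM of each parameter (SEM = SD / sqrt(n_reps)).

    Sizes with fewer than two successful replicates are omitted with a
    warning.
    """
    import warnings

    rows = []
    reps = result.replicates
    ok = reps[~reps["failed"]] if "failed" in reps else reps
    for size, grp in ok.groupby("size"):
        if len(grp) < 2:
            warnings.warn(
                f"size {size}: fewer than 2 successful replicates; omitted",
                stacklevel=2,
            )
            continue
        for param in RESULT_PARAMS:
            vals = grp[param].to_numpy(dtype=float)
            rows.append(
                {
                    "parameter": param,
                    "size": int(size),
                    "mean": vals.mean(),
                    "sem": vals.std(ddof=1) / np.sqrt(len(vals)),
                    "n_reps": len(vals),
                }
            )
    return pd.DataFrame(rows, columns=["parameter", "size", "mean", "sem", "n_reps"])
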