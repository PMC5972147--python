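"""Synthetic single-cell and qPCR data with the noise structure the
analyses assume, plus ground-truth fixtures for parameter-recovery tests.

Single-cell immunofluorescence fold-change distributions are unimodal and
right-skewed with cell-to-cell coefficients of variation of order
30–60%; they are emulated as lognormal draws around a mean trajectory,
optionally mixed with a non-responder subpopulation sitting at basal
levels.  Triplicate qPCR fold changes carry multiplicative replicate
noise (lognormal on the log2 scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .models import build_model
from .params import ParameterSet
from .simulate import basal_state, simulate
from .targets import CONTEXTS, FitTarget
from .stimulus import StimulusProfile


@dataclass(frozen=True)
class PopulationSpec:
    """Lognormal single-cell population around a mean fold-change trajectory."""

    cv: float = 0.4                  # cell-to-cell coefficient of variation
    n_cells: int = 1000              # cells per time point
    nonresponder_fraction: float = 0.0
    nonresponder_level: float = 1.0  # basal fold change
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cv > 0:
            raise ValueError("cv must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.nonresponder_fraction <= 1.0:
            raise ValueError("nonresponder_fraction must lie in [0, 1]")


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float,
                      size: int) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and CV."""
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def sample_population(spec: PopulationSpec, mean_of_t: Callable[[float], float],
                      times) -> pd.DataFrame:
    """Per-cell fold changes at each time point (tidy frame: time_h, cell, value).

    With probability 1-f a cell follows the mean trajectory with the given
    CV; otherwise it is a non-responder around ``nonresponder_level``.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    frames = []
    for t in times:
        m = float(mean_of_t(float(t)))
        resp = rng.random(spec.n_cells) >= spec.nonresponder_fraction
        vals = np.empty(spec.n_cells)
        vals[resp] = _lognormal_around(rng, m, spec.cv, int(resp.sum()))
        n_nr = int((~resp).sum())
        if n_nr:
            vals[~resp] = _lognormal_around(rng, spec.nonresponder_level,
                                            spec.cv, n_nr)
        frames.append(pd.DataFrame({
            "time_h": t, "cell": np.arange(spec.n_cells),
            "responder": resp, "value": vals}))
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class QpcrSpec:
    """Replicate qPCR fold changes with multiplicative noise (log2 scale)."""

    true_fold: tuple[float, ...]
    noise_sd_log2: float = 0.2
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("qPCR emulation requires >= 2 replicates")
        if not self.noise_sd_log2 > 0:
            raise ValueError("noise_sd_log2 must be > 0")
        if any(v <= 0 for v in self.true_fold):
            raise ValueError("true fold changes must be > 0")


def sample_qpcr(spec: QpcrSpec) -> np.ndarray:
    """(n_timepoints, replicates) noisy fold changes; the geometric mean of
    replicates is an asymptotically unbiased estimate of the truth."""
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    truth = np.asarray(spec.true_fold)[:, None]
    noise = rng.normal(0.0, spec.noise_sd_log2,
                       size=(truth.shape[0], spec.replicates))
    return truth * np.exp2(noise)


#: contexts and times sampled by the recovery fixture
RECOVERY_CONTEXTS = ("continuous", "smad_inh_early", "gli_inh_late")
RECOVERY_TIMES = (12.0, 24.0, 48.0, 72.0)


def make_recovery_fixture(true_params: ParameterSet, free_names: tuple[str, ...],
                          seed: int, noise_sd_log2: float = 0.05,
                          species: str = "SNAIL1_mRNA") -> tuple[list[FitTarget], ParameterSet]:
    """Noisy fit targets generated from a known full-model parameter set.

    Simulates the full model under control and early/late inhibition
    contexts, perturbs the fold changes at {12, 24, 48, 72} h with
    qPCR-like noise, and packages them as targets whose truth is
    ``true_params`` — the harness for the parameter-recovery test of the
    Monte Carlo search (searching over ``free_names``).
    """
    model = build_model("FULL")
    bas = basal_state(model, true_params)
    rng = np.random.Generator(np.random.PCG64(seed))
    targets: list[FitTarget] = []
    for ctx in RECOVERY_CONTEXTS:
        stim, inh = CONTEXTS[ctx]
        traj = simulate(model, true_params, stim, inh, t_max=72.0,
                        basal=bas, method="fast")
        for t in RECOVERY_TIMES:
            v = traj.value(species, t)
            if noise_sd_log2 > 0:
                v *= float(np.exp2(rng.normal(0.0, noise_sd_log2)))
            targets.append(FitTarget(species, t, ctx, float(v),
                                     kind="eq", tolerance=0.15, weight=1.0,
                                     note=f"recovery fixture seed={seed}"))
    truth = true_params.replace(name=f"{true_params.name}:recovery_truth")
    return targets, truth
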