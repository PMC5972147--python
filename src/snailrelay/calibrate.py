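"""Staged Monte Carlo calibration of the full relay model.

The network decomposes hierarchically: the GSK3 phosphorylation switch is
driven only by the stimulus, the SMAD module only by stimulus and its own
feedback, and the GLI1/SNAIL1 relay reads both.  Calibration therefore
runs three searches in sequence — GSK3 form fractions, nuclear pSMAD
shape, then the relay against the printed inhibition percentages — each
stage pinning the previous stage's best fit.  This keeps every search in
a small, identifiable subspace while the constraint data remain plain
FitTarget JSON files shipped with the package.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass
from pathlib import Path

from .models import build_model
from .params import ParameterSet
from .search import SearchConfig, SearchResult, mc_search
from .targets import CostEvaluator, load_targets

#: packaged data directory
def data_path(name: str) -> Path:
    return Path(resources.files("snailrelay.data") / name)


def design_center() -> ParameterSet:
    """Prior-center parameter set (order-of-magnitude design values)."""
    return ParameterSet.from_json(data_path("params_design_center.json"))


def calibrated_params() -> ParameterSet:
    """The packaged calibrated full-model parameter set."""
    return ParameterSet.from_json(data_path("params_full_calibrated.json"))


@dataclass(frozen=True)
class Stage:
    name: str
    target_file: str
    free: tuple[str, ...]
    step: float = 0.12
    init_from_base: bool = False


_RELAY_FREE = ("b_S", "a_SR", "K_SR", "a_SG", "K_SG", "d_Sm", "d_Sp", "eps_Sp",
               "b_G", "a_GR", "K_GR", "a_GG", "K_GG", "n_GG", "d_Gm",
               "k_tg", "rho1", "lam_loc", "k_in", "d_Gn", "eps_Gn")

STAGES: tuple[Stage, ...] = (
    Stage("gsk3_switch", "targets_gsk3_forms.json",
          ("r_aa", "k_aa", "tau_b", "r_d", "k_d", "tau_d")),
    Stage("smad_module", "targets_psmad_dynamics.json",
          ("b_R", "k_R", "K_IR", "d_R", "b_I", "k_I", "K_RI", "d_I",
           "k_per", "K_per", "r_per")),
    # the relay stage refines from the prior center: its 21-parameter
    # landscape is a narrow ridge (ignition must be delayed yet sustained)
    # where walks from random corners settle into basins that break the
    # duration discrimination; all walks start at the center and explore
    # with moderate steps, then a small-step polish follows
    Stage("gli_snail_relay", "targets_relay_calibration.json",
          _RELAY_FREE, step=0.06, init_from_base=True),
    Stage("relay_polish", "targets_relay_calibration.json",
          _RELAY_FREE, step=0.025, init_from_base=True),
)


def calibrate_full(seed: int, n_starts: int = 20, n_iters: int = 2000,
                   base: ParameterSet | None = None,
                   stages: tuple[Stage, ...] = STAGES,
                   verbose: bool = False) -> tuple[ParameterSet, dict]:
    """Run the staged search and return (calibrated set, per-stage report)."""
    model = build_model("FULL")
    prior = base if base is not None else design_center()
    current = prior
    report: dict = {"seed": seed, "stages": []}
    for i, stage in enumerate(stages):
        targets = load_targets(data_path(stage.target_file))
        cfg = SearchConfig(n_starts=n_starts, n_iters=n_iters, step=stage.step,
                           seed=seed + 1000 * i, free=stage.free,
                           init_from_base=stage.init_from_base)
        res: SearchResult = mc_search(model, targets, current, cfg)
        # keep the prior box anchored to the design center across stages
        current = ParameterSet(res.best_params.values, dict(prior.bounds),
                               name=f"calibrated[{stage.name}]")
        ev = CostEvaluator(model, targets)
        stage_rep = {
            "stage": stage.name,
            "best_cost": res.best_cost,
            "max_residual": ev.max_residual(current),
            "passes": bool(ev.passes(current)),
            "acceptance_rate": round(res.acceptance_rate, 3),
        }
        report["stages"].append(stage_rep)
        if verbose:
            print(f"[{stage.name}] cost={res.best_cost:.3f} "
                  f"max_resid={stage_rep['max_residual']:.2f} pass={stage_rep['passes']}")
    current = current.replace(name=f"full_calibrated_seed{seed}")
    report["passes_all"] = all(s["passes"] for s in report["stages"])
    return current, report
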