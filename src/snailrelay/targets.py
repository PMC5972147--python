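"""Calibration constraints (fit targets) and the weighted cost function.

A :class:`FitTarget` pins a species value — fold change, absolute GSK3
fraction, or a ratio between two simulation contexts — at one time point,
with a relative tolerance and weight.  The printed fold-change numbers the
models are calibrated against (e.g. "SNAIL1 mRNA reduced to ~9% of
control") are shipped as JSON documents of these targets, so they are
data, not code.

The cost is ``sum_i w_i * ((x_i - v_i) / (tol_i * v_i))**2`` over targets
(one-sided for ``ge``/``le`` kinds); "all targets within tolerance",
i.e. max normalized residual <= 1, is the fit-pass criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import dump_json, load_validated_json
from .models import NetworkModel
from .params import ParameterSet
from .simulate import SimulationError, Trajectory, basal_state, simulate
from .stimulus import InhibitorSpec, StimulusProfile

#: cost assigned to parameter sets with no basal state / failed integration
PENALTY_COST = 1.0e6

#: named experimental protocols used by targets and reports
CONTEXTS: dict[str, tuple[StimulusProfile, tuple[InhibitorSpec, ...]]] = {
    "none": (StimulusProfile.zero(), ()),
    "continuous": (StimulusProfile(), ()),
    "pulse2": (StimulusProfile.pulse(2.0), ()),
    "pulse8": (StimulusProfile.pulse(8.0), ()),
    "smad_inh_early": (StimulusProfile(), (InhibitorSpec("SMAD_PHOS", 0.0),)),
    "smad_inh_late": (StimulusProfile(), (InhibitorSpec("SMAD_PHOS", 48.0),)),
    "gli_inh_early": (StimulusProfile(), (InhibitorSpec("GLI1_ACT", 0.0),)),
    "gli_inh_late": (StimulusProfile(), (InhibitorSpec("GLI1_ACT", 48.0),)),
    "gsk3_inh_no_tgf": (StimulusProfile.zero(), (InhibitorSpec("GSK3_ACT", 0.0),)),
}

_KINDS = ("eq", "ge", "le")
_UNITS = ("fold", "fraction")


@dataclass(frozen=True)
class FitTarget:
    """One calibration constraint.

    ``value`` is the target fold change (``units="fold"``), the absolute
    concentration (``units="fraction"``, used for GSK3 form fractions), or
    — when ``ref_context``/``ref_time_h`` is set — the target ratio of the
    species value to the same species in the reference context/time.
    """

    species: str
    time_h: float
    context: str
    value: float
    kind: str = "eq"
    tolerance: float = 0.2
    weight: float = 1.0
    units: str = "fold"
    ref_context: str | None = None
    ref_time_h: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"target kind must be one of {_KINDS}, got {self.kind!r}")
        if self.units not in _UNITS:
            raise ValueError(f"target units must be one of {_UNITS}, got {self.units!r}")
        if not self.value > 0:
            raise ValueError(f"target value must be > 0, got {self.value}")
        if not self.tolerance > 0:
            raise ValueError(f"target tolerance must be > 0, got {self.tolerance}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.ref_context is not None and self.ref_context not in CONTEXTS:
            raise ValueError(f"unknown ref_context {self.ref_context!r}")

    def observed(self, trajs: dict[str, Trajectory]) -> float:
        traj = trajs[self.context]
        if self.units == "fraction":
            x = traj.raw(self.species, self.time_h)
        else:
            x = traj.value(self.species, self.time_h)
        if self.ref_context is not None or self.ref_time_h is not None:
            rctx = self.ref_context or self.context
            rt = self.ref_time_h if self.ref_time_h is not None else self.time_h
            rtraj = trajs[rctx]
            ref = rtraj.raw(self.species, rt) if self.units == "fraction" \
                else rtraj.value(self.species, rt)
            x = x / ref if ref != 0 else np.inf
        return float(x)

    def residual(self, x: float) -> float:
        """Signed normalized residual; |r| <= 1 means 'within tolerance'."""
        r = (x - self.value) / (self.tolerance * self.value)
        if self.kind == "ge":
            return min(r, 0.0)
        if self.kind == "le":
            return max(r, 0.0)
        return r


def save_targets(targets: list[FitTarget], path: str | Path, note: str = "") -> None:
    dump_json({
        "kind": "fit_targets",
        "note": note,
        "targets": [
            {k: v for k, v in t.__dict__.items() if not (k == "note" and not v)}
            for t in targets],
    }, path)


def load_targets(path: str | Path) -> list[FitTarget]:
    doc = load_validated_json(path, kind="fit_targets")
    return [FitTarget(**t) for t in doc["targets"]]


class CostEvaluator:
    """Cached simulate-and-score harness for one (model, target list) pair.

    Each parameter vector triggers one basal-state solve and one fast
    simulation per distinct context; failures yield :data:`PENALTY_COST`.
    """

    def __init__(self, model: NetworkModel, targets: list[FitTarget],
                 method: str = "fast", dt: float = 0.25):
        self.model = model
        self.targets = list(targets)
        self.method = method
        self.dt = dt
        ctxs: dict[str, float] = {}
        for t in self.targets:
            ctxs[t.context] = max(ctxs.get(t.context, 0.0), t.time_h)
            if t.ref_context is not None:
                rt = t.ref_time_h if t.ref_time_h is not None else t.time_h
                ctxs[t.ref_context] = max(ctxs.get(t.ref_context, 0.0), rt)
            elif t.ref_time_h is not None:
                ctxs[t.context] = max(ctxs[t.context], t.ref_time_h)
        self.context_horizons = {c: max(8.0, h) for c, h in ctxs.items()}

    def simulate_contexts(self, params: ParameterSet | np.ndarray,
                          method: str | None = None) -> dict[str, Trajectory]:
        method = method or self.method
        bas = basal_state(self.model, params)
        out: dict[str, Trajectory] = {}
        for ctx, horizon in self.context_horizons.items():
            stim, inh = CONTEXTS[ctx]
            out[ctx] = simulate(self.model, params, stim, inh, t_max=horizon,
                                dt=self.dt, basal=bas, method=method)
        return out

    def residuals(self, params: ParameterSet | np.ndarray) -> np.ndarray:
        trajs = self.simulate_contexts(params)
        return np.array([t.residual(t.observed(trajs)) for t in self.targets])

    def cost(self, params: ParameterSet | np.ndarray) -> float:
        if not self.targets:
            return 0.0
        try:
            res = self.residuals(params)
        except SimulationError:
            return PENALTY_COST
        if not np.all(np.isfinite(res)):
            return PENALTY_COST
        w = np.array([t.weight for t in self.targets])
        return float(np.sum(w * res * res))

    def max_residual(self, params: ParameterSet | np.ndarray) -> float:
        try:
            return float(np.max(np.abs(self.residuals(params))))
        except SimulationError:
            return np.inf

    def passes(self, params: ParameterSet | np.ndarray) -> bool:
        """All targets within their stated tolerance."""
        return self.max_residual(params) <= 1.0

    def report(self, params: ParameterSet | np.ndarray) -> list[dict]:
        trajs = self.simulate_contexts(params, method="strict")
        rows = []
        for t in self.targets:
            x = t.observed(trajs)
            rows.append({
                "species": t.species, "context": t.context, "time_h": t.time_h,
                "kind": t.kind, "target": t.value, "observed": round(x, 6),
                "residual": round(t.residual(x), 4), "note": t.note,
            })
        return rows
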