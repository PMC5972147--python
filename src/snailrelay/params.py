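"""Named, bounded rate parameters for the signaling network models.

All rates are per hour; concentrations are in arbitrary units and are
reported as fold changes relative to the basal fixed point.  Every
parameter is strictly positive and carries a log-uniform prior range
``[lo, hi]`` used by the Monte Carlo search.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SCHEMA_VERSION = 1

#: Canonical parameter order of the full model.  The ODE kernels unpack a
#: vector in exactly this order, so it must never be re-ordered silently.
PARAM_NAMES: tuple[str, ...] = (
    # SMAD module
    "b_R",     # basal pSMAD2/3-SMAD4 nuclear complex formation
    "k_R",     # TGF-beta driven SMAD phosphorylation flux (the LY2109761 target)
    "K_IR",    # I-SMAD repression constant on pSMAD formation
    "d_R",     # pSMAD complex turnover
    "b_I",     # basal I-SMAD synthesis
    "k_I",     # pSMAD-induced I-SMAD synthesis (negative feedback)
    "K_RI",    # Hill constant, pSMAD -> I-SMAD
    "d_I",     # I-SMAD turnover
    # SNAIL1 module
    "b_S",     # basal SNAIL1 transcription (the "others" node)
    "a_SR",    # pSMAD -> SNAIL1 mRNA activation amplitude
    "K_SR",    # Hill constant, pSMAD -> SNAIL1 mRNA
    "a_SG",    # nuclear GLI1 -> SNAIL1 mRNA activation amplitude
    "K_SG",    # Hill constant, GLI1_nuc -> SNAIL1 mRNA
    "d_Sm",    # SNAIL1 mRNA turnover
    "k_tp",    # SNAIL1 translation
    "d_Sp",    # SNAIL1 protein degradation scale
    "eps_Sp",  # GSK3-independent share of SNAIL1 protein degradation
    # GLI1 module
    "b_G",     # basal GLI1 transcription
    "a_GR",    # pSMAD -> GLI1 mRNA activation amplitude
    "K_GR",    # Hill constant, pSMAD -> GLI1 mRNA
    "a_GG",    # GLI1_nuc -> GLI1 mRNA positive feedback amplitude
    "K_GG",    # Hill constant of the GLI1 positive feedback
    "n_GG",    # Hill coefficient of the GLI1 positive feedback
    "d_Gm",    # GLI1 mRNA turnover
    "k_tg",    # GLI1 translation (to the SUFU-bound cytosolic pool)
    "rho0",    # GSK3-independent SUFU-complex release rate
    "rho1",    # GSK3^AA-driven release rate (per unit ER-local AA activity)
    "lam_loc", # ER/Golgi localization gain of the GSK3^AA transient
    "k_in",    # free cytosolic GLI1 nuclear import
    "d_Gc",    # cytosolic GLI1 degradation scale (bound and free pools)
    "eps_G",   # GSK3-independent share of cytosolic GLI1 degradation
    "d_Gn",    # nuclear GLI1 degradation scale
    "eps_Gn",  # GSK3-independent share of nuclear GLI1 degradation
    # GSK3 module (total normalized to 1; A = 1 - AA - D)
    "f_aa_b",  # basal GSK3^AA fraction
    "f_d_b",   # basal GSK3^D fraction
    "r_aa",    # GSK3^AA -> GSK3^A relaxation
    "k_aa",    # TGF-beta driven A -> AA conversion gain
    "tau_b",   # time constant of the fast (band-pass) stimulus filter, h
    "r_d",     # GSK3^D -> GSK3^A relaxation
    "k_d",     # TGF-beta driven A -> D conversion gain
    "tau_d",   # time constant of the slow stimulus filter, h
    # compartmental activity multipliers (threshold-modulation handles)
    "m_nuc",   # nuclear GSK3 enzymatic-activity multiplier
    "m_cyt",   # cytosolic/ER GSK3 enzymatic-activity multiplier
    # persistent-signaling pool: slowly decaying internalized/autocrine
    # signaling capacity charged by ligand exposure, which keeps SMAD
    # phosphorylation mildly active after ligand washout (but is silenced,
    # like the exogenous ligand, by a receptor-kinase inhibitor)
    "k_per",   # charging rate of the persistent pool (per unit stimulus)
    "K_per",   # soft saturation scale of the pool
    "r_per",   # persistent-pool decay
    "n_SG",    # Hill coefficient, GLI1_nuc -> SNAIL1 mRNA (cooperative)
)

_INDEX = {n: i for i, n in enumerate(PARAM_NAMES)}


class ParameterError(ValueError):
    """Raised for out-of-bounds, non-positive or unknown parameters."""


@dataclass
class ParameterSet:
    """Named positive parameters with log-uniform prior bounds."""

    values: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    name: str = "unnamed"

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(PARAM_NAMES)
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(self.values)
        if missing:
            raise ParameterError(f"missing parameter(s): {sorted(missing)}")
        for k, v in self.values.items():
            if not (v > 0) or not math.isfinite(v):
                raise ParameterError(f"parameter {k!r} must be strictly positive, got {v}")
        for k, (lo, hi) in self.bounds.items():
            if k not in _INDEX:
                raise ParameterError(f"bounds given for unknown parameter {k!r}")
            if not (0 < lo <= hi):
                raise ParameterError(f"bad bounds for {k!r}: ({lo}, {hi})")
            v = self.values[k]
            # small relative slack absorbs log10/exp round trips at the box edge
            if not (lo * (1 - 1e-9) <= v <= hi * (1 + 1e-9)):
                raise ParameterError(f"parameter {k!r}={v} outside bounds ({lo}, {hi})")
        fa, fd = self.values["f_aa_b"], self.values["f_d_b"]
        if fa + fd >= 1.0:
            raise ParameterError("basal GSK3 fractions f_aa_b + f_d_b must be < 1")

    # -- vector interface used by the ODE kernels and the search ---------
    def to_vector(self) -> np.ndarray:
        return np.array([self.values[n] for n in PARAM_NAMES], dtype=np.float64)

    @classmethod
    def from_vector(cls, vec: np.ndarray, bounds: dict | None = None,
                    name: str = "from_vector") -> "ParameterSet":
        if len(vec) != len(PARAM_NAMES):
            raise ParameterError(f"expected {len(PARAM_NAMES)} values, got {len(vec)}")
        return cls(dict(zip(PARAM_NAMES, map(float, vec))), bounds or {}, name)

    def replace(self, name: str | None = None, **updates: float) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(updates)
        return ParameterSet(vals, dict(self.bounds), name or self.name)

    def scaled(self, factors: dict[str, float], name: str | None = None) -> "ParameterSet":
        """Return a copy with each named parameter multiplied by its factor."""
        vals = dict(self.values)
        for k, f in factors.items():
            if k not in vals:
                raise ParameterError(f"unknown parameter {k!r}")
            vals[k] = vals[k] * f
        # scaled values may leave the prior box on purpose (perturbation studies)
        return ParameterSet(vals, {}, name or f"{self.name}:scaled")

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    # -- JSON round trip --------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "kind": "parameter_set",
            "name": self.name,
            "values": {n: self.values[n] for n in PARAM_NAMES},
            "bounds": {k: list(v) for k, v in self.bounds.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        from .io import load_validated_json  # local import to avoid a cycle

        doc = load_validated_json(path, kind="parameter_set")
        bounds = {k: (float(lo), float(hi)) for k, (lo, hi) in doc.get("bounds", {}).items()}
        return cls({k: float(v) for k, v in doc["values"].items()},
                   bounds, doc.get("name", Path(path).stem))


def default_bounds(values: dict[str, float], width: float = 0.5) -> dict[str, tuple[float, float]]:
    """Symmetric log10 prior box of half-width ``width`` decades around ``values``.

    Hill coefficients and basal GSK3 fractions get fixed physiological
    ranges instead (coefficients 1-4; fractions are silver-staining
    measurements, pinned to a narrow band).
    """
    out: dict[str, tuple[float, float]] = {}
    for k, v in values.items():
        if k in ("n_GG", "n_SG"):
            out[k] = (1.0, 4.0)
        elif k in ("f_aa_b", "f_d_b"):
            out[k] = (0.8 * v, 1.2 * v)
        elif k.startswith("eps_"):
            # activity shares live in (0, 1)
            out[k] = (v * 10.0 ** (-width), min(0.97, v * 10.0 ** width))
        else:
            out[k] = (v * 10.0 ** (-width), v * 10.0 ** (width))
    return out
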