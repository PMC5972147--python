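"""TGF-beta stimulus profiles and inhibitor interventions.

Amplitude 1.0 corresponds to the 4 ng/ml TGF-beta1 dose used throughout;
times are in hours.  Both stimulus and inhibitors are piecewise constant,
so a simulation over ``[t0, t1]`` decomposes into segments with constant
(S, gate) values — the integrators exploit this to avoid discontinuities
inside a solver call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Inhibitor targets and their default fractional efficacies.
#: SMAD_PHOS – LY2109761-like block of the TGF-beta receptor kinase flux;
#: GLI1_ACT – GANT61-like block of GLI1 transcriptional-activation output;
#: GSK3_ACT – SB216763-like block of GSK3 (A and AA) catalytic activity.
DEFAULT_EFFICACY = {"SMAD_PHOS": 0.95, "GLI1_ACT": 0.95, "GSK3_ACT": 0.90}
INHIBITOR_TARGETS = tuple(DEFAULT_EFFICACY)


@dataclass(frozen=True)
class StimulusProfile:
    """TGF-beta input: ``zero``, ``constant`` or a single ``pulse``."""

    kind: str = "constant"
    amplitude: float = 1.0
    duration: float | None = None  # hours, pulse only
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("zero", "constant", "pulse"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be >= 0")
        if self.kind == "pulse":
            if self.duration is None or self.duration <= 0:
                raise ValueError("pulse stimulus requires duration > 0")

    def value(self, t: float) -> float:
        if self.kind == "zero":
            return 0.0
        if self.kind == "constant":
            return self.amplitude if t >= self.onset else 0.0
        assert self.duration is not None
        return self.amplitude if self.onset <= t < self.onset + self.duration else 0.0

    def breakpoints(self) -> list[float]:
        if self.kind == "zero":
            return []
        if self.kind == "constant":
            return [self.onset]
        assert self.duration is not None
        return [self.onset, self.onset + self.duration]

    @classmethod
    def zero(cls) -> "StimulusProfile":
        return cls(kind="zero", amplitude=0.0)

    @classmethod
    def pulse(cls, duration: float, amplitude: float = 1.0, onset: float = 0.0) -> "StimulusProfile":
        return cls(kind="pulse", amplitude=amplitude, duration=duration, onset=onset)


@dataclass(frozen=True)
class InhibitorSpec:
    """Multiply a targeted rate by ``1 - efficacy`` inside ``[start, end)``."""

    target: str
    start: float = 0.0
    end: float = np.inf
    efficacy: float | None = None  # None -> target-specific default

    def __post_init__(self) -> None:
        if self.target not in INHIBITOR_TARGETS:
            raise ValueError(
                f"unknown inhibitor target {self.target!r}; expected one of {INHIBITOR_TARGETS}")
        eff = self.efficacy if self.efficacy is not None else DEFAULT_EFFICACY[self.target]
        if not (0.0 <= eff <= 1.0):
            raise ValueError(f"efficacy must be in [0, 1], got {eff}")
        if not self.start < self.end:
            raise ValueError(f"inhibitor window requires start < end, got [{self.start}, {self.end})")

    @property
    def eps(self) -> float:
        return self.efficacy if self.efficacy is not None else DEFAULT_EFFICACY[self.target]

    def gate(self, t: float) -> float:
        return 1.0 - self.eps if self.start <= t < self.end else 1.0


def segment_table(stimulus: StimulusProfile,
                  inhibitors: tuple[InhibitorSpec, ...] | list[InhibitorSpec],
                  t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
    """Decompose ``[t0, t1]`` into segments of constant (S, g_smad, g_gli, g_gsk).

    Returns ``(edges, vals)`` where ``edges`` has length ``n_seg + 1`` and
    ``vals`` is ``(n_seg, 4)``; segment ``i`` spans ``[edges[i], edges[i+1])``.
    """
    if t1 <= t0:
        raise ValueError("segment_table requires t1 > t0")
    pts = {float(t0), float(t1)}
    for b in stimulus.breakpoints():
        if t0 < b < t1:
            pts.add(float(b))
    for inh in inhibitors:
        for b in (inh.start, inh.end):
            if np.isfinite(b) and t0 < b < t1:
                pts.add(float(b))
    edges = np.array(sorted(pts))
    mids = 0.5 * (edges[:-1] + edges[1:])
    vals = np.empty((len(mids), 4))
    for i, tm in enumerate(mids):
        g = {k: 1.0 for k in INHIBITOR_TARGETS}
        for inh in inhibitors:
            g[inh.target] *= inh.gate(tm)
        vals[i] = (stimulus.value(tm), g["SMAD_PHOS"], g["GLI1_ACT"], g["GSK3_ACT"])
    return edges, vals
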