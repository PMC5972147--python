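"""Pulse-duration decoding: wave classification, duration threshold,
coarse-grained state encoding (TOSS) and parameter-modulation predictions.

A short TGF-beta pulse triggers only the pSMAD-driven first SNAIL1 wave;
a pulse longer than a threshold duration additionally ignites the GLI1
positive feedback and produces a sustained second wave.  Coarse-graining
pSMAD (H/M/L) and GLI1, SNAIL1 (H/L) at 12 h and 48 h yields a temporally
ordered state space (TOSS) that jointly encodes stimulus duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .models import NetworkModel
from .params import ParameterSet
from .simulate import SpeciesState, Trajectory, basal_state, simulate
from .stimulus import StimulusProfile

#: wave-detection constants: a wave is a local maximum of the SNAIL1
#: protein fold change of at least WAVE_MIN_FOLD with relative prominence
#: PROMINENCE_FRAC of its height; a two-wave trajectory must also stay
#: elevated (>= WAVE_MIN_FOLD) at 72 h.
WAVE_MIN_FOLD = 1.5
PROMINENCE_FRAC = 0.25

#: default TOSS discretization thresholds (fold-change units, relative to
#: basal): pSMAD has three bins (L < 1.5 <= M < 3.0 <= H), GLI1 and SNAIL1
#: two (L < 1.5 <= H).
TOSS_THRESHOLDS = {"psmad": (1.5, 3.0), "gli1": 1.5, "snail1": 1.5}


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class WaveClassification:
    label: str                       # none | one_wave | two_wave
    peak_times: tuple[float, ...]
    peak_heights: tuple[float, ...]
    level_72h: float


def classify_waves(traj: Trajectory, species: str = "SNAIL1_prot") -> WaveClassification:
    """Label a trajectory as none / one_wave / two_wave.

    A sustained second wave need not present an interior local maximum
    (it may still be rising at the end of the horizon), so the rule is:
    a first wave by peak detection, then a post-dip recovery of at least
    the prominence fraction together with an elevated 72-h level.
    """
    if traj.t_end < 72.0 - 1e-9:
        raise ClassificationError(
            f"wave classification requires a trajectory covering >= 72 h, got {traj.t_end}")
    t = traj.times
    x = traj.series(species)
    lvl72 = float(np.interp(72.0, t, x))

    peaks, props = find_peaks(x, height=WAVE_MIN_FOLD)
    sig = [i for i in peaks
           if _prominence(x, i) >= PROMINENCE_FRAC * x[i]]
    # trailing rise ("edge peak"): treat an elevated, non-declining end as a wave
    end_wave = lvl72 >= WAVE_MIN_FOLD and (not sig or t[sig[-1]] < 60.0)

    if not sig and not end_wave:
        return WaveClassification("none", (), (), lvl72)

    if sig and (end_wave or len(sig) >= 2):
        # two distinct waves: need a real dip between the first wave and the
        # later elevation, and a sustained 72-h level
        i1 = sig[0]
        tail_start = sig[1] if len(sig) >= 2 else None
        seg = x[i1:]
        imin = i1 + int(np.argmin(seg))
        dip = x[imin]
        later_max = float(np.max(x[imin:])) if imin < len(x) - 1 else x[-1]
        if (lvl72 >= WAVE_MIN_FOLD and later_max >= WAVE_MIN_FOLD
                and later_max - dip >= PROMINENCE_FRAC * later_max
                and dip < x[i1]):
            pk_t = [float(t[i1])]
            pk_h = [float(x[i1])]
            j = imin + int(np.argmax(x[imin:]))
            pk_t.append(float(t[j]))
            pk_h.append(float(x[j]))
            return WaveClassification("two_wave", tuple(pk_t), tuple(pk_h), lvl72)

    if sig:
        i1 = sig[0]
        return WaveClassification("one_wave", (float(t[i1]),), (float(x[i1]),), lvl72)
    # rising-only trajectory with no first transient: single (late) wave
    return WaveClassification("one_wave", (float(t[-1]),), (float(x[-1]),), lvl72)


def _prominence(x: np.ndarray, i: int) -> float:
    """Peak prominence over the simple base: the higher of the two minima
    flanking the peak (adequate for these low-peak-count trajectories)."""
    base = max(np.min(x[:i + 1]), np.min(x[i:]))
    return float(x[i] - base)


@dataclass(frozen=True)
class DurationScan:
    durations: np.ndarray
    labels: tuple[str, ...]
    snail1: np.ndarray           # (n_durations, n_times) fold-change matrix
    times: np.ndarray


def duration_scan(model: NetworkModel, params: ParameterSet,
                  durations, t_max: float = 72.0,
                  amplitude: float = 1.0,
                  basal: SpeciesState | None = None,
                  method: str = "strict") -> DurationScan:
    """Simulate one pulse per duration and classify the SNAIL1 response.

    For a calibrated model the labels should be monotone in duration
    (none/one_wave below the threshold, two_wave above); a non-monotone
    sequence triggers a warning naming the offending durations.
    """
    durations = np.asarray(sorted(durations), dtype=float)
    if basal is None:
        basal = basal_state(model, params)
    labels, rows, times = [], [], None
    for dur in durations:
        stim = StimulusProfile.zero() if dur == 0 else \
            StimulusProfile.pulse(float(dur), amplitude=amplitude)
        traj = simulate(model, params, stim, t_max=t_max, basal=basal, method=method)
        labels.append(classify_waves(traj).label)
        rows.append(traj.series("SNAIL1_prot"))
        times = traj.times
    order = {"none": 0, "one_wave": 1, "two_wave": 2}
    ranks = [order[l] for l in labels]
    if any(b < a for a, b in zip(ranks, ranks[1:])):
        bad = [float(durations[i + 1]) for i, (a, b) in
               enumerate(zip(ranks, ranks[1:])) if b < a]
        warnings.warn(f"wave labels not monotone in duration at {bad} h "
                      "(possible mis-calibration)", stacklevel=2)
    return DurationScan(durations, tuple(labels), np.array(rows), times)


def committed(traj: Trajectory, ref_level: float | None = None) -> bool:
    """Has the pulse triggered the sustained (second-wave) SNAIL1 response?

    True for a classified two-wave trajectory, and also when the two waves
    merge into a single sustained elevation (strong-relay perturbations do
    this): the criterion is an elevated (>= 1.5-fold) SNAIL1 protein level
    at 72 h.  Unlike the dip-prominence label this is monotone in pulse
    duration, which makes it the right bisection predicate.

    ``ref_level`` (raw concentration units) replaces the cell's own
    1.5-fold bar; perturbation studies pass the unperturbed cell's level
    so that, e.g., a GLI1-overexpressing cell with an elevated basal is
    still measured against the same absolute output.
    """
    c = classify_waves(traj)
    if ref_level is not None:
        return c.label == "two_wave" or traj.raw("SNAIL1_prot", 72.0) >= ref_level
    return c.label == "two_wave" or c.level_72h >= WAVE_MIN_FOLD


def duration_threshold(model: NetworkModel, params: ParameterSet,
                       lo: float, hi: float, resolution: float = 0.1,
                       amplitude: float = 1.0,
                       basal: SpeciesState | None = None,
                       method: str = "strict",
                       ref_level: float | None = None) -> float:
    """Bisect the sustained-response boundary duration to ``resolution`` h."""
    if not lo < hi:
        raise ValueError(f"invalid bracket [{lo}, {hi}]: requires lo < hi")
    if basal is None:
        basal = basal_state(model, params)

    def is_two(dur: float) -> bool:
        stim = StimulusProfile.zero() if dur == 0 else \
            StimulusProfile.pulse(dur, amplitude=amplitude)
        traj = simulate(model, params, stim, t_max=72.0, basal=basal, method=method)
        return committed(traj, ref_level)

    if is_two(lo):
        raise ValueError(f"bracket invalid: duration {lo} h already triggers "
                         "the sustained response")
    if not is_two(hi):
        raise ValueError(f"bracket invalid: duration {hi} h does not trigger "
                         "the sustained response")
    a, b = lo, hi
    while b - a > resolution:
        m = 0.5 * (a + b)
        if is_two(m):
            b = m
        else:
            a = m
    return 0.5 * (a + b)


#: perturbations probed by the modulation report and the predicted
#: direction of the duration-threshold shift
MODULATIONS = {
    "nuclear_gsk3_x1.5": ({"m_nuc": 1.5}, "+"),
    "cytosolic_gsk3_x1.5": ({"m_cyt": 1.5}, "-"),
    "gli1_synthesis_x2": ({"k_tg": 2.0}, "-"),
    "ismad_synthesis_x0.5": ({"k_I": 0.5, "b_I": 0.5}, "-"),
}


def modulation_report(model: NetworkModel, params: ParameterSet,
                      lo: float = 0.25, hi: float = 12.0,
                      resolution: float = 0.1, method: str = "fast") -> dict:
    """Duration-threshold shifts under the four standard perturbations.

    Raising nuclear GSK3 activity raises the threshold; raising cytosolic
    GSK3 activity, doubling GLI1 synthesis or halving I-SMAD synthesis
    lower it.  Commitment is judged against the unperturbed cell's
    absolute sustained SNAIL1 level, so perturbations that raise the
    basal state (e.g. GLI1 overexpression) are compared fairly; a
    perturbed cell committed even by the shortest tested pulse reports
    the bracket floor as its threshold.
    """
    base_bas = basal_state(model, params)
    ref = WAVE_MIN_FOLD * float(
        base_bas.values[list(model.species).index("SNAIL1_prot")])
    base_thr = duration_threshold(model, params, lo, hi, resolution,
                                  method=method, ref_level=ref)
    rows = {}
    for name, (factors, expected) in MODULATIONS.items():
        mod = params.scaled(factors, name=f"{params.name}:{name}")
        try:
            thr = duration_threshold(model, mod, lo, hi, resolution,
                                     method=method, ref_level=ref)
        except ValueError:
            stim = StimulusProfile.pulse(lo)
            traj = simulate(model, mod, stim, t_max=72.0, method=method)
            if committed(traj, ref):
                thr = lo          # committed even at the bracket floor
            else:
                raise
        shift = thr - base_thr
        rows[name] = {
            "threshold_h": round(thr, 3),
            "shift_h": round(shift, 3),
            "direction": "+" if shift > 0 else ("-" if shift < 0 else "0"),
            "expected_direction": expected,
            "matches": (shift > 0) == (expected == "+") and shift != 0,
        }
    return {"baseline_threshold_h": round(base_thr, 3), "modulations": rows}


@dataclass(frozen=True)
class TossState:
    """Coarse-grained duration code: (pSMAD@12, pSMAD@48; GLI1@12, GLI1@48)
    plus the SNAIL1 pair (@12, @48)."""

    psmad: tuple[str, str]
    gli1: tuple[str, str]
    snail1: tuple[str, str]

    def __str__(self) -> str:
        return (f"({self.psmad[0]}, {self.psmad[1]}; "
                f"{self.gli1[0]}, {self.gli1[1]}) / SNAIL1 ({self.snail1[0]}, {self.snail1[1]})")


def encode_toss(traj: Trajectory, thresholds: dict | None = None) -> TossState:
    """Discretize pSMAD (H/M/L) and GLI1, SNAIL1 (H/L) at 12 h and 48 h."""
    th = dict(TOSS_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    if traj.t_end < 48.0 - 1e-9:
        raise ClassificationError(
            f"TOSS encoding requires a trajectory covering >= 48 h, got {traj.t_end}")

    def tri(x: float) -> str:
        lo, hi = th["psmad"]
        return "L" if x < lo else ("M" if x < hi else "H")

    def bi(x: float, key: str) -> str:
        return "H" if x >= th[key] else "L"

    ps = tuple(tri(traj.value("pSMAD_nuc", t)) for t in (12.0, 48.0))
    gl = tuple(bi(traj.value("GLI1_nuc", t), "gli1") for t in (12.0, 48.0))
    sn = tuple(bi(traj.value("SNAIL1_prot", t), "snail1") for t in (12.0, 48.0))
    return TossState(ps, gl, sn)
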